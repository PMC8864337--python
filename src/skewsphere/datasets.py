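"""Self-contained synthetic fixtures for tests and worked examples.

The generator writes the datasets the synthetic study is built on: circle
samples from the skew-von Mises truths (mu, tau, gamma) = (2, 1, -1) and
(3, 0.6, 1) at n in {20, 50, 100, 500}, a sphere sample at
(mu = (1, 2), tau = 2, gamma = (1, -1)), and a symmetric control (gamma = 0).
Everything is produced at run time from a seed; regeneration with the same
seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .densities import SFvMLParams
from .geometry import to_cartesian
from .io import write_directions
from .samplers import RandomStream, sample_sfvml

__all__ = ["FIXTURE_TRUTHS", "generate_fixtures"]

FIXTURE_TRUTHS = {
    "svm_mu2": dict(p=2, mu=[2.0], tau=1.0, gamma=[-1.0]),
    "svm_mu3": dict(p=2, mu=[3.0], tau=0.6, gamma=[1.0]),
    "sfvml_p3": dict(p=3, mu=[1.0, 2.0], tau=2.0, gamma=[1.0, -1.0]),
    "vm_symmetric": dict(p=2, mu=[2.0], tau=1.0, gamma=[0.0]),
}

_SIZES = {"svm_mu2": (20, 50, 100, 500), "svm_mu3": (20, 50, 100, 500),
          "sfvml_p3": (500,), "vm_symmetric": (500,)}


def generate_fixtures(out_dir, seed: int = 0) -> list:
    """Write all fixture CSVs plus a manifest.json; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stream = RandomStream(seed)
    manifest = []
    for name, truth in FIXTURE_TRUTHS.items():
        params = SFvMLParams(mu=to_cartesian(truth["mu"]), tau=truth["tau"],
                             gamma=truth["gamma"])
        for n in _SIZES[name]:
            data = sample_sfvml(n, params, stream.child(f"{name}-{n}"))
            fname = f"{name}_n{n}.csv"
            write_directions(out_dir / fname, data, seed=seed,
                             config={"truth": truth, "n": n})
            manifest.append(dict(file=fname, truth=truth, n=n, seed=seed))
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
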