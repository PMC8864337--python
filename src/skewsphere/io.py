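"""CSV and YAML I/O: angular data files, scenario configs, chain tables.

CSV dialect: comma-separated, header row mandatory, UTF-8.  Every file the
package writes starts with a provenance comment line
``# skewsphere=<version> seed=<seed> config=<sha1>`` which pandas readers
skip.  Angles are radians internally; degree input is converted on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .priors import ScenarioSpec
from .samplers import DirectionSample

__all__ = [
    "read_directions",
    "write_directions",
    "write_table",
    "read_table",
    "load_scenario_config",
]

_ANGLE_COLS = (("angle",), ("theta1", "theta2"), ("x", "y", "z"))


def _provenance(seed, config) -> str:
    h = hashlib.sha1(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
    return f"# skewsphere={__version__} seed={seed} config={h}"


def read_directions(path, unit: str = "rad") -> DirectionSample:
    """Read angular data from CSV.

    Accepted column sets: ``angle`` (circle), ``theta1,theta2`` (sphere,
    spherical coordinates) or ``x,y,z`` (sphere, Cartesian).  ``unit`` is
    ``rad`` or ``deg`` and applies to angle columns only.
    """
    if unit not in ("rad", "deg"):
        raise ValueError("unit must be 'rad' or 'deg'")
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    scale = np.pi / 180.0 if unit == "deg" else 1.0
    if {"angle"} <= cols:
        return DirectionSample(angles=df["angle"].to_numpy() * scale)
    if {"theta1", "theta2"} <= cols:
        return DirectionSample(angles=df[["theta1", "theta2"]].to_numpy() * scale)
    if {"x", "y", "z"} <= cols:
        xyz = df[["x", "y", "z"]].to_numpy()
        nrm = np.linalg.norm(xyz, axis=1, keepdims=True)
        if np.any(np.abs(nrm - 1) > 1e-6):
            raise ValueError("x,y,z rows must be unit vectors")
        return DirectionSample.from_cartesian(xyz / nrm)
    raise ValueError(
        f"{path}: expected columns 'angle', 'theta1,theta2' or 'x,y,z'; got {sorted(cols)}"
    )


def write_directions(path, data: DirectionSample, seed=None, config=None) -> None:
    cols = ["angle"] if data.p == 2 else ["theta1", "theta2"]
    df = pd.DataFrame(data.angles, columns=cols)
    _write_with_header(path, df, seed, config or {})


def write_table(path, df: pd.DataFrame, seed=None, config=None, index=False) -> None:
    _write_with_header(path, df, seed, config or {}, index=index)


def _write_with_header(path, df, seed, config, index=False) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(seed, config) + "\n")
        df.to_csv(fh, index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_scenario_config(path):
    """Load a YAML scenario config.

    Flat keys: ``scenario`` (1-4, or 0 for the flat baseline), the scenario's
    hyperparameters (``mu0, zeta, eta`` or ``mu0, tau0, alpha, beta``;
    ``xi, sigma`` and optional ``lambda``), optional ``p`` (default 2), and
    the chain sizes ``burnin``, ``N``, ``k`` plus ``seed``.

    Returns ``(ScenarioSpec, run_options_dict)``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "scenario" not in cfg:
        raise ValueError(f"{path}: config must be a mapping with a 'scenario' key")
    p = int(cfg.get("p", 2))
    hyper_keys = {"mu0", "zeta", "eta", "tau0", "alpha", "beta", "xi", "sigma", "tau_max"}
    hyper = {k: cfg[k] for k in hyper_keys if k in cfg}
    if "lambda" in cfg:
        hyper["lam"] = cfg["lambda"]
    try:
        spec = ScenarioSpec.from_scenario(int(cfg["scenario"]), p=p, **hyper)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: invalid scenario config: {err}") from err
    run = {
        "B": int(cfg.get("burnin", 5000)),
        "N": int(cfg.get("N", 500)),
        "k": int(cfg.get("k", 500)),
        "seed": int(cfg.get("seed", 0)),
    }
    return spec, run
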