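"""Configuration loading, serialization helpers and fixture generation.

The CLI in :mod:`memphase.cli` is a thin shell over these helpers and the
library modules; everything it can do is callable directly.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import adhesion_geometry, lattice_mc
from .meanfield import get_eos
from .phase_diagram import build_diagram

__all__ = ["load_config", "segment_state_record", "generate_fixtures", "FLOAT_FMT"]

#: Repr-faithful float formatting for CSV exports.
FLOAT_FMT = "%.17g"

# Reduced-variable keys and raw-energy keys are mutually exclusive ways of
# specifying the thermodynamic state.
_REDUCED_KEYS = {"T_bar", "T_over_Tc", "q1", "dU21_over_kBTc", "Xa", "backend", "regime", "seed"}
_RAW_KEYS = {"Uaa", "Uab", "Ubb", "kBT"}
_ALLOWED_KEYS = _REDUCED_KEYS | _RAW_KEYS


def load_config(path: str) -> dict[str, Any]:
    """Read a JSON or YAML key-value config and validate its schema.

    Unknown keys are rejected; the raw interaction energies (Uaa, Uab, Ubb,
    kBT) may not be mixed with a directly specified reduced temperature.
    """
    with open(path) as fh:
        text = fh.read()
    cfg = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(cfg, dict):
        raise ValueError(f"config must be a mapping, got {type(cfg).__name__}")
    unknown = set(cfg) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    has_raw = bool(set(cfg) & _RAW_KEYS)
    has_tbar = "T_bar" in cfg or "T_over_Tc" in cfg
    if has_raw and has_tbar:
        raise ValueError(
            "give either raw energies (Uaa, Uab, Ubb, kBT) or a reduced "
            "temperature (T_bar / T_over_Tc), not both"
        )
    if "T_bar" in cfg and "T_over_Tc" in cfg:
        raise ValueError("T_bar and T_over_Tc are mutually exclusive")
    return cfg


def segment_state_record(state) -> dict[str, Any]:
    """JSON-safe dict of a SegmentState."""
    rec = dataclasses.asdict(state)
    for k, v in rec.items():
        if isinstance(v, float) and math.isnan(v):
            rec[k] = None
    return rec


def mc_result_record(result: lattice_mc.MCResult) -> dict[str, Any]:
    """JSON-safe dict of an MCResult."""
    rec = dataclasses.asdict(result)

    def clean(v):
        if isinstance(v, float) and math.isnan(v):
            return None
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        return v

    return {k: clean(v) for k, v in rec.items()}


def generate_fixtures(outdir: str, seed: int = 12345) -> list[str]:
    """Write the small deterministic fixture set used by tests and demos.

    Emits a geometry round-trip table, exact-enumeration reference cases for
    tiny lattices, and a mean-field diagram grid.  All outputs are plain
    text (CSV/JSON) and reproducible from the given seed.
    """
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    # Geometry round-trip table over contact angles.
    thetas = np.linspace(0.1, math.pi, 25)
    rows = []
    for th in thetas:
        g = adhesion_geometry.cap_geometry(th)
        rows.append({"theta_eff": th, "q1": g.q1, "v": g.v,
                     "A1_over_A": g.A1 / g.A, "A2_over_A": g.A2 / g.A})
    path = os.path.join(outdir, "geometry_roundtrip.csv")
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)
    written.append(path)

    # Exact enumeration reference cases on tiny lattices.
    cases = []
    for L, c, t_bar, dmu, du2 in [
        (2, 1, 100.0, 0.0, 0.0),
        (2, 1, 2.0, 0.5, -1.0),
        (3, 1, 2.0, 0.0, -2.0),
        (3, 2, 1.5, -0.5, 1.0),
    ]:
        spec = lattice_mc.LatticeSpec(L=L, c=c)
        params = lattice_mc.MCParams(t_bar=t_bar, dmu=dmu, du2=du2,
                                     sweeps=2, burnin=0, seed=seed)
        exact = lattice_mc.enumerate_exact(spec, params)
        cases.append({
            "L": L, "c": c, "t_bar": t_bar, "dmu": dmu, "du1": 0.0, "du2": du2,
            "mean_n_seg": list(exact["mean_n_seg"]),
            "mean_n": exact["mean_n"],
            "mean_energy_per_site": exact["mean_energy_per_site"],
        })
    path = os.path.join(outdir, "enumeration_cases.json")
    with open(path, "w") as fh:
        json.dump({"seed": seed, "cases": cases}, fh, indent=1)
    written.append(path)

    # Mean-field diagram grid (Fig-style slice).
    diagram = build_diagram(q1=0.25, du21_over_kBTc=-0.5, eos=get_eos("meanfield"),
                            t_over_tc=np.linspace(0.05, 1.05, 200))
    path = os.path.join(outdir, "diagram_meanfield_q025.csv")
    diagram.to_csv(path)
    written.append(path)
    return written
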