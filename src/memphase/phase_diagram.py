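"""Phase-diagram assembly in the (Xa, T/Tc) plane for adhering membranes.

For each reduced temperature the two segment coexistence regions are
obtained by lever-projecting the backend binodal interval through the
partitioning relation, with the spectator composition of the other segment
filling the remaining area fraction:

    window1 = [q1*x_beta + (1-q1)*Xs2,  q1*x_alpha + (1-q1)*Xs2]
    window2 = [q1*Xs1 + (1-q1)*x_beta,  q1*Xs1 + (1-q1)*x_alpha]

Temperatures are specified as ``T/Tc`` using each backend's own critical
temperature, so exact-limit and mean-field diagrams share axes.  The uniform
environment (uni-env) binodal interval is carried alongside as the reference
that the two windows merge into at zero affinity contrast or at
``q1 in {0, 1}``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .meanfield import EquationOfState
from .core_model import contrast_per_kBT
from .segment_equilibrium import spectator_fraction

__all__ = ["Window", "PhaseDiagram", "segment_windows", "build_diagram", "uniform_reference"]

#: Number formatting used for all CSV exports (repr-faithful).
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class Window:
    """A closed composition interval; NaN endpoints encode an empty window."""

    lo: float = math.nan
    hi: float = math.nan

    @property
    def is_empty(self) -> bool:
        return math.isnan(self.lo) or math.isnan(self.hi)

    @property
    def width(self) -> float:
        return 0.0 if self.is_empty else self.hi - self.lo

    def contains(self, x: float) -> bool:
        return (not self.is_empty) and self.lo <= x <= self.hi


EMPTY_WINDOW = Window()


def segment_windows(
    t_bar: float,
    q1: float,
    du21: float,
    eos: EquationOfState,
    regime: Optional[str] = None,
) -> tuple[Window, Window]:
    """Coexistence windows of the two segments in overall composition.

    ``du21`` is the affinity contrast per ``kBT``.  Above the backend's
    critical temperature both windows are empty.  At ``q1 = 0`` (``1``) only
    segment 2 (1) exists and its window is the plain binodal interval; at
    zero contrast the two windows coincide with the uni-env interval (the
    merged single region).
    """
    if not (0.0 <= q1 <= 1.0):
        raise ValueError(f"q1 must lie in [0, 1], got {q1}")
    if not (t_bar < eos.tc):
        return EMPTY_WINDOW, EMPTY_WINDOW
    pair = eos.binodals(t_bar)
    if q1 == 0.0:
        return EMPTY_WINDOW, Window(pair.x_beta, pair.x_alpha)
    if q1 == 1.0:
        return Window(pair.x_beta, pair.x_alpha), EMPTY_WINDOW
    if du21 == 0.0:
        uni = Window(pair.x_beta, pair.x_alpha)
        return uni, uni
    xs2 = spectator_fraction(1, t_bar, du21, eos, regime=regime)
    xs1 = spectator_fraction(2, t_bar, du21, eos, regime=regime)
    w1 = Window(q1 * pair.x_beta + (1.0 - q1) * xs2,
                q1 * pair.x_alpha + (1.0 - q1) * xs2)
    w2 = Window(q1 * xs1 + (1.0 - q1) * pair.x_beta,
                q1 * xs1 + (1.0 - q1) * pair.x_alpha)
    return w1, w2


def uniform_reference(t_bar_grid: Sequence[float], eos: EquationOfState) -> pd.DataFrame:
    """Binodal table of the uni-env membrane over a reduced-temperature grid."""
    rows = []
    for tb in t_bar_grid:
        pair = eos.binodals(tb)
        rows.append({"T_bar": tb, "T_over_Tc": tb / eos.tc,
                     "x_beta": pair.x_beta, "x_alpha": pair.x_alpha})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhaseDiagram:
    """Full two-segment phase diagram over a temperature grid.

    Windows are stored per temperature; empty windows keep NaN endpoints so
    the tabular export is schema-stable.
    """

    backend: str
    q1: float
    du21_over_kBTc: float
    regime: Optional[str]
    t_over_tc: np.ndarray
    windows1: tuple[Window, ...]
    windows2: tuple[Window, ...]
    uni: tuple[Window, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T_over_Tc": self.t_over_tc,
            "seg1_lo": [w.lo for w in self.windows1],
            "seg1_hi": [w.hi for w in self.windows1],
            "seg2_lo": [w.lo for w in self.windows2],
            "seg2_hi": [w.hi for w in self.windows2],
            "uni_lo": [w.lo for w in self.uni],
            "uni_hi": [w.hi for w in self.uni],
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)

    def to_json(self, path=None):
        payload = {
            "backend": self.backend,
            "q1": self.q1,
            "du21_over_kBTc": self.du21_over_kBTc,
            "regime": self.regime,
            "rows": json.loads(
                self.to_dataframe().to_json(orient="records", double_precision=15)
            ),
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload


def build_diagram(
    q1: float,
    du21_over_kBTc: float,
    eos: EquationOfState,
    t_over_tc: Optional[Sequence[float]] = None,
    regime: Optional[str] = None,
) -> PhaseDiagram:
    """Assemble a phase diagram on a ``T/Tc`` grid.

    The affinity contrast is given in the temperature-independent reduced
    units ``dU21/(kB*Tc)`` and converted to per-``kBT`` at each grid
    temperature.  The default grid is 200 points on [0.05, 1.05] of
    ``T/Tc``.
    """
    if t_over_tc is None:
        t_over_tc = np.linspace(0.05, 1.05, 200)
    t_over_tc = np.asarray(t_over_tc, dtype=float)
    if np.any(t_over_tc <= 0):
        raise ValueError("T/Tc grid must be positive")
    w1s, w2s, unis = [], [], []
    for frac in t_over_tc:
        tb = frac * eos.tc
        if frac < 1.0:
            pair = eos.binodals(tb)
            unis.append(Window(pair.x_beta, pair.x_alpha))
        else:
            unis.append(EMPTY_WINDOW)
        du21 = contrast_per_kBT(du21_over_kBTc, frac) if du21_over_kBTc != 0.0 else 0.0
        w1, w2 = segment_windows(tb, q1, du21, eos, regime=regime)
        w1s.append(w1)
        w2s.append(w2)
    return PhaseDiagram(
        backend=eos.backend, q1=q1, du21_over_kBTc=du21_over_kBTc, regime=regime,
        t_over_tc=t_over_tc, windows1=tuple(w1s), windows2=tuple(w2s), uni=tuple(unis),
    )
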