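"""Exact square-lattice Ising results: critical point, spontaneous order, binodals.

This is the "exact-limit" thermodynamic backend.  At zero ordering field the
square-lattice Ising model is exactly solvable: the critical temperature is
``T_bar_c = 2/ln(1 + sqrt(2))`` and the spontaneous order parameter below it
is Onsager--Yang's

    Upsilon(T_bar) = (1 - sinh(2/T_bar)**-4) ** (1/8),   T_bar < T_bar_c,

with ``Upsilon = 0`` at and above the critical temperature.  In mixture
language the order parameter sets the binodal compositions of the coexisting
a-rich (alpha) and b-rich (beta) phases,

    x_beta = 1/2 - Upsilon/2,    x_alpha = 1/2 + Upsilon/2,

which are mirror images about ``x = 1/2`` (particle-hole symmetry).  No exact
closed form exists off coexistence (finite field), which is why the
mean-field backend exists alongside this one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["BinodalPair", "TBAR_C", "critical_temperature", "spontaneous_order", "exact_binodals"]


def critical_temperature() -> float:
    """Exact reduced critical temperature ``2 / ln(1 + sqrt(2))`` (~2.269)."""
    return 2.0 / math.log(1.0 + math.sqrt(2.0))


#: Exact reduced critical temperature of the square-lattice Ising model.
TBAR_C = critical_temperature()


@dataclass(frozen=True)
class BinodalPair:
    """Coexisting compositions at one reduced temperature.

    ``x_beta <= 1/2 <= x_alpha`` and ``x_beta + x_alpha = 1``; the pair
    collapses onto (1/2, 1/2) at and above the critical temperature.
    """

    x_beta: float
    x_alpha: float
    t_bar: float

    @property
    def width(self) -> float:
        """Miscibility-gap width ``x_alpha - x_beta`` (equals Upsilon)."""
        return self.x_alpha - self.x_beta

    @property
    def is_critical(self) -> bool:
        return self.width == 0.0

    def contains(self, x: float) -> bool:
        """Closed-interval membership (boundary points coexist)."""
        return self.x_beta <= x <= self.x_alpha


def spontaneous_order(t_bar: float) -> float:
    """Spontaneous order parameter ``Upsilon(T_bar)`` of the square lattice.

    Returns ``(1 - sinh(2/T_bar)**-4)**(1/8)`` below the critical
    temperature and exactly 0 at or above it (the closed form is defined
    piecewise; no complex/NaN leakage).  Strictly decreasing on
    ``(0, T_bar_c)`` with limits 1 as ``T_bar -> 0+`` and 0 at criticality.

    Near the critical point the difference ``1 - sinh(2/T_bar)**-4`` is
    evaluated through ``expm1`` of the log to avoid catastrophic
    cancellation.
    """
    if not (t_bar > 0.0):
        raise ValueError(f"T_bar must be positive, got {t_bar}")
    if t_bar >= TBAR_C:
        return 0.0
    # 1 - sinh(2/T)^-4 = -expm1(-4*log(sinh(2/T))); sinh(2/T) > 1 below Tc.
    s = math.sinh(2.0 / t_bar)
    inner = -math.expm1(-4.0 * math.log(s))
    return inner ** 0.125


def exact_binodals(t_bar: float) -> BinodalPair:
    """Exact binodal pair ``(1/2 - Upsilon/2, 1/2 + Upsilon/2)`` at ``t_bar``."""
    ups = spontaneous_order(t_bar)
    return BinodalPair(x_beta=0.5 - 0.5 * ups, x_alpha=0.5 + 0.5 * ups, t_bar=t_bar)
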