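"""Mean-field (Bragg--Williams) equation of state for the lattice binary mixture.

The exact Ising backend only knows the coexistence line; off coexistence the
chemical potential as a function of composition has no closed form.  The
mean-field closure fills this gap.  Writing the Bragg--Williams per-site free
energy of the nearest-neighbor mixture (coordination number z = 4),

    f(X)/kBT = X ln X + (1-X) ln(1-X)
               + (z/2) [Uaa X^2 + 2 Uab X(1-X) + Ubb (1-X)^2] / kBT,

differentiating with respect to X, and subtracting the transition chemical
potential ``mu_alphabeta = 2 (Uaa - Ubb)`` (which the unshifted derivative
reproduces exactly at X = 1/2), every interaction parameter collapses into
the reduced temperature and the shifted chemical potential becomes

    dG(X)/kBT = ln(X / (1-X)) - (2 z / T_bar) (2 X - 1).

This function is odd about X = 1/2, strictly increasing outside the
mean-field binodals for ``T_bar < z``, and non-monotonic (van der Waals loop)
between them.  The physical, flattened branch replaces the loop by the
constant value 0 on the coexistence interval — by the odd symmetry this
equal-area (Maxwell) construction coincides with the common-tangent one.
The mean-field critical temperature is ``T_bar_c^mf = z = 4``.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod

from scipy.optimize import brentq

from .core_model import Z_COORDINATION
from .ising_exact import TBAR_C, BinodalPair, exact_binodals

__all__ = [
    "TBAR_C_MF",
    "mf_critical_temperature",
    "mf_deltaG",
    "mf_binodals",
    "EquationOfState",
    "MeanFieldEOS",
    "ExactLimitEOS",
    "get_eos",
]

#: Mean-field reduced critical temperature (equals the coordination number).
TBAR_C_MF = float(Z_COORDINATION)

# Root-finding tolerances: absolute tolerance in composition, and the margin
# kept away from the interval endpoints {0, 1/2, 1} when bracketing.
_XTOL = 1e-13
_EPS = 1e-9


def mf_critical_temperature() -> float:
    """Mean-field reduced critical temperature, ``z = 4`` on the square lattice.

    Obtained by linearizing ``dG`` at X = 1/2: the entropic slope there is 4
    and the interaction slope is ``4z/T_bar``, which balance at ``T_bar = z``.
    """
    return TBAR_C_MF


def _mf_deltaG_raw(x: float, t_bar: float) -> float:
    """Unflattened ``dG(X)/kBT`` (contains the van der Waals loop below Tc)."""
    return math.log(x / (1.0 - x)) - (2.0 * Z_COORDINATION / t_bar) * (2.0 * x - 1.0)


def mf_binodals(t_bar: float) -> BinodalPair:
    """Mean-field binodal pair at reduced temperature ``t_bar``.

    For ``t_bar < 4`` these are the nontrivial symmetric roots of the
    unflattened ``dG`` (equivalently of ``m = tanh(z m / T_bar)`` with
    ``m = 2X - 1``), found by bracketed root search on ``(0, 1/2)``; for
    ``t_bar >= 4`` the pair collapses onto (1/2, 1/2).
    """
    if not (t_bar > 0.0):
        raise ValueError(f"T_bar must be positive, got {t_bar}")
    if t_bar >= TBAR_C_MF:
        return BinodalPair(x_beta=0.5, x_alpha=0.5, t_bar=t_bar)
    if t_bar <= 3.9:
        # Away from criticality, root-find the raw dG in composition space.
        # For x < x_beta the raw dG is negative; it first crosses zero near
        # exp(-2z/T_bar), so half that value is a valid lower bracket.
        lo = max(0.5 * math.exp(-2.0 * Z_COORDINATION / t_bar), 5e-324)
        x_beta = brentq(_mf_deltaG_raw, lo, 0.5 - _EPS, args=(t_bar,), xtol=_XTOL)
        return BinodalPair(x_beta=x_beta, x_alpha=1.0 - x_beta, t_bar=t_bar)
    # Near Tc, solve the equivalent self-consistency m = tanh(z m / T_bar)
    # for the gap width m = x_alpha - x_beta, which conditions better.
    r = TBAR_C_MF / t_bar
    delta = 1.0 - t_bar / TBAR_C_MF
    m0_sq = 3.0 * (r - 1.0) / r**3
    if delta < 1e-8:
        # Landau expansion m^2 = 3(r-1)/r^3 + (2/5) r^2 m^4 + O(delta^3):
        # this beats root finding below the noise floor of tanh near Tc.
        m = math.sqrt(m0_sq + 0.4 * r * r * m0_sq * m0_sq)
    else:
        m = brentq(lambda y: y - math.tanh(r * y),
                   0.5 * math.sqrt(m0_sq), 1.0, xtol=_XTOL)
    return BinodalPair(x_beta=0.5 * (1.0 - m), x_alpha=0.5 * (1.0 + m), t_bar=t_bar)


def mf_deltaG(x: float, t_bar: float, flatten: bool = True) -> float:
    """Reduced shifted chemical potential ``dG(X)/kBT`` of the mean-field mixture.

    With ``flatten=True`` (the physical branch) the value is exactly 0 on
    the mean-field coexistence interval; outside it the closed form
    ``ln(X/(1-X)) - (2z/T_bar)(2X-1)`` is returned.  ``flatten=False``
    exposes the raw loop (used internally for binodal root finding).

    Odd about X = 1/2 and, flattened, non-decreasing on (0, 1).
    """
    if not (0.0 < x < 1.0):
        raise ValueError(f"X must lie strictly inside (0, 1), got {x}")
    if not (t_bar > 0.0):
        raise ValueError(f"T_bar must be positive, got {t_bar}")
    if flatten and t_bar < TBAR_C_MF:
        pair = mf_binodals(t_bar)
        if pair.x_beta <= x <= pair.x_alpha:
            return 0.0
    return _mf_deltaG_raw(x, t_bar)


class EquationOfState(ABC):
    """Thermodynamic backend contract used by the segment-equilibrium solver.

    A backend provides its critical temperature and binodals; backends that
    can evaluate the shifted chemical potential off coexistence additionally
    expose ``delta_g`` and set ``supports_off_coexistence``.
    """

    backend: str
    supports_off_coexistence: bool

    @property
    @abstractmethod
    def tc(self) -> float:
        """Reduced critical temperature of this backend."""

    @abstractmethod
    def binodals(self, t_bar: float) -> BinodalPair:
        """Coexisting compositions at reduced temperature ``t_bar``."""

    def delta_g(self, x: float, t_bar: float, flatten: bool = True) -> float:
        """Reduced shifted chemical potential ``dG(X)/kBT`` (if available)."""
        raise NotImplementedError(
            f"backend {self.backend!r} cannot evaluate the chemical potential "
            "off coexistence"
        )


class MeanFieldEOS(EquationOfState):
    """Bragg--Williams backend with a full ``dG(X)`` everywhere in (0, 1)."""

    backend = "meanfield"
    supports_off_coexistence = True

    @property
    def tc(self) -> float:
        return TBAR_C_MF

    def binodals(self, t_bar: float) -> BinodalPair:
        return mf_binodals(t_bar)

    def delta_g(self, x: float, t_bar: float, flatten: bool = True) -> float:
        return mf_deltaG(x, t_bar, flatten=flatten)


class ExactLimitEOS(EquationOfState):
    """Exact Ising backend: exact binodals, no off-coexistence ``dG``.

    Spectator-phase compositions with this backend are the asymptotic
    small/large-contrast limits (0, x_beta, x_alpha or 1); the caller selects
    the regime explicitly.
    """

    backend = "exact-limit"
    supports_off_coexistence = False

    @property
    def tc(self) -> float:
        return TBAR_C

    def binodals(self, t_bar: float) -> BinodalPair:
        return exact_binodals(t_bar)


def get_eos(backend: str) -> EquationOfState:
    """Instantiate a backend by name (``meanfield`` or ``exact-limit``)."""
    if backend in ("meanfield", "mf"):
        return MeanFieldEOS()
    if backend in ("exact-limit", "exact"):
        return ExactLimitEOS()
    raise ValueError(f"unknown backend {backend!r}; expected 'meanfield' or 'exact-limit'")
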