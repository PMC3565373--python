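"""Segment-wise phase coexistence of an adhering two-component membrane.

The adhering membrane consists of two lattice segments that exchange
molecules by lateral diffusion.  Two relations fix the segment compositions
``Xa1``, ``Xa2`` at given overall composition ``Xa``:

* the partitioning (lever) relation  ``q1*Xa1 + (1-q1)*Xa2 = Xa``, and
* chemical equilibrium              ``dG(Xa1) = dG(Xa2) + dU21``,

where ``dG`` is the shifted chemical potential of the chosen thermodynamic
backend and ``dU21`` the affinity contrast (here always in units of the
current thermal energy ``kBT``).

If one segment phase separates, its ``dG`` term vanishes and the other
segment becomes a uniform *spectator phase* whose composition solves
``dG(x) = -dU21`` (segment 1 separating) or ``dG(x) = +dU21`` (segment 2
separating).  Since ``dG`` rises monotonically on each side of the
coexistence plateau, the spectator composition decreases monotonically with
the contrast on each sign branch and jumps across the miscibility gap as the
contrast passes through zero.  The asymptotic spectator values — 0, x_beta,
x_alpha or 1 — are the only ones available to the exact-limit backend, which
has no off-coexistence ``dG``; there the caller labels the regime as
``"small"`` or ``"large"`` contrast explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

from .meanfield import EquationOfState

__all__ = ["SegmentState", "spectator_fraction", "solve_state", "ONE_PHASE", "COEX_SEGMENT_1", "COEX_SEGMENT_2"]

ONE_PHASE = "one_phase"
COEX_SEGMENT_1 = "coex_segment_1"
COEX_SEGMENT_2 = "coex_segment_2"

_XTOL = 1e-14
_EPS = 1e-12


@dataclass(frozen=True)
class SegmentState:
    """Solved state of the two-segment membrane at one ``(Xa, T_bar)`` point.

    ``phase`` is one of ``one_phase``, ``coex_segment_1``,
    ``coex_segment_2``.  For zero affinity contrast the whole membrane
    coexists as a single system; this is labeled ``coex_segment_1`` with
    ``whole_membrane=True`` rather than attributing it to either segment.
    ``spectator_segment``/``spectator_x`` identify the uniform segment and
    its composition during coexistence of the other segment.
    """

    Xa1: float
    Xa2: float
    Xa: float
    q1: float
    t_bar: float
    du21: float
    phase: str
    whole_membrane: bool = False
    spectator_segment: Optional[int] = None
    spectator_x: Optional[float] = None

    @property
    def partitioning_residual(self) -> float:
        """``q1*Xa1 + (1-q1)*Xa2 - Xa`` (should be ~0 at output)."""
        return self.q1 * self.Xa1 + (1.0 - self.q1) * self.Xa2 - self.Xa


def _check_regime(regime: Optional[str]) -> str:
    if regime not in ("small", "large"):
        raise ValueError(
            "the exact-limit backend needs regime='small' or 'large' (asymptotic "
            f"contrast label), got {regime!r}"
        )
    return regime


def spectator_fraction(
    separating_segment: int,
    t_bar: float,
    du21: float,
    eos: EquationOfState,
    regime: Optional[str] = None,
) -> float:
    """Composition of the uniform spectator segment while the other coexists.

    Solves ``dG(x) = -du21`` when segment 1 is the separating one (the
    spectator is segment 2) and ``dG(x) = +du21`` when segment 2 separates.
    ``du21`` is the affinity contrast per ``kBT``.  The root is taken on the
    monotone branch selected by the sign: a negative right-hand side puts the
    spectator below ``x_beta``, a positive one above ``x_alpha``.

    For the exact-limit backend the asymptotic values are returned according
    to ``regime``: ``"small"`` gives the adjacent binodal (x_beta or
    x_alpha), ``"large"`` gives the saturated composition (0 or 1).
    """
    if separating_segment not in (1, 2):
        raise ValueError(f"separating_segment must be 1 or 2, got {separating_segment}")
    if du21 == 0.0:
        raise ValueError(
            "zero affinity contrast is the degenerate whole-membrane coexistence "
            "case; use solve_state"
        )
    if not (t_bar < eos.tc):
        raise ValueError(f"T_bar={t_bar} must be below the backend Tc={eos.tc}")
    pair = eos.binodals(t_bar)
    target = -du21 if separating_segment == 1 else +du21

    if not eos.supports_off_coexistence:
        regime = _check_regime(regime)
        if target < 0.0:
            return pair.x_beta if regime == "small" else 0.0
        return pair.x_alpha if regime == "small" else 1.0

    if target > 0.0:
        # dG is odd about 1/2: solve the mirrored problem on the lower branch.
        return 1.0 - _lower_branch_root(-target, t_bar, pair.x_beta, eos)
    return _lower_branch_root(target, t_bar, pair.x_beta, eos)


def _lower_branch_root(target: float, t_bar: float, x_beta: float, eos: EquationOfState) -> float:
    """Root of ``dG(x) = target`` (target < 0) on the branch ``(0, x_beta]``.

    ``dG`` covers (-inf, 0] there, so a root always exists; for strongly
    negative targets it sits near ``exp(target)``, which fixes the bracket.
    """
    def f(x: float) -> float:
        return eos.delta_g(x, t_bar, flatten=False) - target

    # ln(x/(1-x)) = target + (2z/T)(2x-1) >= target - 2z/T on (0, 1/2),
    # so the root exceeds ~exp(target - 2z/T)/2.
    lo = max(0.25 * math.exp(target - 8.0 / t_bar), 5e-324)
    hi = x_beta
    fhi = f(hi)
    if fhi == 0.0:
        return hi
    flo = f(lo)
    assert flo < 0.0 < fhi, "no spectator root on the selected monotone branch"
    return brentq(f, lo, hi, xtol=_XTOL)


def _one_phase_exact_limit(xa: float, q1: float, du21: float, regime: str) -> tuple[float, float]:
    """One-phase segment compositions in the exact asymptotic regimes.

    In the large-contrast limit the preferred segment fills (or empties)
    completely before the other segment's composition moves: for
    ``du21 > 0`` the a-molecules saturate segment 1 first, so
    ``Xa1 = min(Xa/q1, 1)`` and ``Xa2`` takes the remainder; ``du21 < 0``
    mirrors this.  In the small-contrast limit the two segments are
    indistinguishable off coexistence and share the overall composition.
    """
    if regime == "small":
        return xa, xa
    if du21 > 0.0:
        if xa <= q1:
            return (xa / q1 if q1 > 0 else 0.0), 0.0
        return 1.0, (xa - q1) / (1.0 - q1)
    if xa <= 1.0 - q1:
        return 0.0, (xa / (1.0 - q1) if q1 < 1 else 0.0)
    return (xa - (1.0 - q1)) / q1, 1.0


def _one_phase_meanfield(
    xa: float, t_bar: float, q1: float, du21: float, eos: EquationOfState
) -> tuple[float, float]:
    """Solve {chemical equilibrium, partitioning} for a one-phase membrane.

    Outer bracketed root search on ``Xa1`` along the admissible interval
    where both segment compositions lie in (0, 1); ``Xa2`` follows in closed
    form from the partitioning relation.  The residual function is monotone
    in ``Xa1`` because ``dG`` is non-decreasing and ``Xa2`` decreases as
    ``Xa1`` increases.
    """
    q2 = 1.0 - q1
    lo = max(_EPS, (xa - q2 * (1.0 - _EPS)) / q1)
    hi = min(1.0 - _EPS, (xa - q2 * _EPS) / q1)
    if lo >= hi:  # pinned composition (xa at an extreme)
        x1 = min(max(xa, _EPS), 1.0 - _EPS)
        return x1, x1

    def f(x1: float) -> float:
        x2 = (xa - q1 * x1) / q2
        x2 = min(max(x2, _EPS), 1.0 - _EPS)
        return eos.delta_g(x1, t_bar) - eos.delta_g(x2, t_bar) - du21

    flo, fhi = f(lo), f(hi)
    if flo >= 0.0:
        x1 = lo
    elif fhi <= 0.0:
        x1 = hi
    else:
        x1 = brentq(f, lo, hi, xtol=_XTOL)
    x2 = (xa - q1 * x1) / q2
    return x1, x2


def solve_state(
    xa: float,
    t_bar: float,
    q1: float,
    du21: float,
    eos: EquationOfState,
    regime: Optional[str] = None,
) -> SegmentState:
    """Classify the membrane state and solve the segment compositions.

    Parameters
    ----------
    xa :
        Overall mole fraction of a-molecules, in [0, 1].
    t_bar :
        Reduced temperature ``kBT/J``.
    q1 :
        Area fraction of segment 1, in [0, 1].
    du21 :
        Affinity contrast per ``kBT``.
    eos :
        Thermodynamic backend.
    regime :
        ``"small"`` or ``"large"``; required for the exact-limit backend with
        nonzero contrast.

    Notes
    -----
    Classification order: zero contrast (whole-membrane coexistence window),
    segment-1 coexistence window, segment-2 coexistence window, one-phase
    system otherwise.  The two segment windows in overall composition are the
    binodal interval lever-projected through the partitioning relation with
    the spectator composition filling the other segment; for nonzero contrast
    they are disjoint (asserted), which is the model's statement that the two
    segments never phase separate simultaneously.  Coexistence windows are
    closed intervals: boundary points classify as coexistence.
    """
    for name, val in (("Xa", xa), ("T_bar", t_bar), ("q1", q1), ("du21", du21)):
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val}")
    if not (0.0 <= xa <= 1.0):
        raise ValueError(f"Xa must lie in [0, 1], got {xa}")
    if not (0.0 <= q1 <= 1.0):
        raise ValueError(f"q1 must lie in [0, 1], got {q1}")
    if not (t_bar > 0.0):
        raise ValueError(f"T_bar must be positive, got {t_bar}")

    subcritical = t_bar < eos.tc
    pair = eos.binodals(t_bar) if subcritical else None

    # Degenerate geometries: the membrane is a single uniform-environment
    # segment and the problem reduces to the uni-env mixture on it.
    if q1 in (0.0, 1.0):
        label = COEX_SEGMENT_1 if q1 == 1.0 else COEX_SEGMENT_2
        if subcritical and pair.contains(xa):
            return SegmentState(Xa1=xa, Xa2=xa, Xa=xa, q1=q1, t_bar=t_bar,
                                du21=du21, phase=label)
        return SegmentState(Xa1=xa, Xa2=xa, Xa=xa, q1=q1, t_bar=t_bar,
                            du21=du21, phase=ONE_PHASE)

    if du21 == 0.0:
        # No affinity contrast: segments are equivalent, the whole membrane
        # is one uni-env system with Xa1 = Xa2 = Xa.
        if subcritical and pair.contains(xa):
            return SegmentState(Xa1=xa, Xa2=xa, Xa=xa, q1=q1, t_bar=t_bar,
                                du21=du21, phase=COEX_SEGMENT_1, whole_membrane=True)
        return SegmentState(Xa1=xa, Xa2=xa, Xa=xa, q1=q1, t_bar=t_bar,
                            du21=du21, phase=ONE_PHASE)

    if xa in (0.0, 1.0):
        # Pure membranes are uniform: the coexistence windows exclude the
        # composition endpoints for any nonzero contrast.
        return SegmentState(Xa1=xa, Xa2=xa, Xa=xa, q1=q1, t_bar=t_bar,
                            du21=du21, phase=ONE_PHASE)

    if subcritical:
        xs2 = spectator_fraction(1, t_bar, du21, eos, regime=regime)
        xs1 = spectator_fraction(2, t_bar, du21, eos, regime=regime)
        w1 = (q1 * pair.x_beta + (1.0 - q1) * xs2, q1 * pair.x_alpha + (1.0 - q1) * xs2)
        w2 = (q1 * xs1 + (1.0 - q1) * pair.x_beta, q1 * xs1 + (1.0 - q1) * pair.x_alpha)
        # The two windows must not overlap (they may touch in the
        # small-contrast asymptotic limit).
        tol = 1e-9
        assert w1[1] <= w2[0] + tol or w2[1] <= w1[0] + tol, (
            "segment coexistence windows overlap; the intermediate one-phase "
            "region must separate them for nonzero contrast"
        )
        if w1[0] <= xa <= w1[1]:
            x1 = (xa - (1.0 - q1) * xs2) / q1
            return SegmentState(Xa1=x1, Xa2=xs2, Xa=xa, q1=q1, t_bar=t_bar,
                                du21=du21, phase=COEX_SEGMENT_1,
                                spectator_segment=2, spectator_x=xs2)
        if w2[0] <= xa <= w2[1]:
            x2 = (xa - q1 * xs1) / (1.0 - q1)
            return SegmentState(Xa1=xs1, Xa2=x2, Xa=xa, q1=q1, t_bar=t_bar,
                                du21=du21, phase=COEX_SEGMENT_2,
                                spectator_segment=1, spectator_x=xs1)

    if eos.supports_off_coexistence:
        x1, x2 = _one_phase_meanfield(xa, t_bar, q1, du21, eos)
    else:
        x1, x2 = _one_phase_exact_limit(xa, q1, du21, _check_regime(regime))
    # Restate the partitioning relation exactly at output.
    if q1 >= 0.5:
        x1 = (xa - (1.0 - q1) * x2) / q1
    else:
        x2 = (xa - q1 * x1) / (1.0 - q1)
    return SegmentState(Xa1=x1, Xa2=x2, Xa=xa, q1=q1, t_bar=t_bar,
                        du21=du21, phase=ONE_PHASE)
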