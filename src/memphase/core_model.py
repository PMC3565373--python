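"""Parameter types and exact mappings for the lattice binary-mixture membrane model.

A two-component membrane (species ``a`` and ``b`` on a square lattice with one
molecule per site) maps onto the two-dimensional Ising model.  The mapping is
controlled by two reduced variables:

* the dimensionless temperature ``T_bar = kBT / J`` with the coupling
  ``J = (2*Uab - Uaa - Ubb) / 4`` built from the pairwise nearest-neighbor
  interaction energies, and
* the dimensionless ordering field
  ``H_bar = (dmu/2 - (Uaa - Ubb)) / kBT`` built from the relative chemical
  potential ``dmu = mu_a - mu_b``.

Phase separation into an a-rich (liquid-ordered, alpha) and a b-rich
(liquid-disordered, beta) phase requires ``J > 0`` and occurs along the locus
``H_bar = 0``, i.e. at the transition chemical potential
``mu_alphabeta = 2*(Uaa - Ubb)``.

Adhesion partitions the membrane into two segments exposed to different
environments.  Each environment attracts the two species with potentials
``Ua[m]``, ``Ub[m]`` (attractive = negative); the segment's relative affinity
is ``dU[m] = Ua[m] - Ub[m]`` and the affinity contrast
``dU21 = dU[2] - dU[1]`` is the single parameter through which the two
environments enter the phase behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Z_COORDINATION",
    "InteractionParams",
    "OrderingField",
    "SegmentAffinities",
    "MembraneSpec",
    "reduced_temperature",
    "mu_alphabeta",
    "ordering_field",
    "affinity_contrast",
    "contrast_per_kBT",
]

#: Square-lattice coordination number.  The model is defined on a square
#: lattice throughout (one lattice constant, one molecular area), so this is
#: a constant rather than a free parameter.
Z_COORDINATION = 4


@dataclass(frozen=True)
class InteractionParams:
    """Pairwise nearest-neighbor energies and derived Ising variables.

    Parameters
    ----------
    Uaa, Uab, Ubb :
        Interaction energies for aa, ab and bb neighbor pairs (any energy
        unit, used consistently with ``kBT``).
    kBT :
        Thermal energy in the same unit.  Must be positive.

    Raises
    ------
    ValueError
        If the derived coupling ``J = (2*Uab - Uaa - Ubb)/4`` is not positive
        (no demixing transition) or if ``kBT <= 0``.
    """

    Uaa: float
    Uab: float
    Ubb: float
    kBT: float = 1.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(u) for u in (self.Uaa, self.Uab, self.Ubb, self.kBT)):
            raise ValueError("interaction parameters must be finite")
        if self.kBT <= 0:
            raise ValueError(f"kBT must be positive, got {self.kBT}")
        if self.J <= 0:
            raise ValueError(
                f"coupling J = (2*Uab - Uaa - Ubb)/4 = {self.J} must be positive "
                "for a demixing transition (2*Uab > Uaa + Ubb)"
            )

    @property
    def J(self) -> float:
        """Ising coupling ``(2*Uab - Uaa - Ubb) / 4``."""
        return (2.0 * self.Uab - self.Uaa - self.Ubb) / 4.0

    @property
    def t_bar(self) -> float:
        """Reduced temperature ``kBT / J``."""
        return self.kBT / self.J


def reduced_temperature(params: InteractionParams) -> float:
    """Dimensionless temperature ``T_bar = kBT/J = 4*kBT/(2*Uab - Uaa - Ubb)``.

    Invariant under a uniform shift of all three pair energies.
    """
    return params.t_bar


def mu_alphabeta(params: InteractionParams) -> float:
    """Transition chemical potential ``mu_alphabeta = 2*(Uaa - Ubb)``.

    The lattice binary mixture phase separates at ``dmu = mu_alphabeta`` for
    all temperatures below the critical one; this value makes the Ising
    ordering field vanish.
    """
    return 2.0 * (params.Uaa - params.Ubb)


def ordering_field(dmu: float, params: InteractionParams) -> float:
    """Dimensionless ordering field ``H_bar = (dmu/2 - (Uaa - Ubb)) / kBT``.

    ``ordering_field(mu_alphabeta(p), p) == 0`` identically.
    """
    return (dmu / 2.0 - (params.Uaa - params.Ubb)) / params.kBT


@dataclass(frozen=True)
class OrderingField:
    """Relative chemical potential and its reduced Ising field.

    ``h_bar`` is derived from ``dmu = mu_a - mu_b`` and the interaction
    parameters at construction; the two fields always satisfy the defining
    relation exactly.
    """

    dmu: float
    h_bar: float

    @classmethod
    def from_params(cls, dmu: float, params: InteractionParams) -> "OrderingField":
        return cls(dmu=dmu, h_bar=ordering_field(dmu, params))


@dataclass(frozen=True)
class SegmentAffinities:
    """Environment interaction potentials of the two membrane segments.

    ``Ua1``/``Ub1`` act on a-/b-molecules in segment 1, ``Ua2``/``Ub2`` in
    segment 2; attractive potentials are negative.  An unbound segment has
    both potentials equal to zero and hence zero relative affinity.
    """

    Ua1: float = 0.0
    Ub1: float = 0.0
    Ua2: float = 0.0
    Ub2: float = 0.0

    @property
    def dU1(self) -> float:
        """Relative affinity of segment 1, ``Ua1 - Ub1``."""
        return self.Ua1 - self.Ub1

    @property
    def dU2(self) -> float:
        """Relative affinity of segment 2, ``Ua2 - Ub2``."""
        return self.Ua2 - self.Ub2

    @property
    def dU21(self) -> float:
        """Affinity contrast ``dU[2] - dU[1]``.

        Positive contrast means the b-molecules are the more sticky species
        in segment 2 relative to segment 1 (the environment of segment 2
        recruits b and expels a).
        """
        return self.dU2 - self.dU1

    def swapped(self) -> "SegmentAffinities":
        """Relabel the two segments; negates the affinity contrast."""
        return SegmentAffinities(Ua1=self.Ua2, Ub1=self.Ub2, Ua2=self.Ua1, Ub2=self.Ub1)

    def dU21_reduced(self, kB_Tc: float) -> float:
        """Affinity contrast in units of ``kB*Tc`` for a given ``kB*Tc``."""
        if kB_Tc <= 0:
            raise ValueError("kB*Tc must be positive")
        return self.dU21 / kB_Tc


def affinity_contrast(aff: SegmentAffinities) -> float:
    """Affinity contrast ``dU21 = (Ua2 - Ub2) - (Ua1 - Ub1)``.

    Antisymmetric under segment relabeling.
    """
    return aff.dU21


def contrast_per_kBT(du21_over_kBTc: float, t_over_tc: float) -> float:
    """Convert a reduced affinity contrast ``dU21/(kB*Tc)`` to ``dU21/(kB*T)``.

    The chemical-equilibrium relations compare the contrast against the
    shifted chemical potential in units of the *current* thermal energy, so
    a contrast quoted in units of ``kB*Tc`` picks up a factor ``Tc/T``.
    """
    if t_over_tc <= 0:
        raise ValueError("T/Tc must be positive")
    return du21_over_kBTc / t_over_tc


@dataclass(frozen=True)
class MembraneSpec:
    """Overall composition and segment area fraction of an adhering membrane.

    ``q1`` is the area fraction of segment 1 and ``Xa`` the overall mole
    fraction of a-molecules; both live in [0, 1].
    """

    q1: float
    Xa: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q1 <= 1.0):
            raise ValueError(f"q1 must lie in [0, 1], got {self.q1}")
        if not (0.0 <= self.Xa <= 1.0):
            raise ValueError(f"Xa must lie in [0, 1], got {self.Xa}")

    @property
    def q2(self) -> float:
        return 1.0 - self.q1

    @property
    def Xb(self) -> float:
        return 1.0 - self.Xa
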