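"""Semi-grand-canonical Metropolis Monte Carlo of the two-segment lattice mixture.

The lattice is an L x L torus of occupation numbers (n = 1 for an
a-molecule, 0 for a b-molecule) split by a column index ``c`` into a strip
of segment 1 (columns < c) and segment 2 (columns >= c), so that
``q1 = c/L``.  All energies are carried per ``kBT``.  The configurational
energy of segment m is

    E[m]/kBT = sum over in-segment bonds of u(n_i, n_j)
               + (dU[m] - dmu) * sum over segment sites of n_i

with the bond energy u(1,1) = uaa, u(1,0) = u(0,1) = uab, u(0,0) = ubb.
Bonds crossing the segment boundary (the membrane is physically contiguous)
contribute the domain-boundary term; a flag can exclude them to mimic the
thermodynamic limit of fully decoupled segments.

Unless raw couplings are supplied, the symmetric convention
``uaa = ubb = -J/kBT = -1/T_bar``, ``uab = +1/T_bar`` is used, which puts
the transition chemical potential at ``mu_alphabeta = 0`` so that the Ising
ordering field is simply ``H_bar = dmu/2``.

Moves are single-site species flips (n -> 1-n): species counts fluctuate at
fixed site number, the ensemble in which a membrane of fixed area exchanges
a- against b-molecules.  Randomness comes from one NumPy ``default_rng``
(PCG64) stream per run — identical seed and parameters reproduce the
trajectory bit for bit.  An exact-enumeration oracle over all 2^N states is
provided for lattices of up to 16 sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


__all__ = ["LatticeSpec", "MCParams", "MCResult", "energy", "metropolis_run", "enumerate_exact"]


@dataclass(frozen=True)
class LatticeSpec:
    """L x L periodic lattice split into two column strips.

    ``c`` columns belong to segment 1, the rest to segment 2; the area
    fraction ``q1 = c/L`` is therefore restricted to multiples of 1/L.
    ``include_boundary_couplings`` keeps the bonds that straddle the two
    segment boundaries (there are two on a torus whenever 0 < c < L).
    """

    L: int
    c: int
    include_boundary_couplings: bool = True

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError(f"L must be at least 2, got {self.L}")
        if not (0 <= self.c <= self.L):
            raise ValueError(f"partition column c must lie in [0, L], got {self.c}")

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    @property
    def q1(self) -> float:
        return self.c / self.L

    def segment_of_sites(self) -> np.ndarray:
        """Segment index (0-based: 0 = segment 1, 1 = segment 2) per site."""
        cols = np.arange(self.n_sites) % self.L
        return (cols >= self.c).astype(np.int8)

    def neighbor_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Neighbor indices (N, 4) and inclusion weights (N, 4).

        Weights are 0 for bonds that cross the segment boundary when those
        couplings are excluded, else 1.
        """
        L = self.L
        idx = np.arange(self.n_sites)
        row, col = idx // L, idx % L
        nbr = np.stack([
            ((row + 1) % L) * L + col,
            ((row - 1) % L) * L + col,
            row * L + (col + 1) % L,
            row * L + (col - 1) % L,
        ], axis=1).astype(np.int64)
        seg = self.segment_of_sites()
        w = (seg[:, None] == seg[nbr]).astype(np.float64)
        if self.include_boundary_couplings:
            w[:] = 1.0
        return nbr, w

    def bond_list(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique bonds (M, 2) with each torus bond counted once."""
        L = self.L
        idx = np.arange(self.n_sites)
        row, col = idx // L, idx % L
        right = row * L + (col + 1) % L
        down = ((row + 1) % L) * L + col
        bonds = np.concatenate([np.stack([idx, right], 1), np.stack([idx, down], 1)])
        if not self.include_boundary_couplings:
            seg = self.segment_of_sites()
            bonds = bonds[seg[bonds[:, 0]] == seg[bonds[:, 1]]]
        return bonds[:, 0], bonds[:, 1]


@dataclass(frozen=True)
class MCParams:
    """Simulation parameters; all energies per ``kBT``.

    ``dmu`` is the relative chemical potential, ``du1``/``du2`` the segment
    relative affinities.  Raw bond couplings ``uaa``, ``uab``, ``ubb``
    (per kBT) may be given explicitly; by default the symmetric convention
    derived from ``t_bar`` is used.  ``sweeps`` counts post-burn-in
    measurement sweeps; one sweep is N single-site flip attempts.
    """

    t_bar: float
    dmu: float = 0.0
    du1: float = 0.0
    du2: float = 0.0
    sweeps: int = 2000
    burnin: int = 500
    stride: int = 1
    seed: int = 12345
    uaa: Optional[float] = None
    uab: Optional[float] = None
    ubb: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t_bar <= 0:
            raise ValueError(f"t_bar must be positive, got {self.t_bar}")
        if self.sweeps <= 0:
            raise ValueError("sweeps must be positive")
        if self.burnin < 0:
            raise ValueError("burnin must be non-negative")
        if self.stride < 1:
            raise ValueError("stride must be at least 1")
        raw = (self.uaa, self.uab, self.ubb)
        if any(u is not None for u in raw) and not all(u is not None for u in raw):
            raise ValueError("give all of uaa, uab, ubb or none of them")

    def couplings(self) -> tuple[float, float, float]:
        """Bond couplings per kBT; symmetric convention unless raw ones given."""
        if self.uaa is not None:
            j = (2.0 * self.uab - self.uaa - self.ubb) / 4.0
            if not math.isclose(j, 1.0 / self.t_bar, rel_tol=1e-9):
                raise ValueError(
                    f"raw couplings imply J/kBT = {j}, inconsistent with "
                    f"1/t_bar = {1.0 / self.t_bar}"
                )
            return self.uaa, self.uab, self.ubb
        j = 1.0 / self.t_bar
        return -j, +j, -j

    def field_terms(self) -> tuple[float, float]:
        """Per-site occupation field (dU[m] - dmu) for the two segments."""
        return self.du1 - self.dmu, self.du2 - self.dmu


@dataclass(frozen=True)
class MCResult:
    """Averages from a seeded Metropolis run.

    Per-segment occupation means come with blocked standard errors; an empty
    segment reports NaN.  ``mean_energy_per_site`` is the reduced (per kBT)
    configurational energy including field terms.
    """

    mean_n_seg: tuple[float, float]
    se_n_seg: tuple[float, float]
    mean_n: float
    se_n: float
    mean_energy_per_site: float
    acceptance_rate: float
    n_measurements: int
    seed: int

    @property
    def magnetization(self) -> float:
        """Ising order parameter ``<2n - 1>`` over the whole lattice."""
        return 2.0 * self.mean_n - 1.0


def energy(config: np.ndarray, spec: LatticeSpec, params: MCParams) -> float:
    """Total reduced configurational energy of a configuration.

    Sums bond energies (each torus bond once, boundary bonds subject to the
    spec's inclusion flag) plus the per-site field terms.
    """
    n = np.asarray(config).reshape(-1).astype(np.float64)
    if n.size != spec.n_sites:
        raise ValueError(f"config has {n.size} sites, spec expects {spec.n_sites}")
    uaa, uab, ubb = params.couplings()
    bi, bj = spec.bond_list()
    ni, nj = n[bi], n[bj]
    e_int = float(np.sum(uaa * ni * nj + uab * (ni + nj - 2.0 * ni * nj)
                         + ubb * (1.0 - ni) * (1.0 - nj)))
    f1, f2 = params.field_terms()
    seg = spec.segment_of_sites()
    e_field = f1 * float(n[seg == 0].sum()) + f2 * float(n[seg == 1].sum())
    return e_int + e_field


@_njit(cache=False)
def _sweep_kernel(n, nbr, w, seg, uaa, uab, ubb, f1, f2, sites, us):  # pragma: no cover
    """Run len(sites) flip attempts in place; returns (accepted, dE_total)."""
    acc = 0
    de_total = 0.0
    d_a = uaa - uab  # pair-energy change per occupied neighbor
    d_b = uab - ubb  # ... per empty neighbor
    for t in range(sites.shape[0]):
        i = sites[t]
        s = n[i]
        pair = 0.0
        for k in range(4):
            if w[i, k] != 0.0:
                nj = n[nbr[i, k]]
                pair += nj * d_a + (1 - nj) * d_b
        f = f1 if seg[i] == 0 else f2
        de = (1 - 2 * s) * (pair + f)
        if de <= 0.0 or us[t] < math.exp(-de):
            n[i] = 1 - s
            acc += 1
            de_total += de
    return acc, de_total


def _blocked_se(series: np.ndarray, n_blocks: int = 16) -> float:
    """Standard error from block means (crude decorrelation)."""
    m = len(series)
    n_blocks = max(2, min(n_blocks, m))
    usable = (m // n_blocks) * n_blocks
    blocks = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.std(ddof=1) / math.sqrt(n_blocks))


def metropolis_run(
    spec: LatticeSpec,
    params: MCParams,
    initial: Optional[np.ndarray] = None,
) -> MCResult:
    """Metropolis simulation with single-site species flips.

    Flips are accepted with probability ``min(1, exp(-dE/kBT))``.  The first
    ``burnin`` sweeps are discarded; afterwards the per-segment occupations
    and the running energy are recorded every ``stride`` sweeps and
    summarized with blocked standard errors.  ``initial`` sets the starting
    configuration (default: all-b, n = 0).
    """
    N = spec.n_sites
    rng = np.random.default_rng(params.seed)
    if initial is None:
        n = np.zeros(N, dtype=np.int8)
    else:
        n = np.asarray(initial).reshape(-1).astype(np.int8).copy()
        if n.size != N or not np.isin(n, (0, 1)).all():
            raise ValueError("initial configuration must be 0/1 over all sites")
    nbr, w = spec.neighbor_table()
    seg = spec.segment_of_sites()
    uaa, uab, ubb = params.couplings()
    f1, f2 = params.field_terms()
    mask1, mask2 = seg == 0, seg == 1

    e_current = energy(n, spec, params)
    accepted = 0
    attempted = 0

    def run_sweeps(k: int) -> None:
        nonlocal e_current, accepted, attempted
        sites = rng.integers(0, N, size=k * N, dtype=np.int64)
        us = rng.random(k * N)
        acc, de = _sweep_kernel(n, nbr, w, seg, uaa, uab, ubb, f1, f2, sites, us)
        accepted += int(acc)
        attempted += k * N
        e_current += float(de)

    if params.burnin:
        run_sweeps(params.burnin)

    n_meas = params.sweeps // params.stride
    if n_meas < 2:
        raise ValueError("too few measurement sweeps for the given stride")
    m1 = np.empty(n_meas)
    m2 = np.empty(n_meas)
    e_series = np.empty(n_meas)
    for k in range(n_meas):
        run_sweeps(params.stride)
        m1[k] = n[mask1].mean() if mask1.any() else np.nan
        m2[k] = n[mask2].mean() if mask2.any() else np.nan
        e_series[k] = e_current

    tot = np.empty(n_meas)
    tot[:] = (spec.q1 * np.nan_to_num(m1) + (1.0 - spec.q1) * np.nan_to_num(m2))

    def stats(series: np.ndarray) -> tuple[float, float]:
        if np.isnan(series).any():
            return math.nan, math.nan
        return float(series.mean()), _blocked_se(series)

    mean1, se1 = stats(m1)
    mean2, se2 = stats(m2)
    mean_t, se_t = stats(tot)
    return MCResult(
        mean_n_seg=(mean1, mean2),
        se_n_seg=(se1, se2),
        mean_n=mean_t,
        se_n=se_t,
        mean_energy_per_site=float(e_series.mean()) / N,
        acceptance_rate=accepted / attempted,
        n_measurements=n_meas,
        seed=params.seed,
    )


def enumerate_exact(spec: LatticeSpec, params: MCParams) -> dict:
    """Exact semi-grand-canonical averages by full enumeration (<= 16 sites).

    Sums all 2^N configurations of the same reduced energy the simulator
    uses, stabilized with log-sum-exp.  Returns per-segment and overall mean
    occupations and the mean energy per site.
    """
    N = spec.n_sites
    if N > 16:
        raise ValueError(f"enumeration limited to 16 sites, lattice has {N}")
    states = np.arange(1 << N, dtype=np.uint32)
    occ = ((states[:, None] >> np.arange(N, dtype=np.uint32)) & 1).astype(np.float64)

    uaa, uab, ubb = params.couplings()
    bi, bj = spec.bond_list()
    ni, nj = occ[:, bi], occ[:, bj]
    e = (uaa * ni * nj + uab * (ni + nj - 2.0 * ni * nj)
         + ubb * (1.0 - ni) * (1.0 - nj)).sum(axis=1)
    f1, f2 = params.field_terms()
    seg = spec.segment_of_sites()
    e += f1 * occ[:, seg == 0].sum(axis=1) + f2 * occ[:, seg == 1].sum(axis=1)

    logw = -e
    logz = logsumexp(logw)
    p = np.exp(logw - logz)

    def seg_mean(mask: np.ndarray) -> float:
        if not mask.any():
            return math.nan
        return float(p @ occ[:, mask].mean(axis=1))

    return {
        "mean_n_seg": (seg_mean(seg == 0), seg_mean(seg == 1)),
        "mean_n": float(p @ occ.mean(axis=1)),
        "mean_energy_per_site": float(p @ e) / N,
        "log_partition": float(logz),
    }
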