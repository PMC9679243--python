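"""Multistate integral projection kernels on a shared size mesh.

The population is structured by a continuous size variable (rosette
diameter, mm) crossed with three discrete states: NORMAL rosettes, BOLTER
(terminal-bud reproduction, no measurable rosette) and DORMANT (alive
belowground).  The discretized annual kernel is a 3×3 grid of n×n
submatrices on a common midpoint-rule mesh.

Sizeless states carry *latent-size memory*: a bolter or dormant individual
occupies the mesh cell of its last normal size, so transitions out of those
states may remain size-dependent.  Mass placed into BOLTER/DORMANT from a
source cell therefore sits on the block diagonal; re-entry into NORMAL runs
the source cell through the growth map.

Quadrature is the midpoint rule (entry = h × density).  Growth mass falling
outside the mesh is returned by column renormalization of the truncated
Gaussian growth kernel ("eviction correction"), and the recruit-size
density is normalized the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm

from .census import BOLTER, DORMANT, NORMAL
from .errors import KernelAssemblyError

STATE_ORDER = (NORMAL, BOLTER, DORMANT)


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeshGrid:
    """Midpoint-rule discretization of the size axis."""

    n_points: int
    lower: float
    upper: float

    @property
    def h(self) -> float:
        return (self.upper - self.lower) / self.n_points

    @property
    def midpoints(self) -> np.ndarray:
        i = np.arange(1, self.n_points + 1)
        return self.lower + (i - 0.5) * self.h


def build_mesh(max_observed_diameter: float, n_points: int = 150,
               lower: float = 0.0) -> MeshGrid:
    """Mesh from 0 mm to 110% of the largest observed rosette diameter."""
    if max_observed_diameter <= 0:
        raise ValueError("max_observed_diameter must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    return MeshGrid(n_points=int(n_points), lower=float(lower),
                    upper=1.1 * float(max_observed_diameter))


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------

@dataclass
class RateSet:
    """All size-dependent rate functions needed to assemble one annual kernel.

    Probability-valued callables take an array of sizes and return values in
    [0, 1]; ``fruits_*`` return the expected fruit count (flowering
    probability × conditional fruits).  Transition probabilities are
    conditional on survival; if a pair sums above one for some size it is
    rescaled to the simplex during assembly.
    """

    surv_n: Callable
    surv_b: Callable
    surv_d: Callable
    growth_mean: Callable
    growth_sd: float
    p_nb: Callable          # NORMAL -> BOLTER, given survival
    p_nd: Callable          # NORMAL -> DORMANT
    p_bn: Callable          # BOLTER -> NORMAL
    p_bd: Callable          # BOLTER -> DORMANT
    p_dn: Callable          # DORMANT -> NORMAL
    p_db: Callable          # DORMANT -> BOLTER
    fruits_n: Callable      # expected fruits of a NORMAL plant
    fruits_b: Callable      # expected fruits of a BOLTER (at latent size)
    recruit_rate: float     # new recruits per fruit
    recruit_size_mean: float
    recruit_size_sd: float


def growth_matrix(mesh: MeshGrid, mean_fn: Callable, sd: float) -> np.ndarray:
    """Column-stochastic Gaussian growth kernel G[i, j] = P(z_i | z_j)·h.

    Columns are renormalized to exactly one so that discretization never
    evicts mass from the size domain.
    """
    if sd <= 0:
        raise KernelAssemblyError("growth residual SD must be positive")
    z = mesh.midpoints
    mu = np.asarray(mean_fn(z), dtype=float)
    G = norm.pdf(z[:, None], loc=mu[None, :], scale=sd) * mesh.h
    colsum = G.sum(axis=0)
    if np.any(colsum <= 0):
        raise KernelAssemblyError("growth kernel column with zero mass")
    return G / colsum


def recruit_density(mesh: MeshGrid, mean: float, sd: float) -> np.ndarray:
    """Recruit-size density over mesh cells, truncated at 0 and normalized.

    Returns a vector ``phi`` with ``phi.sum() == 1`` (cell probabilities).
    """
    if sd <= 0:
        raise KernelAssemblyError("recruit size SD must be positive")
    z = mesh.midpoints
    phi = norm.pdf(z, loc=mean, scale=sd)
    phi[z < 0] = 0.0
    total = phi.sum()
    if total <= 0:
        raise KernelAssemblyError("recruit size density has no mass on the mesh")
    return phi / total


# ---------------------------------------------------------------------------
# kernel container
# ---------------------------------------------------------------------------

@dataclass
class MultiMatrixKernel:
    """One annual projection kernel: 3×3 blocks of (dst_state, src_state)."""

    mesh: MeshGrid
    blocks: dict
    population: str | None = None
    label: object = None
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.mesh.n_points

    @property
    def matrix(self) -> np.ndarray:
        """Dense (3n × 3n) matrix with state blocks in STATE_ORDER."""
        if self._matrix is None:
            n = self.n
            M = np.zeros((3 * n, 3 * n))
            for di, dst in enumerate(STATE_ORDER):
                for si, src in enumerate(STATE_ORDER):
                    M[di * n:(di + 1) * n, si * n:(si + 1) * n] = \
                        self.blocks[(dst, src)]
            self._matrix = M
        return self._matrix

    def dominant_eigenvalue(self) -> float:
        vals = np.linalg.eigvals(self.matrix)
        return float(np.max(np.abs(vals)))


def state_vector(mesh: MeshGrid, mode: str = "uniform",
                 total: float = 1.0) -> np.ndarray:
    """Initial density over the 3n cells.

    ``uniform`` puts equal density in every mesh cell of every live state.
    """
    n = mesh.n_points
    if mode != "uniform":
        raise ValueError(f"unknown initial vector mode {mode!r}")
    v = np.full(3 * n, 1.0)
    return v * (total / v.sum())


def apply_kernel(K: MultiMatrixKernel, v: np.ndarray) -> np.ndarray:
    """One projection step; linear and nonnegativity-preserving."""
    v = np.asarray(v, dtype=float)
    if v.shape[0] != 3 * K.n:
        raise ValueError(
            f"state vector length {v.shape[0]} does not match kernel ({3 * K.n})"
        )
    return K.matrix @ v


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _clip01(p, name):
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise KernelAssemblyError(f"non-finite values in rate {name}")
    return np.clip(p, 0.0, 1.0)


def _simplex(p1, p2):
    """Rescale a transition pair onto the simplex where it sums above one."""
    s = p1 + p2
    over = s > 1.0
    if np.any(over):
        p1 = np.where(over, p1 / s, p1)
        p2 = np.where(over, p2 / s, p2)
    return p1, p2


def build_kernel(rates: RateSet, mesh: MeshGrid,
                 population: str | None = None, label=None) -> MultiMatrixKernel:
    """Assemble one annual multistate kernel from a set of rate functions.

    Column ``j`` of each live block distributes the survival mass of a
    source individual in cell ``z_j`` across destination cells and states;
    fecundity adds recruits (NORMAL destination only) from NORMAL and BOLTER
    parents.
    """
    z = mesh.midpoints
    n = mesh.n_points

    s_n = _clip01(rates.surv_n(z), "surv_n")
    s_b = _clip01(rates.surv_b(z), "surv_b")
    s_d = _clip01(rates.surv_d(z), "surv_d")
    p_nb, p_nd = _simplex(_clip01(rates.p_nb(z), "p_nb"), _clip01(rates.p_nd(z), "p_nd"))
    p_bn, p_bd = _simplex(_clip01(rates.p_bn(z), "p_bn"), _clip01(rates.p_bd(z), "p_bd"))
    p_dn, p_db = _simplex(_clip01(rates.p_dn(z), "p_dn"), _clip01(rates.p_db(z), "p_db"))

    G = growth_matrix(mesh, rates.growth_mean, rates.growth_sd)
    phi = recruit_density(mesh, rates.recruit_size_mean, rates.recruit_size_sd)

    fn = np.asarray(rates.fruits_n(z), dtype=float)
    fb = np.asarray(rates.fruits_b(z), dtype=float)
    for name, arr in (("fruits_n", fn), ("fruits_b", fb)):
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            raise KernelAssemblyError(f"invalid expected fruit counts in {name}")
    if rates.recruit_rate < 0:
        raise KernelAssemblyError("recruit_rate must be nonnegative")

    # recruitment pathway: expected fruits × recruits-per-fruit × size density
    F_n = np.outer(phi, fn * rates.recruit_rate)
    F_b = np.outer(phi, fb * rates.recruit_rate)

    blocks = {
        (NORMAL, NORMAL): G * (s_n * (1.0 - p_nb - p_nd))[None, :] + F_n,
        (BOLTER, NORMAL): np.diag(s_n * p_nb),
        (DORMANT, NORMAL): np.diag(s_n * p_nd),
        (NORMAL, BOLTER): G * (s_b * p_bn)[None, :] + F_b,
        (BOLTER, BOLTER): np.diag(s_b * (1.0 - p_bn - p_bd)),
        (DORMANT, BOLTER): np.diag(s_b * p_bd),
        (NORMAL, DORMANT): G * (s_d * p_dn)[None, :],
        (BOLTER, DORMANT): np.diag(s_d * p_db),
        (DORMANT, DORMANT): np.diag(s_d * (1.0 - p_dn - p_db)),
    }
    for (dst, src), B in blocks.items():
        if not np.all(np.isfinite(B)):
            raise KernelAssemblyError(f"non-finite entries in block {dst}<-{src}")
        if np.any(B < -1e-12):
            j = int(np.argwhere(B < -1e-12)[0][1])
            raise KernelAssemblyError(
                f"negative entry in block {dst}<-{src}, column {j}"
            )
        np.maximum(B, 0.0, out=B)
    return MultiMatrixKernel(mesh=mesh, blocks=blocks,
                             population=population, label=label)


def max_relative_error(K: MultiMatrixKernel, ref: MultiMatrixKernel,
                       floor_frac: float = 1e-2,
                       blocks: list | None = None) -> float:
    """Largest relative entry discrepancy against a reference kernel.

    Relative error is evaluated on entries exceeding ``floor_frac`` of the
    reference kernel's largest entry.  On Gaussian growth tails the relative
    entry error grows without bound as entries shrink (a mean shift Δμ
    inflates a tail density at distance d by ≈ Δμ·d/σ²), so a relative
    comparison is informative only over entries carrying non-negligible
    mass; the default floor keeps two orders of magnitude of entries in
    scope.  ``blocks`` restricts the comparison to a subset of
    (dst_state, src_state) blocks — useful when some life-cycle pathway
    carries no observable data.
    """
    keys = list(ref.blocks) if blocks is None else list(blocks)
    ref_max = max(ref.blocks[k].max() for k in keys)
    floor = floor_frac * ref_max
    worst = 0.0
    any_entries = False
    for k in keys:
        A, B = K.blocks[k], ref.blocks[k]
        mask = B > floor
        if mask.any():
            any_entries = True
            worst = max(worst, float(np.max(np.abs(A[mask] - B[mask]) / B[mask])))
    if not any_entries:
        raise ValueError("reference kernel has no entries above the floor")
    return worst
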