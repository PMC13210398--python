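"""Exact linear algebra of the cyclic trait-network model.

The model: T traits influence each other through a direct-effect matrix
``G`` (entry ``g_ij`` = direct causal effect of trait j on trait i, zero
diagonal).  Trait values evolve recursively -- at each step the change in
each trait propagates one hop through ``G`` -- and when the spectral radius
of ``G`` is below 1 the system settles at the equilibrium

    Y = (I - G)^{-1} (Gamma Z + eps),

where ``Gamma`` holds direct SNP effects.  Writing ``W = (I - G)^{-1}``, the
matrix of *total* (marginal) SNP effects is ``B = W Gamma``; these are what
GWAS regressions estimate.  Pairwise univariable MR with valid instruments
estimates the ratio network

    Theta = W Diag(w)^{-1},       theta_ij = w_ij / w_jj,

which has unit diagonal.  The map is invertible in closed form:

    G = I - Diag(w)^{-1} Theta^{-1},    w_jj = (Theta^{-1})_jj,

so the direct-effect graph -- cycles included -- can be recovered exactly
from the MR-effect network.  The total-effect network (all direct plus
path-mediated effects) is ``Gtot = (I - G)^{-1} G = W - I``; cycles show up
as nonzero diagonal "self-loop" entries of ``Gtot``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateScalingError,
    ModelViolationError,
    NonConvergentDynamicsError,
    SingularMatrixError,
)

#: Admissibility margin: a graph is admissible when its spectral radius is
#: at most ``1 - SPECTRAL_MARGIN``.
SPECTRAL_MARGIN = 1e-6

#: Condition-number guard levels for linear solves.
COND_WARN = 1e8
COND_ERROR = 1e12

#: Diagonal entries of Theta^{-1} below this magnitude abort graph recovery.
DEGENERATE_SCALE = 1e-10


def _as_square(G, name: str = "matrix") -> np.ndarray:
    A = np.asarray(G, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square, got shape {A.shape}")
    return A


def spectral_radius(G) -> float:
    """Largest modulus over all (real and complex) eigenvalues of ``G``."""
    A = _as_square(G, "G")
    if A.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def is_admissible(G, margin: float = SPECTRAL_MARGIN) -> bool:
    """Whether ``G`` has zero diagonal and spectral radius <= 1 - margin."""
    A = _as_square(G, "G")
    return bool(np.all(np.diag(A) == 0.0) and spectral_radius(A) <= 1.0 - margin)


def _require_convergent(G, exc=ModelViolationError, what: str = "operation"):
    rho = spectral_radius(G)
    if rho >= 1.0 - SPECTRAL_MARGIN:
        raise exc(
            f"{what} requires spectral radius of G < 1, got {rho:.6g}; "
            "the equilibrium/total-effect series does not converge"
        )


def solve_guarded(A, B, what: str = "linear system"):
    """LU-based solve with a relative condition-number guard.

    Warns above 1e8, raises :class:`SingularMatrixError` above 1e12.
    """
    A = _as_square(A, "A")
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > COND_ERROR:
        raise SingularMatrixError(f"{what} is singular or near-singular", cond)
    if cond > COND_WARN:
        warnings.warn(
            f"{what}: condition number {cond:.3e} exceeds {COND_WARN:.0e}; "
            "results may be inaccurate",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.linalg.solve(A, np.asarray(B, dtype=float))


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


def _default_names(T: int, prefix: str = "Y") -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(T)]


@dataclass
class DirectEffectGraph:
    """Direct causal effects among traits: ``G[i, j]`` = effect of j on i.

    Diagonal entries must be exactly zero (no self-loops).  Graphs used in
    forward computations must additionally have spectral radius < 1;
    *estimated* graphs violating the bound are flagged, not rejected.
    """

    G: np.ndarray
    trait_names: list[str] = field(default_factory=list)
    spectral_warning: bool = False

    def __post_init__(self):
        self.G = _as_square(self.G, "G")
        if np.any(np.diag(self.G) != 0.0):
            raise ModelViolationError("direct-effect graph must have zero diagonal")
        if not self.trait_names:
            self.trait_names = _default_names(self.n_traits)
        if len(self.trait_names) != self.n_traits:
            raise ValueError("trait_names length does not match G")
        if spectral_radius(self.G) > 1.0 - SPECTRAL_MARGIN:
            self.spectral_warning = True

    @property
    def n_traits(self) -> int:
        return self.G.shape[0]

    @property
    def spectral_radius(self) -> float:
        return spectral_radius(self.G)


@dataclass
class MREffectNetwork:
    """Pairwise MR effects: ``Theta[i, j]`` = MR effect of trait j on trait i.

    Unit diagonal by construction (theta_jj = w_jj / w_jj).  ``missing``
    optionally marks entries that could not be estimated (set to 0).
    """

    Theta: np.ndarray
    trait_names: list[str] = field(default_factory=list)
    missing: np.ndarray | None = None

    def __post_init__(self):
        self.Theta = _as_square(self.Theta, "Theta")
        if not np.allclose(np.diag(self.Theta), 1.0):
            raise ValueError("MR-effect network must have unit diagonal")
        np.fill_diagonal(self.Theta, 1.0)
        if not self.trait_names:
            self.trait_names = _default_names(self.n_traits)
        if len(self.trait_names) != self.n_traits:
            raise ValueError("trait_names length does not match Theta")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.Theta.shape:
                raise ValueError("missing mask shape does not match Theta")

    @property
    def n_traits(self) -> int:
        return self.Theta.shape[0]


@dataclass
class MixingMatrix:
    """``W = (I - G)^{-1}`` and its diagonal ``w``; columns of W scale Theta."""

    W: np.ndarray

    def __post_init__(self):
        self.W = _as_square(self.W, "W")

    @property
    def w(self) -> np.ndarray:
        return np.diag(self.W).copy()


@dataclass
class TotalEffectNetwork:
    """Total (direct plus all path-mediated) effects, ``Gtot = W - I``.

    Diagonal entries ``t_jj`` are self-loop effects induced by cycles; they
    vanish for acyclic graphs.
    """

    Gtot: np.ndarray

    def __post_init__(self):
        self.Gtot = _as_square(self.Gtot, "Gtot")

    @property
    def t(self) -> np.ndarray:
        return np.diag(self.Gtot).copy()


@dataclass
class SnpEffectMatrix:
    """Direct (``Gamma``) and total (``B``) SNP-to-trait effects, traits x SNPs."""

    Gamma: np.ndarray | None = None
    B: np.ndarray | None = None

    def __post_init__(self):
        for name in ("Gamma", "B"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=float)
                if arr.ndim != 2:
                    raise ValueError(f"{name} must be 2-D (traits x SNPs)")
                setattr(self, name, arr)
        if self.Gamma is not None and self.B is not None:
            if self.Gamma.shape != self.B.shape:
                raise ValueError("Gamma and B must have matching shapes")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _graph_array(G) -> np.ndarray:
    if isinstance(G, DirectEffectGraph):
        return G.G
    return _as_square(G, "G")


def _theta_array(Theta) -> np.ndarray:
    if isinstance(Theta, MREffectNetwork):
        return Theta.Theta
    return _as_square(Theta, "Theta")


def mixing_matrix(G) -> MixingMatrix:
    """``W = (I - G)^{-1}`` via a guarded linear solve."""
    A = _graph_array(G)
    _require_convergent(A, what="mixing matrix")
    T = A.shape[0]
    W = solve_guarded(np.eye(T) - A, np.eye(T), "I - G")
    return MixingMatrix(W)


def simulate_dynamics(G, Gamma, z, eps, t_max: int) -> np.ndarray:
    """Iterate the recursive trait dynamics for ``t_max`` steps.

    Y(1) = Gamma z + eps;  Y(t) = Y(t-1) + G (Y(t-1) - Y(t-2)), Y(0) = 0.
    Returns an array of shape (t_max, T) with Y(1) .. Y(t_max).  Refuses to
    iterate when the spectral radius of ``G`` is >= 1 (non-convergent).
    """
    A = _graph_array(G)
    _require_convergent(A, NonConvergentDynamicsError, "recursive dynamics")
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    Gamma = np.atleast_2d(np.asarray(Gamma, dtype=float))
    z = np.asarray(z, dtype=float)
    eps = np.asarray(eps, dtype=float)
    base = Gamma @ z + eps
    T = A.shape[0]
    out = np.empty((t_max, T))
    y_prev2 = np.zeros(T)
    y_prev = base
    out[0] = y_prev
    for t in range(1, t_max):
        y = y_prev + A @ (y_prev - y_prev2)
        out[t] = y
        y_prev2, y_prev = y_prev, y
    return out


def equilibrium(G, Gamma, z, eps) -> np.ndarray:
    """Closed-form equilibrium ``(I - G)^{-1} (Gamma z + eps)``."""
    A = _graph_array(G)
    _require_convergent(A, what="equilibrium")
    Gamma = np.atleast_2d(np.asarray(Gamma, dtype=float))
    base = Gamma @ np.asarray(z, dtype=float) + np.asarray(eps, dtype=float)
    return solve_guarded(np.eye(A.shape[0]) - A, base, "I - G")


def steady_state_effects(G, Gamma) -> SnpEffectMatrix:
    """Total SNP effects ``B`` solving ``(I - G) B = Gamma`` (linear solve)."""
    A = _graph_array(G)
    _require_convergent(A, what="steady-state SNP effects")
    Gamma = np.atleast_2d(np.asarray(Gamma, dtype=float))
    B = solve_guarded(np.eye(A.shape[0]) - A, Gamma, "I - G")
    return SnpEffectMatrix(Gamma=Gamma, B=B)


def mr_network_from_graph(G) -> MREffectNetwork:
    """Forward map ``Theta = W Diag(w)^{-1}`` with ``W = (I - G)^{-1}``."""
    A = _graph_array(G)
    _require_convergent(A, what="MR-effect network")
    W = mixing_matrix(A).W
    w = np.diag(W)
    Theta = W / w[np.newaxis, :]
    np.fill_diagonal(Theta, 1.0)
    names = G.trait_names if isinstance(G, DirectEffectGraph) else []
    return MREffectNetwork(Theta, list(names))


def graph_from_mr_network(Theta) -> DirectEffectGraph:
    """Closed-form recovery of the direct-effect graph from an MR network.

    Steps: ``w_jj = (Theta^{-1})_jj``; ``W = Theta Diag(w)``;
    ``G = I - W^{-1} = I - Diag(w)^{-1} Theta^{-1}``.  The diagonal of the
    result is exactly zero by the rescaling; it is zeroed explicitly to kill
    rounding residue.  Theta^{-1} is computed explicitly because its diagonal
    is needed.
    """
    Th = _theta_array(Theta)
    cond = np.linalg.cond(Th)
    if not np.isfinite(cond) or cond > COND_ERROR:
        raise SingularMatrixError("MR-effect network is singular", cond)
    if cond > COND_WARN:
        warnings.warn(
            f"MR-effect network condition number {cond:.3e} exceeds {COND_WARN:.0e}",
            RuntimeWarning,
            stacklevel=2,
        )
    Th_inv = np.linalg.inv(Th)
    w = np.diag(Th_inv)
    if np.any(np.abs(w) < DEGENERATE_SCALE):
        raise DegenerateScalingError(
            "diagonal of Theta^{-1} contains (near-)zero entries; "
            "graph recovery scaling is degenerate"
        )
    G = np.eye(Th.shape[0]) - Th_inv / w[:, np.newaxis]
    np.fill_diagonal(G, 0.0)
    names = Theta.trait_names if isinstance(Theta, MREffectNetwork) else []
    return DirectEffectGraph(G, list(names))


def total_effect_network(G) -> TotalEffectNetwork:
    """Total-effect network ``Gtot = (I - G)^{-1} G`` (equals ``W - I``)."""
    A = _graph_array(G)
    rho = spectral_radius(A)
    if rho >= 1.0 - SPECTRAL_MARGIN:
        raise ModelViolationError(
            f"total-effect network is not well defined: spectral radius {rho:.6g} >= 1"
        )
    Gtot = solve_guarded(np.eye(A.shape[0]) - A, A, "I - G")
    return TotalEffectNetwork(Gtot)


def total_from_mr_network(Theta, t_diag) -> TotalEffectNetwork:
    """Total effects from the MR network: ``Gtot = Theta (Diag(t) + I) - I``.

    With ``t_diag = 0`` (no cycles) this reduces to ``Gtot = Theta - I``.
    """
    Th = _theta_array(Theta)
    t = np.asarray(t_diag, dtype=float)
    if t.shape != (Th.shape[0],):
        raise ValueError("t_diag must be a length-T vector")
    if not np.all(np.isfinite(t)):
        raise ValueError("t_diag must be finite")
    Gtot = Th * (t + 1.0)[np.newaxis, :] - np.eye(Th.shape[0])
    return TotalEffectNetwork(Gtot)
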