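"""Synthetic GWAS data generators for the trait-network model.

Two designs are provided, matching the two study conditions the package's
evaluation is built around.

Three-trait individual-level design
    30 independent biallelic SNPs (MAF 0.3, genotypes Binomial(2, 0.3) on
    additive 0/1/2 coding), split into groups of 8/7/15 SNPs acting
    exclusively on traits Y1/Y2/Y3, with direct effects drawn uniformly from
    (-0.2, -0.1) u (0.1, 0.2).  Residuals are multivariate normal with an
    AR(1) correlation of 0.4 (unit variances) standing in for shared
    unmeasured confounding.  Traits are the equilibrium
    ``Y = (I - G)^{-1} (Gamma Z + eps)``; marginal per-SNP OLS of each trait
    on each SNP yields the summary panel.  Two stock graphs are shipped: an
    acyclic one (Y3 -> Y1 at 0.2, Y3 -> Y2 at 0.1) and a cyclic one
    (Y3 -> Y1 at 0.5, Y1 -> Y2 at 0.05, Y2 -> Y3 at 0.5).

Six-trait summary-level design
    Summary statistics are generated directly: per-SNP direct effects
    N(0, 0.1^2) on exactly one assigned trait, total effects
    ``B = (I - G)^{-1} Gamma``, and observed estimates
    ``B_hat = B + S * E`` with matrix-normal noise E (SNP-side block LD R,
    trait-side overlap P).  The stock graph mirrors a cardiometabolic
    network over BMI, LDL, SBP, CAD, AF and Stroke, including a CAD <-> AF
    feedback loop; edge magnitudes are configurable.  The standard-error
    template is synthesized as ``se = 1 / sqrt(2 f (1 - f) n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CorrelationStructure, SummaryPanel
from .exceptions import ModelViolationError, MonomorphicVariantError
from .network import is_admissible, solve_guarded

#: Stock three-trait graphs: entry (i, j) is the direct effect of Yj+1 on Yi+1.
ACYCLIC_G = np.array(
    [
        [0.0, 0.0, 0.2],
        [0.0, 0.0, 0.1],
        [0.0, 0.0, 0.0],
    ]
)

CYCLIC_G = np.array(
    [
        [0.0, 0.0, 0.5],
        [0.05, 0.0, 0.0],
        [0.0, 0.5, 0.0],
    ]
)

SIX_TRAIT_NAMES = ["BMI", "LDL", "SBP", "CAD", "AF", "Stroke"]


def six_trait_graph(scale: float = 1.0) -> np.ndarray:
    """Stock cardiometabolic 6-trait direct-effect graph (CAD <-> AF cycle).

    Edge magnitudes are synthetic (chosen in a realistic range for
    standardized complex-trait effects); ``scale`` rescales all of them.
    """
    names = SIX_TRAIT_NAMES
    G = np.zeros((6, 6))
    edges = {
        ("SBP", "CAD"): 0.4,
        ("LDL", "CAD"): 0.35,
        ("AF", "CAD"): 0.15,
        ("BMI", "AF"): 0.3,
        ("CAD", "AF"): 0.25,
        ("SBP", "Stroke"): 0.3,
        ("AF", "Stroke"): 0.35,
    }
    for (src, dst), val in edges.items():
        G[names.index(dst), names.index(src)] = val * scale
    return G


def ar1_correlation(T: int, rho: float) -> np.ndarray:
    idx = np.arange(T)
    return rho ** np.abs(idx[:, None] - idx[None, :])


# ---------------------------------------------------------------------------
# GWAS regression
# ---------------------------------------------------------------------------


def gwas_ols(y, z):
    """Simple-regression slope of ``y`` on genotype ``z`` and its classical SE."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    zc = z - z.mean()
    sxx = float(zc @ zc)
    if sxx == 0.0:
        raise MonomorphicVariantError("genotype vector has zero variance")
    yc = y - y.mean()
    sxy = float(yc @ zc)
    beta = sxy / sxx
    rss = max(float(yc @ yc) - beta * sxy, 0.0)
    se = np.sqrt(rss / ((n - 2) * sxx))
    return beta, se


def gwas_matrix(Y: np.ndarray, Z: np.ndarray):
    """Vectorized per-SNP marginal OLS: each trait row of ``Y`` (T x N) on
    each genotype row of ``Z`` (S x N).  Returns (beta, se), both T x S."""
    n = Y.shape[1]
    Zc = Z - Z.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("sn,sn->s", Zc, Zc)
    if np.any(sxx == 0.0):
        raise MonomorphicVariantError("monomorphic SNP in genotype matrix")
    sxy = Yc @ Zc.T
    syy = np.einsum("tn,tn->t", Yc, Yc)
    beta = sxy / sxx[None, :]
    rss = np.maximum(syy[:, None] - beta * sxy, 0.0)
    se = np.sqrt(rss / ((n - 2) * sxx[None, :]))
    return beta, se


# ---------------------------------------------------------------------------
# Three-trait individual-level design
# ---------------------------------------------------------------------------


@dataclass
class ThreeTraitDesign:
    """Study conditions of the three-trait individual-level simulation."""

    G: np.ndarray = field(default_factory=lambda: ACYCLIC_G.copy())
    n_individuals: int = 50_000
    group_sizes: tuple = (8, 7, 15)
    maf: float = 0.3
    effect_low: float = 0.1
    effect_high: float = 0.2
    ar1_corr: float = 0.4
    error_sd: float = 1.0

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (len(self.group_sizes),) * 2:
            raise ValueError("G must be T x T with T = len(group_sizes)")
        if not is_admissible(self.G):
            raise ModelViolationError("design graph is not admissible")

    @property
    def n_traits(self) -> int:
        return self.G.shape[0]

    @property
    def n_snps(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def error_cov(self) -> np.ndarray:
        return (self.error_sd**2) * ar1_correlation(self.n_traits, self.ar1_corr)

    def draw_gamma(self, rng: np.random.Generator) -> np.ndarray:
        """Block-exclusive direct SNP effects, uniform on
        (-high, -low) u (low, high)."""
        Gamma = np.zeros((self.n_traits, self.n_snps))
        start = 0
        for t, size in enumerate(self.group_sizes):
            mags = rng.uniform(self.effect_low, self.effect_high, size)
            signs = rng.choice([-1.0, 1.0], size)
            Gamma[t, start : start + size] = mags * signs
            start += size
        return Gamma


def simulate_three_trait(
    design: ThreeTraitDesign,
    rng: np.random.Generator,
    return_individual: bool = False,
):
    """Generate one replicate of the individual-level design.

    Returns ``(panel, truth)`` where ``truth`` holds the drawn ``Gamma``,
    the design graph, and the realized per-trait proportion of phenotypic
    variance explained by the genetic component.  With
    ``return_individual=True``, the genotype and trait matrices are included.
    """
    T, S, N = design.n_traits, design.n_snps, design.n_individuals
    Z = rng.binomial(2, design.maf, size=(S, N)).astype(float)
    Gamma = design.draw_gamma(rng)
    L = np.linalg.cholesky(design.error_cov)
    eps = L @ rng.standard_normal((T, N))
    I_minus_G = np.eye(T) - design.G
    genetic = solve_guarded(I_minus_G, Gamma @ Z, "I - G")
    Y = genetic + solve_guarded(I_minus_G, eps, "I - G")
    beta, se = gwas_matrix(Y, Z)
    panel = SummaryPanel(
        beta=beta,
        se=se,
        n=np.full(T, N),
        trait_names=[f"Y{i + 1}" for i in range(T)],
    )
    truth = {
        "G": design.G.copy(),
        "Gamma": Gamma,
        "variance_explained": genetic.var(axis=1) / Y.var(axis=1),
    }
    if return_individual:
        truth["Z"] = Z
        truth["Y"] = Y
    return panel, truth


def variance_explained(G, Gamma, maf: float, error_cov) -> np.ndarray:
    """Analytic per-trait proportion of phenotypic variance that is genetic.

    For trait i: ``sum_k (W Gamma)_ik^2 * 2 f (1 - f)`` over
    that plus ``(W Sigma_e W')_ii``, with ``W = (I - G)^{-1}``.
    """
    G = np.asarray(G, dtype=float)
    Gamma = np.atleast_2d(np.asarray(Gamma, dtype=float))
    T = G.shape[0]
    W = solve_guarded(np.eye(T) - G, np.eye(T), "I - G")
    WG = W @ Gamma
    var_g = (WG**2).sum(axis=1) * 2.0 * maf * (1.0 - maf)
    var_e = np.diag(W @ np.asarray(error_cov, dtype=float) @ W.T)
    total = var_g + var_e
    out = np.zeros(T)
    nz = total > 0
    out[nz] = var_g[nz] / total[nz]
    return out


def expected_variance_explained(design: ThreeTraitDesign) -> np.ndarray:
    """Closed-form expectation of :func:`variance_explained` over effect draws.

    Uses ``E[gamma^2] = (high^3 - low^3) / (3 (high - low))`` for the
    two-sided uniform effect law.
    """
    lo, hi = design.effect_low, design.effect_high
    e_gamma2 = (hi**3 - lo**3) / (3.0 * (hi - lo))
    Gamma2 = np.zeros((design.n_traits, design.n_snps))
    start = 0
    for t, size in enumerate(design.group_sizes):
        Gamma2[t, start : start + size] = e_gamma2
        start += size
    T = design.n_traits
    W = solve_guarded(np.eye(T) - design.G, np.eye(T), "I - G")
    var_g = ((W**2) @ Gamma2).sum(axis=1) * 2.0 * design.maf * (1.0 - design.maf)
    var_e = np.diag(W @ design.error_cov @ W.T)
    return var_g / (var_g + var_e)


# ---------------------------------------------------------------------------
# Summary-level design
# ---------------------------------------------------------------------------


@dataclass
class SummaryLevelDesign:
    """Study conditions of the summary-level simulation."""

    G: np.ndarray = field(default_factory=lambda: six_trait_graph())
    trait_names: list[str] = field(default_factory=lambda: list(SIX_TRAIT_NAMES))
    n: np.ndarray = field(
        default_factory=lambda: np.array(
            [700_000, 400_000, 750_000, 180_000, 1_000_000, 440_000], dtype=float
        )
    )
    n_snps: int = 1056
    n_blocks: int = 392
    gamma_sd: float = 0.1
    maf_range: tuple = (0.05, 0.5)
    block_corr: float = 0.5
    P: np.ndarray | None = None
    snp_trait_assignment: np.ndarray | None = None

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        T = self.G.shape[0]
        if len(self.trait_names) != T or len(self.n) != T:
            raise ValueError("trait_names and n must match G")
        if not is_admissible(self.G):
            raise ModelViolationError("design graph is not admissible")
        if self.P is None:
            self.P = np.eye(T)
        if self.n_blocks > self.n_snps:
            raise ValueError("cannot have more LD blocks than SNPs")

    @property
    def n_traits(self) -> int:
        return self.G.shape[0]

    def block_index(self) -> np.ndarray:
        """Deterministic block labels: sizes as even as possible."""
        base = self.n_snps // self.n_blocks
        rem = self.n_snps % self.n_blocks
        sizes = [base + (1 if b < rem else 0) for b in range(self.n_blocks)]
        return np.repeat(np.arange(self.n_blocks), sizes)

    def assignment(self) -> np.ndarray:
        """SNP -> trait assignment (round-robin by default)."""
        if self.snp_trait_assignment is not None:
            a = np.asarray(self.snp_trait_assignment, dtype=int)
            if a.shape != (self.n_snps,):
                raise ValueError("snp_trait_assignment must have one entry per SNP")
            return a
        return np.arange(self.n_snps) % self.n_traits


def build_ld_structure(
    design: SummaryLevelDesign, rng: np.random.Generator | None = None
) -> CorrelationStructure:
    """Block-diagonal LD with AR(1)-decaying within-block correlation."""
    blocks = design.block_index()
    S = design.n_snps
    R = np.eye(S)
    for b in range(design.n_blocks):
        idx = np.flatnonzero(blocks == b)
        if len(idx) > 1:
            R[np.ix_(idx, idx)] = ar1_correlation(len(idx), design.block_corr)
    return CorrelationStructure(R, design.P, block_index=blocks)


def simulate_summary_level(
    design: SummaryLevelDesign,
    rng: np.random.Generator,
    structure: CorrelationStructure | None = None,
    noise: bool = True,
):
    """Generate one replicate of the summary-level design.

    Returns ``(panel, structure, truth)``.  Pass a prebuilt ``structure`` to
    share LD across replicates; ``noise=False`` returns the exact total
    effects (the noiseless limit S -> 0 of the observation model, useful as
    an oracle input).
    """
    if structure is None:
        structure = build_ld_structure(design)
    T, S = design.n_traits, design.n_snps
    assign = design.assignment()
    maf = rng.uniform(*design.maf_range, S)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * design.n[:, None])
    Gamma = np.zeros((T, S))
    Gamma[assign, np.arange(S)] = rng.normal(0.0, design.gamma_sd, S)
    B = solve_guarded(np.eye(T) - design.G, Gamma, "I - G")
    if noise:
        from .inference import _MatrixNormalSampler

        E = _MatrixNormalSampler(structure).draw(rng)  # SNPs x traits
        beta = B + se * E.T
    else:
        beta = B.copy()
    panel = SummaryPanel(
        beta=beta,
        se=se,
        n=design.n.copy(),
        trait_names=list(design.trait_names),
        block_index=structure.block_index,
    )
    truth = {"G": design.G.copy(), "Gamma": Gamma, "B": B, "maf": maf}
    return panel, structure, truth
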