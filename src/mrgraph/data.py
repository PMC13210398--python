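"""In-memory containers for GWAS summary statistics and pipeline results.

Orientation convention: effect and standard-error matrices are traits x SNPs
throughout the package; the matrix-normal perturbation transposes to
SNPs x traits internally (SNP-side LD covariance, trait-side overlap
covariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError


@dataclass
class SummaryPanel:
    """Per-trait GWAS summary statistics aligned over a common SNP set.

    Attributes
    ----------
    beta : (T, S) effect estimates (one row per trait).
    se : (T, S) standard errors, strictly positive.
    n : length-T GWAS sample sizes.
    snp_ids, trait_names : labels.
    block_index : length-S LD-block label per SNP (singleton blocks by default).
    """

    beta: np.ndarray
    se: np.ndarray
    n: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    trait_names: list[str] = field(default_factory=list)
    block_index: np.ndarray | None = None

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.se = np.atleast_2d(np.asarray(self.se, dtype=float))
        if self.beta.shape != self.se.shape:
            raise ValidationError("beta and se must have matching shapes")
        if np.any(self.se <= 0) or not np.all(np.isfinite(self.se)):
            raise ValidationError("standard errors must be finite and > 0")
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("effect estimates must be finite")
        self.n = np.asarray(self.n, dtype=float)
        if self.n.shape != (self.n_traits,):
            raise ValidationError("n must be a length-T vector of sample sizes")
        if not self.snp_ids:
            self.snp_ids = [f"rs{k + 1}" for k in range(self.n_snps)]
        if not self.trait_names:
            self.trait_names = [f"Y{i + 1}" for i in range(self.n_traits)]
        if len(self.snp_ids) != self.n_snps or len(self.trait_names) != self.n_traits:
            raise ValidationError("label lengths do not match matrix dimensions")
        if self.block_index is None:
            self.block_index = np.arange(self.n_snps)
        else:
            self.block_index = np.asarray(self.block_index)
            if self.block_index.shape != (self.n_snps,):
                raise ValidationError("block_index must have one entry per SNP")

    @property
    def n_traits(self) -> int:
        return self.beta.shape[0]

    @property
    def n_snps(self) -> int:
        return self.beta.shape[1]

    @property
    def z(self) -> np.ndarray:
        """Z-score matrix, traits x SNPs."""
        return self.beta / self.se

    def with_beta(self, beta: np.ndarray) -> "SummaryPanel":
        """Copy of the panel with a replacement effect matrix (same se/n)."""
        return SummaryPanel(
            beta=beta,
            se=self.se,
            n=self.n,
            snp_ids=list(self.snp_ids),
            trait_names=list(self.trait_names),
            block_index=self.block_index,
        )


def _check_correlation(M: np.ndarray, name: str, tol: float = 1e-6) -> np.ndarray:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != M.shape[1]:
        raise ValidationError(f"{name} must be square")
    if np.max(np.abs(M - M.T)) > tol:
        raise ValidationError(f"{name} must be symmetric")
    if np.max(np.abs(np.diag(M) - 1.0)) > tol:
        raise ValidationError(f"{name} must have unit diagonal")
    return M


@dataclass
class CorrelationStructure:
    """SNP-side LD matrix ``R`` (block-diagonal) and trait-side correlation
    matrix ``P`` (GWAS sample overlap)."""

    R: np.ndarray
    P: np.ndarray
    block_index: np.ndarray | None = None

    def __post_init__(self):
        self.R = _check_correlation(self.R, "LD matrix R")
        self.P = _check_correlation(self.P, "trait correlation matrix P")
        if self.block_index is None:
            self.block_index = np.arange(self.R.shape[0])
        else:
            self.block_index = np.asarray(self.block_index)
            if self.block_index.shape != (self.R.shape[0],):
                raise ValidationError("block_index must have one entry per SNP")

    @classmethod
    def identity(cls, n_snps: int, n_traits: int) -> "CorrelationStructure":
        return cls(np.eye(n_snps), np.eye(n_traits))

    def blocks(self):
        """Yield (snp_indices, submatrix) per LD block, in first-seen order."""
        seen: dict = {}
        for k, b in enumerate(self.block_index):
            seen.setdefault(b, []).append(k)
        for b, idx in seen.items():
            idx = np.asarray(idx)
            yield idx, self.R[np.ix_(idx, idx)]


@dataclass
class PairSummary:
    """Summary statistics for one ordered exposure -> outcome pair."""

    snp_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    n_exposure: float
    n_outcome: float

    def __post_init__(self):
        arrays = {}
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float).ravel()
            setattr(self, name, arrays[name])
        lengths = {a.shape[0] for a in arrays.values()} | {len(self.snp_ids)}
        if len(lengths) != 1:
            raise ValidationError("pair summary fields must have equal lengths")
        if np.any(arrays["se_exposure"] <= 0) or np.any(arrays["se_outcome"] <= 0):
            raise ValidationError("standard errors must be > 0")

    @property
    def n_ivs(self) -> int:
        return len(self.snp_ids)


def pair_from_panel(panel: SummaryPanel, exposure: int, outcome: int, snps) -> PairSummary:
    """Extract an exposure->outcome :class:`PairSummary` from a panel."""
    snps = np.asarray(snps, dtype=int)
    return PairSummary(
        snp_ids=[panel.snp_ids[k] for k in snps],
        beta_exposure=panel.beta[exposure, snps],
        se_exposure=panel.se[exposure, snps],
        beta_outcome=panel.beta[outcome, snps],
        se_outcome=panel.se[outcome, snps],
        n_exposure=float(panel.n[exposure]),
        n_outcome=float(panel.n[outcome]),
    )


@dataclass
class IVAssignment:
    """Instrument sets per ordered trait pair.

    ``sets[(j, i)]`` holds the SNP indices instrumenting exposure ``j`` when
    estimating the MR effect of trait j on trait i.  ``mode`` records the
    screening strategy ('pair', 'max' or 'aug').
    """

    mode: str
    sets: dict

    def __post_init__(self):
        if self.mode not in {"pair", "max", "aug"}:
            raise ValueError("mode must be one of 'pair', 'max', 'aug'")
        self.sets = {
            key: np.asarray(sorted(val), dtype=int) for key, val in self.sets.items()
        }


@dataclass
class PerturbationEnsemble:
    """Stack of graph estimates from the data-perturbation bootstrap."""

    G_stack: np.ndarray  # (B_ok, T, T), successful replicates only
    G_mean: np.ndarray
    G_sd: np.ndarray
    p_values: np.ndarray
    n_requested: int
    n_failed: int
    flags: list = field(default_factory=list)
    mode: str = "aug"
    trait_names: list[str] = field(default_factory=list)
    reference_graph: object = None
    spectral_warnings: int = 0

    @property
    def n_ok(self) -> int:
        return self.G_stack.shape[0]
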