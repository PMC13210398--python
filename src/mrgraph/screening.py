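"""Instrument screening for bidirectional MR over a trait network.

Three strategies of increasing network awareness, all operating on a pool of
LD-independent SNPs significantly associated (default p < 5e-8) with at
least one trait of each pair:

* ``pair`` -- Steiger-style filtering per pair: a SNP significant for both
  traits instruments only the trait with which its (squared) correlation is
  stronger.  Blind to the rest of the network, so SNPs acting through a
  shared upstream trait can leak in as (correlated-pleiotropy) instruments.
* ``max`` -- global pruning: a SNP instruments only the trait with the
  strongest association among all traits it is significantly associated
  with.  Robust but conservative; it discards instruments that are in fact
  valid for a given pair.
* ``aug`` -- network-aware augmentation: starting from the ``max`` sets, a
  SNP excluded from the pair (j -> i) is re-admitted iff, for every trait l
  that is significantly associated with the SNP and more strongly than the
  exposure j, deleting node j from a reference direct-effect graph leaves
  no directed path from l to the outcome i.  The reference graph is a
  Bonferroni-thresholded first-pass estimate obtained with ``max``
  screening.

Association strength is compared on the squared-correlation proxy
``r^2 = z^2 / (z^2 + n - 2)`` so that traits with unequal GWAS sample sizes
are comparable (a Steiger-type operationalization); exact ties break to the
lower trait index and are logged.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np
from scipy import stats

from .data import CorrelationStructure, IVAssignment, SummaryPanel
from .exceptions import MissingSummaryError

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-8
LD_PRUNE_R = 0.1


# ---------------------------------------------------------------------------
# Association strength and significance
# ---------------------------------------------------------------------------


def strength_matrix(panel: SummaryPanel) -> np.ndarray:
    """Squared-correlation proxy ``r^2 = z^2 / (z^2 + n - 2)``, traits x SNPs."""
    z2 = panel.z**2
    return z2 / (z2 + (panel.n - 2.0)[:, np.newaxis])


def association_strength(panel: SummaryPanel, snp: int, trait: int) -> float:
    """Strength of one SNP-trait association on the r^2 scale."""
    try:
        z = panel.beta[trait, snp] / panel.se[trait, snp]
        n = panel.n[trait]
    except IndexError as exc:
        raise MissingSummaryError(
            f"no summary entry for trait {trait}, snp {snp}"
        ) from exc
    return float(z**2 / (z**2 + n - 2.0))


def pvalue_matrix(panel: SummaryPanel) -> np.ndarray:
    """Two-sided normal p-values of the GWAS z-scores, traits x SNPs."""
    return 2.0 * stats.norm.sf(np.abs(panel.z))


def _stronger(strength, a: int, b: int, snp: int) -> bool:
    """Whether trait ``a`` is more strongly associated with ``snp`` than ``b``
    (exact ties break to the lower trait index, logged)."""
    sa, sb = strength[a, snp], strength[b, snp]
    if sa == sb:
        logger.info(
            "exact strength tie for snp %d between traits %d and %d; "
            "breaking to lower index",
            snp,
            a,
            b,
        )
        return a < b
    return sa > sb


# ---------------------------------------------------------------------------
# Candidate pools (significance + LD pruning)
# ---------------------------------------------------------------------------


def _ld_prune(candidates: np.ndarray, pmin: np.ndarray, structure: CorrelationStructure):
    """Greedy within-block pruning: keep smaller-p SNPs first, drop SNPs with
    |r| >= 0.1 against any kept SNP of the same block."""
    keep: list[int] = []
    by_block: dict = {}
    for k in candidates:
        by_block.setdefault(structure.block_index[k], []).append(k)
    for block_snps in by_block.values():
        block_snps = sorted(block_snps, key=lambda k: (pmin[k], k))
        kept_in_block: list[int] = []
        for k in block_snps:
            if all(abs(structure.R[k, other]) < LD_PRUNE_R for other in kept_in_block):
                kept_in_block.append(k)
        keep.extend(kept_in_block)
    return np.asarray(sorted(keep), dtype=int)


def build_pools(
    panel: SummaryPanel,
    structure: CorrelationStructure | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    pvals: np.ndarray | None = None,
) -> dict:
    """Candidate instrument pool per unordered trait pair.

    A SNP enters the (i, j) pool when it is significant for at least one of
    the two traits; pools are LD-pruned when a non-trivial LD structure is
    supplied.
    """
    if pvals is None:
        pvals = pvalue_matrix(panel)
    sig = pvals < p_threshold
    T = panel.n_traits
    prune = structure is not None and not np.array_equal(
        structure.R, np.eye(structure.R.shape[0])
    )
    pools = {}
    for a, b in itertools.combinations(range(T), 2):
        candidates = np.flatnonzero(sig[a] | sig[b])
        if prune and len(candidates):
            pmin = np.minimum(pvals[a], pvals[b])
            candidates = _ld_prune(candidates, pmin, structure)
        pools[(a, b)] = candidates
    return pools


# ---------------------------------------------------------------------------
# ScreenPair / ScreenMax / ScreenAug
# ---------------------------------------------------------------------------


def screen_pair(panel, pools, p_threshold=DEFAULT_P_THRESHOLD, *, pvals=None, strength=None):
    """Steiger-style pairwise assignment.

    Returns ``sets[(j, i)]`` = SNPs instrumenting exposure j against
    outcome i: SNPs significant for only one trait go to that trait; SNPs
    significant for both go to the more strongly associated trait.
    """
    if pvals is None:
        pvals = pvalue_matrix(panel)
    if strength is None:
        strength = strength_matrix(panel)
    sig = pvals < p_threshold
    sets: dict = {}
    for (a, b), pool in pools.items():
        to_a, to_b = [], []
        for k in pool:
            if sig[a, k] and sig[b, k]:
                (to_a if _stronger(strength, a, b, k) else to_b).append(k)
            elif sig[a, k]:
                to_a.append(k)
            elif sig[b, k]:
                to_b.append(k)
        sets[(a, b)] = np.asarray(to_a, dtype=int)  # exposure a -> outcome b
        sets[(b, a)] = np.asarray(to_b, dtype=int)
    return sets


def _best_trait(strength: np.ndarray, sig: np.ndarray, snp: int) -> int:
    """Trait with the strongest association among traits where ``snp`` is
    significant (ties to the lower index)."""
    traits = np.flatnonzero(sig[:, snp])
    if len(traits) == 0:
        return -1
    return int(traits[np.argmax(strength[traits, snp])])  # argmax ties -> first


def screen_max(panel, pools, pair_sets, p_threshold=DEFAULT_P_THRESHOLD, *, pvals=None, strength=None):
    """Global pruning: keep a SNP in the (j -> i) set only when the exposure
    j is its strongest significantly-associated trait across *all* traits."""
    if pvals is None:
        pvals = pvalue_matrix(panel)
    if strength is None:
        strength = strength_matrix(panel)
    sig = pvals < p_threshold
    sets = {}
    for (j, i), snps in pair_sets.items():
        sets[(j, i)] = np.asarray(
            [k for k in snps if _best_trait(strength, sig, k) == j], dtype=int
        )
    return sets


def has_directed_path(graph: nx.DiGraph, source, target) -> bool:
    """Whether a directed path source -> ... -> target exists (cycles allowed).

    ``source == target`` counts as reachable (trivial path).
    """
    if source not in graph or target not in graph:
        return source == target
    return nx.has_path(graph, source, target)


def _reachability_without(graph: nx.DiGraph, removed: int, T: int) -> np.ndarray:
    """(T, T) boolean reachability (diagonal True) after deleting one node."""
    sub = graph.copy()
    if removed in sub:
        sub.remove_node(removed)
    reach = np.zeros((T, T), dtype=bool)
    np.fill_diagonal(reach, True)
    for u in range(T):
        if u == removed or u not in sub:
            continue
        for v in nx.descendants(sub, u):
            reach[u, v] = True
    return reach


def screen_aug(
    panel,
    pools,
    pair_sets,
    max_sets,
    reference: nx.DiGraph | None,
    p_threshold=DEFAULT_P_THRESHOLD,
    *,
    pvals=None,
    strength=None,
):
    """Network-aware augmentation of the ScreenMax sets.

    A SNP in ``pair_sets[(j, i)] \\ max_sets[(j, i)]`` is re-admitted iff for
    every trait l (significantly associated with the SNP, more strongly than
    the exposure j) there is no directed path l -> i once node j is removed
    from the reference graph.  An empty/None reference graph re-admits
    everything, reducing to the ScreenPair sets.
    """
    if pvals is None:
        pvals = pvalue_matrix(panel)
    if strength is None:
        strength = strength_matrix(panel)
    sig = pvals < p_threshold
    T = panel.n_traits
    if reference is None:
        reference = nx.DiGraph()
    reach_cache: dict[int, np.ndarray] = {}
    sets = {}
    for (j, i), snps in pair_sets.items():
        base = set(max_sets[(j, i)].tolist())
        aug = set(base)
        if j not in reach_cache:
            reach_cache[j] = _reachability_without(reference, j, T)
        reach = reach_cache[j]
        for k in snps:
            if k in base:
                continue
            qualifying = [
                l
                for l in range(T)
                if l != j and sig[l, k] and _stronger(strength, l, j, k)
            ]
            if all(not reach[l, i] for l in qualifying):
                aug.add(int(k))
        sets[(j, i)] = np.asarray(sorted(aug), dtype=int)
    return sets


# ---------------------------------------------------------------------------
# Reference graph and one-call assignment
# ---------------------------------------------------------------------------


def reference_graph_from_pvalues(p_values: np.ndarray, alpha: float) -> nx.DiGraph:
    """Directed trait graph with an edge j -> i for each significant entry
    ``p_values[i, j] < alpha`` (self-edges excluded)."""
    p = np.asarray(p_values, dtype=float)
    T = p.shape[0]
    graph = nx.DiGraph()
    graph.add_nodes_from(range(T))
    for i in range(T):
        for j in range(T):
            if i != j and p[i, j] < alpha:
                graph.add_edge(j, i)
    return graph


def build_assignment(
    panel: SummaryPanel,
    mode: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    structure: CorrelationStructure | None = None,
    reference: nx.DiGraph | None = None,
) -> IVAssignment:
    """Screen instruments for every ordered trait pair with one strategy."""
    pvals = pvalue_matrix(panel)
    strength = strength_matrix(panel)
    pools = build_pools(panel, structure, p_threshold, pvals=pvals)
    pair_sets = screen_pair(panel, pools, p_threshold, pvals=pvals, strength=strength)
    if mode == "pair":
        return IVAssignment("pair", pair_sets)
    max_sets = screen_max(
        panel, pools, pair_sets, p_threshold, pvals=pvals, strength=strength
    )
    if mode == "max":
        return IVAssignment("max", max_sets)
    if mode == "aug":
        aug_sets = screen_aug(
            panel,
            pools,
            pair_sets,
            max_sets,
            reference,
            p_threshold,
            pvals=pvals,
            strength=strength,
        )
        return IVAssignment("aug", aug_sets)
    raise ValueError(f"unknown screening mode {mode!r}")
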