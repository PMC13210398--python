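"""Replicated simulation studies: rejection rates, bias, RMSE.

These drivers tie the simulators to the perturbation-inference pipeline and
aggregate over replicates.  When both 'max' and 'aug' screening are
requested, the ScreenMax ensemble doubles as the first pass whose
Bonferroni-thresholded p-values define the ScreenAug reference graph, so
the two modes share work and use identical instrument pools per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CorrelationStructure
from .inference import PipelineConfig, run_pipeline
from .screening import reference_graph_from_pvalues
from .simulate import (
    SummaryLevelDesign,
    ThreeTraitDesign,
    build_ld_structure,
    simulate_summary_level,
    simulate_three_trait,
)


@dataclass
class StudyResult:
    """Per-mode stacks of p-value and point-estimate matrices."""

    p_stack: np.ndarray  # (reps, T, T)
    g_stack: np.ndarray  # (reps, T, T)
    G_true: np.ndarray
    variance_explained: np.ndarray | None = None  # (reps, T), realized
    failures: list = field(default_factory=list)

    def rejection_rate(self, alpha: float) -> np.ndarray:
        """Element-wise proportion of replicates with p < alpha."""
        return (self.p_stack < alpha).mean(axis=0)

    def bias(self) -> np.ndarray:
        return self.g_stack.mean(axis=0) - self.G_true

    def rmse(self) -> np.ndarray:
        return np.sqrt(((self.g_stack - self.G_true) ** 2).mean(axis=0))


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def three_trait_study(
    design: ThreeTraitDesign,
    modes,
    n_reps: int,
    b_reps: int = 100,
    seed=None,
    p_threshold: float = 5e-8,
) -> dict:
    """Run the individual-level design for ``n_reps`` replicates per mode.

    Returns ``{mode: StudyResult}``.  Replicates where the pipeline fails
    outright contribute p = 1 everywhere (no rejection) and are recorded.
    """
    modes = list(modes)
    T = design.n_traits
    ss = np.random.SeedSequence(seed)
    acc = {m: {"p": [], "g": [], "fail": []} for m in modes}
    ve = []
    for rep in range(n_reps):
        sim_ss, pipe_ss = ss.spawn(2)
        rng = np.random.default_rng(sim_ss)
        panel, truth = simulate_three_trait(design, rng)
        ve.append(truth["variance_explained"])
        ensembles = _run_modes(panel, None, modes, b_reps, pipe_ss, p_threshold)
        for m in modes:
            _collect(acc[m], ensembles.get(m), T, rep)
    out = {}
    for m in modes:
        out[m] = StudyResult(
            p_stack=np.asarray(acc[m]["p"]),
            g_stack=np.asarray(acc[m]["g"]),
            G_true=design.G.copy(),
            variance_explained=np.asarray(ve),
            failures=acc[m]["fail"],
        )
    return out


def summary_level_study(
    design: SummaryLevelDesign,
    modes,
    n_reps: int,
    b_reps: int = 100,
    seed=None,
    p_threshold: float = 5e-8,
) -> dict:
    """Run the summary-level design for ``n_reps`` replicates per mode."""
    modes = list(modes)
    T = design.n_traits
    structure = build_ld_structure(design)
    ss = np.random.SeedSequence(seed)
    acc = {m: {"p": [], "g": [], "fail": []} for m in modes}
    for rep in range(n_reps):
        sim_ss, pipe_ss = ss.spawn(2)
        rng = np.random.default_rng(sim_ss)
        panel, _, _ = simulate_summary_level(design, rng, structure=structure)
        ensembles = _run_modes(panel, structure, modes, b_reps, pipe_ss, p_threshold)
        for m in modes:
            _collect(acc[m], ensembles.get(m), T, rep)
    out = {}
    for m in modes:
        out[m] = StudyResult(
            p_stack=np.asarray(acc[m]["p"]),
            g_stack=np.asarray(acc[m]["g"]),
            G_true=design.G.copy(),
            failures=acc[m]["fail"],
        )
    return out


def _run_modes(
    panel,
    structure: CorrelationStructure | None,
    modes,
    b_reps: int,
    ss: np.random.SeedSequence,
    p_threshold: float,
) -> dict:
    """Run the requested screening modes on one replicate, sharing the
    ScreenMax ensemble with ScreenAug's reference-graph first pass."""
    T = panel.n_traits
    seeds = dict(zip(("pair", "max", "aug"), ss.spawn(3)))
    out = {}
    if "pair" in modes:
        out["pair"] = _try_run(panel, structure, "pair", b_reps, seeds["pair"], p_threshold)
    need_max = ("max" in modes) or ("aug" in modes)
    ens_max = None
    if need_max:
        ens_max = _try_run(panel, structure, "max", b_reps, seeds["max"], p_threshold)
        if "max" in modes:
            out["max"] = ens_max
    if "aug" in modes:
        reference = None
        if ens_max is not None:
            alpha = 0.05 / (T * (T - 1))
            reference = reference_graph_from_pvalues(ens_max.p_values, alpha)
        out["aug"] = _try_run(
            panel, structure, "aug", b_reps, seeds["aug"], p_threshold, reference
        )
    return out


def _try_run(panel, structure, mode, b_reps, seed, p_threshold, reference=None):
    config = PipelineConfig(mode=mode, p_threshold=p_threshold, b_reps=b_reps)
    try:
        return run_pipeline(panel, structure, config, seed=seed, reference=reference)
    except Exception as exc:  # replicate-level failure: no rejections
        return exc


def _collect(acc: dict, ensemble, T: int, rep: int):
    if ensemble is None or isinstance(ensemble, Exception):
        acc["p"].append(np.ones((T, T)))
        acc["g"].append(np.zeros((T, T)))
        if ensemble is not None:
            acc["fail"].append(f"replicate {rep}: {ensemble}")
        return
    acc["p"].append(ensemble.p_values)
    acc["g"].append(ensemble.G_mean)
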