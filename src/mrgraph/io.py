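"""File formats: summary panels, LD and correlation matrices, graphs, configs.

All tabular formats are TSV with explicit headers.  Floats are serialized at
17 significant digits so write -> read round-trips are lossless; matrices
carry trait/SNP labels and are aligned by name on load, never by position.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .data import CorrelationStructure, SummaryPanel
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# Summary panels
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ("snp", "beta", "se", "n")


def read_summary_panel(paths, trait_names=None) -> SummaryPanel:
    """Load per-trait GWAS TSV files (columns snp, beta, se, n; extras
    ignored) and align them over the SNP intersection.

    SNP order follows the first file; dropped SNPs are logged.
    """
    paths = [Path(p) for p in paths]
    if trait_names is None:
        trait_names = [p.stem for p in paths]
    if len(trait_names) != len(paths):
        raise ValidationError("one trait name per file required")
    tables = []
    for p in paths:
        df = pd.read_csv(p, sep="\t", float_precision="round_trip")
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"{p}: missing columns {missing}")
        bad = df.index[~(df["se"] > 0)]
        if len(bad):
            raise ValidationError(
                f"{p}: nonpositive standard error at row(s) {list(bad[:5])}"
            )
        if df["snp"].duplicated().any():
            raise ValidationError(f"{p}: duplicated SNP ids")
        tables.append(df.set_index("snp"))
    common = [s for s in tables[0].index if all(s in t.index for t in tables[1:])]
    if not common:
        raise ValidationError("no SNPs shared across all trait files")
    dropped = sum(len(t) - len(common) for t in tables)
    if dropped:
        logger.info("dropped %d non-shared SNP rows across %d files", dropped, len(paths))
    beta = np.array([t.loc[common, "beta"].to_numpy(float) for t in tables])
    se = np.array([t.loc[common, "se"].to_numpy(float) for t in tables])
    n = np.array([float(t["n"].iloc[0]) for t in tables])
    return SummaryPanel(beta=beta, se=se, n=n, snp_ids=list(common), trait_names=list(trait_names))


def write_summary_panel(panel: SummaryPanel, out_dir) -> list[Path]:
    """Write one TSV per trait (snp, beta, se, n); returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, name in enumerate(panel.trait_names):
        path = out_dir / f"{name}.tsv"
        df = pd.DataFrame(
            {
                "snp": panel.snp_ids,
                "beta": [_fmt(v) for v in panel.beta[t]],
                "se": [_fmt(v) for v in panel.se[t]],
                "n": [_fmt(panel.n[t])] * panel.n_snps,
            }
        )
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Labeled matrices (adjacency, correlation)
# ---------------------------------------------------------------------------


def write_matrix(M: np.ndarray, labels, path) -> Path:
    """Square matrix as TSV: header row of labels, first column = labels."""
    path = Path(path)
    M = np.asarray(M, dtype=float)
    with path.open("w") as fh:
        fh.write("name\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, M):
            fh.write(lab + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    return path


def read_matrix(path, labels=None):
    """Read a labeled square TSV matrix; optionally realign to ``labels``.

    Returns (matrix, labels).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column labels differ")
    if labels is not None:
        missing = [l for l in labels if l not in df.index]
        if missing:
            raise ValidationError(f"{path}: labels not found: {missing[:5]}")
        df = df.loc[list(labels), list(labels)]
    return df.to_numpy(float), list(df.index)


def read_ld(path, snp_ids) -> CorrelationStructure | np.ndarray:
    """Read an LD matrix aligned to ``snp_ids``.

    Accepts either a labeled square matrix TSV, or a 3-column pair list
    (snp_a, snp_b, r) whose connected components define the LD blocks.
    SNPs absent from the file get identity rows.  Returns the dense R
    together with inferred block labels as a tuple ``(R, block_index)``.
    """
    path = Path(path)
    S = len(snp_ids)
    pos = {s: k for k, s in enumerate(snp_ids)}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if set(header[:3]) >= {"snp_a", "snp_b", "r"} or header[:3] == ["snp_a", "snp_b", "r"]:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        R = np.eye(S)
        graph = nx.Graph()
        graph.add_nodes_from(range(S))
        for _, row in df.iterrows():
            a, b = row["snp_a"], row["snp_b"]
            if a not in pos or b not in pos:
                continue
            i, j = pos[a], pos[b]
            R[i, j] = R[j, i] = float(row["r"])
            graph.add_edge(i, j)
        blocks = np.empty(S, dtype=int)
        for label, comp in enumerate(nx.connected_components(graph)):
            for k in comp:
                blocks[k] = label
    else:
        M, labels = read_matrix(path)
        if np.max(np.abs(M - M.T)) > 1e-6:
            raise ValidationError(f"{path}: LD matrix is not symmetric")
        if np.max(np.abs(np.diag(M) - 1.0)) > 1e-6:
            raise ValidationError(f"{path}: LD matrix diagonal is not 1")
        lpos = {s: k for k, s in enumerate(labels)}
        R = np.eye(S)
        listed = [s for s in snp_ids if s in lpos]
        idx = np.array([pos[s] for s in listed], dtype=int)
        src = np.array([lpos[s] for s in listed], dtype=int)
        if len(idx):
            R[np.ix_(idx, idx)] = M[np.ix_(src, src)]
        graph = nx.Graph()
        graph.add_nodes_from(range(S))
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if R[idx[a], idx[b]] != 0.0:
                    graph.add_edge(idx[a], idx[b])
        blocks = np.empty(S, dtype=int)
        for label, comp in enumerate(nx.connected_components(graph)):
            for k in comp:
                blocks[k] = label
    return R, blocks


def read_trait_correlation(path, trait_names, zero_small: bool = False, small: float = 0.1):
    """Read the trait-overlap correlation matrix P, aligned by trait name.

    With ``zero_small=True``, off-diagonal entries with |rho| < 0.1 are
    zeroed on load (flagged option for weakly-correlated GWAS pairs).
    """
    P, _ = read_matrix(path, labels=trait_names)
    if zero_small:
        mask = (np.abs(P) < small) & ~np.eye(P.shape[0], dtype=bool)
        if mask.any():
            logger.info("zeroing %d small trait-correlation entries", int(mask.sum()))
            P = P.copy()
            P[mask] = 0.0
    return P


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------


def write_edge_list(G: np.ndarray, trait_names, path, se=None, p=None, alpha=None) -> Path:
    """Edge-list TSV (source, target, estimate[, se, p, bonferroni_significant])."""
    path = Path(path)
    T = len(trait_names)
    n_tests = T * (T - 1)
    rows = []
    for i in range(T):
        for j in range(T):
            if i == j:
                continue
            row = {"source": trait_names[j], "target": trait_names[i], "estimate": _fmt(G[i, j])}
            if se is not None:
                row["se"] = _fmt(se[i, j])
            if p is not None:
                row["p"] = _fmt(p[i, j])
                if alpha is not None:
                    row["bonferroni_significant"] = int(p[i, j] < alpha / n_tests)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def _as_digraph(G: np.ndarray, trait_names) -> nx.DiGraph:
    graph = nx.DiGraph()
    graph.add_nodes_from(trait_names)
    T = len(trait_names)
    for i in range(T):
        for j in range(T):
            if i != j and G[i, j] != 0.0:
                graph.add_edge(trait_names[j], trait_names[i], weight=float(G[i, j]))
    return graph


def export_dot(G: np.ndarray, trait_names, path) -> Path:
    """Minimal DOT export (node per trait, labeled weighted edges)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("digraph traits {\n")
        for name in trait_names:
            fh.write(f'  "{name}";\n')
        T = len(trait_names)
        for i in range(T):
            for j in range(T):
                if i != j and G[i, j] != 0.0:
                    fh.write(
                        f'  "{trait_names[j]}" -> "{trait_names[i]}" '
                        f'[label="{G[i, j]:.4g}"];\n'
                    )
        fh.write("}\n")
    return path


def export_graphml(G: np.ndarray, trait_names, path) -> Path:
    path = Path(path)
    nx.write_graphml(_as_digraph(G, trait_names), path)
    return path


# ---------------------------------------------------------------------------
# Run configuration and manifest
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML/JSON serializable)."""

    trait_files: list
    ld_file: str | None = None
    trait_correlation_file: str | None = None
    mode: str = "aug"
    p_threshold: float = 5e-8
    b_reps: int = 100
    bonferroni_alpha: float = 0.05
    seed: int = 0
    output_dir: str = "mrgraph_out"
    zero_small_trait_corr: bool = False

    def __post_init__(self):
        if self.mode not in {"pair", "max", "aug"}:
            raise ValidationError("mode must be one of 'pair', 'max', 'aug'")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValidationError("p_threshold must lie in (0, 1)")
        if self.b_reps < 1:
            raise ValidationError("b_reps must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(path, config: dict, seed, extra=None) -> Path:
    """Run manifest JSON: config echo, seed, package versions."""
    import networkx
    import numpy
    import pandas
    import scipy

    from . import __version__

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "mrgraph": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
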