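"""Host-gene association screen and term overrepresentation.

The procedure: globally normalize the gene x sample count matrix, keep
genes with at least ``min_tags`` detected, correlate each surviving gene
with the per-sample HERV-K env abundance (Pearson, screened on r^2 so both
signs pass), in clinical mode additionally require a fold change of at
least ``fold_change_threshold`` between case and control means, and test
the selected set for overrepresented annotation terms with a
hypergeometric upper-tail test under Benjamini-Hochberg control.

The overrepresentation test is implemented internally over a user-supplied
gene -> term table (GO-style or pathway-style maps are just different
tables), so the pipeline has no network dependence and is exactly testable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import global_normalize

__all__ = [
    "AssociationParams",
    "AssociationResult",
    "EnrichmentResult",
    "detection_filter",
    "correlate_with_env",
    "fold_change_filter",
    "enrich",
    "run_association",
    "read_count_matrix",
    "read_term_map",
]


@dataclass(frozen=True)
class AssociationParams:
    min_tags: int = 2
    r2_threshold: float = 0.5
    fold_change_threshold: float = 0.3
    fdr_q: float = 0.05
    per_sample_detection: bool = False  # strict: >= min_tags in every sample

    def __post_init__(self) -> None:
        if self.min_tags < 0:
            raise ValueError("min_tags must be >= 0")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.fold_change_threshold < 0:
            raise ValueError("fold_change_threshold must be >= 0")


@dataclass
class AssociationResult:
    gene: str
    r: float  # nan when undefined (zero variance)
    r2: float
    passes_detection: bool
    passes_r2: bool
    fold_change: float | None = None
    passes_fc: bool | None = None
    selected: bool = False


@dataclass
class EnrichmentResult:
    term: str
    k: int  # overlap of selected set with term
    K: int  # term size within universe
    n: int  # selected-set size
    N: int  # universe size
    p: float  # hypergeometric upper tail P[X >= k]
    q: float  # BH-adjusted


def detection_filter(
    matrix: pd.DataFrame, min_tags: int, per_sample: bool = False
) -> pd.DataFrame:
    """Keep genes with >= ``min_tags`` detected; order preserved.

    Default reading: detected in at least one sample (max across samples);
    ``per_sample`` demands the threshold in every sample.
    """
    if min_tags == 0:
        return matrix
    stat = matrix.min(axis=1) if per_sample else matrix.max(axis=1)
    return matrix.loc[stat >= min_tags]


def correlate_with_env(
    matrix: pd.DataFrame,
    env_abundance: pd.Series,
    params: AssociationParams,
) -> list[AssociationResult]:
    """Pearson correlation of every gene against the env abundance vector.

    Genes with zero variance get r = nan and fail the screen.  Passing is
    r^2 >= threshold regardless of sign.
    """
    if matrix.shape[1] < 3:
        raise ValueError("correlation needs >= 3 samples")
    if list(matrix.columns) != list(env_abundance.index):
        raise ValueError(
            "sample mismatch between count matrix and env abundance vector"
        )
    env = env_abundance.to_numpy(dtype=float)
    if np.unique(env).size < 2:
        raise ValueError("env abundance has < 2 distinct values")
    env_c = env - env.mean()
    env_ss = float(env_c @ env_c)

    data = matrix.to_numpy(dtype=float)
    centered = data - data.mean(axis=1, keepdims=True)
    gene_ss = (centered**2).sum(axis=1)
    results: list[AssociationResult] = []
    for gi, gene in enumerate(matrix.index):
        if gene_ss[gi] <= 0.0:
            results.append(
                AssociationResult(
                    gene=gene,
                    r=float("nan"),
                    r2=float("nan"),
                    passes_detection=True,
                    passes_r2=False,
                )
            )
            continue
        r = float(centered[gi] @ env_c / np.sqrt(gene_ss[gi] * env_ss))
        r = max(-1.0, min(1.0, r))
        results.append(
            AssociationResult(
                gene=gene,
                r=r,
                r2=r * r,
                passes_detection=True,
                passes_r2=r * r >= params.r2_threshold,
            )
        )
    return results


def fold_change_filter(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    threshold: float,
    case: str = "HIVpos",
    control: str = "HIVneg",
) -> pd.DataFrame:
    """Per-gene fold change |mean(case)/mean(control) - 1| and pass flag.

    Symmetric reading: 1.3x up and 0.7x down both give 0.3.  A control mean
    of zero with a positive case mean is flagged infinite and passes.
    """
    labels = group_labels.reindex(matrix.columns)
    if labels.isna().any():
        missing = list(labels[labels.isna()].index)
        raise ValueError(f"samples without group label: {missing}")
    case_cols = labels[labels == case].index
    ctl_cols = labels[labels == control].index
    if len(case_cols) == 0 or len(ctl_cols) == 0:
        raise ValueError("both groups need >= 1 sample")
    case_mean = matrix[case_cols].mean(axis=1)
    ctl_mean = matrix[ctl_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.abs(case_mean / ctl_mean - 1.0)
    fc = fc.where(~((ctl_mean == 0) & (case_mean > 0)), np.inf)
    fc = fc.where(~((ctl_mean == 0) & (case_mean == 0)), 0.0)
    passes = fc >= threshold
    return pd.DataFrame({"fold_change": fc, "passes_fc": passes})


def enrich(
    selected: set[str] | list[str],
    universe: set[str] | list[str],
    term_map: pd.DataFrame,
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of each term in the selected set.

    p = P[X >= k] for X ~ Hypergeom(N=len(universe), K=term size within the
    universe, n=len(selected)); q by Benjamini-Hochberg across all tested
    terms.  Sorted by (p, term).
    """
    selected_set = set(selected)
    universe_set = set(universe)
    offenders = sorted(selected_set - universe_set)
    if offenders:
        raise ValueError(f"selected genes outside universe: {offenders}")
    n = len(selected_set)
    N = len(universe_set)
    terms = (
        term_map[term_map["gene"].isin(universe_set)]
        .groupby("term")["gene"]
        .apply(set)
    )
    results: list[EnrichmentResult] = []
    for term, members in terms.items():
        K = len(members)
        k = len(members & selected_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(term=term, k=k, K=K, n=n, N=N, p=min(p, 1.0), q=1.0)
        )
    if results:
        pvals = np.array([r.p for r in results])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.term))
    return results


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_association(
    matrix: pd.DataFrame,
    env_abundance: pd.Series,
    term_map: pd.DataFrame,
    params: AssociationParams | None = None,
    group_labels: pd.Series | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full screen: normalize -> detect -> correlate -> (clinical only)
    fold-change -> enrich.

    ``group_labels`` switches on clinical mode.  Returns the per-gene result
    table and the enrichment table; with ``out_dir`` every intermediate and
    a parameter manifest are written as TSV/text.
    """
    params = params or AssociationParams()
    normalized = global_normalize(matrix)
    detected = detection_filter(
        matrix, params.min_tags, params.per_sample_detection
    )
    normalized = normalized.loc[detected.index]
    results = correlate_with_env(normalized, env_abundance, params)
    table = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "r": [r.r for r in results],
            "r2": [r.r2 for r in results],
            "passes_detection": True,
            "passes_r2": [r.passes_r2 for r in results],
        }
    ).set_index("gene")

    if group_labels is not None:
        fc = fold_change_filter(
            normalized, group_labels, params.fold_change_threshold
        )
        table["fold_change"] = fc["fold_change"]
        table["passes_fc"] = fc["passes_fc"]
        table["selected"] = table["passes_r2"] & table["passes_fc"]
    else:
        table["selected"] = table["passes_r2"]

    universe = list(table.index)
    selected = list(table.index[table["selected"]])
    enr = enrich(selected, universe, term_map)
    enr_table = pd.DataFrame(
        {
            "term": [e.term for e in enr],
            "k": [e.k for e in enr],
            "K": [e.K for e in enr],
            "n": [e.n for e in enr],
            "N": [e.N for e in enr],
            "p": [e.p for e in enr],
            "q": [e.q for e in enr],
        }
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        normalized.to_csv(out / "normalized_counts.tsv", sep="\t")
        table.to_csv(out / "association.tsv", sep="\t")
        table[table["selected"]].to_csv(out / "selected_genes.tsv", sep="\t")
        enr_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest = {
            "min_tags": params.min_tags,
            "r2_threshold": params.r2_threshold,
            "fold_change_threshold": params.fold_change_threshold,
            "fdr_q": params.fdr_q,
            "per_sample_detection": params.per_sample_detection,
            "clinical_mode": group_labels is not None,
            "n_genes_in": int(matrix.shape[0]),
            "n_genes_detected": int(detected.shape[0]),
            "n_selected": len(selected),
        }
        with open(out / "manifest.txt", "w") as fh:
            for key in sorted(manifest):
                fh.write(f"{key}\t{manifest[key]}\n")

    return table, enr_table


# -- table I/O --------------------------------------------------------------


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index.name = "gene"
    return m


def read_term_map(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype=str)
    if list(t.columns[:2]) != ["gene", "term"]:
        t.columns = ["gene", "term"] + list(t.columns[2:])
    return t[["gene", "term"]]
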