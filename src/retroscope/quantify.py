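"""Family and region abundance quantification and group comparison.

Family tag frequency: a family's percent share of all *unambiguously*
HERV-assigned tags in a sample (ambiguous tags excluded from the
denominator by default; a flag includes them as their own category).

Region frequency: per-region tag counts are first length-normalized
(tags per nt of annotated region, summed over the family's references)
and then rescaled to percent within the family — so a short LTR with dense
coverage outranks a long gag-pol with the same raw count.

Group comparison uses the two-sided Mann-Whitney U test, exact by full
enumeration of the C(n1+n2, n1) group assignments when both groups have at
most ``exact_threshold`` values (ties handled through midranks), and the
tie-corrected normal approximation with continuity correction above that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classify import Category
from .reference import ReferenceSet, RegionLabel, region_lengths

__all__ = [
    "AbundanceProfile",
    "GroupComparison",
    "family_frequencies",
    "region_frequencies",
    "build_profile",
    "global_normalize",
    "compare_groups",
    "write_profile",
]


@dataclass
class AbundanceProfile:
    """Per-sample family and region abundance summaries."""

    sample_id: str
    family_counts: dict[str, int] = field(default_factory=dict)
    family_freq: dict[str, float] = field(default_factory=dict)
    total_herv_tags: int = 0
    region_counts: dict[str, dict[RegionLabel, int]] = field(default_factory=dict)
    region_rate: dict[str, dict[RegionLabel, float]] = field(default_factory=dict)
    region_freq: dict[str, dict[RegionLabel, float]] = field(default_factory=dict)


@dataclass
class GroupComparison:
    metric: str
    group_values: dict[str, list[float]]
    medians: dict[str, float]
    U: float
    p_two_sided: float
    exact: bool


def family_frequencies(
    table: pd.DataFrame,
    sample_id: str = "",
    include_ambiguous: bool = False,
) -> AbundanceProfile:
    """Family tag counts and percent frequencies from an assignment table.

    With ``include_ambiguous`` the HERV_AMBIGUOUS tags enter the denominator
    as their own "(ambiguous)" category; by default frequencies are over
    unambiguously assigned tags only.
    """
    herv = table[table["category"] == Category.HERV.value]
    counts: dict[str, int] = (
        herv.groupby("family").size().sort_index().to_dict()
    )
    if include_ambiguous:
        n_amb = int((table["category"] == Category.HERV_AMBIGUOUS.value).sum())
        if n_amb:
            counts["(ambiguous)"] = n_amb
    total = sum(counts.values())
    if total == 0:
        raise ValueError(
            f"sample {sample_id!r}: no HERV tags; family frequencies undefined"
        )
    freq = {f: 100.0 * c / total for f, c in counts.items()}
    return AbundanceProfile(
        sample_id=sample_id,
        family_counts=counts,
        family_freq=freq,
        total_herv_tags=total,
    )


def region_frequencies(
    table: pd.DataFrame, ref: ReferenceSet, family: str
) -> tuple[dict[RegionLabel, int], dict[RegionLabel, float], dict[RegionLabel, float]]:
    """(counts, per-nt rates, percent frequencies) for one family's regions.

    Rates divide the tag count of each region label by the label's total
    annotated length across the family's references; frequencies rescale the
    rates to sum to 100 within the family.  A family absent from the table
    yields empty results.
    """
    lengths = region_lengths(ref, family)
    sub = table[
        (table["category"] == Category.HERV.value)
        & (table["family"] == family)
        & (table["region"] != "")
    ]
    if sub.empty:
        return {}, {}, {}
    raw = sub.groupby("region").size().to_dict()
    counts = {RegionLabel(lbl): int(n) for lbl, n in raw.items()}
    rate = {lbl: counts[lbl] / lengths[lbl] for lbl in counts}
    total_rate = sum(rate.values())
    freq = {lbl: 100.0 * r / total_rate for lbl, r in rate.items()}
    return counts, rate, freq


def build_profile(
    table: pd.DataFrame,
    ref: ReferenceSet,
    sample_id: str = "",
    include_ambiguous: bool = False,
) -> AbundanceProfile:
    """Full per-sample profile: family frequencies plus per-family region
    counts/rates/frequencies."""
    prof = family_frequencies(table, sample_id, include_ambiguous)
    for fam in ref.families:
        counts, rate, freq = region_frequencies(table, ref, fam)
        if counts:
            prof.region_counts[fam] = counts
            prof.region_rate[fam] = rate
            prof.region_freq[fam] = freq
    return prof


def write_profile(prof: AbundanceProfile, path: str | Path) -> None:
    rows: list[dict[str, object]] = []
    for fam in sorted(prof.family_counts):
        rows.append(
            {
                "sample_id": prof.sample_id,
                "family": fam,
                "region": "ALL",
                "count": prof.family_counts[fam],
                "percent": round(prof.family_freq[fam], 4),
            }
        )
        for lbl, n in sorted(
            prof.region_counts.get(fam, {}).items(), key=lambda kv: kv[0].value
        ):
            rows.append(
                {
                    "sample_id": prof.sample_id,
                    "family": fam,
                    "region": lbl.value,
                    "count": n,
                    "percent": round(prof.region_freq[fam][lbl], 4),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def global_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column so all column totals equal the mean of the
    original totals.

    This is the between-sample normalization that assumes similar expression
    distributions across experiments; using the mean total as the target
    preserves overall scale and makes the operation idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("global normalization needs >= 2 samples")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("count matrix must be non-negative")
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total counts: {list(zero.index)}"
        )
    target = totals.mean()
    return matrix * (target / totals)


def _enumerate_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration.

    Midranks handle ties.  The two-sided p-value is the fraction of the
    C(n1+n2, n1) group assignments whose U is at least as far from the null
    mean n1*n2/2 as the observed U.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0
    r1_offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - r1_offset)
    d_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - r1_offset
        total += 1
        if abs(u - mu) >= d_obs - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def compare_groups(
    values_by_group: dict[str, list[float]],
    metric: str = "",
    exact_threshold: int = 8,
) -> GroupComparison:
    """Two-sided Mann-Whitney comparison of exactly two groups.

    Exact by enumeration when both n <= ``exact_threshold``, otherwise the
    tie-corrected normal approximation with continuity correction.  Medians
    are the per-group headline summaries.
    """
    if len(values_by_group) != 2:
        raise ValueError("compare_groups needs exactly two groups")
    (g1, v1), (g2, v2) = values_by_group.items()
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("each group needs >= 2 values")
    x = np.asarray(v1, dtype=float)
    y = np.asarray(v2, dtype=float)
    if len(x) <= exact_threshold and len(y) <= exact_threshold:
        u, p = _enumerate_p(x, y)
        exact = True
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        )
        u, p = float(res.statistic), float(res.pvalue)
        exact = False
    return GroupComparison(
        metric=metric,
        group_values={g1: list(map(float, v1)), g2: list(map(float, v2))},
        medians={g1: float(np.median(x)), g2: float(np.median(y))},
        U=u,
        p_two_sided=min(p, 1.0),
        exact=exact,
    )
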