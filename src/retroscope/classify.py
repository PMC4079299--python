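"""Hierarchical classification of short sequence tags.

Each tag is triaged through source-class tiers in a fixed order —
rRNA → host transcriptome → nuclear genome → mtDNA → microbial → HERV —
and the first tier producing at least one alignment decides its category,
so a tag matching both rRNA and a HERV reference is counted as rRNA only.

Within the HERV tier a tag is assigned to a family only when that family's
best Hamming distance beats every other family's by at least
``ambiguity_margin`` mismatches; otherwise it is HERV_AMBIGUOUS and never
contributes to any single family's count.  The region (env / gag-pol / LTR)
is the annotation containing the midpoint of the aligned interval, which
counts boundary-straddling tags exactly once, deterministically.

Alignment is exact-seed-and-extend: the tag is cut into
``max(max_mismatches + 1, ceil(L / seed_length))`` disjoint chunks, and any
placement with at most ``max_mismatches`` mismatches leaves at least one
chunk mismatch-free (pigeonhole), so the candidate lookup of each chunk's
index-k prefix is fully sensitive and the output equals an exhaustive
all-position Hamming scan.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .reference import (
    ReferenceSet,
    RegionLabel,
    SourceClass,
    reverse_complement,
)

__all__ = [
    "Category",
    "ClassifierParams",
    "Hit",
    "TagAssignment",
    "CategoryBreakdown",
    "align_tag",
    "classify_tag",
    "classify_sample",
    "read_fastq_tags",
    "write_assignments",
    "write_breakdown",
    "TIER_ORDER",
]


class Category(str, enum.Enum):
    """Final per-tag label; extends the source classes with the two
    HERV-specific outcomes and the unmapped bucket."""

    RRNA = "RRNA"
    HOST_TX = "HOST_TX"
    NUCLEAR = "NUCLEAR"
    MTDNA = "MTDNA"
    MICROBIAL = "MICROBIAL"
    HERV = "HERV"
    HERV_AMBIGUOUS = "HERV_AMBIGUOUS"
    UNASSIGNED = "UNASSIGNED"


#: Triage order: earlier tier wins.  Host transcriptome precedes the
#: nuclear-genome bucket ("nuclear but not transcriptome").
TIER_ORDER: tuple[SourceClass, ...] = (
    SourceClass.RRNA,
    SourceClass.HOST_TX,
    SourceClass.NUCLEAR,
    SourceClass.MTDNA,
    SourceClass.MICROBIAL,
    SourceClass.HERV,
)


@dataclass(frozen=True)
class ClassifierParams:
    seed_length: int = 18
    max_mismatches: int = 2
    ambiguity_margin: int = 1

    def __post_init__(self) -> None:
        if self.seed_length <= 0:
            raise ValueError("seed_length must be positive")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.ambiguity_margin < 1:
            raise ValueError("ambiguity_margin must be >= 1")


@dataclass(frozen=True)
class Hit:
    ref_id: str
    position: int
    strand: str  # '+' or '-'
    mismatches: int

    def sort_key(self) -> tuple[int, str, int, str]:
        return (self.mismatches, self.ref_id, self.position, self.strand)


@dataclass(frozen=True)
class TagAssignment:
    tag_id: str
    category: Category
    family: str | None = None
    region: RegionLabel | None = None
    ref_id: str | None = None
    position: int | None = None
    strand: str | None = None
    mismatches: int | None = None


@dataclass
class CategoryBreakdown:
    """Per-sample tag counts and percentages by category."""

    sample_id: str
    counts: dict[Category, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[Category, float]:
        n = self.total
        return {c: 100.0 * k / n for c, k in self.counts.items()}


def _hamming_leq(a: str, b: str, limit: int) -> int:
    """Mismatch count between equal-length strings, or limit+1 if exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def align_tag(
    tag: str,
    ref: ReferenceSet,
    class_filter: set[SourceClass] | frozenset[SourceClass],
    params: ClassifierParams,
) -> list[Hit]:
    """All placements of ``tag`` within ``max_mismatches`` on both strands of
    references in ``class_filter``, sorted by (mismatches, ref_id, position,
    strand).

    A '-' strand hit at position p means the reverse complement of the tag
    matches the forward reference starting at p.
    """
    L = len(tag)
    if L < params.seed_length:
        raise ValueError(
            f"tag length {L} is shorter than seed_length {params.seed_length}"
        )
    k = ref.index_k
    m = params.max_mismatches
    n_chunks = max(m + 1, -(-L // params.seed_length))
    if L // n_chunks < k:
        raise ValueError(
            f"tag length {L} too short for {n_chunks} seed chunks at index "
            f"k={k}; sensitivity cannot be guaranteed"
        )
    chunk_starts = [i * L // n_chunks for i in range(n_chunks)]

    hits: list[Hit] = []
    seen: set[tuple[str, int, str]] = set()
    for source_class in class_filter:
        index = ref.seed_index(source_class)
        refs = ref.class_sequences(source_class)
        for strand, oriented in (("+", tag), ("-", reverse_complement(tag))):
            for off in chunk_starts:
                seed = oriented[off : off + k]
                for rid, pos in index.get(seed, ()):
                    start = pos - off
                    key = (rid, start, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    seq = refs[rid]
                    if start < 0 or start + L > len(seq):
                        continue
                    mm = _hamming_leq(oriented, seq[start : start + L], m)
                    if mm <= m:
                        hits.append(Hit(rid, start, strand, mm))
    hits.sort(key=Hit.sort_key)
    return hits


def classify_tag(
    tag_id: str, tag: str, ref: ReferenceSet, params: ClassifierParams
) -> TagAssignment:
    """Triage one tag through the tier hierarchy and, within HERV, apply the
    unambiguous-family rule."""
    for tier in TIER_ORDER:
        hits = align_tag(tag, ref, {tier}, params)
        if not hits:
            continue
        if tier is not SourceClass.HERV:
            best = hits[0]
            return TagAssignment(
                tag_id=tag_id,
                category=Category(tier.value),
                ref_id=best.ref_id,
                position=best.position,
                strand=best.strand,
                mismatches=best.mismatches,
            )
        # HERV tier: best distance per family, then the margin rule.
        fam_of = ref.family_of_ref()
        best_by_family: dict[str, Hit] = {}
        for hit in hits:  # sorted: first hit per family is its best
            fam = fam_of[hit.ref_id]
            if fam not in best_by_family:
                best_by_family[fam] = hit
        ranked = sorted(
            best_by_family.items(), key=lambda kv: (kv[1].mismatches, kv[0])
        )
        best_fam, best_hit = ranked[0]
        if len(ranked) > 1:
            d2 = ranked[1][1].mismatches
            if d2 < best_hit.mismatches + params.ambiguity_margin:
                return TagAssignment(
                    tag_id=tag_id,
                    category=Category.HERV_AMBIGUOUS,
                    ref_id=best_hit.ref_id,
                    position=best_hit.position,
                    strand=best_hit.strand,
                    mismatches=best_hit.mismatches,
                )
        midpoint = best_hit.position + len(tag) // 2
        region = ref.region_at(best_hit.ref_id, midpoint)
        return TagAssignment(
            tag_id=tag_id,
            category=Category.HERV,
            family=best_fam,
            region=region,
            ref_id=best_hit.ref_id,
            position=best_hit.position,
            strand=best_hit.strand,
            mismatches=best_hit.mismatches,
        )
    return TagAssignment(tag_id=tag_id, category=Category.UNASSIGNED)


def read_fastq_tags(fastq_path: str | Path) -> list[tuple[str, str]]:
    """(tag_id, sequence) pairs from a FASTQ file; qualities are ignored."""
    tags: list[tuple[str, str]] = []
    with open(fastq_path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"empty FASTQ: {fastq_path}")
    if len(lines) % 4 != 0:
        raise ValueError(
            f"malformed FASTQ {fastq_path}: {len(lines)} lines is not a "
            "multiple of 4"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith("@") or not plus.startswith("+"):
            raise ValueError(
                f"malformed FASTQ record at index {i // 4} in {fastq_path}"
            )
        tags.append((header[1:].split()[0], seq.upper()))
    return tags


def classify_sample(
    fastq_path: str | Path,
    ref: ReferenceSet,
    params: ClassifierParams | None = None,
    sample_id: str | None = None,
) -> tuple[pd.DataFrame, CategoryBreakdown]:
    """Classify every record of a FASTQ file.

    Returns the tag-assignment table (one row per tag) and the per-category
    breakdown.  Deterministic given inputs; invariant to record order up to
    row permutation.
    """
    params = params or ClassifierParams()
    sample_id = sample_id or Path(fastq_path).stem
    tags = read_fastq_tags(fastq_path)
    assignments = [classify_tag(tid, seq, ref, params) for tid, seq in tags]
    table = assignments_to_frame(assignments)
    counts: dict[Category, int] = {}
    for a in assignments:
        counts[a.category] = counts.get(a.category, 0) + 1
    return table, CategoryBreakdown(sample_id=sample_id, counts=counts)


ASSIGNMENT_COLUMNS = [
    "tag_id",
    "category",
    "family",
    "region",
    "ref_id",
    "position",
    "strand",
    "mismatches",
]


def assignments_to_frame(assignments: list[TagAssignment]) -> pd.DataFrame:
    rows = [
        {
            "tag_id": a.tag_id,
            "category": a.category.value,
            "family": a.family or "",
            "region": a.region.value if a.region else "",
            "ref_id": a.ref_id or "",
            "position": -1 if a.position is None else a.position,
            "strand": a.strand or "",
            "mismatches": -1 if a.mismatches is None else a.mismatches,
        }
        for a in assignments
    ]
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def write_assignments(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_breakdown(breakdown: CategoryBreakdown, path: str | Path) -> None:
    fracs = breakdown.fractions
    rows = [
        {
            "sample_id": breakdown.sample_id,
            "category": c.value,
            "count": breakdown.counts.get(c, 0),
            "percent": round(fracs.get(c, 0.0), 4),
        }
        for c in Category
        if c in breakdown.counts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
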