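"""Labeled reference universe for tag classification.

A :class:`ReferenceSet` bundles the sequences the classifier maps short tags
against (rRNA, host transcripts, nuclear-genome decoys, mtDNA, microbial
sequences and HERV proviral mRNAs), the per-reference region annotations
(env / gag-pol / LTR intervals on HERV references) and an exact k-mer index
used by the seed-and-extend aligner.

Coordinates are 0-based half-open (BED convention).  Sequences are uppercased
on load and restricted to the {A, C, G, T} alphabet: the classifier scores
Hamming distance, which needs a fixed alphabet, and the bundled simulator
never emits ambiguity codes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SourceClass",
    "RegionLabel",
    "ReferenceSequence",
    "RegionAnnotation",
    "ReferenceSet",
    "ReferenceError",
    "load_reference",
    "write_reference",
    "region_lengths",
    "DEFAULT_INDEX_K",
]

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: k-mer length of the exact-match seed index.  Seeds looked up by the
#: aligner are prefixes of tag chunks, so the index k bounds the shortest
#: usable chunk; 12 keeps random collisions negligible (4^12 ≈ 1.7e7) while
#: supporting up to (36 // 12) − 1 = 2 mismatches on 36-nt tags.
DEFAULT_INDEX_K = 12


class ReferenceError(ValueError):
    """Raised when a reference set violates a structural invariant."""


class SourceClass(str, enum.Enum):
    """Origin of a reference sequence in the triage hierarchy."""

    RRNA = "RRNA"
    HOST_TX = "HOST_TX"
    NUCLEAR = "NUCLEAR"
    MTDNA = "MTDNA"
    MICROBIAL = "MICROBIAL"
    HERV = "HERV"


class RegionLabel(str, enum.Enum):
    """Countable proviral regions: env, gag-pol (reported jointly), LTR."""

    ENV = "ENV"
    GAG_POL = "GAG_POL"
    LTR = "LTR"


@dataclass(frozen=True)
class ReferenceSequence:
    """One labeled reference sequence.

    ``family`` is present exactly when ``source_class`` is HERV (e.g.
    "HERV-K", "HERV-H").
    """

    id: str
    source_class: SourceClass
    sequence: str
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"reference {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ReferenceError(
                f"reference {self.id!r}: characters outside ACGT: {sorted(bad)}"
            )
        if (self.source_class is SourceClass.HERV) != (self.family is not None):
            raise ReferenceError(
                f"reference {self.id!r}: family must be present iff source_class "
                f"is HERV (got class={self.source_class.value}, family={self.family!r})"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionAnnotation:
    """A half-open [start, end) interval on a HERV reference."""

    ref_id: str
    start: int
    end: int
    label: RegionLabel

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ReferenceError(
                f"annotation on {self.ref_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceSet:
    """Validated collection of references, annotations and the seed index."""

    sequences: dict[str, ReferenceSequence]
    annotations: list[RegionAnnotation]
    index_k: int = DEFAULT_INDEX_K
    # class -> {kmer -> [(ref_id, pos), ...]}; built lazily on first access
    _index: dict[SourceClass, dict[str, list[tuple[str, int]]]] = field(
        default_factory=dict, repr=False
    )
    _regions_by_ref: dict[str, list[RegionAnnotation]] = field(
        default_factory=dict, repr=False
    )
    _seqs_by_class: dict[SourceClass, dict[str, str]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self._validate()
        self._regions_by_ref = {}
        for ann in self.annotations:
            self._regions_by_ref.setdefault(ann.ref_id, []).append(ann)
        for anns in self._regions_by_ref.values():
            anns.sort(key=lambda a: a.start)

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        for ann in self.annotations:
            ref = self.sequences.get(ann.ref_id)
            if ref is None:
                raise ReferenceError(
                    f"annotation references unknown ref_id {ann.ref_id!r}"
                )
            if ann.end > ref.length:
                raise ReferenceError(
                    f"annotation on {ann.ref_id!r} extends to {ann.end} beyond "
                    f"sequence length {ref.length}"
                )
        by_ref: dict[str, list[RegionAnnotation]] = {}
        for ann in self.annotations:
            by_ref.setdefault(ann.ref_id, []).append(ann)
        for ref_id, anns in by_ref.items():
            anns = sorted(anns, key=lambda a: a.start)
            for prev, cur in zip(anns, anns[1:]):
                if cur.start < prev.end:
                    raise ReferenceError(
                        f"overlapping annotations on {ref_id!r}: "
                        f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                    )
        for ref in self.sequences.values():
            if ref.source_class is SourceClass.HERV and ref.id not in by_ref:
                raise ReferenceError(
                    f"HERV reference {ref.id!r} has no region annotation"
                )

    # -- lookup helpers -----------------------------------------------------

    @property
    def families(self) -> list[str]:
        fams = {
            r.family
            for r in self.sequences.values()
            if r.source_class is SourceClass.HERV and r.family
        }
        return sorted(fams)

    def refs_of_class(self, source_class: SourceClass) -> list[ReferenceSequence]:
        return [
            r for r in self.sequences.values() if r.source_class is source_class
        ]

    def family_refs(self, family: str) -> list[ReferenceSequence]:
        refs = [
            r
            for r in self.sequences.values()
            if r.source_class is SourceClass.HERV and r.family == family
        ]
        if not refs:
            raise KeyError(f"unknown HERV family {family!r}")
        return refs

    def regions_of(self, ref_id: str) -> list[RegionAnnotation]:
        return self._regions_by_ref.get(ref_id, [])

    def region_at(self, ref_id: str, position: int) -> RegionLabel | None:
        """Label of the annotation containing ``position``, if any."""
        for ann in self._regions_by_ref.get(ref_id, []):
            if ann.start <= position < ann.end:
                return ann.label
        return None

    def class_sequences(self, source_class: SourceClass) -> dict[str, str]:
        """Cached id -> sequence map for one class (hot path of alignment)."""
        seqs = self._seqs_by_class.get(source_class)
        if seqs is None:
            seqs = {
                r.id: r.sequence for r in self.refs_of_class(source_class)
            }
            self._seqs_by_class[source_class] = seqs
        return seqs

    def family_of_ref(self) -> dict[str, str]:
        """Cached ref_id -> family map over HERV references."""
        fam = getattr(self, "_family_of", None)
        if fam is None:
            fam = {
                r.id: r.family  # type: ignore[misc]
                for r in self.refs_of_class(SourceClass.HERV)
            }
            object.__setattr__(self, "_family_of", fam)
        return fam

    def seed_index(
        self, source_class: SourceClass
    ) -> dict[str, list[tuple[str, int]]]:
        """Exact k-mer index of all forward-strand references of one class."""
        idx = self._index.get(source_class)
        if idx is None:
            idx = {}
            k = self.index_k
            for ref in self.refs_of_class(source_class):
                seq = ref.sequence
                rid = ref.id
                for pos in range(len(seq) - k + 1):
                    idx.setdefault(seq[pos : pos + k], []).append((rid, pos))
            self._index[source_class] = idx
        return idx


# -- region lengths ---------------------------------------------------------


def region_lengths(ref: ReferenceSet, family: str) -> dict[RegionLabel, int]:
    """Total annotated length (nt) per region label for one HERV family.

    Lengths are summed over all of the family's references; labels with no
    annotation are omitted.  These totals are the denominators of the
    length-normalized region frequencies.
    """
    totals: dict[RegionLabel, int] = {}
    for r in ref.family_refs(family):
        for ann in ref.regions_of(r.id):
            totals[ann.label] = totals.get(ann.label, 0) + ann.length
    return totals


# -- I/O --------------------------------------------------------------------

REGIONS_COLUMNS = ["ref_id", "start", "end", "label", "family", "source_class"]


def load_reference(
    fasta_path: str | Path,
    regions_path: str | Path,
    index_k: int = DEFAULT_INDEX_K,
) -> ReferenceSet:
    """Load and validate a reference set from FASTA + regions TSV.

    The regions TSV carries one row per annotated interval and one row with
    label ``na`` per non-HERV reference (so the table is also the class
    sidecar).  Columns: ``ref_id  start  end  label  family  source_class``.
    """
    raw: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in raw:
            raise ReferenceError(f"duplicated FASTA id {rec.id!r}")
        raw[rec.id] = str(rec.seq).upper()
    if not raw:
        raise ReferenceError(f"no FASTA records in {fasta_path}")

    table = pd.read_csv(
        regions_path, sep="\t", dtype=str, keep_default_na=False
    )
    missing = set(REGIONS_COLUMNS) - set(table.columns)
    if missing:
        raise ReferenceError(f"regions table missing columns: {sorted(missing)}")

    seq_meta: dict[str, tuple[SourceClass, str | None]] = {}
    annotations: list[RegionAnnotation] = []
    for row in table.itertuples(index=False):
        ref_id = row.ref_id
        if ref_id not in raw:
            raise ReferenceError(
                f"regions table names unknown ref_id {ref_id!r}"
            )
        try:
            source_class = SourceClass(row.source_class.upper())
        except ValueError:
            raise ReferenceError(
                f"unknown source_class {row.source_class!r} for {ref_id!r}"
            ) from None
        family = row.family or None
        meta = (source_class, family)
        if seq_meta.setdefault(ref_id, meta) != meta:
            raise ReferenceError(
                f"inconsistent class/family for {ref_id!r} across rows"
            )
        label_raw = row.label.strip().lower()
        if label_raw == "na":
            continue
        try:
            label = RegionLabel(label_raw.upper())
        except ValueError:
            raise ReferenceError(
                f"unknown region label {row.label!r} on {ref_id!r}"
            ) from None
        annotations.append(
            RegionAnnotation(ref_id, int(row.start), int(row.end), label)
        )

    unlabeled = set(raw) - set(seq_meta)
    if unlabeled:
        raise ReferenceError(
            f"FASTA records absent from regions table: {sorted(unlabeled)}"
        )

    sequences = {
        ref_id: ReferenceSequence(
            id=ref_id,
            source_class=seq_meta[ref_id][0],
            family=seq_meta[ref_id][1],
            sequence=seq,
        )
        for ref_id, seq in raw.items()
    }
    return ReferenceSet(sequences=sequences, annotations=annotations, index_k=index_k)


def write_reference(
    ref: ReferenceSet, fasta_path: str | Path, regions_path: str | Path
) -> None:
    """Write a reference set back to FASTA (unwrapped) + regions TSV."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in ref.sequences.values()
    ]
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")

    rows: list[dict[str, object]] = []
    for r in ref.sequences.values():
        anns = ref.regions_of(r.id)
        if not anns:
            rows.append(
                {
                    "ref_id": r.id,
                    "start": 0,
                    "end": r.length,
                    "label": "na",
                    "family": r.family or "",
                    "source_class": r.source_class.value,
                }
            )
        for ann in anns:
            rows.append(
                {
                    "ref_id": r.id,
                    "start": ann.start,
                    "end": ann.end,
                    "label": ann.label.value.lower(),
                    "family": r.family or "",
                    "source_class": r.source_class.value,
                }
            )
    pd.DataFrame(rows, columns=REGIONS_COLUMNS).to_csv(
        regions_path, sep="\t", index=False
    )


def concat_annotations(
    ref: ReferenceSet, extra: Iterable[RegionAnnotation]
) -> ReferenceSet:
    """New ReferenceSet with additional annotations (revalidated)."""
    return ReferenceSet(
        sequences=dict(ref.sequences),
        annotations=list(ref.annotations) + list(extra),
        index_k=ref.index_k,
    )
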