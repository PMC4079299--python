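"""Synthetic reference sets, tag libraries and cohort data with ground truth.

The generator emulates the study regime the downstream stages assume:

* fixed-length single-end tags (default 36 nt, the short-tag era);
* a source-class mixture over rRNA / host transcriptome / nuclear-only /
  mtDNA / microbial / HERV / junk, with defaults patterned on the observed
  triage of a brain transcriptome (rRNA ~33 %, transcriptome ~12 %,
  mtDNA ~8 %, microbial ~0.1 %, a sizeable unmapped fraction), with the
  nuclear and unmapped mass partly reallocated to HERV so the HERV stages
  see usable tag counts at simulation scale;
* several HERV families derived from one common ancestor by i.i.d.
  substitution, each annotated LTR / gag-pol / env, with one LTR motif
  copied verbatim into every family — the planted, genuinely ambiguous
  sequence that the unambiguous-assignment rule must reject;
* a two-group cohort (HIV+ / HIV-) whose per-sample HERV-K env abundance
  differs by group and drives a planted module of host genes through a
  negative-binomial count model, plus a term map in which one planted term
  covers the module.

Everything is a pure function of (config, seed): repeated runs are
byte-identical.  Substitution-only errors (no indels): the classifier
scores Hamming distance, and substitutions dominated short-tag platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reference import (
    RegionAnnotation,
    RegionLabel,
    ReferenceSequence,
    ReferenceSet,
    SourceClass,
    reverse_complement,
)

__all__ = [
    "SimulationConfig",
    "SampleSpec",
    "SimulationTruth",
    "CohortTruth",
    "build_reference",
    "simulate_tags",
    "simulate_cohort",
    "write_fastq",
    "DEFAULT_CLASS_MIXTURE",
    "DEFAULT_FAMILY_MIXTURE",
    "FAMILY_NAMES",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent RNG stream per (seed, stage key).

    Distinct entropy tuples give non-overlapping streams, so tag sequences
    can never replay the draws that generated the reference sequences.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _sample_key(sample_id: str) -> int:
    import zlib

    return zlib.crc32(sample_id.encode()) % (2**31)

FAMILY_NAMES = ["HERV-K", "HERV-H", "HERV-W", "HERV-R", "HERV-E", "HERV-FRD"]

#: Default source-class mixture.  rRNA / transcriptome / mtDNA / microbial
#: follow the observed triage proportions of a brain transcriptome; part of
#: the nuclear-only and unmapped mass is shifted to HERV so that family- and
#: region-level statistics are estimable from ~1e4-1e5 tags per sample.
DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    "RRNA": 0.328,
    "HOST_TX": 0.123,
    "NUCLEAR": 0.170,
    "MTDNA": 0.080,
    "MICROBIAL": 0.001,
    "HERV": 0.150,
    "JUNK": 0.148,
}

#: Default family mixture, patterned on healthy-brain proportions where
#: HERV-H dominates, followed by HERV-K, with minor W/R/E/FRD contributions.
DEFAULT_FAMILY_MIXTURE: dict[str, float] = {
    "HERV-H": 0.57,
    "HERV-K": 0.31,
    "HERV-W": 0.05,
    "HERV-R": 0.04,
    "HERV-E": 0.02,
    "HERV-FRD": 0.01,
}


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str  # "HIVpos" or "HIVneg"


def _default_samples() -> list[SampleSpec]:
    return [
        SampleSpec(f"{g}{i + 1}", g)
        for g in ("HIVpos", "HIVneg")
        for i in range(4)
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; every default is a study condition.

    Region lengths default to LTR 500 / gag-pol 2000 / env 500 nt (1:4:1),
    giving distinct per-nt rates for equal planted coverage.  The shared LTR
    motif (60 nt > tag length) guarantees tags drawn wholly inside it are
    exactly equidistant from every family.
    """

    seed: int = 0
    tag_length: int = 36
    n_tags: int = 20_000
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    herv_family_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_MIXTURE)
    )
    error_rate: float = 0.01
    n_families: int = 6
    family_divergence: float = 0.10
    ltr_length: int = 500
    gag_pol_length: int = 2000
    env_length: int = 500
    shared_ltr_motif_length: int = 60
    # decoy universe
    n_genes: int = 200
    gene_length: int = 500
    rrna_length: int = 1500
    nuclear_length: int = 2000
    mtdna_length: int = 2000
    microbial_length: int = 1500
    # cohort design
    samples: list[SampleSpec] = field(default_factory=_default_samples)
    module_size: int = 20
    module_effect: float = 1.0  # 0 = null; 1 = gene mean proportional to env
    dispersion: float = 0.1  # NB dispersion; 0 degenerates to rounded means
    env_mean_neg: float = 0.5
    env_mean_pos: float = 3.0
    env_spread: float = 0.3  # half-width of the uniform jitter around means
    n_decoy_terms: int = 50
    term_size: int = 15
    planted_term_decoys: int = 5  # non-module genes added to the planted term

    def __post_init__(self) -> None:
        for name, mix in (
            ("class_mixture", self.class_mixture),
            ("herv_family_mixture", self.herv_family_mixture),
        ):
            if any(not (0.0 <= v <= 1.0) for v in mix.values()):
                raise ValueError(f"{name}: fractions must be in [0,1]")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: fractions must sum to 1")
        if not (0.0 <= self.error_rate <= 0.25):
            raise ValueError("error_rate must be in [0, 0.25]")
        if self.shared_ltr_motif_length > self.ltr_length:
            raise ValueError("shared_ltr_motif_length exceeds LTR length")
        if self.n_tags <= 0:
            raise ValueError("n_tags must be positive")
        shortest = min(
            self.ltr_length + self.gag_pol_length + self.env_length,
            self.gene_length,
            self.rrna_length,
            self.nuclear_length,
            self.mtdna_length,
            self.microbial_length,
        )
        if self.tag_length > shortest:
            raise ValueError("tag_length exceeds shortest reference length")

    def family_names(self) -> list[str]:
        if self.n_families <= len(FAMILY_NAMES):
            return FAMILY_NAMES[: self.n_families]
        return FAMILY_NAMES + [
            f"HERV-X{i}" for i in range(self.n_families - len(FAMILY_NAMES))
        ]

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: v
            for k, v in self.__dict__.items()
            if k != "samples"
        }
        data["samples"] = [
            {"sample_id": s.sample_id, "group": s.group} for s in self.samples
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "samples" in data:
            data["samples"] = [SampleSpec(**s) for s in data["samples"]]
        return cls(**data)


@dataclass
class SimulationTruth:
    """Per-sample generative ground truth for recovery tests."""

    sample_id: str
    class_counts: dict[str, int]
    family_counts: dict[str, int]
    # one row per tag: tag_id, class, family, ref_id, start, strand,
    # planted_ambiguous (tag lies wholly inside the shared LTR motif)
    origins: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.origins.to_csv(path, sep="\t", index=False)


@dataclass
class CohortTruth:
    env_abundance: dict[str, float]  # per sample, in arbitrary units
    planted_module_genes: list[str]
    planted_term: str
    per_sample: dict[str, SimulationTruth] = field(default_factory=dict)


# -- reference construction -------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """i.i.d. substitution at ``rate``; substituted bases are drawn uniformly
    from the three alternatives."""
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        codes = np.frombuffer(arr[hit].tobytes(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        new_idx = (lut[codes] + shift) % 4
        arr[hit] = _BASES[new_idx]
    return arr.tobytes().decode()


def build_reference(
    cfg: SimulationConfig,
) -> tuple[ReferenceSet, dict[str, object]]:
    """Build the synthetic labeled reference universe.

    HERV families descend from one random ancestor by i.i.d. substitution at
    ``family_divergence``; the shared LTR motif is then copied verbatim into
    every family at the same offset, creating tags that no classifier can
    assign to a single family.  Host transcripts double as the gene universe
    of the association stage.  Deterministic given ``cfg.seed``.
    """
    rng = _stream(cfg.seed, 1)
    herv_len = cfg.ltr_length + cfg.gag_pol_length + cfg.env_length
    ancestor = _random_seq(rng, herv_len)
    motif = _random_seq(rng, cfg.shared_ltr_motif_length)
    motif_offset = (
        (cfg.ltr_length - cfg.shared_ltr_motif_length) // 2
        if cfg.shared_ltr_motif_length
        else 0
    )

    sequences: dict[str, ReferenceSequence] = {}
    annotations: list[RegionAnnotation] = []
    for fam in cfg.family_names():
        seq = _mutate(rng, ancestor, cfg.family_divergence)
        if cfg.shared_ltr_motif_length:
            seq = (
                seq[:motif_offset]
                + motif
                + seq[motif_offset + cfg.shared_ltr_motif_length :]
            )
        rid = f"{fam}_ref"
        sequences[rid] = ReferenceSequence(
            id=rid, source_class=SourceClass.HERV, family=fam, sequence=seq
        )
        annotations += [
            RegionAnnotation(rid, 0, cfg.ltr_length, RegionLabel.LTR),
            RegionAnnotation(
                rid,
                cfg.ltr_length,
                cfg.ltr_length + cfg.gag_pol_length,
                RegionLabel.GAG_POL,
            ),
            RegionAnnotation(
                rid,
                cfg.ltr_length + cfg.gag_pol_length,
                herv_len,
                RegionLabel.ENV,
            ),
        ]

    for rid, source_class, length in (
        ("rRNA_18S", SourceClass.RRNA, cfg.rrna_length),
        ("rRNA_28S", SourceClass.RRNA, cfg.rrna_length),
        ("nuclear_seg1", SourceClass.NUCLEAR, cfg.nuclear_length),
        ("nuclear_seg2", SourceClass.NUCLEAR, cfg.nuclear_length),
        ("mtDNA", SourceClass.MTDNA, cfg.mtdna_length),
        ("microbe_1", SourceClass.MICROBIAL, cfg.microbial_length),
    ):
        sequences[rid] = ReferenceSequence(
            id=rid, source_class=source_class, sequence=_random_seq(rng, length)
        )

    gene_ids = [f"gene{g:04d}" for g in range(cfg.n_genes)]
    for gid in gene_ids:
        sequences[gid] = ReferenceSequence(
            id=gid,
            source_class=SourceClass.HOST_TX,
            sequence=_random_seq(rng, cfg.gene_length),
        )

    ref = ReferenceSet(sequences=sequences, annotations=annotations)
    meta = {
        "motif": motif,
        "motif_offset": motif_offset,
        "gene_ids": gene_ids,
        "herv_length": herv_len,
    }
    return ref, meta


# -- tag simulation ---------------------------------------------------------


def write_fastq(path: str | Path, records: list[tuple[str, str]]) -> None:
    """Plain single-end FASTQ with constant 'I' qualities."""
    with open(path, "w") as fh:
        for tag_id, seq in records:
            fh.write(f"@{tag_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_tags(
    ref: ReferenceSet,
    cfg: SimulationConfig,
    sample_id: str,
    fastq_path: str | Path | None = None,
    rng: np.random.Generator | None = None,
    herv_family_mixture: dict[str, float] | None = None,
) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Draw ``cfg.n_tags`` tags for one sample and record their true origins.

    Class drawn from ``class_mixture`` (JUNK = i.i.d. random sequence), then
    a reference uniformly within class (HERV references weighted by the
    family mixture), start uniform over valid positions, strand uniform,
    substitution errors at ``error_rate``.  ``planted_ambiguous`` marks tags
    whose source interval lies wholly inside the shared LTR motif.
    """
    if rng is None:
        rng = _stream(cfg.seed, 2, _sample_key(sample_id))
    fam_mix = herv_family_mixture or cfg.herv_family_mixture
    L = cfg.tag_length

    class_names = sorted(cfg.class_mixture)
    class_probs = np.array([cfg.class_mixture[c] for c in class_names])
    class_draw = rng.choice(len(class_names), size=cfg.n_tags, p=class_probs)

    fam_names = sorted(fam_mix)
    fam_probs = np.array([fam_mix[f] for f in fam_names])

    refs_by_class: dict[str, list[ReferenceSequence]] = {
        c: ref.refs_of_class(SourceClass(c))
        for c in class_names
        if c != "JUNK"
    }
    fam_ref: dict[str, list[ReferenceSequence]] = {}
    if "HERV" in class_names:
        for f in fam_names:
            fam_ref[f] = ref.family_refs(f)

    # motif interval per HERV ref, for the planted_ambiguous flag
    motif_ival: dict[str, tuple[int, int]] = {}
    if cfg.shared_ltr_motif_length and cfg.n_families > 1:
        off = (cfg.ltr_length - cfg.shared_ltr_motif_length) // 2
        for r in ref.refs_of_class(SourceClass.HERV):
            motif_ival[r.id] = (off, off + cfg.shared_ltr_motif_length)

    records: list[tuple[str, str]] = []
    rows: list[tuple] = []
    class_counts: dict[str, int] = {c: 0 for c in class_names}
    family_counts: dict[str, int] = {f: 0 for f in fam_names}

    for i in range(cfg.n_tags):
        cname = class_names[class_draw[i]]
        class_counts[cname] += 1
        tag_id = f"{sample_id}:{i}"
        if cname == "JUNK":
            seq = _random_seq(rng, L)
            rows.append((tag_id, cname, "", "", -1, ".", False))
        else:
            fam = ""
            if cname == "HERV":
                fam = fam_names[rng.choice(len(fam_names), p=fam_probs)]
                family_counts[fam] += 1
                pool = fam_ref[fam]
            else:
                pool = refs_by_class[cname]
            r = pool[rng.integers(len(pool))]
            start = int(rng.integers(0, r.length - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = r.sequence[start : start + L]
            if strand == "-":
                seq = reverse_complement(seq)
            seq = _mutate(rng, seq, cfg.error_rate)
            ival = motif_ival.get(r.id)
            planted = bool(
                ival and start >= ival[0] and start + L <= ival[1]
            )
            rows.append((tag_id, cname, fam, r.id, start, strand, planted))
        records.append((tag_id, seq))

    origins = pd.DataFrame(
        rows,
        columns=[
            "tag_id",
            "source_class",
            "family",
            "ref_id",
            "start",
            "strand",
            "planted_ambiguous",
        ],
    )
    truth = SimulationTruth(
        sample_id=sample_id,
        class_counts=class_counts,
        family_counts=family_counts,
        origins=origins,
    )
    if fastq_path is not None:
        write_fastq(fastq_path, records)
    return records, truth


# -- cohort simulation ------------------------------------------------------


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2; dispersion 0
    degenerates to rounded means (exact, noise-free counts)."""
    if dispersion <= 0.0:
        return np.rint(mean).astype(int)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort(
    cfg: SimulationConfig,
    out_dir: str | Path | None = None,
    write_fastqs: bool = True,
) -> tuple[
    ReferenceSet, pd.DataFrame, pd.DataFrame, CohortTruth, dict[str, Path]
]:
    """Simulate the full two-group cohort.

    Returns (reference, count matrix [genes x samples], gene->term map,
    truth, written paths).  Per-sample env abundance is drawn around a
    higher mean in the HIV+ group; counts of the planted module genes scale
    with env abundance via ``mean_gs = mu_g * (1 + effect * (env_s/mean(env)
    - 1))``, background genes keep constant means.  The per-sample HERV
    family mixture tilts HERV-K proportionally to env abundance so the
    classifier-measured env signal tracks the generative one.
    """
    groups = {s.group for s in cfg.samples}
    for g in groups:
        if sum(1 for s in cfg.samples if s.group == g) < 3:
            raise ValueError(f"group {g!r} needs >= 3 samples")
    rng = _stream(cfg.seed, 3)
    ref, meta = build_reference(cfg)

    sample_ids = [s.sample_id for s in cfg.samples]
    env = {}
    for s in cfg.samples:
        base = cfg.env_mean_pos if s.group == "HIVpos" else cfg.env_mean_neg
        env[s.sample_id] = float(
            base + rng.uniform(-cfg.env_spread, cfg.env_spread)
        )
    env_vals = np.array([env[s] for s in sample_ids])
    if np.unique(np.round(env_vals, 12)).size < 2:
        raise ValueError("fewer than 2 distinct env abundance values")

    gene_ids: list[str] = list(meta["gene_ids"])
    module = list(rng.choice(gene_ids, size=cfg.module_size, replace=False))
    base_mu = rng.lognormal(mean=np.log(50.0), sigma=0.6, size=len(gene_ids))
    env_rel = env_vals / env_vals.mean()

    counts = np.zeros((len(gene_ids), len(sample_ids)), dtype=int)
    module_set = set(module)
    for gi, gid in enumerate(gene_ids):
        if gid in module_set:
            mu = base_mu[gi] * np.maximum(
                1.0 + cfg.module_effect * (env_rel - 1.0), 1e-6
            )
        else:
            mu = np.full(len(sample_ids), base_mu[gi])
        counts[gi] = _nb_draw(rng, mu, cfg.dispersion)
    matrix = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    matrix.index.name = "gene"

    # term map: one planted term covering the module (+ decoys), plus
    # random background terms
    term_rows: list[tuple[str, str]] = []
    planted_term = "TERM_PLANTED"
    non_module = [g for g in gene_ids if g not in module_set]
    decoy_members = list(
        rng.choice(non_module, size=cfg.planted_term_decoys, replace=False)
    )
    for g in module + decoy_members:
        term_rows.append((g, planted_term))
    for t in range(cfg.n_decoy_terms):
        members = rng.choice(gene_ids, size=cfg.term_size, replace=False)
        for g in members:
            term_rows.append((g, f"TERM_{t:03d}"))
    term_map = pd.DataFrame(term_rows, columns=["gene", "term"])

    truth = CohortTruth(
        env_abundance=env,
        planted_module_genes=module,
        planted_term=planted_term,
    )

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .reference import write_reference

        write_reference(ref, out / "reference.fasta", out / "regions.tsv")
        matrix.to_csv(out / "counts.tsv", sep="\t")
        term_map.to_csv(out / "terms.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": [s.group for s in cfg.samples],
                "env_abundance": env_vals,
            }
        ).to_csv(out / "samples.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": module}).to_csv(
            out / "truth_module.tsv", sep="\t", index=False
        )
        cfg.to_yaml(out / "config.yaml")
        paths = {
            "reference": out / "reference.fasta",
            "regions": out / "regions.tsv",
            "counts": out / "counts.tsv",
            "terms": out / "terms.tsv",
            "samples": out / "samples.tsv",
        }

    if write_fastqs and out_dir is not None:
        out = Path(out_dir)
        base_k = cfg.herv_family_mixture.get("HERV-K", 0.31)
        for s in cfg.samples:
            mix = dict(cfg.herv_family_mixture)
            # tilt HERV-K with env abundance, renormalize the rest
            k_w = base_k * env[s.sample_id] / env_vals.mean()
            k_w = min(k_w, 0.95)
            other = {f: w for f, w in mix.items() if f != "HERV-K"}
            scale = (1.0 - k_w) / sum(other.values())
            mix = {f: w * scale for f, w in other.items()}
            mix["HERV-K"] = k_w
            fq = out / f"{s.sample_id}.fastq"
            _, st = simulate_tags(
                ref,
                cfg,
                s.sample_id,
                fastq_path=fq,
                rng=rng,
                herv_family_mixture=mix,
            )
            truth.per_sample[s.sample_id] = st
            st.to_tsv(out / f"{s.sample_id}.truth.tsv")
            paths[f"fastq:{s.sample_id}"] = fq

    return ref, matrix, term_map, truth, paths
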