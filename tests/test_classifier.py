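"""Seed-and-extend alignment, triage hierarchy and the ambiguity rule."""

import numpy as np
import pandas as pd
import pytest

from retroscope.classify import (
    Category,
    ClassifierParams,
    align_tag,
    classify_sample,
    classify_tag,
    read_fastq_tags,
)
from retroscope.reference import (
    RegionAnnotation,
    RegionLabel,
    ReferenceSequence,
    ReferenceSet,
    SourceClass,
)
from retroscope.simulate import SimulationConfig, build_reference, simulate_tags, write_fastq

from _oracles import hamming_scan, revcomp


ALL_CLASSES = set(SourceClass)


def _mutate_at(seq: str, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def test_exact_substring_single_hit(tiny_ref, default_params):
    tag = tiny_ref.sequences["K1"].sequence[10:46]
    hits = align_tag(tag, tiny_ref, {SourceClass.HERV}, default_params)
    assert hits[0].ref_id == "K1"
    assert hits[0].position == 10
    assert hits[0].strand == "+"
    assert hits[0].mismatches == 0


def test_no_match_returns_empty(tiny_ref, default_params):
    # a tag matching nothing within max_mismatches
    tag = "AC" * 18
    hits = align_tag(tag, tiny_ref, {SourceClass.HERV}, default_params)
    oracle = hamming_scan(
        tag,
        {"K1": tiny_ref.sequences["K1"].sequence,
         "H1": tiny_ref.sequences["H1"].sequence},
        default_params.max_mismatches,
    )
    assert [(h.ref_id, h.position, h.strand, h.mismatches) for h in hits] == oracle


def test_reverse_strand_hit(tiny_ref, default_params):
    tag = revcomp(tiny_ref.sequences["K1"].sequence[50:86])
    hits = align_tag(tag, tiny_ref, {SourceClass.HERV}, default_params)
    assert any(
        h.ref_id == "K1" and h.position == 50 and h.strand == "-" and h.mismatches == 0
        for h in hits
    )


def test_tag_shorter_than_seed_rejected(tiny_ref, default_params):
    with pytest.raises(ValueError, match="seed_length"):
        align_tag("ACGT", tiny_ref, {SourceClass.HERV}, default_params)


@pytest.mark.parametrize("n_cases", [150])
def test_align_matches_bruteforce_oracle(tiny_ref, default_params, rng, n_cases):
    """Randomized equivalence: seed-and-extend output identical to the
    exhaustive all-position Hamming scan, for planted-with-errors and fully
    random tags, across strands and classes."""
    seqs = {rid: r.sequence for rid, r in tiny_ref.sequences.items()}
    ids = sorted(seqs)
    for _ in range(n_cases):
        if rng.random() < 0.7:
            rid = ids[rng.integers(len(ids))]
            start = int(rng.integers(0, len(seqs[rid]) - 36 + 1))
            tag = seqs[rid][start : start + 36]
            n_err = int(rng.integers(0, 4))  # up to 3: sometimes beyond limit
            if n_err:
                tag = _mutate_at(
                    tag, list(rng.choice(36, size=n_err, replace=False))
                )
            if rng.random() < 0.5:
                tag = revcomp(tag)
        else:
            tag = "".join(rng.choice(list("ACGT"), size=36))
        hits = align_tag(tag, tiny_ref, ALL_CLASSES, default_params)
        oracle = hamming_scan(tag, seqs, default_params.max_mismatches)
        assert [
            (h.ref_id, h.position, h.strand, h.mismatches) for h in hits
        ] == oracle


def test_triage_order_earlier_tier_wins(default_params):
    """A tag present verbatim in both an rRNA and a HERV reference is
    counted as rRNA (hierarchy exclusivity)."""
    rng = np.random.default_rng(7)
    shared = "".join(rng.choice(list("ACGT"), size=36))
    pad = lambda: "".join(rng.choice(list("ACGT"), size=60))
    seqs = {
        "rrna": ReferenceSequence(
            "rrna", SourceClass.RRNA, pad() + shared + pad()
        ),
        "k": ReferenceSequence(
            "k", SourceClass.HERV, pad() + shared + pad(), family="HERV-K"
        ),
    }
    ref = ReferenceSet(
        sequences=seqs,
        annotations=[RegionAnnotation("k", 0, 156, RegionLabel.LTR)],
    )
    a = classify_tag("t", shared, ref, default_params)
    assert a.category == Category.RRNA


def test_herv_family_and_region_assignment(small_sim, default_params):
    """An error-free tag from a family's env region maps to that family with
    region ENV."""
    cfg, ref, meta, records, truth = small_sim
    env_start = cfg.ltr_length + cfg.gag_pol_length
    k_ref = next(
        r for r in ref.refs_of_class(SourceClass.HERV) if r.family == "HERV-K"
    )
    tag = k_ref.sequence[env_start + 100 : env_start + 136]
    a = classify_tag("t", tag, ref, default_params)
    assert a.category == Category.HERV
    assert a.family == "HERV-K"
    assert a.region == RegionLabel.ENV


def test_planted_motif_tag_is_ambiguous(small_sim, default_params):
    """A tag wholly inside the shared LTR motif ties across all families."""
    cfg, ref, meta, records, truth = small_sim
    motif = meta["motif"]
    tag = motif[5 : 5 + 36]
    a = classify_tag("t", tag, ref, default_params)
    assert a.category == Category.HERV_AMBIGUOUS


def test_ambiguity_margin_semantics(default_params):
    """Best family at 2 mismatches, runner-up at 3: assigned to the best
    family at margin 1, HERV_AMBIGUOUS at margin 2 (distances verified
    against the brute-force scanner)."""
    rng = np.random.default_rng(11)
    base = "".join(rng.choice(list("ACGT"), size=120))
    kseq = base
    hseq = _mutate_at(base, list(range(0, 120, 8)))  # 15 spread substitutions
    seqs = {
        "k": ReferenceSequence("k", SourceClass.HERV, kseq, family="HERV-K"),
        "h": ReferenceSequence("h", SourceClass.HERV, hseq, family="HERV-H"),
    }
    # index_k=9: four seed chunks of 9 nt keep pigeonhole sensitivity at
    # max_mismatches=3 on 36-nt tags
    ref = ReferenceSet(
        sequences=seqs,
        annotations=[
            RegionAnnotation("k", 0, 120, RegionLabel.LTR),
            RegionAnnotation("h", 0, 120, RegionLabel.LTR),
        ],
        index_k=9,
    )
    # window [40, 76) of kseq differs from hseq at 40,48,56,64,72 (5 sites);
    # mutate 4 of them toward hseq and one extra neutral site -> craft a tag
    # with d(K)=1 and d(H)=2
    window = kseq[40:76]
    to_h = {p - 40: hseq[p] for p in (40, 48, 56)}
    tag = list(window)
    for off, b in to_h.items():
        tag[off] = b  # now d(K)=3, d(H)=2 ... adjust below
    tag = "".join(tag)
    dk = sum(a != b for a, b in zip(tag, kseq[40:76]))
    dh = sum(a != b for a, b in zip(tag, hseq[40:76]))
    assert (dk, dh) == (3, 2)
    # use max_mismatches=3 so both families hit; margin decides
    p1 = ClassifierParams(max_mismatches=3, ambiguity_margin=1)
    a1 = classify_tag("t", tag, ref, p1)
    assert a1.category == Category.HERV and a1.family == "HERV-H"
    p2 = ClassifierParams(max_mismatches=3, ambiguity_margin=2)
    a2 = classify_tag("t", tag, ref, p2)
    assert a2.category == Category.HERV_AMBIGUOUS
    # cross-check the distances with the oracle
    oracle = hamming_scan(tag, {"k": kseq, "h": hseq}, 3)
    best = {rid: min(m for r2, p, s, m in oracle if r2 == rid) for rid in ("k", "h")}
    assert best == {"k": 3, "h": 2}


def test_classify_sample_pure_class(tmp_path, small_sim, default_params):
    """A FASTQ drawn 100% from rRNA yields a 100% rRNA breakdown."""
    cfg, ref, meta, records, truth = small_sim
    pure = SimulationConfig(
        seed=13, n_tags=400, error_rate=0.0, class_mixture={"RRNA": 1.0}
    )
    fq = tmp_path / "pure.fastq"
    simulate_tags(ref, pure, "p", fastq_path=fq)
    table, breakdown = classify_sample(fq, ref, default_params, "p")
    assert breakdown.counts == {Category.RRNA: 400}
    assert breakdown.fractions[Category.RRNA] == 100.0


def test_classify_sample_additive_and_order_invariant(
    tmp_path, small_sim, default_params
):
    """Concatenating two FASTQs sums the breakdowns; permuting record order
    permutes rows but leaves the breakdown identical."""
    cfg, ref, meta, records, truth = small_sim
    half = len(records) // 8
    a, b = records[:half], records[half : 2 * half]
    write_fastq(tmp_path / "a.fastq", a)
    write_fastq(tmp_path / "b.fastq", b)
    write_fastq(tmp_path / "ab.fastq", a + b)
    write_fastq(tmp_path / "ba.fastq", b + a)
    _, bd_a = classify_sample(tmp_path / "a.fastq", ref, default_params)
    _, bd_b = classify_sample(tmp_path / "b.fastq", ref, default_params)
    t_ab, bd_ab = classify_sample(tmp_path / "ab.fastq", ref, default_params)
    t_ba, bd_ba = classify_sample(tmp_path / "ba.fastq", ref, default_params)
    for cat in Category:
        assert bd_ab.counts.get(cat, 0) == bd_a.counts.get(cat, 0) + bd_b.counts.get(cat, 0)
    assert bd_ab.counts == bd_ba.counts
    key = lambda t: t.sort_values("tag_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(key(t_ab), key(t_ba))


def test_breakdown_fractions_sum_to_100(small_sim, default_params, tmp_path):
    cfg, ref, meta, records, truth = small_sim
    write_fastq(tmp_path / "s.fastq", records[:1000])
    _, bd = classify_sample(tmp_path / "s.fastq", ref, default_params)
    assert abs(sum(bd.fractions.values()) - 100.0) < 0.01
    assert bd.total == 1000


def test_empty_and_malformed_fastq(tmp_path):
    empty = tmp_path / "e.fastq"
    empty.write_text("")
    with pytest.raises(ValueError, match="empty"):
        read_fastq_tags(empty)
    bad = tmp_path / "b.fastq"
    bad.write_text("@r1\nACGT\nBAD\nIIII\n")
    with pytest.raises(ValueError, match="record at index 0"):
        read_fastq_tags(bad)
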