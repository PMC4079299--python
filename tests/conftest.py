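import numpy as np
import pytest

from retroscope.reference import (
    RegionAnnotation,
    RegionLabel,
    ReferenceSequence,
    ReferenceSet,
    SourceClass,
)
from retroscope.classify import ClassifierParams
from retroscope.simulate import SimulationConfig, build_reference, simulate_tags


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def tiny_ref(rng):
    """Two diverged HERV families plus one decoy per non-HERV class."""
    base = random_seq(rng, 300)
    # ~15% divergence between the two families
    fam2 = list(base)
    for i in rng.choice(300, size=45, replace=False):
        fam2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[fam2[i]]
    fam2 = "".join(fam2)
    seqs = {
        "K1": ReferenceSequence("K1", SourceClass.HERV, base, family="HERV-K"),
        "H1": ReferenceSequence("H1", SourceClass.HERV, fam2, family="HERV-H"),
        "rrna": ReferenceSequence("rrna", SourceClass.RRNA, random_seq(rng, 200)),
        "tx": ReferenceSequence("tx", SourceClass.HOST_TX, random_seq(rng, 200)),
        "nuc": ReferenceSequence("nuc", SourceClass.NUCLEAR, random_seq(rng, 200)),
        "mt": ReferenceSequence("mt", SourceClass.MTDNA, random_seq(rng, 200)),
        "mic": ReferenceSequence("mic", SourceClass.MICROBIAL, random_seq(rng, 200)),
    }
    annotations = [
        RegionAnnotation("K1", 0, 100, RegionLabel.LTR),
        RegionAnnotation("K1", 100, 250, RegionLabel.GAG_POL),
        RegionAnnotation("K1", 250, 300, RegionLabel.ENV),
        RegionAnnotation("H1", 0, 100, RegionLabel.LTR),
        RegionAnnotation("H1", 100, 250, RegionLabel.GAG_POL),
        RegionAnnotation("H1", 250, 300, RegionLabel.ENV),
    ]
    return ReferenceSet(sequences=seqs, annotations=annotations)


@pytest.fixture
def default_params():
    return ClassifierParams()


@pytest.fixture(scope="session")
def small_sim():
    """One simulated sample shared across read-only tests."""
    cfg = SimulationConfig(seed=42, n_tags=5000)
    ref, meta = build_reference(cfg)
    records, truth = simulate_tags(ref, cfg, "s1")
    return cfg, ref, meta, records, truth
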