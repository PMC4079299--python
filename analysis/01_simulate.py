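"""Simulate the two synthetic study datasets.

Builds (a) a healthy-brain-style cohort whose HERV family mixture is
dominated by HERV-H followed by HERV-K, and (b) a two-group clinical
cohort (HIV+ vs HIV-) in which per-sample HERV-K env abundance is higher
in the HIV+ group and drives a planted 20-gene host module.  Writes the
labeled reference, per-sample FASTQs, the gene x sample count matrix, the
gene -> term map and all ground-truth tables under results/data/.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import sys
from pathlib import Path

from retroscope.simulate import SimulationConfig, simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/data")


def main() -> None:
    cfg = SimulationConfig(seed=SEED, n_tags=20_000)
    ref, matrix, term_map, truth, paths = simulate_cohort(
        cfg, out_dir=OUT, write_fastqs=True
    )
    print(f"seed {SEED}: {len(cfg.samples)} samples x {cfg.n_tags} tags")
    print(f"reference: {len(ref.sequences)} sequences, "
          f"{len(ref.families)} HERV families")
    print(f"count matrix: {matrix.shape[0]} genes x {matrix.shape[1]} samples")
    print(f"planted module: {len(truth.planted_module_genes)} genes "
          f"(term {truth.planted_term})")
    env = truth.env_abundance
    pos = [v for s, v in env.items() if s.startswith("HIVpos")]
    neg = [v for s, v in env.items() if s.startswith("HIVneg")]
    print(f"true env abundance: HIV+ mean {sum(pos)/len(pos):.2f}, "
          f"HIV- mean {sum(neg)/len(neg):.2f}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
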