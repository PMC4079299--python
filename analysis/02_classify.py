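"""Classify every simulated sample's tags through the triage hierarchy.

Each tag is assigned to rRNA, host transcriptome, nuclear genome, mtDNA,
microbial, HERV (one family + region, or ambiguous) or unassigned, in that
priority order.  Writes per-sample assignment tables and category
breakdowns under results/classification/ and prints the triage summary
next to the generative truth.

Run after 01_simulate.py:  python analysis/02_classify.py
"""

from pathlib import Path

import pandas as pd

from retroscope.classify import (
    Category,
    ClassifierParams,
    classify_sample,
    write_assignments,
    write_breakdown,
)
from retroscope.reference import load_reference

DATA = Path("results/data")
OUT = Path("results/classification")


def main() -> None:
    ref = load_reference(DATA / "reference.fasta", DATA / "regions.tsv")
    params = ClassifierParams()
    OUT.mkdir(parents=True, exist_ok=True)
    samples = pd.read_csv(DATA / "samples.tsv", sep="\t")["sample_id"]
    print("sample      tags     rRNA%   host%   HERV%   ambig%  unass%")
    for sid in samples:
        table, breakdown = classify_sample(
            DATA / f"{sid}.fastq", ref, params, sid
        )
        write_assignments(table, OUT / f"{sid}.assignments.tsv")
        write_breakdown(breakdown, OUT / f"{sid}.breakdown.tsv")
        fr = breakdown.fractions
        print(
            f"{sid:<10} {breakdown.total:>6}  "
            f"{fr.get(Category.RRNA, 0):6.2f}  "
            f"{fr.get(Category.HOST_TX, 0):6.2f}  "
            f"{fr.get(Category.HERV, 0):6.2f}  "
            f"{fr.get(Category.HERV_AMBIGUOUS, 0):6.2f}  "
            f"{fr.get(Category.UNASSIGNED, 0):6.2f}"
        )
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
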