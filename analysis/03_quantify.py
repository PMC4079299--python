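"""Family and region abundance profiles, and the group contrast.

Computes each sample's HERV family tag frequencies (percent of
unambiguously assigned HERV tags) and the length-normalized env /
gag-pol / LTR region frequencies, then compares per-family frequencies
between the HIV+ and HIV- groups with the exact two-sided Mann-Whitney
test.  Writes profiles and the comparison table under
results/quantification/.

Run after 02_classify.py:  python analysis/03_quantify.py
"""

from pathlib import Path

import pandas as pd

from retroscope.quantify import build_profile, compare_groups, write_profile
from retroscope.reference import RegionLabel, load_reference

DATA = Path("results/data")
CLS = Path("results/classification")
OUT = Path("results/quantification")


def main() -> None:
    ref = load_reference(DATA / "reference.fasta", DATA / "regions.tsv")
    samples = pd.read_csv(DATA / "samples.tsv", sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)

    profiles = {}
    for sid in samples["sample_id"]:
        table = pd.read_csv(
            CLS / f"{sid}.assignments.tsv", sep="\t", keep_default_na=False
        )
        prof = build_profile(table, ref, sid)
        write_profile(prof, OUT / f"{sid}.profile.tsv")
        profiles[sid] = prof

    print("median family frequencies (% of HERV tags):")
    rows = []
    for fam in ref.families:
        vals = pd.Series(
            {s: p.family_freq.get(fam, 0.0) for s, p in profiles.items()}
        )
        rows.append({"family": fam, "median_freq": vals.median()})
        print(f"  {fam:<10} {vals.median():6.2f}")
    pd.DataFrame(rows).to_csv(OUT / "family_medians.tsv", sep="\t", index=False)

    print("\nHERV-K region frequencies (length-normalized, % within family):")
    for lbl in (RegionLabel.ENV, RegionLabel.GAG_POL, RegionLabel.LTR):
        vals = [
            p.region_freq.get("HERV-K", {}).get(lbl, 0.0)
            for p in profiles.values()
        ]
        med = pd.Series(vals).median()
        print(f"  {lbl.value:<8} {med:6.2f}")

    groups = samples.set_index("sample_id")["group"]
    print("\ngroup contrast (exact Mann-Whitney, two-sided):")
    cmp_rows = []
    for fam in ref.families:
        by_group: dict[str, list[float]] = {}
        for sid, prof in profiles.items():
            by_group.setdefault(groups[sid], []).append(
                prof.family_freq.get(fam, 0.0)
            )
        cmp = compare_groups(by_group, metric=f"{fam} frequency")
        cmp_rows.append(
            {
                "metric": cmp.metric,
                **{f"median_{g}": round(m, 3) for g, m in cmp.medians.items()},
                "U": cmp.U,
                "p_two_sided": cmp.p_two_sided,
            }
        )
        print(
            f"  {fam:<10} median HIV+ {cmp.medians.get('HIVpos', 0):6.2f}  "
            f"HIV- {cmp.medians.get('HIVneg', 0):6.2f}  p={cmp.p_two_sided:.4f}"
        )
    pd.DataFrame(cmp_rows).to_csv(
        OUT / "group_comparison.tsv", sep="\t", index=False
    )
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
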