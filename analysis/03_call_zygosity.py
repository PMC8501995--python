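#!/usr/bin/env python
"""Call insertion zygosity from the truth alignments.

Applies the alignment filter (primary, properly paired with insert size
150-700, MAPQ > 28), counts reads and pairs spanning each insertion
point, and classifies homozygous / heterozygous / undetermined using the
10x minimum-coverage rule in a 2 kb window.  Also demonstrates the
pooled-sibling rule on the per-line verdicts.
"""

from pathlib import Path

import pandas as pd

from temkit import insertions, io, zygosity

SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    calls_path = RESULTS / "02_insertion_calls.tsv"
    if not calls_path.exists():
        raise SystemExit("run analysis/02_find_insertions.py first")
    calls_df = pd.read_csv(calls_path, sep="\t", keep_default_na=False)
    truth = pd.read_csv(RESULTS / "01_truth_insertions.tsv", sep="\t").set_index(
        ["line", "chrom", "position"]
    )
    genome = io.read_fasta(SCRATCH / "genome.fa")
    sizes = {c: len(s) for c, s in genome.items()}

    rows = []
    for line_id, group in calls_df.groupby("line_id"):
        records = io.read_sam(SCRATCH / f"{line_id}.sam")
        line_calls = [
            insertions.InsertionCall(
                r.chrom, int(r.position), r.tsd, r.orientation,
                int(r.head_support), int(r.tail_support), line_id,
            )
            for r in group.itertuples()
        ]
        zcalls = zygosity.classify_all(records, line_calls, contig_sizes=sizes)
        n_correct = 0
        for z in zcalls:
            key = (line_id, z.insertion.chrom, z.insertion.position)
            truth_z = truth.loc[key, "zygosity"] if key in truth.index else "NA"
            n_correct += z.verdict == truth_z
            rows.append(
                {
                    "line": line_id,
                    "chrom": z.insertion.chrom,
                    "position": z.insertion.position,
                    "verdict": z.verdict,
                    "truth": truth_z,
                    "spanning_reads": z.spanning_reads,
                    "spanning_pairs": z.spanning_pairs,
                    "min_window_coverage": z.min_window_coverage_observed,
                }
            )
        tally = pd.Series([z.verdict for z in zcalls]).value_counts().to_dict()
        print(f"{line_id}: {tally}, {n_correct}/{len(zcalls)} match truth")

    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "03_zygosity.tsv", sep="\t", index=False)

    # pooled rule: verdicts of four identical siblings collapse per the
    # all-homozygous-or-heterozygous rule
    demo = out[out["line"] == "hcSimA"].head(1)
    if len(demo):
        r = demo.iloc[0]
        ins = insertions.InsertionCall(r["chrom"], int(r["position"]), "", "+", 1, 1)
        sibs = [
            zygosity.ZygosityCall(ins, v, 0, 0, 20.0)
            for v in ["homozygous", "homozygous", "heterozygous", "homozygous"]
        ]
        print("pooled [hom,hom,het,hom] ->", zygosity.pool_zygosity(sibs).verdict)
    print(f"wrote {len(out)} zygosity calls to {RESULTS}/03_zygosity.tsv")


if __name__ == "__main__":
    main()
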