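#!/usr/bin/env python
"""Detect novel TE insertions from junction reads in each simulated line.

Reads the FASTQ and genome written by 01_simulate_cohort.py, scans for
the donor LTR head/tail 20-mers, anchors the genomic flanks and pairs
breakpoints into calls; reports precision/recall against the truth table
and writes the calls as TSV and BED6.
"""

from pathlib import Path

import pandas as pd

from temkit import insertions, io

SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    if not (SCRATCH / "genome.fa").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    genome = io.read_fasta(SCRATCH / "genome.fa")
    donors = io.read_fasta(SCRATCH / "donors.fa")
    head, tail = donors["consensus"][:20], donors["consensus"][-20:]
    cfg = insertions.JunctionConfig(head=head, tail=tail)
    truth = pd.read_csv(RESULTS / "01_truth_insertions.tsv", sep="\t")

    all_calls = []
    for line_id in ("hcSimA", "hcSimB", "controlSim"):
        reads = io.read_fastq(SCRATCH / f"{line_id}_R1.fastq") + io.read_fastq(
            SCRATCH / f"{line_id}_R2.fastq"
        )
        calls = insertions.find_insertions(reads, genome, cfg, line_id=line_id)
        t = truth[truth["line"] == line_id]
        truth_set = set(zip(t["chrom"], t["position"]))
        found = {(c.chrom, c.position) for c in calls}
        tp = len(found & truth_set)
        recall = tp / len(truth_set) if truth_set else float("nan")
        precision = tp / len(found) if found else float("nan")
        print(
            f"{line_id}: {len(calls)} calls, recall={recall:.3f} "
            f"precision={precision:.3f}"
            if truth_set
            else f"{line_id}: {len(calls)} calls (control, none expected)"
        )
        all_calls.extend(calls)

    io.write_table(all_calls, RESULTS / "02_insertion_calls.tsv")
    io.calls_to_bed6(all_calls, RESULTS / "02_insertion_calls.bed")
    print(f"wrote {len(all_calls)} calls to {RESULTS}/02_insertion_calls.tsv/.bed")


if __name__ == "__main__":
    main()
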