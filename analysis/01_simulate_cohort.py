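#!/usr/bin/env python
"""Simulate the study cohort: a two-chromosome toy genome with genes and
nine tiling chromatin states, a family of eight donor TE copies with
private SNPs, and three resequenced lines — two carrying planted
insertions and one insertion-free control — each with 30x paired-end
reads and ground-truth alignments.

Bulky intermediates (FASTA/FASTQ/SAM) go to scratch/cohort/; the truth
tables land in results/.
"""

from pathlib import Path

import pandas as pd

from temkit import io, simulate

SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")

LINES = {"hcSimA": 25, "hcSimB": 15, "controlSim": 0}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = simulate.SimulationConfig(seed=11, depth=30.0, het_fraction=0.4)
    sim = simulate.simulate_genome(cfg)
    donors = simulate.make_donor_copies(cfg)

    io.write_fasta(sim.chromosomes, SCRATCH / "genome.fa")
    io.write_fasta(
        {"consensus": donors.consensus, **donors.copies}, SCRATCH / "donors.fa"
    )
    io.write_gff3(sim.annotation, SCRATCH / "annotation.gff3")
    io.write_states_bed(sim.states, SCRATCH / "chromatin_states.bed")
    for mark, track in sim.tracks.items():
        io.write_bedgraph(track, SCRATCH / f"{mark.replace('.', '')}.bedGraph")

    truth_rows = []
    for i, (line_id, n_ins) in enumerate(LINES.items()):
        line = simulate.plant_insertions(
            sim, donors, n_ins, cfg, seed=100 + i, line_id=line_id
        )
        reads = simulate.simulate_reads(line, cfg, seed=200 + i)
        io.write_fastq_pair(
            reads, SCRATCH / f"{line_id}_R1.fastq", SCRATCH / f"{line_id}_R2.fastq"
        )
        io.write_truth_sam(reads, SCRATCH / f"{line_id}.sam")
        truth_rows.extend(
            {
                "line": line_id,
                "chrom": ins.chrom,
                "position": ins.position,
                "strand": ins.strand,
                "tsd": ins.tsd,
                "zygosity": ins.zygosity,
                "donor_copy": ins.donor_id,
            }
            for ins in line.insertions
        )
        print(f"{line_id}: {n_ins} planted insertions, {len(reads.pairs)} read pairs")

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(RESULTS / "01_truth_insertions.tsv", sep="\t", index=False)
    snps = pd.DataFrame(
        [
            {"copy_id": s.copy_id, "position": s.position + 1, "ref": s.ref, "alt": s.alt}
            for s in donors.snps
        ]
    )
    snps.to_csv(RESULTS / "01_truth_donor_snps.tsv", sep="\t", index=False)
    print(
        f"wrote {len(truth)} truth insertions and {len(snps)} donor SNPs; "
        f"genome/reads under {SCRATCH}/"
    )


if __name__ == "__main__":
    main()
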