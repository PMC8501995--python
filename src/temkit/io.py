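"""Readers and writers for the standard formats the pipeline exchanges.

All emitted files use their community conventions: FASTA/FASTQ, GFF3 and
SAM/VCF are 1-based, BED and bedGraph are 0-based half-open.  In-memory
objects (see :mod:`temkit.simulate`) are 0-based half-open throughout.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .simulate import (
    Annotation,
    Feature,
    ReadSet,
    StateSegmentation,
)

# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fastq_pair(readset: ReadSet, r1_path, r2_path) -> None:
    q = "I"
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in readset.pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{q * len(p.seq1)}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{q * len(p.seq2)}\n")


def read_fastq(path) -> list[str]:
    seqs = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            seqs.append(rec.sequence)
    return seqs


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

_GFF_KIND = {
    "gene": "gene",
    "lncRNA": "lnc_RNA",
    "pseudogene": "pseudogene",
    "transposable_element": "transposable_element",
}
_GFF_KIND_BACK = {v: k for k, v in _GFF_KIND.items()}


def write_gff3(annotation: Annotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotation.features:
            top = _GFF_KIND[f.kind]
            fh.write(
                f"{f.chrom}\ttemkit\t{top}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.feature_id}\n"
            )
            if f.kind != "gene":
                continue
            parts = [("exon", s, e) for s, e in f.exons]
            if f.utr5:
                parts.append(("five_prime_UTR", *f.utr5))
            if f.utr3:
                parts.append(("three_prime_UTR", *f.utr3))
            for sub, s, e in sorted(parts, key=lambda t: t[1]):
                fh.write(
                    f"{f.chrom}\ttemkit\t{sub}\t{s + 1}\t{e}\t.\t{f.strand}\t.\t"
                    f"Parent={f.feature_id}\n"
                )


def read_gff3(path) -> Annotation:
    features: dict[str, Feature] = []
    by_id: dict[str, Feature] = {}
    features = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            start0, end0 = int(start) - 1, int(end)
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype in _GFF_KIND_BACK:
                feat = Feature(
                    feature_id=fields["ID"],
                    chrom=chrom,
                    start=start0,
                    end=end0,
                    strand=strand,
                    kind=_GFF_KIND_BACK[ftype],
                )
                by_id[feat.feature_id] = feat
                features.append(feat)
            elif ftype == "exon":
                by_id[fields["Parent"]].exons.append((start0, end0))
            elif ftype == "five_prime_UTR":
                by_id[fields["Parent"]].utr5 = (start0, end0)
            elif ftype == "three_prime_UTR":
                by_id[fields["Parent"]].utr3 = (start0, end0)
    for f in features:
        f.exons.sort()
    return Annotation(features)


# ---------------------------------------------------------------------------
# chromatin states (BED) and signal tracks (bedGraph)
# ---------------------------------------------------------------------------


def write_states_bed(states: StateSegmentation, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, st in states.segments:
            fh.write(f"{chrom}\t{s}\t{e}\t{st}\n")


def read_states_bed(path) -> StateSegmentation:
    segs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, st = line.split()[:4]
            segs.append((chrom, int(s), int(e), int(st)))
    return StateSegmentation(segs)


def write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in track.items():
            arr = np.asarray(arr)
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate(([0], change, [len(arr)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    track = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()[:4]
            track[chrom][int(s) : int(e)] = float(v)
    return track


# ---------------------------------------------------------------------------
# truth alignments (SAM)
# ---------------------------------------------------------------------------

_CIGAR_OP = {"M": 0, "S": 4}


def sam_header(chrom_sizes: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_references(
        list(chrom_sizes), list(chrom_sizes.values())
    )


def sam_records(readset: ReadSet, header: pysam.AlignmentHeader | None = None):
    """Yield the truth alignments of a read set as pysam records.

    Both mates of a fragment with at least one aligned mate are emitted; a
    mate wholly inside an inserted element is placed (RNAME/POS of its
    mate) and flagged unmapped.  TLEN records the true fragment length.
    """
    header = header or sam_header(readset.chrom_sizes)
    for p in readset.pairs:
        if p.aln1 is None and p.aln2 is None:
            continue
        for which, (aln, mate, seq) in enumerate(
            [(p.aln1, p.aln2, p.seq1), (p.aln2, p.aln1, p.seq2)]
        ):
            a = pysam.AlignedSegment(header)
            a.query_name = p.name
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            flag = 1  # paired
            if p.proper:
                flag |= 2
            flag |= 64 if which == 0 else 128
            anchor = aln if aln is not None else mate
            a.reference_id = header.get_tid(anchor.chrom)
            if aln is None:
                flag |= 4
                a.reference_start = mate.ref_start
                a.mapping_quality = 0
            else:
                a.reference_start = aln.ref_start
                a.mapping_quality = 60
                a.cigartuples = [(_CIGAR_OP[op], ln) for op, ln in aln.cigar]
                if aln.reverse:
                    flag |= 16
            if mate is None:
                flag |= 8
                a.next_reference_id = a.reference_id
                a.next_reference_start = a.reference_start
            else:
                a.next_reference_id = header.get_tid(mate.chrom)
                a.next_reference_start = mate.ref_start
                if mate.reverse:
                    flag |= 32
            a.flag = flag
            # signed template length: leftmost mate positive
            if aln is not None and mate is not None:
                sign = 1 if aln.ref_start <= mate.ref_start else -1
                if aln.ref_start == mate.ref_start:
                    sign = 1 if which == 0 else -1
                a.template_length = sign * p.fragment_length
            else:
                a.template_length = p.fragment_length if aln is not None else 0
            yield a


def write_truth_sam(readset: ReadSet, path) -> None:
    header = sam_header(readset.chrom_sizes)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in sorted(
            sam_records(readset, header), key=lambda a: (a.reference_id, a.reference_start)
        ):
            out.write(rec)


def read_sam(path) -> list[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return list(fh)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_table(records: Sequence, path, columns: list[str] | None = None) -> None:
    """Write dataclass records (or dicts) as a TSV."""
    rows = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for r in records
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def calls_to_bed6(calls: Sequence, path) -> None:
    """Insertion calls as BED6 (score = total junction support)."""
    with open(path, "w") as fh:
        for c in calls:
            start = c.position - 1 - len(c.tsd)
            score = getattr(c, "head_support", 0) + getattr(c, "tail_support", 0)
            fh.write(
                f"{c.chrom}\t{start}\t{c.position - 1}\tinsertion\t{score}\t{c.orientation}\n"
            )


# ---------------------------------------------------------------------------
# multi-sample VCF
# ---------------------------------------------------------------------------


def write_multisample_vcf(path, contigs: dict[str, int], samples: list[str], records) -> None:
    """Write a minimal multi-sample VCF.

    ``records`` yield dicts with chrom, pos (1-based), ref, alts (tuple),
    mq (INFO/MQ) and ``genotypes``: per-sample dict with GT (tuple), DP,
    GQ, AD (tuple, ref first).
    """
    header = pysam.VariantHeader()
    for name, size in contigs.items():
        header.contigs.add(name, length=size)
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            r = out.new_record(
                contig=rec["chrom"],
                start=rec["pos"] - 1,
                alleles=(rec["ref"], *rec["alts"]),
            )
            r.info["MQ"] = float(rec["mq"])
            for s in samples:
                g = rec["genotypes"][s]
                r.samples[s]["GT"] = g["GT"]
                r.samples[s]["DP"] = g["DP"]
                r.samples[s]["GQ"] = g["GQ"]
                r.samples[s]["AD"] = g["AD"]
            out.write(r)
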