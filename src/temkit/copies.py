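"""Attribution of TE-family reads to individual donor genomic copies.

Each full-length donor copy of the family carries a handful of private
SNPs relative to the family consensus.  In any read set aligned to the
consensus (transcriptome, eccDNA/mobilome, or newly integrated genomic
copies), the allele frequency of a copy-private SNP estimates that copy's
share of the reads; averaging over a copy's private SNPs gives its
relative abundance.  For genomic data, a control line with no new
insertions calibrates each SNP: in such a line every copy is present in
exactly one dose, so each private SNP should sit at 1/n_copies — the
observed deviation becomes a per-SNP weight.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import DonorSNP

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class CopySNPTable:
    snps: list[DonorSNP]
    consensus: str
    ambiguous_columns: list[int] = field(default_factory=list)

    def attribution_snps(self) -> list[DonorSNP]:
        return [s for s in self.snps if not s.is_ltr]

    def copies(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.snps:
            seen.setdefault(s.copy_id)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "copy_id": s.copy_id,
                    "position": s.position + 1,
                    "consensus_base": s.ref,
                    "copy_base": s.alt,
                    "is_ltr": s.is_ltr,
                }
                for s in self.snps
            ]
        )


@dataclass
class CopyAbundanceProfile:
    dataset: str
    mean_frequency: dict[str, float]  # unweighted (or weighted) mean per copy
    abundance: dict[str, float]  # renormalized to sum 1 over attributable copies
    n_informative_snps: dict[str, int]
    non_attributable: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "copy_id": list(self.mean_frequency),
                "mean_frequency": list(self.mean_frequency.values()),
                "abundance": [self.abundance.get(c, np.nan) for c in self.mean_frequency],
                "n_informative_snps": [
                    self.n_informative_snps[c] for c in self.mean_frequency
                ],
                "dataset": self.dataset,
            }
        )


def derive_copy_snps(
    aligned_copies: dict[str, str],
    ltr_length: int = 0,
) -> CopySNPTable:
    """Consensus and copy-private SNPs from equal-length aligned copies.

    The consensus takes the majority base per column (ties resolved by
    alphabet order and the column excluded from SNP calling).  A column
    yields a SNP only when exactly one copy deviates from the consensus.
    Columns within ``ltr_length`` of either end are flagged ``is_ltr`` and
    excluded from attribution.
    """
    ids = list(aligned_copies)
    seqs = [aligned_copies[i].upper() for i in ids]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("aligned copies must all have the same length")
    L = lengths.pop()
    consensus = []
    snps: list[DonorSNP] = []
    ambiguous: list[int] = []
    for j in range(L):
        column = [s[j] for s in seqs]
        counts = defaultdict(int)
        for b in column:
            counts[b] += 1
        best = max(counts.values())
        majority = sorted(b for b, c in counts.items() if c == best)
        cons = majority[0]
        consensus.append(cons)
        if len(majority) > 1:
            ambiguous.append(j)
            continue
        deviants = [(ids[k], column[k]) for k in range(len(ids)) if column[k] != cons]
        if len(deviants) == 1:
            copy_id, alt = deviants[0]
            is_ltr = j < ltr_length or j >= L - ltr_length
            snps.append(DonorSNP(copy_id, j, cons, alt, is_ltr=is_ltr))
    return CopySNPTable(snps, "".join(consensus), ambiguous)


def pileup_base_counts(alignments, consensus_length: int) -> np.ndarray:
    """(L, 4) base counts over the consensus from (start, seq) records or
    pysam alignments."""
    counts = np.zeros((consensus_length, 4), dtype=np.int64)
    lut = np.full(256, -1, dtype=np.int8)
    for b, j in _BASE_INDEX.items():
        lut[ord(b)] = j
        lut[ord(b.lower())] = j
    for rec in alignments:
        if isinstance(rec, tuple):
            start, seq = rec
        else:  # pysam AlignedSegment, gapless alignment assumed
            if rec.is_unmapped:
                continue
            start, seq = rec.reference_start, rec.query_sequence
        idx = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        pos = np.arange(start, start + len(seq))
        ok = (idx >= 0) & (pos >= 0) & (pos < consensus_length)
        np.add.at(counts, (pos[ok], idx[ok]), 1)
    return counts


def snp_allele_frequencies(
    pileup: np.ndarray,
    table: CopySNPTable,
    min_coverage: int = 5,
) -> dict[int, float]:
    """Per-SNP alternative-allele frequency: alt reads / total reads at the
    SNP position.  SNPs covered by fewer than ``min_coverage`` reads are
    missing (absent from the result)."""
    freqs: dict[int, float] = {}
    for s in table.attribution_snps():
        total = int(pileup[s.position].sum())
        if total < min_coverage:
            continue
        alt = int(pileup[s.position, _BASE_INDEX[s.alt]])
        freqs[s.position] = alt / total
    return freqs


def calibrate_weights(
    control_frequencies: dict[int, float],
    n_copies: int = 8,
) -> dict[int, float]:
    """Per-SNP weight from a control (no new insertions) genome pileup:
    weight = (1/n_copies) / observed control frequency.  SNPs at zero
    control frequency are excluded."""
    expected = 1.0 / n_copies
    weights: dict[int, float] = {}
    for pos, f in control_frequencies.items():
        if f > 0:
            weights[pos] = expected / f
    return weights


def copy_abundance(
    frequencies: dict[int, float],
    table: CopySNPTable,
    weights: dict[int, float] | None = None,
    dataset: str = "dataset",
    min_informative_snps: int = 1,
) -> CopyAbundanceProfile:
    """Per-copy relative abundance: mean of (optionally weighted) private-SNP
    allele frequencies, renormalized to sum to one over attributable copies."""
    per_copy: dict[str, list[float]] = {c: [] for c in table.copies()}
    for s in table.attribution_snps():
        if s.position not in frequencies:
            continue
        if weights is not None:
            if s.position not in weights:
                continue
            per_copy[s.copy_id].append(frequencies[s.position] * weights[s.position])
        else:
            per_copy[s.copy_id].append(frequencies[s.position])
    if not any(per_copy.values()):
        raise ValueError("no informative SNPs in any copy")
    mean_freq: dict[str, float] = {}
    n_snps: dict[str, int] = {}
    non_attributable: list[str] = []
    for c, vals in per_copy.items():
        n_snps[c] = len(vals)
        if len(vals) >= min_informative_snps:
            mean_freq[c] = float(np.mean(vals))
        else:
            non_attributable.append(c)
            mean_freq[c] = float("nan")
    total = sum(v for c, v in mean_freq.items() if c not in non_attributable)
    abundance = {
        c: (mean_freq[c] / total if total > 0 else 0.0)
        for c in mean_freq
        if c not in non_attributable
    }
    return CopyAbundanceProfile(
        dataset=dataset,
        mean_frequency=mean_freq,
        abundance=abundance,
        n_informative_snps=n_snps,
        non_attributable=non_attributable,
    )
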