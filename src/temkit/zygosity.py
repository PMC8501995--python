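"""Zygosity of TE insertions from reference alignments.

An insertion is homozygous when the resequenced line carries it on both
haplotypes: no read (and no properly mapped pair) can then span the
insertion point on the reference, while coverage around the point stays
high.  The caller therefore filters alignments the way the original
screen did (primary, properly paired with insert size in [150, 700],
MAPQ > 28, non-duplicate), counts spanning reads and spanning pairs, and
requires a minimum per-base coverage in a 2 kb window centred on the
insertion point before calling homozygous.

Spanning is defined conservatively: a read spans only if its alignment is
unclipped and strictly contains the point (start < point <= end, 1-based);
soft-clipped alignments at a junction are junction evidence, not spanning
evidence.  A pair spans if both mates are unclipped and the outer fragment
interval contains the point.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .insertions import InsertionCall

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ZygosityConfig:
    min_mapq: int = 28  # exclusive: keep MAPQ > min_mapq
    insert_min: int = 150
    insert_max: int = 700
    window: int = 2000  # centred on the insertion point
    min_window_coverage: int = 10
    proper_pair_only: bool = True
    primary_only: bool = True

    def __post_init__(self):
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min must be <= insert_max")
        if self.window <= 0:
            raise ValueError("window must be > 0")


@dataclass
class FilteredAln:
    """Minimal alignment record kept after filtering."""

    qname: str
    chrom: str
    start: int  # 0-based
    end: int  # 0-based exclusive
    clipped: bool


@dataclass
class ZygosityCall:
    insertion: InsertionCall
    verdict: str
    spanning_reads: int
    spanning_pairs: int
    min_window_coverage_observed: float
    window_truncated: bool = False


def filter_alignments(alignments, cfg: ZygosityConfig = ZygosityConfig()) -> list[FilteredAln]:
    """Apply the screen's alignment filter to pysam-style records.

    Keeps primary, non-duplicate, properly paired records whose template
    length lies within the configured insert range and whose MAPQ exceeds
    the (exclusive) threshold.  Malformed records are skipped.
    """
    kept: list[FilteredAln] = []
    for a in alignments:
        try:
            if a.is_unmapped:
                continue
            if cfg.primary_only and (a.is_secondary or a.is_supplementary):
                continue
            if a.is_duplicate:
                continue
            if cfg.proper_pair_only:
                if not a.is_proper_pair:
                    continue
                if not (cfg.insert_min <= abs(a.template_length) <= cfg.insert_max):
                    continue
            if not (a.mapping_quality > cfg.min_mapq):
                continue
            cig = a.cigartuples or []
            clipped = any(op in (4, 5) for op, _ in cig)
            kept.append(
                FilteredAln(
                    qname=a.query_name,
                    chrom=a.reference_name,
                    start=a.reference_start,
                    end=a.reference_end,
                    clipped=clipped,
                )
            )
        except (AttributeError, TypeError):
            continue
    return kept


class AlignmentIndex:
    """Filtered alignments indexed by chromosome for window queries."""

    def __init__(self, filtered: list[FilteredAln], contig_sizes: dict[str, int]):
        self.contig_sizes = contig_sizes
        self._by_chrom: dict[str, list[FilteredAln]] = defaultdict(list)
        for a in filtered:
            self._by_chrom[a.chrom].append(a)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, alns in self._by_chrom.items():
            alns.sort(key=lambda a: a.start)
            self._starts[chrom] = [a.start for a in alns]
            self._max_len[chrom] = max((a.end - a.start for a in alns), default=0)

    def overlapping(self, chrom: str, lo: int, hi: int) -> list[FilteredAln]:
        alns = self._by_chrom.get(chrom, [])
        if not alns:
            return []
        starts = self._starts[chrom]
        i = bisect_left(starts, lo - self._max_len[chrom])
        j = bisect_right(starts, hi)
        return [a for a in alns[i:j] if a.end > lo and a.start < hi]


def classify_zygosity(
    alignments,
    insertion: InsertionCall,
    cfg: ZygosityConfig = ZygosityConfig(),
    contig_sizes: dict[str, int] | None = None,
) -> ZygosityCall:
    """Classify one insertion; ``alignments`` is a filtered list or an
    :class:`AlignmentIndex` (records are NOT re-filtered here)."""
    if isinstance(alignments, AlignmentIndex):
        index = alignments
    else:
        index = AlignmentIndex(list(alignments), contig_sizes or {})
    point = insertion.position  # 1-based
    contig_size = index.contig_sizes.get(insertion.chrom)
    half = cfg.window // 2
    lo = (point - 1) - half
    hi = (point - 1) + (cfg.window - half)
    truncated = False
    if lo < 0:
        lo, truncated = 0, True
    if contig_size is not None and hi > contig_size:
        hi, truncated = contig_size, True
    records = index.overlapping(insertion.chrom, lo, hi)

    cov = np.zeros(hi - lo, dtype=np.int32)
    spanning_reads = 0
    mates: dict[str, list[FilteredAln]] = defaultdict(list)
    for a in records:
        s = max(a.start, lo) - lo
        e = min(a.end, hi) - lo
        if e > s:
            cov[s:e] += 1
        mates[a.qname].append(a)
        # read-level spanning: unclipped and strictly containing the point
        if not a.clipped and a.start + 1 < point <= a.end:
            spanning_reads += 1
    spanning_pairs = 0
    for recs in mates.values():
        if len(recs) != 2:
            continue
        m1, m2 = recs
        if m1.clipped or m2.clipped:
            continue
        frag_start = min(m1.start, m2.start)
        frag_end = max(m1.end, m2.end)
        if frag_start + 1 < point <= frag_end:
            spanning_pairs += 1
    min_cov = float(cov.min()) if len(cov) else 0.0

    spanning = spanning_reads > 0 or spanning_pairs > 0
    if min_cov >= cfg.min_window_coverage:
        verdict = HETEROZYGOUS if spanning else HOMOZYGOUS
    else:
        verdict = UNDETERMINED
    return ZygosityCall(
        insertion=insertion,
        verdict=verdict,
        spanning_reads=spanning_reads,
        spanning_pairs=spanning_pairs,
        min_window_coverage_observed=min_cov,
        window_truncated=truncated,
    )


def classify_all(
    alignments,
    insertions,
    cfg: ZygosityConfig = ZygosityConfig(),
    contig_sizes: dict[str, int] | None = None,
) -> list[ZygosityCall]:
    """Filter once, classify every insertion."""
    filtered = filter_alignments(alignments, cfg)
    index = AlignmentIndex(filtered, contig_sizes or {})
    return [classify_zygosity(index, ins, cfg) for ins in insertions]


def pool_zygosity(sibling_calls: list[ZygosityCall]) -> ZygosityCall:
    """Pooled-sample rule: homozygous only if every sibling is homozygous;
    undetermined only if all are; anything else is heterozygous."""
    if not sibling_calls:
        raise ValueError("need at least one sibling call")
    first = sibling_calls[0].insertion
    for c in sibling_calls[1:]:
        if (c.insertion.chrom, c.insertion.position) != (first.chrom, first.position):
            raise ValueError("pooled calls must refer to the same insertion")
    verdicts = [c.verdict for c in sibling_calls]
    if all(v == HOMOZYGOUS for v in verdicts):
        verdict = HOMOZYGOUS
    elif all(v == UNDETERMINED for v in verdicts):
        verdict = UNDETERMINED
    else:
        verdict = HETEROZYGOUS
    return ZygosityCall(
        insertion=first,
        verdict=verdict,
        spanning_reads=sum(c.spanning_reads for c in sibling_calls),
        spanning_pairs=sum(c.spanning_pairs for c in sibling_calls),
        min_window_coverage_observed=min(
            c.min_window_coverage_observed for c in sibling_calls
        ),
    )
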