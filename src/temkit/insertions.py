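"""Junction-read detection of novel LTR-retrotransposon insertions.

A new insertion creates two junctions in a resequenced genome: genomic
flank followed by the first 20 bases of the LTR ("head"), and the last 20
bases of the LTR ("tail") followed by genomic flank (mirrored for a minus
orientation insertion).  Reads carrying a motif are split into motif and
flank; flanks are anchored on the reference by exact match; a head-side
and tail-side breakpoint within a small distance of each other define an
insertion call, whose target-site duplication (TSD) is the reference
interval between the two breakpoints.

Positions follow one convention throughout the package: an insertion's
``position`` is the 1-based reference base immediately 3' of the TSD.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._seq import check_dna, find_all, revcomp


@dataclass(frozen=True)
class JunctionConfig:
    head: str
    tail: str
    min_flank: int = 20
    max_pair_distance: int = 30
    require_unique_flank_match: bool = True

    def __post_init__(self):
        head = check_dna(self.head, "head")
        tail = check_dna(self.tail, "tail")
        if len(head) != 20 or len(tail) != 20:
            raise ValueError("head and tail motifs must be exactly 20 bases")
        object.__setattr__(self, "head", head)
        object.__setattr__(self, "tail", tail)
        if self.min_flank < 1:
            raise ValueError("min_flank must be >= 1")
        if self.max_pair_distance < 0:
            raise ValueError("max_pair_distance must be >= 0")


@dataclass(frozen=True)
class Flank:
    """Genomic fragment flanking a motif hit in a read.

    ``motif`` records which terminal motif produced it; the flank precedes a
    head hit and follows a tail hit (in the scanned orientation of the read).
    """

    seq: str
    motif: str  # "head" | "tail"


@dataclass
class Anchor:
    chrom: str
    breakpoint: int  # 0-based reference coordinate of the junction
    side: str  # "left" (5' genomic) | "right" (3' genomic)
    orientation: str  # "+" | "-"
    motif: str
    support: int


@dataclass
class InsertionCall:
    chrom: str
    position: int  # 1-based first reference base 3' of the TSD
    tsd: str
    orientation: str
    head_support: int
    tail_support: int
    line_id: str = ""
    ambiguous: bool = False

    def sort_key(self):
        return (self.chrom, self.position)


@dataclass
class MappingStats:
    unmapped: int = 0
    multimapped_dropped: int = 0


def scan_junction_reads(reads: Iterable[str], cfg: JunctionConfig) -> list[Flank]:
    """Extract motif-flanking genomic fragments from raw read sequences.

    Each read and its reverse complement are scanned, so the caller never
    needs to know the sequencing strand.  Flanks shorter than
    ``cfg.min_flank`` are discarded.
    """
    flanks: list[Flank] = []
    head, tail = cfg.head, cfg.tail
    reads = list(reads)
    if not reads:
        raise ValueError("reads must be nonempty")
    for read in reads:
        read = read.upper()
        for seq in (read, revcomp(read)):
            for i in find_all(head, seq):
                if i >= cfg.min_flank:
                    flanks.append(Flank(seq[:i], "head"))
            for i in find_all(tail, seq):
                rest = seq[i + len(tail) :]
                if len(rest) >= cfg.min_flank:
                    flanks.append(Flank(rest, "tail"))
    return flanks


def map_flanks(
    flanks: Sequence[Flank],
    genome: dict[str, str],
    cfg: JunctionConfig,
) -> tuple[list[Anchor], MappingStats]:
    """Anchor flanks on the reference by exact match (both strands).

    A head flank matching the forward strand marks the 5'-genomic breakpoint
    of a plus-orientation insertion; matching the reverse strand it marks the
    3'-genomic breakpoint of a minus-orientation insertion — and mirrored for
    tail flanks.  Multi-hit flanks are dropped when uniqueness is required,
    otherwise every hit becomes an anchor.
    """
    stats = MappingStats()
    counted = Counter(flanks)
    anchors: dict[tuple, int] = defaultdict(int)
    for flank, support in counted.items():
        hits: list[tuple[str, int, int, str]] = []  # chrom, start, end, strand
        rc = revcomp(flank.seq)
        for chrom, seq in genome.items():
            for i in find_all(flank.seq, seq):
                hits.append((chrom, i, i + len(flank.seq), "+"))
            for i in find_all(rc, seq):
                hits.append((chrom, i, i + len(flank.seq), "-"))
        if not hits:
            stats.unmapped += support
            continue
        if len(hits) > 1 and cfg.require_unique_flank_match:
            stats.multimapped_dropped += support
            continue
        for chrom, start, end, strand in hits:
            if flank.motif == "head":
                if strand == "+":
                    key = (chrom, end, "left", "+", "head")
                else:
                    key = (chrom, start, "right", "-", "head")
            else:  # tail
                if strand == "+":
                    key = (chrom, start, "right", "+", "tail")
                else:
                    key = (chrom, end, "left", "-", "tail")
            anchors[key] += support
    out = [
        Anchor(chrom, bp, side, orient, motif, support)
        for (chrom, bp, side, orient, motif), support in anchors.items()
    ]
    out.sort(key=lambda a: (a.chrom, a.breakpoint, a.side, a.orientation))
    return out, stats


def call_insertions(
    anchors: Sequence[Anchor],
    genome: dict[str, str],
    cfg: JunctionConfig,
    line_id: str = "",
) -> list[InsertionCall]:
    """Pair left and right breakpoints into insertion calls.

    A call requires a left (5' genomic) and a right (3' genomic) anchor of
    the same orientation on the same chromosome with
    ``0 <= left - right <= max_pair_distance``; the TSD is the reference
    interval between them (empty when the breakpoints abut).  Each left
    anchor takes its nearest admissible right anchor (ties to the lower
    coordinate); a right anchor claimed by several left anchors yields one
    call per pairing, flagged ambiguous.
    """
    by_group: dict[tuple[str, str], dict[str, list[Anchor]]] = defaultdict(
        lambda: {"left": [], "right": []}
    )
    for a in anchors:
        by_group[(a.chrom, a.orientation)][a.side].append(a)
    raw_calls: list[InsertionCall] = []
    for (chrom, orientation), sides in sorted(by_group.items()):
        lefts = sorted(sides["left"], key=lambda a: a.breakpoint)
        rights = sorted(sides["right"], key=lambda a: a.breakpoint)
        pairings: list[tuple[Anchor, Anchor, InsertionCall]] = []
        for left in lefts:
            candidates = [
                r
                for r in rights
                if 0 <= left.breakpoint - r.breakpoint <= cfg.max_pair_distance
            ]
            if not candidates:
                continue
            best = min(
                candidates,
                key=lambda r: (left.breakpoint - r.breakpoint, r.breakpoint),
            )
            tsd = genome[chrom][best.breakpoint : left.breakpoint]
            call = InsertionCall(
                chrom=chrom,
                position=left.breakpoint + 1,
                tsd=tsd,
                orientation=orientation,
                head_support=sum(a.support for a in (left, best) if a.motif == "head"),
                tail_support=sum(a.support for a in (left, best) if a.motif == "tail"),
                line_id=line_id,
            )
            pairings.append((left, best, call))
            raw_calls.append(call)
        # a right anchor claimed by >1 left anchor marks contradictory pairings
        claims = Counter(id(right) for _, right, _ in pairings)
        for _, right, call in pairings:
            if claims[id(right)] > 1:
                call.ambiguous = True
    # merge duplicates (same chrom/position/orientation) with support summed
    merged: dict[tuple, InsertionCall] = {}
    for c in raw_calls:
        key = (c.chrom, c.position, c.orientation)
        if key in merged:
            m = merged[key]
            m.head_support += c.head_support
            m.tail_support += c.tail_support
            m.ambiguous = m.ambiguous or c.ambiguous
        else:
            merged[key] = c
    calls = sorted(merged.values(), key=InsertionCall.sort_key)
    return [c for c in calls if c.head_support >= 1 and c.tail_support >= 1]


def find_insertions(
    reads: Iterable[str],
    genome: dict[str, str],
    cfg: JunctionConfig,
    line_id: str = "",
) -> list[InsertionCall]:
    """Full junction-calling pipeline: scan reads, anchor flanks, pair
    breakpoints."""
    flanks = scan_junction_reads(reads, cfg)
    if not flanks:
        return []
    anchors, _ = map_flanks(flanks, genome, cfg)
    return call_insertions(anchors, genome, cfg, line_id=line_id)
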