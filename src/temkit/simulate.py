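"""Synthetic-data generator: toy genome, donor TE copies, planted insertions,
paired-end reads with ground-truth alignments, and stranded expression tracks.

Everything downstream (junction calling, zygosity, copy attribution, site
preference, transcript impact) is exercised on data produced here, so every
operation records its ground truth in a :class:`TruthTable` or scenario label.

Coordinates are 0-based half-open internally.  The one deliberate exception is
the *insertion position* carried by truth records and calls: the 1-based
coordinate of the reference base immediately 3' of the duplicated target-site
motif (TSD), which matches the convention used by the junction caller.

The integration model is the Ty1/Copia one: at a chosen target site the
``tsd_length`` bases 5' of the insertion point are duplicated so that they
flank the full-length element on both sides, and the element keeps identical
LTRs whose first and last 20-mers are the head/tail motifs used for junction
scanning.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import random_dna, revcomp

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of the simulated study.

    Defaults mirror the design of the mobilization experiment the package
    models: eight donor copies of a ~5 kb element distinguished by
    copy-specific SNPs, nine genome-tiling chromatin states, 150 bp
    paired-end reads, and a 5 bp target-site duplication.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 200_000
    n_genes: int = 60
    n_states: int = 9
    n_donor_copies: int = 8
    snps_per_copy: int = 6
    te_length: int = 4949
    ltr_length: int = 400
    tsd_length: int = 5
    read_length: int = 150
    insert_size_mean: float = 400.0
    insert_size_sd: float = 60.0
    depth: float = 30.0
    het_fraction: float = 0.4
    sequencing_error_rate: float = 0.0
    preference_weights: dict[int, float] | None = None
    state_segment_mean: int = 2000
    h2az_states: tuple[int, ...] = (1, 2, 5, 6)
    h3k27me3_states: tuple[int, ...] = (2, 5)
    #: minimum distance between planted insertions; keeps zygosity windows
    #: free of neighbouring junctions at the default read depth
    min_insertion_spacing: int = 2500
    #: insertion-free margin at chromosome ends
    edge_margin: int = 2500

    def __post_init__(self) -> None:
        if self.te_length <= 2 * self.ltr_length:
            raise ValueError("invalid config: te_length must exceed 2*ltr_length")
        if self.tsd_length < 0:
            raise ValueError("invalid config: tsd_length must be >= 0")
        if self.depth <= 0:
            raise ValueError("invalid config: depth must be > 0")
        if self.n_chromosomes < 1 or self.chromosome_length < 10_000:
            raise ValueError("invalid config: need >=1 chromosome of >=10 kb")
        if self.n_states < 1:
            raise ValueError("invalid config: n_states must be >= 1")
        if self.n_genes < 0:
            raise ValueError("invalid config: n_genes must be >= 0")
        if self.read_length < 30:
            raise ValueError("invalid config: read_length must be >= 30")
        if not (0.0 <= self.het_fraction <= 1.0):
            raise ValueError("invalid config: het_fraction must be in [0, 1]")
        if self.preference_weights is not None:
            w = self.preference_weights
            if any(v < 0 for v in w.values()) or not any(v > 0 for v in w.values()):
                raise ValueError(
                    "invalid config: preference_weights must be nonnegative, not all zero"
                )

    def state_weight(self, state: int) -> float:
        if self.preference_weights is None:
            return 1.0
        return float(self.preference_weights.get(state, 0.0))


# ---------------------------------------------------------------------------
# genome, annotation, chromatin states
# ---------------------------------------------------------------------------


@dataclass
class Feature:
    """One annotated feature.  For protein-coding genes, ``exons`` are the
    coding exons and the UTR intervals flank them; other kinds are flat."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # gene | lncRNA | pseudogene | transposable_element
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def introns(self) -> list[tuple[int, int]]:
        if len(self.exons) < 2:
            return []
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex[:-1], ex[1:])]


@dataclass
class Annotation:
    features: list[Feature]

    def by_id(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "gene"]

    def on(self, chrom: str) -> list[Feature]:
        return sorted(
            (f for f in self.features if f.chrom == chrom), key=lambda f: f.start
        )

    def containing(self, chrom: str, pos0: int) -> Feature | None:
        """Feature containing the 0-based position, genes first."""
        hits = [
            f
            for f in self.features
            if f.chrom == chrom and f.start <= pos0 < f.end
        ]
        if not hits:
            return None
        order = {"gene": 0, "lncRNA": 1, "pseudogene": 2, "transposable_element": 3}
        return sorted(hits, key=lambda f: order.get(f.kind, 9))[0]


@dataclass
class StateSegmentation:
    """Chromatin states tiling each chromosome exactly (no gaps, no overlap)."""

    segments: list[tuple[str, int, int, int]]  # chrom, start, end, state

    def chrom_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for chrom, _, end, _ in self.segments:
            sizes[chrom] = max(sizes.get(chrom, 0), end)
        return sizes

    def state_array(self, chrom: str) -> np.ndarray:
        size = self.chrom_sizes()[chrom]
        arr = np.zeros(size, dtype=np.int16)
        for c, s, e, st in self.segments:
            if c == chrom:
                arr[s:e] = st
        return arr

    def state_at(self, chrom: str, pos0: int) -> int:
        for c, s, e, st in self.segments:
            if c == chrom and s <= pos0 < e:
                return st
        raise ValueError(f"position {chrom}:{pos0} not covered by any state segment")

    def genome_fractions(self) -> dict[int, float]:
        total = sum(e - s for _, s, e, _ in self.segments)
        frac: dict[int, float] = {}
        for _, s, e, st in self.segments:
            frac[st] = frac.get(st, 0.0) + (e - s) / total
        return frac


@dataclass
class SimulatedGenome:
    chromosomes: dict[str, str]
    annotation: Annotation
    states: StateSegmentation
    tracks: dict[str, dict[str, np.ndarray]]  # mark -> chrom -> per-base signal

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}


def _make_gene(
    rng: np.random.Generator, chrom: str, start: int, idx: int, kind: str
) -> Feature:
    if kind != "gene":
        length = int(rng.integers(500, 3000))
        return Feature(
            feature_id=f"{kind[:4].upper()}{idx:04d}",
            chrom=chrom,
            start=start,
            end=start + length,
            strand="+" if rng.random() < 0.5 else "-",
            kind=kind,
        )
    strand = "+" if rng.random() < 0.5 else "-"
    utr5_len = int(rng.integers(100, 300))
    utr3_len = int(rng.integers(100, 300))
    n_exons = int(rng.integers(2, 7))
    exon_lens = [int(rng.integers(150, 600)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(100, 400)) for _ in range(n_exons - 1)]
    # left-to-right genomic layout; for '-' strand the UTRs swap ends
    left_utr = utr5_len if strand == "+" else utr3_len
    right_utr = utr3_len if strand == "+" else utr5_len
    pos = start + left_utr
    exons: list[tuple[int, int]] = []
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < n_exons - 1:
            pos += intron_lens[i]
    end = pos + right_utr
    utr_left = (start, start + left_utr)
    utr_right = (pos, end)
    return Feature(
        feature_id=f"GENE{idx:04d}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        kind="gene",
        exons=exons,
        utr5=utr_left if strand == "+" else utr_right,
        utr3=utr_right if strand == "+" else utr_left,
    )


def simulate_genome(config: SimulationConfig, seed=None) -> SimulatedGenome:
    """Generate chromosome sequences, gene/TE annotation, a chromatin-state
    tiling and two histone-signal tracks.  Deterministic given the seed."""
    rng = _as_rng(config.seed if seed is None else seed)
    chroms = {
        f"chr{i + 1}": random_dna(rng, config.chromosome_length)
        for i in range(config.n_chromosomes)
    }

    # --- annotation ---------------------------------------------------
    features: list[Feature] = []
    n_aux_each = max(2, config.n_genes // 12) if config.n_genes else 0
    per_chrom_genes = _split_counts(config.n_genes, config.n_chromosomes)
    aux_kinds = ["lncRNA", "pseudogene", "transposable_element"]
    per_chrom_aux = _split_counts(n_aux_each * len(aux_kinds), config.n_chromosomes)
    gi = ai = 0
    for ci, (chrom, seq) in enumerate(chroms.items()):
        todo = ["gene"] * per_chrom_genes[ci]
        aux_cycle = [aux_kinds[(ai + k) % 3] for k in range(per_chrom_aux[ci])]
        ai += per_chrom_aux[ci]
        # interleave aux features among genes at random order
        todo = todo + aux_cycle
        order = rng.permutation(len(todo))
        todo = [todo[i] for i in order]
        pos = int(rng.integers(1000, 3000))
        for kind in todo:
            gap = int(rng.integers(400, 2500))
            feat = _make_gene(rng, chrom, pos, gi, kind)
            gi += 1
            if feat.end > len(seq) - 1000:
                raise ValueError(
                    "invalid config: n_genes does not fit on the chromosomes"
                )
            features.append(feat)
            pos = feat.end + gap

    # --- chromatin states ---------------------------------------------
    segments: list[tuple[str, int, int, int]] = []
    for chrom, seq in chroms.items():
        pos = 0
        size = len(seq)
        while pos < size:
            seg_len = int(
                np.clip(rng.exponential(config.state_segment_mean), 300, 20_000)
            )
            end = min(pos + seg_len, size)
            state = int(rng.integers(1, config.n_states + 1))
            segments.append((chrom, pos, end, state))
            pos = end
    states = StateSegmentation(segments)

    # --- histone tracks ------------------------------------------------
    tracks: dict[str, dict[str, np.ndarray]] = {"H2A.Z": {}, "H3K27me3": {}}
    mark_states = {"H2A.Z": set(config.h2az_states), "H3K27me3": set(config.h3k27me3_states)}
    for mark in tracks:
        for chrom, seq in chroms.items():
            arr = np.full(len(seq), 0.2, dtype=np.float32)
            for c, s, e, st in segments:
                if c == chrom and st in mark_states[mark]:
                    arr[s:e] = 5.0
            arr += rng.gamma(1.0, 0.05, size=len(seq)).astype(np.float32)
            tracks[mark][chrom] = arr

    return SimulatedGenome(chroms, Annotation(features), states, tracks)


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# donor copies
# ---------------------------------------------------------------------------


@dataclass
class DonorSNP:
    copy_id: str
    position: int  # 0-based on the consensus/copy (no indels simulated)
    ref: str  # consensus base
    alt: str  # copy-specific base
    is_ltr: bool = False


@dataclass
class DonorSet:
    consensus: str
    copies: dict[str, str]
    snps: list[DonorSNP]
    ltr_length: int

    @property
    def head(self) -> str:
        return self.consensus[:20]

    @property
    def tail(self) -> str:
        return self.consensus[-20:]


def make_donor_copies(config: SimulationConfig, seed=None) -> DonorSet:
    """Donor TE family: identical LTRs, each copy distinguished from the
    consensus by its own private interior SNPs (no position shared)."""
    if config.snps_per_copy < 1:
        raise ValueError(
            "snps_per_copy must be >= 1: without private SNPs the copies "
            "would be indistinguishable"
        )
    rng = _as_rng(config.seed + 1 if seed is None else seed)
    interior_len = config.te_length - 2 * config.ltr_length
    n_snps = config.n_donor_copies * config.snps_per_copy
    if interior_len < 4 * n_snps:
        raise ValueError(
            "te interior too short to host the requested copy-specific SNPs"
        )
    ltr = random_dna(rng, config.ltr_length)
    interior = random_dna(rng, interior_len)
    consensus = ltr + interior + ltr
    lo, hi = config.ltr_length, config.te_length - config.ltr_length
    positions = rng.choice(np.arange(lo, hi), size=n_snps, replace=False)
    positions = np.sort(positions)
    order = rng.permutation(n_snps)  # scatter copies over positions
    copies: dict[str, str] = {}
    snps: list[DonorSNP] = []
    per_copy: dict[int, list[int]] = {i: [] for i in range(config.n_donor_copies)}
    for k, pos in enumerate(positions):
        per_copy[order[k] % config.n_donor_copies].append(int(pos))
    for i in range(config.n_donor_copies):
        copy_id = f"copy{i + 1}"
        seq = list(consensus)
        for pos in sorted(per_copy[i]):
            ref = consensus[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            seq[pos] = alt
            snps.append(DonorSNP(copy_id, pos, ref, str(alt)))
        copies[copy_id] = "".join(seq)
    return DonorSet(consensus, copies, snps, config.ltr_length)


# ---------------------------------------------------------------------------
# planted insertions and haplotypes
# ---------------------------------------------------------------------------


@dataclass
class PlantedInsertion:
    chrom: str
    position: int  # 1-based first reference base 3' of the TSD
    strand: str
    tsd: str
    zygosity: str
    donor_id: str
    line_id: str = ""


@dataclass
class TruthTable:
    insertions: list[PlantedInsertion]
    donor_snps: list[DonorSNP]

    def insertions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(i) for i in self.insertions])

    def snps_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.donor_snps])


@dataclass
class _Block:
    hap_start: int
    hap_end: int
    kind: str  # "ref" | "ins"
    ref_start: int = -1  # for ref blocks
    seq: str = ""  # for ins blocks


class HaplotypeMap:
    """One haplotype of one chromosome: the modified sequence plus the
    block structure mapping haplotype intervals back to the reference."""

    def __init__(self, chrom: str, ref_seq: str, insertions: Sequence[tuple[int, str]]):
        # insertions: list of (position_1based, oriented insert sequence with
        # the duplicated TSD appended 3')
        self.chrom = chrom
        parts: list[str] = []
        self.blocks: list[_Block] = []
        cursor = 0  # reference cursor
        hap_pos = 0
        for pos1, insert_seq in sorted(insertions):
            q = pos1 - 1
            seg = ref_seq[cursor:q]
            if seg:
                self.blocks.append(_Block(hap_pos, hap_pos + len(seg), "ref", cursor))
                parts.append(seg)
                hap_pos += len(seg)
            self.blocks.append(_Block(hap_pos, hap_pos + len(insert_seq), "ins", seq=insert_seq))
            parts.append(insert_seq)
            hap_pos += len(insert_seq)
            cursor = q
        seg = ref_seq[cursor:]
        if seg:
            self.blocks.append(_Block(hap_pos, hap_pos + len(seg), "ref", cursor))
            parts.append(seg)
            hap_pos += len(seg)
        self.seq = "".join(parts)

    def __len__(self) -> int:
        return len(self.seq)

    def project(self, start: int, end: int):
        """Project a haplotype interval to the reference.

        Returns ``(ref_start, cigar, n_aligned)`` where cigar is a list of
        (op, length) with op in {"M", "S"} in haplotype order, or
        ``(None, None, 0)`` when no base aligns.  Alignments that would be
        split across two reference blocks (possible only when a read is
        longer than an inserted element) are treated as unmapped.
        """
        cigar: list[tuple[str, int]] = []
        ref_start = None
        n_aligned = 0
        n_ref_blocks = 0
        for blk in self.blocks:
            lo = max(start, blk.hap_start)
            hi = min(end, blk.hap_end)
            if lo >= hi:
                continue
            if blk.kind == "ins":
                cigar.append(("S", hi - lo))
            else:
                n_ref_blocks += 1
                if ref_start is None:
                    ref_start = blk.ref_start + (lo - blk.hap_start)
                cigar.append(("M", hi - lo))
                n_aligned += hi - lo
        if n_ref_blocks != 1 or n_aligned == 0:
            return None, None, 0
        # merge adjacent same ops
        merged: list[tuple[str, int]] = []
        for op, ln in cigar:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + ln)
            else:
                merged.append((op, ln))
        return ref_start, merged, n_aligned


@dataclass
class Line:
    line_id: str
    haplotypes: dict[str, tuple[HaplotypeMap, HaplotypeMap]]
    insertions: list[PlantedInsertion]

    def truth_zygosity(self) -> dict[tuple[str, int], str]:
        return {(i.chrom, i.position): i.zygosity for i in self.insertions}


def sample_insertion_sites(
    sim: SimulatedGenome, n: int, config: SimulationConfig, rng
) -> list[tuple[str, int]]:
    """Draw insertion points (chrom, 1-based position), with the probability
    of a site proportional to the preference weight of its chromatin state.

    Sites keep a margin from chromosome ends and a minimum mutual distance
    so that downstream read-level analyses see isolated junctions.
    """
    rng = _as_rng(rng)
    segs = [
        (c, s, e, st)
        for (c, s, e, st) in sim.states.segments
        if config.state_weight(st) > 0
    ]
    weights = np.array(
        [config.state_weight(st) * (e - s) for (_, s, e, st) in segs], dtype=float
    )
    if not len(segs) or weights.sum() <= 0:
        raise ValueError("no insertable sites under the given preference weights")
    probs = weights / weights.sum()
    chosen: list[tuple[str, int]] = []
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while len(chosen) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} insertions: exceeds available sites under "
                "the margin/separation constraints"
            )
        idx = rng.choice(len(segs), p=probs)
        chrom, s, e, _ = segs[idx]
        q = int(rng.integers(s, e))  # 0-based insertion point
        size = len(sim.chromosomes[chrom])
        if q < config.edge_margin or q > size - config.edge_margin:
            continue
        if any(
            c == chrom and abs(q - (p - 1)) < config.min_insertion_spacing
            for c, p in chosen
        ):
            continue
        chosen.append((chrom, q + 1))
    return chosen


def plant_insertions(
    sim: SimulatedGenome,
    donors: DonorSet,
    n: int,
    config: SimulationConfig,
    seed=None,
    line_id: str = "line1",
    sites: Sequence[tuple[str, int]] | None = None,
) -> Line:
    """Plant ``n`` full-length donor copies into a diploid line.

    Each insertion duplicates the ``tsd_length`` reference bases 5' of the
    insertion point so they flank the element; heterozygous insertions
    modify exactly one of the two haplotypes.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(config.seed + 2 if seed is None else seed)
    if sites is None:
        sites = sample_insertion_sites(sim, n, config, rng)
    elif len(sites) != n:
        raise ValueError("len(sites) must equal n")
    donor_ids = list(donors.copies)
    per_hap: dict[tuple[str, int], list[tuple[int, str]]] = {}
    truth: list[PlantedInsertion] = []
    for chrom, pos1 in sites:
        q = pos1 - 1
        ref = sim.chromosomes[chrom]
        tsd = ref[q - config.tsd_length : q]
        donor_id = donor_ids[int(rng.integers(len(donor_ids)))]
        strand = "+" if rng.random() < 0.5 else "-"
        zygosity = HETEROZYGOUS if rng.random() < config.het_fraction else HOMOZYGOUS
        te = donors.copies[donor_id]
        oriented = te if strand == "+" else revcomp(te)
        insert_seq = oriented + tsd  # upstream copy of the TSD stays in place
        targets = [0, 1] if zygosity == HOMOZYGOUS else [int(rng.integers(2))]
        for h in targets:
            per_hap.setdefault((chrom, h), []).append((pos1, insert_seq))
        truth.append(
            PlantedInsertion(chrom, pos1, strand, tsd, zygosity, donor_id, line_id)
        )
    haplotypes = {
        chrom: tuple(
            HaplotypeMap(chrom, seq, per_hap.get((chrom, h), [])) for h in (0, 1)
        )
        for chrom, seq in sim.chromosomes.items()
    }
    return Line(line_id, haplotypes, truth)


# ---------------------------------------------------------------------------
# paired-end reads with truth alignments
# ---------------------------------------------------------------------------

_MIN_ALIGNED = 20  # aligned bases below which a mate is recorded as unmapped


@dataclass
class MateAlignment:
    chrom: str
    ref_start: int  # 0-based leftmost aligned base
    cigar: list[tuple[str, int]]
    reverse: bool

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(ln for op, ln in self.cigar if op == "M")

    @property
    def clipped(self) -> bool:
        return any(op == "S" for op, _ in self.cigar)


@dataclass
class ReadPair:
    name: str
    seq1: str  # as sequenced (reverse mate already reverse-complemented)
    seq2: str
    aln1: MateAlignment | None
    aln2: MateAlignment | None
    fragment_length: int
    proper: bool
    hap_index: int
    chrom: str


@dataclass
class ReadSet:
    pairs: list[ReadPair]
    chrom_sizes: dict[str, int]
    read_length: int

    def sequences(self) -> Iterable[str]:
        for p in self.pairs:
            yield p.seq1
            yield p.seq2

    def coverage(self, stranded: bool = False) -> dict:
        """Per-base aligned coverage from the truth alignments.

        With ``stranded`` the result maps chrom -> (plus, minus) arrays.
        """
        cov = {
            c: (np.zeros(n), np.zeros(n)) if stranded else np.zeros(n)
            for c, n in self.chrom_sizes.items()
        }
        for p in self.pairs:
            for aln in (p.aln1, p.aln2):
                if aln is None:
                    continue
                target = cov[aln.chrom]
                if stranded:
                    target = target[1] if aln.reverse else target[0]
                pos = aln.ref_start
                for op, ln in aln.cigar:
                    if op == "M":
                        target[pos : pos + ln] += 1
                        pos += ln
        return cov


def simulate_reads(
    haplotypes: dict[str, tuple[HaplotypeMap, HaplotypeMap]] | Line,
    config: SimulationConfig,
    seed=None,
    proper_insert_range: tuple[int, int] = (150, 700),
    line_id: str | None = None,
) -> ReadSet:
    """Simulate inward-pointing paired-end reads from a diploid line.

    Each haplotype is sequenced at ``depth/2``; fragment lengths follow the
    configured normal distribution (draws shorter than the read length are
    resampled, never emitted malformed).  Truth alignments project each mate
    onto the reference: bases inside an inserted element are soft-clipped,
    mates fully inside an element are recorded as placed-unmapped.  The
    properly-paired flag reflects the true fragment (inward orientation and
    insert size within ``proper_insert_range``).
    """
    if isinstance(haplotypes, Line):
        line_id = line_id or haplotypes.line_id
        haplotypes = haplotypes.haplotypes
    line_id = line_id or "sample"
    if config.depth <= 0:
        raise ValueError("invalid config: depth must be > 0")
    rng = _as_rng(config.seed + 3 if seed is None else seed)
    rl = config.read_length
    pairs: list[ReadPair] = []
    chrom_sizes: dict[str, int] = {}
    for chrom, haps in haplotypes.items():
        # reference size: from the ref blocks of the first haplotype
        ref_size = max(
            (b.ref_start + (b.hap_end - b.hap_start) for b in haps[0].blocks if b.kind == "ref"),
            default=0,
        )
        chrom_sizes[chrom] = ref_size
        for h, hap in enumerate(haps):
            hap_len = len(hap)
            n_pairs = int(round((config.depth / 2) * hap_len / (2 * rl)))
            for i in range(n_pairs):
                frag = 0
                while frag < rl or frag > hap_len:
                    frag = int(round(rng.normal(config.insert_size_mean, config.insert_size_sd)))
                start = int(rng.integers(0, hap_len - frag + 1))
                fwd = hap.seq[start : start + rl]
                rev = revcomp(hap.seq[start + frag - rl : start + frag])
                if config.sequencing_error_rate > 0:
                    fwd = _add_errors(fwd, config.sequencing_error_rate, rng)
                    rev = _add_errors(rev, config.sequencing_error_rate, rng)
                aln_f = _project_mate(hap, chrom, start, start + rl, reverse=False)
                aln_r = _project_mate(hap, chrom, start + frag - rl, start + frag, reverse=True)
                proper = proper_insert_range[0] <= frag <= proper_insert_range[1]
                # half the fragments are sequenced with mate 1 on the reverse strand
                if rng.random() < 0.5:
                    seq1, seq2, a1, a2 = fwd, rev, aln_f, aln_r
                else:
                    seq1, seq2, a1, a2 = rev, fwd, aln_r, aln_f
                pairs.append(
                    ReadPair(
                        name=f"{line_id}:{chrom}:h{h}:{i}",
                        seq1=seq1,
                        seq2=seq2,
                        aln1=a1,
                        aln2=a2,
                        fragment_length=frag,
                        proper=proper,
                        hap_index=h,
                        chrom=chrom,
                    )
                )
    return ReadSet(pairs, chrom_sizes, rl)


def _project_mate(
    hap: HaplotypeMap, chrom: str, start: int, end: int, reverse: bool
) -> MateAlignment | None:
    ref_start, cigar, n_aligned = hap.project(start, end)
    if ref_start is None or n_aligned < _MIN_ALIGNED:
        return None
    if reverse:
        pass  # cigar stays in reference order; sequence already oriented
    return MateAlignment(chrom, ref_start, cigar, reverse)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    n_err = rng.binomial(len(seq), rate)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return "".join(out)


# ---------------------------------------------------------------------------
# reads over the donor consensus (copy attribution)
# ---------------------------------------------------------------------------


def simulate_copy_reads(
    donors: DonorSet,
    proportions: dict[str, float],
    depth: float,
    read_length: int = 150,
    seed=None,
) -> list[tuple[int, str]]:
    """Single-end reads over the consensus drawn from a donor-copy mixture.

    Copies carry only substitutions relative to the consensus, so a read from
    copy ``c`` starting at position ``p`` aligns at ``p`` on the consensus.
    Returns (start, sequence) records.
    """
    rng = _as_rng(seed)
    ids = list(proportions)
    p = np.array([proportions[i] for i in ids], dtype=float)
    if p.sum() <= 0:
        raise ValueError("proportions must not all be zero")
    p = p / p.sum()
    L = len(donors.consensus)
    n_reads = int(round(depth * L / read_length))
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    which = rng.choice(len(ids), size=n_reads, p=p)
    return [
        (int(s), donors.copies[ids[w]][s : s + read_length])
        for s, w in zip(starts, which)
    ]


# ---------------------------------------------------------------------------
# stranded expression tracks encoding transcript-impact scenarios
# ---------------------------------------------------------------------------

#: categories the track generator knows how to paint
TRACK_CATEGORIES = frozenset(
    {
        "exonisation",
        "truncation_5p",
        "truncation_3p",
        "intron_retention",
        "exon_skipping",
        "fusion_intergenic",
        "fusion_gene",
        "silent_both",
        "normal_transcript",
        "upregulated",
        "downregulated",
        "knockout",
        "antisense",
        "novel_transcript",
        "acquired_heat_response",
    }
)

_HI = 10.0  # expressed level painted by the generator (arbitrary TPM-like units)


@dataclass
class ImpactScenario:
    """One planted insertion with its intended transcriptional consequences.

    ``categories`` maps condition ("control" / "heat_stress") to the set of
    categories the emitted tracks should realize.  ``expected`` (filled by
    the generator) is the exact per-condition category set a rule-based
    classifier should report, which can differ from the request in two
    benign ways: intact expressed loci additionally satisfy
    ``normal_transcript``, and ``acquired_heat_response`` expands to the
    per-condition evidence plus the cross-condition gain flag.
    """

    gene_id: str | None
    chrom: str
    position: int  # 1-based insertion point
    categories: dict[str, frozenset]
    expected: dict[str, frozenset] = field(default_factory=dict)
    expects_gain: bool = False


@dataclass
class StrandedCoverage:
    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]

    def strand(self, s: str) -> dict[str, np.ndarray]:
        return self.plus if s == "+" else self.minus


@dataclass
class ImpactTrackSet:
    tracks: dict[tuple[str, str], StrandedCoverage]  # (sample, condition)
    transcripts: dict[tuple[str, str], dict[str, str]]  # (sample, condition) -> gene -> mRNA
    scenarios: list[ImpactScenario]
    te_sequence: str


def simulate_impact_tracks(
    sim: SimulatedGenome,
    scenarios: Sequence[ImpactScenario],
    te_sequence: str,
    seed=None,
    conditions: tuple[str, str] = ("control", "heat_stress"),
) -> ImpactTrackSet:
    """Emit stranded per-base coverage for wt/line x condition realizing the
    requested impact categories, with exact truth labels."""
    rng = _as_rng(seed)
    for sc in scenarios:
        for cond, cats in sc.categories.items():
            unknown = set(cats) - TRACK_CATEGORIES
            if unknown:
                raise ValueError(
                    f"unknown impact category {sorted(unknown)}; valid: "
                    f"{sorted(TRACK_CATEGORIES)}"
                )
            if cond not in conditions:
                raise ValueError(f"unknown condition {cond!r}")
    sizes = sim.chrom_sizes()

    def empty() -> StrandedCoverage:
        return StrandedCoverage(
            {c: np.zeros(n) for c, n in sizes.items()},
            {c: np.zeros(n) for c, n in sizes.items()},
        )

    tracks = {(s, c): empty() for s in ("wt", "line") for c in conditions}
    transcripts: dict[tuple[str, str], dict[str, str]] = {
        key: {} for key in tracks
    }

    for sc in scenarios:
        for cond in conditions:
            cats = set(sc.categories.get(cond, frozenset()))
            expected = _paint_scenario(
                sim, sc, cats, tracks[("wt", cond)], tracks[("line", cond)],
                transcripts[("wt", cond)], transcripts[("line", cond)],
                te_sequence, rng,
            )
            sc.expected[cond] = frozenset(expected)
        sc.expects_gain = "acquired_heat_response" in set().union(
            *sc.categories.values()
        )
    return ImpactTrackSet(tracks, transcripts, list(scenarios), te_sequence)


def _spliced_exonic(sim: SimulatedGenome, gene: Feature) -> str:
    seq = "".join(sim.chromosomes[gene.chrom][s:e] for s, e in sorted(gene.exons))
    return seq if gene.strand == "+" else revcomp(seq)


def _paint_gene(cov: np.ndarray, gene: Feature, level: float) -> None:
    for s, e in gene.exons:
        cov[s:e] = level
    for interval in (gene.utr5, gene.utr3):
        if interval:
            cov[interval[0] : interval[1]] = level


def _paint_scenario(
    sim: SimulatedGenome,
    sc: ImpactScenario,
    cats: set,
    wt: StrandedCoverage,
    line: StrandedCoverage,
    wt_tx: dict[str, str],
    line_tx: dict[str, str],
    te_sequence: str,
    rng: np.random.Generator,
) -> set:
    """Apply one scenario's categories for one condition; return the exact
    category set a rule-based classifier should recover."""
    chrom = sc.chrom
    q = sc.position - 1
    expected = set(cats)

    if sc.gene_id is None:
        # intergenic locus: only novel_transcript / silent_both make sense
        if "novel_transcript" in cats:
            lo, hi = max(0, q - 200), min(len(line.plus[chrom]), q + 300)
            line.plus[chrom][lo:hi] = _HI
        expected.discard("silent_both")
        if "novel_transcript" in cats:
            expected = {"novel_transcript"}
        else:
            expected = set()
        return expected

    gene = sim.annotation.by_id(sc.gene_id)
    sense_wt = wt.strand(gene.strand)[chrom]
    sense_line = line.strand(gene.strand)[chrom]
    anti_line = line.strand("-" if gene.strand == "+" else "+")[chrom]

    gain = "acquired_heat_response" in cats
    wt_silent = "silent_both" in cats or gain
    if not wt_silent:
        _paint_gene(sense_wt, gene, _HI)
        wt_tx[gene.feature_id] = _spliced_exonic(sim, gene)

    structural = cats & {
        "truncation_5p",
        "truncation_3p",
        "intron_retention",
        "exon_skipping",
        "fusion_gene",
        "fusion_intergenic",
    }
    line_silent = "silent_both" in cats or "knockout" in cats
    line_level = _HI
    if "upregulated" in cats:
        line_level = _HI * 4
    elif "downregulated" in cats:
        line_level = _HI / 4
    elif gain:
        line_level = _HI

    if not line_silent:
        _paint_gene(sense_line, gene, line_level)
        line_tx[gene.feature_id] = _spliced_exonic(sim, gene)

    if "truncation_5p" in cats:
        # transcription starts at the insertion point: silence the 5' part
        if gene.strand == "+":
            sense_line[gene.start : q] = 0.0
        else:
            sense_line[q + 1 : gene.end] = 0.0
    if "truncation_3p" in cats:
        if gene.strand == "+":
            sense_line[q : gene.end] = 0.0
        else:
            sense_line[gene.start : q + 1] = 0.0
    if "intron_retention" in cats:
        intron = _nearest_interval(gene.introns(), q)
        sense_line[intron[0] : intron[1]] = line_level
    if "exon_skipping" in cats:
        exon = _nearest_interval(gene.exons, q)
        sense_line[exon[0] : exon[1]] = 0.0
    if "fusion_gene" in cats or "fusion_intergenic" in cats:
        neighbor = _next_feature(sim.annotation, gene)
        if "fusion_gene" in cats:
            if neighbor is None:
                raise ValueError(f"{gene.feature_id}: no 3' neighbor for fusion_gene")
            stop = min(neighbor.start + 300, neighbor.end)
            sense_line[gene.end : stop] = line_level
        else:
            stop = gene.end + 400
            if neighbor is not None:
                stop = min(stop, neighbor.start - 100)
            sense_line[gene.end : stop] = line_level
    if "antisense" in cats:
        anti_line[gene.start : gene.end] = _HI
    if "exonisation" in cats:
        base = line_tx.get(gene.feature_id, _spliced_exonic(sim, gene))
        frag = te_sequence[: min(120, len(te_sequence))]
        cut = len(base) // 2
        line_tx[gene.feature_id] = base[:cut] + frag + base[cut:]

    # --- derive the exact expected category set --------------------------
    expected.discard("acquired_heat_response")
    line_expressed = not line_silent
    if gain and line_expressed and not structural:
        expected.add("upregulated")
    if (
        line_expressed
        and not wt_silent
        and not structural
        and "upregulated" not in cats
        and "downregulated" not in cats
        and not gain
    ):
        expected.add("normal_transcript")
    if "knockout" in cats and wt_silent:
        # degenerate request; keep silent_both semantics
        expected.discard("knockout")
        expected.add("silent_both")
    return expected


_SCENARIO_KINDS = [
    "knockout",
    "truncation_5p",
    "truncation_3p",
    "intron_retention",
    "exon_skipping",
    "exonisation",
    "fusion_gene",
    "fusion_intergenic",
    "antisense",
    "upregulated",
    "downregulated",
    "normal_transcript",
    "silent_both",
    "novel_transcript",
    "truncation_3p+antisense",
    "knockout+antisense",
    "gain_intact",
    "gain_truncation_5p",
]


def random_impact_scenarios(
    sim: SimulatedGenome,
    n: int,
    seed=None,
    conditions: tuple[str, str] = ("control", "heat_stress"),
    kinds: Sequence[str] | None = None,
) -> list[ImpactScenario]:
    """Draw ``n`` scenarios spanning the impact taxonomy, one gene (or
    intergenic site) each, with positions chosen so every category's
    defining signal fits inside the gene model."""
    rng = _as_rng(seed)
    kinds = list(kinds or _SCENARIO_KINDS)
    genes = [f for f in sim.annotation.genes()]
    rng.shuffle(genes)
    used: set[str] = set()
    used_intergenic: list[tuple[str, int]] = []
    scenarios: list[ImpactScenario] = []
    ctl, hs = conditions

    def mid(iv: tuple[int, int]) -> int:
        return (iv[0] + iv[1]) // 2

    def central_exon(gene: Feature, interior_only: bool) -> tuple[int, int] | None:
        exons = sorted(gene.exons)
        pool = exons[1:-1] if interior_only else exons
        if not pool:
            return None
        center = (gene.start + gene.end) // 2
        return min(pool, key=lambda iv: abs(mid(iv) - center))

    def take_gene(predicate, reserve_neighbor: bool = False) -> Feature | None:
        for g in genes:
            if g.feature_id in used:
                continue
            if not predicate(g):
                continue
            used.add(g.feature_id)
            if reserve_neighbor:
                nb = _next_feature(sim.annotation, g)
                if nb is not None:
                    used.add(nb.feature_id)
            return g
        return None

    attempts = 0
    while len(scenarios) < n:
        attempts += 1
        if attempts > 50 * n:
            raise ValueError("not enough genes/intergenic space for the scenarios")
        kind = kinds[int(rng.integers(len(kinds)))]
        parts = set(kind.split("+"))
        gain = kind.startswith("gain_")
        if gain:
            parts = {kind.removeprefix("gain_")}

        if kind == "novel_transcript":
            site = _intergenic_site(sim, rng, used_intergenic)
            if site is None:
                continue
            chrom, q = site
            used_intergenic.append((chrom, q))
            cats = frozenset({"novel_transcript"})
            scenarios.append(
                ImpactScenario(None, chrom, q + 1, {ctl: cats, hs: cats})
            )
            continue

        need_mid_exon = bool(parts & {"truncation_5p", "truncation_3p", "exon_skipping"})
        need_interior = "exon_skipping" in parts
        need_intron = "intron_retention" in parts
        need_neighbor = "fusion_gene" in parts
        need_gap = "fusion_intergenic" in parts

        def ok(g: Feature) -> bool:
            if need_interior and len(g.exons) < 3:
                return False
            if need_intron and len(g.exons) < 2:
                return False
            if need_mid_exon:
                ex = central_exon(g, need_interior)
                if ex is None:
                    return False
                q = mid(ex)
                if q - g.start < 300 or g.end - q < 300:
                    return False
            if need_neighbor:
                nb = _next_feature(sim.annotation, g)
                # the painted read-through must not touch another scenario's
                # gene, so the neighbor must be free (and gets reserved)
                if nb is None or nb.feature_id in used:
                    return False
            if need_gap:
                nb = _next_feature(sim.annotation, g)
                if nb is not None and nb.start - g.end < 320:
                    return False
                if g.end + 450 > len(sim.chromosomes[g.chrom]):
                    return False
            return True

        gene = take_gene(ok, reserve_neighbor=need_neighbor)
        if gene is None:
            continue
        if need_mid_exon:
            q = mid(central_exon(gene, need_interior))
        elif need_intron:
            introns = gene.introns()
            center = (gene.start + gene.end) // 2
            q = mid(min(introns, key=lambda iv: abs(mid(iv) - center)))
        else:
            q = (gene.start + gene.end) // 2
        if gain:
            cats = {
                ctl: frozenset({"silent_both"}),
                hs: frozenset(parts - {"intact"} | {"acquired_heat_response"})
                if kind != "gain_intact"
                else frozenset({"acquired_heat_response"}),
            }
        else:
            cats_set = frozenset(parts)
            cats = {ctl: cats_set, hs: cats_set}
        scenarios.append(ImpactScenario(gene.feature_id, gene.chrom, q + 1, cats))
    return scenarios


def _intergenic_site(
    sim: SimulatedGenome, rng: np.random.Generator, used: list[tuple[str, int]]
) -> tuple[str, int] | None:
    for _ in range(50):
        chrom = list(sim.chromosomes)[int(rng.integers(len(sim.chromosomes)))]
        feats = sim.annotation.on(chrom)
        bounds = [(f.start, f.end) for f in feats]
        size = len(sim.chromosomes[chrom])
        q = int(rng.integers(1000, size - 1000))
        if any(s - 600 <= q < e + 600 for s, e in bounds):
            continue
        if any(c == chrom and abs(q - u) < 1200 for c, u in used):
            continue
        return chrom, q
    return None


def _nearest_interval(intervals: list[tuple[int, int]], q: int) -> tuple[int, int]:
    if not intervals:
        raise ValueError("gene has no interval of the requested kind")
    return min(intervals, key=lambda iv: 0 if iv[0] <= q < iv[1] else min(abs(q - iv[0]), abs(q - iv[1])))


def _next_feature(annotation: Annotation, gene: Feature) -> Feature | None:
    after = [
        f
        for f in annotation.on(gene.chrom)
        if f.start >= gene.end and f.feature_id != gene.feature_id
    ]
    return after[0] if after else None
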