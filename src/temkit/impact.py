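"""Rule-based classification of an insertion's transcriptional consequences
from stranded per-base coverage, mirroring the taxonomy used to describe
TE-disrupted loci: knockout, 5'/3' truncation, exon skipping, intron
retention, exonisation, transcript fusions, antisense transcription, novel
transcripts, expression-level changes, and the cross-condition acquisition
of heat-stress responsiveness.

All thresholds are explicit configuration; the defining verbal rules are
implemented as coverage predicates over the annotated gene model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .simulate import Annotation, Feature, StrandedCoverage

CONTROL = "control"
HEAT_STRESS = "heat_stress"

ALL_CATEGORIES = frozenset(
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


@dataclass(frozen=True)
class ImpactConfig:
    expressed_threshold: float = 1.0  # mean coverage over transcribed bases
    breakpoint_tolerance: int = 100  # bp slack for truncation changepoints
    antisense_threshold: float = 1.0
    exonisation_kmer: int = 31
    fold_change_min: float = 2.0
    fusion_min_extension: int = 200  # bp of expressed run beyond the gene

    def __post_init__(self):
        for name in (
            "expressed_threshold",
            "breakpoint_tolerance",
            "antisense_threshold",
            "exonisation_kmer",
            "fold_change_min",
            "fusion_min_extension",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ImpactCall:
    chrom: str
    position: int
    gene_id: str | None
    condition: str
    categories: set
    evidence: dict = field(default_factory=dict)


def _pos_of(insertion) -> tuple[str, int]:
    if isinstance(insertion, tuple):
        return insertion[0], int(insertion[1])
    return insertion.chrom, int(insertion.position)


def _transcribed_intervals(gene: Feature) -> list[tuple[int, int]]:
    parts = list(gene.exons)
    for iv in (gene.utr5, gene.utr3):
        if iv:
            parts.append(iv)
    return sorted(parts)


def _mean_over(cov: np.ndarray, intervals) -> float:
    vals = [cov[s:e] for s, e in intervals if e > s]
    if not vals:
        return 0.0
    cat = np.concatenate(vals)
    return float(cat.mean()) if len(cat) else 0.0


def _expressed_span(cov: np.ndarray, intervals, thr: float) -> tuple[int, int] | None:
    """First and last transcribed base with coverage >= thr (genomic)."""
    first = last = None
    for s, e in intervals:
        idx = np.flatnonzero(cov[s:e] >= thr)
        if len(idx):
            lo, hi = s + idx[0], s + idx[-1]
            first = lo if first is None else min(first, lo)
            last = hi if last is None else max(last, hi)
    return None if first is None else (first, last)


def _run_extension(cov: np.ndarray, start: int, direction: int, thr: float) -> int:
    """Length of the contiguous expressed run from ``start`` moving
    ``direction`` (+1 right of the gene, -1 left)."""
    n = 0
    pos = start
    while 0 <= pos < len(cov) and cov[pos] >= thr:
        n += 1
        pos += direction
    return n


def classify_impact(
    insertion,
    tracks: dict[tuple[str, str], StrandedCoverage],
    annotation: Annotation,
    te_sequence: str,
    cfg: ImpactConfig = ImpactConfig(),
    transcripts: dict[tuple[str, str], dict[str, str]] | None = None,
    conditions: tuple[str, ...] = (CONTROL, HEAT_STRESS),
) -> dict[str, ImpactCall]:
    """Classify one insertion in every condition.

    ``tracks`` maps (sample, condition) with sample in {"wt", "line"} to
    stranded coverage; a missing track is an error naming it.
    """
    for sample in ("wt", "line"):
        for cond in conditions:
            if (sample, cond) not in tracks:
                raise KeyError(f"missing coverage track ({sample}, {cond})")
    chrom, pos1 = _pos_of(insertion)
    q = pos1 - 1
    gene = annotation.containing(chrom, q)
    out: dict[str, ImpactCall] = {}
    for cond in conditions:
        wt = tracks[("wt", cond)]
        line = tracks[("line", cond)]
        wt_tx = (transcripts or {}).get(("wt", cond), {})
        line_tx = (transcripts or {}).get(("line", cond), {})
        if gene is None or gene.kind != "gene":
            call = _classify_intergenic(chrom, q, wt, line, annotation, cfg)
        else:
            call = _classify_genic(
                chrom, q, gene, wt, line, wt_tx, line_tx, te_sequence, annotation, cfg
            )
        call.condition = cond
        out[cond] = call
    return out


def _classify_intergenic(
    chrom: str,
    q: int,
    wt: StrandedCoverage,
    line: StrandedCoverage,
    annotation: Annotation,
    cfg: ImpactConfig,
) -> ImpactCall:
    cats: set = set()
    evidence: dict = {}
    window = 250
    lo = max(0, q - window)
    best_line = 0.0
    best_wt = 0.0
    for strand in ("+", "-"):
        lcov = line.strand(strand)[chrom]
        wcov = wt.strand(strand)[chrom]
        hi = min(len(lcov), q + window)
        line_mean = float(lcov[lo:hi].mean())
        wt_mean = float(wcov[lo:hi].mean())
        best_line = max(best_line, line_mean)
        best_wt = max(best_wt, wt_mean)
        if line_mean >= cfg.expressed_threshold and wt_mean < cfg.expressed_threshold:
            # expressed run around the insertion, absent in wt
            left = _run_extension(lcov, q, -1, cfg.expressed_threshold)
            right = _run_extension(lcov, q + 1, +1, cfg.expressed_threshold)
            run = (q - left + 1, q + right) if (left or right) else None
            if run is not None:
                overlaps = [
                    f
                    for f in annotation.on(chrom)
                    if f.start < run[1] and f.end > run[0]
                ]
                if not overlaps:
                    cats.add("novel_transcript")
                    evidence["novel_run"] = run
    evidence["line_expr"] = best_line
    evidence["wt_expr"] = best_wt
    return ImpactCall(chrom, q + 1, None, "", cats, evidence)


def _classify_genic(
    chrom: str,
    q: int,
    gene: Feature,
    wt: StrandedCoverage,
    line: StrandedCoverage,
    wt_tx: dict[str, str],
    line_tx: dict[str, str],
    te_sequence: str,
    annotation: Annotation,
    cfg: ImpactConfig,
) -> ImpactCall:
    thr = cfg.expressed_threshold
    tol = cfg.breakpoint_tolerance
    sense_wt = wt.strand(gene.strand)[chrom]
    sense_line = line.strand(gene.strand)[chrom]
    anti = "-" if gene.strand == "+" else "+"
    anti_wt = wt.strand(anti)[chrom]
    anti_line = line.strand(anti)[chrom]
    tx_iv = _transcribed_intervals(gene)
    wt_expr = _mean_over(sense_wt, tx_iv)
    line_expr = _mean_over(sense_line, tx_iv)
    wt_on = wt_expr >= thr
    line_on = line_expr >= thr

    cats: set = set()
    evidence: dict = {
        "wt_expr": wt_expr,
        "line_expr": line_expr,
        "gene_id": gene.feature_id,
    }

    # antisense transcription is independent of the sense-strand structure
    anti_line_mean = _mean_over(anti_line, [(gene.start, gene.end)])
    anti_wt_mean = _mean_over(anti_wt, [(gene.start, gene.end)])
    if anti_line_mean >= cfg.antisense_threshold and anti_wt_mean < cfg.antisense_threshold:
        cats.add("antisense")
        evidence["antisense_level"] = anti_line_mean

    if not wt_on and not line_on:
        if not cats:
            cats.add("silent_both")
        return ImpactCall(chrom, q + 1, gene.feature_id, "", cats, evidence)
    if wt_on and not line_on:
        cats.add("knockout")
        return ImpactCall(chrom, q + 1, gene.feature_id, "", cats, evidence)

    # --- structural predicates (line expressed from here on) -------------
    structural: set = set()
    span_line = _expressed_span(sense_line, tx_iv, thr)
    t_start, t_end = tx_iv[0][0], tx_iv[-1][1] - 1
    if span_line is not None:
        first, last = span_line
        miss_left = first - t_start
        miss_right = t_end - last
        # map genomic ends to transcript 5'/3' by strand
        miss_5p, near_5p = (
            (miss_left, abs(first - q)) if gene.strand == "+" else (miss_right, abs(last - q))
        )
        miss_3p, near_3p = (
            (miss_right, abs(last - q)) if gene.strand == "+" else (miss_left, abs(first - q))
        )
        if miss_5p > tol and near_5p <= tol:
            structural.add("truncation_5p")
        if miss_3p > tol and near_3p <= tol:
            structural.add("truncation_3p")

    exons = sorted(gene.exons)
    exon_idx = next((i for i, (s, e) in enumerate(exons) if s <= q < e), None)
    if exon_idx is not None and 0 < exon_idx < len(exons) - 1:
        left_m = _mean_over(sense_line, [exons[exon_idx - 1]])
        right_m = _mean_over(sense_line, [exons[exon_idx + 1]])
        mid_line = _mean_over(sense_line, [exons[exon_idx]])
        mid_wt = _mean_over(sense_wt, [exons[exon_idx]])
        if left_m >= thr and right_m >= thr and mid_line < thr <= mid_wt:
            structural.add("exon_skipping")

    introns = gene.introns()
    if introns:
        intron = min(
            introns,
            key=lambda iv: 0 if iv[0] <= q < iv[1] else min(abs(q - iv[0]), abs(q - iv[1])),
        )
        i_idx = introns.index(intron)
        left_ex, right_ex = exons[i_idx], exons[i_idx + 1]
        line_i = _mean_over(sense_line, [intron])
        wt_i = _mean_over(sense_wt, [intron])
        if (
            line_i >= thr > wt_i
            and _mean_over(sense_line, [left_ex]) >= thr
            and _mean_over(sense_line, [right_ex]) >= thr
        ):
            structural.add("intron_retention")

    # transcript fusion: expressed run continues beyond the gene boundary
    for direction, boundary in ((+1, gene.end), (-1, gene.start - 1)):
        ext_line = _run_extension(sense_line, boundary, direction, thr)
        ext_wt = _run_extension(sense_wt, boundary, direction, thr)
        if ext_line >= cfg.fusion_min_extension and ext_wt < cfg.fusion_min_extension:
            lo = boundary if direction > 0 else boundary - ext_line + 1
            hi = boundary + ext_line if direction > 0 else boundary + 1
            overlaps = [
                f
                for f in annotation.on(chrom)
                if f.feature_id != gene.feature_id and f.start < hi and f.end > lo
            ]
            structural.add("fusion_gene" if overlaps else "fusion_intergenic")
            evidence[f"fusion_extension_{'3p' if direction > 0 else '5p'}"] = ext_line

    cats |= structural

    # exonisation: TE-derived k-mers in the locus transcript
    k = cfg.exonisation_kmer
    tx = line_tx.get(gene.feature_id)
    if tx and len(te_sequence) >= k:
        wt_seq = wt_tx.get(gene.feature_id, "")
        if _shares_kmer(tx, te_sequence, k) and not _shares_kmer(wt_seq, te_sequence, k):
            cats.add("exonisation")

    # expression-level calls require an intact structure
    if not structural:
        floor = max(wt_expr, thr / 10.0)
        fold = line_expr / floor
        if fold >= cfg.fold_change_min:
            cats.add("upregulated")
        elif wt_on and fold <= 1.0 / cfg.fold_change_min:
            cats.add("downregulated")
        elif wt_on and line_on:
            cats.add("normal_transcript")
    evidence["fold_change"] = line_expr / max(wt_expr, thr / 10.0)
    return ImpactCall(chrom, q + 1, gene.feature_id, "", cats, evidence)


def _shares_kmer(seq: str, te: str, k: int) -> bool:
    if not seq or len(seq) < k:
        return False
    te_kmers = {te[i : i + k] for i in range(0, len(te) - k + 1)}
    te_rc = revcomp(te)
    te_kmers |= {te_rc[i : i + k] for i in range(0, len(te_rc) - k + 1)}
    return any(seq[i : i + k] in te_kmers for i in range(0, len(seq) - k + 1))


def detect_heat_response_gain(
    calls_by_condition: list[dict[str, ImpactCall]],
    cfg: ImpactConfig = ImpactConfig(),
) -> list[ImpactCall]:
    """Flag loci that became heat-stress responsive through the insertion:
    expressed in the line under heat stress, silent in wt under heat stress,
    and silent in the line under control conditions.

    The heat-stress call of each flagged locus gains the
    ``acquired_heat_response`` category; flagged calls are returned.
    """
    thr = cfg.expressed_threshold
    gained: list[ImpactCall] = []
    for pair in calls_by_condition:
        if CONTROL not in pair or HEAT_STRESS not in pair:
            continue
        hs, ctl = pair[HEAT_STRESS], pair[CONTROL]
        if (
            hs.evidence.get("line_expr", 0.0) >= thr
            and hs.evidence.get("wt_expr", 0.0) < thr
            and ctl.evidence.get("line_expr", 0.0) < thr
        ):
            hs.categories.add("acquired_heat_response")
            gained.append(hs)
    return gained


def tally_impacts(calls: list[ImpactCall]):
    """Category x condition count matrix (multi-category calls count once
    per category)."""
    import pandas as pd

    if not calls:
        raise ValueError("no impact calls to tally")
    conditions = sorted({c.condition for c in calls})
    rows = {}
    for cat in sorted(ALL_CATEGORIES):
        rows[cat] = {
            cond: sum(1 for c in calls if c.condition == cond and cat in c.categories)
            for cond in conditions
        }
    return pd.DataFrame(rows).T
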