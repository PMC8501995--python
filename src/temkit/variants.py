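"""Treatment-induced mutational load: private SNP/indel/CNV counts from
multi-sample variant calls, one-sample t-tests against control counts,
organelle coverage folds and genome-size gain accounting.

A variant is *private* to a line when that line carries a non-reference
genotype and every other line in the cohort is homozygous reference; the
per-line private counts proxy the mutation load induced by the treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy import stats


@dataclass(frozen=True)
class PrivateVariantFilter:
    """Read/quality thresholds applied to the carrier sample (all bounds
    inclusive) and to site mapping quality."""

    dp_min: int = 10
    dp_max: int = 60
    mq_min: float = 30.0
    gq_min: int = 40
    alt_ad_min: int = 5

    def __post_init__(self):
        if self.dp_min > self.dp_max:
            raise ValueError("dp_min must be <= dp_max")


@dataclass
class PrivateVariantReport:
    counts: dict[str, int]
    skipped_missing_format: int = 0
    diagnostics: list[str] = field(default_factory=list)


def _is_nonref(gt) -> bool:
    return gt is not None and any(a not in (None, 0) for a in gt)


def _is_homref(gt) -> bool:
    return gt is not None and all(a == 0 for a in gt)


def count_private_variants(
    vcf,
    filt: PrivateVariantFilter = PrivateVariantFilter(),
    kind: str = "snp",
) -> PrivateVariantReport:
    """Per-sample private SNP or indel counts from a multi-sample VCF.

    ``vcf`` is a path or an open :class:`pysam.VariantFile`.  Multi-allelic
    records are split per ALT allele before the privacy test; a record
    counts for sample s only if s is the single non-reference carrier of
    that allele, all other samples are homozygous reference, and s's
    FORMAT fields pass the filter.
    """
    if kind not in ("snp", "indel"):
        raise ValueError("kind must be 'snp' or 'indel'")
    close = False
    if not isinstance(vcf, pysam.VariantFile):
        vcf = pysam.VariantFile(str(vcf))
        close = True
    try:
        samples = list(vcf.header.samples)
        counts = {s: 0 for s in samples}
        skipped = 0
        for rec in vcf:
            try:
                mq = rec.info.get("MQ")
            except KeyError:
                mq = None
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                is_snp = len(rec.ref) == 1 and len(alt) == 1
                if (kind == "snp") != is_snp:
                    continue
                carriers = [
                    s
                    for s in samples
                    if (gt := rec.samples[s].get("GT")) is not None
                    and alt_index in gt
                ]
                if len(carriers) != 1:
                    continue
                # every non-carrier must be homozygous reference
                ok = all(
                    _is_homref(rec.samples[s].get("GT"))
                    for s in samples
                    if s != carriers[0]
                )
                if not ok:
                    continue
                s = carriers[0]
                fmt = rec.samples[s]
                dp, gq, ad = fmt.get("DP"), fmt.get("GQ"), fmt.get("AD")
                if dp is None or gq is None or ad is None or mq is None:
                    skipped += 1
                    continue
                if not (filt.dp_min <= dp <= filt.dp_max):
                    continue
                if mq < filt.mq_min or gq < filt.gq_min:
                    continue
                if ad[alt_index] is None or ad[alt_index] < filt.alt_ad_min:
                    continue
                counts[s] += 1
        return PrivateVariantReport(counts, skipped)
    finally:
        if close:
            vcf.close()


@dataclass
class CNVEvent:
    sample: str
    chrom: str
    start: int
    end: int
    cnv_type: str  # e.g. deletion | duplication


def count_private_cnvs(
    events: list[CNVEvent], reciprocal_overlap: float = 0.5
) -> dict[str, int]:
    """Private CNV counts: two events are the same when they have the same
    type and reciprocal overlap >= the threshold; an event shared by any
    other sample is not private."""
    counts: dict[str, int] = {}
    for ev in events:
        shared = False
        for other in events:
            if other.sample == ev.sample or other.cnv_type != ev.cnv_type:
                continue
            if other.chrom != ev.chrom:
                continue
            inter = min(ev.end, other.end) - max(ev.start, other.start)
            if inter <= 0:
                continue
            if (
                inter / (ev.end - ev.start) >= reciprocal_overlap
                and inter / (other.end - other.start) >= reciprocal_overlap
            ):
                shared = True
                break
        counts.setdefault(ev.sample, 0)
        if not shared:
            counts[ev.sample] += 1
    return counts


def one_sample_t(values, mu: float) -> tuple[float, int, float]:
    """Two-sided one-sample Student's t-test: t, df, p."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two observations")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero sample variance: t statistic undefined")
    t = (values.mean() - mu) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def organelle_coverage(
    depths: dict[str, dict[str, float]], reference_line: str
) -> dict[str, dict[str, float]]:
    """Fold coverage per line per organelle contig relative to a reference
    line: fold = line depth / reference depth."""
    ref = depths[reference_line]
    out: dict[str, dict[str, float]] = {}
    for line, per_contig in depths.items():
        out[line] = {}
        for contig, depth in per_contig.items():
            if ref.get(contig, 0) <= 0:
                raise ValueError(
                    f"reference line {reference_line} has zero depth on {contig}"
                )
            out[line][contig] = depth / ref[contig]
    return out


def genome_size_gain(
    n_insertions: int, element_length: int, genome_size: int
) -> tuple[int, float]:
    """Base pairs added by full-length insertions and the percent genome
    size increase."""
    if n_insertions < 0 or element_length <= 0 or genome_size <= 0:
        raise ValueError("inputs must be positive (n_insertions may be zero)")
    added = n_insertions * element_length
    return added, 100.0 * added / genome_size
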