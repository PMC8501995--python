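"""Insertion-site preference: genomic features, chromatin states, histone
signal profiles, metagene positions, orientation, TSD logos, hotspots and
target-gene expression.

Every classification carries its genome-wide baseline (fraction of the
genome covered by the class) so observed-versus-expected statements can be
made directly from the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Annotation, StateSegmentation

# feature precedence used to resolve overlapping annotation (highest first)
FEATURE_CLASSES = [
    "coding_exon",
    "utr",
    "intron",
    "lncRNA",
    "pseudogene",
    "transposable_element",
    "intergenic",
]
_CLASS_CODE = {name: i for i, name in enumerate(FEATURE_CLASSES)}


def _position_of(call) -> tuple[str, int]:
    if isinstance(call, tuple):
        return call[0], int(call[1])
    return call.chrom, int(call.position)


@dataclass
class SitePreferenceReport:
    feature_freq: dict[str, tuple[int, float, float]]  # class -> (count, fraction, genomic_fraction)
    state_freq: dict[int, tuple[int, float, float]]
    n_sites: int

    def feature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"feature": k, "count": c, "fraction": f, "genomic_fraction": g}
                for k, (c, f, g) in self.feature_freq.items()
            ]
        )

    def state_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"state": k, "count": c, "fraction": f, "genomic_fraction": g}
                for k, (c, f, g) in self.state_freq.items()
            ]
        )

    def genic_fraction(self) -> float:
        """Fraction of sites in any annotated feature (non-intergenic)."""
        non_genic = self.feature_freq.get("intergenic", (0, 0.0, 0.0))[1]
        return 1.0 - non_genic


def feature_class_arrays(
    annotation: Annotation, chrom_sizes: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-base feature class (by precedence) for each chromosome."""
    arrays = {
        c: np.full(n, _CLASS_CODE["intergenic"], dtype=np.int8)
        for c, n in chrom_sizes.items()
    }
    # paint lowest precedence first so higher precedence overwrites
    flat_kind = {
        "transposable_element": "transposable_element",
        "pseudogene": "pseudogene",
        "lncRNA": "lncRNA",
    }
    for kind in ("transposable_element", "pseudogene", "lncRNA"):
        for f in annotation.features:
            if f.kind == kind:
                arrays[f.chrom][f.start : f.end] = _CLASS_CODE[flat_kind[kind]]
    for f in annotation.features:
        if f.kind != "gene":
            continue
        arr = arrays[f.chrom]
        arr[f.start : f.end] = _CLASS_CODE["intron"]
        for interval in (f.utr5, f.utr3):
            if interval:
                arr[interval[0] : interval[1]] = _CLASS_CODE["utr"]
        for s, e in f.exons:
            arr[s:e] = _CLASS_CODE["coding_exon"]
    return arrays


def classify_sites(
    calls,
    annotation: Annotation,
    states: StateSegmentation,
) -> SitePreferenceReport:
    """Assign each insertion one feature class (by precedence) and one
    chromatin state, with genome-wide baselines from the same inputs."""
    chrom_sizes = states.chrom_sizes()
    class_arr = feature_class_arrays(annotation, chrom_sizes)
    state_arr = {c: states.state_array(c) for c in chrom_sizes}

    positions = [_position_of(c) for c in calls]
    n = len(positions)
    feat_counts = {k: 0 for k in FEATURE_CLASSES}
    state_counts: dict[int, int] = {}
    for chrom, pos1 in positions:
        q = pos1 - 1
        feat_counts[FEATURE_CLASSES[class_arr[chrom][q]]] += 1
        st = int(state_arr[chrom][q])
        if st == 0:
            raise ValueError(
                f"insertion {chrom}:{pos1} not covered by any chromatin state"
            )
        state_counts[st] = state_counts.get(st, 0) + 1

    genome_total = sum(chrom_sizes.values())
    feat_genomic = {
        k: sum(int((arr == code).sum()) for arr in class_arr.values()) / genome_total
        for k, code in _CLASS_CODE.items()
    }
    state_genomic = states.genome_fractions()

    feature_freq = {
        k: (feat_counts[k], feat_counts[k] / n if n else 0.0, feat_genomic[k])
        for k in FEATURE_CLASSES
    }
    all_states = sorted(set(state_genomic) | set(state_counts))
    state_freq = {
        s: (
            state_counts.get(s, 0),
            state_counts.get(s, 0) / n if n else 0.0,
            state_genomic.get(s, 0.0),
        )
        for s in all_states
    }
    return SitePreferenceReport(feature_freq, state_freq, n)


def state_enrichment_test(
    report: SitePreferenceReport, state: int
) -> tuple[float, float]:
    """One-sided binomial test of a state's observed insertion share against
    its genomic share.  Returns (observed fraction, p value)."""
    count, frac, genomic = report.state_freq[state]
    res = stats.binomtest(count, report.n_sites, genomic, alternative="greater")
    return frac, res.pvalue


def signal_profile(
    calls,
    track: dict[str, np.ndarray],
    flank: int = 1000,
    bin_size: int = 50,
) -> np.ndarray:
    """Mean signal in ``bin_size`` windows over ±``flank`` around insertion
    points (40 bins for the defaults).  Sites truncated by a contig end
    contribute only their covered bins."""
    n_bins = (2 * flank) // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for call in calls:
        chrom, pos1 = _position_of(call)
        arr = track[chrom]
        center = pos1 - 1
        for b in range(n_bins):
            lo = center - flank + b * bin_size
            hi = lo + bin_size
            if lo < 0 or hi > len(arr):
                continue
            sums[b] += arr[lo:hi].mean()
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def metagene_positions(
    calls,
    features,
    bin_percent: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative positions (percent of feature length, 0% = 5' end) for calls
    inside features, plus the histogram over ``bin_percent`` bins."""
    feats = list(features)
    rel: list[float] = []
    for call in calls:
        chrom, pos1 = _position_of(call)
        q = pos1 - 1
        hit = next(
            (f for f in feats if f.chrom == chrom and f.start <= q < f.end), None
        )
        if hit is None:
            continue
        if hit.length == 0:
            raise ValueError(f"zero-length feature {hit.feature_id}")
        frac = (q - hit.start) / hit.length
        if hit.strand == "-":
            frac = 1.0 - frac
        rel.append(100.0 * frac)
    edges = np.arange(0, 100 + bin_percent, bin_percent)
    hist, _ = np.histogram(rel, bins=edges)
    return np.array(rel), hist


def orientation_concordance(calls, features) -> tuple[int, int]:
    """(same, opposite) orientation counts for calls inside stranded
    features; calls outside any feature are skipped."""
    feats = list(features)
    same = opposite = 0
    for call in calls:
        chrom, pos1 = _position_of(call)
        orient = getattr(call, "orientation", None)
        if orient is None:
            continue
        q = pos1 - 1
        hit = next(
            (f for f in feats if f.chrom == chrom and f.start <= q < f.end), None
        )
        if hit is None:
            continue
        if orient == hit.strand:
            same += 1
        else:
            opposite += 1
    return same, opposite


def tsd_logo(tsds: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Position frequency matrix (4 x L, rows A/C/G/T) and per-position
    information content IC_j = 2 - H_j bits for equal-length TSDs."""
    if not tsds:
        raise ValueError("no TSD sequences given")
    lengths = {len(t) for t in tsds}
    if len(lengths) != 1:
        raise ValueError("TSDs must have equal length; stratify by length first")
    L = lengths.pop()
    pfm = np.zeros((4, L))
    index = {b: i for i, b in enumerate("ACGT")}
    for t in tsds:
        for j, b in enumerate(t.upper()):
            if b in index:
                pfm[index[b], j] += 1
    freqs = pfm / pfm.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(freqs), 0.0)
    entropy = -(freqs * logs).sum(axis=0)
    ic = 2.0 - entropy
    return freqs, ic


@dataclass
class HotspotTally:
    clusters: list[tuple[str, int, int, int]]  # chrom, start, end, n_insertions
    size_histogram: dict[int, int]
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    window: int = 10_000
    sources: dict = field(default_factory=dict)


def cluster_insertions(
    positions: list[tuple[str, int]], window: int
) -> list[tuple[str, int, int, int]]:
    """Greedy left-anchored clustering: a cluster extends while the next
    insertion lies within ``window`` of the cluster's leftmost member."""
    clusters: list[tuple[str, int, int, int]] = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom in sorted(by_chrom):
        pos_sorted = sorted(by_chrom[chrom])
        i = 0
        while i < len(pos_sorted):
            anchor = pos_sorted[i]
            j = i
            while j + 1 < len(pos_sorted) and pos_sorted[j + 1] - anchor <= window:
                j += 1
            clusters.append((chrom, anchor, pos_sorted[j], j - i + 1))
            i = j + 1
    return clusters


def find_hotspots(
    insertion_sets: dict[str, list],
    chrom_sizes: dict[str, int],
    window: int = 10_000,
) -> HotspotTally:
    """Cluster the union of the named insertion sets and test the per-tile
    insertion counts against a Poisson (uniform-random) null.

    The chi-square compares the histogram of insertions per ``window``-sized
    genomic tile with the Poisson expectation for n insertions over
    G/window tiles, pooling tail classes so expected counts stay >= 5.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if not insertion_sets:
        raise ValueError("need at least one insertion set")
    positions: list[tuple[str, int]] = []
    sources: dict[str, int] = {}
    for name, calls in insertion_sets.items():
        pts = [_position_of(c) for c in calls]
        positions.extend(pts)
        sources[name] = len(pts)
    clusters = cluster_insertions(positions, window)
    size_hist: dict[int, int] = {}
    for _, _, _, size in clusters:
        if size >= 2:
            size_hist[size] = size_hist.get(size, 0) + 1

    # tile the genome and count insertions per tile
    tile_counts: list[int] = []
    for chrom, size in chrom_sizes.items():
        n_tiles = max(1, size // window)
        counts = np.zeros(n_tiles, dtype=int)
        for c, pos in positions:
            if c == chrom:
                t = min((pos - 1) // window, n_tiles - 1)
                counts[t] += 1
        tile_counts.extend(counts.tolist())
    tile_counts = np.array(tile_counts)
    n_tiles = len(tile_counts)
    n_ins = len(positions)
    lam = n_ins / n_tiles
    max_k = int(tile_counts.max())
    observed = np.bincount(tile_counts, minlength=max_k + 1).astype(float)
    expected = np.array(
        [stats.poisson.pmf(k, lam) * n_tiles for k in range(max_k + 1)]
    )
    expected[-1] = n_tiles - expected[:-1].sum()  # absorb the tail
    # pool classes from the right until every expected count >= 5
    obs_p, exp_p = list(observed), list(expected)
    while len(exp_p) > 2 and exp_p[-1] < 5:
        e_last, o_last = exp_p.pop(), obs_p.pop()
        exp_p[-1] += e_last
        obs_p[-1] += o_last
    # also pool from the left (tiny lambda regimes)
    while len(exp_p) > 2 and exp_p[0] < 5:
        e_first, o_first = exp_p.pop(0), obs_p.pop(0)
        exp_p[0] += e_first
        obs_p[0] += o_first
    obs_p, exp_p = np.array(obs_p), np.array(exp_p)
    if len(obs_p) < 2:
        chi2, p, df = 0.0, 1.0, 0
    else:
        # one df lost to the tile total, one to the fixed insertion total
        df = max(1, len(obs_p) - 2)
        chi2 = float(((obs_p - exp_p) ** 2 / exp_p).sum())
        p = float(stats.chi2.sf(chi2, df))
    return HotspotTally(
        clusters=[c for c in clusters if c[3] >= 2],
        size_histogram=size_hist,
        chi2_stat=float(chi2),
        chi2_df=int(df),
        chi2_p=float(p),
        window=window,
        sources=sources,
    )


@dataclass
class ExpressionTestResult:
    statistic: float
    pvalue: float
    direction: str  # "lower" | "higher" | "none"
    group_medians: list[float]
    pairwise: pd.DataFrame  # group pairs with Bonferroni-corrected p


def target_expression_test(
    targets: list[str],
    expression: pd.Series,
    n_random_sets: int = 4,
    seed: int | None = None,
) -> ExpressionTestResult:
    """Kruskal-Wallis comparison of target genes' expression against
    ``n_random_sets`` random same-size gene sets (sampled without
    replacement from the non-target background), with rank-sum pairwise
    post-hoc tests (Bonferroni)."""
    rng = np.random.default_rng(seed)
    expression = expression.dropna()
    targets = [t for t in targets if t in expression.index]
    if not targets:
        raise ValueError("no target genes present in the expression table")
    background = expression.index.difference(targets)
    k = len(targets)
    if len(background) < n_random_sets * k:
        raise ValueError(
            "expression table too small for the requested number of random sets"
        )
    pool = rng.permutation(np.array(background))
    groups = [expression.loc[targets].to_numpy()]
    names = ["targets"]
    for i in range(n_random_sets):
        sel = pool[i * k : (i + 1) * k]
        groups.append(expression.loc[sel].to_numpy())
        names.append(f"random{i + 1}")
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = stats.kruskal(*groups)
        if not np.isfinite(stat):  # all values identical across groups
            stat, p = 0.0, 1.0
    except ValueError:
        stat, p = 0.0, 1.0
    rows = []
    n_pairs = n_random_sets  # targets vs each random set
    for i in range(1, len(groups)):
        try:
            u_stat, u_p = stats.mannwhitneyu(groups[0], groups[i], alternative="two-sided")
        except ValueError:
            u_stat, u_p = 0.0, 1.0
        rows.append(
            {
                "group_a": "targets",
                "group_b": names[i],
                "u": u_stat,
                "p_bonferroni": min(1.0, u_p * n_pairs),
            }
        )
    medians = [float(np.median(g)) for g in groups]
    other_median = float(np.median(np.concatenate(groups[1:])))
    if medians[0] < other_median:
        direction = "lower"
    elif medians[0] > other_median:
        direction = "higher"
    else:
        direction = "none"
    return ExpressionTestResult(
        statistic=float(stat),
        pvalue=float(p),
        direction=direction,
        group_medians=medians,
        pairwise=pd.DataFrame(rows),
    )
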