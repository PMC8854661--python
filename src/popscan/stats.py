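"""Population-genetic estimators: windowed pi, Weir–Cockerham F_ST,
observed heterozygosity, folded SFS, genotype r² and LD decay.

Estimator definitions
---------------------
*Nucleotide diversity.*  Per site, with ``j`` alt alleles among ``n`` called
alleles in the population, ``pi_s = 2 j (n-j) / (n (n-1))`` (the mean number
of pairwise differences); window pi is the sum of ``pi_s`` over the window
divided by the full window length in bp, so monomorphic and unsampled bases
count in the denominator (per-bp diversity, the windowed-pi convention of
VCFtools and friends).

*F_ST.*  Weir & Cockerham (1984) variance components for two populations:
per site the among-population (``a``), among-individual (``b``) and
within-individual (``c``) components are computed from sample sizes,
frequencies and observed heterozygosity; the window estimate is the weighted
ratio ``sum(a) / sum(a+b+c)``.  Negative estimates are reported as computed.

*LD.*  Genotype-based (composite) r²: the squared Pearson correlation of
alt-allele counts across samples called at both sites — appropriate for
unphased data.  Decay curves bin mean r² by physical distance; the
half-maximum distance is read off an isotonic (monotone-decreasing)
smoothing of the binned means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .core import MISSING, GenotypeMatrix, WindowSpec

__all__ = [
    "site_pi",
    "window_pi",
    "wc_site_components",
    "site_fst",
    "window_fst",
    "window_stats_table",
    "observed_heterozygosity",
    "folded_sfs",
    "ld_r2",
    "LDDecayCurve",
    "ld_half_max",
    "ld_decay",
    "compare_chromosome_groups",
]


# ----------------------------------------------------------------------
# nucleotide diversity
# ----------------------------------------------------------------------

def site_pi(j: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site pi from alt-allele count ``j`` and called-allele count ``n``.

    Sites with fewer than two called alleles contribute 0 (they are skipped,
    not counted as variation).
    """
    j = np.asarray(j, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    return np.where(n >= 2, pi, 0.0)


def _window_slices(
    gm: GenotypeMatrix, windows: Sequence[WindowSpec]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window [lo, hi) row ranges into the variant table."""
    chrom_rows: dict[str, np.ndarray] = {}
    chrom_pos: dict[str, np.ndarray] = {}
    chroms = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        rows = np.flatnonzero(chroms == chrom)
        chrom_rows[chrom] = rows
        chrom_pos[chrom] = pos[rows] - 1  # 0-based
    lo = np.zeros(len(windows), dtype=np.int64)
    hi = np.zeros(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        if w.chrom not in chrom_rows:
            lo[i] = hi[i] = 0
            continue
        p = chrom_pos[w.chrom]
        base = chrom_rows[w.chrom][0] if chrom_rows[w.chrom].size else 0
        lo[i] = base + np.searchsorted(p, w.start, side="left")
        hi[i] = base + np.searchsorted(p, w.end, side="left")
    return lo, hi


def _window_sums(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    return cs[hi] - cs[lo]


def window_pi(
    gm: GenotypeMatrix, windows: Sequence[WindowSpec], population: str
) -> pd.DataFrame:
    """Windowed per-bp nucleotide diversity for one population."""
    j, n = gm.allele_counts(population)
    pi_s = site_pi(j, n)
    seg = (j > 0) & (j < n)
    lo, hi = _window_slices(gm, windows)
    sums = _window_sums(pi_s, lo, hi)
    nvar = _window_sums(seg.astype(float), lo, hi)
    lengths = np.array([w.length for w in windows], dtype=float)
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start1 for w in windows],
            "end": [w.end1 for w in windows],
            "pi": sums / lengths,
            "n_variants": nvar.astype(int),
        }
    )


# ----------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ----------------------------------------------------------------------

def wc_site_components(
    gm: GenotypeMatrix, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site variance components (a, b, c) and a validity mask.

    Sites are valid when each population has at least one called diploid and
    the populations together have more than two (the component denominators
    require ``n_bar > 1``).
    """
    comps = []
    for pop in (pop_a, pop_b):
        cols = gm.sample_indices(pop)
        g = gm.genotypes[:, cols]
        called = g >= 0
        n_dip = called.sum(axis=1).astype(float)  # diploids called
        j = np.where(called, g, 0).sum(axis=1).astype(float)
        het = np.where(called, g == 1, False).sum(axis=1).astype(float)
        comps.append((n_dip, j, het))
    (n1, j1, h1), (n2, j2, h2) = comps
    valid = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = j1 / (2.0 * n1)
        p2 = j2 / (2.0 * n2)
        hf1 = h1 / n1
        hf2 = h2 / n2
        r = 2.0
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * hf1 + n2 * hf2) / (r * n_bar)
        pq = p_bar * (1.0 - p_bar)
        inner = pq - s2 * (r - 1.0) / r - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            pq - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
    for arr in (a, b, c):
        arr[~valid] = 0.0
    return a, b, c, valid


def site_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> np.ndarray:
    """Per-site Weir–Cockerham F_ST (NaN where undefined)."""
    a, b, c, valid = wc_site_components(gm, pop_a, pop_b)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = a / denom
    fst[~valid | (denom == 0)] = np.nan
    return fst


def window_fst(
    gm: GenotypeMatrix,
    windows: Sequence[WindowSpec],
    pop_pair: tuple[str, str],
) -> pd.DataFrame:
    """Windowed weighted Weir–Cockerham F_ST: sum(a)/sum(a+b+c) per window.

    Windows whose component denominator sums to zero are reported as NaN
    (missing), not zero; negative estimates are kept as computed.
    """
    a, b, c, valid = wc_site_components(gm, *pop_pair)
    lo, hi = _window_slices(gm, windows)
    num = _window_sums(a, lo, hi)
    den = _window_sums(a + b + c, lo, hi)
    nsit = _window_sums(valid.astype(float), lo, hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den != 0, num / den, np.nan)
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start1 for w in windows],
            "end": [w.end1 for w in windows],
            "fst": fst,
            "n_sites": nsit.astype(int),
        }
    )


def window_stats_table(
    gm: GenotypeMatrix,
    windows: Sequence[WindowSpec],
    populations: Sequence[str] | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Joint per-window table: per-population pi and per-pair weighted F_ST.

    Column layout: chrom, start, end (1-based inclusive), then ``pi_<pop>``
    and ``nvar_<pop>`` per population and ``fst_<a>__<b>`` / ``nsit_<a>__<b>``
    per pair.
    """
    if populations is None:
        populations = gm.population_names
    if pairs is None:
        pairs = [
            (a, b)
            for i, a in enumerate(populations)
            for b in list(populations)[i + 1 :]
        ]
    out = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start1 for w in windows],
            "end": [w.end1 for w in windows],
        }
    )
    for pop in populations:
        sub = window_pi(gm, windows, pop)
        out[f"pi_{pop}"] = sub["pi"].to_numpy()
        out[f"nvar_{pop}"] = sub["n_variants"].to_numpy()
    for pair in pairs:
        sub = window_fst(gm, windows, pair)
        out[f"fst_{pair[0]}__{pair[1]}"] = sub["fst"].to_numpy()
        out[f"nsit_{pair[0]}__{pair[1]}"] = sub["n_sites"].to_numpy()
    return out


# ----------------------------------------------------------------------
# heterozygosity and the folded SFS
# ----------------------------------------------------------------------

def observed_heterozygosity(
    gm: GenotypeMatrix,
    samples: Sequence[str] | None = None,
    region: tuple[str, int, int] | None = None,
) -> pd.Series:
    """Per-sample fraction of called sites that are heterozygous.

    ``region`` is (chrom, start, end) 0-based half-open; None means
    genome-wide.  Samples with no called site in the region get NaN.
    """
    if region is not None:
        rows = gm.variant_indices_in(*region)
        g = gm.genotypes[rows]
    else:
        g = gm.genotypes
    if samples is not None:
        cols = [gm.samples.index(s) for s in samples]
        g = g[:, cols]
        names = list(samples)
    else:
        names = list(gm.samples)
    called = (g != MISSING).sum(axis=0)
    het = (g == 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return pd.Series(frac, index=names, name="het")


@dataclass
class FoldedSFS:
    """Minor-allele-count histogram plus summary fractions."""

    counts: np.ndarray  # index = minor allele count, 0..floor(n/2)
    n_alleles: int
    n_segregating: int
    rare_proportion: float  # segregating sites with maf < threshold
    singleton_proportion: float
    maf_threshold: float


def folded_sfs(
    gm: GenotypeMatrix, population: str, maf_threshold: float = 0.05
) -> FoldedSFS:
    """Folded site-frequency spectrum over fully comparable allele counts.

    Minor-allele counts are taken relative to each site's called alleles;
    the histogram is indexed by the minor count.  Monomorphic sites
    contribute nothing, so the histogram totals the segregating-site count.
    """
    cols = gm.sample_indices(population)
    if cols.size < 2:
        raise ValueError("folded SFS needs at least 2 samples")
    j, n = gm.allele_counts(population)
    seg = (j > 0) & (j < n)
    minor = np.minimum(j[seg], n[seg] - j[seg])
    n_max = int(2 * cols.size)
    counts = np.bincount(minor, minlength=n_max // 2 + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = minor / n[seg]
    n_seg = int(seg.sum())
    rare = float((maf < maf_threshold).mean()) if n_seg else 0.0
    singleton = float((minor == 1).mean()) if n_seg else 0.0
    return FoldedSFS(
        counts=counts,
        n_alleles=n_max,
        n_segregating=n_seg,
        rare_proportion=rare,
        singleton_proportion=singleton,
        maf_threshold=maf_threshold,
    )


# ----------------------------------------------------------------------
# linkage disequilibrium
# ----------------------------------------------------------------------

def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Composite r²: squared Pearson correlation of genotype codes.

    Computed over samples called at both sites; returns NaN when fewer than
    two joint calls remain or either site is monomorphic among them.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    x, y = g1[ok], g2[ok]
    if x.size < 2:
        return float("nan")
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


@dataclass
class LDDecayCurve:
    """Binned mean r² against physical distance."""

    bin_edges: np.ndarray  # len = n_bins + 1, bp
    mean_r2: np.ndarray  # NaN for empty bins
    counts: np.ndarray
    smoothed_r2: np.ndarray  # isotonic-decreasing fit over non-empty bins
    half_max_bp: float | None  # None = never decayed to half its maximum

    @property
    def bin_mids(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def ld_half_max(
    bin_mids: np.ndarray,
    mean_r2: np.ndarray,
    counts: np.ndarray | None = None,
) -> tuple[float | None, np.ndarray]:
    """Half-maximum distance of a binned decay curve.

    The binned means are smoothed with a monotone-decreasing isotonic
    regression (weights = pair counts) to suppress bin noise; the
    half-maximum is the distance at which the smoothed curve first drops to
    half its maximum, linearly interpolated between the bracketing bin
    midpoints for sub-bin accuracy (a tie at exactly half resolves to the
    smaller distance).  Returns (distance or None, smoothed values).
    """
    bin_mids = np.asarray(bin_mids, dtype=float)
    mean_r2 = np.asarray(mean_r2, dtype=float)
    ok = np.isfinite(mean_r2)
    if ok.sum() == 0:
        return None, np.full_like(mean_r2, np.nan)
    w = None if counts is None else np.asarray(counts, dtype=float)[ok]
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    smooth_ok = iso.fit_transform(bin_mids[ok], mean_r2[ok], sample_weight=w)
    smoothed = np.full_like(mean_r2, np.nan)
    smoothed[ok] = smooth_ok
    top = float(np.max(smooth_ok))
    if top <= 0:
        return None, smoothed
    half = top / 2.0
    below = np.flatnonzero(smooth_ok <= half)
    if below.size == 0:
        return None, smoothed
    i = below[0]
    mids_ok = bin_mids[ok]
    if i == 0 or smooth_ok[i] == half:
        return float(mids_ok[i]), smoothed
    y0, y1 = smooth_ok[i - 1], smooth_ok[i]
    frac = (y0 - half) / (y0 - y1)  # y0 > half >= y1, so frac in (0, 1]
    return float(mids_ok[i - 1] + frac * (mids_ok[i] - mids_ok[i - 1])), smoothed


def _standardize_rows(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize a complete genotype block; mask monomorphic rows."""
    mu = g.mean(axis=1, keepdims=True)
    sd = g.std(axis=1, keepdims=True)
    poly = sd[:, 0] > 0
    z = np.where(sd > 0, (g - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, poly


def ld_decay(
    gm: GenotypeMatrix,
    population: str,
    max_dist: int = 50_000,
    bin_width: int = 100,
    max_pairs: int = 2_000_000,
) -> LDDecayCurve:
    """LD decay curve for one population over all chromosomes.

    All site pairs within ``max_dist`` are used; if their number exceeds
    ``max_pairs`` the anchor sites are deterministically thinned.  Sites with
    missing genotypes are mean-imputed for the pairwise correlations (the
    composite-r² convention for near-complete data); heavily missing data
    should be filtered first.
    """
    cols = gm.sample_indices(population)
    chroms = gm.variants["chrom"].to_numpy()
    pos_all = gm.variants["pos"].to_numpy()
    edges = np.arange(0, max_dist + bin_width, bin_width, dtype=float)
    nbins = edges.size - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)

    # estimate total pairs to set the anchor stride
    total_pairs = 0
    per_chrom: list[tuple[np.ndarray, np.ndarray]] = []
    for chrom in dict.fromkeys(chroms):
        rows = np.flatnonzero(chroms == chrom)
        pos = pos_all[rows]
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        total_pairs += int((hi - np.arange(pos.size) - 1).sum())
        per_chrom.append((rows, pos))
    stride = max(1, int(np.ceil(total_pairs / max_pairs))) if total_pairs else 1

    for rows, pos in per_chrom:
        g = gm.genotypes[np.ix_(rows, cols)].astype(float)
        g[g == MISSING] = np.nan
        site_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=1)
        site_mean = np.where(np.isfinite(site_mean), site_mean, 0.0)
        inds = np.where(np.isnan(g))
        g[inds] = site_mean[inds[0]]
        z, poly = _standardize_rows(g)
        n = cols.size
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        for i in range(0, pos.size, stride):
            if not poly[i] or hi[i] <= i + 1:
                continue
            block = slice(i + 1, hi[i])
            ok = poly[block]
            if not ok.any():
                continue
            r = (z[block][ok] @ z[i]) / n
            d = pos[block][ok] - pos[i]
            b = np.minimum((d // bin_width).astype(int), nbins - 1)
            np.add.at(sums, b, r * r)
            np.add.at(counts, b, 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = 0.5 * (edges[:-1] + edges[1:])
    half, smoothed = ld_half_max(mids, mean_r2, counts)
    return LDDecayCurve(
        bin_edges=edges,
        mean_r2=mean_r2,
        counts=counts,
        smoothed_r2=smoothed,
        half_max_bp=half,
    )


# ----------------------------------------------------------------------
# chromosome-group comparison (99% CI non-overlap rule)
# ----------------------------------------------------------------------

def compare_chromosome_groups(
    stats: pd.DataFrame,
    group_a_chroms: Sequence[str],
    group_b_chroms: Sequence[str],
    metric: str,
    z: float = 2.58,
) -> dict:
    """Compare a window statistic between two chromosome groups.

    Each group is summarized as mean ± ``z`` x standard error over its
    windows (z = 2.58 gives the 99% interval); the groups are judged
    "different" iff the intervals are disjoint.  Also reports the A/B ratio
    of means.
    """
    def summarize(chroms: Sequence[str]) -> tuple[float, float, float, int]:
        vals = stats.loc[stats["chrom"].isin(chroms), metric].dropna().to_numpy()
        if vals.size < 2:
            raise ValueError("each group needs at least 2 windows with data")
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(vals.size))
        return mean, mean - z * se, mean + z * se, vals.size

    mean_a, lo_a, hi_a, n_a = summarize(group_a_chroms)
    mean_b, lo_b, hi_b, n_b = summarize(group_b_chroms)
    disjoint = hi_a < lo_b or hi_b < lo_a
    return {
        "metric": metric,
        "mean_a": mean_a,
        "ci_a": (lo_a, hi_a),
        "n_a": n_a,
        "mean_b": mean_b,
        "ci_b": (lo_b, hi_b),
        "n_b": n_b,
        "different": bool(disjoint),
        "ratio": mean_a / mean_b if mean_b != 0 else float("inf"),
    }
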