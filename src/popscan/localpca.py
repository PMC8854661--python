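"""Local PCA along the genome, MDS outlier detection, inversion genotyping.

The scan follows the lostruct recipe: each chromosome is cut into
non-overlapping windows of a fixed SNP count (default 100); each window's
mean-centered genotype matrix yields a sample x sample covariance whose
top-k eigenpairs summarize local population structure.  Windows are compared
through the Frobenius distance between their rank-k covariance
reconstructions, the window x window distance matrix is embedded with
classical (Torgerson) MDS, and runs of MDS outliers become candidate
structural-variant regions.

A chromosomal inversion suppresses recombination in heterozygotes, so SNPs
inside it segregate as one locus: PCA of the region splits samples into
three clusters along PC1 (the two homozygous arrangements and the
heterozygotes in between), the middle cluster shows elevated observed
heterozygosity, and LD across the region collapses once inverted-arrangement
carriers are removed.  :func:`genotype_inversion` and
:func:`verify_inversion_ld` implement those checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .stats import observed_heterozygosity

logger = logging.getLogger(__name__)

__all__ = [
    "LocalPCAResult",
    "CandidateRegion",
    "InversionCall",
    "LDVerification",
    "local_pca_windows",
    "window_distance",
    "mds_embed",
    "detect_candidate_regions",
    "genotype_inversion",
    "verify_inversion_ld",
    "scan_genome",
]


# ----------------------------------------------------------------------
# windowed eigen-summaries
# ----------------------------------------------------------------------

@dataclass
class LocalPCAResult:
    """Per-window eigen-summaries for one or more chromosomes.

    ``windows`` has one row per window: chrom, start, end (1-based inclusive
    genomic extent of the member SNPs), first/last variant row, and a
    ``degenerate`` flag for windows with zero variance.  ``eigvals`` is
    (n_windows, k) with eigenvalues of the trace-normalized covariance,
    sorted descending; ``eigvecs`` is (n_windows, n_samples, k).
    """

    windows: pd.DataFrame
    eigvals: np.ndarray
    eigvecs: np.ndarray
    samples: list[str]
    snps_per_window: int
    k: int

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.windows["chrom"].to_numpy() == chrom)


def _centered_window(gm: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
    """Mean-impute missing calls, center each site; returns sites x samples."""
    x = gm.genotypes[rows].astype(float)
    x[x == MISSING] = np.nan
    mu = np.nanmean(x, axis=1)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    idx = np.where(np.isnan(x))
    x[idx] = mu[idx[0]]
    return x - x.mean(axis=1, keepdims=True)


def local_pca_windows(
    gm: GenotypeMatrix, snps_per_window: int = 100, k: int = 2
) -> LocalPCAResult:
    """Eigen-summaries of non-overlapping fixed-SNP-count windows.

    Each chromosome is processed independently; trailing SNPs that do not
    fill a window are dropped, and chromosomes with fewer SNPs than one
    window are skipped with a log message.
    """
    chroms = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    recs: list[dict] = []
    vals: list[np.ndarray] = []
    vecs: list[np.ndarray] = []
    for chrom in dict.fromkeys(chroms):
        rows = np.flatnonzero(chroms == chrom)
        n_win = rows.size // snps_per_window
        if n_win == 0:
            logger.info(
                "local_pca: skipping %s (%d SNPs < one %d-SNP window)",
                chrom, rows.size, snps_per_window,
            )
            continue
        for w in range(n_win):
            sub = rows[w * snps_per_window : (w + 1) * snps_per_window]
            xc = _centered_window(gm, sub)
            cov = xc.T @ xc
            tr = np.trace(cov)
            degenerate = tr <= 0
            if not degenerate:
                cov = cov / tr
            ev, evec = np.linalg.eigh(cov)
            order = np.argsort(ev)[::-1][:k]
            recs.append(
                {
                    "chrom": chrom,
                    "start": int(pos[sub[0]]),
                    "end": int(pos[sub[-1]]),
                    "first_variant": int(sub[0]),
                    "last_variant": int(sub[-1]),
                    "degenerate": bool(degenerate),
                }
            )
            vals.append(np.clip(ev[order], 0.0, None) if not degenerate else np.zeros(k))
            vecs.append(evec[:, order] if not degenerate else np.zeros((gm.n_samples, k)))
    if not recs:
        raise ValueError("no chromosome had enough SNPs for a single window")
    return LocalPCAResult(
        windows=pd.DataFrame(recs),
        eigvals=np.asarray(vals),
        eigvecs=np.asarray(vecs),
        samples=list(gm.samples),
        snps_per_window=snps_per_window,
        k=k,
    )


def window_distance(result: LocalPCAResult, chrom: str | None = None) -> np.ndarray:
    """Frobenius distances between rank-k covariance reconstructions.

    For window i with eigenpairs (lambda_l, v_l), the reconstruction is
    ``R_i = sum_l lambda_l v_l v_l^T``; the distance is ||R_i - R_j||_F.
    Restricting to one chromosome mirrors per-chromosome processing.
    """
    idx = (
        result.chrom_indices(chrom)
        if chrom is not None
        else np.arange(len(result.windows))
    )
    n = result.eigvecs.shape[1]
    flat = np.empty((idx.size, n * n))
    for out_i, w in enumerate(idx):
        v = result.eigvecs[w]
        r = (v * result.eigvals[w]) @ v.T
        flat[out_i] = r.ravel()
    sq = np.sum(flat**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (flat @ flat.T)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.clip(d2, 0.0, None))


def mds_embed(distances: np.ndarray, n_axes: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Double-centers -D²/2 and takes the top eigenpairs; axes are ordered by
    eigenvalue and axes with non-positive eigenvalues are returned as zeros.
    A warning is issued when more than half the spectral mass is negative
    (strongly non-Euclidean input).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    ev, evec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(ev)[::-1]
    ev, evec = ev[order], evec[:, order]
    # trace(B) >= 0 caps negative mass at the positive mass, so the
    # non-Euclidean alarm compares the two directly
    neg_mass = float(np.abs(ev[ev < 0]).sum())
    pos_mass = float(ev[ev > 0].sum())
    if pos_mass > 0 and neg_mass > 0.5 * pos_mass:
        warnings.warn(
            "MDS input is strongly non-Euclidean "
            f"(negative spectral mass is {neg_mass / pos_mass:.0%} of positive)",
            stacklevel=2,
        )
    coords = np.zeros((n, n_axes))
    for ax in range(min(n_axes, n)):
        if ev[ax] > 0:
            coords[:, ax] = evec[:, ax] * np.sqrt(ev[ax])
    return coords


# ----------------------------------------------------------------------
# candidate regions from MDS outliers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateRegion:
    """A run of MDS-outlier windows on one chromosome (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    axis: int
    window_indices: tuple[int, ...]  # indices into the chromosome's windows


def _outlier_runs(outlier: np.ndarray, min_windows: int, max_gap: int) -> list[list[int]]:
    """Maximal runs of outlier indices allowing up to ``max_gap`` interior gaps."""
    idx = np.flatnonzero(outlier)
    runs: list[list[int]] = []
    for i in idx:
        if runs and i - runs[-1][-1] <= max_gap + 1:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    return [r for r in runs if len(r) >= min_windows]


def detect_candidate_regions(
    windows: pd.DataFrame,
    mds: np.ndarray,
    threshold_mads: float = 4.0,
    min_windows: int = 3,
    max_gap: int = 1,
) -> list[CandidateRegion]:
    """MDS-outlier regions on one chromosome.

    Per axis, windows whose score deviates from the median by more than
    ``threshold_mads`` x MAD (raw median absolute deviation) are outliers;
    maximal runs of at least ``min_windows`` outliers, tolerating
    ``max_gap`` interior non-outlier windows, become regions whose bounds
    come from the member windows' genomic extent.  Overlapping regions from
    different axes are not merged (each records its axis).
    """
    mds = np.atleast_2d(np.asarray(mds, dtype=float))
    if mds.shape[0] == 1 and len(windows) > 1:
        mds = mds.T
    regions: list[CandidateRegion] = []
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    for ax in range(mds.shape[1]):
        scores = mds[:, ax]
        med = float(np.median(scores))
        mad = float(np.median(np.abs(scores - med)))
        if mad == 0:
            outlier = scores != med
        else:
            outlier = np.abs(scores - med) > threshold_mads * mad
        for run in _outlier_runs(outlier, min_windows, max_gap):
            members = tuple(i for i in run if outlier[i])
            regions.append(
                CandidateRegion(
                    chrom=str(windows["chrom"].iloc[0]),
                    start=int(starts[members[0]]),
                    end=int(ends[members[-1]]),
                    axis=ax,
                    window_indices=members,
                )
            )
    return regions


# ----------------------------------------------------------------------
# inversion genotyping
# ----------------------------------------------------------------------

@dataclass
class InversionCall:
    """Three-cluster genotype call for a putative inversion region."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    success: bool
    reason: str
    genotypes: pd.Series | None  # per sample: 0, 1, 2 inverted copies
    pc1: pd.Series | None
    cluster_centers: np.ndarray | None  # ordered by PC1 center
    cluster_sizes: np.ndarray | None
    cluster_het: np.ndarray | None  # mean observed het per ordered cluster
    flipped: bool = False  # True when high-PC1 cluster is the non-inverted class

    @property
    def genotype_labels(self) -> pd.Series | None:
        if self.genotypes is None:
            return None
        return self.genotypes.map({0: "0/0", 1: "0/1", 2: "1/1"})


def _kmeans3_1d(x: np.ndarray) -> np.ndarray | None:
    """Exact 1-D 3-means: labels 0/1/2 ordered by center, or None on collapse.

    The optimal 1-D k-means partition is contiguous in sorted order, so the
    global optimum is found by enumerating the two breakpoints with prefix
    sums — deterministic, no initialization heuristics.  Returns None when
    the data cannot support three non-empty groups with distinct centers
    (fewer than three distinct values).
    """
    n = x.size
    if np.unique(x).size < 3:
        return None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    c2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def sse(lo: int, hi: int) -> float:  # [lo, hi)
        s = c1[hi] - c1[lo]
        return float(c2[hi] - c2[lo] - s * s / (hi - lo))

    best, best_ij = np.inf, None
    for i in range(1, n - 1):
        left = sse(0, i)
        for jj in range(i + 1, n):
            total = left + sse(i, jj) + sse(jj, n)
            if total < best:
                best, best_ij = total, (i, jj)
    i, jj = best_ij
    labels_sorted = np.zeros(n, dtype=int)
    labels_sorted[i:jj] = 1
    labels_sorted[jj:] = 2
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def genotype_inversion(
    gm: GenotypeMatrix, region: tuple[str, int, int]
) -> InversionCall:
    """Genotype samples for an inversion from region-wide PCA + PC1 clustering.

    ``region`` is (chrom, start, end), 1-based inclusive.  PC1 of the
    region's SNPs is split into three groups by exact (globally optimal,
    deterministic) 1-D 3-means; clusters are ordered by center.  The call
    succeeds iff three non-empty clusters form and the middle cluster has
    the maximal mean observed heterozygosity — the inversion-heterozygote
    signature.  Genotype orientation (which homozygote cluster is 1/1) is
    resolved by calling the minor homozygote class the inverted one.
    """
    chrom, start1, end1 = region
    rows = gm.variant_indices_in(chrom, start1 - 1, end1)
    if rows.size < 20:
        raise ValueError(
            f"region {chrom}:{start1}-{end1} has {rows.size} SNPs; >=20 required"
        )
    xc = _centered_window(gm, rows)
    cov = xc.T @ xc
    ev, evec = np.linalg.eigh(cov)
    pc1 = evec[:, -1] * np.sqrt(max(ev[-1], 0.0))
    fail = InversionCall(
        chrom=chrom, start=start1, end=end1, success=False,
        reason="", genotypes=None, pc1=pd.Series(pc1, index=gm.samples),
        cluster_centers=None, cluster_sizes=None, cluster_het=None,
    )
    ordered = _kmeans3_1d(pc1)  # 0 = low PC1, 1 = middle, 2 = high PC1
    if ordered is None:
        fail.reason = "fewer than 3 groups"
        return fail
    het = observed_heterozygosity(gm, region=(chrom, start1 - 1, end1)).to_numpy()
    cluster_het = np.array([np.nanmean(het[ordered == c]) for c in range(3)])
    sizes = np.bincount(ordered, minlength=3)
    centers = np.array([pc1[ordered == c].mean() for c in range(3)])
    if not (cluster_het[1] > cluster_het[0] and cluster_het[1] > cluster_het[2]):
        fail.reason = "middle cluster lacks maximal heterozygosity"
        fail.cluster_centers = centers
        fail.cluster_sizes = sizes
        fail.cluster_het = cluster_het
        return fail
    # orientation: the rarer homozygote class carries the inversion
    flipped = sizes[2] > sizes[0]
    geno = np.where(ordered == 1, 1, np.where(ordered == 2, 0 if flipped else 2,
                                              2 if flipped else 0))
    return InversionCall(
        chrom=chrom, start=start1, end=end1, success=True, reason="ok",
        genotypes=pd.Series(geno, index=gm.samples),
        pc1=pd.Series(pc1, index=gm.samples),
        cluster_centers=centers, cluster_sizes=sizes, cluster_het=cluster_het,
        flipped=bool(flipped),
    )


# ----------------------------------------------------------------------
# LD verification
# ----------------------------------------------------------------------

@dataclass
class LDVerification:
    """Within-region LD with and without inverted-arrangement carriers."""

    performed: bool
    reason: str
    mean_r2_all: float = float("nan")
    mean_r2_noncarrier: float = float("nan")
    background_all: float = float("nan")
    background_noncarrier: float = float("nan")
    passes: bool = False
    heatmap: np.ndarray | None = None  # upper = all samples, lower = non-carriers
    window_bounds: list[tuple[int, int]] = field(default_factory=list)


def _pair_mean_r2(
    g: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray, cols: np.ndarray,
    rng: np.random.Generator, max_pairs: int,
) -> float:
    """Mean composite r² over (sub-sampled) cross pairs of two SNP sets."""
    x = g[np.ix_(rows_a, cols)].astype(float)
    y = g[np.ix_(rows_b, cols)].astype(float)
    for m in (x, y):
        m[m == MISSING] = np.nan
        mu = np.nanmean(m, axis=1)
        mu = np.where(np.isfinite(mu), mu, 0.0)
        idx = np.where(np.isnan(m))
        m[idx] = mu[idx[0]]
    sx = x.std(axis=1)
    sy = y.std(axis=1)
    ax = np.flatnonzero(sx > 0)
    by = np.flatnonzero(sy > 0)
    if ax.size == 0 or by.size == 0:
        return float("nan")
    if ax.size * by.size > max_pairs:
        ia = rng.choice(ax, size=min(ax.size, int(np.sqrt(max_pairs)) + 1), replace=False)
        ib = rng.choice(by, size=min(by.size, int(np.sqrt(max_pairs)) + 1), replace=False)
    else:
        ia, ib = ax, by
    zx = (x[ia] - x[ia].mean(axis=1, keepdims=True)) / sx[ia][:, None]
    zy = (y[ib] - y[ib].mean(axis=1, keepdims=True)) / sy[ib][:, None]
    r = (zx @ zy.T) / cols.size
    return float(np.mean(r**2))


def verify_inversion_ld(
    gm: GenotypeMatrix,
    region: tuple[str, int, int],
    call: InversionCall,
    ld_window: int = 50_000,
    collapse_factor: float = 1.5,
    elevation_factor: float = 2.0,
    max_pairs: int = 10_000,
    n_background: int = 200,
    seed: int = 0,
) -> LDVerification:
    """Check that region LD is elevated and collapses without carriers.

    The region is tiled into ``ld_window``-bp windows; mean composite r²
    over all between-window SNP pairs is computed twice — for all samples
    and for non-carriers (called 0/0) only — and compared against a
    genome-background mean r² from distant SNP pairs computed for the same
    two sample sets.  Verification passes when the all-sample mean exceeds
    ``elevation_factor`` x background while the carrier-excluded mean is at
    most ``collapse_factor`` x its background.  The returned heatmap stores
    all-sample values in the upper triangle and non-carrier values in the
    lower (the two triangles of an LD heatmap figure).
    """
    if not call.success or call.genotypes is None:
        return LDVerification(performed=False, reason="inversion call failed")
    noncarrier_cols = np.flatnonzero(call.genotypes.to_numpy() == 0)
    if noncarrier_cols.size < 2:
        logger.info("verify_inversion_ld: <2 non-carriers, verification skipped")
        return LDVerification(performed=False, reason="fewer than 2 non-carriers")
    chrom, start1, end1 = region
    all_cols = np.arange(gm.n_samples)
    rng = np.random.default_rng(seed)

    bounds: list[tuple[int, int]] = []
    win_rows: list[np.ndarray] = []
    s = start1
    while s <= end1:
        e = min(s + ld_window - 1, end1)
        rows = gm.variant_indices_in(chrom, s - 1, e)
        if rows.size >= 2:
            bounds.append((s, e))
            win_rows.append(rows)
        s += ld_window
    if len(win_rows) < 2:
        return LDVerification(performed=False, reason="fewer than 2 LD windows in region")

    nw = len(win_rows)
    heat = np.full((nw, nw), np.nan)
    vals_all: list[float] = []
    vals_non: list[float] = []
    for i in range(nw):
        for jj in range(i + 1, nw):
            r_all = _pair_mean_r2(
                gm.genotypes, win_rows[i], win_rows[jj], all_cols, rng, max_pairs
            )
            r_non = _pair_mean_r2(
                gm.genotypes, win_rows[i], win_rows[jj], noncarrier_cols, rng, max_pairs
            )
            heat[i, jj] = r_all
            heat[jj, i] = r_non
            if np.isfinite(r_all):
                vals_all.append(r_all)
            if np.isfinite(r_non):
                vals_non.append(r_non)

    # background: distant pairs outside the region (other windows of the genome)
    region_rows = set(gm.variant_indices_in(chrom, start1 - 1, end1).tolist())
    outside = np.array(
        [i for i in range(gm.n_variants) if i not in region_rows], dtype=int
    )
    bg_all = bg_non = float("nan")
    if outside.size >= 4:
        picks = rng.choice(outside, size=min(outside.size, 2 * n_background), replace=False)
        half = picks.size // 2
        bg_all = _pair_mean_r2(gm.genotypes, picks[:half], picks[half:], all_cols, rng, max_pairs)
        bg_non = _pair_mean_r2(
            gm.genotypes, picks[:half], picks[half:], noncarrier_cols, rng, max_pairs
        )
    mean_all = float(np.mean(vals_all)) if vals_all else float("nan")
    mean_non = float(np.mean(vals_non)) if vals_non else float("nan")
    passes = (
        np.isfinite(mean_all)
        and np.isfinite(bg_all)
        and mean_all > elevation_factor * bg_all
        and np.isfinite(mean_non)
        and np.isfinite(bg_non)
        and mean_non <= collapse_factor * bg_non
    )
    return LDVerification(
        performed=True,
        reason="ok",
        mean_r2_all=mean_all,
        mean_r2_noncarrier=mean_non,
        background_all=bg_all,
        background_noncarrier=bg_non,
        passes=bool(passes),
        heatmap=heat,
        window_bounds=bounds,
    )


# ----------------------------------------------------------------------
# genome-wide driver
# ----------------------------------------------------------------------

def scan_genome(
    gm: GenotypeMatrix,
    snps_per_window: int = 100,
    k: int = 2,
    n_axes: int = 2,
    threshold_mads: float = 4.0,
    min_windows: int = 3,
    max_gap: int = 1,
    verify: bool = True,
    seed: int = 0,
) -> tuple[LocalPCAResult, dict[str, np.ndarray], list[CandidateRegion],
           list[tuple[CandidateRegion, InversionCall, LDVerification | None]]]:
    """Full structural-variant scan: local PCA -> MDS -> regions -> calls.

    Returns the eigen-summaries, per-chromosome MDS coordinates, all
    candidate regions, and per-region (region, call, verification) triples.
    """
    result = local_pca_windows(gm, snps_per_window=snps_per_window, k=k)
    mds_by_chrom: dict[str, np.ndarray] = {}
    regions: list[CandidateRegion] = []
    for chrom in dict.fromkeys(result.windows["chrom"]):
        idx = result.chrom_indices(chrom)
        if idx.size < 2:
            continue
        d = window_distance(result, chrom=chrom)
        mds = mds_embed(d, n_axes=n_axes)
        mds_by_chrom[chrom] = mds
        regions.extend(
            detect_candidate_regions(
                result.windows.iloc[idx].reset_index(drop=True),
                mds,
                threshold_mads=threshold_mads,
                min_windows=min_windows,
                max_gap=max_gap,
            )
        )
    calls: list[tuple[CandidateRegion, InversionCall, LDVerification | None]] = []
    seen: set[tuple[str, int, int]] = set()
    for reg in regions:
        key = (reg.chrom, reg.start, reg.end)
        if key in seen:
            continue
        seen.add(key)
        call = genotype_inversion(gm, key)
        ver = None
        if verify and call.success:
            ver = verify_inversion_ld(gm, key, call, seed=seed)
        calls.append((reg, call, ver))
    return result, mds_by_chrom, regions, calls
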