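"""Composite selective-sweep scan.

A sweep in the focal population leaves two joint signals in a window: loss
of diversity (high pi ratio, defined as pi_other / pi_focal so the top tail
means focal diversity loss) and elevated differentiation (high pairwise
F_ST).  Each chromosome is ranked independently; a window is a pair-scan
outlier when it sits in the top-q tail (default 5%) of *both* statistics.
Two pair scans against different reference populations are intersected so
that drift artifacts private to one comparison drop out, and surviving
windows are merged into maximal regions.

Within those regions, missense SNPs with overall maf above the threshold
are retained as outlier SNPs when their per-site F_ST against *both*
reference populations strictly exceeds the reference-vs-reference F_ST (the
conservative "both exceed" reading of differential differentiation; an
"either" mode is available).  Genes within ±1 bp of an outlier SNP are
candidates; optional term enrichment uses one-sided hypergeometric tests
with Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import GenotypeMatrix
from .stats import site_fst

logger = logging.getLogger(__name__)

__all__ = [
    "top_quantile_windows",
    "combine_pair_scans",
    "merge_windows",
    "select_outlier_snps",
    "map_genes_and_enrich",
    "SweepCandidateSet",
    "run_sweep_scan",
]


def top_quantile_windows(
    stats: pd.DataFrame,
    focal_pop: str,
    other_pop: str,
    q: float = 0.05,
) -> pd.Index:
    """Per-chromosome top-q F_ST ∩ top-q pi-ratio windows for one pair.

    ``stats`` is a window_stats_table frame carrying ``pi_<pop>`` columns
    and the pair's ``fst_<a>__<b>`` column (either orientation).  The pi
    ratio is pi_other / pi_focal.  Within each chromosome the quantile cut
    is the value at rank ceil(q * W) from the top (ties included), with W
    counting windows that have both statistics.  Returns the index labels
    of outlier windows.
    """
    fst_col = f"fst_{focal_pop}__{other_pop}"
    if fst_col not in stats.columns:
        fst_col = f"fst_{other_pop}__{focal_pop}"
        if fst_col not in stats.columns:
            raise ValueError(f"no F_ST column for pair ({focal_pop}, {other_pop})")
    pi_f = stats[f"pi_{focal_pop}"].to_numpy(dtype=float)
    pi_o = stats[f"pi_{other_pop}"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pi_f > 0, pi_o / pi_f, np.nan)
    fst = stats[fst_col].to_numpy(dtype=float)
    usable = np.isfinite(ratio) & np.isfinite(fst)
    selected: list = []
    for chrom, grp in stats.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        mask = usable[stats.index.get_indexer(rows)]
        rows = rows[mask]
        w = rows.size
        if w == 0:
            continue
        if w < 1.0 / q:
            logger.warning(
                "top_quantile_windows: %s has only %d usable windows; "
                "top-%g%% quantile is unstable", chrom, w, 100 * q,
            )
        k = math.ceil(q * w)
        pos = stats.index.get_indexer(rows)
        fst_cut = np.sort(fst[pos])[::-1][k - 1]
        ratio_cut = np.sort(ratio[pos])[::-1][k - 1]
        hit = (fst[pos] >= fst_cut) & (ratio[pos] >= ratio_cut)
        selected.extend(rows[hit].tolist())
    return pd.Index(selected)


def combine_pair_scans(scan_a: pd.Index, scan_b: pd.Index) -> pd.Index:
    """Window-wise intersection of two pair scans sharing one window grid."""
    return scan_a.intersection(scan_b)


def merge_windows(stats: pd.DataFrame, window_index: pd.Index) -> pd.DataFrame:
    """Merge overlapping/adjacent outlier windows into maximal regions.

    Returns a frame with chrom, start, end (1-based inclusive) and
    ``n_windows`` per merged region; robust to the sliding-window grid.
    """
    if len(window_index) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows"])
    sub = stats.loc[window_index, ["chrom", "start", "end"]].sort_values(
        ["chrom", "start"]
    )
    regions: list[dict] = []
    cur: dict | None = None
    for chrom, start, end in sub.itertuples(index=False):
        if cur is not None and chrom == cur["chrom"] and start <= cur["end"] + 1:
            cur["end"] = max(cur["end"], end)
            cur["n_windows"] += 1
        else:
            if cur is not None:
                regions.append(cur)
            cur = {"chrom": chrom, "start": int(start), "end": int(end), "n_windows": 1}
    regions.append(cur)
    return pd.DataFrame(regions)


def select_outlier_snps(
    gm: GenotypeMatrix,
    regions: pd.DataFrame,
    focal_pop: str,
    refuge_pops: tuple[str, str],
    maf_min: float = 0.05,
    mode: str = "both",
) -> pd.DataFrame:
    """Missense outlier SNPs inside combined sweep regions.

    A SNP is retained when it (i) lies inside a region, (ii) is flagged
    missense, (iii) has overall maf strictly above ``maf_min``, and (iv)
    shows differential differentiation: per-site F_ST(focal, refuge) exceeds
    F_ST(refuge_1, refuge_2) for *both* refuges (``mode="both"``, default)
    or for at least one (``mode="either"``).
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    if not bool(gm.variants["missense"].any()):
        raise ValueError(
            "no missense annotations present; provide an annotated VCF or a "
            "sidecar missense TSV when reading the VCF"
        )
    r1, r2 = refuge_pops
    in_region = np.zeros(gm.n_variants, dtype=bool)
    chrom_col = gm.variants["chrom"].to_numpy()
    pos_col = gm.variants["pos"].to_numpy()
    for chrom, start, end in regions[["chrom", "start", "end"]].itertuples(index=False):
        in_region |= (chrom_col == chrom) & (pos_col >= start) & (pos_col <= end)
    j, n = gm.allele_counts(np.arange(gm.n_samples))
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(n > 0, j / np.maximum(n, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)
    cand = in_region & gm.variants["missense"].to_numpy() & (maf > maf_min)
    if not cand.any():
        return pd.DataFrame(
            columns=["chrom", "pos", "maf", "fst_focal_r1", "fst_focal_r2", "fst_r1_r2"]
        )
    fst_f1 = site_fst(gm, focal_pop, r1)
    fst_f2 = site_fst(gm, focal_pop, r2)
    fst_rr = site_fst(gm, r1, r2)
    with np.errstate(invalid="ignore"):
        if mode == "both":
            diff = (fst_f1 > fst_rr) & (fst_f2 > fst_rr)
        else:
            diff = (fst_f1 > fst_rr) | (fst_f2 > fst_rr)
    keep = cand & np.where(np.isnan(diff.astype(float)), False, diff)
    out = pd.DataFrame(
        {
            "chrom": chrom_col[keep],
            "pos": pos_col[keep],
            "maf": maf[keep],
            "fst_focal_r1": fst_f1[keep],
            "fst_focal_r2": fst_f2[keep],
            "fst_r1_r2": fst_rr[keep],
        }
    )
    return out.reset_index(drop=True)


def map_genes_and_enrich(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    term_map: Mapping[str, Sequence[str]] | None = None,
    alpha: float = 0.05,
    slop: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Candidate genes near outlier SNPs, with optional term enrichment.

    A gene (internal 0-based half-open interval) is a candidate when its
    interval expanded by ``slop`` bp on each side contains an outlier SNP.
    With a ``term_map`` (gene -> terms), each term gets a one-sided
    hypergeometric over-representation p-value (universe = genes in the
    map; draws = candidate genes in the map), BH-adjusted, significant at
    adjusted p < ``alpha``.
    """
    hits: list[dict] = []
    if len(snps):
        for chrom, grp in genes.groupby("chrom", sort=False):
            spos0 = snps.loc[snps["chrom"] == chrom, "pos"].to_numpy() - 1
            if spos0.size == 0:
                continue
            spos0 = np.sort(spos0)
            for start, end, gene_id in grp[["start", "end", "gene_id"]].itertuples(
                index=False
            ):
                lo = np.searchsorted(spos0, start - slop, side="left")
                hi = np.searchsorted(spos0, end + slop, side="left")
                if hi > lo:
                    inside = spos0[lo:hi]
                    dist = int(
                        np.min(np.maximum(0, np.maximum(start - inside, inside - (end - 1))))
                    )
                    hits.append(
                        {
                            "gene_id": gene_id,
                            "chrom": chrom,
                            "start": int(start),
                            "end": int(end),
                            "n_snps": int(hi - lo),
                            "distance": dist,
                        }
                    )
    gene_hits = pd.DataFrame(
        hits, columns=["gene_id", "chrom", "start", "end", "n_snps", "distance"]
    )
    if term_map is None:
        return gene_hits, None
    universe = list(term_map)
    candidates = [g for g in gene_hits["gene_id"] if g in term_map]
    terms: dict[str, set[str]] = {}
    for gene, gene_terms in term_map.items():
        for t in gene_terms:
            terms.setdefault(t, set()).add(gene)
    big_n = len(universe)
    n_draw = len(candidates)
    rows = []
    for term, members in sorted(terms.items()):
        k = len(members.intersection(candidates))
        big_k = len(members)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n_draw)) if n_draw else 1.0
        rows.append(
            {"term": term, "overlap": k, "term_size": big_k,
             "n_candidates": n_draw, "universe": big_n, "p": p}
        )
    enrich = pd.DataFrame(rows)
    if len(enrich):
        reject, p_adj, _, _ = multipletests(enrich["p"], alpha=alpha, method="fdr_bh")
        enrich["p_adj"] = p_adj
        enrich["significant"] = enrich["p_adj"] < alpha
    return gene_hits, enrich


@dataclass
class SweepCandidateSet:
    """Everything the composite scan produced for one focal population."""

    focal_pop: str
    reference_pops: tuple[str, str]
    pair_outliers: dict[str, pd.Index]
    combined_windows: pd.Index
    regions: pd.DataFrame
    outlier_snps: pd.DataFrame
    candidate_genes: pd.DataFrame
    enrichment: pd.DataFrame | None = None


def run_sweep_scan(
    gm: GenotypeMatrix,
    stats: pd.DataFrame,
    focal_pop: str,
    reference_pops: tuple[str, str],
    genes: pd.DataFrame | None = None,
    term_map: Mapping[str, Sequence[str]] | None = None,
    q: float = 0.05,
    maf_min: float = 0.05,
    mode: str = "both",
) -> SweepCandidateSet:
    """Composite scan driver: pair scans -> intersection -> SNPs -> genes."""
    r1, r2 = reference_pops
    scan1 = top_quantile_windows(stats, focal_pop, r1, q=q)
    scan2 = top_quantile_windows(stats, focal_pop, r2, q=q)
    combined = combine_pair_scans(scan1, scan2)
    regions = merge_windows(stats, combined)
    snps = select_outlier_snps(
        gm, regions, focal_pop, reference_pops, maf_min=maf_min, mode=mode
    )
    if genes is not None:
        gene_hits, enrich = map_genes_and_enrich(snps, genes, term_map=term_map)
    else:
        gene_hits = pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "n_snps", "distance"]
        )
        enrich = None
    return SweepCandidateSet(
        focal_pop=focal_pop,
        reference_pops=reference_pops,
        pair_outliers={f"{focal_pop}__{r1}": scan1, f"{focal_pop}__{r2}": scan2},
        combined_windows=combined,
        regions=regions,
        outlier_snps=snps,
        candidate_genes=gene_hits,
        enrichment=enrich,
    )
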