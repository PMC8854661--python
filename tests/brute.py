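"""Independent brute-force oracles used only by the tests.

Each function re-derives a statistic from first principles (explicit loops
over sites, samples and allele pairs) without sharing code with the package
implementations it checks.
"""

import math
from itertools import combinations

import numpy as np

MISSING = -1


def alleles_of(code):
    return {0: [0, 0], 1: [0, 1], 2: [1, 1]}[code]


def brute_site_pi(genotype_column):
    """Mean pairwise difference among called alleles at one site."""
    alleles = []
    for g in genotype_column:
        if g != MISSING:
            alleles.extend(alleles_of(g))
    if len(alleles) < 2:
        return 0.0
    diffs = sum(1 for x, y in combinations(alleles, 2) if x != y)
    return diffs / math.comb(len(alleles), 2)


def brute_window_pi(genotypes, window_length):
    """Sum of per-site pairwise diversity over a window / window length."""
    return sum(brute_site_pi(col) for col in genotypes) / window_length


def brute_wc_site(col_a, col_b):
    """Weir–Cockerham (1984) a, b, c for one site, two populations (r=2)."""
    def summarize(col):
        called = [g for g in col if g != MISSING]
        n = len(called)
        if n == 0:
            return None
        p = sum(called) / (2 * n)
        h = sum(1 for g in called if g == 1) / n
        return n, p, h
    sa, sb = summarize(col_a), summarize(col_b)
    if sa is None or sb is None or sa[0] + sb[0] <= 2:
        return None
    (n1, p1, h1), (n2, p2, h2) = sa, sb
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    return a, b, c


def brute_window_fst(genotypes_a, genotypes_b):
    """Weighted window F_ST: explicit per-site component sums."""
    num = den = 0.0
    for col_a, col_b in zip(genotypes_a, genotypes_b):
        comp = brute_wc_site(col_a, col_b)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def brute_hudson_fst(j1, n1, j2, n2):
    """Hudson estimator (ratio of sums) from per-site allele counts."""
    num = den = 0.0
    for a1, m1, a2, m2 in zip(j1, n1, j2, n2):
        if m1 < 2 or m2 < 2:
            continue
        p1, p2 = a1 / m1, a2 / m2
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (m1 - 1) - p2 * (1 - p2) / (m2 - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den != 0 else float("nan")


def brute_bh(pvalues):
    """Benjamini–Hochberg step-up adjusted p-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
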