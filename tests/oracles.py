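"""Brute-force reference implementations used only by the tests.

These deliberately use explicit loops, exact rational arithmetic and
exhaustive enumeration so they stay independent of the vectorized
library code they check.
"""

from fractions import Fraction
from math import comb

import numpy as np

MISSING = -1


# -- call rates --------------------------------------------------------------


def locus_call_rates(dosages):
    n, m = dosages.shape
    out = []
    for j in range(m):
        called = sum(1 for i in range(n) if dosages[i][j] != MISSING)
        out.append(called / n)
    return out


def sample_call_rates(dosages):
    n, m = dosages.shape
    out = []
    for i in range(n):
        called = sum(1 for j in range(m) if dosages[i][j] != MISSING)
        out.append(called / m)
    return out


# -- allele frequencies and heterozygosity -----------------------------------


def mafs(dosages):
    n, m = dosages.shape
    out = []
    for j in range(m):
        b = 0
        called = 0
        for i in range(n):
            if dosages[i][j] != MISSING:
                b += dosages[i][j]
                called += 1
        if called == 0:
            out.append(float("nan"))
        else:
            p = b / (2 * called)
            out.append(min(p, 1 - p))
    return out


def observed_het(dosages):
    n, m = dosages.shape
    per_locus = []
    for j in range(m):
        het = sum(1 for i in range(n) if dosages[i][j] == 1)
        called = sum(1 for i in range(n) if dosages[i][j] != MISSING)
        if called:
            per_locus.append(het / called)
    return sum(per_locus) / len(per_locus)


def expected_het(dosages):
    n, m = dosages.shape
    per_locus = []
    for j in range(m):
        b = sum(dosages[i][j] for i in range(n) if dosages[i][j] != MISSING)
        nc = sum(1 for i in range(n) if dosages[i][j] != MISSING)
        if nc == 0:
            continue
        p = b / (2 * nc)
        per_locus.append((2 * nc / (2 * nc - 1)) * (1 - p * p - (1 - p) * (1 - p)))
    return sum(per_locus) / len(per_locus)


# -- HWE exact test ----------------------------------------------------------


def hwe_exact(n_aa, n_ab, n_bb):
    """Exact conditional HWE p-value via full enumeration with Fractions."""
    n = n_aa + n_ab + n_bb
    nb = 2 * n_bb + n_ab
    na = 2 * n - nb
    rare = min(na, nb)
    if rare == 0:
        return Fraction(1)

    def weight(het):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        if hom_rare < 0 or hom_common < 0:
            return Fraction(0)
        # multinomial genotype configurations x 2^het haplotype phasings
        return Fraction(
            comb(n, het) * comb(n - het, hom_rare) * (2**het), 1
        )

    hets = [h for h in range(rare + 1) if (rare - h) % 2 == 0]
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs)


# -- LD r² -------------------------------------------------------------------


def r_squared(x, y):
    """Pairwise-complete squared Pearson correlation; None if undefined."""
    pairs = [(a, b) for a, b in zip(x, y) if a != MISSING and b != MISSING]
    if len(pairs) < 2:
        return None
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    nx = len(xs)
    mx = sum(xs) / nx
    my = sum(ys) / nx
    vx = sum((a - mx) ** 2 for a in xs) / nx
    vy = sum((b - my) ** 2 for b in ys) / nx
    if vx == 0 or vy == 0:
        return None
    cov = sum((a - mx) * (b - my) for a, b in pairs) / nx
    return (cov * cov) / (vx * vy)


# -- VanRaden G and IBS ------------------------------------------------------


def vanraden_g(dosages):
    """Direct double-loop G with observed frequencies and mean imputation."""
    n, m = dosages.shape
    ps = []
    for j in range(m):
        b = sum(dosages[i][j] for i in range(n) if dosages[i][j] != MISSING)
        nc = sum(1 for i in range(n) if dosages[i][j] != MISSING)
        ps.append(b / (2 * nc) if nc else None)
    denom = 2 * sum(p * (1 - p) for p in ps if p is not None)
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            acc = 0.0
            for j in range(m):
                if ps[j] is None:
                    continue
                zi = 0.0 if dosages[i][j] == MISSING else dosages[i][j] - 2 * ps[j]
                zk = 0.0 if dosages[k][j] == MISSING else dosages[k][j] - 2 * ps[j]
                acc += zi * zk
            G[i, k] = acc / denom
    return G


def ibs_distances(dosages):
    n, m = dosages.shape
    D = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            shared = 0
            total = 0
            for j in range(m):
                if dosages[i][j] != MISSING and dosages[k][j] != MISSING:
                    shared += 2 - abs(dosages[i][j] - dosages[k][j])
                    total += 2
            D[i, k] = 1 - shared / total if total else float("nan")
    return D


# -- ROH ---------------------------------------------------------------------


def roh_segments(geno, pos, params):
    """Exhaustive sliding-window ROH detection for one sample/chromosome.

    Window eligibility is recomputed per SNP by enumerating every
    window; runs and filters use plain loops.
    """
    m = len(geno)
    W = params.window_snps
    eligible = [False] * m
    for i in range(m):
        hom = 0
        covering = 0
        for w in range(0, m - W + 1):
            if w <= i <= w + W - 1:
                covering += 1
                window = geno[w : w + W]
                n_het = sum(1 for g in window if g == 1)
                n_mis = sum(1 for g in window if g == MISSING)
                if n_het <= params.window_max_het and n_mis <= params.window_max_missing:
                    hom += 1
        if covering:
            eligible[i] = hom / covering >= params.min_hit_proportion

    # candidate runs of eligible SNPs, split at oversized gaps
    runs = []
    start = None
    for k in range(m):
        if eligible[k]:
            if start is None:
                start = k
            gap_next = k + 1 < m and (pos[k + 1] - pos[k]) > params.max_gap_kb * 1000
            if k == m - 1 or not eligible[k + 1] or gap_next:
                runs.append((start, k))
                start = None
    out = []
    for s, e in runs:
        n_snps = e - s + 1
        length_kb = (pos[e] - pos[s] + 1) / 1000
        if (
            n_snps > params.min_snps_per_segment
            and length_kb > params.min_length_kb
            and length_kb / n_snps <= params.min_density_kb_per_snp
        ):
            out.append((int(pos[s]), int(pos[e]), n_snps))
    return out
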