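"""Independent brute-force oracles used by the test suite.

These are deliberately naive, loop-based transcriptions of the textbook
definitions (Weir & Cockerham 1984 variance components, mean pairwise
differences, allele tallies).  They share no code with the package
implementations they check.
"""

from __future__ import annotations

from itertools import combinations

MISSING = -1


def wc84_site(genos_a: list[int], genos_b: list[int]):
    """Literal two-population WC84 variance components for one site.

    ``genos_*`` are diploid alt-dosage codes; missing (-1) entries are
    dropped.  Returns (a, b, c) or None when either population has fewer
    than two called individuals.
    """
    ga = [g for g in genos_a if g != MISSING]
    gb = [g for g in genos_b if g != MISSING]
    if len(ga) < 2 or len(gb) < 2:
        return None
    r = 2
    n1, n2 = float(len(ga)), float(len(gb))
    p1 = sum(ga) / (2 * n1)
    p2 = sum(gb) / (2 * n2)
    h1 = sum(1 for g in ga if g == 1) / n1
    h2 = sum(1 for g in gb if g == 1) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def brute_allele_tally(genos: list[int]):
    """(n alleles, alt frequency) by explicit counting."""
    called = [g for g in genos if g != MISSING]
    n = 2 * len(called)
    if n == 0:
        return 0, float("nan")
    alt = sum(called)
    return n, alt / n


def brute_pi_site(genos: list[int]) -> float:
    """Mean pairwise difference among the alleles at one site.

    Expands each diploid dosage into explicit allele lists and counts
    differing pairs over all allele pairs.
    """
    alleles: list[int] = []
    for g in genos:
        if g == MISSING:
            continue
        alleles += [1] * g + [0] * (2 - g)
    n = len(alleles)
    if n < 2:
        return 0.0
    diffs = sum(1 for x, y in combinations(alleles, 2) if x != y)
    return diffs / (n * (n - 1) / 2)


def brute_pi_window(site_genos: list[list[int]], window_bp: int) -> float:
    """Per-bp nucleotide diversity of one window by pairwise counting."""
    return sum(brute_pi_site(g) for g in site_genos) / window_bp
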