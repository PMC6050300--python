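"""Allele frequencies, Weir–Cockerham F_ST and windowed diversity statistics.

Per-site F_ST follows Weir & Cockerham (1984) with observed heterozygote
counts; the two-population variance components (a, b, c) are kept so that
windowed F_ST can be formed as a ratio of sums (sum a / sum (a+b+c)), the
"weighted" estimator VCFtools reports for windows.  Per-site values are
left unclamped and may be negative.

Nucleotide diversity pi uses the unbiased per-site heterozygosity
2*p*(1-p) * n/(n-1) (identical to the mean pairwise difference among the
n sampled alleles) summed over SNPs and divided by the full window length
in bp, so values are per-base and comparable across windows regardless of
SNP density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

PopLabel = "str | Sequence[str]"


def allele_frequencies(
    gm: GenotypeMatrix, pm: PopulationMap, pop: str | Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (n, p) for one population.

    n is the number of non-missing *alleles* (2 x called samples) and p
    the alt-allele frequency among them (NaN where n == 0).
    """
    g = gm.genotypes[:, pm.indices(gm, pop)]
    miss = g == MISSING
    n = 2 * (~miss).sum(axis=1)
    ac = np.where(miss, 0, g).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, ac / n, np.nan)
    return n.astype(np.int64), p


def _freq_het(gm: GenotypeMatrix, idx: np.ndarray):
    """(called sample count, alt freq, observed het fraction) per site."""
    g = gm.genotypes[:, idx]
    miss = g == MISSING
    cnt = (~miss).sum(axis=1)
    ac = np.where(miss, 0, g).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(cnt > 0, ac / (2.0 * cnt), np.nan)
        h = np.where(cnt > 0, (g == 1).sum(axis=1) / cnt, np.nan)
    return cnt, p, h


def wc84_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
):
    """Two-population Weir–Cockerham (1984) variance components.

    Arguments are per-site sample sizes in *individuals*, alt-allele
    frequencies and observed heterozygote fractions.  Returns arrays
    (a, b, c): among-population, among-individual-within-population and
    within-individual components.  Sites with fewer than 2 called
    individuals in either population come out as NaN.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    # at opposite fixation b is algebraically zero; clear the floating
    # residue so that F_ST = a/(a+b+c) comes out exactly 1
    opp = (((p1 == 0.0) & (p2 == 1.0)) | ((p1 == 1.0) & (p2 == 0.0))) \
        & (h1 == 0.0) & (h2 == 0.0)
    b[opp] = 0.0
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(p1) | ~np.isfinite(p2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


@dataclass
class SiteStats:
    """Per-site two-population summaries and WC84 components."""

    chrom: np.ndarray
    pos: np.ndarray
    n_a: np.ndarray          # allele counts (2 x called) per pop
    p_a: np.ndarray
    n_b: np.ndarray
    p_b: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    fst: np.ndarray          # a/(a+b+c); NaN where undefined
    defined: np.ndarray      # bool: components computable and denominator != 0


def site_fst(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop_a: str | Sequence[str],
    pop_b: str | Sequence[str],
) -> SiteStats:
    """Per-site Weir–Cockerham F_ST between two populations.

    F_ST is a/(a+b+c) and is flagged undefined where either population has
    fewer than two called samples or where the site is monomorphic across
    the pair (zero denominator).  Values are not clamped and can be
    slightly negative.  Swapping the populations leaves F_ST unchanged.
    """
    ia = pm.indices(gm, pop_a)
    ib = pm.indices(gm, pop_b)
    cnt_a, p_a, h_a = _freq_het(gm, ia)
    cnt_b, p_b, h_b = _freq_het(gm, ib)
    a, b, c = wc84_components(cnt_a, p_a, h_a, cnt_b, p_b, h_b)
    denom = a + b + c
    defined = np.isfinite(denom) & (denom != 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(defined, a / denom, np.nan)
    return SiteStats(
        chrom=gm.chrom, pos=gm.pos,
        n_a=2 * cnt_a, p_a=p_a, n_b=2 * cnt_b, p_b=p_b,
        a=a, b=b, c=c, fst=fst, defined=defined,
    )


def genome_fst(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop_a: str | Sequence[str],
    pop_b: str | Sequence[str],
    snps_only: bool = True,
) -> float:
    """Genome-wide weighted (ratio-of-sums) Weir–Cockerham F_ST."""
    sub = gm.take(gm.is_snp) if snps_only else gm
    st = site_fst(sub, pm, pop_a, pop_b)
    num = np.nansum(np.where(st.defined, st.a, 0.0))
    den = np.nansum(np.where(st.defined, st.a + st.b + st.c, 0.0))
    return float(num / den) if den != 0 else float("nan")


def site_pi_terms(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity n/(n-1) * 2p(1-p) (n = alleles).

    Equals the mean number of pairwise differences among the n alleles at
    the site; zero contribution where n < 2.
    """
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return np.where((n >= 2) & np.isfinite(p), t, 0.0)


@dataclass(frozen=True)
class ScanConfig:
    """Window/scan tuning knobs.

    Defaults reproduce a 40-kb window, 10-kb step autosomal scan with a
    one-sided Z-test at P < 0.005 applied to both F_ST and the pi
    ln-ratio, windows with fewer than 40 SNPs dropped from
    standardization, and candidate regions closer than 200 kb merged.
    The fixation thresholds (derived allele frequency > 0.95 fixed;
    < 0.5 standing in the wild population; >= 5 nearly fixed standing
    variants per region) drive the fixed/standing-variation scans.
    """

    window: int = 40_000
    step: int = 10_000
    min_snps: int = 40
    alpha: float = 0.005
    merge_gap: int = 200_000
    fixed_daf: float = 0.95
    standing_max_af: float = 0.5
    min_fixed_sites_per_cdr: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if not 0.5 <= self.fixed_daf <= 1.0:
            raise ValueError("fixed_daf must be in [0.5, 1]")
        if self.step > self.window:
            raise ValueError("step must be <= window")


def window_stats(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pair: tuple,
    cfg: ScanConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window F_ST, per-population pi and pi ln-ratio.

    ``pair`` is (ancestral-stage population, derived-stage population);
    the ln-ratio is ln(pi_ancestral / pi_derived) so that diversity loss
    in the derived population yields large positive values.  Windows tile
    each chromosome from position 1 at ``cfg.step``; the last, possibly
    partial, window is kept and flagged.  Only SNP records enter the
    statistics (indels are excluded from scans).

    Returns a DataFrame with one row per window: chrom, start, end,
    n_snps, fst, pi_a, pi_b, pi_ln_ratio and a ``flag`` column
    ('ok', 'low_snps', 'partial', 'inf_ratio', combinations joined by
    ',').  pi_b == 0 with pi_a > 0 produces +inf and the 'inf_ratio'
    flag; such windows are excluded from Z standardization but remain
    eligible as sweep outliers.
    """
    cfg = cfg or ScanConfig()
    pop_anc, pop_der = pair
    snp_mask = gm.is_snp
    sub = gm.take(snp_mask)
    ia = pm.indices(sub, pop_anc)
    ib = pm.indices(sub, pop_der)
    cnt_a, p_a, h_a = _freq_het(sub, ia)
    cnt_b, p_b, h_b = _freq_het(sub, ib)
    a, b, c = wc84_components(cnt_a, p_a, h_a, cnt_b, p_b, h_b)
    denom = a + b + c
    comp_ok = np.isfinite(denom)
    pi_a_site = site_pi_terms(2 * cnt_a, p_a)
    pi_b_site = site_pi_terms(2 * cnt_b, p_b)

    rows = []
    n_per = max(1, cfg.window // cfg.step)
    for chrom in dict.fromkeys(gm.chrom.astype(str)):
        m = sub.chrom == chrom
        pos = sub.pos[m]
        clen = int(chrom_lengths[chrom]) if chrom_lengths and chrom in chrom_lengths \
            else int(gm.pos[gm.chrom == chrom].max())
        n_win = max(1, math.ceil(max(clen - cfg.window, 0) / cfg.step) + 1)
        num = np.zeros(n_win)
        den = np.zeros(n_win)
        cnt = np.zeros(n_win, dtype=int)
        pa_sum = np.zeros(n_win)
        pb_sum = np.zeros(n_win)
        j_hi = (pos - 1) // cfg.step  # last window index whose start <= pos
        av = np.where(comp_ok[m], a[m], 0.0)
        dv = np.where(comp_ok[m], denom[m], 0.0)
        for off in range(n_per):
            j = j_hi - off
            ok = (j >= 0) & (j < n_win) & (pos <= j * cfg.step + cfg.window)
            jj = j[ok]
            np.add.at(cnt, jj, 1)
            np.add.at(num, jj, av[ok])
            np.add.at(den, jj, dv[ok])
            np.add.at(pa_sum, jj, pi_a_site[m][ok])
            np.add.at(pb_sum, jj, pi_b_site[m][ok])
        starts = 1 + cfg.step * np.arange(n_win)
        ends = starts + cfg.window - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(den != 0, num / den, np.nan)
            pi_a_win = pa_sum / cfg.window
            pi_b_win = pb_sum / cfg.window
            ratio = np.log(pi_a_win / pi_b_win)
        for k in range(n_win):
            flags = []
            if cnt[k] < cfg.min_snps:
                flags.append("low_snps")
            if ends[k] > clen:
                flags.append("partial")
            if pi_b_win[k] == 0 and pi_a_win[k] > 0:
                flags.append("inf_ratio")
            rows.append(
                (chrom, int(starts[k]), int(ends[k]), int(cnt[k]),
                 fst[k], pi_a_win[k], pi_b_win[k], ratio[k],
                 ",".join(flags) if flags else "ok")
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_snps", "fst",
                 "pi_a", "pi_b", "pi_ln_ratio", "flag"],
    )
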