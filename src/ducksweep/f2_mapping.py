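"""Wild x domestic F2 fine-mapping machinery.

Covers the post-GWAS steps used to localize a major-effect locus inside a
sweep region with a segregating intercross: diagnostic-marker selection
from founder allele-frequency contrast, recombination-breakpoint
haplotype classification of F2 genotype tracks, covariate adjustment of
phenotypes with a general linear model, genotype-class effect and
variance-explained estimation by one-way ANOVA, Mendelian segregation
chi-square tests, read-support genotyping of a structural variant, and
relative expression by the 2^-ddCt method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap
from .popgen_stats import allele_frequencies

__all__ = [
    "DiagnosticMarker", "HaplotypeCall", "AssocResult",
    "select_diagnostic_markers", "classify_haplotypes", "adjust_phenotypes",
    "genotype_association", "segregation_chi2", "genotype_sv",
    "genotype_sv_table", "relative_expression_ddct",
]

_CODE_CHARS = {0: "M", 1: "H", 2: "P"}  # wild hom / het / domestic hom


@dataclass
class DiagnosticMarker:
    """A founder-contrast SNP used to trace parental origin in the cross."""

    chrom: str
    pos: int
    delta_af: float
    elite_allele: str  # "ref" or "alt": allele more frequent in elite founders


@dataclass
class HaplotypeCall:
    """One F2 individual's smoothed genotype track over the marker panel.

    ``segments`` is a list of (code, first_marker_idx, last_marker_idx)
    with codes in {0: M, 1: H, 2: P}; ``breakpoints`` holds the 0-based
    index of the last marker of each segment but the final one (i.e. the
    breakpoint lies in the interval (marker i, marker i+1)).
    """

    individual: str
    raw_codes: np.ndarray
    smoothed: np.ndarray
    segments: list[tuple[int, int, int]]
    breakpoints: list[int]
    haplotype_class: str | None = None
    classified: bool = True

    @property
    def signature(self) -> str:
        return "|".join(_CODE_CHARS[c] for c, _, _ in self.segments)


@dataclass
class AssocResult:
    """Genotype-class means, effect size and variance explained for a trait."""

    trait: str
    group_means: dict
    group_sizes: dict
    effect_pct: float
    variance_explained: float
    anova_p: float | None


def select_diagnostic_markers(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    wild_pop: str | Sequence[str],
    elite_pop: str | Sequence[str],
    min_delta: float = 0.6,
) -> list[DiagnosticMarker]:
    """Markers whose founder allele-frequency contrast exceeds ``min_delta``.

    |dAF| = |p_elite - p_wild| must be strictly greater than the
    threshold; the allele more frequent in the elite founders is recorded
    so F2 genotypes can be recoded as elite-allele dosage.
    """
    _, p_w = allele_frequencies(gm, pm, wild_pop)
    _, p_e = allele_frequencies(gm, pm, elite_pop)
    with np.errstate(invalid="ignore"):
        delta = np.abs(p_e - p_w)
        hit = delta > min_delta
    hit &= np.isfinite(delta)
    markers = [
        DiagnosticMarker(
            chrom=str(gm.chrom[i]), pos=int(gm.pos[i]),
            delta_af=float(delta[i]),
            elite_allele="alt" if p_e[i] > p_w[i] else "ref",
        )
        for i in np.flatnonzero(hit)
    ]
    if not markers:
        warnings.warn("no markers pass the dAF threshold", stacklevel=2)
    return sorted(markers, key=lambda m: (m.chrom, m.pos))


def _majority_smooth(codes: np.ndarray, k: int) -> np.ndarray:
    """Sliding-majority smoothing over k markers, ignoring missing.

    Edge windows are clipped.  Ties keep the previous smoothed value when
    it is among the tied codes, else the site's own raw code, else the
    lowest tied code; all-missing windows carry the previous value.
    """
    n = codes.size
    half = k // 2
    out = np.empty(n, dtype=np.int8)
    prev = -1
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win = codes[lo:hi]
        counts = np.array([(win == c).sum() for c in (0, 1, 2)])
        top = counts.max()
        if top == 0:
            out[i] = prev if prev >= 0 else MISSING
            continue
        tied = [c for c in (0, 1, 2) if counts[c] == top]
        if len(tied) == 1:
            out[i] = tied[0]
        elif prev in tied:
            out[i] = prev
        elif codes[i] in tied:
            out[i] = codes[i]
        else:
            out[i] = tied[0]
        prev = out[i]
    # leading all-missing stretch: backfill with first resolved code
    if (out == MISSING).any():
        resolved = np.flatnonzero(out != MISSING)
        if resolved.size == 0:
            return out
        out[: resolved[0]] = out[resolved[0]]
    return out


def _segments_from_codes(sm: np.ndarray, min_segment: int) -> list[tuple[int, int, int]]:
    """Run-length segments with runs shorter than min_segment absorbed
    into the longer flanking neighbour (ties go left)."""
    runs: list[list[int]] = []  # [code, start, end]
    for i, c in enumerate(sm):
        if runs and runs[-1][0] == c:
            runs[-1][2] = i
        else:
            runs.append([int(c), i, i])

    def _len(r):
        return r[2] - r[1] + 1

    changed = True
    while changed and len(runs) > 1:
        changed = False
        order = sorted(range(len(runs)), key=lambda j: _len(runs[j]))
        for j in order:
            if _len(runs[j]) >= min_segment:
                continue
            left = runs[j - 1] if j > 0 else None
            right = runs[j + 1] if j < len(runs) - 1 else None
            if left is not None and (right is None or _len(left) >= _len(right)):
                left[2] = runs[j][2]
            elif right is not None:
                right[1] = runs[j][1]
            del runs[j]
            # merge now-equal neighbours
            merged: list[list[int]] = []
            for r in runs:
                if merged and merged[-1][0] == r[0]:
                    merged[-1][2] = r[2]
                else:
                    merged.append(r)
            runs = merged
            changed = True
            break
    return [(r[0], r[1], r[2]) for r in runs]


def classify_haplotypes(
    f2_gm: GenotypeMatrix,
    markers: Sequence[DiagnosticMarker],
    smooth_k: int = 7,
    min_segment: int = 3,
    max_missing: float = 0.5,
    breakpoint_bin_tol: int = 3,
) -> list[HaplotypeCall]:
    """Classify F2 individuals by recombination-breakpoint haplotype.

    Raw per-marker codes are elite-allele dosages (0 = M wild homozygote,
    1 = H heterozygote, 2 = P domestic homozygote); missing genotypes
    stay missing.  Tracks are smoothed by a sliding ``smooth_k``-marker
    majority vote, runs shorter than ``min_segment`` are absorbed, and
    breakpoints are placed at the remaining code changes.  Breakpoints
    from all individuals are then pooled and single-linkage clustered
    (gap <= ``breakpoint_bin_tol`` markers) into shared bins; a
    haplotype class is the pair (segment-code sequence, breakpoint-bin
    sequence), labelled H1, H2, ... in decreasing class size.
    Individuals with more than ``max_missing`` missing markers are
    returned unclassified.
    """
    if smooth_k % 2 != 1:
        raise ValueError("smooth_k must be odd")
    mk_index = {(m.chrom, m.pos): m for m in markers}
    keep = np.array(
        [(str(c), int(p)) in mk_index for c, p in zip(f2_gm.chrom, f2_gm.pos)]
    )
    sub = f2_gm.take(keep)
    order = np.argsort(sub.pos, kind="stable")
    sub = sub.take(order)
    elite_is_alt = np.array([
        mk_index[(str(c), int(p))].elite_allele == "alt"
        for c, p in zip(sub.chrom, sub.pos)
    ])
    g = sub.genotypes.T.astype(np.int8)  # individuals x markers
    codes = np.where(elite_is_alt[None, :], g, 2 - g).astype(np.int8)
    codes[g == MISSING] = MISSING

    calls: list[HaplotypeCall] = []
    for i, ind in enumerate(sub.samples):
        row = codes[i]
        if (row == MISSING).mean() > max_missing:
            calls.append(HaplotypeCall(
                individual=ind, raw_codes=row, smoothed=row.copy(),
                segments=[], breakpoints=[], classified=False,
            ))
            continue
        sm = _majority_smooth(row, smooth_k)
        segs = _segments_from_codes(sm, min_segment)
        bps = [seg[2] for seg in segs[:-1]]
        calls.append(HaplotypeCall(
            individual=ind, raw_codes=row, smoothed=sm,
            segments=segs, breakpoints=bps,
        ))

    # pool breakpoints into shared bins (single-linkage on marker index)
    all_bps = sorted({bp for c in calls for bp in c.breakpoints})
    bins: list[list[int]] = []
    for bp in all_bps:
        if bins and bp - bins[-1][-1] <= breakpoint_bin_tol:
            bins[-1].append(bp)
        else:
            bins.append([bp])
    bin_of = {bp: b for b, grp in enumerate(bins) for bp in grp}

    key_of: dict[tuple, list[HaplotypeCall]] = {}
    for c in calls:
        if not c.classified:
            continue
        key = (
            tuple(code for code, _, _ in c.segments),
            tuple(bin_of[bp] for bp in c.breakpoints),
        )
        key_of.setdefault(key, []).append(c)
    for rank, (key, members) in enumerate(
        sorted(key_of.items(), key=lambda kv: (-len(kv[1]), kv[0])), start=1
    ):
        label = f"H{rank}"
        for c in members:
            c.haplotype_class = label
    n_unclassified = sum(not c.classified for c in calls)
    if n_unclassified:
        warnings.warn(
            f"{n_unclassified} individual(s) unclassified (>50% missing markers)",
            stacklevel=2,
        )
    return calls


def adjust_phenotypes(
    pt: pd.DataFrame,
    traits: Sequence[str],
    factors: Sequence[str],
) -> pd.DataFrame:
    """Covariate-adjust traits with an additive fixed-factor linear model.

    Each trait is regressed on the factor dummies by least squares and
    replaced by grand mean + residual, so factor-level differences (site,
    sex, cross direction) are removed while the trait scale is kept.
    Factors with fewer than two observed levels are dropped with a
    warning; missing trait values stay missing.
    """
    out = pt.copy()
    usable = []
    for f in factors:
        if pt[f].nunique(dropna=True) >= 2:
            usable.append(f)
        else:
            warnings.warn(f"factor {f!r} has < 2 levels; dropped", stacklevel=2)
    for trait in traits:
        y = pd.to_numeric(pt[trait], errors="coerce")
        obs = y.notna()
        if not obs.any():
            warnings.warn(f"trait {trait!r} entirely missing; skipped",
                          stacklevel=2)
            continue
        if not usable:
            continue  # identity transform
        X = pd.get_dummies(
            pt.loc[obs, usable], columns=list(usable), drop_first=True
        ).to_numpy(dtype=float)
        X = np.column_stack([np.ones(int(obs.sum())), X])
        yv = y[obs].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        out.loc[obs, trait] = yv.mean() + resid
    return out


def genotype_association(
    genotypes: Iterable,
    pt: pd.DataFrame,
    trait: str,
    codes: tuple = (0, 1, 2),
) -> AssocResult:
    """One-way ANOVA of an adjusted trait across genotype classes.

    ``genotypes`` holds one code per row of ``pt`` (0/1/2 or M/H/P).
    Variance explained is SS_between / SS_total over individuals in
    groups of size >= 2; the effect percentage contrasts the homozygote
    means: (mean_P - mean_M) / mean_M x 100.
    """
    geno = pd.Series(list(genotypes), index=pt.index)
    geno = geno.replace({"M": 0, "H": 1, "P": 2})
    y = pd.to_numeric(pt[trait], errors="coerce")
    ok = y.notna() & geno.notna() & geno.isin(codes)
    groups = {c: y[ok & (geno == c)].to_numpy() for c in codes}
    sizes = {c: len(v) for c, v in groups.items()}
    means = {c: float(np.mean(v)) if len(v) else float("nan")
             for c, v in groups.items()}

    mean_m, mean_p = means.get(0, np.nan), means.get(2, np.nan)
    effect_pct = float("nan")
    if np.isfinite(mean_m) and np.isfinite(mean_p) and mean_m != 0:
        effect_pct = (mean_p - mean_m) / mean_m * 100.0

    usable = [v for v in groups.values() if len(v) >= 2]
    if len(usable) >= 2:
        allv = np.concatenate(usable)
        gmean = allv.mean()
        ss_total = float(((allv - gmean) ** 2).sum())
        ss_between = float(sum(len(v) * (v.mean() - gmean) ** 2 for v in usable))
        r2 = ss_between / ss_total if ss_total > 0 else 0.0
        if all(np.ptp(v) == 0 for v in usable) or ss_total == ss_between == 0:
            p = None
        else:
            p = float(sps.f_oneway(*usable).pvalue)
    else:
        r2, p = float("nan"), None
    return AssocResult(
        trait=trait, group_means={_CODE_CHARS[c]: means[c] for c in codes},
        group_sizes={_CODE_CHARS[c]: sizes[c] for c in codes},
        effect_pct=effect_pct, variance_explained=r2, anova_p=p,
    )


def segregation_chi2(
    observed: tuple[int, int], expected_ratio: tuple[float, float] = (3.0, 1.0)
) -> dict:
    """Pearson chi-square (df = 1) of a two-class count against a ratio.

    Returns the uncorrected statistic, the Yates continuity-corrected
    statistic, and their P values.
    """
    o = np.asarray(observed, dtype=float)
    a, b = expected_ratio
    if a <= 0 or b <= 0:
        raise ValueError("expected ratio terms must be positive")
    total = o.sum()
    if total == 0:
        raise ValueError("zero total count")
    e = total * np.array([a, b]) / (a + b)
    chi2 = float(((o - e) ** 2 / e).sum())
    adj = np.maximum(np.abs(o - e) - 0.5, 0.0)
    chi2_yates = float((adj**2 / e).sum())
    return {
        "chi2": chi2,
        "p": float(sps.chi2.sf(chi2, df=1)),
        "chi2_yates": chi2_yates,
        "p_yates": float(sps.chi2.sf(chi2_yates, df=1)),
        "df": 1,
    }


def genotype_sv(
    ref_support: int,
    ins_support: int,
    min_depth: int = 4,
    min_allele_reads: int = 2,
    min_minor_frac: float = 0.2,
) -> str:
    """Call an insertion genotype from junction read-support counts.

    NN (no insertion) when insertion support is below ``min_allele_reads``
    and reference support reaches ``min_depth``; II symmetrically; IN
    (heterozygous) when both junctions have at least ``min_allele_reads``
    supporting reads AND the minor junction carries at least
    ``min_minor_frac`` of the total (an allele-balance sanity check that
    turns conflicting low-level evidence into a missing call rather than
    a confident heterozygote).  Everything else is 'missing'.
    Set ``min_minor_frac=0`` to disable the balance check.
    """
    ref_support = int(ref_support)
    ins_support = int(ins_support)
    total = ref_support + ins_support
    if ins_support < min_allele_reads and ref_support >= min_depth:
        return "NN"
    if ref_support < min_allele_reads and ins_support >= min_depth:
        return "II"
    if (
        ref_support >= min_allele_reads
        and ins_support >= min_allele_reads
        and min(ref_support, ins_support) >= min_minor_frac * total
    ):
        return "IN"
    return "missing"


def genotype_sv_table(
    counts: pd.DataFrame,
    min_depth: int = 4,
    min_allele_reads: int = 2,
    min_minor_frac: float = 0.2,
) -> pd.DataFrame:
    """Vector version of :func:`genotype_sv` over a read-support table.

    ``counts`` needs columns individual, ref_support, ins_support.
    """
    out = counts.copy()
    out["genotype"] = [
        genotype_sv(r, i, min_depth, min_allele_reads, min_minor_frac)
        for r, i in zip(counts["ref_support"], counts["ins_support"])
    ]
    return out


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative qPCR expression by the 2^-ddCt method.

    ddCt = (Ct_target,sample - Ct_reference,sample)
         - (Ct_target,calibrator - Ct_reference,calibrator).
    """
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))
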