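"""Candidate divergent region (CDR) calling and fixation scans.

A CDR is a run of sliding windows that are simultaneous upper-tail
outliers (one-sided Z test on the empirical window distribution) for both
F_ST and the pi ln-ratio between an ancestral-stage and a derived-stage
population.  Window standardization uses only windows with enough SNPs
and a finite ln-ratio; windows whose derived-population diversity is
exactly zero (+inf ratio) are excluded from the mean/sd estimate but
count as passing the ratio criterion, since total diversity loss is the
strongest possible sweep signal.  Significant windows are merged into
regions, and regions separated by less than ``merge_gap`` are merged
again so fragmented signals are reported once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import GenotypeMatrix, PopulationMap
from .polarize import AncestralAssignment, derived_allele_frequency
from .popgen_stats import ScanConfig, site_fst

__all__ = [
    "CDR", "call_cdrs", "find_fixed_sites", "find_standing_fixed_sites",
    "annotate_cdrs", "read_genes",
]


@dataclass
class CDR:
    """One called candidate divergent region (1-based inclusive span)."""

    chrom: str
    start: int
    end: int
    stage: str = "custom"
    n_windows: int = 0
    mean_fst: float = float("nan")
    max_fst: float = float("nan")
    mean_pi_ln_ratio: float = float("nan")
    n_fixed_sites: int = 0
    n_standing_fixed_sites: int = 0
    gene_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def standardize_windows(
    windows: pd.DataFrame, cfg: ScanConfig | None = None
) -> pd.DataFrame:
    """Attach z_fst/z_ratio and one-sided upper-tail P columns.

    Mean and sd come from windows with ``n_snps >= cfg.min_snps``, a
    defined F_ST and a finite ln-ratio.  +inf ratio windows with enough
    SNPs get P = 0 for the ratio (automatic pass).
    """
    cfg = cfg or ScanConfig()
    w = windows.copy()
    enough = w["n_snps"].to_numpy() >= cfg.min_snps
    fst = w["fst"].to_numpy(dtype=float)
    ratio = w["pi_ln_ratio"].to_numpy(dtype=float)
    fst_ok = enough & np.isfinite(fst)
    ratio_ok = enough & np.isfinite(ratio)
    if fst_ok.sum() < 30:
        warnings.warn(
            f"only {int(fst_ok.sum())} windows usable for standardization; "
            "Z thresholds unreliable", stacklevel=2,
        )
    for name, vals, ok in (("fst", fst, fst_ok), ("ratio", ratio, ratio_ok)):
        mu = float(np.mean(vals[ok])) if ok.any() else np.nan
        sd = float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else np.nan
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(mu)):
            raise ValueError(f"degenerate window distribution for {name} (sd=0)")
        z = (vals - mu) / sd
        p = sps.norm.sf(z)
        w[f"z_{name}"] = z
        w[f"p_{name}"] = p
    # +inf ratio with enough SNPs: strongest sweep evidence, passes outright
    inf_pass = enough & np.isposinf(ratio)
    w.loc[inf_pass, "p_ratio"] = 0.0
    w.loc[inf_pass, "z_ratio"] = np.inf
    return w


def _merge_rows(
    rows: pd.DataFrame, merge_gap: int
) -> list[tuple[str, int, int, list[int]]]:
    """Merge sorted significant windows; gap between regions < merge_gap."""
    out: list[list] = []
    for idx, r in rows.iterrows():
        if out and r["chrom"] == out[-1][0] and (r["start"] - out[-1][2] - 1) < max(merge_gap, 1):
            out[-1][2] = max(out[-1][2], int(r["end"]))
            out[-1][3].append(idx)
        else:
            out.append([r["chrom"], int(r["start"]), int(r["end"]), [idx]])
    return [tuple(x) for x in out]


def call_cdrs(
    windows: pd.DataFrame,
    cfg: ScanConfig | None = None,
    stage: str = "custom",
) -> tuple[list[CDR], dict]:
    """Call CDRs from a window-statistics table.

    A window is significant iff its one-sided upper-tail P is below
    ``cfg.alpha`` for BOTH F_ST and the pi ln-ratio.  Overlapping or
    adjacent significant windows are merged, and resulting regions closer
    than ``cfg.merge_gap`` bp are merged again, so no two returned CDRs
    on one chromosome are within ``merge_gap`` of each other.

    Returns (cdrs, info); ``info`` reports the empirical statistic values
    at P = alpha (the printed-style cutoffs) and the standardized table.
    """
    cfg = cfg or ScanConfig()
    w = standardize_windows(windows, cfg)
    sig = (w["p_fst"] < cfg.alpha) & (w["p_ratio"] < cfg.alpha) \
        & (w["n_snps"] >= cfg.min_snps)
    z_alpha = sps.norm.isf(cfg.alpha)
    enough = w["n_snps"] >= cfg.min_snps
    fin_f = enough & np.isfinite(w["fst"])
    fin_r = enough & np.isfinite(w["pi_ln_ratio"])
    info = {
        "fst_threshold": float(
            np.mean(w.loc[fin_f, "fst"]) + z_alpha * np.std(w.loc[fin_f, "fst"], ddof=1)
        ),
        "ratio_threshold": float(
            np.mean(w.loc[fin_r, "pi_ln_ratio"])
            + z_alpha * np.std(w.loc[fin_r, "pi_ln_ratio"], ddof=1)
        ),
        "n_significant_windows": int(sig.sum()),
        "windows": w,
    }
    sig_rows = w[sig].sort_values(["chrom", "start"])
    cdrs = []
    for chrom, start, end, members in _merge_rows(sig_rows, cfg.merge_gap):
        sub = w.loc[members]
        finite_ratio = sub["pi_ln_ratio"].replace([np.inf, -np.inf], np.nan)
        cdrs.append(CDR(
            chrom=str(chrom), start=start, end=end, stage=stage,
            n_windows=len(members),
            mean_fst=float(sub["fst"].mean()),
            max_fst=float(sub["fst"].max()),
            mean_pi_ln_ratio=float(finite_ratio.mean()),
        ))
    return cdrs, info


def find_fixed_sites(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop_a: str | Sequence[str],
    pop_b: str | Sequence[str],
    anc: AncestralAssignment | None = None,
) -> pd.DataFrame:
    """Sites at opposite fixation between two populations (F_ST = 1).

    A site qualifies when the two populations are fixed for different
    alleles among their non-missing calls (each with at least two called
    samples).  When a polarization is supplied, the derived allele
    frequency in each population is reported alongside.
    """
    st = site_fst(gm, pm, pop_a, pop_b)
    opp = (
        (st.n_a >= 4) & (st.n_b >= 4)
        & (((st.p_a == 0.0) & (st.p_b == 1.0)) | ((st.p_a == 1.0) & (st.p_b == 0.0)))
    )
    out = pd.DataFrame({
        "chrom": gm.chrom[opp].astype(str),
        "pos": gm.pos[opp],
        "p_a": st.p_a[opp],
        "p_b": st.p_b[opp],
        "fst": st.fst[opp],
    })
    if anc is not None:
        daf_a = derived_allele_frequency(gm, pm, pop_a, anc)
        daf_b = derived_allele_frequency(gm, pm, pop_b, anc)
        out["daf_a"] = daf_a[opp]
        out["daf_b"] = daf_b[opp]
    return out.reset_index(drop=True)


def find_standing_fixed_sites(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    wild_pop: str | Sequence[str],
    derived_pop: str | Sequence[str],
    anc: AncestralAssignment,
    cfg: ScanConfig | None = None,
    cdrs: Sequence[CDR] | None = None,
) -> tuple[pd.DataFrame, list[CDR]]:
    """Standing variants in the wild population nearly fixed downstream.

    Keeps polarized sites whose derived allele frequency is strictly
    below ``standing_max_af`` in the wild population and strictly above
    ``fixed_daf`` in the derived-stage population.  Unpolarized sites are
    skipped (and counted in the returned frame's attrs).  When CDRs are
    supplied, each gets its ``n_standing_fixed_sites`` count filled in
    and the subset with >= ``min_fixed_sites_per_cdr`` such sites is
    returned as the second element.
    """
    cfg = cfg or ScanConfig()
    if anc.n_polarized == 0:
        warnings.warn("no polarized sites; standing-variation scan empty",
                      stacklevel=2)
    daf_w = derived_allele_frequency(gm, pm, wild_pop, anc)
    daf_d = derived_allele_frequency(gm, pm, derived_pop, anc)
    with np.errstate(invalid="ignore"):
        hit = (daf_w < cfg.standing_max_af) & (daf_d > cfg.fixed_daf)
    hit &= anc.polarized
    sites = pd.DataFrame({
        "chrom": gm.chrom[hit].astype(str),
        "pos": gm.pos[hit],
        "daf_wild": daf_w[hit],
        "daf_derived": daf_d[hit],
    }).reset_index(drop=True)
    sites.attrs["n_unpolarized_skipped"] = int((~anc.polarized).sum())

    passing: list[CDR] = []
    if cdrs is not None:
        for cdr in cdrs:
            in_cdr = (sites["chrom"] == str(cdr.chrom)) \
                & (sites["pos"] >= cdr.start) & (sites["pos"] <= cdr.end)
            cdr.n_standing_fixed_sites = int(in_cdr.sum())
            if cdr.n_standing_fixed_sites >= cfg.min_fixed_sites_per_cdr:
                passing.append(cdr)
    return sites, passing


def read_genes(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from GFF3 or BED into (chrom, start, end, gene_id).

    GFF3: rows with feature type 'gene' (coordinates already 1-based
    inclusive); the gene id is taken from the ID= or Name= attribute.
    BED: 0-based half-open converted to 1-based inclusive; the name
    column (4th) is the gene id.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"} or "".join(path.suffixes).endswith(("gff.gz", "gff3.gz")):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
            dtype={"chrom": str},
        )
        df = df[df["type"] == "gene"].copy()

        def _gid(attr: str) -> str:
            fields = dict(
                kv.split("=", 1) for kv in str(attr).split(";") if "=" in kv
            )
            return fields.get("ID", fields.get("Name", "NA"))

        df["gene_id"] = df["attributes"].map(_gid)
        return df[["chrom", "start", "end", "gene_id"]].reset_index(drop=True)
    # BED
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    out = pd.DataFrame({
        "chrom": df[0],
        "start": df[1].astype(int) + 1,
        "end": df[2].astype(int),
        "gene_id": df[3] if df.shape[1] > 3 else [f"g{i}" for i in range(len(df))],
    })
    return out


def annotate_cdrs(
    cdrs: Sequence[CDR], genes: pd.DataFrame, known_chroms: set | None = None
) -> list[CDR]:
    """Attach overlapping gene ids (>= 1 bp overlap) to each CDR in place."""
    if known_chroms is None:
        known_chroms = {str(c.chrom) for c in cdrs}
    unknown = set(genes["chrom"].astype(str)) - set(known_chroms)
    if unknown:
        warnings.warn(
            f"annotation chromosomes not in scan: {sorted(unknown)[:5]} (skipped)",
            stacklevel=2,
        )
    for cdr in cdrs:
        m = (
            (genes["chrom"].astype(str) == str(cdr.chrom))
            & (genes["start"] <= cdr.end)
            & (genes["end"] >= cdr.start)
        )
        cdr.gene_ids = list(genes.loc[m, "gene_id"].astype(str))
    return list(cdrs)


def cdrs_to_frame(cdrs: Sequence[CDR]) -> pd.DataFrame:
    """Tabular CDR report (one row per region)."""
    return pd.DataFrame([
        {
            "chrom": c.chrom, "start": c.start, "end": c.end, "stage": c.stage,
            "n_windows": c.n_windows, "mean_fst": c.mean_fst,
            "max_fst": c.max_fst, "mean_pi_ln_ratio": c.mean_pi_ln_ratio,
            "n_fixed_sites": c.n_fixed_sites,
            "n_standing_fixed_sites": c.n_standing_fixed_sites,
            "n_genes": len(c.gene_ids),
            "gene_ids": ",".join(c.gene_ids),
        }
        for c in cdrs
    ])
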