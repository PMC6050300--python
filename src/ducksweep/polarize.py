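"""Ancestral/derived allele assignment from outgroup genotypes.

A site is polarized when enough outgroup samples are called, all of them
are homozygous, and all carry the same allele; that allele is declared
ancestral and the other allele derived.  Heterozygous outgroup genotypes
never polarize a site (a heterozygote carries both states, so no fixed
ancestral state can be read off it).  This is the genotype-level analogue
of read-level concordance counting against outgroup resequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class AncestralAssignment:
    """Per-site polarization result for one genotype matrix.

    ``polarized`` marks sites with a resolved ancestral state;
    ``ancestral_is_alt`` is only meaningful where ``polarized`` is True.
    """

    polarized: np.ndarray          # (S,) bool
    ancestral_is_alt: np.ndarray   # (S,) bool

    @property
    def n_polarized(self) -> int:
        return int(self.polarized.sum())

    def to_tsv(self, gm: GenotypeMatrix, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tstatus\tancestral_allele\n")
            for i in range(gm.n_sites):
                if self.polarized[i]:
                    allele = gm.alt[i] if self.ancestral_is_alt[i] else gm.ref[i]
                    fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\tpolarized\t{allele}\n")
                else:
                    fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\tunpolarized\t.\n")


def assign_ancestral(
    gm: GenotypeMatrix,
    outgroup_samples: Sequence[str] | None = None,
    *,
    pm: PopulationMap | None = None,
    outgroup_pop: str | None = None,
    min_og_samples: int = 2,
) -> AncestralAssignment:
    """Polarize each site from outgroup homozygote concordance.

    Outgroup samples are given either directly (``outgroup_samples``) or
    via a population map and label.  A site is polarized iff at least
    ``min_og_samples`` outgroup genotypes are non-missing, none is
    heterozygous, and all homozygotes agree; the shared allele is
    ancestral.  The result is invariant to outgroup sample order.
    """
    if outgroup_samples is None:
        if pm is None or outgroup_pop is None:
            raise ValueError("need outgroup_samples, or pm with outgroup_pop")
        outgroup_samples = pm.samples(outgroup_pop)
    if len(outgroup_samples) == 0:
        raise ValueError("zero outgroup samples")
    if min_og_samples < 1:
        raise ValueError("min_og_samples must be >= 1")

    og = gm.genotypes[:, gm.sample_index(outgroup_samples)]
    called = og != MISSING
    n_called = called.sum(axis=1)
    any_het = np.any(og == 1, axis=1)
    all_ref = np.all((og == 0) | ~called, axis=1)
    all_alt = np.all((og == 2) | ~called, axis=1)

    polarized = (n_called >= min_og_samples) & ~any_het & (all_ref | all_alt)
    ancestral_is_alt = polarized & all_alt
    return AncestralAssignment(
        polarized=polarized, ancestral_is_alt=ancestral_is_alt
    )


def derived_allele_frequency(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop: str | Sequence[str],
    anc: AncestralAssignment,
) -> np.ndarray:
    """Per-site derived allele frequency in ``pop`` (NaN where unpolarized
    or uncalled).  Flipping ref/alt labels leaves this quantity unchanged
    because the ancestral assignment flips with them."""
    g = gm.genotypes[:, pm.indices(gm, pop)]
    miss = g == MISSING
    n = 2.0 * (~miss).sum(axis=1)
    ac = np.where(miss, 0, g).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n > 0, ac / n, np.nan)
    daf = np.where(anc.ancestral_is_alt, 1.0 - p_alt, p_alt)
    daf[~anc.polarized] = np.nan
    return daf
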