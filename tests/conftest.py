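"""Shared fixtures: small genotype-matrix builders and cached simulations."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ducksweep import GenotypeMatrix, PopulationMap


def make_gm(
    dosages,
    pos=None,
    chrom="1",
    samples=None,
    ref=None,
    alt=None,
    mean_depth=None,
):
    """Build a GenotypeMatrix from a sites x samples dosage list."""
    g = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = g.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    chroms = np.full(n_sites, chrom, dtype=object) if isinstance(chrom, str) \
        else np.asarray(chrom, dtype=object)
    return GenotypeMatrix(
        chrom=chroms,
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites, dtype=object),
        alt=np.asarray(alt if alt is not None else ["G"] * n_sites, dtype=object),
        genotypes=g,
        samples=list(samples),
        mean_depth=mean_depth,
    )


def make_pm(gm: GenotypeMatrix, split: dict[str, int]) -> PopulationMap:
    """Assign the first k samples to pop A, next to pop B, etc."""
    mapping = {}
    it = iter(gm.samples)
    for pop, k in split.items():
        for _ in range(k):
            mapping[next(it)] = pop
    return PopulationMap(mapping)


def random_gm(rng, n_sites=30, n_samples=12, missing_rate=0.05):
    """Random dosage matrix with missing entries for oracle comparisons."""
    g = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    g[rng.random(g.shape) < missing_rate] = -1
    return make_gm(g)


@pytest.fixture(scope="session")
def two_stage_sim():
    """One default two-stage history shared by several tests."""
    from ducksweep import PopSimConfig, simulate_populations

    cfg = PopSimConfig(seed=42)
    gm, pm, truth = simulate_populations(cfg)
    return cfg, gm, pm, truth
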