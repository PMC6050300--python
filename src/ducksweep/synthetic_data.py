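"""Synthetic inputs with the population structure the analyses assume.

Two generators live here:

* :func:`simulate_populations` — a forward-in-time diploid Wright–Fisher
  simulator with recombination, infinite-sites mutation and additive
  selection, run along a three-population domestication topology: an
  ancestral population splits into a wild population and a domestic
  lineage; the domestic lineage later founds an elite breed through a
  bottleneck (and can optionally split into two indigenous demes, one of
  which may exchange migrants with the elite population).  An outgroup is
  emitted as a fixed homozygous ancestral haplotype, which is all that
  polarization and the ABBA-BABA test require of it.  Sweep loci are
  seeded as standing variants and driven by additive selection in a
  target lineage.

* :func:`simulate_f2` — a wild x elite F2 intercross over one fine-mapping
  region: F1 gametes recombine as a Poisson process on the genetic map
  (Haldane, no interference); a major-effect additive QTL and a recessive
  plumage-color locus segregate; phenotypes include site/sex/cross-direction
  covariates; structural-variant junction read counts are generated from
  the true insertion genotype.

Everything is driven by a single integer seed and is reproducible to the
byte.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "SweepLocus", "MigrationEdge", "PopSimConfig", "F2SimConfig",
    "simulate_populations", "simulate_single_population",
    "simulate_founder_panels", "simulate_f2", "simulate_sv_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SweepLocus:
    """A selected site: position, selection coefficient, target lineage.

    ``start_freq`` is the frequency at which the beneficial allele is
    seeded into the target lineage when it is founded — a standing
    variant rather than a de-novo copy, which matches selection acting
    mostly on standing variation during domestication.
    """

    pos: int
    s: float
    target_pop: str = "indigenous"
    start_freq: float = 0.05


@dataclass(frozen=True)
class MigrationEdge:
    """Symmetric per-generation migration between two coexisting pops."""

    pop_a: str
    pop_b: str
    rate: float

    def __post_init__(self):
        if not 0.0 <= self.rate <= 0.5:
            raise ValueError("migration rate must be in [0, 0.5]")


@dataclass(frozen=True)
class PopSimConfig:
    """Forward-simulation parameters (desk scale).

    Sample sizes default to the resequencing design being emulated
    (40 wild mallards, 36 indigenous-breed ducks, 30 elite Pekin ducks,
    16 outgroup genomes).  Effective sizes, sequence length and rates are
    desk-scale: N = 100 diploids and a 2-Mb chromosome keep a full
    two-stage history under a minute while leaving hundreds of 20-kb
    scan windows.  ``mu`` is set so that pi = 4*N*mu is approximately
    2e-4 per bp, a realistic avian genome-wide diversity.  Split times
    are calibrated so that genome-wide F_ST is about 0.07 for the
    wild/indigenous (domestication) contrast and about 0.10 for the
    indigenous/elite (improvement) contrast, the bottleneck in the elite
    founding doing most of the work for the latter.
    """

    n_wild: int = 40
    n_indigenous: int = 36
    n_elite: int = 30
    n_outgroup: int = 16
    N: int = 100
    bottleneck_factor: float = 0.3
    split_gens: tuple[int, int] = (16, 12)
    indigenous_demes: int = 1
    deme_split_gen: int | None = None  # default: split_gens[1] // 2
    mu: float = 5e-7
    rec: float = 5e-7
    L: int = 2_000_000
    sweep_loci: tuple[SweepLocus, ...] = ()
    migration: tuple[MigrationEdge, ...] = ()
    burn_in_gens: int | None = None    # default: N
    chrom: str = "1"
    missing_rate: float = 0.0
    depth_mean: float | None = 10.0
    depth_sd: float = 1.5
    max_sweep_reseeds: int = 50
    seed: int = 0

    def __post_init__(self):
        t1, t2 = self.split_gens
        if not (t1 >= t2 >= 1):
            raise ValueError("need split_gens[0] >= split_gens[1] >= 1")
        if self.indigenous_demes not in (1, 2):
            raise ValueError("indigenous_demes must be 1 or 2")
        for n in (self.n_wild, self.n_indigenous, self.n_elite, self.N):
            if n < 1:
                raise ValueError("sample and population sizes must be >= 1")
        if self.L < 1000:
            raise ValueError("L too short")
        if not 0 < self.bottleneck_factor <= 1:
            raise ValueError("bottleneck_factor in (0, 1]")


class _WrightFisher:
    """Minimal multi-population forward WF engine on discrete sites."""

    def __init__(self, L: int, mu: float, rec: float, rng: np.random.Generator):
        self.L = int(L)
        self.mu_L = mu * L
        self.rec_L = rec * L
        self.rng = rng
        self.pos = np.empty(0, dtype=np.int64)
        self.posset: set[int] = set()
        self.pops: dict[str, np.ndarray] = {}

    # -- initialisation ------------------------------------------------
    def init_sfs(self, name: str, n_dip: int, theta_site: float) -> None:
        """Start a population at neutral mutation-drift equilibrium.

        Site counts per derived-allele class i follow the standard
        neutral SFS expectation theta*L/i, assigned to random haplotypes;
        a subsequent burn-in builds linkage structure.
        """
        two_n = 2 * n_dip
        theta_L = theta_site * self.L
        cols = []
        for i in range(1, two_n):
            k = self.rng.poisson(theta_L / i)
            for _ in range(k):
                col = np.zeros(two_n, dtype=np.uint8)
                col[self.rng.choice(two_n, size=i, replace=False)] = 1
                cols.append(col)
        n_sites = len(cols)
        self.pos = self._draw_positions(n_sites)
        self.pops[name] = (
            np.array(cols, dtype=np.uint8).T if cols
            else np.zeros((two_n, 0), dtype=np.uint8)
        )

    def init_fixed_freqs(
        self, name: str, n_dip: int, sites: Sequence[tuple[int, float]]
    ) -> None:
        two_n = 2 * n_dip
        cols = []
        pos = []
        for p, f in sites:
            k = int(round(f * two_n))
            col = np.zeros(two_n, dtype=np.uint8)
            if k > 0:
                col[self.rng.choice(two_n, size=min(k, two_n), replace=False)] = 1
            cols.append(col)
            pos.append(int(p))
            self.posset.add(int(p))
        self.pos = np.asarray(pos, dtype=np.int64)
        self.pops[name] = (
            np.array(cols, dtype=np.uint8).T if cols
            else np.zeros((two_n, 0), dtype=np.uint8)
        )

    def _draw_positions(self, k: int) -> np.ndarray:
        out = np.empty(k, dtype=np.int64)
        for i in range(k):
            while True:
                p = int(self.rng.integers(1, self.L + 1))
                if p not in self.posset:
                    self.posset.add(p)
                    out[i] = p
                    break
        return out

    # -- per-generation machinery --------------------------------------
    def _fitness_probs(self, name: str, pairs) -> np.ndarray | None:
        """Parent-sampling weights from additive fitness 1 + s*dose/2.

        ``pairs`` is a list of (SweepLocus, column) active in ``name``;
        returns None (uniform sampling) when empty or neutral."""
        if not pairs:
            return None
        H = self.pops[name]
        n_dip = H.shape[0] // 2
        w = np.ones(n_dip)
        for sw, col in pairs:
            dose = H[0::2, col].astype(float) + H[1::2, col].astype(float)
            w *= 1.0 + sw.s * dose / 2.0
        total = w.sum()
        return None if total == 0 else w / total

    def make_offspring(
        self,
        src: str,
        n_dip_out: int,
        partner: str | None = None,
        m: float = 0.0,
        sweeps=(),
    ) -> np.ndarray:
        """One generation of gametes: 2*n_dip_out rows sampled from src
        (or from the migration partner with probability m per gamete)."""
        rng = self.rng
        n_g = 2 * n_dip_out
        S = self.pos.size
        out = np.empty((n_g, S), dtype=np.uint8)
        from_partner = (
            rng.random(n_g) < m if partner is not None and m > 0
            else np.zeros(n_g, dtype=bool)
        )
        parents = np.empty(n_g, dtype=np.int64)
        for pop, mask in ((src, ~from_partner), (partner, from_partner)):
            if pop is None or not mask.any():
                continue
            n_dip_src = self.pops[pop].shape[0] // 2
            probs = self._fitness_probs(
                pop, [(sw, col) for sw, col, p in sweeps if p == pop]
            )
            if probs is None:
                parents[mask] = rng.integers(0, n_dip_src, mask.sum())
            else:
                parents[mask] = rng.choice(n_dip_src, size=int(mask.sum()), p=probs)
        ks = rng.poisson(self.rec_L, n_g)
        phases = rng.integers(0, 2, n_g)
        for g in range(n_g):
            H = self.pops[partner if from_partner[g] else src]
            p2 = 2 * parents[g]
            if ks[g] == 0:
                out[g] = H[p2 + phases[g]]
            else:
                xs = np.sort(rng.integers(1, self.L + 1, ks[g]))
                par = (np.searchsorted(xs, self.pos, side="left") + phases[g]) & 1
                out[g] = np.where(par.astype(bool), H[p2 + 1], H[p2])
        return out

    def mutate(self, new_pops: dict[str, np.ndarray]) -> None:
        """Add infinite-sites mutations (Poisson(mu*L) per gamete)."""
        rng = self.rng
        events: list[tuple[str, int]] = []
        for name, H in new_pops.items():
            k = rng.poisson(self.mu_L * H.shape[0])
            for _ in range(k):
                events.append((name, int(rng.integers(H.shape[0]))))
        if not events:
            return
        newpos = self._draw_positions(len(events))
        blocks = {
            name: np.zeros((H.shape[0], len(events)), dtype=np.uint8)
            for name, H in new_pops.items()
        }
        for j, (name, row) in enumerate(events):
            blocks[name][row, j] = 1
        self.pos = np.concatenate([self.pos, newpos])
        for name in new_pops:
            new_pops[name] = np.hstack([new_pops[name], blocks[name]])

    def prune_lost(self) -> None:
        """Drop columns whose derived allele is lost in every population."""
        if self.pos.size == 0:
            return
        total = np.zeros(self.pos.size, dtype=np.int64)
        for H in self.pops.values():
            total += H.sum(axis=0, dtype=np.int64)
        keep = total > 0
        if keep.all():
            return
        self.pos = self.pos[keep]
        for name in self.pops:
            self.pops[name] = self.pops[name][:, keep]
        self.posset = set(int(p) for p in self.pos)

    def col_of(self, pos: int) -> int | None:
        idx = np.flatnonzero(self.pos == pos)
        return int(idx[0]) if idx.size else None

    def ensure_site(self, pos: int) -> int:
        col = self.col_of(pos)
        if col is not None:
            return col
        self.posset.add(int(pos))
        self.pos = np.concatenate([self.pos, [np.int64(pos)]])
        for name, H in self.pops.items():
            self.pops[name] = np.hstack(
                [H, np.zeros((H.shape[0], 1), dtype=np.uint8)]
            )
        return self.pos.size - 1

    def seed_allele(self, name: str, pos: int, freq: float) -> int:
        col = self.ensure_site(pos)
        H = self.pops[name]
        k = max(1, int(round(freq * H.shape[0])))
        rows = self.rng.choice(H.shape[0], size=min(k, H.shape[0]), replace=False)
        H[:, col] = 0
        H[rows, col] = 1
        return col

    def frequency(self, name: str, pos: int) -> float:
        col = self.col_of(pos)
        if col is None:
            return 0.0
        H = self.pops[name]
        return float(H[:, col].sum() / H.shape[0])


def _sweep_scope(target: str, pop: str) -> bool:
    """Which concrete populations a sweep's target lineage covers."""
    if target == "indigenous":
        return pop in ("domestic", "indigenous", "indigenousA", "indigenousB",
                       "elite")
    return pop == target


def simulate_populations(
    cfg: PopSimConfig | None = None,
) -> tuple[GenotypeMatrix, PopulationMap, dict]:
    """Forward-simulate the two-stage domestication history and sample it.

    Runs an SFS-initialised burn-in of the ancestral population, splits
    wild and domestic lineages ``split_gens[0]`` generations before
    sampling, founds the elite population from the domestic lineage with
    a bottleneck ``split_gens[1]`` generations before sampling
    (optionally splitting the domestic lineage into two indigenous
    demes), applies any configured migration and sweep selection, and
    finally samples diploid individuals plus a fixed-ancestral outgroup.

    Returns (genotype matrix, population map, truth record).  The truth
    record carries sweep outcomes (final frequencies, reseed counts),
    event times and all parameters, and is sufficient to score any
    downstream recovery test.  The same seed reproduces the output
    exactly.
    """
    cfg = cfg or PopSimConfig()
    rng = np.random.default_rng(cfg.seed)
    t1, t2 = cfg.split_gens
    demes = cfg.indigenous_demes
    t3 = cfg.deme_split_gen if cfg.deme_split_gen is not None else (
        max(1, t2 // 2) if demes == 2 else None
    )
    if demes == 2 and not (t2 > t3 >= 1):
        raise ValueError("deme split must postdate the elite founding")
    n_elite_pop = max(2, int(round(cfg.N * cfg.bottleneck_factor)))
    if cfg.n_elite > n_elite_pop:
        raise ValueError(
            f"n_elite={cfg.n_elite} exceeds elite population size {n_elite_pop}"
        )

    sim = _WrightFisher(cfg.L, cfg.mu, cfg.rec, rng)
    theta = 4 * cfg.N * cfg.mu
    sim.init_sfs("ancestral", cfg.N, theta)
    burn = cfg.burn_in_gens if cfg.burn_in_gens is not None else cfg.N
    reseeds = {sw: 0 for sw in cfg.sweep_loci}
    failed = {sw: False for sw in cfg.sweep_loci}

    def active_sweeps_for(pop: str):
        out = []
        for sw in cfg.sweep_loci:
            if _sweep_scope(sw.target_pop, pop):
                col = sim.col_of(sw.pos)
                if col is not None:
                    out.append((sw, col, pop))
        return out

    def step_all():
        new = {}
        mig = {}
        for e in cfg.migration:
            if e.pop_a in sim.pops and e.pop_b in sim.pops:
                mig[e.pop_a] = (e.pop_b, e.rate)
                mig[e.pop_b] = (e.pop_a, e.rate)
        for name, H in sim.pops.items():
            partner, m = mig.get(name, (None, 0.0))
            sweeps = active_sweeps_for(name)
            if partner is not None:
                sweeps += active_sweeps_for(partner)
            new[name] = sim.make_offspring(
                name, H.shape[0] // 2, partner=partner, m=m, sweeps=sweeps
            )
        sim.mutate(new)
        sim.pops = new
        sim.prune_lost()
        # reseed sweeps lost in their whole scope
        for sw in cfg.sweep_loci:
            scope = [p for p in sim.pops if _sweep_scope(sw.target_pop, p)]
            if not scope or failed[sw]:
                continue
            tot = sum(
                sim.pops[p][:, sim.col_of(sw.pos)].sum()
                if sim.col_of(sw.pos) is not None else 0
                for p in scope
            )
            if tot == 0:
                if reseeds[sw] < cfg.max_sweep_reseeds:
                    reseeds[sw] += 1
                    sim.seed_allele(scope[0], sw.pos, sw.start_freq)
                else:
                    failed[sw] = True

    for _ in range(burn):
        for sw in cfg.sweep_loci:  # sweeps targeting the ancestral pop
            if sw.target_pop == "ancestral" and sim.col_of(sw.pos) is None:
                sim.seed_allele("ancestral", sw.pos, sw.start_freq)
        step_all()

    # split 1: wild | domestic
    anc = sim.pops.pop("ancestral")
    sim.pops["ancestral"] = anc  # temporary source for offspring draws
    wild = sim.make_offspring("ancestral", cfg.N)
    domestic = sim.make_offspring("ancestral", cfg.N)
    del sim.pops["ancestral"]
    sim.pops = {"wild": wild, "domestic": domestic}
    sim.prune_lost()
    for sw in cfg.sweep_loci:
        if sw.target_pop == "indigenous":
            sim.seed_allele("domestic", sw.pos, sw.start_freq)
        elif sw.target_pop == "wild":
            sim.seed_allele("wild", sw.pos, sw.start_freq)

    for t in range(t1 - 1, -1, -1):
        if t == t2 - 1:
            # elite founded with a bottleneck from the domestic lineage
            sim.pops["elite"] = sim.make_offspring("domestic", n_elite_pop)
            for sw in cfg.sweep_loci:
                if sw.target_pop == "elite":
                    sim.seed_allele("elite", sw.pos, sw.start_freq)
        if demes == 2 and t == t3 - 1:
            a = sim.make_offspring("domestic", cfg.N)
            b = sim.make_offspring("domestic", cfg.N)
            del sim.pops["domestic"]
            sim.pops["indigenousA"] = a
            sim.pops["indigenousB"] = b
        if t == 0:
            break
        step_all()

    if "domestic" in sim.pops:
        sim.pops["indigenous"] = sim.pops.pop("domestic")

    sweep_truth = []
    for sw in cfg.sweep_loci:
        scope = [p for p in sim.pops if _sweep_scope(sw.target_pop, p)]
        freqs = {p: sim.frequency(p, sw.pos) for p in scope}
        primary = freqs.get(
            {"indigenous": "indigenous", "elite": "elite", "wild": "wild"}
            .get(sw.target_pop, sw.target_pop),
            max(freqs.values()) if freqs else 0.0,
        )
        if sw.target_pop == "indigenous" and "indigenous" not in freqs:
            vals = [freqs[p] for p in ("indigenousA", "indigenousB") if p in freqs]
            primary = float(np.mean(vals)) if vals else 0.0
        sweep_truth.append({
            "pos": sw.pos, "s": sw.s, "target_pop": sw.target_pop,
            "start_freq": sw.start_freq, "final_freq": float(primary),
            "fixed": bool(primary >= 1.0), "reseeds": reseeds[sw],
            "failed": failed[sw],
        })

    # ---- sample individuals ------------------------------------------
    def sample_pop(name: str, n: int) -> np.ndarray:
        H = sim.pops[name]
        n_dip = H.shape[0] // 2
        idx = rng.choice(n_dip, size=n, replace=False)
        return (H[2 * idx].astype(np.int8) + H[2 * idx + 1].astype(np.int8))

    blocks: list[np.ndarray] = []
    labels: list[tuple[str, str]] = []
    plan = [("wild", cfg.n_wild)]
    if demes == 2:
        n_a = cfg.n_indigenous // 2
        plan += [("indigenousA", n_a), ("indigenousB", cfg.n_indigenous - n_a)]
    else:
        plan += [("indigenous", cfg.n_indigenous)]
    plan += [("elite", cfg.n_elite)]
    for name, n in plan:
        blocks.append(sample_pop(name, n))
        labels += [(f"{name}_{i:02d}", name) for i in range(n)]
    S = sim.pos.size
    blocks.append(np.zeros((cfg.n_outgroup, S), dtype=np.int8))
    labels += [(f"outgroup_{i:02d}", "outgroup") for i in range(cfg.n_outgroup)]
    geno = np.concatenate(blocks, axis=0).T  # sites x samples

    order = np.argsort(sim.pos, kind="stable")
    pos = sim.pos[order]
    geno = geno[order]

    # randomize which allele is labelled REF so the ancestral state is
    # sometimes the alt allele (exercises polarization)
    flip = rng.random(pos.size) < 0.5
    geno[flip] = 2 - geno[flip]
    ref_idx = rng.integers(0, 4, pos.size)
    alt_off = rng.integers(1, 4, pos.size)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_off) % 4]

    if cfg.missing_rate > 0:
        miss = rng.random(geno.shape) < cfg.missing_rate
        geno[miss] = MISSING

    depth = None
    if cfg.depth_mean is not None:
        depth = np.clip(
            rng.normal(cfg.depth_mean, cfg.depth_sd, pos.size), 1.0, None
        )

    gm = GenotypeMatrix(
        chrom=np.full(pos.size, cfg.chrom, dtype=object),
        pos=pos,
        ref=ref.astype(object),
        alt=alt.astype(object),
        genotypes=geno,
        samples=[s for s, _ in labels],
        mean_depth=depth,
        meta={"simulated": True, "L": cfg.L},
    )
    pm = PopulationMap(dict(labels))
    truth = {
        "sweeps": sweep_truth,
        "splits": {"wild_domestic": t1, "elite_founding": t2,
                   "deme_split": t3},
        "migration": [asdict(e) for e in cfg.migration],
        "burn_in_gens": burn,
        "chrom_lengths": {cfg.chrom: cfg.L},
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
    }
    return gm, pm, truth


def simulate_single_population(
    N: int,
    L: int,
    mu: float,
    rec: float,
    gens: int,
    seed: int,
    init_sites: Sequence[tuple[int, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve one WF population and return (haplotypes, positions).

    ``init_sites`` pins the starting state to given (position, frequency)
    pairs (useful for drift-decay checks with mu = 0); otherwise the
    population starts from the neutral SFS.
    """
    rng = np.random.default_rng(seed)
    sim = _WrightFisher(L, mu, rec, rng)
    if init_sites is None:
        sim.init_sfs("pop", N, 4 * N * mu)
    else:
        sim.init_fixed_freqs("pop", N, init_sites)
    for _ in range(gens):
        new = {"pop": sim.make_offspring("pop", N)}
        sim.mutate(new)
        sim.pops = new
        sim.prune_lost()
    return sim.pops["pop"], sim.pos


# ======================================================================
# F2 intercross
# ======================================================================

@dataclass(frozen=True)
class F2SimConfig:
    """Wild x elite F2 intercross over one fine-mapping region.

    Defaults emulate the mapping design being studied: 1026 F2
    individuals genotyped at 243 markers across a ~1-Mb region, a
    single additive QTL explaining 15% of the (covariate-free) variance
    in body weight, and a recessive colorless locus fixed in the elite
    founders, expected to segregate 3:1 colored:colorless.  The genetic
    length (20 cM) is a desk-scale choice that yields enough recombinant
    individuals to exercise breakpoint classification; the residual
    standard deviation (254 g on a 2000-g mean) makes the implied
    homozygote effect about 15% of the mean.
    """

    n_f2: int = 1026
    n_markers: int = 243
    region_start: int = 4_400_000
    region_bp: int = 1_000_000
    map_length_cM: float = 20.0
    chrom: str = "28"
    frac_nondiagnostic: float = 0.15
    n_wild_founders: int = 12
    n_elite_founders: int = 12
    n_families: int = 30
    qtl_pos_frac: float = 0.5
    qtl_variance_frac: float = 0.15
    color_pos_frac: float = 0.25
    mean_body_weight_g: float = 2000.0
    residual_sd_g: float = 254.0
    site_levels: tuple[str, ...] = ("site1", "site2", "site3")
    site_effects_g: tuple[float, ...] = (0.0, 120.0, -80.0)
    sex_effect_g: float = -100.0        # female minus male
    cross_effect_g: float = 25.0        # reciprocal-cross offset
    expr_mean: float = 1.0
    expr_variance_frac: float = 0.4
    expr_residual_sd: float = 0.35
    missing_rate: float = 0.02
    geno_error_rate: float = 0.005
    sv_depth: float = 25.0
    sv_error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_f2 < 10:
            raise ValueError("n_f2 must be >= 10")
        for v in (self.qtl_variance_frac, self.expr_variance_frac):
            if not 0.0 <= v < 1.0:
                raise ValueError("variance fractions must be in [0, 1)")

    @property
    def qtl_effect_g(self) -> float:
        """Additive (per-allele) effect implied by the programmed
        variance fraction: var_QTL = beta^2 * 0.5 in an F2."""
        v = self.qtl_variance_frac
        return math.sqrt(v / (1.0 - v) * self.residual_sd_g**2 / 0.5)

    @property
    def expr_effect(self) -> float:
        v = self.expr_variance_frac
        return math.sqrt(v / (1.0 - v) * self.expr_residual_sd**2 / 0.5)


def _marker_truth(cfg: F2SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Marker positions and founder-population allele frequencies.

    Most markers are opposite-fixed between the founder populations
    (dAF = 1, diagnostic); a fraction are ancestry-uninformative with
    dAF < 0.6 drawn uniformly.
    """
    pos = np.sort(rng.choice(
        np.arange(cfg.region_start + 1, cfg.region_start + cfg.region_bp + 1),
        size=cfg.n_markers, replace=False,
    ))
    diag = rng.random(cfg.n_markers) >= cfg.frac_nondiagnostic
    p_w = np.where(diag, 0.0, 0.0)
    p_e = np.where(diag, 1.0, 0.0)
    nd = ~diag
    base = rng.uniform(0.2, 0.8, nd.sum())
    delta = rng.uniform(0.0, 0.5, nd.sum()) * rng.choice([-1, 1], nd.sum())
    p_w[nd] = base
    p_e[nd] = np.clip(base + delta, 0.0, 1.0)
    # elite allele reported on a randomized ref/alt labelling
    elite_is_alt = rng.random(cfg.n_markers) < 0.5
    ref_idx = rng.integers(0, 4, cfg.n_markers)
    alt_off = rng.integers(1, 4, cfg.n_markers)
    return pd.DataFrame({
        "chrom": cfg.chrom, "pos": pos, "p_wild": p_w, "p_elite": p_e,
        "diagnostic": diag, "elite_is_alt": elite_is_alt,
        "ref": _BASES[ref_idx], "alt": _BASES[(ref_idx + alt_off) % 4],
        "cM": (pos - cfg.region_start) / cfg.region_bp * cfg.map_length_cM,
    })


def _emit_matrix(
    cfg: F2SimConfig, mk: pd.DataFrame, elite_dosage: np.ndarray,
    samples: list[str], rng: np.random.Generator,
    missing_rate: float = 0.0, error_rate: float = 0.0,
) -> GenotypeMatrix:
    """Convert elite-allele dosages to an alt-dosage GenotypeMatrix."""
    dosage = elite_dosage.T.astype(np.int8)  # markers x individuals
    elite_is_alt = mk["elite_is_alt"].to_numpy()
    g = np.where(elite_is_alt[:, None], dosage, 2 - dosage).astype(np.int8)
    if error_rate > 0:
        err = rng.random(g.shape) < error_rate
        bump = rng.integers(1, 3, size=g.shape).astype(np.int8)
        g = np.where(err, (g + bump) % 3, g).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    return GenotypeMatrix(
        chrom=mk["chrom"].to_numpy(dtype=object),
        pos=mk["pos"].to_numpy(np.int64),
        ref=mk["ref"].to_numpy(dtype=object),
        alt=mk["alt"].to_numpy(dtype=object),
        genotypes=g,
        samples=samples,
    )


def simulate_founder_panels(
    cfg: F2SimConfig | None = None,
) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Genotype the wild and elite founder panels at all markers.

    Returns (matrix, popmap with 'wild'/'elite' labels, marker truth
    table).  Uses the same marker truth as :func:`simulate_f2` for the
    same seed, so diagnostic-marker selection on the panels can be
    compared against the generating frequencies.
    """
    cfg = cfg or F2SimConfig()
    rng = np.random.default_rng(cfg.seed)
    mk = _marker_truth(cfg, rng)
    n_w, n_e = cfg.n_wild_founders, cfg.n_elite_founders
    p_w = mk["p_wild"].to_numpy()
    p_e = mk["p_elite"].to_numpy()
    gw = rng.binomial(2, p_w[None, :].repeat(n_w, axis=0))
    ge = rng.binomial(2, p_e[None, :].repeat(n_e, axis=0))
    dosage = np.vstack([gw, ge]).astype(np.int8)
    samples = [f"wildF_{i:02d}" for i in range(n_w)] + \
              [f"eliteF_{i:02d}" for i in range(n_e)]
    gm = _emit_matrix(cfg, mk, dosage, samples, rng)
    pm = PopulationMap(
        {s: ("wild" if s.startswith("wild") else "elite") for s in samples}
    )
    return gm, pm, mk


def _gamete_origins(
    cM_positions: np.ndarray, map_length: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Origin (0 = wild, 1 = elite) of one F1 gamete at given cM positions.

    Crossovers are a Poisson process on the genetic map (Haldane, no
    interference).  Returns (origin vector, crossover cM positions).
    """
    k = rng.poisson(map_length / 100.0)
    phase = int(rng.integers(0, 2))
    if k == 0:
        return np.full(cM_positions.size, phase, dtype=np.int8), np.empty(0)
    xs = np.sort(rng.uniform(0.0, map_length, k))
    par = (np.searchsorted(xs, cM_positions, side="left") + phase) & 1
    return par.astype(np.int8), xs


def simulate_f2(
    cfg: F2SimConfig | None = None,
    founders: tuple[GenotypeMatrix, PopulationMap] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Simulate the F2 intercross: genotypes, phenotypes, truth record.

    F2 individuals are produced in families; each family draws four
    grandparent haplotypes (two wild, two elite) from the founder
    frequencies, and every F2 genome is the sum of two recombinant F1
    gametes.  Phenotype = grand mean + additive QTL effect x dosage +
    site + sex + cross-direction + Gaussian residual, with the additive
    effect solved from the programmed variance fraction.  Plumage is
    colorless iff the individual is homozygous for the elite allele at
    the color locus, and the same locus defines the structural-variant
    insertion genotype used to generate junction read counts.

    Returns (genotype matrix over all markers, phenotype table, truth).
    The truth record includes the per-individual QTL dosage, color/SV
    genotype, and true recombination-breakpoint indices on the
    diagnostic-marker track.
    """
    cfg = cfg or F2SimConfig()
    rng = np.random.default_rng(cfg.seed)
    if founders is not None:
        f_gm, f_pm = founders
        from .popgen_stats import allele_frequencies
        _, p_w = allele_frequencies(f_gm, f_pm, "wild")
        _, p_e = allele_frequencies(f_gm, f_pm, "elite")
        elite_is_alt = p_e >= p_w
        mk = pd.DataFrame({
            "chrom": f_gm.chrom.astype(str), "pos": f_gm.pos,
            "p_wild": np.where(elite_is_alt, p_w, 1 - p_w),
            "p_elite": np.where(elite_is_alt, p_e, 1 - p_e),
            "diagnostic": np.abs(p_e - p_w) > 0.6,
            "elite_is_alt": elite_is_alt,
            "ref": f_gm.ref, "alt": f_gm.alt,
            "cM": (f_gm.pos - f_gm.pos.min())
                  / max(int(np.ptp(f_gm.pos)), 1) * cfg.map_length_cM,
        })
    else:
        mk = _marker_truth(cfg, rng)

    cM = mk["cM"].to_numpy()
    p_w = mk["p_wild"].to_numpy()
    p_e = mk["p_elite"].to_numpy()
    qtl_cM = cfg.qtl_pos_frac * cfg.map_length_cM
    color_cM = cfg.color_pos_frac * cfg.map_length_cM
    eval_cM = np.concatenate([cM, [qtl_cM, color_cM]])

    n = cfg.n_f2
    fam_of = rng.integers(0, cfg.n_families, n)
    # grandparent haplotypes per family, stored as elite-allele carrier state
    fam_w = (rng.random((cfg.n_families, 2, cfg.n_markers)) < p_w).astype(np.int8)
    fam_e = (rng.random((cfg.n_families, 2, cfg.n_markers)) < p_e).astype(np.int8)

    elite_dosage = np.empty((n, cfg.n_markers), dtype=np.int8)
    qtl_dosage = np.empty(n, dtype=np.int8)
    color_dosage = np.empty(n, dtype=np.int8)
    true_bp: list[list[int]] = []
    diag_idx = np.flatnonzero(mk["diagnostic"].to_numpy())
    for i in range(n):
        f = fam_of[i]
        hap = np.empty((2, cfg.n_markers), dtype=np.int8)
        origins = np.empty((2, eval_cM.size), dtype=np.int8)
        for gidx, (wh, eh) in enumerate(
            ((fam_w[f, 0], fam_e[f, 0]), (fam_w[f, 1], fam_e[f, 1]))
        ):
            orig, _ = _gamete_origins(eval_cM, cfg.map_length_cM, rng)
            origins[gidx] = orig
            hap[gidx] = np.where(orig[: cfg.n_markers] == 1, eh, wh)
        elite_dosage[i] = hap.sum(axis=0)
        qtl_dosage[i] = origins[:, -2].sum()
        color_dosage[i] = origins[:, -1].sum()
        # true breakpoints on the diagnostic-marker origin-dosage track
        track = origins[0, diag_idx] + origins[1, diag_idx]
        chg = np.flatnonzero(np.diff(track) != 0)
        true_bp.append(chg.tolist())

    samples = [f"F2_{i:04d}" for i in range(n)]
    gm = _emit_matrix(
        cfg, mk, elite_dosage, samples, rng,
        missing_rate=cfg.missing_rate, error_rate=cfg.geno_error_rate,
    )

    site = rng.choice(list(cfg.site_levels), n)
    sex = rng.choice(["F", "M"], n)
    cross = rng.choice(["MxP", "PxM"], n)
    site_eff = dict(zip(cfg.site_levels, cfg.site_effects_g))
    beta = cfg.qtl_effect_g
    y = (
        cfg.mean_body_weight_g
        + beta * (qtl_dosage.astype(float) - 1.0)
        + np.vectorize(site_eff.get)(site)
        + np.where(sex == "F", cfg.sex_effect_g, 0.0)
        + np.where(cross == "PxM", cfg.cross_effect_g, 0.0)
        + rng.normal(0.0, cfg.residual_sd_g, n)
    )
    expr = (
        cfg.expr_mean
        + cfg.expr_effect * (qtl_dosage.astype(float) - 1.0)
        + rng.normal(0.0, cfg.expr_residual_sd, n)
    )
    color = np.where(color_dosage == 2, "colorless", "colored")
    pheno = pd.DataFrame({
        "individual": samples, "site": site, "sex": sex, "cross": cross,
        "body_weight_g": y, "igf2bp1_expr": expr, "color": color,
    }).set_index("individual", drop=False)

    sv_geno = np.array(["NN", "IN", "II"])[color_dosage]
    sv_counts = simulate_sv_reads(
        sv_geno, cfg.sv_depth, cfg.sv_error_rate,
        rng=rng, individuals=samples,
    )

    truth = {
        "markers": mk,
        "diag_marker_idx": diag_idx.tolist(),
        "qtl": {"cM": qtl_cM, "effect_g": beta,
                "variance_frac": cfg.qtl_variance_frac},
        "color_locus_cM": color_cM,
        "qtl_dosage": qtl_dosage,
        "color_dosage": color_dosage,
        "sv_genotype": sv_geno,
        "sv_counts": sv_counts,
        "breakpoints": true_bp,
        "family": fam_of,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }
    return gm, pheno, truth


def simulate_sv_reads(
    true_genotypes: Sequence[str],
    depth: float,
    error_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    individuals: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Junction read-support counts from true insertion genotypes.

    Per individual the total junction-spanning read count is
    Poisson(depth); each read derives from a uniformly chosen chromosome
    copy and supports that copy's junction, mislabelled with probability
    ``error_rate``.  Returns a DataFrame (individual, true_genotype,
    ref_support, ins_support).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    geno = np.asarray(true_genotypes)
    frac = np.select([geno == "NN", geno == "IN", geno == "II"],
                     [0.0, 0.5, 1.0], default=np.nan)
    if np.isnan(frac).any():
        raise ValueError("true genotypes must be NN/IN/II")
    n = geno.size
    total = rng.poisson(depth, n)
    ins_true = rng.binomial(total, frac)
    # mislabelling flips a read's apparent junction
    ins_obs = rng.binomial(ins_true, 1.0 - error_rate) \
        + rng.binomial(total - ins_true, error_rate)
    if individuals is None:
        individuals = [f"ind_{i:04d}" for i in range(n)]
    return pd.DataFrame({
        "individual": list(individuals),
        "true_genotype": geno,
        "ref_support": total - ins_obs,
        "ins_support": ins_obs,
    })
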