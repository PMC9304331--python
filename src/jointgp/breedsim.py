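"""Simplified wheat-style breeding-program simulator.

Generates genotype/phenotype datasets with a known additive architecture by
emulating a line-breeding program: 70 inbred founders, yearly rounds of 100
biparental crosses with 100 doubled-haploid (DH) offspring each, and
multi-stage phenotypic selection through a head-row nursery (h2 = 0.1),
preliminary yield trial (PYT, h2 = 0.2), advanced yield trial (AYT,
h2 = 0.5) and elite yield trial (EYT, h2 = 0.67).  After 10 burn-in plus 10
recorded years the simulator returns the 10 x 1000 = 10,000 PYT lines with
their genotypes ({0,1,2}; DHs are fully homozygous so heterozygotes never
occur), true breeding values and PYT phenotypes.

The genome is 21 chromosomes x 1000 biallelic SNPs.  QTLs (2, 10, 100 or
1000 per chromosome) are drawn among the SNPs with zero-mean normal additive
effects rescaled so the founder genetic values follow the nominal
Normal(mean 4, variance 0.1) — the stochastic-simulation convention in which
trait mean/variance, not per-locus effects, are specified.  Internally
genetic values are kept standardized to founder mean 0 and variance 1
(min-max normalization downstream erases the nominal scale anyway), and the
stage heritabilities are realized against that founder variance.
``directional_effects=True`` switches to the literal reading in which every
QTL effect itself is drawn from Normal(4, 0.1), a strongly directional
allele-count architecture kept for sensitivity checks.  Founder haplotypes use an i.i.d. neutral-like site-frequency
spectrum (P(freq) proportional to 1/i) rather than a coalescent, the main
fidelity gap versus a full stochastic simulator.  Each chromosome is one
Morgan with uniform marker spacing; crossovers are Poisson(1) per meiosis
without interference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix, TraitVector, minmax_normalize

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_founders",
    "cross_and_dh",
    "run_breeding_program",
    "sample_dataset",
]


@dataclass
class SimConfig:
    """Breeding-program and genetic-architecture settings."""

    chromosomes: int = 21
    snps_per_chrom: int = 1000
    qtl_per_chrom: int = 100
    trait_mean: float = 4.0  # nominal founder genetic-value mean
    trait_var: float = 0.1  # nominal founder genetic-value variance
    env_var: float = 0.4  # burn-in selection phenotypes
    gxe_var: float = 0.2
    founders: int = 70
    burn_in_years: int = 10
    recorded_years: int = 10
    families: int = 100
    family_size: int = 100
    select_per_family: int = 10
    ayt_size: int = 100
    eyt_size: int = 10
    h2_nursery: float = 0.1
    h2_pyt: float = 0.2
    h2_ayt: float = 0.5
    h2_eyt: float = 0.67
    seed: int = 0
    directional_effects: bool = False  # literal per-QTL N(4, 0.1) effects

    def __post_init__(self) -> None:
        if self.qtl_per_chrom > self.snps_per_chrom:
            raise ValueError("more QTLs than SNPs on a chromosome")
        if min(self.env_var, self.gxe_var, self.trait_var) < 0:
            raise ValueError("variances must be non-negative")

    @property
    def n_markers(self) -> int:
        return self.chromosomes * self.snps_per_chrom

    @property
    def n_pyt(self) -> int:
        return self.families * self.select_per_family


@dataclass
class SimulatedDataset:
    """The recorded PYT pool of a simulated program."""

    genotypes: np.ndarray  # (n, markers) codes {0, 2} (DHs carry no 1s)
    ids: list[str]
    marker_ids: list[str]
    breeding_values: np.ndarray  # true, standardized to founder variance 1
    phenotypes: np.ndarray  # PYT stage phenotypes
    year: np.ndarray  # recorded year of origin, 1-based
    qtl: pd.DataFrame  # marker, chrom, pos (1-based index on chrom), effect

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


def _marker_ids(cfg: SimConfig) -> list[str]:
    return [f"c{c + 1}_s{s + 1}" for c in range(cfg.chromosomes) for s in range(cfg.snps_per_chrom)]


def simulate_founders(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Founder haplotypes (founders x markers, uint8 0/1), all sites polymorphic.

    Derived-allele counts follow the 1/i spectrum over 1..founders-1, sites
    independent; monomorphic draws are resampled.
    """
    n, m = cfg.founders, cfg.n_markers
    i = np.arange(1, n)
    spectrum = (1.0 / i) / (1.0 / i).sum()
    freqs = rng.choice(i, size=m, p=spectrum) / n
    hap = (rng.random((n, m)) < freqs[None, :]).astype(np.uint8)
    mono = (hap.sum(axis=0) == 0) | (hap.sum(axis=0) == n)
    while mono.any():
        cols = np.nonzero(mono)[0]
        hap[:, cols] = (rng.random((n, cols.size)) < freqs[None, cols]).astype(np.uint8)
        s = hap[:, cols].sum(axis=0)
        mono[cols] = (s == 0) | (s == n)
    return hap


class _CrossoverPlan:
    """Sampled meiosis patterns for a batch of gametes.

    Each chromosome is 1 Morgan: crossover counts are Poisson(1) per gamete,
    breakpoint positions uniform over the marker grid, and the starting
    haplotype is chosen at random.  Storing only (start, breakpoints) lets
    the caller evaluate the gamete at an arbitrary subset of loci — all of
    them, or just the QTLs — without materializing the full genome.
    """

    def __init__(self, n: int, cfg: SimConfig, rng: np.random.Generator):
        self.n = n
        self.cfg = cfg
        self.start = rng.integers(0, 2, size=(cfg.chromosomes, n)).astype(np.int32)
        self.breaks = []
        L = cfg.snps_per_chrom
        for _ in range(cfg.chromosomes):
            n_co = rng.poisson(1.0, size=n)
            kmax = max(1, int(n_co.max()))
            pos = np.full((n, kmax), L, dtype=np.int32)  # pad past chromosome end
            total = int(n_co.sum())
            if total:
                rows = np.repeat(np.arange(n), n_co)
                offs = np.zeros(n + 1, dtype=np.int64)
                np.cumsum(n_co, out=offs[1:])
                col = np.arange(total) - offs[rows]
                pos[rows, col] = rng.integers(0, L, size=total)
            self.breaks.append(pos)

    def use_b(self, chrom: int, cols: np.ndarray, rows=None) -> np.ndarray:
        """0/1 indicator of the second haplotype at ``cols`` (chromosome-local)."""
        pos = self.breaks[chrom] if rows is None else self.breaks[chrom][rows]
        start = self.start[chrom] if rows is None else self.start[chrom][rows]
        cnt = (pos[:, :, None] <= cols[None, None, :]).sum(axis=1)
        return (start[:, None] + cnt) % 2

    def realize(self, hap_a: np.ndarray, hap_b: np.ndarray, rows=None) -> np.ndarray:
        """Materialize gametes; ``hap_a``/``hap_b`` already match ``rows``."""
        L = self.cfg.snps_per_chrom
        out = np.empty_like(hap_a)
        cols = np.arange(L)
        for c in range(self.cfg.chromosomes):
            sl = slice(c * L, (c + 1) * L)
            ub = self.use_b(c, cols, rows)
            out[:, sl] = np.where(ub == 1, hap_b[:, sl], hap_a[:, sl])
        return out


def cross_and_dh(parent1: np.ndarray, parent2: np.ndarray, n_offspring: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Doubled-haploid offspring of a biparental cross (haplotypes, 0/1).

    Both parents are fully homozygous, so the F1 carries one haplotype from
    each; every DH is a single recombinant F1 gamete with its genome doubled
    (genotype code = 2 x haplotype, never heterozygous).
    """
    if parent1.shape != parent2.shape:
        raise ValueError("parents must share the marker map")
    plan = _CrossoverPlan(n_offspring, cfg, rng)
    ha = np.ascontiguousarray(np.broadcast_to(parent1, (n_offspring, parent1.size)))
    hb = np.ascontiguousarray(np.broadcast_to(parent2, (n_offspring, parent2.size)))
    return plan.realize(ha, hb)


class _Architecture:
    """QTL placement and the founder-standardized genetic-value map."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator, founder_hap: np.ndarray):
        idx = []
        for c in range(cfg.chromosomes):
            pos = rng.choice(cfg.snps_per_chrom, size=cfg.qtl_per_chrom, replace=False)
            idx.append(np.sort(pos) + c * cfg.snps_per_chrom)
        self.qtl_idx = np.concatenate(idx)
        if cfg.directional_effects:
            self.effects = rng.normal(cfg.trait_mean, np.sqrt(cfg.trait_var), size=self.qtl_idx.size)
        else:
            self.effects = rng.standard_normal(self.qtl_idx.size)
        raw = (2.0 * founder_hap[:, self.qtl_idx]) @ self.effects
        self.center = float(raw.mean())
        sd = float(raw.std())
        self.scale = sd if sd > 0 else 1.0

    def breeding_values(self, hap: np.ndarray) -> np.ndarray:
        raw = (2.0 * hap[:, self.qtl_idx]) @ self.effects
        return (raw - self.center) / self.scale

    def breeding_values_at_qtl(self, hap_qtl: np.ndarray) -> np.ndarray:
        """As above but from haplotypes already restricted to the QTL columns."""
        raw = (2.0 * hap_qtl) @ self.effects
        return (raw - self.center) / self.scale

    def table(self, cfg: SimConfig, marker_ids: list[str]) -> pd.DataFrame:
        chrom = self.qtl_idx // cfg.snps_per_chrom + 1
        pos = self.qtl_idx % cfg.snps_per_chrom + 1
        return pd.DataFrame(
            {
                "marker": [marker_ids[j] for j in self.qtl_idx],
                "chrom": chrom,
                "pos": pos,
                "effect": self.effects,
            }
        )


def _stage_phenotype(g: np.ndarray, h2: float, gxe_var: float, rng: np.random.Generator) -> np.ndarray:
    """Phenotype = g + GxE deviation + stage error, h2 against founder varG = 1."""
    var_e = max((1.0 - h2) / h2 - gxe_var, 0.0)
    noise = rng.normal(0.0, np.sqrt(gxe_var + var_e), size=g.size)
    return g + noise


def run_breeding_program(cfg: SimConfig) -> SimulatedDataset:
    """Run burn-in plus recorded years and return the recorded PYT pool."""
    rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(cfg, rng)
    arch = _Architecture(cfg, rng, founders)
    marker_ids = _marker_ids(cfg)

    parents = founders
    total_years = cfg.burn_in_years + cfg.recorded_years
    rec_geno, rec_bv, rec_phen, rec_year, rec_ids = [], [], [], [], []

    for year in range(1, total_years + 1):
        n_par = parents.shape[0]
        # random biparental crosses among current parents
        p1 = rng.integers(0, n_par, size=cfg.families)
        shift = rng.integers(1, n_par, size=cfg.families)
        p2 = (p1 + shift) % n_par  # always two distinct parents
        fam = np.repeat(np.arange(cfg.families), cfg.family_size)
        n_off = fam.size
        plan = _CrossoverPlan(n_off, cfg, rng)

        # breeding values of all offspring from the QTL columns only
        L = cfg.snps_per_chrom
        hap_qtl = np.empty((n_off, arch.qtl_idx.size), dtype=np.uint8)
        col0 = 0
        for c in range(cfg.chromosomes):
            on_c = arch.qtl_idx[(arch.qtl_idx >= c * L) & (arch.qtl_idx < (c + 1) * L)]
            if on_c.size == 0:
                continue
            pa_q = parents[:, on_c]
            ha_q, hb_q = pa_q[p1][fam], pa_q[p2][fam]
            ub = plan.use_b(c, on_c - c * L)
            hap_qtl[:, col0 : col0 + on_c.size] = np.where(ub == 1, hb_q, ha_q)
            col0 += on_c.size
        bv = arch.breeding_values_at_qtl(hap_qtl)

        # nursery: within-family selection on low-heritability phenotypes
        nursery = _stage_phenotype(bv, cfg.h2_nursery, cfg.gxe_var, rng)
        by_family = nursery.reshape(cfg.families, cfg.family_size)
        top = np.argsort(by_family, axis=1)[:, ::-1][:, : cfg.select_per_family]
        pyt_rows = (top + np.arange(cfg.families)[:, None] * cfg.family_size).ravel()

        # materialize full genomes only for the selected lines
        sel_fam = fam[pyt_rows]
        pyt_hap = plan.realize(parents[p1[sel_fam]], parents[p2[sel_fam]], rows=pyt_rows)
        pyt_bv = bv[pyt_rows]
        pyt_phen = _stage_phenotype(pyt_bv, cfg.h2_pyt, cfg.gxe_var, rng)

        ayt_rows = np.argsort(pyt_phen)[::-1][: cfg.ayt_size]
        ayt_hap, ayt_bv = pyt_hap[ayt_rows], pyt_bv[ayt_rows]
        ayt_phen = _stage_phenotype(ayt_bv, cfg.h2_ayt, cfg.gxe_var, rng)

        eyt_rows = np.argsort(ayt_phen)[::-1][: cfg.eyt_size]
        eyt_hap = ayt_hap[eyt_rows]
        _ = _stage_phenotype(ayt_bv[eyt_rows], cfg.h2_eyt, cfg.gxe_var, rng)  # variety trial

        if year > cfg.burn_in_years:
            ry = year - cfg.burn_in_years
            rec_geno.append(pyt_hap)
            rec_bv.append(pyt_bv)
            rec_phen.append(pyt_phen)
            rec_year.append(np.full(pyt_rows.size, ry))
            rec_ids.extend(f"Y{ry:02d}_L{i:04d}" for i in range(pyt_rows.size))

        # recycle parents: EYT + AYT, topped up from the best remaining PYT
        new_parents = [eyt_hap, ayt_hap[np.setdiff1d(np.arange(cfg.ayt_size), eyt_rows)]]
        pool = np.vstack(new_parents)
        if pool.shape[0] < cfg.founders:
            extra_rows = np.argsort(pyt_phen)[::-1][cfg.ayt_size : cfg.ayt_size + cfg.founders - pool.shape[0]]
            pool = np.vstack([pool, pyt_hap[extra_rows]])
        parents = pool[: cfg.founders]

    return SimulatedDataset(
        genotypes=(2 * np.vstack(rec_geno)).astype(np.uint8),
        ids=rec_ids,
        marker_ids=marker_ids,
        breeding_values=np.concatenate(rec_bv),
        phenotypes=np.concatenate(rec_phen),
        year=np.concatenate(rec_year),
        qtl=arch.table(cfg, marker_ids),
    )


def sample_dataset(ds: SimulatedDataset, n: int, seed: int = 0) -> tuple[GenotypeMatrix, TraitVector]:
    """Uniformly sample ``n`` PYT lines as pipeline-ready inputs.

    Genotype codes {0,1,2} are rescaled to allele proportions {0, 0.5, 1}
    and the PYT phenotype is min-max normalized.
    """
    if n > ds.n:
        raise ValueError(f"requested {n} individuals but only {ds.n} available")
    rng = np.random.default_rng(seed)
    rows = rng.choice(ds.n, size=n, replace=False)
    ids = [ds.ids[i] for i in rows]
    g = GenotypeMatrix(ds.genotypes[rows].astype(float) / 2.0, ids, list(ds.marker_ids))
    y = TraitVector(ids, ds.phenotypes[rows], name="yield")
    y.normalized = minmax_normalize(y.values)
    return g, y
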