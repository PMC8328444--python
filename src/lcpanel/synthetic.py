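"""Synthetic cod-like low-coverage sequencing data with planted signals.

The generator emulates the data regime of a two-population marine fish
study at desk scale: two weakly differentiated populations (genome-wide
baseline FST around 0.006), one chromosome carrying an inversion-like block
of tightly linked, strongly differentiated sites (FST around 0.3 — the LG18
analogue), a handful of isolated minor FST peaks, and an XY-like
sex-determining region on another chromosome (the LG11 analogue) where
males are heterozygous for a male-specific allele and females homozygous.

Population divergence is realized with the Balding-Nichols model: given an
ancestral frequency p and a differentiation level F, each population's
frequency is an independent draw from Beta(p(1-F)/F, (1-p)(1-F)/F). The
inversion analogue is modeled as a single latent biallelic "arrangement"
per individual whose frequency diverges by the block FST; every block site
copies the arrangement genotype, which reproduces the clustered-FST and
high-LD signature of a real inversion without simulating recombination
suppression.

Sequencing is modeled as Poisson read depth per individual-site with a
per-individual mean coverage drawn log-uniformly from a configured range
(default 0.5-3.6x, the coverage regime this generator emulates), and a
symmetric two-allele base-calling error: each read reports the true allele
with probability 1-eps and the other allele with probability eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Truth",
    "ReadCountMatrix",
    "sample_divergent_freqs",
    "simulate_genotypes",
    "simulate_sex_region",
    "simulate_reads",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions.

    FST values are Balding-Nichols differentiation parameters in [0, 1);
    ``coverage_range`` is the (low, high) of the log-uniform per-individual
    mean coverage; ``error_rate`` is the symmetric two-allele read error.
    ``sex_leak`` is the probability that a male is erroneously homozygous at
    a sex site, so sex assignment is not trivially perfect.
    """

    n_pop1: int = 100
    n_pop2: int = 100
    n_chrom: int = 4
    sites_per_chrom: int = 500
    chrom_length_bp: int = 1_000_000
    baseline_fst: float = 0.006
    block_chrom: int = 1          # 0-based chromosome index of the inversion analogue
    block_span_bp: tuple = (400_000, 600_000)
    block_fst: float = 0.3
    n_block_sites: int = 25
    n_minor_peaks: int = 5
    peak_fst: float = 0.1
    sex_region_chrom: int = 2     # LG11 analogue
    sex_region_span_bp: tuple = (100_000, 200_000)
    n_sex_sites: int = 20
    sex_leak: float = 0.02
    coverage_range: tuple = (0.5, 3.6)
    error_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_pop1, self.n_pop2, self.n_chrom, self.sites_per_chrom,
               self.chrom_length_bp) <= 0:
            raise ValueError("all counts must be positive")
        for f in (self.baseline_fst, self.block_fst, self.peak_fst):
            if not (0.0 <= f < 1.0):
                raise ValueError(f"fst value {f} outside [0, 1)")
        if not (0.0 < self.error_rate < 0.5):
            raise ValueError("error_rate must be in (0, 0.5)")
        if not (0.0 <= self.sex_leak < 1.0):
            raise ValueError("sex_leak must be in [0, 1)")
        spans = []
        if self.n_block_sites > 0:
            if not (0 <= self.block_chrom < self.n_chrom):
                raise ValueError("block_chrom out of range")
            spans.append(self.block_span_bp)
        if self.n_sex_sites > 0:
            if not (0 <= self.sex_region_chrom < self.n_chrom):
                raise ValueError("sex_region_chrom out of range")
            spans.append(self.sex_region_span_bp)
        for lo, hi in spans:
            if not (1 <= lo < hi <= self.chrom_length_bp):
                raise ValueError("region span must fit inside its chromosome")
        if self.n_block_sites + (self.block_chrom == self.sex_region_chrom) * \
                self.n_sex_sites > self.sites_per_chrom:
            raise ValueError("planted sites exceed sites_per_chrom")

    @property
    def n_ind(self) -> int:
        return self.n_pop1 + self.n_pop2

    def chrom_names(self) -> list:
        return [f"LG{c + 1:02d}" for c in range(self.n_chrom)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Truth:
    """Ground truth for recovery tests.

    ``sites``: chrom, pos, class (neutral/block/peak/sex), ancestral and
    per-population frequencies. ``individuals``: population, sex (0=female,
    1=male), target mean coverage.
    """

    sites: pd.DataFrame
    individuals: pd.DataFrame


@dataclass
class ReadCountMatrix:
    """Allele-resolved read counts, shape (n_sites, n_ind, 2): reads
    supporting allele1 (axis -1 index 0) and allele2 (index 1)."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 2:
            raise ValueError("counts must have shape (n_sites, n_ind, 2)")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=2)


def sample_divergent_freqs(p_anc: float, fst: float, rng: np.random.Generator):
    """Draw two population frequencies around ``p_anc`` under Balding-Nichols.

    For fst > 0 both frequencies are independent Beta(p(1-F)/F, (1-p)(1-F)/F)
    draws; fst = 0 degenerates to both equalling ``p_anc``.
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if np.any((p_anc <= 0) | (p_anc >= 1)):
        raise ValueError("p_anc must be in (0, 1)")
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must be in [0, 1)")
    if fst == 0.0:
        return p_anc.copy(), p_anc.copy()
    scale = (1.0 - fst) / fst
    a = p_anc * scale
    b = (1.0 - p_anc) * scale
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    return p1, p2


def exact_divergent_freqs(p_anc, fst: float, rng: np.random.Generator):
    """Population frequencies realizing a target Hudson FST exactly.

    Unlike the Balding-Nichols draw (whose realized per-locus divergence is
    itself random, often near zero), this places the two frequencies
    symmetrically around ``p_anc`` at the offset d that solves
    (2d)^2 / (2 [p(1-p) + d^2]) = fst, with a random sign — so every
    planted outlier locus carries the nominal effect size. Used for the
    isolated high-FST peak sites, where "FST" is a per-locus effect size
    rather than a distribution parameter.
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must be in [0, 1)")
    d = np.sqrt(fst * p_anc * (1 - p_anc) / (2.0 - fst))
    sign = np.where(rng.random(p_anc.shape) < 0.5, 1.0, -1.0)
    p1 = np.clip(p_anc + sign * d, 1e-3, 1 - 1e-3)
    p2 = np.clip(p_anc - sign * d, 1e-3, 1 - 1e-3)
    return p1, p2


def _site_positions(cfg: SimConfig, rng: np.random.Generator):
    """Place sites per chromosome; planted classes get reserved positions
    inside their spans so class counts match the config exactly."""
    chroms, positions, classes = [], [], []
    names = cfg.chrom_names()
    for c in range(cfg.n_chrom):
        n_block = cfg.n_block_sites if c == cfg.block_chrom else 0
        n_sex = cfg.n_sex_sites if c == cfg.sex_region_chrom else 0
        n_rest = cfg.sites_per_chrom - n_block - n_sex
        cls = []
        pos = []
        if n_block:
            lo, hi = cfg.block_span_bp
            pos.append(rng.choice(np.arange(lo, hi + 1), size=n_block, replace=False))
            cls += ["block"] * n_block
        if n_sex:
            lo, hi = cfg.sex_region_span_bp
            pos.append(rng.choice(np.arange(lo, hi + 1), size=n_sex, replace=False))
            cls += ["sex"] * n_sex
        # remaining sites anywhere outside the planted spans
        forbidden = []
        if n_block:
            forbidden.append(cfg.block_span_bp)
        if n_sex:
            forbidden.append(cfg.sex_region_span_bp)
        free = np.ones(cfg.chrom_length_bp, dtype=bool)
        for lo, hi in forbidden:
            free[lo - 1:hi] = False
        candidates = np.flatnonzero(free) + 1
        pos.append(rng.choice(candidates, size=n_rest, replace=False))
        cls += ["neutral"] * n_rest
        pos = np.concatenate(pos)
        order = np.argsort(pos, kind="stable")
        chroms.extend([names[c]] * cfg.sites_per_chrom)
        positions.append(pos[order])
        classes.extend([cls[i] for i in order])
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": np.concatenate(positions), "class": classes}
    )
    # promote random neutral sites to isolated minor peaks
    neutral_idx = sites.index[sites["class"] == "neutral"].to_numpy()
    if cfg.n_minor_peaks > 0:
        peak_idx = rng.choice(neutral_idx, size=cfg.n_minor_peaks, replace=False)
        sites.loc[peak_idx, "class"] = "peak"
    return sites


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator):
    """Draw genotypes for every individual at every site.

    Returns ``(genotypes, truth)`` where ``genotypes`` has shape
    (n_sites, n_ind) and counts copies of allele2. Neutral/peak sites are
    independent Hardy-Weinberg draws from Balding-Nichols population
    frequencies; all block sites copy one latent per-individual arrangement
    genotype; sex sites follow the XY model of :func:`simulate_sex_region`.
    """
    cfg.validate()
    sites = _site_positions(cfg, rng)
    n_sites = len(sites)
    n = cfg.n_ind
    population = np.repeat([0, 1], [cfg.n_pop1, cfg.n_pop2])
    sexes = (rng.random(n) < 0.5).astype(int)  # 1 = male

    cls = sites["class"].to_numpy()
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    p1 = np.empty(n_sites)
    p2 = np.empty(n_sites)
    neutral = cls == "neutral"
    if neutral.any():
        p1[neutral], p2[neutral] = sample_divergent_freqs(
            p_anc[neutral], cfg.baseline_fst, rng
        )
    peak = cls == "peak"
    if peak.any():
        # planted outliers carry the nominal effect size exactly; keep the
        # ancestral frequency mid-range so both populations stay polymorphic
        p_anc[peak] = rng.uniform(0.25, 0.75, size=int(peak.sum()))
        p1[peak], p2[peak] = exact_divergent_freqs(p_anc[peak], cfg.peak_fst, rng)

    genotypes = np.zeros((n_sites, n), dtype=np.int8)
    hw = (cls == "neutral") | (cls == "peak")
    pmat = np.where(population[None, :] == 0, p1[:, None], p2[:, None])
    genotypes[hw] = rng.binomial(2, pmat[hw]).astype(np.int8)

    block = cls == "block"
    if block.any():
        q_anc = rng.uniform(0.3, 0.7)
        q1, q2 = sample_divergent_freqs(np.array(q_anc), cfg.block_fst, rng)
        q = np.where(population == 0, float(q1), float(q2))
        arrangement = rng.binomial(2, q).astype(np.int8)  # one latent locus
        genotypes[block] = arrangement[None, :]
        p_anc[block] = q_anc
        p1[block] = float(q1)
        p2[block] = float(q2)

    sex = cls == "sex"
    if sex.any():
        genotypes[sex] = simulate_sex_region(cfg, sexes, rng)
        # allele2 is the male-specific variant: freq ~ 0.25 in males pooled
        p_anc[sex] = np.nan
        p1[sex] = np.nan
        p2[sex] = np.nan

    coverage = np.exp(
        rng.uniform(np.log(cfg.coverage_range[0]), np.log(cfg.coverage_range[1]), size=n)
    )
    truth = Truth(
        sites=sites.assign(p_anc=p_anc, p_pop1=p1, p_pop2=p2),
        individuals=pd.DataFrame(
            {
                "individual_id": [f"Ind{i}" for i in range(n)],
                "population": population,
                "sex": sexes,
                "target_coverage": coverage,
            }
        ),
    )
    return genotypes, truth


def simulate_sex_region(cfg: SimConfig, sexes: np.ndarray, rng: np.random.Generator):
    """XY-like genotypes at the sex sites.

    Allele2 is the male-specific (Y-linked) variant. Females are homozygous
    for the X variant (genotype 0). A male is heterozygous (genotype 1) with
    probability 1 - sex_leak and erroneously homozygous otherwise, so the
    planted signal is strong but not a perfect separator.
    """
    sexes = np.asarray(sexes)
    g = np.zeros((cfg.n_sex_sites, len(sexes)), dtype=np.int8)
    male = sexes == 1
    het = rng.random((cfg.n_sex_sites, int(male.sum()))) >= cfg.sex_leak
    g[:, male] = het.astype(np.int8)
    return g


def simulate_reads(genotypes: np.ndarray, cfg: SimConfig,
                   rng: np.random.Generator, coverage=None) -> ReadCountMatrix:
    """Low-coverage read counts given true genotypes.

    Depth at (site, individual) is Poisson with the individual's mean
    coverage (drawn log-uniformly from ``cfg.coverage_range`` unless
    ``coverage`` supplies per-individual means). Each read reports the true
    allele with probability 1 - error_rate, the other allele otherwise;
    depth 0 means missing.
    """
    n_sites, n = genotypes.shape
    if coverage is None:
        coverage = np.exp(
            rng.uniform(np.log(cfg.coverage_range[0]), np.log(cfg.coverage_range[1]), size=n)
        )
    coverage = np.asarray(coverage, dtype=float)
    depth = rng.poisson(np.broadcast_to(coverage[None, :], (n_sites, n)))
    eps = cfg.error_rate
    # probability a read reports allele2 given g copies of allele2
    p_read2 = genotypes / 2.0 * (1 - eps) + (1 - genotypes / 2.0) * eps
    n2 = rng.binomial(depth, p_read2)
    counts = np.stack([depth - n2, n2], axis=2).astype(np.int32)
    return ReadCountMatrix(counts)


def simulate_dataset(cfg: SimConfig):
    """Full generator: genotypes, truth, reads and allele codes, all from
    one seeded RNG. Returns (reads, genotypes, truth, site table with
    allele1/allele2 base codes)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genotypes, truth = simulate_genotypes(cfg, rng)
    reads = simulate_reads(
        genotypes, cfg, rng, coverage=truth.individuals["target_coverage"].to_numpy()
    )
    n_sites = len(truth.sites)
    allele1 = rng.integers(0, 4, size=n_sites)
    allele2 = (allele1 + rng.integers(1, 4, size=n_sites)) % 4
    sites = truth.sites[["chrom", "pos"]].copy()
    sites["allele1"] = allele1
    sites["allele2"] = allele2
    return reads, genotypes, truth, sites
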