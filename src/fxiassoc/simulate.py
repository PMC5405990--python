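"""Synthetic cohorts for a two-locus targeted-sequencing study.

Generates biallelic genotypes with block-LD structure (a latent Gaussian
copula with AR(1) correlation inside each block, thresholded at the MAF
quantile to produce haplotypes), an FXI-activity-like phenotype with age and
sex covariate effects plus a configurable set of additive causal variants,
and the phenotype-tail discovery design used to pick a sequencing
subsample.

Randomness: a single integer seed drives everything through named
``numpy.random.SeedSequence`` substreams (``genotypes``, ``positions``,
``alleles``, ``covariates``, ``noise``, ``tails``), so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .variants import GenotypeMatrix, VariantRecord

__all__ = [
    "LocusSpec",
    "SimulationConfig",
    "TailDesign",
    "TailShortfallError",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_study_cohort",
    "select_tails",
    "detection_power",
    "write_vcf",
    "default_study_config",
    "annotate_variants_synthetic",
]

# Printed GRCh37 spans of the two sequenced loci.
KNG1_SPAN = ("KNG1", "chr3", 186_435_098, 186_460_678)
F11_SPAN = ("F11", "chr4", 187_187_118, 187_210_835)

_SUBSTREAMS = ("genotypes", "positions", "alleles", "covariates", "noise", "tails")


def _rng_for(seed: int, stage: str) -> np.random.Generator:
    key = _SUBSTREAMS.index(stage)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class LocusSpec:
    """One locus: a 1-based inclusive genomic interval plus a per-variant
    target MAF spectrum partitioned into AR(1) LD blocks.

    ``ld_blocks`` is a list of ``(n_variants, rho)`` pairs partitioning the
    MAF vector; ``rho`` is the target correlation between adjacent allele
    indicators inside the block (0 <= rho < 1), realised through a
    tetrachoric-calibrated latent AR(1) chain.
    """

    name: str
    chrom: str
    start_bp: int
    end_bp: int
    mafs: tuple[float, ...]
    ld_blocks: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.name}: start_bp > end_bp")
        mafs = np.asarray(self.mafs, dtype=float)
        if mafs.size and (mafs.min() < 0 or mafs.max() > 0.5):
            raise ValueError(f"{self.name}: target MAFs must be in [0, 0.5]")
        blocks = self.ld_blocks or ((len(self.mafs), 0.0),)
        object.__setattr__(self, "ld_blocks", tuple(blocks))
        if sum(b[0] for b in self.ld_blocks) != len(self.mafs):
            raise ValueError(f"{self.name}: LD blocks must partition the MAF vector")
        for size, rho in self.ld_blocks:
            if size < 1 or not 0 <= rho < 1:
                raise ValueError(f"{self.name}: invalid LD block ({size}, {rho})")
        if len(self.mafs) > self.end_bp - self.start_bp + 1:
            raise ValueError(f"{self.name}: more variants than positions")

    @property
    def n_variants(self) -> int:
        return len(self.mafs)


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative model for one cohort.

    Phenotype model:
    ``y_i = mean + beta_age * age_i + beta_sex * sex_i + sum_j beta_j g_ij + eps_i``
    with ``eps ~ Normal(0, resid_sd^2)``. ``causal_betas`` maps a global
    variant index (column order across loci) to its per-allele effect in
    phenotype units (% activity per ALT allele). Age is Uniform(18, 80)
    years and sex Bernoulli(0.5) coded 0 = female, 1 = male, unless the
    ranges are overridden.
    """

    n_individuals: int
    loci: tuple[LocusSpec, ...]
    causal_betas: dict[int, float] = field(default_factory=dict)
    beta_age: float = 0.0
    beta_sex: float = 0.0
    mean: float = 120.0
    resid_sd: float = 30.0
    age_range: tuple[float, float] = (18.0, 80.0)
    male_prob: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.resid_sd <= 0:
            raise ValueError("resid_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        m = sum(l.n_variants for l in self.loci)
        for j in self.causal_betas:
            if not 0 <= j < m:
                raise ValueError(f"causal index {j} out of range for {m} variants")

    @property
    def n_variants(self) -> int:
        return sum(l.n_variants for l in self.loci)


@dataclass(frozen=True)
class TailDesign:
    """Discovery subsample taken from both phenotype tails."""

    n_low: int = 20
    low_range: tuple[float, float] = (36.0, 80.0)
    n_high: int = 20
    high_range: tuple[float, float] = (158.0, 250.0)

    def __post_init__(self) -> None:
        if self.low_range[1] >= self.high_range[0]:
            raise ValueError("tail ranges must not overlap")
        if self.n_low < 0 or self.n_high < 0:
            raise ValueError("tail counts must be non-negative")


class TailShortfallError(ValueError):
    """Raised when a phenotype range holds fewer individuals than requested."""


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _bvn_p11(a: float, b: float, r: float) -> float:
    """P(Z1 < a, Z2 < b) for standard bivariate normal with correlation r,
    by 64-node Gauss-Legendre quadrature over x in (-8, a)."""
    lo = -8.0
    if a <= lo:
        return 0.0
    x = 0.5 * (a - lo) * _GL_NODES + 0.5 * (a + lo)
    w = 0.5 * (a - lo) * _GL_WEIGHTS
    inner = stats.norm.cdf((b - r * x) / np.sqrt(max(1e-12, 1.0 - r * r)))
    return float((w * stats.norm.pdf(x) * inner).sum())


@lru_cache(maxsize=4096)
def _latent_rho(p1: float, p2: float, rho: float) -> float:
    """Latent Gaussian correlation whose thresholded binary variables (allele
    frequencies p1, p2) have Pearson correlation ``rho`` (tetrachoric
    inversion). Clipped to the maximum achievable when ``rho`` is infeasible
    for the given frequency pair."""
    if rho == 0.0 or min(p1, p2) <= 0.0:
        return rho
    a, b = stats.norm.ppf(p1), stats.norm.ppf(p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    target = rho * denom + p1 * p2

    def f(r: float) -> float:
        return _bvn_p11(a, b, r) - target

    hi = 0.9995
    if f(hi) <= 0:
        return hi
    return float(brentq(f, 0.0, hi, xtol=1e-6))


def _simulate_haplotype_block(
    rng: np.random.Generator, n_hap: int, mafs: np.ndarray, rho: float
) -> np.ndarray:
    """Latent AR(1) Gaussians thresholded at the MAF quantile -> 0/1 alleles.

    ``rho`` is the target correlation of adjacent *allele indicators*; the
    latent AR coefficient is found per adjacent pair by tetrachoric
    inversion, so thresholding does not attenuate the requested LD.
    """
    m = mafs.size
    e = rng.standard_normal((n_hap, m))
    z = np.empty_like(e)
    z[:, 0] = e[:, 0]
    for j in range(1, m):
        r = _latent_rho(round(float(mafs[j - 1]), 6), round(float(mafs[j]), 6), rho)
        z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * e[:, j]
    thresholds = stats.norm.ppf(mafs)  # maf 0 -> -inf -> no minor alleles
    return (z < thresholds).astype(float)


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Draw genotypes for every locus of ``config``.

    Two haplotypes are generated per individual and summed to dosages, so
    sites are in Hardy-Weinberg proportions and the realized sample MAF
    converges to the target as n grows. Within-block LD follows the latent
    AR(1) correlation. Positions are drawn uniformly without replacement
    within each locus interval and sorted.
    """
    geno_rng = _rng_for(config.seed, "genotypes")
    pos_rng = _rng_for(config.seed, "positions")
    allele_rng = _rng_for(config.seed, "alleles")
    n = config.n_individuals

    columns: list[np.ndarray] = []
    records: list[VariantRecord] = []
    bases = np.array(list("ACGT"))
    for locus in config.loci:
        mafs = np.asarray(locus.mafs, dtype=float)
        offset = 0
        dosage_cols = []
        for size, rho in locus.ld_blocks:
            block_mafs = mafs[offset : offset + size]
            h1 = _simulate_haplotype_block(geno_rng, n, block_mafs, rho)
            h2 = _simulate_haplotype_block(geno_rng, n, block_mafs, rho)
            dosage_cols.append(h1 + h2)
            offset += size
        dosages = np.hstack(dosage_cols) if dosage_cols else np.empty((n, 0))
        positions = np.sort(
            pos_rng.choice(
                np.arange(locus.start_bp, locus.end_bp + 1),
                size=locus.n_variants,
                replace=False,
            )
        )
        for k, pos in enumerate(positions):
            ref, alt = allele_rng.choice(bases, size=2, replace=False)
            records.append(
                VariantRecord(
                    chrom=locus.chrom, pos=int(pos), ref=str(ref), alt=str(alt),
                    gene=locus.name,
                )
            )
            columns.append(dosages[:, k])

    mat = np.column_stack(columns) if columns else np.empty((n, 0))
    if config.missing_rate > 0:
        mask = geno_rng.random(mat.shape) < config.missing_rate
        # never blank out a whole column
        for j in np.where(mask.all(axis=0))[0]:
            mask[geno_rng.integers(0, mat.shape[0]), j] = False
        mat = np.where(mask, np.nan, mat)
    individual_ids = [f"ind{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(mat, individual_ids, [r.variant_id for r in records])
    return gm, records


def simulate_phenotype(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> pd.DataFrame:
    """Phenotype/covariate table with columns id, fxi_pct, age, sex.

    The linear predictor is additive in dosage; missing causal dosages
    contribute their variant's mean dosage (mean imputation keeps the
    predictor defined for every individual).
    """
    if genotypes.n_individuals != config.n_individuals:
        raise ValueError(
            f"genotypes have {genotypes.n_individuals} individuals, "
            f"config says {config.n_individuals}"
        )
    cov_rng = _rng_for(config.seed, "covariates")
    noise_rng = _rng_for(config.seed, "noise")
    n = config.n_individuals
    age = cov_rng.uniform(*config.age_range, size=n)
    sex = (cov_rng.random(n) < config.male_prob).astype(float)
    y = config.mean + config.beta_age * age + config.beta_sex * sex
    for j, beta in config.causal_betas.items():
        g = genotypes.dosages[:, j]
        if np.isnan(g).any():
            g = np.where(np.isnan(g), np.nanmean(g), g)
        y = y + beta * g
    y = y + noise_rng.normal(0.0, config.resid_sd, size=n)
    return pd.DataFrame(
        {"id": genotypes.individual_ids, "fxi_pct": y, "age": age, "sex": sex}
    )


def select_tails(
    phenotypes: pd.DataFrame, design: TailDesign, seed: int = 0
) -> list[str]:
    """Pick ``n_low`` ids from the low range and ``n_high`` from the high
    range, uniformly at random within each range; deterministic given seed."""
    rng = _rng_for(seed, "tails")
    ids: list[str] = []
    for n_want, (lo, hi), label in (
        (design.n_low, design.low_range, "low"),
        (design.n_high, design.high_range, "high"),
    ):
        pool = phenotypes.loc[
            (phenotypes["fxi_pct"] >= lo) & (phenotypes["fxi_pct"] <= hi), "id"
        ].tolist()
        if len(pool) < n_want:
            raise TailShortfallError(
                f"{label} tail [{lo}, {hi}]: requested {n_want}, "
                f"only {len(pool)} individuals in range"
            )
        ids.extend(sorted(rng.choice(pool, size=n_want, replace=False).tolist()))
    return ids


def simulate_study_cohort(
    config: SimulationConfig,
    design: TailDesign = TailDesign(),
    n_cohort: int = 110,
    pool_size: int = 935,
) -> tuple[GenotypeMatrix, list[VariantRecord], pd.DataFrame, list[str]]:
    """Simulate the full study sampling design.

    A pool of ``pool_size`` unrelated individuals (defaults to the size of
    the project the study drew from) is simulated under ``config``; the
    phenotype-tail discovery subjects are selected per ``design``, and the
    cohort is completed to ``n_cohort`` with a random draw from the
    remainder. Returns (genotypes, variants, phenotypes, discovery_ids)
    restricted to the cohort.
    """
    if design.n_low + design.n_high > n_cohort:
        raise ValueError("tail design larger than cohort")
    pool_config = SimulationConfig(
        n_individuals=pool_size,
        loci=config.loci,
        causal_betas=config.causal_betas,
        beta_age=config.beta_age,
        beta_sex=config.beta_sex,
        mean=config.mean,
        resid_sd=config.resid_sd,
        age_range=config.age_range,
        male_prob=config.male_prob,
        missing_rate=config.missing_rate,
        seed=config.seed,
    )
    genotypes, variants = simulate_genotypes(pool_config)
    phenotypes = simulate_phenotype(genotypes, pool_config)
    discovery = select_tails(phenotypes, design, seed=config.seed)
    rng = _rng_for(config.seed, "tails")
    rest = [i for i in phenotypes["id"] if i not in set(discovery)]
    n_fill = n_cohort - len(discovery)
    if n_fill > len(rest):
        raise ValueError("pool too small for requested cohort")
    fill = sorted(rng.choice(rest, size=n_fill, replace=False).tolist())
    cohort_ids = sorted(discovery + fill)
    gm = genotypes.subset_individuals(cohort_ids)
    ph = (
        phenotypes.set_index("id").loc[cohort_ids].reset_index()
    )
    return gm, variants, ph, discovery


def detection_power(maf: float, n: int) -> float:
    """Probability that >= 1 copy of an allele at frequency ``maf`` appears
    among the ``2n`` chromosomes of ``n`` diploid individuals:
    ``1 - (1 - maf)^(2n)``."""
    if not 0 <= maf <= 0.5:
        raise ValueError(f"maf must be in [0, 0.5], got {maf}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - (1.0 - maf) ** (2 * n)


def write_vcf(
    genotypes: GenotypeMatrix, variants: list[VariantRecord], path: str
) -> None:
    """Write a minimal VCF 4.2 with GT fields (unphased, dosage-faithful)."""
    if len(variants) != genotypes.n_variants:
        raise ValueError("variant list does not match genotype columns")
    idx = sorted(range(len(variants)), key=lambda k: (variants[k].chrom, variants[k].pos))
    gt_for = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = {}
        for v in variants:
            if v.chrom not in seen:
                seen[v.chrom] = True
                fh.write(f"##contig=<ID={v.chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for k in idx:
            v = variants[k]
            col = genotypes.dosages[:, genotypes.variant_ids.index(v.variant_id)]
            gts = "\t".join(
                "./." if np.isnan(d) else gt_for[float(d)] for d in col
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.dbsnp_id or '.'}\t{v.ref}\t{v.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Study-shaped default simulation: two loci at their printed GRCh37
    spans with 504 and 258 variants, a mixed MAF spectrum (about 41% of
    targets at or above 10%), AR(1) LD blocks of a dozen variants with
    alternating strength, one strong common causal variant per locus
    region plus a cluster of three low-frequency causal variants, age and
    sex covariate effects, and a residual SD that puts roughly 95% of the
    cohort inside the 55-185% clinical reference range.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(99,)))

    def spectrum(m: int) -> tuple[float, ...]:
        common = rng.random(m) < 0.41
        mafs = np.where(
            common,
            rng.uniform(0.10, 0.50, size=m),
            10 ** rng.uniform(np.log10(0.004), np.log10(0.095), size=m),
        )
        return tuple(float(x) for x in mafs)

    def blocks(m: int) -> tuple[tuple[int, float], ...]:
        rhos = (0.9, 0.5, 0.8, 0.2, 0.7)
        out = []
        k = 0
        while m > 0:
            size = min(12, m)
            out.append((size, rhos[k % len(rhos)]))
            m -= size
            k += 1
        return tuple(out)

    kng1_mafs = spectrum(504)
    f11_mafs = spectrum(258)
    loci = (
        LocusSpec(*KNG1_SPAN, mafs=kng1_mafs, ld_blocks=blocks(504)),
        LocusSpec(*F11_SPAN, mafs=f11_mafs, ld_blocks=blocks(258)),
    )

    causal: dict[int, float] = {}
    # a strong common variant in the first locus (the rs710446 analogue)
    for j, maf in enumerate(kng1_mafs):
        if maf >= 0.40:
            causal[j] = 19.1
            break
    # a physically adjacent cluster of rare-ish causal variants (kept well
    # below the 10% class boundary so tail enrichment cannot promote them)
    run: list[int] = []
    for j, maf in enumerate(kng1_mafs):
        if 0.015 < maf < 0.05 and j not in causal:
            run.append(j)
            if len(run) == 3 and run[-1] - run[0] <= 8:
                break
        elif not 0.015 < maf < 0.05:
            run = []
    if len(run) < 3:  # fall back to the three rarest eligible sites
        run = sorted(
            (j for j, maf in enumerate(kng1_mafs) if 0.015 < maf < 0.05 and j not in causal),
            key=lambda j: kng1_mafs[j],
        )[:3]
    for j in run[:3]:
        causal[j] = 45.0
    # a milder common signal in the second locus
    for j, maf in enumerate(f11_mafs):
        if maf >= 0.35:
            causal[504 + j] = 11.5
            break

    return SimulationConfig(
        n_individuals=110,
        loci=loci,
        causal_betas=causal,
        beta_age=0.2,
        beta_sex=-5.0,
        mean=95.0,
        resid_sd=28.0,
        seed=seed,
    )


def annotate_variants_synthetic(
    variants: list[VariantRecord],
    target_mafs: np.ndarray,
    seed: int = 0,
) -> list[VariantRecord]:
    """Attach plausible synthetic annotations to simulated variants.

    Roughly 43% of variants get a dbSNP-style id; annotated variants with
    an appreciable MAF also get 1000-Genomes-like and exome-server-like
    panel frequencies (the target MAF perturbed on the log scale). Feature
    locations are mostly intronic with a near-exon minority, so the
    location rule of the mutation screen is exercised in both directions.
    Returns new records (inputs are not modified).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(17,)))
    target_mafs = np.asarray(target_mafs, dtype=float)
    out: list[VariantRecord] = []
    for k, v in enumerate(variants):
        u = rng.random()
        if u < 0.85:
            loc = f"intron {rng.integers(1, 11)}"
            dist = int(min(1500, rng.geometric(0.02)))
        elif u < 0.88:
            loc, dist = f"exon {rng.integers(1, 11)}", None
        elif u < 0.92:
            loc, dist = "upstream", None
        elif u < 0.96:
            loc, dist = "downstream", None
        else:
            loc, dist = ("5'UTR", None) if rng.random() < 0.5 else ("3'UTR", None)
        dbsnp = f"rs{rng.integers(10**6, 10**8)}" if rng.random() < 0.43 else None
        panels: dict[str, float] = {}
        if dbsnp is not None and target_mafs[k] >= 0.005 and rng.random() < 0.8:
            for panel in ("1000g_all", "evs"):
                af = float(
                    np.clip(target_mafs[k] * np.exp(rng.normal(0, 0.3)), 1e-4, 0.5)
                )
                panels[panel] = af
        out.append(
            VariantRecord(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                dbsnp_id=dbsnp,
                is_indel=v.is_indel,
                hgvs_c=v.hgvs_c,
                gene=v.gene,
                feature_location=loc,
                exon_distance_bp=dist,
                ref_panel_afs=panels,
            )
        )
    return out
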