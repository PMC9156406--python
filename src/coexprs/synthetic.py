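"""Synthetic inputs with known ground truth for every pipeline stage.

Generates block-LD genotypes, anchor-gene co-expression structure with
planted developmental fold changes, cis-eQTL catalogs with known slopes,
GWAS summary statistics, and phenotypes with a planted (possibly zero)
score effect.  Every generator is seed-deterministic and returns the
parameters it was given, so downstream recovery tests always have an
oracle to compare against.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from coexprs.types import (
    AMBIGUOUS_PAIRS,
    STAGE_ADULT,
    STAGE_EARLY,
    UNAMBIGUOUS_PAIRS as _UNAMBIGUOUS_PAIRS,
    ExpressionMatrix,
    GenotypeDosageMatrix,
)


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator derived from one global seed and a stage label."""
    digest = zlib.crc32(label.encode("utf-8"))  # stable across processes
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSimSpec:
    """Targets for the co-expression / developmental-enrichment generator.

    ``target_correlations[g]`` is the desired Pearson r between gene g and
    the anchor gene; ``fold_changes[g]`` the desired ratio of mean early
    (0-18 months) to mean adult (20-40 years) expression.  Expression is
    built as ``baseline-by-stage + noise_sd * (r*z + sqrt(1-r^2)*e)`` with
    a shared latent anchor factor z per sample, so the planted r is exact
    in expectation within each stage.
    """

    n_genes: int
    anchor_index: int
    target_correlations: np.ndarray
    fold_changes: np.ndarray
    n_samples_early: int
    n_samples_adult: int
    noise_sd: float = 1.0
    seed: int = 0
    baseline: float = 10.0
    region: str = "PFC"
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.target_correlations = np.asarray(self.target_correlations, dtype=float)
        self.fold_changes = np.asarray(self.fold_changes, dtype=float)
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.anchor_index < self.n_genes):
            raise ValueError("anchor_index out of range")
        if self.target_correlations.shape != (self.n_genes,):
            raise ValueError("target_correlations must have length n_genes")
        if self.fold_changes.shape != (self.n_genes,):
            raise ValueError("fold_changes must have length n_genes")
        if np.any(np.abs(self.target_correlations) > 1):
            raise ValueError("target correlations must lie in [-1, 1]")
        if abs(abs(self.target_correlations[self.anchor_index]) - 1) > 1e-12:
            raise ValueError("anchor target correlation must be +/-1")
        if np.any(self.fold_changes <= 0):
            raise ValueError("fold changes must be positive")
        if min(self.n_samples_early, self.n_samples_adult) < 3:
            raise ValueError("need at least 3 samples per stage")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.gene_ids is None:
            self.gene_ids = [f"G{i:04d}" for i in range(self.n_genes)]
        if len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length mismatch")


def simulate_expression(spec: ExpressionSimSpec) -> ExpressionMatrix:
    """Draw a gene x sample matrix hitting the spec's correlation and fold targets."""
    rng = _substream(spec.seed, f"expression:{spec.region}")
    n_total = spec.n_samples_early + spec.n_samples_adult
    z = rng.standard_normal(n_total)
    eps = rng.standard_normal((spec.n_genes, n_total))
    r = spec.target_correlations[:, None]
    latent = r * z[None, :] + np.sqrt(1.0 - r**2) * eps
    latent[spec.anchor_index] = np.sign(spec.target_correlations[spec.anchor_index]) * z

    stage = np.array(
        [STAGE_EARLY] * spec.n_samples_early + [STAGE_ADULT] * spec.n_samples_adult
    )
    means = np.where(
        stage[None, :] == STAGE_EARLY,
        spec.baseline * spec.fold_changes[:, None],
        spec.baseline,
    )
    values = means + spec.noise_sd * latent

    sample_ids = [f"{spec.region}_s{i:05d}" for i in range(n_total)]
    samples = pd.DataFrame(
        {"region": spec.region, "stage": stage}, index=pd.Index(sample_ids, name="sample_id")
    )
    frame = pd.DataFrame(values, index=pd.Index(spec.gene_ids, name="gene_id"), columns=sample_ids)
    return ExpressionMatrix(values=frame, samples=samples)


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeSimSpec:
    """Block-LD genotype generator settings.

    ``blocks`` is a list of ``(size, r)`` pairs: within each block every
    SNP pair has allele-level correlation r (so dosage r-squared converges
    to r^2); across blocks SNPs are independent.  One MAF is drawn per
    block from ``maf_range`` (equal within-block MAFs keep every target r
    up to 1 attainable for the binary alleles).
    """

    n_individuals: int
    blocks: list[tuple[int, float]]
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        for size, r in self.blocks:
            if size < 1:
                raise ValueError("block size must be positive")
            if not (0 <= r <= 1):
                raise ValueError("within-block r must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_snps(self) -> int:
        return sum(size for size, _ in self.blocks)


def _latent_correlation(target_r: float, maf: float) -> float:
    """Gaussian correlation whose thresholded indicators have correlation target_r.

    Thresholding a bivariate normal at the MAF quantile attenuates the
    correlation of the resulting 0/1 alleles below the latent Gaussian r;
    this inverts that map (tetrachoric inversion) so the allele-level r is
    exactly the requested one.
    """
    if target_r <= 0:
        return 0.0
    if target_r >= 1:
        return 1.0
    t = stats.norm.ppf(maf)

    def allele_corr(rho: float) -> float:
        # Owen's-T closed form for the standard bivariate normal orthant
        # probability P(X < t, Y < t); exact and stable up to rho -> 1.
        if rho >= 1:
            return 1.0
        a = (1 - rho) / np.sqrt(1 - rho**2)
        p11 = stats.norm.cdf(t) - 2 * special.owens_t(t, a)
        return float((p11 - maf**2) / (maf * (1 - maf)))

    return float(
        optimize.brentq(lambda rho: allele_corr(rho) - target_r, 0.0, 1 - 1e-12, xtol=1e-10)
    )


def simulate_genotypes(
    spec: GenotypeSimSpec, variants: pd.DataFrame
) -> GenotypeDosageMatrix:
    """Draw hard-call dosages (0/1/2, NaN missing) with the spec's LD blocks.

    ``variants`` must be indexed by variant id with chrom / pos /
    effect_allele / other_allele columns (see :func:`make_variant_table`)
    and have exactly as many rows as the spec has SNPs, in block order.
    """
    if len(variants) != spec.n_snps:
        raise ValueError(
            f"variant table has {len(variants)} rows but blocks define {spec.n_snps} SNPs"
        )
    rng = _substream(spec.seed, "genotypes")
    n = spec.n_individuals
    cols: list[np.ndarray] = []
    mafs: list[float] = []
    for size, r in spec.blocks:
        maf = float(rng.uniform(*spec.maf_range))
        rho = _latent_correlation(r, maf)
        t = stats.norm.ppf(maf)
        block = np.zeros((n, size))
        for _hap in range(2):
            shared = rng.standard_normal(n)[:, None]
            noise = rng.standard_normal((n, size))
            if rho >= 1:
                u = np.repeat(shared, size, axis=1)
            else:
                u = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
            block += (u < t).astype(float)
        cols.append(block)
        mafs.extend([maf] * size)
    dosages = np.concatenate(cols, axis=1)
    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages = np.where(mask, np.nan, dosages)
    individuals = pd.Index([f"ind{i:05d}" for i in range(n)], name="individual_id")
    frame = pd.DataFrame(dosages, index=individuals, columns=variants.index)
    vtab = variants.copy()
    vtab["maf_target"] = mafs
    return GenotypeDosageMatrix(dosages=frame, variants=vtab)


def make_variant_table(
    n_snps: int,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    spacing: int = 1_000,
    seed: int = 0,
    prefix: str = "rs",
    allow_ambiguous: bool = False,
) -> pd.DataFrame:
    """Evenly spaced variant ids with random (by default strand-unambiguous) alleles."""
    rng = _substream(seed, "variants")
    pairs = (
        [(a, b) for a in "ACGT" for b in "ACGT" if a != b]
        if allow_ambiguous
        else _UNAMBIGUOUS_PAIRS
    )
    draws = rng.integers(0, len(pairs), size=n_snps)
    eff, oth = zip(*(pairs[i] for i in draws)) if n_snps else ((), ())
    pos = start_pos + spacing * np.arange(n_snps)
    return pd.DataFrame(
        {
            "chrom": str(chrom),
            "pos": pos.astype(int),
            "effect_allele": list(eff),
            "other_allele": list(oth),
        },
        index=pd.Index([f"{prefix}{chrom}_{p}" for p in pos], name="variant_id"),
    )


# ---------------------------------------------------------------------------
# eQTL catalog


def simulate_eqtl_catalog(
    genes: list[str],
    annotation: pd.DataFrame,
    snps_per_gene: int | dict[str, int],
    slope_sd: float = 0.5,
    seed: int = 0,
    cis_window: int = 1_000_000,
    constant_slope: float | None = None,
) -> pd.DataFrame:
    """cis gene-SNP records with known slopes, emulating a GTEx association table.

    Each gene receives ``snps_per_gene`` SNPs placed uniformly inside its
    cis window (gene start +/- ``cis_window``); slopes are N(0, slope_sd)
    unless ``constant_slope`` pins them.  Returned columns: gene_id,
    variant_id, chrom, pos, effect_allele, other_allele, slope,
    pval_nominal.
    """
    if slope_sd < 0:
        raise ValueError("slope_sd must be nonnegative")
    rng = _substream(seed, "eqtl")
    rows = []
    for gene in genes:
        if gene not in annotation.index:
            raise KeyError(f"gene {gene!r} missing from annotation")
        chrom = str(annotation.loc[gene, "chrom"])
        start = int(annotation.loc[gene, "start"])
        k = snps_per_gene[gene] if isinstance(snps_per_gene, dict) else snps_per_gene
        lo = max(1, start - cis_window)
        hi = start + cis_window
        positions = np.sort(rng.choice(np.arange(lo, hi), size=k, replace=False))
        pair_idx = rng.integers(0, len(_UNAMBIGUOUS_PAIRS), size=k)
        for j, pos in enumerate(positions):
            eff, oth = _UNAMBIGUOUS_PAIRS[pair_idx[j]]
            slope = (
                constant_slope
                if constant_slope is not None
                else float(rng.normal(0.0, slope_sd))
            )
            rows.append(
                {
                    "gene_id": gene,
                    "variant_id": f"rs{chrom}_{pos}",
                    "chrom": chrom,
                    "pos": int(pos),
                    "effect_allele": eff,
                    "other_allele": oth,
                    "slope": slope,
                    "pval_nominal": float(10 ** rng.uniform(-8, -1)),
                }
            )
    catalog = pd.DataFrame(rows)
    validate_cis(catalog, annotation, cis_window)
    return catalog


def validate_cis(
    catalog: pd.DataFrame, annotation: pd.DataFrame, cis_window: int = 1_000_000
) -> None:
    """Raise if any record's SNP lies outside the cis window of its gene."""
    for gene, grp in catalog.groupby("gene_id"):
        start = int(annotation.loc[gene, "start"])
        end = int(annotation.loc[gene, "end"])
        bad = grp[(grp["pos"] < start - cis_window) | (grp["pos"] > end + cis_window)]
        if len(bad):
            raise ValueError(
                f"{len(bad)} SNPs outside the cis window of gene {gene!r}"
            )


def make_gene_annotation(
    genes: list[str],
    gene_length: int = 100_000,
    spacing: int = 4_000_000,
    chroms: int = 22,
    seed: int = 0,
) -> pd.DataFrame:
    """Autosomal GRCh37-style coordinates (1-based, start <= end) for *genes*."""
    rows = []
    for i, gene in enumerate(genes):
        chrom = str(i % chroms + 1)
        start = 5_000_000 + (i // chroms) * spacing
        rows.append({"chrom": chrom, "start": start, "end": start + gene_length})
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeSimSpec:
    """Linear-model phenotype generator: planted score/sex/PC effects + noise."""

    beta_score: float
    beta_sex: float = 0.0
    beta_pcs: tuple[float, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def simulate_phenotypes(
    scores: np.ndarray | pd.Series,
    sex: np.ndarray | pd.Series,
    pcs: np.ndarray | pd.DataFrame | None,
    spec: PhenotypeSimSpec,
) -> pd.Series:
    """phenotype = beta_score*score + beta_sex*sex + sum(beta_pc*pc) + N(0, noise_sd)."""
    index = scores.index if isinstance(scores, pd.Series) else None
    scores_a = np.asarray(scores, dtype=float)
    sex_a = np.asarray(sex, dtype=float)
    if len(sex_a) != len(scores_a):
        raise ValueError("sex and scores must have the same length")
    y = spec.beta_score * scores_a + spec.beta_sex * sex_a
    if pcs is not None:
        pcs_a = np.asarray(pcs, dtype=float)
        if pcs_a.ndim == 1:
            pcs_a = pcs_a[:, None]
        if pcs_a.shape[0] != len(scores_a):
            raise ValueError("pcs and scores must have the same length")
        if pcs_a.shape[1] != len(spec.beta_pcs):
            raise ValueError("beta_pcs length must match number of PC columns")
        y = y + pcs_a @ np.asarray(spec.beta_pcs, dtype=float)
    elif spec.beta_pcs:
        raise ValueError("beta_pcs given but no pcs")
    rng = _substream(spec.seed, "phenotype")
    y = y + rng.normal(0.0, spec.noise_sd, size=len(scores_a))
    return pd.Series(y, index=index, name="phenotype")


# ---------------------------------------------------------------------------
# GWAS summary statistics


def simulate_gwas_summary(
    n_snps: int,
    prop_null: float = 1.0,
    effect_sd: float = 0.1,
    seed: int = 0,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP GWAS table (variant_id, alleles, beta, p); null SNP p ~ U(0,1).

    Non-null SNPs get inflated |beta| (N(0, 10*effect_sd)) and small
    p-values (10^U(-30,-5)), which is enough structure to exercise
    threshold and top-k selection.
    """
    if not (0 <= prop_null <= 1):
        raise ValueError("prop_null must lie in [0, 1]")
    rng = _substream(seed, "gwas")
    if variants is None:
        variants = make_variant_table(n_snps, chrom="2", seed=seed, prefix="gw")
    if len(variants) != n_snps:
        raise ValueError("variant table size must equal n_snps")
    is_null = rng.random(n_snps) < prop_null
    beta = np.where(
        is_null,
        rng.normal(0.0, effect_sd, n_snps),
        rng.normal(0.0, 10 * effect_sd, n_snps),
    )
    p = np.where(is_null, rng.uniform(0.0, 1.0, n_snps), 10 ** rng.uniform(-30, -5, n_snps))
    out = variants.reset_index()[["variant_id", "effect_allele", "other_allele"]].copy()
    out["beta"] = beta
    out["p"] = p
    out["is_null_truth"] = is_null
    return out
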