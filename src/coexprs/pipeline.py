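"""End-to-end orchestration: network -> assemble -> score -> associate.

Also provides the study-level synthetic builder that wires every
generator in :mod:`coexprs.synthetic` into a coherent dataset (planted
regional networks, cis-eQTL catalogs over the planted genes, block-LD
genotypes covering the catalog variants, and phenotypes with a planted
effect of the combined score), which is what the test-bench and the
worked examples run on.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from coexprs import assembly, association, io, network, scoring, synthetic
from coexprs.types import ExpressionMatrix, GenotypeDosageMatrix


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Thresholds and paths for a full run; every constant is overridable.

    Threshold defaults: correlation filter |r| >= 0.5, developmental fold
    >= 1.5, clump r^2 < 0.2 in a 250 kb window, conventional-PRS GWAS
    p-threshold 4.912e-5 (or top_k 4515 when set).
    """

    expression_path: str = ""
    sample_meta_path: str = ""
    eqtl_paths: dict = field(default_factory=dict)  # region -> path
    annotation_path: str = ""
    genotypes_path: str = ""
    gwas_path: str = ""
    phenotype_path: str = ""
    out_dir: str = "."

    anchor_gene: str = "DCC"
    regions: tuple = ("PFC", "NAcc")
    min_abs_r: float = 0.5
    min_fold: float = 1.5
    r2_max: float = 0.2
    window_kb: float = 250.0
    prs_p_threshold: float = 4.912e-5
    prs_top_k: int | None = None
    include_anchor: bool = True
    corr_stage: str | None = None
    covariates: tuple = ("sex", "PC1", "PC2", "PC3")
    bonferroni_m: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.min_abs_r <= 1):
            raise ValueError("min_abs_r must lie in [0, 1]")
        if self.min_fold <= 0:
            raise ValueError("min_fold must be positive")
        if not (0 < self.r2_max <= 1):
            raise ValueError("r2_max must lie in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not (0 < self.prs_p_threshold < 1):
            raise ValueError("prs_p_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class RunManifest:
    """Per-stage record counts plus the config snapshot of a run."""

    config: dict
    counts: dict = field(default_factory=dict)  # region -> stage -> count
    version: str = ""

    def record(self, region: str, stage: str, count: int) -> None:
        self.counts.setdefault(region, {})[stage] = int(count)

    def check_monotone(self) -> None:
        """Counts must be non-increasing along the filtering stages."""
        order = ["pairs_in", "pairs_harmonized", "pairs_deduplicated", "pairs_clumped"]
        for region, stages in self.counts.items():
            seq = [stages[s] for s in order if s in stages]
            if any(a < b for a, b in zip(seq, seq[1:])):
                raise AssertionError(f"non-monotone counts for {region}: {stages}")

    def write(self, path: str) -> None:
        self.check_monotone()
        with open(path, "w") as fh:
            json.dump({"config": self.config, "counts": self.counts, "version": self.version}, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# core orchestration on in-memory objects


@dataclass
class PipelineResult:
    networks: dict
    weights: dict
    scores: scoring.ScoreTable
    manifest: RunManifest
    clump_reports: dict = field(default_factory=dict)
    harmonization: dict = field(default_factory=dict)


def assemble_region(
    net: network.CoexpressionNetwork,
    catalog: pd.DataFrame,
    annotation: pd.DataFrame,
    genotypes: GenotypeDosageMatrix,
    config: PipelineConfig,
    manifest: RunManifest | None = None,
) -> tuple[pd.DataFrame, assembly.ClumpResult, assembly.HarmonizationResult]:
    """collect -> harmonize -> deduplicate -> clump for one region."""
    region = net.region
    pairs, unannotated = assembly.collect_cis_pairs(net, catalog, annotation)
    if unannotated:
        warnings.warn(f"{len(unannotated)} unannotated network genes in {region}", stacklevel=2)
    harm = assembly.harmonize_alleles(pairs, genotypes.variants)
    dedup = assembly.deduplicate_snp_gene(harm.pairs)
    present = dedup[dedup["variant_id"].isin(genotypes.variant_ids)]
    clump = assembly.ld_clump(present, genotypes, config.r2_max, config.window_kb)
    if manifest is not None:
        manifest.record(region, "genes_network", net.size)
        manifest.record(region, "pairs_in", len(pairs))
        manifest.record(region, "pairs_harmonized", len(harm.pairs))
        manifest.record(region, "pairs_deduplicated", len(dedup))
        manifest.record(region, "pairs_clumped", len(clump.pairs))
    return clump.pairs, clump, harm


def run_from_objects(
    expr: ExpressionMatrix,
    catalogs: dict,
    annotation: pd.DataFrame,
    genotypes: GenotypeDosageMatrix,
    config: PipelineConfig,
) -> PipelineResult:
    """Run network construction through scoring on in-memory inputs."""
    config.validate()
    manifest = RunManifest(config=asdict(config))
    networks, weights, clump_reports, harms = {}, {}, {}, {}
    for region in config.regions:
        net = network.build_network(
            expr,
            config.anchor_gene,
            region,
            min_abs_r=config.min_abs_r,
            min_fold=config.min_fold,
            include_anchor=config.include_anchor,
            corr_stage=config.corr_stage,
        )
        networks[region] = net
        pairs, clump, harm = assemble_region(
            net, catalogs[region], annotation, genotypes, config, manifest
        )
        weights[region] = scoring.build_weights(pairs, region)
        clump_reports[region] = clump
        harms[region] = harm
        manifest.record(region, "snps_scored", len(weights[region]))
    score_table = scoring.score_pipeline(genotypes, weights)
    manifest.check_monotone()
    return PipelineResult(
        networks=networks,
        weights=weights,
        scores=score_table,
        manifest=manifest,
        clump_reports=clump_reports,
        harmonization=harms,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run; writes stage outputs and the manifest."""
    config.validate()
    expr = io.read_expression(config.expression_path, config.sample_meta_path)
    annotation, rej = io.read_table(config.annotation_path, "annotation")
    annotation = annotation.set_index("gene_id")
    catalogs = {}
    for region in config.regions:
        cat, _ = io.read_table(config.eqtl_paths[region], "eqtl")
        catalogs[region] = cat
    genotypes = io.read_genotypes(config.genotypes_path)
    result = run_from_objects(expr, catalogs, annotation, genotypes, config)

    os.makedirs(config.out_dir, exist_ok=True)
    for region, net in result.networks.items():
        io.write_table(
            net.genes.reset_index(), os.path.join(config.out_dir, f"network_{region}.tsv")
        )
        io.write_table(
            result.weights[region].reset_index(),
            os.path.join(config.out_dir, f"weights_{region}.tsv"),
        )
    scores = result.scores.to_frame()
    scores.insert(0, "individual_id", scores.index)
    io.write_table(scores, os.path.join(config.out_dir, "scores.tsv"))
    result.manifest.write(os.path.join(config.out_dir, "manifest.json"))
    return result


# ---------------------------------------------------------------------------
# synthetic study builder


@dataclass
class RegionPlan:
    """Planted composition of one regional network.

    ``n_pass`` genes pass both filters (half of them negatively
    correlated with the anchor); ``n_fail_r`` genes fail the correlation
    filter only; ``n_fail_fold`` pass the correlation filter but fail the
    developmental filter.  Planted values sit far from the 0.5 / 1.5
    boundaries (|r| 0.8 vs 0.1, fold 2.0 vs 1.0) so sampling noise cannot
    flip membership at the default sample sizes.
    """

    region: str
    n_pass: int
    n_fail_r: int = 20
    n_fail_fold: int = 10
    snps_per_gene: int = 6
    r_pass: float = 0.8
    r_fail: float = 0.1
    fold_pass: float = 2.0
    fold_fail: float = 1.0


@dataclass
class StudyData:
    """A full synthetic study with its ground truth."""

    expr: ExpressionMatrix
    annotation: pd.DataFrame
    catalogs: dict
    genotypes: GenotypeDosageMatrix
    gwas: pd.DataFrame
    sex: pd.Series
    pcs: pd.DataFrame
    expected_networks: dict  # region -> set of gene ids (incl. anchor)
    plans: dict
    seed: int


def simulate_study(
    plans: list[RegionPlan],
    n_individuals: int = 500,
    n_samples_early: int = 120,
    n_samples_adult: int = 120,
    anchor: str = "DCC",
    ld_block_size: int = 3,
    ld_r: float = 0.85,
    maf_range: tuple = (0.1, 0.5),
    missing_rate: float = 0.01,
    slope_sd: float = 0.5,
    noise_sd: float = 1.0,
    n_gwas_snps: int = 0,
    seed: int = 0,
) -> StudyData:
    """Build every pipeline input with planted, recoverable structure.

    One expression matrix covers all regions (union of the per-region
    gene panels; a gene planted for one region is null — r = 0, fold = 1
    — in the other region's samples, so it cannot leak across networks).
    Each gene's cis-SNPs form LD blocks of ``ld_block_size`` at
    allele-level correlation ``ld_r``, so clumping has real work to do.
    """
    gene_ids = [anchor]
    targets: dict = {}
    for plan in plans:
        tag = plan.region
        passers, fail_r, fail_fold = [], [], []
        for i in range(plan.n_pass):
            g = f"{tag}_P{i:04d}"
            r = plan.r_pass if i % 2 == 0 else -plan.r_pass
            passers.append(g)
            targets[g] = {plan.region: (r, plan.fold_pass)}
        for i in range(plan.n_fail_r):
            g = f"{tag}_R{i:04d}"
            fail_r.append(g)
            targets[g] = {plan.region: (plan.r_fail, plan.fold_pass)}
        for i in range(plan.n_fail_fold):
            g = f"{tag}_F{i:04d}"
            fail_fold.append(g)
            targets[g] = {plan.region: (plan.r_pass, plan.fold_fail)}
        gene_ids.extend(passers + fail_r + fail_fold)
        plan._passers = passers  # type: ignore[attr-defined]

    # per-region expression over the shared gene panel
    matrices = []
    for k, plan in enumerate(plans):
        r_targets, folds = [], []
        for g in gene_ids:
            if g == anchor:
                r_targets.append(1.0)
                folds.append(plans[0].fold_pass)
            else:
                r, fold = targets[g].get(plan.region, (0.0, 1.0))
                r_targets.append(r)
                folds.append(fold)
        spec = synthetic.ExpressionSimSpec(
            n_genes=len(gene_ids),
            anchor_index=0,
            target_correlations=np.array(r_targets),
            fold_changes=np.array(folds),
            n_samples_early=n_samples_early,
            n_samples_adult=n_samples_adult,
            noise_sd=noise_sd,
            seed=seed + 101 * (k + 1),
            region=plan.region,
            gene_ids=list(gene_ids),
        )
        matrices.append(synthetic.simulate_expression(spec))
    expr = ExpressionMatrix(
        values=pd.concat([m.values for m in matrices], axis=1),
        samples=pd.concat([m.samples for m in matrices], axis=0),
    )

    annotation = synthetic.make_gene_annotation(gene_ids)

    catalogs = {}
    variant_frames = []
    blocks: list = []
    for k, plan in enumerate(plans):
        region_genes = [anchor] + [g for g in gene_ids[1:] if g.startswith(plan.region + "_")]
        cat = synthetic.simulate_eqtl_catalog(
            region_genes,
            annotation,
            plan.snps_per_gene,
            slope_sd=slope_sd,
            seed=seed + 211 * (k + 1),
        )
        catalogs[plan.region] = cat
        vf = cat.set_index("variant_id")[["chrom", "pos", "effect_allele", "other_allele"]]
        variant_frames.append(vf)
        # one LD-block list entry per chunk of each gene's SNPs
        for _gene, grp in cat.groupby("gene_id", sort=False):
            k_snps = len(grp)
            for start in range(0, k_snps, ld_block_size):
                blocks.append((min(ld_block_size, k_snps - start), ld_r))

    variants = pd.concat(variant_frames)
    variants = variants[~variants.index.duplicated(keep="first")]
    # rebuild block list if duplicate variants were removed (anchor shared)
    n_dupes = sum(len(vf) for vf in variant_frames) - len(variants)
    if n_dupes:
        blocks = []  # recompute uniform blocks over the unique variants
        remaining = len(variants)
        while remaining > 0:
            size = min(ld_block_size, remaining)
            blocks.append((size, ld_r))
            remaining -= size

    gspec = synthetic.GenotypeSimSpec(
        n_individuals=n_individuals,
        blocks=blocks,
        maf_range=maf_range,
        missing_rate=missing_rate,
        seed=seed + 977,
    )
    genotypes = synthetic.simulate_genotypes(gspec, variants)

    gwas = synthetic.simulate_gwas_summary(
        n_gwas_snps or 5 * len(variants), prop_null=0.9, seed=seed + 1999
    )

    rng = np.random.default_rng(seed + 4242)
    sex = pd.Series(
        rng.integers(0, 2, n_individuals), index=genotypes.dosages.index, name="sex"
    )
    pcs = pd.DataFrame(
        rng.standard_normal((n_individuals, 3)),
        index=genotypes.dosages.index,
        columns=["PC1", "PC2", "PC3"],
    )

    expected = {
        plan.region: {anchor, *plan._passers}  # type: ignore[attr-defined]
        for plan in plans
    }
    return StudyData(
        expr=expr,
        annotation=annotation,
        catalogs=catalogs,
        genotypes=genotypes,
        gwas=gwas,
        sex=sex,
        pcs=pcs,
        expected_networks=expected,
        plans={p.region: p for p in plans},
        seed=seed,
    )


def default_config_for_study(study: StudyData) -> PipelineConfig:
    """Config matching a :func:`simulate_study` dataset (in-memory use)."""
    return PipelineConfig(
        regions=tuple(study.plans),
        anchor_gene="DCC",
        corr_stage="early",
        seed=study.seed,
    )
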