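"""Per-region ePRS computation and the conventional GWAS-threshold PRS.

The expression-based polygenic score (ePRS) of an individual in one brain
region is

    score_i = sum_j dosage_ij * slope_j * sign_j

over the region's post-clump SNP set, where ``slope_j`` is the eQTL
effect of the counted allele on its source gene's expression and
``sign_j`` the sign of that gene's correlation with the anchor gene.  A
SNP that raises the expression of a negatively co-expressed gene thereby
lowers the network-aligned score.  Regional scores are summed, without
standardization, into the combined corticolimbic score.

The comparator PRS replaces eQTL slopes by GWAS effect sizes for SNPs
passing a GWAS p-value threshold (or an exact top-k by significance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from coexprs.assembly import harmonize_alleles
from coexprs.types import GenotypeDosageMatrix

DEFAULT_PRS_P_THRESHOLD = 4.912e-5
DEFAULT_PRS_TOP_K = 4515


def build_weights(pairs: pd.DataFrame, region: str) -> pd.DataFrame:
    """SNP weight table from harmonized, clumped pairs: weight = slope x sign.

    Columns: variant_id (index), region, weight, gene_id, slope,
    network_sign, flip.  The flip flag travels with the weight so scoring
    can recode dosages without consulting allele labels again.
    """
    required = {"variant_id", "slope", "network_sign", "gene_id", "flip"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table lacks columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "region": region,
            "weight": pairs["slope"].to_numpy() * pairs["network_sign"].to_numpy(),
            "gene_id": pairs["gene_id"].to_numpy(),
            "slope": pairs["slope"].to_numpy(),
            "network_sign": pairs["network_sign"].to_numpy(),
            "flip": pairs["flip"].to_numpy(),
        },
        index=pd.Index(pairs["variant_id"], name="variant_id"),
    )
    if out.index.duplicated().any():
        raise ValueError("duplicate variants in weight table; deduplicate first")
    return out


def _oriented_dosages(
    genotypes: GenotypeDosageMatrix, variant_ids: list[str], flip: np.ndarray
) -> np.ndarray:
    """Dosage block oriented to the eQTL effect allele, mean-imputed.

    Flip-flagged variants contribute via 2 - dosage.  Missing entries are
    replaced by the SNP's cohort mean dosage (computed before flipping;
    the flip maps the mean consistently), which preserves each SNP's
    expected contribution under missingness completely at random.
    """
    absent = [v for v in variant_ids if v not in genotypes.variant_ids]
    if absent:
        raise KeyError(
            f"{len(absent)} weighted variants absent from genotypes, e.g. {absent[:3]}"
        )
    dos = genotypes.dosages[variant_ids].to_numpy(dtype=float)
    col_means = np.nanmean(dos, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)  # all-missing SNP
    nan_mask = np.isnan(dos)
    dos = np.where(nan_mask, col_means[None, :], dos)
    return np.where(flip[None, :], 2.0 - dos, dos)


def compute_region_score(
    genotypes: GenotypeDosageMatrix, weights: pd.DataFrame, region: str | None = None
) -> pd.Series:
    """Per-individual regional ePRS: sum of oriented dosages times weights."""
    if region is not None:
        weights = weights[weights["region"] == region]
    if weights.empty:
        return pd.Series(0.0, index=genotypes.dosages.index, name="score")
    vids = list(weights.index)
    flip = weights["flip"].to_numpy(dtype=bool)
    dos = _oriented_dosages(genotypes, vids, flip)
    scores = dos @ weights["weight"].to_numpy(dtype=float)
    return pd.Series(scores, index=genotypes.dosages.index, name="score")


def combine_regions(score_a: pd.Series, score_b: pd.Series) -> pd.Series:
    """Elementwise sum of the two regional scores, aligned by individual id."""
    if set(score_a.index) != set(score_b.index):
        raise ValueError("regional scores cover different individuals")
    combined = score_a.add(score_b.reindex(score_a.index))
    combined.name = "score_combined"
    return combined


@dataclass
class ScoreTable:
    """Per-individual regional and combined scores with SNP-count bookkeeping."""

    scores: pd.DataFrame  # columns score_pfc.., score_combined
    n_snps: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return self.scores.copy()


def score_pipeline(
    genotypes: GenotypeDosageMatrix,
    weights_by_region: dict[str, pd.DataFrame],
) -> ScoreTable:
    """Regional scores for every region plus their combined sum.

    Variants present in more than one region's weight set contribute to
    each regional score independently (and hence more than once to the
    sum); the regions are constructed independently and then summed.
    """
    frame = pd.DataFrame(index=genotypes.dosages.index)
    n_snps = {}
    combined = pd.Series(0.0, index=genotypes.dosages.index)
    for region, weights in weights_by_region.items():
        s = compute_region_score(genotypes, weights)
        frame[f"score_{region.lower()}"] = s
        n_snps[region] = len(weights)
        combined = combined + s
    frame["score_combined"] = combined
    return ScoreTable(scores=frame, n_snps=n_snps)


def compute_conventional_prs(
    genotypes: GenotypeDosageMatrix,
    gwas: pd.DataFrame,
    p_threshold: float | None = DEFAULT_PRS_P_THRESHOLD,
    top_k: int | None = None,
    drop_ambiguous: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """GWAS-threshold PRS: sum of dosages weighted by GWAS betas.

    SNPs are selected by ``p < p_threshold``, or as exactly the ``top_k``
    most significant when ``top_k`` is given (ties broken by variant id).
    GWAS alleles are harmonized to the cohort with the same rules as the
    eQTL pairs (flip or drop).  Returns (scores, selected table).
    """
    if p_threshold is None and top_k is None:
        raise ValueError("give p_threshold or top_k")
    required = {"variant_id", "effect_allele", "other_allele", "beta", "p"}
    missing = required - set(gwas.columns)
    if missing:
        raise ValueError(f"GWAS table lacks columns: {sorted(missing)}")
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be positive")
        selected = gwas.sort_values(["p", "variant_id"], kind="mergesort").head(top_k)
    else:
        selected = gwas[gwas["p"] < p_threshold]
    selected = selected.copy()

    harm = harmonize_alleles(selected, genotypes.variants, drop_ambiguous=drop_ambiguous)
    kept = harm.pairs
    if kept.empty:
        return pd.Series(0.0, index=genotypes.dosages.index, name="prs"), kept
    dos = _oriented_dosages(
        genotypes, list(kept["variant_id"]), kept["flip"].to_numpy(dtype=bool)
    )
    scores = dos @ kept["beta"].to_numpy(dtype=float)
    return pd.Series(scores, index=genotypes.dosages.index, name="prs"), kept
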