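"""Anchor-gene co-expression network construction.

Two sequential filters define a regional network around an anchor gene:

1. co-expression filter — keep genes whose Pearson correlation with the
   anchor over the region's samples satisfies ``|r| >= min_abs_r``
   (boundary inclusive), carrying the sign of r;
2. developmental-enrichment filter — keep genes whose mean early-postnatal
   expression is at least ``min_fold`` times the adult mean (boundary
   inclusive, with a small pseudocount guarding zero adult expression).

A stability analysis compares the network's gene-gene correlation
structure between childhood and adulthood, holding the childhood
hierarchical-clustering leaf order fixed in the adult matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from coexprs.types import STAGE_ADULT, STAGE_EARLY, ExpressionMatrix

DEFAULT_MIN_ABS_R = 0.5
DEFAULT_MIN_FOLD = 1.5
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass
class CoexpressionProfile:
    """Per-gene correlation with the anchor gene over one region's samples."""

    region: str
    anchor_gene: str
    correlations: pd.Series  # gene_id -> Pearson r with anchor
    excluded: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    method: str = "pearson"

    def __post_init__(self) -> None:
        r = self.correlations.dropna()
        if (r.abs() > 1 + 1e-9).any():
            raise ValueError("correlations outside [-1, 1]")


@dataclass
class CoexpressionNetwork:
    """The regional anchor-gene network: retained genes with signed r and fold change."""

    region: str
    anchor_gene: str
    genes: pd.DataFrame  # index gene_id; columns r, sign, fold_change
    min_abs_r: float
    min_fold: float
    include_anchor: bool

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes.index)

    @property
    def size(self) -> int:
        return len(self.genes)

    def signs(self) -> pd.Series:
        return self.genes["sign"]


def compute_coexpression(
    expr: ExpressionMatrix,
    anchor: str,
    region: str,
    stage: str | None = None,
    method: str = "pearson",
) -> CoexpressionProfile:
    """Correlation of every gene with the anchor over the region's samples.

    Genes with zero variance over those samples have undefined correlation
    and are reported in ``excluded`` (reason ``constant_expression``)
    rather than given an r.  ``method`` is ``pearson`` (default) or
    ``spearman``.
    """
    if anchor not in expr.gene_ids:
        raise KeyError(f"anchor gene {anchor!r} not in expression matrix")
    sub = expr.subset(region, stage)
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    mat = sub.to_numpy(dtype=float)
    if method == "spearman":
        mat = np.apply_along_axis(lambda v: pd.Series(v).rank().to_numpy(), 1, mat)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    anchor_pos = expr.gene_ids.get_loc(anchor)
    if norms[anchor_pos] == 0:
        raise ValueError("anchor gene has constant expression in this region")
    constant = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centered @ centered[anchor_pos] / (norms * norms[anchor_pos])
    r = np.clip(r, -1.0, 1.0)
    r[anchor_pos] = 1.0
    corr = pd.Series(r, index=expr.gene_ids, name="r")
    excluded = pd.Series("constant_expression", index=expr.gene_ids[constant], dtype=object)
    corr = corr[~constant]
    return CoexpressionProfile(
        region=region, anchor_gene=anchor, correlations=corr, excluded=excluded, method=method
    )


def apply_coexpression_filter(
    profile: CoexpressionProfile, min_abs_r: float = DEFAULT_MIN_ABS_R
) -> pd.DataFrame:
    """Genes with |r| >= min_abs_r (inclusive), each carrying sign(r) in {+1, -1}.

    The anchor itself (r = 1) always passes.  A gene at exactly r = 0
    cannot pass for any positive threshold, so sign 0 never appears.
    """
    if not (0 <= min_abs_r <= 1):
        raise ValueError("min_abs_r must lie in [0, 1]")
    r = profile.correlations
    kept = r[r.abs() >= min_abs_r]
    out = pd.DataFrame({"r": kept, "sign": np.sign(kept).astype(int)})
    out.index.name = "gene_id"
    return out


def developmental_enrichment(
    expr: ExpressionMatrix,
    region: str,
    genes: list[str] | pd.Index | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene early/adult means and fold change mean_early / (mean_adult + eps)."""
    early = expr.subset(region, STAGE_EARLY)
    try:
        adult = expr.subset(region, STAGE_ADULT)
    except ValueError as err:
        raise ValueError(f"region {region!r} has no adult samples") from err
    if genes is not None:
        early, adult = early.loc[genes], adult.loc[genes]
    mean_early = early.mean(axis=1)
    mean_adult = adult.mean(axis=1)
    fold = mean_early / (mean_adult + pseudocount)
    out = pd.DataFrame(
        {"mean_early": mean_early, "mean_adult": mean_adult, "fold_change": fold}
    )
    out.index.name = "gene_id"
    return out


def apply_developmental_filter(
    expr: ExpressionMatrix,
    candidates: pd.DataFrame,
    region: str,
    min_fold: float = DEFAULT_MIN_FOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict *candidates* to genes with fold change >= min_fold (inclusive).

    Returns ``(retained, enrichment)`` where ``retained`` is the candidate
    table joined with its fold changes and ``enrichment`` the full
    early/adult mean table for all candidates.
    """
    if min_fold <= 0:
        raise ValueError("min_fold must be positive")
    enrich = developmental_enrichment(expr, region, candidates.index, pseudocount)
    retained = candidates.join(enrich["fold_change"])
    retained = retained[retained["fold_change"] >= min_fold]
    return retained, enrich


def build_network(
    expr: ExpressionMatrix,
    anchor: str,
    region: str,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
    min_fold: float = DEFAULT_MIN_FOLD,
    include_anchor: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "pearson",
    corr_stage: str | None = None,
) -> CoexpressionNetwork:
    """Compose the two filters into the regional anchor-gene network.

    The anchor is included with sign +1 when ``include_anchor`` (default),
    regardless of its own developmental fold change; set False to score
    only its co-expression partners.  ``corr_stage`` restricts the
    correlation filter to one developmental stage (recommended when a
    single matrix serves both filters: pooling stages lets shared
    developmental mean shifts masquerade as co-expression).  An empty
    network is a warning, not an error.
    """
    profile = compute_coexpression(expr, anchor, region, stage=corr_stage, method=method)
    candidates = apply_coexpression_filter(profile, min_abs_r)
    retained, _enrich = apply_developmental_filter(
        expr, candidates, region, min_fold, pseudocount
    )
    if include_anchor and anchor not in retained.index:
        anchor_fold = developmental_enrichment(expr, region, [anchor], pseudocount)
        retained = pd.concat(
            [
                pd.DataFrame(
                    {"r": [1.0], "sign": [1], "fold_change": anchor_fold["fold_change"]},
                    index=pd.Index([anchor], name="gene_id"),
                ),
                retained,
            ]
        )
    elif not include_anchor and anchor in retained.index:
        retained = retained.drop(index=anchor)
    if retained.index.duplicated().any():
        raise ValueError("duplicate gene ids in network")
    if retained.empty:
        warnings.warn(f"network for region {region!r} is empty", stacklevel=2)
    return CoexpressionNetwork(
        region=region,
        anchor_gene=anchor,
        genes=retained.sort_index(),
        min_abs_r=min_abs_r,
        min_fold=min_fold,
        include_anchor=include_anchor,
    )


# ---------------------------------------------------------------------------
# developmental co-expression stability


@dataclass
class StabilityReport:
    """Childhood vs adulthood co-expression of a fixed gene set.

    ``corr_child`` carries the childhood gene-gene correlation matrix in
    hierarchical-clustering leaf order; ``corr_adult`` is the adulthood
    matrix in the SAME order.  ``clusters`` maps each gene to its
    childhood cluster; ``preservation`` holds, per childhood cluster, the
    mean within-cluster off-diagonal correlation in childhood and in
    adulthood (the preservation statistic).
    """

    corr_child: pd.DataFrame
    corr_adult: pd.DataFrame
    clusters: pd.Series
    preservation: pd.DataFrame
    linkage: np.ndarray


def _within_cluster_mean(corr: pd.DataFrame, members: list[str]) -> float:
    if len(members) < 2:
        return float("nan")
    sub = corr.loc[members, members].to_numpy()
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def coexpression_stability(
    expr_child: pd.DataFrame,
    expr_adult: pd.DataFrame,
    genes: list[str] | None = None,
    linkage_method: str = "average",
    cut_height: float = 0.5,
) -> StabilityReport:
    """Compare network co-expression between childhood and adulthood.

    Both inputs are gene x sample matrices over the same gene set.  Genes
    are clustered on the childhood matrix (linkage on distance 1 - r, cut
    at ``cut_height``); the adulthood matrix is reported in the identical
    leaf order so preserved childhood clusters remain visible as blocks.
    The preservation statistic per childhood cluster is the mean
    within-cluster correlation recomputed in adulthood.
    """
    if genes is not None:
        expr_child = expr_child.loc[genes]
        expr_adult = expr_adult.loc[genes]
    if set(expr_child.index) != set(expr_adult.index):
        raise ValueError("childhood and adulthood matrices cover different genes")
    expr_adult = expr_adult.loc[expr_child.index]
    if len(expr_child) < 2:
        raise ValueError("need at least 2 genes")

    corr_child = expr_child.T.corr()
    corr_adult = expr_adult.T.corr()

    dist = 1.0 - corr_child.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # guard tiny asymmetries
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    order = hierarchy.leaves_list(link)
    ordered = list(corr_child.index[order])

    corr_child = corr_child.loc[ordered, ordered]
    corr_adult = corr_adult.loc[ordered, ordered]

    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    clusters = pd.Series(labels, index=expr_child.index, name="cluster").loc[ordered]

    rows = []
    for cluster_id in sorted(clusters.unique()):
        members = list(clusters.index[clusters == cluster_id])
        rows.append(
            {
                "cluster": cluster_id,
                "n_genes": len(members),
                "mean_r_child": _within_cluster_mean(corr_child, members),
                "mean_r_adult": _within_cluster_mean(corr_adult, members),
            }
        )
    preservation = pd.DataFrame(rows).set_index("cluster")
    return StabilityReport(
        corr_child=corr_child,
        corr_adult=corr_adult,
        clusters=clusters,
        preservation=preservation,
        linkage=link,
    )


def plot_stability_heatmaps(report: StabilityReport, path_child: str, path_adult: str) -> None:
    """Write childhood/adulthood correlation heatmaps (same gene order) to files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for corr, path, title in (
        (report.corr_child, path_child, "childhood"),
        (report.corr_adult, path_adult, "adulthood"),
    ):
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(f"co-expression ({title})")
        fig.colorbar(im, ax=ax, label="Pearson r")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
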