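"""Assemble the cis-eQTL SNP set for a regional co-expression network.

Stages: restrict the eQTL catalog to network genes (tagging each record
with the gene's network sign), harmonize catalog alleles against the
cohort's variant table (flip or drop), collapse multi-gene SNPs to one
record, and greedily LD-clump on cohort dosage r-squared.  Every drop is
reason-coded so the record counts of a run can be audited end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexprs.network import CoexpressionNetwork
from coexprs.types import AMBIGUOUS_PAIRS, GenotypeDosageMatrix

DEFAULT_R2_MAX = 0.2
DEFAULT_WINDOW_KB = 250

PAIR_COLUMNS = [
    "gene_id",
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "slope",
    "pval_nominal",
    "network_sign",
    "flip",
]


def collect_cis_pairs(
    network: CoexpressionNetwork,
    catalog: pd.DataFrame,
    annotation: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Catalog records for network genes, each tagged with the gene's sign.

    Network genes absent from the annotation are excluded with a warning
    list (second return value); the GRCh37 annotation is only consulted
    for membership here because GTEx-style catalogs already encode the
    cis pairing.
    """
    unannotated = [g for g in network.gene_ids if g not in annotation.index]
    genes = [g for g in network.gene_ids if g in annotation.index]
    pairs = catalog[catalog["gene_id"].isin(genes)].copy()
    signs = network.genes["sign"]
    pairs["network_sign"] = pairs["gene_id"].map(signs).astype(int)
    return pairs.reset_index(drop=True), unannotated


@dataclass
class HarmonizationResult:
    """Harmonized pairs plus a reason-coded log of dropped records."""

    pairs: pd.DataFrame
    dropped: pd.DataFrame  # columns variant_id, gene_id, reason

    def drop_counts(self) -> pd.Series:
        if self.dropped.empty:
            return pd.Series(dtype=int)
        return self.dropped["reason"].value_counts()


def harmonize_alleles(
    pairs: pd.DataFrame,
    cohort_variants: pd.DataFrame,
    drop_ambiguous: bool = True,
) -> HarmonizationResult:
    """Orient each record's alleles to the cohort's dosage-counted allele.

    The cohort table (indexed by variant id) declares which allele its
    dosages count (``effect_allele``) and the other allele.  Records whose
    alleles match as-is keep ``flip = False``; records matching after
    swapping effect and other allele get ``flip = True`` (scoring then
    uses 2 - dosage); strand-ambiguous pairs (A/T, C/G) are dropped by
    default; anything else is dropped with a reason code
    (``absent_from_cohort`` / ``allele_mismatch``).
    """
    kept_rows, dropped_rows = [], []
    cohort_eff = cohort_variants["effect_allele"]
    cohort_oth = cohort_variants["other_allele"]
    for row in pairs.itertuples(index=False):
        rec = row._asdict()
        pair = (rec["effect_allele"], rec["other_allele"])
        if drop_ambiguous and pair in AMBIGUOUS_PAIRS:
            dropped_rows.append({**rec, "reason": "strand_ambiguous"})
            continue
        vid = rec["variant_id"]
        if vid not in cohort_eff.index:
            dropped_rows.append({**rec, "reason": "absent_from_cohort"})
            continue
        ce, co = cohort_eff[vid], cohort_oth[vid]
        if pair == (ce, co):
            rec["flip"] = False
        elif pair == (co, ce):
            rec["flip"] = True
        else:
            dropped_rows.append({**rec, "reason": "allele_mismatch"})
            continue
        kept_rows.append(rec)
    kept = pd.DataFrame(kept_rows, columns=list(pairs.columns) + ["flip"])
    dropped = pd.DataFrame(dropped_rows, columns=list(pairs.columns) + ["reason"])
    return HarmonizationResult(pairs=kept, dropped=dropped)


def deduplicate_snp_gene(pairs: pd.DataFrame) -> pd.DataFrame:
    """One record per variant: smallest eQTL p, ties by larger |slope| then gene id.

    A variant can be a cis-eQTL for several network genes; scoring needs a
    single weight per SNP, so the most significant gene-SNP record wins.
    """
    if pairs.empty:
        return pairs.copy()
    ranked = pairs.assign(_abs_slope=pairs["slope"].abs()).sort_values(
        ["variant_id", "pval_nominal", "_abs_slope", "gene_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    out = ranked.drop_duplicates("variant_id", keep="first").drop(columns="_abs_slope")
    return out.reset_index(drop=True)


@dataclass
class ClumpResult:
    """Retained pairs plus the per-index-SNP removal report."""

    pairs: pd.DataFrame
    report: pd.DataFrame  # columns index_snp, removed_snp, r2
    dropped_monomorphic: list[str] = field(default_factory=list)


def _dosage_r2(dosages: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns over shared non-missing rows."""
    a, b = dosages[:, i], dosages[:, j]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2:
        return 0.0
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_clump(
    pairs: pd.DataFrame,
    genotypes: GenotypeDosageMatrix,
    r2_max: float = DEFAULT_R2_MAX,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> ClumpResult:
    """Greedy LD clumping on cohort dosage r-squared.

    Index SNPs are taken in order of ascending eQTL nominal p (ties:
    larger |slope|, then variant id); each index removes every not-yet
    retained SNP on the same chromosome within ``window_kb`` whose dosage
    r-squared with it is >= ``r2_max``.  Monomorphic SNPs are dropped
    before clumping.  Post-condition (asserted): no two retained SNPs
    within the window have r-squared >= ``r2_max``.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must lie in (0, 1]")
    if pairs.empty:
        return ClumpResult(pairs.copy(), pd.DataFrame(columns=["index_snp", "removed_snp", "r2"]))
    missing = [v for v in pairs["variant_id"] if v not in genotypes.variant_ids]
    if missing:
        raise KeyError(f"no dosages for {len(missing)} variants, e.g. {missing[:3]}")

    cols = list(pairs["variant_id"])
    dos = genotypes.dosages[cols].to_numpy(dtype=float)
    stds = np.nanstd(dos, axis=0)
    mono = stds == 0
    dropped_monomorphic = [cols[i] for i in np.where(mono)[0]]
    work = pairs[~pairs["variant_id"].isin(dropped_monomorphic)].copy()

    order = work.assign(_abs_slope=work["slope"].abs()).sort_values(
        ["pval_nominal", "_abs_slope", "variant_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    col_of = {v: i for i, v in enumerate(cols)}
    vids = work["variant_id"].to_numpy()
    chroms = work["chrom"].astype(str).to_numpy()
    positions = work["pos"].to_numpy(dtype=float)
    pos_of = dict(zip(vids, positions))
    chrom_of = dict(zip(vids, chroms))
    window = float(window_kb) * 1000.0

    retained: set[str] = set()
    retained_order: list[str] = []
    removed: set[str] = set()
    report_rows = []
    for row in order.itertuples(index=False):
        vid = row.variant_id
        if vid in removed:
            continue
        retained.add(vid)
        retained_order.append(vid)
        near_mask = (chroms == chrom_of[vid]) & (
            np.abs(positions - pos_of[vid]) <= window
        )
        for other in vids[near_mask]:
            if other == vid or other in removed or other in retained:
                continue
            r2 = _dosage_r2(dos, col_of[vid], col_of[other])
            if r2 >= r2_max:
                removed.add(other)
                report_rows.append({"index_snp": vid, "removed_snp": other, "r2": r2})

    kept = work[work["variant_id"].isin(retained)].reset_index(drop=True)
    report = pd.DataFrame(report_rows, columns=["index_snp", "removed_snp", "r2"])
    _assert_clump_postcondition(kept, dos, col_of, r2_max, window)
    return ClumpResult(pairs=kept, report=report, dropped_monomorphic=dropped_monomorphic)


def max_retained_r2(
    pairs: pd.DataFrame,
    genotypes: GenotypeDosageMatrix,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> float:
    """Largest dosage r-squared among retained within-window SNP pairs.

    Audit statistic for a clumped set: by the clump post-condition it must
    be below the r2_max used.  Returns 0.0 when no within-window pair exists.
    """
    if pairs.empty:
        return 0.0
    cols = list(pairs["variant_id"])
    dos = genotypes.dosages[cols].to_numpy(dtype=float)
    col_of = {v: i for i, v in enumerate(cols)}
    srt = pairs[["variant_id", "chrom", "pos"]].sort_values(["chrom", "pos"], kind="mergesort")
    vids = srt["variant_id"].to_numpy()
    chroms = srt["chrom"].astype(str).to_numpy()
    positions = srt["pos"].to_numpy(dtype=float)
    window_bp = float(window_kb) * 1000.0
    worst = 0.0
    for i in range(len(vids)):
        j = i + 1
        while (
            j < len(vids)
            and chroms[j] == chroms[i]
            and positions[j] - positions[i] <= window_bp
        ):
            worst = max(worst, _dosage_r2(dos, col_of[vids[i]], col_of[vids[j]]))
            j += 1
    return worst


def _assert_clump_postcondition(
    kept: pd.DataFrame,
    dosages: np.ndarray,
    col_of: dict[str, int],
    r2_max: float,
    window_bp: float,
) -> None:
    """Exhaustive check: no retained within-window pair with r2 >= r2_max.

    Pairs outside the window (different chromosome or too far apart) are
    exempt by construction, so only position-sorted neighbours are tested.
    """
    srt = kept[["variant_id", "chrom", "pos"]].sort_values(["chrom", "pos"], kind="mergesort")
    vids = srt["variant_id"].to_numpy()
    chroms = srt["chrom"].astype(str).to_numpy()
    positions = srt["pos"].to_numpy(dtype=float)
    for i in range(len(vids)):
        j = i + 1
        while (
            j < len(vids)
            and chroms[j] == chroms[i]
            and positions[j] - positions[i] <= window_bp
        ):
            r2 = _dosage_r2(dosages, col_of[vids[i]], col_of[vids[j]])
            if r2 >= r2_max:
                raise AssertionError(
                    f"clump post-condition violated: {vids[i]} vs {vids[j]} "
                    f"r2={r2:.3f} >= {r2_max}"
                )
            j += 1
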