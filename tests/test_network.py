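"""Co-expression network construction against hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from coexprs import network as net
from coexprs.types import STAGE_ADULT, STAGE_EARLY, ExpressionMatrix

from conftest import toy_expression


def _pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


class TestComputeCoexpression:
    def test_toy_vectors_match_hand_pearson(self):
        anchor = [1, 2, 3, 4, 5]
        rows = {
            "DCC": anchor,
            "twice": [2, 4, 6, 8, 10],      # r = 1
            "reversed": [5, 4, 3, 2, 1],    # r = -1
            "bump": [1, 1, 2, 1, 1],        # hand-check oracle below
        }
        expr = toy_expression(np.array(list(rows.values()), float), list(rows))
        prof = net.compute_coexpression(expr, "DCC", "PFC")
        assert prof.correlations["DCC"] == 1.0
        assert prof.correlations["twice"] == pytest.approx(1.0)
        assert prof.correlations["reversed"] == pytest.approx(-1.0)
        assert prof.correlations["bump"] == pytest.approx(_pearson(anchor, rows["bump"]))

    def test_constant_gene_excluded_with_reason(self):
        expr = toy_expression(
            np.array([[1.0, 2, 3, 4], [7, 7, 7, 7]]), ["DCC", "flat"]
        )
        prof = net.compute_coexpression(expr, "DCC", "PFC")
        assert "flat" not in prof.correlations.index
        assert prof.excluded["flat"] == "constant_expression"

    def test_absent_anchor_raises(self):
        expr = toy_expression(np.random.default_rng(0).random((2, 5)), ["a", "b"])
        with pytest.raises(KeyError):
            net.compute_coexpression(expr, "DCC", "PFC")


class TestFilters:
    def test_correlation_boundary_inclusive_both_signs(self):
        prof = net.CoexpressionProfile(
            region="PFC",
            anchor_gene="DCC",
            correlations=pd.Series({"DCC": 1.0, "a": 0.50, "b": -0.50, "c": 0.499}),
        )
        kept = net.apply_coexpression_filter(prof, 0.5)
        assert set(kept.index) == {"DCC", "a", "b"}
        assert kept.loc["a", "sign"] == 1
        assert kept.loc["b", "sign"] == -1

    def test_fold_boundary_inclusive_and_pseudocount(self):
        vals = np.array(
            [
                [3.0, 3.0, 2.0, 2.0],   # fold exactly 1.5 -> retained (inclusive)
                [2.9, 2.9, 2.0, 2.0],   # fold 1.45 -> out
                [1.0, 1.0, 0.0, 0.0],   # adult mean 0 -> pseudocount rule
            ]
        )
        genes = ["g_at_boundary", "g_below", "g_zero_adult"]
        cols = [f"s{j}" for j in range(4)]
        samples = pd.DataFrame(
            {
                "region": "PFC",
                "stage": [STAGE_EARLY] * 2 + [STAGE_ADULT] * 2,
            },
            index=pd.Index(cols, name="sample_id"),
        )
        expr = ExpressionMatrix(
            values=pd.DataFrame(vals, index=pd.Index(genes, name="gene_id"), columns=cols),
            samples=samples,
        )
        candidates = pd.DataFrame(
            {"r": [0.9, 0.9, 0.9], "sign": [1, 1, 1]},
            index=pd.Index(genes, name="gene_id"),
        )
        # exact boundary check without the pseudocount perturbation
        retained0, enrich0 = net.apply_developmental_filter(
            expr, candidates.drop(index="g_zero_adult"), "PFC", min_fold=1.5, pseudocount=0.0
        )
        assert enrich0.loc["g_at_boundary", "fold_change"] == pytest.approx(1.5)
        assert "g_at_boundary" in retained0.index      # >= is inclusive
        assert "g_below" not in retained0.index        # 1.45 < 1.5
        # pseudocount rescues the zero-adult denominator
        retained, enrich = net.apply_developmental_filter(
            expr, candidates, "PFC", min_fold=1.5, pseudocount=0.01
        )
        assert "g_zero_adult" in retained.index
        assert enrich.loc["g_zero_adult", "fold_change"] == pytest.approx(1.0 / 0.01)

    def test_no_adult_samples_rejected(self):
        expr = toy_expression(np.ones((2, 4)) + np.arange(4), ["DCC", "g"], stage=STAGE_EARLY)
        with pytest.raises(ValueError, match="adult"):
            net.developmental_enrichment(expr, "PFC")


def _brute_force_network(values, samples, anchor, region, min_abs_r, min_fold,
                         include_anchor=True, pseudocount=0.01):
    """Direct Pearson + explicit threshold loops, independent of the package path."""
    region_cols = [s for s in values.columns if samples.loc[s, "region"] == region]
    early = [s for s in region_cols if samples.loc[s, "stage"] == STAGE_EARLY]
    adult = [s for s in region_cols if samples.loc[s, "stage"] == STAGE_ADULT]
    anchor_vec = values.loc[anchor, region_cols]
    kept = {}
    for gene in values.index:
        vec = values.loc[gene, region_cols]
        if np.std(vec) == 0:
            continue
        r = _pearson(anchor_vec, vec)
        if abs(r) < min_abs_r:
            continue
        fold = values.loc[gene, early].mean() / (values.loc[gene, adult].mean() + pseudocount)
        if fold >= min_fold:
            kept[gene] = np.sign(r)
    if include_anchor:
        kept[anchor] = 1.0
    return kept


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_build_network_matches_brute_force(seed):
    """On <=20x20 matrices the composed filters equal the explicit loop oracle."""
    rng = np.random.default_rng(seed)
    genes = ["DCC"] + [f"g{i}" for i in range(19)]
    cols = [f"s{j}" for j in range(20)]
    values = pd.DataFrame(
        rng.random((20, 20)) * 3 + 0.5, index=pd.Index(genes, name="gene_id"), columns=cols
    )
    # correlate a handful of genes with the anchor so some pass
    for i in (1, 3, 5, 7):
        values.iloc[i] = values.iloc[0] * (1 if i < 5 else -1) + rng.normal(0, 0.4, 20)
    samples = pd.DataFrame(
        {"region": "PFC", "stage": [STAGE_EARLY] * 10 + [STAGE_ADULT] * 10},
        index=pd.Index(cols, name="sample_id"),
    )
    # plant some developmental enrichment
    values.loc[:, cols[:10]] *= rng.choice([1.0, 1.8], size=20)[:, None]
    expr = ExpressionMatrix(values=values, samples=samples)
    oracle = _brute_force_network(values, samples, "DCC", "PFC", 0.5, 1.5)
    result = net.build_network(expr, "DCC", "PFC", 0.5, 1.5)
    assert set(result.gene_ids) == set(oracle)
    for gene, sign in oracle.items():
        assert result.genes.loc[gene, "sign"] == sign


def test_filter_monotonicity_in_both_thresholds(small_study):
    """Raising either threshold never adds a gene (network shrinks)."""
    expr = small_study.expr
    prev = None
    for min_r in (0.3, 0.5, 0.7, 0.9):
        got = set(
            net.build_network(expr, "DCC", "PFC", min_r, 1.5, corr_stage="early").gene_ids
        )
        if prev is not None:
            assert got <= prev
        prev = got
    prev = None
    for min_fold in (1.0, 1.5, 2.5, 4.0):
        got = set(
            net.build_network(expr, "DCC", "PFC", 0.5, min_fold, corr_stage="early").gene_ids
        )
        if prev is not None:
            assert got <= prev
        prev = got


def test_sign_consistency_with_recomputed_correlation(small_result, small_study):
    for region, network in small_result.networks.items():
        prof = net.compute_coexpression(small_study.expr, "DCC", region, stage="early")
        for gene in network.gene_ids:
            assert network.genes.loc[gene, "sign"] == np.sign(prof.correlations[gene])


def test_all_null_correlations_give_anchor_only_or_empty():
    rng = np.random.default_rng(10)
    from coexprs import synthetic as syn

    spec = syn.ExpressionSimSpec(
        n_genes=6,
        anchor_index=0,
        target_correlations=[1.0, 0, 0, 0, 0, 0],
        fold_changes=[2.0] * 6,
        n_samples_early=200,
        n_samples_adult=200,
        seed=13,
    )
    expr = syn.simulate_expression(spec)
    # correlation within one stage: pooled stages would confound the shared
    # developmental mean shift with co-expression
    with_anchor = net.build_network(
        expr, "G0000", "PFC", include_anchor=True, corr_stage="early"
    )
    assert with_anchor.gene_ids == ["G0000"]
    with pytest.warns(UserWarning, match="empty"):
        without = net.build_network(
            expr, "G0000", "PFC", include_anchor=False, corr_stage="early"
        )
    assert without.size == 0


class TestStability:
    @staticmethod
    def _clustered_matrix(rng, n_samples, preserved=True):
        """Two planted clusters; the second decorrelates when not preserved."""
        z1, z2 = rng.standard_normal((2, n_samples))
        rows = []
        for _ in range(4):
            rows.append(z1 + rng.normal(0, 0.3, n_samples))
        for _ in range(4):
            base = z2 if preserved else rng.standard_normal(n_samples)
            rows.append(base + rng.normal(0, 0.3, n_samples))
        return np.array(rows)

    def test_identity_case_preservation_equals_childhood(self):
        rng = np.random.default_rng(0)
        child = pd.DataFrame(
            self._clustered_matrix(rng, 60),
            index=[f"g{i}" for i in range(8)],
        )
        rep = net.coexpression_stability(child, child.copy())
        assert np.allclose(rep.preservation["mean_r_adult"], rep.preservation["mean_r_child"])
        assert rep.corr_child.index.equals(rep.corr_adult.index)

    def test_independent_adult_noise_kills_preservation(self):
        rng = np.random.default_rng(1)
        child = pd.DataFrame(
            self._clustered_matrix(rng, 400), index=[f"g{i}" for i in range(8)]
        )
        adult = pd.DataFrame(
            rng.standard_normal((8, 400)), index=child.index
        )
        rep = net.coexpression_stability(child, adult)
        tight = rep.preservation[rep.preservation["n_genes"] >= 2]
        assert (tight["mean_r_adult"].abs() < 0.15).all()
        assert (tight["mean_r_child"] > 0.5).any()

    def test_partially_preserved_cluster_ranks_higher(self):
        rng = np.random.default_rng(2)
        child = self._clustered_matrix(rng, 300)
        # adulthood: cluster 1 (genes 0-3) preserved, cluster 2 decorrelated
        z1 = rng.standard_normal(300)
        adult = np.vstack(
            [z1 + rng.normal(0, 0.3, 300) for _ in range(4)]
            + [rng.standard_normal(300) for _ in range(4)]
        )
        genes = [f"g{i}" for i in range(8)]
        rep = net.coexpression_stability(
            pd.DataFrame(child, index=genes), pd.DataFrame(adult, index=genes)
        )
        by_member = rep.clusters
        pres = rep.preservation
        c_kept = by_member["g0"]
        c_lost = by_member["g5"]
        assert pres.loc[c_kept, "mean_r_adult"] > pres.loc[c_lost, "mean_r_adult"]

    def test_adult_matrix_in_childhood_leaf_order(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(8)]
        child = pd.DataFrame(self._clustered_matrix(rng, 50), index=genes)
        adult = pd.DataFrame(rng.standard_normal((8, 50)), index=genes)
        rep = net.coexpression_stability(child, adult)
        assert list(rep.corr_adult.index) == list(rep.corr_child.index)
        assert list(rep.corr_adult.columns) == list(rep.corr_child.index)

    def test_gene_set_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        a = pd.DataFrame(rng.standard_normal((3, 30)), index=["a", "b", "c"])
        b = pd.DataFrame(rng.standard_normal((3, 30)), index=["a", "b", "d"])
        with pytest.raises(ValueError, match="different genes"):
            net.coexpression_stability(a, b)
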