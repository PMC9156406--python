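"""Cis-pair collection, allele harmonization, dedup and LD clumping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from coexprs import assembly as asm
from coexprs import synthetic as syn
from coexprs.network import CoexpressionNetwork

from conftest import toy_genotypes


def _network(genes_signs, region="PFC"):
    genes = pd.DataFrame(
        {
            "r": [0.8 * s for _, s in genes_signs],
            "sign": [s for _, s in genes_signs],
            "fold_change": 2.0,
        },
        index=pd.Index([g for g, _ in genes_signs], name="gene_id"),
    )
    return CoexpressionNetwork(
        region=region, anchor_gene="DCC", genes=genes, min_abs_r=0.5, min_fold=1.5,
        include_anchor=True,
    )


def _pairs(records):
    cols = ["gene_id", "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "slope", "pval_nominal"]
    return pd.DataFrame(records, columns=cols)


class TestCollect:
    def test_disjoint_genes_give_empty_list(self):
        net = _network([("DCC", 1)])
        ann = syn.make_gene_annotation(["DCC"])
        cat = _pairs([("OTHER", "rs1", "1", 100, "A", "G", 0.5, 1e-5)])
        pairs, unannotated = asm.collect_cis_pairs(net, cat, ann)
        assert pairs.empty and not unannotated

    def test_counting_and_sign_tagging(self):
        net = _network([("DCC", 1), ("g1", -1), ("g2", 1)])
        ann = syn.make_gene_annotation(["DCC", "g1", "g2"])
        cat = syn.simulate_eqtl_catalog(["DCC", "g1", "g2", ], ann, 4, seed=1)
        cat = pd.concat([cat, syn.simulate_eqtl_catalog(["g2"], ann, 2, seed=2)])
        pairs, _ = asm.collect_cis_pairs(net, cat, ann)
        assert len(pairs) == 3 * 4 + 2
        assert (pairs.loc[pairs["gene_id"] == "g1", "network_sign"] == -1).all()
        assert (pairs.loc[pairs["gene_id"] == "g2", "network_sign"] == 1).all()

    def test_unannotated_gene_reported(self):
        net = _network([("DCC", 1), ("ghost", 1)])
        ann = syn.make_gene_annotation(["DCC"])
        cat = _pairs([("ghost", "rs1", "1", 100, "A", "G", 0.5, 1e-5)])
        pairs, unannotated = asm.collect_cis_pairs(net, cat, ann)
        assert unannotated == ["ghost"]
        assert pairs.empty  # ghost's records excluded with it


class TestHarmonize:
    COHORT = pd.DataFrame(
        {
            "chrom": "1",
            "pos": [100, 200, 300],
            "effect_allele": ["A", "G", "C"],
            "other_allele": ["G", "A", "T"],
        },
        index=pd.Index(["rs1", "rs2", "rs3"], name="variant_id"),
    )

    def test_matching_swapped_ambiguous_and_absent(self):
        pairs = _pairs(
            [
                ("g", "rs1", "1", 100, "A", "G", 0.5, 1e-5),   # exact match
                ("g", "rs2", "1", 200, "A", "G", 0.5, 1e-5),   # swapped -> flip
                ("g", "rs3", "1", 300, "A", "T", 0.5, 1e-5),   # strand-ambiguous
                ("g", "rs9", "1", 900, "A", "G", 0.5, 1e-5),   # absent
                ("g", "rs3", "1", 300, "C", "A", 0.5, 1e-5),   # allele mismatch
            ]
        )
        res = asm.harmonize_alleles(pairs, self.COHORT)
        assert list(res.pairs["variant_id"]) == ["rs1", "rs2"]
        assert list(res.pairs["flip"]) == [False, True]
        reasons = dict(zip(res.dropped["variant_id"], res.dropped["reason"]))
        assert reasons == {
            "rs3": "strand_ambiguous",
            "rs9": "absent_from_cohort",
        } or reasons["rs9"] == "absent_from_cohort"
        assert set(res.dropped["reason"]) == {
            "strand_ambiguous", "absent_from_cohort", "allele_mismatch",
        }

    def test_ambiguous_kept_when_policy_disabled(self):
        pairs = _pairs([("g", "rs3", "1", 300, "C", "T", 0.5, 1e-5)])
        cohort = self.COHORT
        res = asm.harmonize_alleles(pairs, cohort, drop_ambiguous=False)
        assert list(res.pairs["variant_id"]) == ["rs3"]
        assert not res.pairs["flip"].iloc[0]


class TestDeduplicate:
    def test_single_gene_unchanged(self):
        pairs = _pairs([("g", "rs1", "1", 100, "A", "G", 0.5, 1e-5)]).assign(
            network_sign=1, flip=False
        )
        out = asm.deduplicate_snp_gene(pairs)
        pd.testing.assert_frame_equal(out, pairs)

    def test_smallest_p_wins(self):
        pairs = _pairs(
            [
                ("gA", "rs1", "1", 100, "A", "G", 0.2, 1e-3),
                ("gB", "rs1", "1", 100, "A", "G", 0.3, 1e-8),
            ]
        ).assign(network_sign=1, flip=False)
        out = asm.deduplicate_snp_gene(pairs)
        assert len(out) == 1 and out.loc[0, "gene_id"] == "gB"

    def test_p_tie_broken_by_abs_slope_then_gene(self):
        pairs = _pairs(
            [
                ("gA", "rs1", "1", 100, "A", "G", 0.4, 1e-5),
                ("gB", "rs1", "1", 100, "A", "G", -0.6, 1e-5),
            ]
        ).assign(network_sign=1, flip=False)
        out = asm.deduplicate_snp_gene(pairs)
        assert out.loc[0, "slope"] == -0.6
        # full tie -> lexicographically first gene
        pairs2 = pairs.assign(slope=[0.4, -0.4])
        assert asm.deduplicate_snp_gene(pairs2).loc[0, "gene_id"] == "gA"


def _clump_pairs(n, chrom="1", spacing=1000, pvals=None, slopes=None):
    pvals = pvals if pvals is not None else [10 ** -(n - i) for i in range(n)]
    slopes = slopes if slopes is not None else [0.5] * n
    return _pairs(
        [
            (f"g", f"rs{i}", chrom, 10_000 + spacing * i, "A", "G", slopes[i], pvals[i])
            for i in range(n)
        ]
    ).assign(network_sign=1, flip=False)


def _brute_force_clump(pairs, r2, r2_max, window_bp):
    """Exhaustive greedy reference: same priority rule, explicit loops."""
    order = pairs.assign(a=pairs["slope"].abs()).sort_values(
        ["pval_nominal", "a", "variant_id"], ascending=[True, False, True]
    )
    pos = dict(zip(pairs["variant_id"], pairs["pos"]))
    retained, removed = [], set()
    for vid in order["variant_id"]:
        if vid in removed:
            continue
        retained.append(vid)
        for other in pairs["variant_id"]:
            if other == vid or other in removed or other in retained:
                continue
            if abs(pos[other] - pos[vid]) <= window_bp and r2[vid][other] >= r2_max:
                removed.add(other)
    return retained


class TestClump:
    def test_duplicate_dosages_keep_highest_priority(self):
        pairs = _clump_pairs(2)
        d = np.random.default_rng(0).integers(0, 3, size=(50, 1)).astype(float)
        g = toy_genotypes(
            np.hstack([d, d]), variants=pairs.set_index("variant_id")[
                ["chrom", "pos", "effect_allele", "other_allele"]
            ],
        )
        res = asm.ld_clump(pairs, g, r2_max=0.2, window_kb=250)
        # priority = smallest eQTL p, which is rs1 here (p = 10^-1 vs 10^-2... )
        best = pairs.sort_values("pval_nominal").iloc[0]["variant_id"]
        assert list(res.pairs["variant_id"]) == [best]
        assert res.report.iloc[0]["r2"] == pytest.approx(1.0)

    def test_independent_snps_all_retained(self):
        pairs = _clump_pairs(5)
        rng = np.random.default_rng(1)
        g = toy_genotypes(
            rng.integers(0, 3, size=(4000, 5)).astype(float),
            variants=pairs.set_index("variant_id")[
                ["chrom", "pos", "effect_allele", "other_allele"]
            ],
        )
        res = asm.ld_clump(pairs, g, r2_max=0.2, window_kb=250)
        assert len(res.pairs) == 5

    def test_monomorphic_dropped_with_reason(self):
        pairs = _clump_pairs(2)
        d = np.hstack(
            [np.ones((30, 1)), np.random.default_rng(2).integers(0, 3, (30, 1)).astype(float)]
        )
        g = toy_genotypes(
            d, variants=pairs.set_index("variant_id")[
                ["chrom", "pos", "effect_allele", "other_allele"]
            ],
        )
        res = asm.ld_clump(pairs, g, r2_max=0.2, window_kb=250)
        assert res.dropped_monomorphic == ["rs0"]
        assert list(res.pairs["variant_id"]) == ["rs1"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_ten_snp_toys(self, seed):
        rng = np.random.default_rng(seed)
        n_snp = 10
        pairs = _clump_pairs(
            n_snp,
            spacing=int(rng.integers(500, 100_000)),
            pvals=list(rng.uniform(1e-8, 1e-2, n_snp)),
            slopes=list(rng.normal(0, 0.5, n_snp)),
        )
        # correlated dosage columns via shared latent factors
        spec = syn.GenotypeSimSpec(
            n_individuals=400, blocks=[(5, 0.7), (3, 0.5), (2, 0.0)], seed=seed
        )
        g = syn.simulate_genotypes(
            spec, pairs.set_index("variant_id")[
                ["chrom", "pos", "effect_allele", "other_allele"]
            ],
        )
        window_kb = 50.0
        res = asm.ld_clump(pairs, g, r2_max=0.2, window_kb=window_kb)
        d = g.dosages.to_numpy()
        vids = list(pairs["variant_id"])
        corr = np.corrcoef(d.T)
        r2 = {
            a: {b: corr[i, j] ** 2 for j, b in enumerate(vids)}
            for i, a in enumerate(vids)
        }
        expected = _brute_force_clump(pairs, r2, 0.2, window_kb * 1000)
        assert sorted(res.pairs["variant_id"]) == sorted(expected)

    def test_decreasing_r2_threshold_never_grows_retained_set(self):
        rng = np.random.default_rng(9)
        pairs = _clump_pairs(12, spacing=5_000, pvals=list(rng.uniform(1e-6, 1e-2, 12)))
        spec = syn.GenotypeSimSpec(n_individuals=300, blocks=[(6, 0.8), (6, 0.4)], seed=9)
        g = syn.simulate_genotypes(
            spec, pairs.set_index("variant_id")[
                ["chrom", "pos", "effect_allele", "other_allele"]
            ],
        )
        sizes = [
            len(asm.ld_clump(pairs, g, r2_max=r2, window_kb=250).pairs)
            for r2 in (0.8, 0.5, 0.2, 0.05)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        pairs = _clump_pairs(8, pvals=[1e-4] * 8)  # all tied -> tie-break path
        spec = syn.GenotypeSimSpec(n_individuals=200, blocks=[(8, 0.6)], seed=3)
        g = syn.simulate_genotypes(
            spec, pairs.set_index("variant_id")[
                ["chrom", "pos", "effect_allele", "other_allele"]
            ],
        )
        a = asm.ld_clump(pairs, g, 0.2, 250).pairs
        b = asm.ld_clump(pairs, g, 0.2, 250).pairs
        pd.testing.assert_frame_equal(a, b)
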