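import numpy as np
import pandas as pd
import pytest

from coexprs import synthetic as syn
from coexprs.pipeline import RegionPlan, default_config_for_study, run_from_objects, simulate_study
from coexprs.types import ExpressionMatrix, GenotypeDosageMatrix


@pytest.fixture(scope="session")
def small_study():
    """Two-region planted study, small enough for per-test reuse."""
    return simulate_study(
        [
            RegionPlan("PFC", n_pass=12, n_fail_r=6, n_fail_fold=4, snps_per_gene=5),
            RegionPlan("NAcc", n_pass=6, n_fail_r=6, n_fail_fold=4, snps_per_gene=5),
        ],
        n_individuals=400,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_result(small_study):
    cfg = default_config_for_study(small_study)
    return run_from_objects(
        small_study.expr,
        small_study.catalogs,
        small_study.annotation,
        small_study.genotypes,
        cfg,
    )


def toy_genotypes(dosages: np.ndarray, variants: pd.DataFrame | None = None,
                  ids=None) -> GenotypeDosageMatrix:
    """Wrap a raw dosage array in a GenotypeDosageMatrix with stub variants."""
    n, m = dosages.shape
    if variants is None:
        variants = syn.make_variant_table(m, seed=5)
    frame = pd.DataFrame(
        dosages,
        index=pd.Index(ids if ids is not None else [f"i{k}" for k in range(n)],
                       name="individual_id"),
        columns=variants.index,
    )
    return GenotypeDosageMatrix(dosages=frame, variants=variants)


def toy_expression(values: np.ndarray, genes, region="PFC", stage="early") -> ExpressionMatrix:
    """Single-region, single-stage expression matrix from a raw array."""
    n_samples = values.shape[1]
    cols = [f"s{j}" for j in range(n_samples)]
    samples = pd.DataFrame(
        {"region": region, "stage": stage},
        index=pd.Index(cols, name="sample_id"),
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols),
        samples=samples,
    )
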