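import numpy as np
import pytest

from scmulti import (
    AssayMatrix,
    CloneSpec,
    DnaVariantAssay,
    SyntheticConfig,
    build_sample,
    default_config,
    simulate_sample,
)


def make_dna(barcodes, n_variants=3, af=None, ngt=None, gq=None, dp=None):
    """Tiny hand-rolled DNA assay with benign defaults (all calls valid)."""
    n = len(barcodes)
    shape = (n, n_variants)
    return DnaVariantAssay(
        AF=np.zeros(shape) if af is None else np.asarray(af, float),
        NGT=np.zeros(shape, int) if ngt is None else np.asarray(ngt, int),
        GQ=np.full(shape, 99.0) if gq is None else np.asarray(gq, float),
        DP=np.full(shape, 50) if dp is None else np.asarray(dp, int),
        cell_barcodes=np.array(barcodes, dtype=object),
        variant_ids=np.array(
            [f"chr1:{100 + i}:A/T" for i in range(n_variants)], dtype=object
        ),
    )


def make_counts(barcodes, n_features=2, values=None, prefix="F", units="count"):
    n = len(barcodes)
    if values is None:
        values = np.ones((n, n_features), dtype=int)
    values = np.asarray(values)
    return AssayMatrix(
        values=values,
        cell_barcodes=np.array(barcodes, dtype=object),
        feature_ids=np.array(
            [f"{prefix}{i}" for i in range(values.shape[1])], dtype=object
        ),
        units=units,
    )


def make_sample(barcodes=("c1", "c2", "c3"), n_variants=3, **dna_kwargs):
    dna = make_dna(barcodes, n_variants, **dna_kwargs)
    cnv = make_counts(barcodes, prefix="AMP")
    protein = make_counts(barcodes, prefix="P")
    sample, _ = build_sample(dna, cnv, protein)
    return sample


@pytest.fixture
def toy_sample():
    return make_sample()


@pytest.fixture(scope="session")
def fixture_sample():
    """The default separated 3-clone synthetic sample plus its ground truth."""
    return simulate_sample(default_config(seed=7))


def random_config(rng, max_cells=12):
    """Small random generator config for property tests."""
    n_clones = int(rng.integers(1, 4))
    n_variants = int(rng.integers(1, 6))
    n_amplicons = int(rng.integers(1, 6))
    n_proteins = int(rng.integers(2, 6))
    clones = [
        CloneSpec(
            n_cells=int(rng.integers(1, max_cells)),
            genotypes=rng.integers(0, 3, n_variants),
            copy_numbers=rng.integers(1, 5, n_amplicons),
            protein_means=rng.uniform(5, 200, n_proteins),
        )
        for _ in range(n_clones)
    ]
    return SyntheticConfig(clones=clones, seed=int(rng.integers(0, 2**31)))
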