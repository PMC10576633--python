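import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from scmulti import (
    CloneLabels,
    CloneSpec,
    ClusterParams,
    QCThresholds,
    SyntheticConfig,
    annotate_variants,
    call_validity_mask,
    clone_sorted_matrix,
    feature_overlay,
    filter_variants,
    identify_clones,
    simulate_sample,
)
from scmulti.data_model import SampleError
from scmulti.dna_variants import (
    DictAnnotationProvider,
    FilterError,
    TableAnnotationProvider,
    parse_variant_id,
)

from conftest import make_counts, make_dna, make_sample


class TestCallValidityMask:
    def test_all_rules_pass(self):
        dna = make_dna(["a"], 1, dp=[[50]], gq=[[99]], ngt=[[1]], af=[[45.0]])
        assert call_validity_mask(dna, QCThresholds())[0, 0]

    def test_depth_rule_fails_alone(self):
        dna = make_dna(["a"], 1, dp=[[9]], gq=[[99]], ngt=[[0]], af=[[0.0]])
        assert not call_validity_mask(dna, QCThresholds())[0, 0]

    def test_boundary_grid_matches_enumeration(self):
        # every combination of boundary values, checked one call at a time
        # against a scalar re-statement of the rules
        combos = list(itertools.product((9, 10), (29, 30), (0, 1, 3), (19.0, 20.0)))
        dp = np.array([[c[0] for c in combos]])
        gq = np.array([[c[1] for c in combos]])
        ngt = np.array([[c[2] for c in combos]])
        af = np.array([[c[3] for c in combos]])
        dna = make_dna(["a"], len(combos), dp=dp, gq=gq, ngt=ngt, af=af)
        mask = call_validity_mask(dna, QCThresholds())
        for j, (d, g, n, a) in enumerate(combos):
            expected = (n != 3) and d >= 10 and g >= 30 and (n == 0 or a >= 20)
            assert mask[0, j] == expected, f"combo {(d, g, n, a)}"


class TestFilterVariants:
    def test_all_pass_keeps_everything(self):
        ngt = np.zeros((10, 3), int)
        ngt[0, :] = 1  # each variant mutated in 1 of 10 cells
        sample = make_sample([f"c{i}" for i in range(10)], 3, ngt=ngt,
                             af=np.where(ngt == 1, 50.0, 0.0))
        out, report = filter_variants(sample)
        assert report.cells_after == 10
        assert report.variants_after == 3
        assert out.status.dna_filtered

    def test_toy_example_by_hand(self):
        # 6 cells x 4 variants; thresholds (cell 0.5, variant 0.5, mutated 0.1)
        # cell 5 valid at only 1/4 variants -> dropped
        # variant 2 valid in 2/6 remaining cells -> dropped (completeness)
        # variant 3 never mutated -> dropped (mutated fraction)
        n_cells, n_variants = 6, 4
        dp = np.full((n_cells, n_variants), 50)
        gq = np.full((n_cells, n_variants), 99.0)
        ngt = np.zeros((n_cells, n_variants), int)
        ngt[:, 0] = [1, 1, 0, 0, 0, 1]
        ngt[:, 1] = [0, 1, 1, 0, 0, 0]
        dp[5, [1, 2, 3]] = 0        # cell 5: only variant 0 valid
        gq[[0, 1, 2], 2] = 0.0      # variant 2: invalid in cells 0-2 (+cell 5)
        ngt[0, 2] = 1               # variant 2 mutated where invalid anyway
        # variant 3 stays NGT=0 everywhere: never mutated
        af = np.where(np.isin(ngt, [1, 2]), 50.0, 0.0)
        sample = make_sample([f"c{i}" for i in range(n_cells)], n_variants,
                             dp=dp, gq=gq, ngt=ngt, af=af)
        qc = QCThresholds(variant_min_mutated_fraction=0.1)
        out, report = filter_variants(sample, qc)
        assert report.cells_after == 5
        assert "c5" not in out.cell_barcodes
        assert report.variants_after == 2
        assert list(out.dna.variant_ids) == ["chr1:100:A/T", "chr1:101:A/T"]
        assert report.removed["cells_low_valid_fraction"] == 1
        assert report.removed["variants_low_valid_fraction"] == 1
        assert report.removed["variants_low_mutated_fraction"] == 1

    def test_cell_removal_hits_all_assays(self):
        ngt = np.zeros((4, 2), int)
        ngt[0] = 1
        dp = np.full((4, 2), 50)
        dp[3] = 0  # cell d fails everywhere
        sample = make_sample(["a", "b", "c", "d"], 2, ngt=ngt,
                             af=np.where(ngt == 1, 50.0, 0.0), dp=dp)
        out, _ = filter_variants(sample)
        assert out.n_cells == 3
        assert out.cnv.n_cells == 3 and out.protein.n_cells == 3
        # feature axes untouched
        assert out.cnv.n_features == sample.cnv.n_features
        assert out.protein.n_features == sample.protein.n_features

    def test_all_cells_removed_is_fatal(self):
        sample = make_sample(["a", "b"], 2, dp=np.zeros((2, 2), int))
        with pytest.raises(FilterError, match="cells removed"):
            filter_variants(sample)

    def test_all_variants_removed_is_fatal(self):
        # valid calls everywhere but nothing ever mutated
        sample = make_sample(["a", "b", "c"], 2)
        with pytest.raises(FilterError, match="variants removed"):
            filter_variants(sample)

    def test_monotone_in_each_threshold(self):
        config = SyntheticConfig(
            clones=[
                CloneSpec(40, [0, 1, 2, 0, 1], [2, 2], [50, 50]),
                CloneSpec(30, [1, 0, 0, 2, 0], [2, 2], [50, 50]),
            ],
            seed=5,
            mean_depth=14.0,  # DP straddles the min_depth boundary
            dropout_rate=0.1,
        )
        sample, _ = simulate_sample(config)

        def dims(qc):
            try:
                _, report = filter_variants(sample, qc)
                return report.cells_after, report.variants_after
            except FilterError:
                return 0, 0

        grids = {
            "min_depth": [5, 10, 15, 20],
            "min_af_mutated": [10.0, 30.0, 60.0],
            "cell_min_valid_fraction": [0.2, 0.5, 0.8, 0.95],
            "variant_min_valid_fraction": [0.2, 0.5, 0.8, 0.95],
            "variant_min_mutated_fraction": [0.0, 0.2, 0.5],
        }
        for name, values in grids.items():
            results = [dims(QCThresholds(**{name: v})) for v in values]
            for (c0, v0), (c1, v1) in zip(results, results[1:]):
                assert c1 <= c0 and v1 <= v0, f"non-monotone in {name}: {results}"


class TestIdentifyClones:
    def test_identical_rows_single_clone(self):
        af = np.full((20, 3), 50.0)
        sample = make_sample([f"c{i:02d}" for i in range(20)], 3, af=af,
                             ngt=np.ones((20, 3), int))
        sample.status.dna_filtered = True
        labels = identify_clones(sample, ClusterParams(epsilon=0.1, min_points=5))
        assert labels.n_clones == 1
        assert (labels.labels == 1).all()

    def test_separated_clones_recovered_exactly(self):
        config = SyntheticConfig(
            clones=[
                CloneSpec(100, [0] * 10, [2] * 4, [50] * 4),
                CloneSpec(100, [1] * 5 + [0] * 5, [2] * 4, [50] * 4),
                CloneSpec(100, [0] * 5 + [2] * 5, [2] * 4, [50] * 4),
            ],
            seed=11,
            vaf_noise_sd=2.0,  # 0.02 in scaled-VAF space
            dropout_rate=0.0,
        )
        sample, truth = simulate_sample(config)
        sample.status.dna_filtered = True
        labels = identify_clones(sample, ClusterParams(epsilon=0.2, min_points=10))
        assert adjusted_rand_score(truth.true_labels.labels, labels.labels) == 1.0

    def test_row_permutation_permutes_labels(self):
        config = SyntheticConfig(
            clones=[
                CloneSpec(30, [0, 0, 0], [2], [50, 50]),
                CloneSpec(20, [2, 2, 0], [2], [50, 50]),
            ],
            seed=3,
            dropout_rate=0.0,
        )
        sample, _ = simulate_sample(config)
        sample.status.dna_filtered = True
        params = ClusterParams(epsilon=0.2, min_points=5)
        labels = identify_clones(sample, params)
        rng = np.random.default_rng(0)
        perm = rng.permutation(sample.n_cells)
        shuffled = sample.subset_cells(perm)
        shuffled.status.dna_filtered = True
        labels_perm = identify_clones(shuffled, params)
        assert adjusted_rand_score(labels.labels[perm], labels_perm.labels) == 1.0

    def test_too_few_cells_errors(self):
        sample = make_sample(["a", "b"])
        sample.status.dna_filtered = True
        with pytest.raises(SampleError, match="min_points"):
            identify_clones(sample, ClusterParams(min_points=10))

    def test_unfiltered_sample_warns_but_runs(self, caplog):
        af = np.zeros((15, 3))
        sample = make_sample([f"c{i:02d}" for i in range(15)], 3, af=af)
        with caplog.at_level("WARNING"):
            identify_clones(sample, ClusterParams(epsilon=0.1, min_points=5))
        assert any("not been QC-filtered" in r.message for r in caplog.records)

    def test_auto_epsilon_is_logged(self, caplog):
        config = SyntheticConfig(
            clones=[CloneSpec(40, [0, 1], [2], [50, 50]),
                    CloneSpec(40, [2, 0], [2], [50, 50])],
            seed=9, dropout_rate=0.0,
        )
        sample, _ = simulate_sample(config)
        sample.status.dna_filtered = True
        with caplog.at_level("INFO"):
            identify_clones(sample, ClusterParams(min_points=10))
        assert any("auto-estimated epsilon" in r.message for r in caplog.records)


class TestCloneSortedMatrix:
    def test_sort_key_example(self):
        matrix = make_counts(["a", "b", "c"], values=np.array([[1], [2], [3]]))
        labels = CloneLabels(np.array([2, 1, 1]))
        reordered, annotation = clone_sorted_matrix(matrix, labels)
        assert list(reordered.cell_barcodes) == ["b", "c", "a"]
        np.testing.assert_array_equal(annotation["clone"], [1, 1, 2])

    def test_equal_labels_sorts_by_barcode(self):
        matrix = make_counts(["z", "a", "m"])
        labels = CloneLabels(np.ones(3, dtype=int))
        reordered, _ = clone_sorted_matrix(matrix, labels)
        assert list(reordered.cell_barcodes) == ["a", "m", "z"]

    def test_rows_are_a_permutation(self):
        rng = np.random.default_rng(4)
        values = rng.integers(0, 100, (8, 3))
        matrix = make_counts([f"c{i}" for i in range(8)], values=values)
        labels = CloneLabels(np.array([0, 2, 1, 1, 2, 0, 1, 2]))
        reordered, _ = clone_sorted_matrix(matrix, labels)
        assert sorted(map(tuple, reordered.values)) == sorted(map(tuple, values))

    def test_length_mismatch_errors(self):
        matrix = make_counts(["a", "b"])
        with pytest.raises(SampleError, match="labels length"):
            clone_sorted_matrix(matrix, CloneLabels(np.array([1])))


class TestFeatureOverlay:
    def test_preserves_order(self):
        coords = np.array([[0.0, 0], [1, 1], [2, 2]])
        frame = feature_overlay(coords, [0, 50, 100], "VAF:chr1:100")
        np.testing.assert_array_equal(frame["value"], [0, 50, 100])
        np.testing.assert_array_equal(frame["x"], [0, 1, 2])
        assert (frame["feature"] == "VAF:chr1:100").all()

    def test_af_column_maps_identically(self, fixture_sample):
        sample, _ = fixture_sample
        coords = np.zeros((sample.n_cells, 2))
        frame = feature_overlay(coords, sample.dna.AF[:, 3], "v3")
        np.testing.assert_array_equal(frame["value"], sample.dna.AF[:, 3])

    def test_length_mismatch_errors(self):
        with pytest.raises(SampleError, match="values length"):
            feature_overlay(np.zeros((3, 2)), [1.0, 2.0], "x")


class TestAnnotateVariants:
    def test_empty_list(self):
        table = annotate_variants([], provider=DictAnnotationProvider({}))
        assert len(table) == 0

    def test_stub_lookup_in_query_order(self):
        records = {
            "chr1:100:A/T": {"gene": "G1", "protein_change": "p.A1T",
                             "function_class": "missense"},
            "chr2:200:C/G": {"gene": "G2", "protein_change": "p.C2G",
                             "function_class": "synonymous"},
            "chrX:5:G/A": {"gene": "G3", "protein_change": "p.G3A",
                           "function_class": "nonsense"},
        }
        ids = ["chrX:5:G/A", "chr1:100:A/T", "chr2:200:C/G"]
        table = annotate_variants(ids, provider=DictAnnotationProvider(records))
        assert list(table["variant_id"]) == ids
        assert list(table["gene"]) == ["G3", "G1", "G2"]
        assert list(table["pos"]) == [5, 100, 200]

    def test_provider_miss_gives_nulls(self):
        table = annotate_variants(
            ["chr9:1:A/T"], provider=DictAnnotationProvider({})
        )
        assert table.loc[0, "gene"] is None

    def test_malformed_id_errors(self):
        with pytest.raises(ValueError, match="chr:notanumber:A/T"):
            annotate_variants(["chr:notanumber:A/T"],
                              provider=DictAnnotationProvider({}))

    def test_parse_variant_id(self):
        parts = parse_variant_id("chr13:28592642:C/A")
        assert parts == {"chrom": "chr13", "pos": "28592642", "ref": "C", "alt": "A"}

    def test_bundled_table_provider(self):
        table = annotate_variants(["chr13:28592642:C/A"],
                                  provider=TableAnnotationProvider())
        assert table.loc[0, "gene"] == "FLT3"
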