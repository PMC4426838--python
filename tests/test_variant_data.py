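"""Variant table I/O and dataset-assembly rules."""

import numpy as np
import pytest

from varmkl.variant_data import (
    FeatureGroupSet,
    LabeledDataset,
    Variant,
    VariantTableError,
    assemble_training_set,
    filter_controls_by_maf,
    read_feature_group,
    read_variant_table,
    remove_pathogenic_overlap,
    select_negatives_within_window,
    split_by_coding,
    write_feature_group,
    write_variant_table,
)


class TestVariantInvariants:
    def test_rejects_bad_position_allele_maf(self):
        with pytest.raises(VariantTableError):
            Variant("chr1", 0, "A", "G")
        with pytest.raises(VariantTableError):
            Variant("chr1", 10, "A", "A")
        with pytest.raises(VariantTableError):
            Variant("chr1", 10, "A", "G", maf=0.6)

    def test_duplicate_key_rejected(self):
        v = Variant("chr1", 10, "A", "G", 1)
        with pytest.raises(VariantTableError, match="duplicate"):
            LabeledDataset.from_variants([v, v])


class TestReadWrite:
    def test_three_row_tsv_in_file_order(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "#chrom\tpos\tref\talt\tlabel\tmaf\tcoding\n"
            "chr2\t50\tG\tC\t1\t.\t1\n"
            "chr1\t10\tA\tG\t-1\t0.2\t0\n"
            "chr1\t5\tT\tA\t-1\t0.05\t.\n"
        )
        ds = read_variant_table(path)
        assert len(ds) == 3
        assert ds.keys() == [("chr2", 50, "G", "C"), ("chr1", 10, "A", "G"),
                             ("chr1", 5, "T", "A")]
        assert list(ds.labels) == [1, -1, -1]

    def test_duplicate_key_error_names_the_key(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "#chrom\tpos\tref\talt\tlabel\tmaf\tcoding\n"
            "chr1\t10\tA\tG\t1\t.\t.\n"
            "chr1\t10\tA\tG\t-1\t0.2\t.\n"
        )
        with pytest.raises(VariantTableError, match=r"chr1.*10.*A.*G"):
            read_variant_table(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "#chrom\tpos\tref\talt\tlabel\tmaf\tcoding\n"
            "chr1\tten\tA\tG\t1\t.\t.\n"
        )
        with pytest.raises(VariantTableError, match=r":2"):
            read_variant_table(path)

    def test_unknown_label_token_rejected(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "#chrom\tpos\tref\talt\tlabel\tmaf\tcoding\n"
            "chr1\t10\tA\tG\tpathogenic\t.\t.\n"
        )
        with pytest.raises(VariantTableError, match="label"):
            read_variant_table(path)

    def test_vcf_dialect_round_trips_to_same_dataset(self, tmp_path, toy_dataset):
        tsv, vcf = tmp_path / "v.tsv", tmp_path / "v.vcf"
        write_variant_table(toy_dataset, tsv, dialect="tsv")
        write_variant_table(toy_dataset, vcf, dialect="vcf-like")
        assert read_variant_table(tsv, "tsv") == read_variant_table(vcf, "vcf-like")

    def test_feature_group_round_trip_with_missingness(self, tmp_path,
                                                       toy_dataset, toy_features):
        path = tmp_path / "B.tsv"
        write_feature_group("B", toy_features, toy_dataset, path)
        mat = read_feature_group(path, toy_dataset)
        np.testing.assert_array_equal(
            np.isnan(mat), np.isnan(toy_features.matrices["B"])
        )
        np.testing.assert_allclose(
            mat[~np.isnan(mat)], toy_features.matrices["B"][~np.isnan(mat)]
        )


class TestMafFilter:
    def test_boundary_inclusive_and_below_removed(self, toy_dataset):
        out = filter_controls_by_maf(toy_dataset, min_maf=0.01)
        assert len(out) == 6  # 0.05, 0.01, 0.30 all pass
        tighter = filter_controls_by_maf(toy_dataset, min_maf=0.011)
        assert len(tighter) == 5  # the maf=0.01 control drops

    def test_just_below_threshold_removed(self):
        ds = LabeledDataset.from_variants(
            [Variant("chr1", 1, "A", "G", -1, maf=0.0099)]
        )
        assert len(filter_controls_by_maf(ds)) == 0

    def test_pathogenic_pass_through_and_empty_ok(self):
        empty = LabeledDataset.from_variants([])
        assert len(filter_controls_by_maf(empty)) == 0
        ds = LabeledDataset.from_variants([Variant("chr1", 1, "A", "G", 1)])
        assert len(filter_controls_by_maf(ds)) == 1

    def test_missing_maf_policy(self):
        ds = LabeledDataset.from_variants([Variant("chr1", 1, "A", "G", -1)])
        assert len(filter_controls_by_maf(ds, missing="drop")) == 0
        with pytest.raises(VariantTableError):
            filter_controls_by_maf(ds, missing="error")

    def test_idempotent(self, toy_dataset):
        once = filter_controls_by_maf(toy_dataset)
        assert filter_controls_by_maf(once) == once


class TestOverlapRemoval:
    def test_disjoint_unchanged_and_subset_annihilates(self, toy_dataset):
        other = LabeledDataset.from_variants([Variant("chrX", 7, "A", "G", 1)])
        assert remove_pathogenic_overlap(toy_dataset, other) == toy_dataset
        assert len(remove_pathogenic_overlap(toy_dataset, toy_dataset)) == 0

    def test_shared_keys_removed_in_order(self):
        controls = LabeledDataset.from_variants(
            [Variant("chr1", p, "A", "G", -1, maf=0.1) for p in (10, 20, 30, 40, 50)]
        )
        pathogenic = LabeledDataset.from_variants(
            [Variant("chr1", p, "A", "G", 1) for p in (20, 40)]
        )
        out = remove_pathogenic_overlap(controls, pathogenic)
        # brute-force key difference preserves original relative order
        expected = [k for k in controls.keys() if k not in set(pathogenic.keys())]
        assert out.keys() == expected
        assert len(out) == 3


class TestNegativeWindow:
    @staticmethod
    def _mk(label, coords):
        return LabeledDataset.from_variants(
            [Variant(c, p, "A", "G", label, maf=0.1) for c, p in coords]
        )

    def test_zero_distance_kept(self):
        neg = self._mk(-1, [("chr1", 500)])
        pos = self._mk(1, [("chr1", 500)])
        assert len(select_negatives_within_window(neg, pos, 1000)) == 1

    def test_just_outside_window_removed(self):
        neg = self._mk(-1, [("chr1", 2001), ("chr1", 2000)])
        pos = self._mk(1, [("chr1", 1000)])
        out = select_negatives_within_window(neg, pos, 1000)
        assert out.keys() == [("chr1", 2000, "A", "G")]

    def test_chromosome_mismatch_removed(self):
        neg = self._mk(-1, [("chr2", 500)])
        pos = self._mk(1, [("chr1", 500)])
        assert len(select_negatives_within_window(neg, pos, 1000)) == 0

    def test_infinite_window_keeps_shared_chromosomes(self):
        neg = self._mk(-1, [("chr1", 1), ("chr2", 10**8)])
        pos = self._mk(1, [("chr2", 5)])
        out = select_negatives_within_window(neg, pos, np.inf)
        assert out.keys() == [("chr2", 10**8, "A", "G")]

    def test_zero_window_keeps_exact_matches_only(self):
        neg = self._mk(-1, [("chr1", 500), ("chr1", 501)])
        pos = self._mk(1, [("chr1", 500)])
        out = select_negatives_within_window(neg, pos, 0)
        assert out.keys() == [("chr1", 500, "A", "G")]

    def test_idempotent(self):
        neg = self._mk(-1, [("chr1", 100), ("chr1", 5000), ("chr2", 100)])
        pos = self._mk(1, [("chr1", 400)])
        once = select_negatives_within_window(neg, pos, 1000)
        assert select_negatives_within_window(once, pos, 1000) == once


class TestSplitByCoding:
    def test_partition_sizes_and_union(self, toy_dataset):
        coding, noncoding = split_by_coding(toy_dataset)
        assert len(coding) == 3 and len(noncoding) == 3
        assert set(coding.keys()) | set(noncoding.keys()) == set(toy_dataset.keys())

    def test_all_coding_degenerate(self):
        ds = LabeledDataset.from_variants(
            [Variant("chr1", 1, "A", "G", 1, coding=True)]
        )
        coding, noncoding = split_by_coding(ds)
        assert len(coding) == 1 and len(noncoding) == 0

    def test_empty_input(self):
        coding, noncoding = split_by_coding(LabeledDataset.from_variants([]))
        assert len(coding) == 0 and len(noncoding) == 0

    def test_missing_flag_error_lists_keys(self):
        ds = LabeledDataset.from_variants([Variant("chr1", 1, "A", "G", 1)])
        with pytest.raises(VariantTableError, match="chr1"):
            split_by_coding(ds)


class TestAssembleTrainingSet:
    def test_identity_when_complete_and_unbalanced(self, toy_dataset):
        n = len(toy_dataset)
        features = FeatureGroupSet({"A": np.ones((n, 2))})
        ds, fg = assemble_training_set(toy_dataset, features)
        assert ds == toy_dataset
        assert fg.n_variants == n

    def test_balanced_max_takes_min_class_count(self):
        variants = [Variant("chr1", i + 1, "A", "G", 1) for i in range(10)]
        variants += [Variant("chr2", i + 1, "A", "G", -1, maf=0.1) for i in range(4)]
        ds = LabeledDataset.from_variants(variants)
        features = FeatureGroupSet({"A": np.ones((14, 2))})
        out, _ = assemble_training_set(ds, features, balanced=True, seed=0)
        labels = out.labels
        assert (labels == 1).sum() == 4 and (labels == -1).sum() == 4

    def test_group_missing_rows_excluded(self, toy_dataset, toy_features):
        out, fg = assemble_training_set(toy_dataset, toy_features)
        assert len(out) == 5  # row 1 is group-missing in B
        assert not any(fg.group_missing[g].any() for g in fg.group_names)

    def test_seed_reproducibility(self):
        variants = [Variant("chr1", i + 1, "A", "G", 1 if i < 20 else -1,
                            maf=0.1) for i in range(40)]
        ds = LabeledDataset.from_variants(variants)
        features = FeatureGroupSet({"A": np.ones((40, 1))})
        a1, _ = assemble_training_set(ds, features, balanced=True,
                                      n_per_class=5, seed=7)
        a2, _ = assemble_training_set(ds, features, balanced=True,
                                      n_per_class=5, seed=7)
        b, _ = assemble_training_set(ds, features, balanced=True,
                                     n_per_class=5, seed=8)
        assert a1 == a2
        assert a1.keys() != b.keys()

    def test_empty_class_errors(self):
        ds = LabeledDataset.from_variants([Variant("chr1", 1, "A", "G", 1)])
        features = FeatureGroupSet({"A": np.ones((1, 1))})
        with pytest.raises(VariantTableError):
            assemble_training_set(ds, features, balanced=True)
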