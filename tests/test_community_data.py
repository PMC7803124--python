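"""Data model, file round-trips, rank aggregation, rarefying, filtering."""

import numpy as np
import pandas as pd
import pytest

from rumenakp import community_data as cd
from tests.conftest import random_table


class TestCommunityTable:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            cd.CommunityTable(["a"], ["o1"], np.array([[-1]]))
        with pytest.raises(ValueError):
            cd.CommunityTable(["a", "a"], ["o1"], np.array([[1], [2]]))
        with pytest.raises(ValueError):
            cd.CommunityTable(["a", "b"], ["o1"], np.array([[1], [0]]))
        with pytest.raises(ValueError):
            cd.CommunityTable(["a"], ["o1", "o2"], np.array([[1.5, 2.0]]))

    def test_relative_abundances_sum_to_one(self, tiny_table):
        assert np.allclose(tiny_table.relative_abundances().sum(axis=1), 1.0)


class TestSharedFormat:
    def test_round_trip_identity(self, tiny_table, tmp_path):
        path = tmp_path / "t.shared"
        cd.write_shared(tiny_table, path)
        back = cd.read_shared(path)
        assert back.sample_ids == tiny_table.sample_ids
        assert back.otu_ids == tiny_table.otu_ids
        assert np.array_equal(back.counts, tiny_table.counts)

    def test_reads_handwritten_fixture(self, tmp_path):
        path = tmp_path / "f.shared"
        path.write_text(
            "label\tGroup\tnumOtus\tOtuA\tOtuB\tOtuC\n"
            "0.03\tv1\t3\t10\t0\t2\n"
            "0.03\tv2\t3\t1\t5\t9\n")
        t = cd.read_shared(path)
        assert t.counts.shape == (2, 3)
        assert t.sample_ids == ["v1", "v2"]
        assert t.counts[1, 2] == 9

    def test_inconsistent_numotus_rejected(self, tmp_path):
        path = tmp_path / "bad.shared"
        path.write_text("label\tGroup\tnumOtus\tA\tB\tC\tD\n"
                        "0.03\tv1\t3\t1\t2\t3\t4\n")
        with pytest.raises(cd.FormatError):
            cd.read_shared(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.shared"
        path.write_text("Group\tlabel\tnumOtus\tA\n0.03\tv1\t1\t3\n")
        with pytest.raises(cd.FormatError):
            cd.read_shared(path)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.shared"
        path.write_text("label\tGroup\tnumOtus\tA\n0.03\tv1\t1\t-3\n")
        with pytest.raises(ValueError):
            cd.read_shared(path)

    def test_multiple_labels_rejected(self, tmp_path):
        path = tmp_path / "bad.shared"
        path.write_text("label\tGroup\tnumOtus\tA\n"
                        "0.03\tv1\t1\t3\n0.05\tv2\t1\t2\n")
        with pytest.raises(cd.FormatError):
            cd.read_shared(path)


class TestTaxonomyFormat:
    def test_round_trip(self, tiny_taxonomy, tmp_path):
        path = tmp_path / "tax.tsv"
        cd.write_taxonomy(tiny_taxonomy, path)
        back = cd.read_taxonomy(path)
        for otu in tiny_taxonomy.lineages:
            for rank in cd.CANONICAL_RANKS:
                assert back.name_at(otu, rank) == tiny_taxonomy.name_at(otu, rank)

    def test_bootstrap_suffixes_stripped(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("Otu1\tBacteria(100);Firmicutes(97);Clostridia(88);\n")
        tax = cd.read_taxonomy(path)
        assert tax.name_at("Otu1", "phylum") == "Firmicutes"

    def test_unclassified_tail_propagates_parent(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("Otu1\tBacteria;Firmicutes;\n")
        tax = cd.read_taxonomy(path)
        assert tax.name_at("Otu1", "genus") == "unclassified_Firmicutes"
        assert tax.name_at("Otu1", "class") == "unclassified_Firmicutes"


class TestMetadata:
    def test_round_trip(self, small_metadata, tmp_path):
        path = tmp_path / "meta.tsv"
        cd.write_metadata(small_metadata, path)
        back = cd.read_metadata(path)
        pd.testing.assert_frame_equal(
            back.frame, small_metadata.frame, check_dtype=False)

    def test_time_consistency_enforced(self, small_metadata):
        bad = small_metadata.frame.copy()
        bad.loc[0, "time_h"] = 99.0
        with pytest.raises(ValueError):
            cd.SampleMetadata(bad)

    def test_condition_constant_per_vessel(self, small_metadata):
        bad = small_metadata.frame.copy()
        bad.loc[0, "condition"] = "treatment"
        with pytest.raises(ValueError):
            cd.SampleMetadata(bad)


class TestDistanceFormat:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        m = rng.random((4, 4))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        dm = cd.DistanceMatrix(["a", "b", "c", "d"], d)
        path = tmp_path / "m.dist"
        cd.write_distance(dm, path)
        back = cd.read_distance(path)
        assert back.ids == dm.ids
        assert np.allclose(back.d, dm.d, atol=1e-9)

    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            cd.DistanceMatrix(["a", "b"], np.array([[0.0, 0.3], [0.5, 0.0]]))


class TestAggregateToRank:
    def test_shared_genus_merges_columns(self, tiny_table, tiny_taxonomy):
        # Otu01/Otu02 share a family, so family-level has 3 columns
        agg = cd.aggregate_to_rank(tiny_table, tiny_taxonomy, "family")
        assert agg.n_otus == 3
        assert np.array_equal(agg.library_sizes, tiny_table.library_sizes)

    def test_single_kingdom_column_equals_library_sizes(self, tiny_table,
                                                        tiny_taxonomy):
        # two kingdoms present: Bacteria and Archaea
        agg = cd.aggregate_to_rank(tiny_table, tiny_taxonomy, "kingdom")
        assert set(agg.otu_ids) == {"Bacteria", "Archaea"}
        assert np.array_equal(agg.counts.sum(axis=1), tiny_table.library_sizes)

    def test_conserves_totals_random_table(self, tiny_taxonomy):
        rng = np.random.default_rng(11)
        table = random_table(rng, n_samples=5, n_otus=4)
        table = cd.CommunityTable(table.sample_ids,
                                  list(tiny_taxonomy.lineages), table.counts)
        for rank in cd.CANONICAL_RANKS:
            agg = cd.aggregate_to_rank(table, tiny_taxonomy, rank)
            # oracle: direct summation via pandas groupby on lineage names
            names = [tiny_taxonomy.name_at(o, rank) for o in table.otu_ids]
            oracle = (pd.DataFrame(table.counts, columns=names)
                      .T.groupby(level=0).sum().T)
            assert np.array_equal(
                agg.to_dataframe().sort_index(axis=1).to_numpy(),
                oracle.sort_index(axis=1).to_numpy())

    def test_unknown_rank_and_unmapped_otu(self, tiny_table, tiny_taxonomy):
        with pytest.raises(ValueError):
            cd.aggregate_to_rank(tiny_table, tiny_taxonomy, "species")
        incomplete = cd.TaxonomyMap(
            {k: v for k, v in tiny_taxonomy.lineages.items() if k != "Otu04"})
        with pytest.raises(KeyError):
            cd.aggregate_to_rank(tiny_table, incomplete, "genus")


class TestRarefy:
    def test_rows_sum_to_depth_and_reproducible(self, tiny_table):
        out = cd.rarefy(tiny_table, 5, seed=3)
        assert (out.library_sizes == 5).all()
        again = cd.rarefy(tiny_table, 5, seed=3)
        assert np.array_equal(out.counts, again.counts)

    def test_depth_equal_to_library_size_is_identity(self):
        t = cd.CommunityTable(["a"], ["o1", "o2", "o3"],
                              np.array([[1000, 0, 0]]))
        out = cd.rarefy(t, 1000, seed=0)
        assert np.array_equal(out.counts, t.counts)

    def test_concentrated_sample_forced(self):
        t = cd.CommunityTable(["a"], ["o1", "o2", "o3"],
                              np.array([[1000, 0, 0]]))
        out = cd.rarefy(t, 100, seed=0)
        assert np.array_equal(out.counts, [[100, 0, 0]])

    def test_shallow_samples_dropped_with_warning(self, tiny_table):
        with pytest.warns(UserWarning):
            out = cd.rarefy(tiny_table, 9, seed=0)
        assert out.n_samples == 2  # s3 has library size 8

    def test_nonpositive_depth_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            cd.rarefy(tiny_table, 0)

    def test_hypergeometric_expectation(self):
        """Mean count of each OTU over repeated draws matches depth*x_k/N."""
        counts = np.array([[600, 250, 100, 40, 10]])
        t = cd.CommunityTable(["a"], [f"o{i}" for i in range(5)], counts)
        rng = np.random.default_rng(42)
        depth, reps = 100, 3000
        draws = np.array([cd.rarefy(t, depth, rng).counts[0]
                          for _ in range(reps)])
        n = counts.sum()
        expect = depth * counts[0] / n
        # hypergeometric variance per OTU
        var = (depth * (counts[0] / n) * (1 - counts[0] / n)
               * (n - depth) / (n - 1))
        se = np.sqrt(var / reps)
        assert (np.abs(draws.mean(axis=0) - expect) <= 3 * se + 1e-9).all()

    def test_column_permutation_equivariance_in_distribution(self):
        """Rarefying a column-permuted table gives the same per-OTU means."""
        counts = np.array([[300, 120, 60, 20]])
        t = cd.CommunityTable(["a"], ["o0", "o1", "o2", "o3"], counts)
        perm = [2, 0, 3, 1]
        tp = cd.CommunityTable(["a"], [t.otu_ids[i] for i in perm],
                               counts[:, perm])
        reps, depth = 2000, 50
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        m1 = np.mean([cd.rarefy(t, depth, rng1).counts[0]
                      for _ in range(reps)], axis=0)
        m2 = np.mean([cd.rarefy(tp, depth, rng2).counts[0]
                      for _ in range(reps)], axis=0)
        # align permuted means back to original order
        m2_aligned = np.empty_like(m2)
        for j, orig in enumerate(perm):
            m2_aligned[orig] = m2[j]
        se = np.sqrt(depth * 0.25 / reps) * 2  # loose bound on mean SE
        assert (np.abs(m1 - m2_aligned) < 3 * se + 0.5).all()


class TestFilterSingletons:
    def test_single_total_count_removed(self):
        t = cd.CommunityTable(["a", "b"], ["o1", "o2"],
                              np.array([[1, 5], [0, 3]]))
        out = cd.filter_singletons(t)
        assert out.otu_ids == ["o2"]

    def test_no_singletons_identity(self, tiny_table):
        out = cd.filter_singletons(tiny_table)
        assert np.array_equal(out.counts, tiny_table.counts)

    def test_removed_count_matches_direct_count(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, n_samples=6, n_otus=20, max_count=3)
        expected_removed = int((t.counts.sum(axis=0) == 1).sum())
        out = cd.filter_singletons(t)
        assert t.n_otus - out.n_otus == expected_removed
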