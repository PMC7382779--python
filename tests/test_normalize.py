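"""Normalization chain: impurity inversion, loading, ratios, joining."""

import numpy as np
import pandas as pd
import pytest

from kinodelta import normalize as nz
from kinodelta import phenotype as ph
from kinodelta.containers import RatioMatrix
from kinodelta.errors import DataError, DesignError, NumericError

from conftest import make_plex


class TestImpurityCorrection:
    def test_identity_matrix_is_noop(self):
        table = make_plex([[100.0, 200.0, 300.0], [50.0, 60.0, 70.0]])
        out = nz.correct_isotopic_impurities(table, np.eye(3))
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_two_channel_spillover_solved_by_hand(self):
        # 10% of channel 1 spills into channel 2: observed (90, 110)
        # comes from true (100, 100)
        table = make_plex([[90.0, 110.0]], strains=["sA"],
                          bridge_first=True)
        M = np.array([[0.9, 0.0], [0.1, 1.0]])
        out = nz.correct_isotopic_impurities(table, M)
        assert out.data.iloc[0].tolist() == pytest.approx([100.0, 100.0])

    def test_remixing_recovers_observed(self):
        rng = np.random.default_rng(4)
        observed = rng.uniform(50, 500, size=(5, 3))
        M = np.array([[0.92, 0.05, 0.0], [0.08, 0.90, 0.04],
                      [0.0, 0.05, 0.96]])
        table = make_plex(observed)
        out = nz.correct_isotopic_impurities(table, M)
        assert np.allclose(M @ out.data.to_numpy().T,
                           observed.T)

    def test_singular_matrix_raises(self):
        table = make_plex([[1.0, 2.0]])
        with pytest.raises(NumericError):
            nz.correct_isotopic_impurities(table, np.zeros((2, 2)))

    def test_rows_with_missing_pass_through(self):
        table = make_plex([[90.0, np.nan]])
        out = nz.correct_isotopic_impurities(
            table, np.array([[0.9, 0.0], [0.1, 1.0]]))
        assert out.data.iloc[0, 0] == 90.0


class TestPeptideFilter:
    def _table(self, rows):
        return make_plex(rows, level="peptide")

    def test_thresholds_are_inclusive(self):
        # summed S/N exactly 200 and specificity exactly 0.5 both retained
        table = self._table([[100.0, 100.0], [99.9, 100.0]])
        noise = pd.Series(1.0, index=table.data.columns)
        spec = pd.Series([0.5, 0.9], index=table.data.index)
        out = nz.filter_peptides(table, noise, spec)
        assert list(out.data.index) == ["M0"]

    def test_hand_enumerated_toy(self):
        table = self._table([[300, 10], [100, 120], [50, 20],
                             [400, 400], [150, 49]])
        noise = pd.Series(1.0, index=table.data.columns)
        spec = pd.Series([0.9, 0.6, 0.9, 0.4, 0.5], index=table.data.index)
        out = nz.filter_peptides(table, noise, spec)
        # M0: 310 S/N & 0.9 pass; M1: 220 & 0.6 pass; M2: 70 fails S/N;
        # M3: fails specificity; M4: 199 fails S/N
        assert list(out.data.index) == ["M0", "M1"]

    def test_missing_noise_column_is_input_error(self):
        table = self._table([[300.0, 10.0]])
        with pytest.raises(DataError):
            nz.filter_peptides(table, pd.Series(1.0, index=["ch01"]),
                               pd.Series(1.0, index=table.data.index))


class TestRollup:
    def test_simple_sum(self):
        table = make_plex([[10.0, 20.0], [5.0, 5.0]], level="peptide")
        out = nz.rollup_peptides_to_protein(table, {"M0": "P1", "M1": "P1"})
        assert out.data.loc["P1"].tolist() == [15.0, 25.0]
        assert out.level == "protein"

    def test_shared_peptide_excluded_from_both(self):
        table = make_plex([[10.0, 20.0], [5.0, 5.0]], level="peptide")
        out = nz.rollup_peptides_to_protein(
            table, {"M0": {"P1", "P2"}, "M1": "P1"})
        assert out.data.loc["P1"].tolist() == [5.0, 5.0]
        assert "P2" not in out.data.index

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(1, 100, size=(30, 4))
        table = make_plex(values, level="peptide")
        mapping = {f"M{i}": f"P{rng.integers(0, 5)}" for i in range(30)}
        out = nz.rollup_peptides_to_protein(table, mapping)
        for prot in out.data.index:
            members = [m for m, p in mapping.items() if p == prot]
            expected = table.data.loc[members].sum(axis=0)
            assert np.allclose(out.data.loc[prot], expected)


class TestLoadingEqualization:
    def test_already_equal_gives_unit_factors(self):
        table = make_plex([[100.0, 100.0], [50.0, 50.0]])
        _, factors = nz.equalize_loading(table)
        assert np.allclose(factors, 1.0)

    def test_hand_arithmetic(self):
        table = make_plex([[100.0, 300.0]])
        out, factors = nz.equalize_loading(table)
        assert factors.tolist() == pytest.approx([2.0, 2.0 / 3.0])
        assert out.data.iloc[0].tolist() == pytest.approx([200.0, 200.0])

    def test_column_sums_equal_after(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(10, 1e5, size=(40, 5))
        values[3, 2] = np.nan    # incomplete molecule must not bias factors
        out, _ = nz.equalize_loading(make_plex(values))
        sums = out.data.dropna().sum(axis=0)
        assert np.allclose(sums, sums.mean(), rtol=1e-9)

    def test_global_rescaling_invariance_downstream(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(10, 1e5, size=(30, 4))
        t1, _ = nz.equalize_loading(make_plex(values))
        t2, _ = nz.equalize_loading(make_plex(values * 7.0))
        r1 = nz.bridge_log2_ratios(t1)
        r2 = nz.bridge_log2_ratios(t2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_zero_channel_raises(self):
        with pytest.raises(DataError):
            nz.equalize_loading(make_plex([[100.0, 0.0]]))


class TestApplyLoadingToPhospho:
    def test_unit_factors_noop(self):
        table = make_plex([[10.0, 20.0]], level="phosphosite")
        factors = pd.Series(1.0, index=table.data.columns)
        out = nz.apply_loading_to_phospho(table, factors)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_elementwise_product(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(1, 100, size=(10, 3))
        table = make_plex(values, level="phosphosite")
        factors = pd.Series([2.0, 0.5, 1.5], index=table.data.columns)
        out = nz.apply_loading_to_phospho(table, factors)
        assert np.allclose(out.data, values * factors.to_numpy())

    def test_channel_mismatch_raises(self):
        table = make_plex([[10.0, 20.0]], level="phosphosite")
        with pytest.raises(DesignError):
            nz.apply_loading_to_phospho(table,
                                        pd.Series([1.0], index=["chXX"]))


class TestBridgeRatios:
    def test_hand_values(self):
        table = make_plex([[100.0, 100.0, 200.0],
                           [8.0, 4.0, 2.0],
                           [16.0, 16.0, 64.0]], strains=["sA", "sB"])
        ratios = nz.bridge_log2_ratios(table)
        expected = np.array([[0.0, 1.0], [-1.0, -2.0], [0.0, 2.0]])
        assert np.allclose(ratios.to_numpy(), expected)
        assert list(ratios.columns.get_level_values("strain")) == ["sA", "sB"]

    def test_missing_bridge_blanks_molecule(self):
        table = make_plex([[np.nan, 100.0]])
        ratios = nz.bridge_log2_ratios(table)
        assert ratios.isna().all().all()

    def test_zero_intensity_becomes_missing(self):
        table = make_plex([[100.0, 0.0]])
        ratios = nz.bridge_log2_ratios(table)
        assert ratios.isna().all().all()


class TestTrimmedCentering:
    def test_constant_column_becomes_zero(self):
        col = pd.DataFrame({"a": [3.0] * 20})
        out = nz.center_trimmed_mean(col)
        assert np.allclose(out["a"], 0.0)

    def test_outlier_excluded_from_center(self):
        values = list(np.linspace(-1, 1, 19)) + [100.0]
        col = pd.DataFrame({"a": values})
        out = nz.center_trimmed_mean(col, trim_fraction=0.05)
        # trimmed mean removes floor(0.05·20)=1 from each tail:
        # mean of the 18 middle values of the sorted column
        middle = sorted(values)[1:-1]
        assert out["a"].iloc[0] == pytest.approx(values[0] - np.mean(middle))

    def test_post_centering_trimmed_mean_is_zero(self):
        rng = np.random.default_rng(5)
        col = pd.DataFrame({"a": rng.normal(0.3, 1.0, 200)})
        out = nz.center_trimmed_mean(col)
        from scipy.stats import trim_mean
        assert abs(trim_mean(out["a"], 0.05)) < 1e-9


class TestJoinPlexes:
    def _cols(self, strains, rep, values, molecules):
        frame = pd.DataFrame(values, index=molecules,
                             columns=pd.MultiIndex.from_tuples(
                                 [(s, rep) for s in strains],
                                 names=["strain", "replicate"]))
        return frame

    def test_disjoint_molecules_block_missing(self):
        a = self._cols(["s1"], 1, [[0.1]], ["m1"])
        b = self._cols(["s2"], 1, [[0.2]], ["m2"])
        joined = nz.join_plexes([a, b])
        assert joined.data.shape == (2, 2)
        assert joined.data.isna().sum().sum() == 2

    def test_shared_molecules_dense(self):
        a = self._cols(["s1"], 1, [[0.1], [0.2]], ["m1", "m2"])
        b = self._cols(["s2"], 1, [[0.3], [0.4]], ["m1", "m2"])
        joined = nz.join_plexes([a, b])
        assert joined.data.notna().all().all()

    def test_union_counts(self):
        a = self._cols(["s1"], 1, [[0.1], [0.2]], ["m1", "m2"])
        b = self._cols(["s2"], 1, [[0.3], [0.4]], ["m2", "m3"])
        joined = nz.join_plexes([a, b])
        assert set(joined.data.index) == {"m1", "m2", "m3"}
        assert joined.data.shape == (3, 2)

    def test_duplicate_columns_rejected(self):
        a = self._cols(["s1"], 1, [[0.1]], ["m1"])
        with pytest.raises(DesignError):
            nz.join_plexes([a, a.copy()])


class TestProteinNormalization:
    def _matrix(self, values, molecules, level="phosphosite"):
        cols = pd.MultiIndex.from_tuples([("s1", 1), ("s1", 2)],
                                         names=["strain", "replicate"])
        return RatioMatrix(level, pd.DataFrame(values, index=molecules,
                                               columns=cols))

    def test_zero_protein_ratio_is_identity(self):
        phospho = self._matrix([[0.7, 0.9]], ["P1_pS5"])
        protein = self._matrix([[0.0, 0.0]], ["P1"], level="protein")
        out, frac = nz.normalize_phospho_by_protein(phospho, protein,
                                                    {"P1_pS5": "P1"})
        assert np.allclose(out.data, phospho.data)
        assert frac == 1.0

    def test_protein_driven_site_normalizes_to_zero(self):
        phospho = self._matrix([[-1.2, -1.2]], ["P1_pT331"])
        protein = self._matrix([[-1.2, -1.2]], ["P1"], level="protein")
        out, _ = nz.normalize_phospho_by_protein(phospho, protein,
                                                 {"P1_pT331": "P1"})
        assert np.allclose(out.data, 0.0)

    def test_masked_change_unmasked_by_normalization(self):
        phospho = self._matrix([[0.0, 0.0]], ["P1_pS356"])
        protein = self._matrix([[1.0, 1.0]], ["P1"], level="protein")
        out, _ = nz.normalize_phospho_by_protein(phospho, protein,
                                                 {"P1_pS356": "P1"})
        assert np.allclose(out.data, -1.0)

    def test_unmapped_site_passes_through_flagged(self):
        phospho = self._matrix([[0.4, 0.5]], ["X_pS1"])
        protein = self._matrix([[1.0, 1.0]], ["P1"], level="protein")
        out, frac = nz.normalize_phospho_by_protein(phospho, protein,
                                                    {"X_pS1": "UNKNOWN"})
        assert np.allclose(out.data, phospho.data)
        assert not out.protein_normalized.any().any()
        assert frac == 0.0

    def test_adding_protein_back_restores_input(self):
        rng = np.random.default_rng(8)
        sites = [f"P{i}_pS1" for i in range(10)]
        phospho = self._matrix(rng.normal(size=(10, 2)), sites)
        protein = self._matrix(rng.normal(size=(10, 2)),
                               [f"P{i}" for i in range(10)], level="protein")
        mapping = {s: s.split("_")[0] for s in sites}
        out, _ = nz.normalize_phospho_by_protein(phospho, protein, mapping)
        restored = out.data + protein.data.set_axis(sites, axis=0)
        assert np.allclose(restored, phospho.data)


class TestCoverageFilter:
    def _matrix(self, n_strains, present_in):
        cols = pd.MultiIndex.from_product([[f"s{i}" for i in range(n_strains)],
                                           [1]],
                                          names=["strain", "replicate"])
        row = [0.1 if i < present_in else np.nan for i in range(n_strains)]
        return RatioMatrix("protein", pd.DataFrame([row], index=["m"],
                                                   columns=cols))

    def test_exact_50_percent_boundary(self):
        # 55 of 110 strains retained, 54 removed (ceil(0.5·110) = 55)
        assert len(nz.filter_min_coverage(self._matrix(110, 55)).data) == 1
        assert len(nz.filter_min_coverage(self._matrix(110, 54)).data) == 0

    def test_full_coverage_retained_and_empty_ok(self):
        assert len(nz.filter_min_coverage(self._matrix(10, 10)).data) == 1
        empty = self._matrix(10, 10)
        empty.data = empty.data.iloc[[]]
        assert len(nz.filter_min_coverage(empty).data) == 0


class TestSampleClustering:
    def test_duplicated_columns_merge_first(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        cols = pd.MultiIndex.from_tuples(
            [("sA", 1), ("sA", 2), ("sB", 1)],
            names=["strain", "replicate"])
        data = pd.DataFrame(
            np.column_stack([base, base, rng.normal(size=30)]), columns=cols)
        linkage, order, labels = nz.cluster_samples(
            RatioMatrix("protein", data))
        first = sorted([int(linkage[0, 0]), int(linkage[0, 1])])
        assert [labels[i] for i in first] == ["sA|1", "sA|2"]
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_columns_single_merge(self):
        rng = np.random.default_rng(1)
        cols = pd.MultiIndex.from_tuples([("sA", 1), ("sB", 1)],
                                         names=["strain", "replicate"])
        data = pd.DataFrame(rng.normal(size=(20, 2)), columns=cols)
        linkage, order, labels = nz.cluster_samples(
            RatioMatrix("protein", data))
        assert linkage.shape == (1, 4)

    def test_replicates_are_mutual_nearest_neighbors(self, noiseless_study):
        matrix = noiseless_study.norm["protein"]
        from kinodelta._stats import pairwise_complete_pearson
        r, _ = pairwise_complete_pearson(matrix.data.to_numpy().T)
        labels = [f"{s}|{rep}" for s, rep in matrix.data.columns]
        np.fill_diagonal(r, -np.inf)
        for i, lab in enumerate(labels):
            strain = lab.split("|")[0]
            partner = labels[int(np.nanargmax(r[i]))].split("|")[0]
            assert partner == strain


class TestFullChainExactness:
    def test_noiseless_effects_recovered_exactly(self, noiseless_study):
        truth = noiseless_study.truth
        merged, _ = ph.merge_replicates(noiseless_study.norm["protein"])
        for (strain, prot), effect in truth.protein_effects.items():
            assert merged.loc[prot, strain] == pytest.approx(effect,
                                                             abs=1e-9)
        mergedn, _ = ph.merge_replicates(noiseless_study.norm["phospho_norm"])
        for (strain, site), effect in truth.phospho_effects.items():
            assert mergedn.loc[site, strain] == pytest.approx(effect,
                                                              abs=1e-9)

    def test_normalizable_fraction_complete_when_no_missingness(
            self, noiseless_study):
        assert noiseless_study.norm["normalizable_fraction"] == 1.0
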