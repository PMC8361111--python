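import itertools

import numpy as np
import pandas as pd
import pytest

from flavoscreen import (
    AnnotationRecord,
    cluster_profiles,
    generate_abundances,
    group_ratios,
    load_library,
    log10_mean_transform,
    match,
    percent_composition,
    presence_sets,
)
from flavoscreen.synthetic_data import SyntheticSpec, generate_library_spectra


def records_for_library(library):
    spectra = generate_library_spectra(library, SyntheticSpec(seed=9))
    return [match(s, library, rt_tol=0.05) for s in spectra]


class TestPercentComposition:
    def test_simple_column(self):
        m = pd.DataFrame({"KB": [2.0, 3.0, 5.0]}, index=["a", "b", "c"])
        out = percent_composition(m)
        assert list(out["KB"]) == pytest.approx([20.0, 30.0, 50.0])

    def test_single_compound_is_100(self):
        m = pd.DataFrame({"KB": [7.0]}, index=["a"])
        assert percent_composition(m).iloc[0, 0] == 100.0

    def test_columns_sum_to_100_and_scale_invariant(self):
        rng = np.random.default_rng(31)
        m = pd.DataFrame(rng.uniform(0, 1e6, size=(10, 3)),
                         index=[f"c{i}" for i in range(10)], columns=list("XYZ"))
        out = percent_composition(m)
        assert out.sum(axis=0).to_numpy() == pytest.approx([100.0] * 3)
        scaled = m.copy()
        scaled["Y"] *= 17.3
        pd.testing.assert_frame_equal(percent_composition(scaled), out)

    def test_zero_column_fatal(self):
        m = pd.DataFrame({"KB": [1.0], "PP": [0.0]}, index=["a"])
        with pytest.raises(ValueError, match="PP"):
            percent_composition(m)


class TestGroupRatios:
    def test_acylation_fractions_with_equal_areas(self, library):
        records = records_for_library(library)
        areas = pd.DataFrame(
            {"KB": 1.0, "PP": 1.0},
            index=[r.spectrum_id for r in records],
        )
        out = group_ratios(records, areas, "acylation")
        assert out.loc["Non", "KB"] == pytest.approx(2 / 18)
        assert out.sum(axis=0).to_numpy() == pytest.approx([1.0, 1.0])

    def test_aglycone_fractions_include_ambiguous_category(self, library):
        records = records_for_library(library)
        areas = pd.DataFrame({"KB": 1.0}, index=[r.spectrum_id for r in records])
        out = group_ratios(records, areas, "aglycone")
        assert set(out.index) == {"cyanidin", "peonidin", "ambiguous(cyanidin/peonidin)"}
        assert out["KB"].sum() == pytest.approx(1.0)

    def test_single_group_fraction_one(self, library):
        records = [r for r in records_for_library(library)
                   if r.entry.acylation_class == "Di"]
        areas = pd.DataFrame({"KB": 1.0}, index=[r.spectrum_id for r in records])
        out = group_ratios(records, areas, "acylation")
        assert list(out.index) == ["Di"] and out.iloc[0, 0] == 1.0

    def test_missing_compound_fatal(self, library):
        records = records_for_library(library)[:1]
        areas = pd.DataFrame({"KB": [1.0]}, index=["other"])
        with pytest.raises(KeyError):
            group_ratios(records, areas, "acylation")


class TestClusterProfiles:
    def test_identical_profiles_merge_at_zero(self):
        m = pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [9.0, 9.0]})
        z, order, newick = cluster_profiles(m, axis="columns")
        assert z[0, 2] == pytest.approx(0.0)  # first merge distance
        assert set(order) == {"A", "B", "C"}
        assert newick.endswith(";")

    def test_first_merge_is_closest_pair(self):
        m = pd.DataFrame({"A": [0.0], "B": [0.1], "C": [5.0]})
        z, _, _ = cluster_profiles(m, axis="columns")
        assert sorted(z[0, :2]) == [0, 1]  # A and B merge first

    def test_merge_heights_match_brute_force_distances(self):
        rng = np.random.default_rng(33)
        m = pd.DataFrame(rng.uniform(0, 10, size=(4, 5)),
                         columns=[f"s{i}" for i in range(5)])
        z, _, _ = cluster_profiles(m, axis="columns")
        pts = m.T.to_numpy()
        d = {
            frozenset((i, j)): float(np.sqrt(((pts[i] - pts[j]) ** 2).sum()))
            for i, j in itertools.combinations(range(5), 2)
        }
        # the first merge joins the globally closest pair at exactly that distance
        i, j = int(z[0, 0]), int(z[0, 1])
        assert z[0, 2] == pytest.approx(min(d.values()))
        assert d[frozenset((i, j))] == pytest.approx(min(d.values()))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(34)
        m = pd.DataFrame(rng.uniform(0, 10, size=(4, 6)),
                         columns=[f"s{i}" for i in range(6)])
        z1, _, _ = cluster_profiles(m, axis="columns")
        shuffled = m[[f"s{i}" for i in (3, 1, 5, 0, 4, 2)]]
        z2, _, _ = cluster_profiles(shuffled, axis="columns")
        assert np.sort(z1[:, 2]) == pytest.approx(np.sort(z2[:, 2]))

    def test_single_item_trivial_tree(self):
        m = pd.DataFrame({"A": [1.0, 2.0]})
        z, order, newick = cluster_profiles(m, axis="columns")
        assert len(z) == 0 and order == ["A"] and newick == "A;"

    def test_row_axis(self):
        m = pd.DataFrame({"A": [1.0, 1.0, 9.0], "B": [1.1, 1.0, 9.0]},
                         index=["x", "y", "z"])
        _, order, _ = cluster_profiles(m, axis="rows")
        assert set(order) == {"x", "y", "z"}


class TestPresenceSets:
    def test_all_zero_matrix(self):
        m = pd.DataFrame(np.zeros((3, 2)), index=list("abc"), columns=["K", "P"])
        sets, inter = presence_sets(m)
        assert all(len(s) == 0 for s in sets.values())
        assert all(v == 0 for v in inter.values())

    def test_single_nonzero_cell(self):
        m = pd.DataFrame({"K": [1.0, 0.0], "P": [0.0, 0.0]}, index=["a", "b"])
        sets, inter = presence_sets(m, presence_floor=0.0)
        assert sets == {"K": {"a"}, "P": set()}
        assert inter[frozenset({"K", "P"})] == 0

    def test_random_binary_matrix_matches_set_arithmetic(self):
        rng = np.random.default_rng(35)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(12, 4)).astype(float),
            index=[f"c{i}" for i in range(12)],
            columns=list("WXYZ"),
        )
        sets, inter = presence_sets(m)
        for r in range(1, 5):
            for combo in itertools.combinations("WXYZ", r):
                manual = set(m.index)
                for col in combo:
                    manual &= {i for i in m.index if m.loc[i, col] > 0}
                assert inter[frozenset(combo)] == len(manual)

    def test_monotone_in_floor(self):
        rng = np.random.default_rng(36)
        m = pd.DataFrame(rng.uniform(0, 10, size=(8, 3)),
                         index=[f"c{i}" for i in range(8)], columns=list("KPA"))
        _, lo = presence_sets(m, presence_floor=1.0)
        _, hi = presence_sets(m, presence_floor=5.0)
        assert all(hi[k] <= lo[k] for k in lo)


class TestTransforms:
    def test_log10_mean_transform_handles_zeros(self):
        m = pd.DataFrame({"K": [0.0, 9.0]}, index=["a", "b"])
        out = log10_mean_transform(m)
        assert out.loc["a", "K"] == 0.0
        assert out.loc["b", "K"] == pytest.approx(1.0)

    def test_generated_abundance_matrix_shape(self, library):
        m = generate_abundances(library, SyntheticSpec(seed=8))
        assert m.shape == (18, 3)
        assert (m.to_numpy() >= 0).all()
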