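import itertools

import numpy as np
import pandas as pd
import pytest

from ednariver.diversity import (
    DEFAULT_RATIOS,
    functional_richness,
    functional_space,
    impute_traits,
    incidence_extrapolation,
    nucleotide_diversity,
    site_genetic_diversity,
    taxonomic_richness,
    trait_ratios,
)
from ednariver.io_formats import SequenceRecord


class TestRichness:
    def test_row_sums(self):
        inc = pd.DataFrame(
            [[0, 0, 0], [1, 0, 1], [1, 1, 1]],
            index=["s1", "s2", "s3"],
            columns=["a", "b", "c"],
        )
        td = taxonomic_richness(inc)
        assert td.tolist() == [0, 2, 3]

    def test_distinct_asvs_match_occupied_columns(self, rng):
        inc = pd.DataFrame(rng.integers(0, 2, (6, 9)))
        assert (inc.sum(axis=0) > 0).sum() == (taxonomic_richness(inc.T) > 0).sum()


class TestTraits:
    def test_ratio_arithmetic(self):
        raw = pd.DataFrame({"Bl": [10.0], "Bd": [2.0], "CFd": [3.0], "CPd": [1.5]}, index=["a"])
        r = trait_ratios(raw, [("Bl", "Bd"), ("CFd", "CPd")])
        assert r.loc["a", "Bl/Bd"] == 5
        assert r.loc["a", "CFd/CPd"] == 2

    def test_scale_invariance(self, rng):
        raw = pd.DataFrame(
            rng.uniform(1, 50, (4, 11)), columns=[n for n, _ in DEFAULT_RATIOS[:0]] or
            ["Bl", "Bd", "Hd", "CPd", "CFd", "Ed", "Eh", "Om", "Jl", "PFl", "PFp"],
        )
        r1 = trait_ratios(raw)
        r2 = trait_ratios(raw * 3.7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_zero_denominator_becomes_missing(self):
        raw = pd.DataFrame({"Bl": [10.0], "Bd": [0.0]}, index=["a"])
        r = trait_ratios(raw, [("Bl", "Bd")])
        assert r.isna().all().all()


class TestImputation:
    def _lineage(self):
        return pd.DataFrame(
            {
                "genus": ["G1", "G1", "G1", "G2", "G2"],
                "family": ["F1", "F1", "F1", "F1", "F1"],
                "order": ["O1"] * 5,
            },
            index=[f"a{i}" for i in range(5)],
        )

    def test_genus_mean_fills_gap(self):
        traits = pd.DataFrame({"x": [4.0, 6.0, np.nan, 1.0, 3.0]}, index=[f"a{i}" for i in range(5)])
        out = impute_traits(traits, self._lineage())
        assert out.loc["a2", "x"] == 5.0

    def test_family_fallback_when_no_genus_mates(self):
        traits = pd.DataFrame(
            {"x": [4.0, 6.0, 2.0, np.nan, np.nan]}, index=[f"a{i}" for i in range(5)]
        )
        lineage = self._lineage()
        out = impute_traits(traits, lineage)
        # a3/a4 form genus G2 with no observed value → family mean (4+6+2)/3
        assert out.loc["a3", "x"] == pytest.approx(4.0)

    def test_complete_matrix_unchanged(self):
        traits = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=[f"a{i}" for i in range(5)])
        pd.testing.assert_frame_equal(impute_traits(traits, self._lineage()), traits)

    def test_fully_missing_column_raises(self):
        traits = pd.DataFrame({"x": [np.nan] * 5}, index=[f"a{i}" for i in range(5)])
        with pytest.raises(ValueError):
            impute_traits(traits, self._lineage())


class TestFunctionalSpace:
    def test_collinear_points_load_on_one_axis(self):
        t = np.linspace(0, 1, 10)
        traits = pd.DataFrame({"x": t, "y": 2 * t, "z": -t})
        fs = functional_space(traits)
        assert fs.variance_explained[0] == pytest.approx(1.0)
        assert fs.k == 1  # the two-axis floor is capped by the rank

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        traits = pd.DataFrame(rng.normal(size=(40, 5)))
        fs = functional_space(traits)
        Z = (traits - traits.mean()) / traits.std(ddof=1)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Z.values.T)))[::-1]
        np.testing.assert_allclose(fs.variance_explained, eig / eig.sum(), atol=1e-10)

    def test_isotropic_cloud_has_near_equal_axes(self, rng):
        traits = pd.DataFrame(rng.normal(size=(4000, 2)))
        fs = functional_space(traits)
        assert abs(fs.variance_explained[0] - fs.variance_explained[1]) < 0.05

    def test_column_rescaling_invariance(self, rng):
        traits = pd.DataFrame(rng.normal(size=(30, 4)))
        scaled = traits.copy()
        scaled[0] = traits[0] * 100 + 7
        f1, f2 = functional_space(traits), functional_space(scaled)
        np.testing.assert_allclose(f1.variance_explained, f2.variance_explained, atol=1e-10)


class TestFunctionalRichness:
    def _square_space(self):
        # four corners of the unit square, already 2-D
        coords = pd.DataFrame(
            {"x": [0, 1, 0, 1], "y": [0, 0, 1, 1]},
            index=["a", "b", "c", "d"],
            dtype=float,
        )
        fs = functional_space(coords)
        assert fs.k == 2
        return fs

    def test_full_pool_site_is_one(self):
        fs = self._square_space()
        inc = pd.DataFrame([[1, 1, 1, 1]], index=["s"], columns=["a", "b", "c", "d"])
        assert functional_richness(fs, inc)["s"] == pytest.approx(1.0)

    def test_three_corners_give_half(self):
        fs = self._square_space()
        inc = pd.DataFrame(
            [[1, 1, 1, 0], [1, 1, 1, 1]], index=["s", "pool"], columns=["a", "b", "c", "d"]
        )
        assert functional_richness(fs, inc)["s"] == pytest.approx(0.5)

    def test_too_few_points_warns_and_zero(self):
        fs = self._square_space()
        inc = pd.DataFrame([[1, 1, 0, 0]], index=["s"], columns=["a", "b", "c", "d"])
        with pytest.warns(UserWarning, match="degenerate"):
            fd = functional_richness(fs, inc)
        assert fd["s"] == 0.0

    def test_monotone_in_added_asvs(self, rng):
        traits = pd.DataFrame(rng.normal(size=(12, 2)), index=[f"a{i}" for i in range(12)])
        fs = functional_space(traits)
        base = rng.integers(0, 2, 12)
        base[:4] = 1
        grown = base.copy()
        grown[rng.integers(0, 12)] = 1
        inc = pd.DataFrame([base, grown], index=["s0", "s1"], columns=traits.index)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fd = functional_richness(fs, inc)
        assert fd["s1"] >= fd["s0"] - 1e-12


def _pi_oracle(seqs):
    """Exhaustive pairwise oracle for nucleotide diversity."""
    vals = []
    for a, b in itertools.combinations(seqs, 2):
        cols = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
        vals.append(sum(x != y for x, y in cols) / len(cols))
    return float(np.mean(vals))


class TestNucleotideDiversity:
    def test_identical_pair_is_zero(self):
        assert nucleotide_diversity(["AAAA", "AAAA"]) == 0.0

    def test_single_difference(self):
        assert nucleotide_diversity(["AAAA", "AAAT"]) == pytest.approx(0.25)

    def test_three_sequences_brute_force(self):
        assert nucleotide_diversity(["AAAA", "AAAT", "AATT"]) == pytest.approx(1 / 3)

    def test_gap_handling(self):
        # gap vs base is a difference; gap vs gap drops the column
        assert nucleotide_diversity(["A-CG", "A-CT"]) == pytest.approx(1 / 3)
        assert nucleotide_diversity(["A-CG", "AACG"]) == pytest.approx(1 / 4)

    def test_matches_exhaustive_oracle_random_sets(self, rng):
        for n in (2, 3, 4, 5, 6):
            seqs = ["".join(rng.choice(list("ACGT-"), size=12)) for _ in range(n)]
            if any(all(x == "-" for x in s) for s in seqs):
                continue
            assert nucleotide_diversity(seqs) == pytest.approx(_pi_oracle(seqs))

    def test_fewer_than_two_is_missing(self):
        assert np.isnan(nucleotide_diversity(["AAAA"]))


class TestSiteGeneticDiversity:
    def test_single_order_pair(self):
        seqs = {
            "a": SequenceRecord("a", "A" * 9 + "C"),
            "b": SequenceRecord("b", "A" * 10),
        }
        inc = pd.DataFrame([[1, 1]], index=["s"], columns=["a", "b"])
        gd = site_genetic_diversity(inc, seqs, [], order_of={"a": "O1", "b": "O1"})
        assert gd["s"] == pytest.approx(0.1)

    def test_unweighted_mean_across_orders(self):
        seqs = {
            "a": SequenceRecord("a", "A" * 98 + "CC"),
            "b": SequenceRecord("b", "A" * 100),
            "c": SequenceRecord("c", "G" * 94 + "TTTTTT"),
            "d": SequenceRecord("d", "G" * 100),
        }
        inc = pd.DataFrame([[1, 1, 1, 1]], index=["s"], columns=list("abcd"))
        order_of = {"a": "O1", "b": "O1", "c": "O2", "d": "O2"}
        gd = site_genetic_diversity(inc, seqs, [], order_of=order_of)
        assert gd["s"] == pytest.approx((0.02 + 0.06) / 2)

    def test_all_singleton_orders_is_missing(self):
        seqs = {"a": SequenceRecord("a", "AAAA"), "b": SequenceRecord("b", "TTTT")}
        inc = pd.DataFrame([[1, 1]], index=["s"], columns=["a", "b"])
        gd = site_genetic_diversity(inc, seqs, [], order_of={"a": "O1", "b": "O2"})
        assert np.isnan(gd["s"])


class TestChao2:
    def test_no_uniques_means_full_coverage(self):
        # every ASV occurs in ≥3 sites → Q1 = 0
        inc = pd.DataFrame(np.ones((4, 3), dtype=int))
        s_obs, s_hat, cov = incidence_extrapolation(inc)
        assert s_hat == s_obs and cov == 1.0

    def test_closed_form_example(self):
        # S_obs=10, Q1=4, Q2=2, T=33 → 10 + (32/33)·16/4
        t, s_obs = 33, 10
        inc = pd.DataFrame(0, index=range(t), columns=range(s_obs))
        for j in range(4):
            inc.iloc[j, j] = 1  # uniques
        for j in range(4, 6):
            inc.iloc[[10, 11], j] = 1  # duplicates
        for j in range(6, 10):
            inc.iloc[[20, 21, 22], j] = 1
        s_o, s_hat, cov = incidence_extrapolation(inc)
        assert s_o == 10
        assert s_hat == pytest.approx(10 + (32 / 33) * 16 / 4)
        assert cov == pytest.approx(10 / s_hat)

    def test_bias_corrected_form_when_no_duplicates(self):
        inc = pd.DataFrame(0, index=range(5), columns=range(3))
        for j in range(3):
            inc.iloc[j, j] = 1
        s_obs, s_hat, _ = incidence_extrapolation(inc)
        assert s_hat == pytest.approx(3 + (4 / 5) * 3 * 2 / 2)

    def test_asymptote_bounds_and_coverage_range(self, rng):
        # the estimator never drops below the observed richness and coverage
        # stays in (0, 1]; duplicating a site can move coverage either way
        # (extra occurrences can demote duplicates to triples, shrinking Q2)
        for _ in range(20):
            inc = pd.DataFrame(rng.integers(0, 2, (5, 8)))
            if inc.values.sum() == 0:
                continue
            s_obs, s_hat, cov = incidence_extrapolation(inc)
            assert s_hat >= s_obs
            assert 0 < cov <= 1

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            incidence_extrapolation(pd.DataFrame())
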