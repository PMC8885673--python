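"""Microbiome community analysis: collapsing, diversity, ordination, LDA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from coinflam import (
    OtuCountTable,
    bray_curtis,
    collapse_to_rank,
    lda_effect_size,
    pcoa,
    richness,
    shannon_index,
)
from coinflam.errors import (
    CoinflamError,
    DegenerateClassError,
    EmptySampleError,
    InvalidDistanceError,
)


class TestCollapse:
    def test_conserves_sample_totals(self, small_otu_table):
        res = collapse_to_rank(small_otu_table, "family")
        assert (
            res.table.counts.sum(axis=1) == small_otu_table.counts.sum(axis=1)
        ).all()

    def test_single_family_collapses_to_totals(self):
        counts = pd.DataFrame({"a": [3, 4], "b": [5, 6]}, index=["s1", "s2"])
        lin = pd.Series({
            "a": "k__B;p__F;c__C;o__O;f__Fam;g__G1;s__",
            "b": "k__B;p__F;c__C;o__O;f__Fam;g__G2;s__",
        })
        res = collapse_to_rank(OtuCountTable(counts, lin), "family")
        assert list(res.table.counts.columns) == ["k__B;p__F;c__C;o__O;f__Fam"]
        assert (res.table.counts.iloc[:, 0] == [8, 10]).all()
        assert res.mapped_fraction == 1.0

    def test_mapped_fraction_reporting(self):
        # 999,100 of 1,000,000 reads family-assigned -> 99.91%
        counts = pd.DataFrame(
            {"a": [999_100], "b": [900]}, index=["s1"]
        )
        lin = pd.Series({
            "a": "k__B;p__F;c__C;o__O;f__Fam;g__G;s__S",
            "b": "k__B;p__F;c__C;o__O",  # order level only
        })
        res = collapse_to_rank(OtuCountTable(counts, lin), "family")
        assert res.mapped_fraction == pytest.approx(0.9991)
        assert res.n_total_reads == 1_000_000

    def test_idempotent(self, small_otu_table):
        once = collapse_to_rank(small_otu_table, "family")
        twice = collapse_to_rank(once.table, "family")
        pd.testing.assert_frame_equal(
            once.table.counts, twice.table.counts, check_like=True
        )

    def test_unknown_rank(self, small_otu_table):
        with pytest.raises(CoinflamError):
            collapse_to_rank(small_otu_table, "tribe")


class TestAlphaDiversity:
    def test_single_otu_zero(self):
        assert shannon_index([42]) == 0.0

    def test_even_pair_one_bit(self):
        assert shannon_index([50, 50]) == pytest.approx(1.0)

    def test_direct_summation_oracle(self):
        counts = np.array([1, 2, 3, 4], float)
        p = counts / counts.sum()
        expected = -(p * np.log2(p)).sum()
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            c = rng.integers(0, 50, size=rng.integers(2, 30))
            if c.sum() == 0:
                continue
            assert shannon_index(c) <= np.log2(richness(c)) + 1e-12

    def test_uniform_attains_bound(self):
        assert shannon_index([7, 7, 7, 7]) == pytest.approx(2.0)

    def test_empty_sample_raises(self):
        with pytest.raises(EmptySampleError):
            shannon_index([0, 0, 0])

    @pytest.mark.parametrize("counts,expected", [([0, 0, 5], 1), ([], 0)])
    def test_richness(self, counts, expected):
        assert richness(counts) == expected

    def test_richness_all_positive(self):
        assert richness(np.ones(173)) == 173


class TestBrayCurtis:
    def test_identical_zero(self):
        assert bray_curtis([3, 1, 4], [3, 1, 4]) == pytest.approx(0.0)

    def test_disjoint_one(self):
        assert bray_curtis([5, 0, 0], [0, 2, 9]) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert bray_curtis([6, 0, 2], [0, 1, 1]) == pytest.approx(0.8)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = rng.integers(0, 20, size=(2, 15)) + 1
        assert bray_curtis(a, b) == pytest.approx(bray_curtis(b, a))

    def test_zero_total_raises(self):
        with pytest.raises(EmptySampleError):
            bray_curtis([0, 0], [1, 2])


class TestPcoa:
    def test_three_equidistant_points(self):
        d = 1 - np.eye(3)
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-8)

    def test_round_trip_of_euclidean_configuration(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 2))
        dm = squareform(pdist(pts))
        res = pcoa(dm)
        recovered = squareform(pdist(res.coordinates.to_numpy()[:, :2]))
        assert np.max(np.abs(recovered - dm)) < 1e-8

    def test_two_samples_single_axis(self):
        res = pcoa(np.array([[0.0, 0.7], [0.7, 0.0]]))
        coords = res.coordinates.to_numpy()
        assert coords.shape[1] == 1
        assert abs(coords[0, 0] - coords[1, 0]) == pytest.approx(0.7)

    def test_asymmetric_rejected(self):
        with pytest.raises(InvalidDistanceError):
            pcoa(np.array([[0.0, 1.0], [0.5, 0.0]]))


def planted_table(n_per_class=8, factor=10.0, seed=0):
    """Feature f0 `factor`-fold more abundant in class B, tight noise."""
    rng = np.random.default_rng(seed)
    rows, ids, labels = [], [], {}
    for cls, mult in (("A", 1.0), ("B", factor)):
        for i in range(n_per_class):
            base = np.array([40.0 * mult, 100.0, 80.0, 60.0, 40.0])
            rows.append(rng.poisson(base * 20))
            sid = f"{cls}{i}"
            ids.append(sid)
            labels[sid] = cls
    counts = pd.DataFrame(
        rows, index=ids, columns=[f"f{j}" for j in range(5)]
    )
    lineages = pd.Series(
        {f"f{j}": f"k__B;p__P;c__C;o__O;f__Fam{j}" for j in range(5)}
    )
    return OtuCountTable(counts, lineages), labels


class TestLdaEffectSize:
    def test_planted_signal_flagged(self):
        table, labels = planted_table()
        res = lda_effect_size(table, labels, seed=1)
        row = res.loc["f0"]
        assert row["significant"]
        assert row["enriched_class"] == "B"
        assert abs(row["lda_score"]) >= 2.0

    def test_identical_class_distributions_nothing_significant(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            rng.poisson(100, size=(12, 6)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"f{j}" for j in range(6)],
        )
        lineages = pd.Series({f"f{j}": f"k__B;p__P;c__C;o__O;f__F{j}"
                              for j in range(6)})
        table = OtuCountTable(counts, lineages)
        labels = {f"s{i}": ("A" if i < 6 else "B") for i in range(12)}
        res = lda_effect_size(table, labels, seed=2)
        # homogeneous Poisson noise: at most a chance hit across 6 features
        assert res["significant"].sum() <= 1

    def test_significance_monotone_in_cutoff_and_alpha(self):
        table, labels = planted_table(factor=3.0, seed=3)
        prev = None
        for cutoff in (1.0, 2.0, 3.0, 4.0):
            n = lda_effect_size(
                table, labels, lda_cutoff=cutoff, seed=4
            )["significant"].sum()
            if prev is not None:
                assert n <= prev
            prev = n
        loose = lda_effect_size(table, labels, alpha=0.10, seed=4)
        tight = lda_effect_size(table, labels, alpha=0.01, seed=4)
        assert tight["significant"].sum() <= loose["significant"].sum()

    def test_degenerate_class_rejected(self):
        table, labels = planted_table(n_per_class=4)
        labels = dict(labels)
        for k in list(labels):
            if labels[k] == "B" and k != "B0":
                labels[k] = "A"
        with pytest.raises(DegenerateClassError):
            lda_effect_size(table, labels)

    def test_deterministic_under_seed(self):
        table, labels = planted_table(seed=9)
        a = lda_effect_size(table, labels, seed=5)
        b = lda_effect_size(table, labels, seed=5)
        pd.testing.assert_frame_equal(a, b)
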