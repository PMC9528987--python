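"""Size factors, dispersion, NB Wald test, VST and time-course operations."""

import math

import numpy as np
import pandas as pd
import pytest

from helpers import nb_draws
from scaprna.core import ValidationError
from scaprna.enrichment import (
    EnrichmentParams,
    anova_filter,
    estimate_dispersion,
    mean_assay_dispersion,
    nb_enrichment_test,
    size_factors,
    timecourse_fold_changes,
    venn_classify,
    vst,
)


def _cols(n_rep=3):
    return pd.MultiIndex.from_tuples(
        [(f"s{i}", "short") for i in range(n_rep)]
        + [(f"s{i}", "long") for i in range(n_rep)],
        names=["sample", "assay"],
    )


class TestSizeFactors:
    def test_hand_computed_two_columns(self):
        mat = np.array([[10, 20], [20, 40], [30, 60]])
        s = size_factors(mat)
        assert s == pytest.approx([2 / 3, 4 / 3])

    def test_identical_columns_give_ones(self):
        mat = np.tile(np.array([[5], [9], [14]]), (1, 4))
        assert size_factors(mat) == pytest.approx([1, 1, 1, 1])

    def test_single_column_is_one(self):
        assert size_factors(np.array([[3], [7]])) == pytest.approx([1.0])

    def test_scaling_one_column_scales_its_factor(self, rng):
        mat = rng.poisson(50, size=(200, 3)) + 1
        s0 = size_factors(mat)
        mat2 = mat.copy().astype(float)
        mat2[:, 1] *= 5
        s1 = size_factors(mat2)
        # pre-normalisation ratio of column 1 to the others scales by 5
        assert s1[1] / s1[0] == pytest.approx(5 * s0[1] / s0[0], rel=1e-9)

    def test_no_positive_row_errors(self):
        with pytest.raises(ValidationError):
            size_factors(np.array([[0, 1], [1, 0]]))


class TestDispersion:
    def test_poisson_counts_near_zero(self, rng):
        y = rng.poisson(50, size=(2000, 3))
        assert estimate_dispersion(y) <= 0.02

    def test_nb_dispersion_recovered(self, rng):
        y = nb_draws(rng, 100, 0.2, (2000, 3))
        assert 0.1 <= estimate_dispersion(y) <= 0.3

    def test_constant_rows_give_zero(self):
        y = np.tile(np.array([[7], [13]]), (1, 4))
        assert estimate_dispersion(y) == 0.0

    def test_needs_two_columns(self):
        with pytest.raises(ValidationError):
            estimate_dispersion(np.array([[1], [2]]))


class TestNBEnrichment:
    def test_equal_counts_are_ns_with_zero_ratio(self):
        mat = pd.DataFrame(np.full((5, 6), 40), columns=_cols())
        results = nb_enrichment_test(mat, s=np.ones(6), alpha=0.05)
        for r in results:
            assert r.enriched == "ns"
            assert r.log2_ratio == pytest.approx(0.0)

    def test_all_zero_peak_flagged(self):
        mat = pd.DataFrame(np.zeros((1, 6), dtype=int), columns=_cols())
        (r,) = nb_enrichment_test(mat, s=np.ones(6), alpha=0.05)
        assert r.all_zero and r.enriched == "ns" and r.log2_ratio == 0.0

    def test_label_swap_antisymmetry(self, rng):
        y = np.c_[nb_draws(rng, 80, 0.1, (300, 3)), nb_draws(rng, 30, 0.1, (300, 3))]
        df = pd.DataFrame(y, columns=_cols())
        swapped_cols = pd.MultiIndex.from_tuples(
            [(s, {"short": "long", "long": "short"}[a]) for s, a in _cols()],
            names=["sample", "assay"],
        )
        df_swapped = pd.DataFrame(y, columns=swapped_cols)
        res = nb_enrichment_test(df, s=np.ones(6), alpha=0.1)
        res_swapped = nb_enrichment_test(df_swapped, s=np.ones(6), alpha=0.1)
        for a, b in zip(res, res_swapped):
            assert a.log2_ratio == pytest.approx(-b.log2_ratio)
            assert a.p == pytest.approx(b.p)
            swap = {"short_enriched": "long_enriched",
                    "long_enriched": "short_enriched", "ns": "ns"}
            assert swap[a.enriched] == b.enriched

    def test_discovery_count_invariant_under_row_permutation(self, rng):
        y = np.c_[nb_draws(rng, 100, 0.1, (400, 3)), nb_draws(rng, 25, 0.1, (400, 3))]
        df = pd.DataFrame(y, columns=_cols(), index=[f"p{i}" for i in range(400)])
        res = nb_enrichment_test(df, s=np.ones(6), alpha=0.1)
        perm = rng.permutation(400)
        res_perm = nb_enrichment_test(df.iloc[perm], s=np.ones(6), alpha=0.1)
        n1 = sum(r.enriched != "ns" for r in res)
        n2 = sum(r.enriched != "ns" for r in res_perm)
        assert n1 == n2

    def test_bh_adjustment_monotone_in_p(self, rng):
        y = np.c_[nb_draws(rng, 60, 0.1, (500, 3)), nb_draws(rng, 40, 0.1, (500, 3))]
        df = pd.DataFrame(y, columns=_cols())
        res = nb_enrichment_test(df, s=np.ones(6), alpha=0.1)
        by_p = sorted(res, key=lambda r: r.p)
        padj = [r.p_adj for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(padj, padj[1:]))


class TestVenn:
    def _res(self, short, long, enriched="ns"):
        from scaprna.enrichment import EnrichmentResult

        return EnrichmentResult("p", 0.0, 1.0, 1.0, enriched,
                                short >= 1, long >= 1)

    def test_partition(self):
        res = [self._res(5, 0), self._res(0, 3), self._res(2, 2), self._res(0, 0)]
        counts = venn_classify(res)
        assert counts["short_only"] == 1
        assert counts["long_only"] == 1
        assert counts["both"] == 1
        assert counts["total_expressed"] == 3  # 0/0 peak excluded

    def test_recovers_simulated_composition(self, rng):
        n = 5000
        truth = rng.random(n)
        rows = []
        for u in truth:
            if u < 0.3:  # short-only
                rows.append(np.r_[nb_draws(rng, 50, 0.1, 3), np.zeros(3, int)])
            elif u < 0.5:  # long-only
                rows.append(np.r_[np.zeros(3, int), nb_draws(rng, 50, 0.1, 3)])
            else:
                rows.append(nb_draws(rng, 30, 0.1, 6))
        df = pd.DataFrame(np.array(rows), columns=_cols())
        res = nb_enrichment_test(df, s=np.ones(6), alpha=0.1)
        counts = venn_classify(res)
        frac_short_only = counts["short_only"] / counts["total_expressed"]
        assert abs(frac_short_only - 0.3) <= 0.03


class TestVST:
    @pytest.mark.parametrize("variant", ["sqrt", "literal"])
    @pytest.mark.parametrize("a", [0.1, 1.0, 5.0])
    def test_zero_value_follows_formula(self, variant, a):
        # arcsinh(0) = 0, so vst(0, a) = -(ln a + ln 4)/ln 2 = -2 - log2(a)
        assert vst(0.0, a, variant) == pytest.approx(-2.0 - math.log2(a))

    def test_zero_at_unit_dispersion_is_minus_two(self):
        assert vst(0.0, 1.0, "sqrt") == pytest.approx(-2.0)
        assert vst(0.0, 1.0, "literal") == pytest.approx(-2.0)

    def test_sqrt_variant_log2_asymptote(self):
        assert abs(vst(1e6, 1.0, "sqrt") - math.log2(1e6)) < 1e-3

    def test_literal_variant_doubled_asymptote(self):
        # 2*arcsinh(ax) ~ 2*ln(2ax) for large x
        expected = 2 * math.log2(2e6) - 2
        assert vst(1e6, 1.0, "literal") == pytest.approx(expected, abs=0.01)

    def test_strictly_monotone(self):
        xs = np.linspace(0, 1000, 2001)
        for variant in ("sqrt", "literal"):
            vals = vst(xs, 0.3, variant)
            assert np.all(np.diff(vals) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            vst(-1.0, 1.0)
        with pytest.raises(ValidationError):
            vst(1.0, 0.0)


class TestTimecourse:
    def test_constant_counts_center_to_zero(self):
        cols = pd.MultiIndex.from_tuples(
            [(f"t{t}_r{r}", a) for a in ("short", "long")
             for t in range(2) for r in range(2)],
            names=["sample", "assay"],
        )
        mat = pd.DataFrame(np.full((3, 8), 25), columns=cols)
        tmap = {f"t{t}_r{r}": t for t in range(2) for r in range(2)}
        fc = timecourse_fold_changes(mat, np.ones(8), 0.1, tmap)
        assert np.allclose(fc.to_numpy(), 0.0)

    def test_two_timepoint_symmetry_and_row_means_zero(self, rng):
        cols = pd.MultiIndex.from_tuples(
            [(f"t{t}_r{r}", "short") for t in range(3) for r in range(2)],
            names=["sample", "assay"],
        )
        mat = pd.DataFrame(rng.poisson(40, size=(20, 6)), columns=cols)
        tmap = {f"t{t}_r{r}": t for t in range(3) for r in range(2)}
        fc = timecourse_fold_changes(mat, np.ones(6), 0.1, tmap)
        assert np.max(np.abs(fc.to_numpy().mean(axis=1))) < 1e-12


class TestAnova:
    def test_separated_constant_groups_kept(self):
        keep, p = anova_filter([[np.ones(3), np.full(3, 2.0)]])
        assert keep[0] and p[0] == 0.0

    def test_identical_values_dropped(self):
        keep, p = anova_filter([[np.ones(3), np.ones(3)]])
        assert not keep[0] and p[0] == 1.0

    def test_null_rejection_rate_calibrated(self, rng):
        groups = [
            [rng.normal(size=3) for _ in range(3)] for _ in range(2000)
        ]
        keep, _ = anova_filter(groups)
        assert 0.03 <= keep.mean() <= 0.07
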