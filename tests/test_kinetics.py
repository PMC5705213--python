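"""Initial-rate fitting, selectivity statistics, and Storey q-values."""

import math

import pandas as pd

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import proteospec as ps
from proteospec.kinetics import DEFAULT_RATE_TIMEPOINTS


def _curve(times, areas, enzyme="iP", rep=1, sid="s1", pid=None):
    return ps.ProgressCurve(product_id=pid or f"{sid}_N", substrate_id=sid,
                            enzyme=enzyme, replicate=rep,
                            times=tuple(times), areas=tuple(areas))


class TestInitialRate:
    def test_exact_linear_curve(self):
        t = DEFAULT_RATE_TIMEPOINTS
        est = ps.initial_rate(_curve(t, [2.0 * x for x in t]))
        assert est.v0 == pytest.approx(2.0)
        assert est.r_squared == pytest.approx(1.0)
        assert est.flag == ""

    def test_saturating_curve_recovers_initial_slope(self):
        # A(1 - e^(-kt)) has initial slope A·k = 1.0 area/min
        A, k = 1000.0, 0.001
        areas = [A * (1 - math.exp(-k * t)) for t in DEFAULT_RATE_TIMEPOINTS]
        est = ps.initial_rate(_curve(DEFAULT_RATE_TIMEPOINTS, areas))
        assert est.v0 == pytest.approx(A * k, rel=0.10)

    def test_plateau_from_first_point_is_zero_rate(self):
        est = ps.initial_rate(_curve(DEFAULT_RATE_TIMEPOINTS, [500.0] * 7))
        assert est.v0 == 0.0
        assert est.flag == "no_linear_region"

    def test_all_zero_areas_flagged(self):
        est = ps.initial_rate(_curve(DEFAULT_RATE_TIMEPOINTS, [0.0] * 7))
        assert est.v0 == 0.0
        assert est.flag == "all_zero"

    def test_rate_never_negative(self):
        # noisy, even decreasing early points: the origin-anchored fit of
        # non-negative areas keeps v0 ≥ 0
        areas = [30.0, 20.0, 10.0, 5.0, 2.0, 100.0, 100.0]
        est = ps.initial_rate(_curve(DEFAULT_RATE_TIMEPOINTS, areas))
        assert est.v0 >= 0.0

    def test_minimum_three_points_enforced(self):
        # only the first point is below half-max; fit still uses 3
        areas = [1.0, 80.0, 90.0, 95.0, 99.0, 100.0, 100.0]
        est = ps.initial_rate(_curve(DEFAULT_RATE_TIMEPOINTS, areas))
        assert est.n_points_used == 3

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            _curve((1.0, 2.0), (1.0, 2.0))
        with pytest.raises(ValueError):
            _curve((1.0, 2.0, 2.0), (1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            _curve((1.0, 2.0, 3.0), (1.0, -2.0, 3.0))


class TestSelectivity:
    def _rates(self, values, enzyme, sid="s1"):
        return [
            ps.RateEstimate(v0=v, n_points_used=4, r_squared=1.0,
                            product_id=f"{sid}_N", substrate_id=sid,
                            enzyme=enzyme, replicate=i + 1)
            for i, v in enumerate(values)
        ]

    def test_identical_rate_vectors(self):
        a = self._rates([5.0, 5.0, 5.0, 5.0], "iP")
        b = self._rates([5.0, 5.0, 5.0, 5.0], "cP")
        res = ps.selectivity(a, b)
        assert res.mean_log2_ratio == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fifteen_fold_selectivity(self):
        a = self._rates([15.0] * 4, "iP")
        b = self._rates([1.0] * 4, "cP")
        res = ps.selectivity(a, b)
        assert res.mean_log2_ratio == pytest.approx(math.log2(15.0), abs=1e-9)

    def test_twofold_boundary_is_log2_one(self):
        a = self._rates([2.0] * 4, "iP")
        b = self._rates([1.0] * 4, "cP")
        assert ps.selectivity(a, b).mean_log2_ratio == pytest.approx(1.0)

    def test_single_enzyme_substrate_flagged_and_untested(self):
        a = self._rates([3.0, 4.0], "iP")
        res = ps.selectivity(a, [], substrate_id="s1")
        assert res.flag == "infinite_selectivity"
        assert math.isinf(res.mean_log2_ratio)
        assert math.isnan(res.p_value)

    def test_products_average_within_replicate_first(self):
        # replicate 1 sees both products, replicate 2 only one: rep means
        # are (10+20)/2 = 15 and 12
        a = [
            ps.RateEstimate(10.0, 4, 1.0, "", "s_N", "s", "iP", 1),
            ps.RateEstimate(20.0, 4, 1.0, "", "s_C", "s", "iP", 1),
            ps.RateEstimate(12.0, 4, 1.0, "", "s_N", "s", "iP", 2),
        ]
        b = self._rates([1.0, 1.0], "cP", sid="s")
        res = ps.selectivity(a, b)
        assert res.mean_log2_ratio == pytest.approx(math.log2(13.5))

    @settings(max_examples=40, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=50),
    )
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        va = rng.lognormal(2.0, 0.3, size=4)
        vb = rng.lognormal(1.0, 0.3, size=4)
        base = ps.selectivity(self._rates(va, "iP"), self._rates(vb, "cP"))
        scaled = ps.selectivity(self._rates(va * scale, "iP"),
                                self._rates(vb * scale, "cP"))
        assert scaled.mean_log2_ratio == pytest.approx(base.mean_log2_ratio,
                                                       rel=1e-9)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-6)


class TestStoreyQvalues:
    def test_all_ones(self):
        assert (ps.storey_qvalues([1.0, 1.0, 1.0]) == 1.0).all()

    def test_bh_by_hand(self):
        q = ps.storey_qvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_empty_input(self):
        assert ps.storey_qvalues([]).size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            ps.storey_qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            ps.storey_qvalues([0.5, 1.5])

    def test_lambda_zero_equals_bh_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = int(rng.integers(1, 60))
            p = rng.uniform(1e-12, 1.0, size=m)
            q = ps.storey_qvalues(p, lam=0.0)
            bh = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_positive_lambda_shrinks_pi0(self):
        p = [0.001, 0.002, 0.003, 0.9]
        q0 = ps.storey_qvalues(p, lam=0.0)
        q5 = ps.storey_qvalues(p, lam=0.5)
        # π̂0 = 0.5 at λ=0.5 here, so q-values halve (before capping)
        np.testing.assert_allclose(q5[:3], q0[:3] * 0.5)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=40))
    def test_q_monotone_in_p(self, pvals):
        q = ps.storey_qvalues(pvals)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(pvals) - 1e-12).all()  # q ≥ p at λ=0


class TestSelectivityAnalysis:
    def test_recovers_designed_ratios(self):
        """Curves generated with known bond-7 hazard ratios come back with
        the right per-substrate selectivity and significance."""
        deltas = {"A": -3, "C": 0, "D": 3}
        ip = ps.GroundTruthSpecificity.from_elevations(
            {"P1": {r: 2.0 ** d for r, d in deltas.items()}}
        )
        cp = ps.GroundTruthSpecificity.uniform()
        peptides = {f"s{r}": "GGGGGG" + r + "GGGGGGG" for r in deltas}
        curves = ps.simulate_progress_curves(peptides, ip, cp, k0=2e-4, seed=2)
        table = ps.selectivity_analysis(curves, "iP", "cP").set_index("substrate_id")
        for r, d in deltas.items():
            assert table.at[f"s{r}", "mean_log2_ratio"] == pytest.approx(d, abs=0.3)
        assert bool(table.at["sA", "significant"])
        assert bool(table.at["sD", "significant"])
        assert not bool(table.at["sC", "significant"])

    def test_noise_free_equal_truths_show_no_selectivity(self):
        uni = ps.GroundTruthSpecificity.uniform()
        peptides = {f"s{i}": "GGGGGGAGGGGGGG" for i in range(3)}
        curves = ps.simulate_progress_curves(peptides, uni, uni, noise_cv=0.0,
                                             seed=0)
        table = ps.selectivity_analysis(curves, "iP", "cP")
        assert (table["mean_log2_ratio"].abs() < 1e-12).all()
        assert not table["significant"].any()

    def test_roundtrip_through_tsv(self, tmp_path):
        uni = ps.GroundTruthSpecificity.uniform()
        curves = ps.simulate_progress_curves({"s1": "GGGGGGAGGGGGGG"}, uni, uni,
                                             seed=1)
        path = tmp_path / "areas.tsv"
        ps.kinetics.write_peak_area_table(curves, path)
        again = ps.read_peak_area_table(path)
        assert sorted(c.product_id for c in again) == \
            sorted(c.product_id for c in curves)
        t1 = ps.selectivity_analysis(curves, "iP", "cP")
        t2 = ps.selectivity_analysis(again, "iP", "cP")
        pd.testing.assert_frame_equal(t1, t2, rtol=1e-9, atol=1e-12)
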