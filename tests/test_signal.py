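"""Sequential correlation diagnostic: pairing, differencing, windows, regimes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coredisorder import signal as sig
from coredisorder.disorder import disorder_series
from coredisorder.diversity import diversity_series
from coredisorder.synthetic import ScenarioConfig, generate_core, perturb_dates

# the worked micro-example: three dated (°disorder, biodiversity) pairs
WORKED_DATES = [1898.0, 1900.0, 1903.0]
WORKED_T = [41.35, 38.59, 36.98]
WORKED_BIO = [18.64, 21.71, 19.90]


def worked_paired():
    return sig.PairedSeries(np.array(WORKED_DATES), np.array(WORKED_T),
                            np.array(WORKED_BIO))


class TestPairing:
    def test_worked_triple_builds_three_pairs(self):
        disorder = pd.DataFrame({"date": WORKED_DATES, "t": WORKED_T})
        diversity = pd.DataFrame({"date": WORKED_DATES, "n2": WORKED_BIO,
                                  "richness": [6, 9, 8]})
        paired = sig.pair_series(disorder, diversity)
        assert len(paired) == 3
        assert paired.t == pytest.approx(WORKED_T)
        assert paired.bio == pytest.approx(WORKED_BIO)

    def test_empty_overlap_is_an_error(self):
        disorder = pd.DataFrame({"date": [1900.0], "t": [40.0]})
        diversity = pd.DataFrame({"date": [1950.0], "n2": [5.0]})
        with pytest.raises(ValueError):
            sig.pair_series(disorder, diversity)

    def test_single_common_date(self):
        disorder = pd.DataFrame({"date": [1900.0], "t": [40.0]})
        diversity = pd.DataFrame({"date": [1900.0], "n2": [5.0]})
        assert len(sig.pair_series(disorder, diversity)) == 1

    def test_unknown_channel_rejected(self):
        disorder = pd.DataFrame({"date": [1900.0], "t": [40.0]})
        diversity = pd.DataFrame({"date": [1900.0], "n2": [5.0]})
        with pytest.raises(KeyError):
            sig.pair_series(disorder, diversity, channel="simpson")


class TestFirstDifferences:
    def test_worked_example_differences(self):
        """The printed pairs yield °disorder diffs (-2.76, -1.61) and
        biodiversity diffs (3.07, -1.81), labelled by the earlier dates."""
        diffs = sig.first_differences(worked_paired())
        assert diffs.dt == pytest.approx([-2.76, -1.61], abs=1e-9)
        assert diffs.dbio == pytest.approx([3.07, -1.81], abs=1e-9)
        assert diffs.dates == pytest.approx([1898.0, 1900.0])

    def test_constant_series_all_zero(self):
        p = sig.PairedSeries(np.arange(5.0), np.full(5, 7.0), np.full(5, 3.0))
        diffs = sig.first_differences(p)
        assert np.all(diffs.dt == 0) and np.all(diffs.dbio == 0)

    def test_linear_trend_constant_diffs(self):
        p = sig.PairedSeries(np.arange(6.0), 2.0 * np.arange(6.0),
                             5.0 - np.arange(6.0))
        diffs = sig.first_differences(p)
        assert np.ptp(diffs.dt) == 0 and np.ptp(diffs.dbio) == 0

    def test_too_short_rejected(self):
        p = sig.PairedSeries(np.array([1.0]), np.array([2.0]), np.array([3.0]))
        with pytest.raises(ValueError):
            sig.first_differences(p)


class TestSequentialCorrelations:
    def test_exact_antiphase_gives_minus_one(self, rng):
        n = 30
        x = rng.standard_normal(n).cumsum()
        p = sig.PairedSeries(np.arange(float(n)), x, -x + 10.0)
        seq = sig.sequential_correlations(sig.first_differences(p), window=15)
        assert seq["pre_r"].to_numpy() == pytest.approx(-1.0)

    def test_window_equal_to_series_matches_direct_formula(self, rng):
        n = 16
        t = rng.standard_normal(n)
        b = rng.standard_normal(n)
        p = sig.PairedSeries(np.arange(float(n)), t, b)
        diffs = sig.first_differences(p)
        seq = sig.sequential_correlations(diffs, window=n)
        assert len(seq) == 1
        dt, db = np.diff(t), np.diff(b)
        oracle = np.sum((dt - dt.mean()) * (db - db.mean())) / np.sqrt(
            np.sum((dt - dt.mean()) ** 2) * np.sum((db - db.mean()) ** 2)
        )
        assert seq["pre_r"].iloc[0] == pytest.approx(oracle)

    def test_independent_channels_centre_on_zero(self, rng):
        """Monte-Carlo oracle: mean windowed r over 10^4 independent windows
        is within 3 standard errors of zero."""
        n_windows, w = 10_000, 14
        x = rng.standard_normal((n_windows, w))
        y = rng.standard_normal((n_windows, w))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
        assert abs(r.mean()) < 3.0 * r.std(ddof=1) / np.sqrt(n_windows)

    def test_zero_variance_window_reported_missing(self):
        n = 20
        t = np.arange(float(n))  # constant diffs -> zero variance
        b = np.arange(float(n)) ** 2
        p = sig.PairedSeries(np.arange(float(n)), t, b)
        seq = sig.sequential_correlations(sig.first_differences(p), window=15)
        assert seq["pre_r"].isna().all()

    def test_lead_in_withheld_until_minimum(self, rng):
        n = 25
        p = sig.PairedSeries(np.arange(float(n)), rng.standard_normal(n),
                             rng.standard_normal(n))
        seq = sig.sequential_correlations(sig.first_differences(p), window=15,
                                          min_lead_in=5)
        assert seq.loc[seq["lead_n"] < 5, "lead_r"].isna().all()
        assert seq.loc[seq["lead_n"] >= 5, "lead_r"].notna().all()

    def test_dated_by_most_recent_section(self, rng):
        n = 20
        dates = np.arange(float(n)) + 1900.0
        p = sig.PairedSeries(dates, rng.standard_normal(n), rng.standard_normal(n))
        seq = sig.sequential_correlations(sig.first_differences(p), window=15)
        assert seq["date"].iloc[-1] == dates[-1]


class TestRegimeClassification:
    def make(self, pre_r, pre_p, lead_r):
        return sig.CorrelationPair(2000.0, pre_r, pre_p, 14, lead_r, 0.5, 20)

    def test_strong_negative_switch_is_keystone_favored(self):
        pair = self.make(-0.51, 0.03, 0.24)
        assert sig.classify_regime(pair) == "keystone-favored"

    def test_flat_coefficients_indeterminate(self):
        pair = self.make(0.0, 1.0, 0.0)
        assert sig.classify_regime(pair) == "indeterminate"

    def test_significant_positive_above_lead_is_weed_favored(self):
        pair = self.make(0.6, 0.01, -0.1)
        assert sig.classify_regime(pair) == "weed-favored"

    def test_significant_positive_below_lead_is_canary_favored(self):
        pair = self.make(0.55, 0.02, 0.8)
        assert sig.classify_regime(pair) == "canary-favored"

    def test_missing_lead_in_indeterminate(self):
        pair = self.make(-0.6, 0.01, float("nan"))
        assert sig.classify_regime(pair) == "indeterminate"


class TestPearsonProperties:
    @settings(deadline=None, max_examples=50)
    @given(
        data=st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
            min_size=5, max_size=20,
        ),
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_symmetry_and_affine_invariance(self, data, a, b):
        x = np.array([d[0] for d in data])
        y = np.array([d[1] for d in data])
        r_xy, _ = sig._pearson(x, y)
        r_yx, _ = sig._pearson(y, x)
        r_scaled, _ = sig._pearson(a * x + b, y)
        if np.isnan(r_xy):
            assert np.isnan(r_yx)
        else:
            assert -1.0 - 1e-12 <= r_xy <= 1.0 + 1e-12
            assert r_xy == pytest.approx(r_yx)
            assert r_xy == pytest.approx(r_scaled, abs=1e-6)


class TestDateRobustness:
    def test_correlations_identical_under_monotone_redating(self, anti_phase_core):
        """Only section order enters the computation, so compaction-style
        redating cannot change a single coefficient."""
        def run(core):
            d = disorder_series(core)
            v = diversity_series(core)
            p = sig.pair_series(d, v)
            return sig.sequential_correlations(sig.first_differences(p))

        base = run(anti_phase_core)
        warped = run(perturb_dates(anti_phase_core, "compaction", seed=5))
        for col in ("pre_r", "pre_p", "lead_r", "lead_p"):
            a, b = base[col].to_numpy(), warped[col].to_numpy()
            assert np.array_equal(a, b, equal_nan=True)


class TestWindowSensitivity:
    def test_default_alternation_peaks_at_fifteen(self):
        core = generate_core(ScenarioConfig(phase="anti-phase", seed=3), 150)
        table = sig.window_sensitivity(core, [10, 15, 20])
        best = table.loc[table["mean_abs_pre_r"].idxmax(), "window"]
        assert best == 15

    def test_single_window_consistent_with_sequential(self, anti_phase_core):
        table = sig.window_sensitivity(anti_phase_core, [15])
        d = disorder_series(anti_phase_core, window=15)
        v = diversity_series(anti_phase_core)
        p = sig.pair_series(d, v)
        seq = sig.sequential_correlations(sig.first_differences(p), window=15)
        assert table["mean_abs_pre_r"].iloc[0] == pytest.approx(
            seq["pre_r"].abs().mean()
        )

    def test_oversized_window_rejected(self, anti_phase_core):
        with pytest.raises(ValueError):
            sig.window_sensitivity(anti_phase_core, [80])
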