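"""Duration clustering, baseline normalization, summaries, correlations."""

import numpy as np
import pandas as pd
import pytest

from seizurepath import adf, stats
from seizurepath.model import N_X, N_XI
from seizurepath.stats import (DurationCatalog, NormalizedTrajectory,
                               baseline_normalize, bonferroni_divisor,
                               cluster_durations, compare_long_short,
                               correlate_duration, summarize_trajectories,
                               window_theta_means)


def _make_estimate(theta_traj, fs=50.0, t0=-60.0, seizure_id="s", channel=0):
    n = theta_traj.shape[0]
    means = np.zeros((n, N_XI))
    means[:, N_X:] = theta_traj
    return adf.TrajectoryEstimate(
        time=t0 + np.arange(n) / fs, means=means,
        variances=np.zeros((n, N_XI)),
        diagnostics=adf.FilterDiagnostics(np.zeros(n), np.zeros((n, N_XI)),
                                          np.ones(n, dtype=bool), 0.0),
        valid=True, n_valid=n, fs=fs, channel=channel, seizure_id=seizure_id)


class TestBonferroniDivisor:
    def test_cohort_product(self):
        assert bonferroni_divisor(12, 5) == 60
        assert bonferroni_divisor(1, 5) == 5

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bonferroni_divisor(0, 5)


class TestClusterDurations:
    def test_well_separated_bimodal_gives_two(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            d = np.exp(np.concatenate([r.normal(2.5, 0.3, 100),
                                       r.normal(4.5, 0.3, 100)]))
            res = cluster_durations(DurationCatalog("p", d), seed=seed)
            hits += (res.optimal_k == 2 and res.optimal_k_gmm == 2)
        assert hits == 5

    def test_unimodal_gives_one(self):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            d = np.exp(r.normal(3.0, 0.3, 200))
            res = cluster_durations(DurationCatalog("p", d), seed=seed)
            hits += (res.optimal_k == 1)
        assert hits >= 4

    def test_identical_durations_short_circuit(self):
        res = cluster_durations(DurationCatalog("p", np.full(40, 30.0)), seed=0)
        assert res.optimal_k == 1
        assert res.method_agreement

    def test_small_catalog_excluded(self):
        with pytest.raises(ValueError, match="fewer than 20"):
            cluster_durations(DurationCatalog("p", np.full(10, 30.0)))

    def test_boundary_separates_clusters(self):
        r = np.random.default_rng(7)
        d = np.exp(np.concatenate([r.normal(2.5, 0.3, 100),
                                   r.normal(4.5, 0.3, 100)]))
        res = cluster_durations(DurationCatalog("p", d), seed=7)
        assert res.optimal_k == 2
        b = res.long_short_boundary
        assert np.all(d[res.assignments == 0] < b * np.exp(0.8))
        short_means = d[res.assignments == 0].mean()
        long_means = d[res.assignments == 1].mean()
        assert short_means < b < long_means

    def test_duplication_invariance(self):
        """Doubling every duration point does not change the chosen k."""
        for seed, mus in [(3, (2.5, 4.5)), (4, (3.0,))]:
            r = np.random.default_rng(seed)
            d = np.exp(np.concatenate([r.normal(m, 0.3, 80) for m in mus]))
            k1 = cluster_durations(DurationCatalog("p", d), seed=1).optimal_k
            k2 = cluster_durations(DurationCatalog("p", np.repeat(d, 2)),
                                   seed=1).optimal_k
            assert k1 == k2


class TestBaselineNormalize:
    def test_constant_trajectory_is_zero(self):
        theta = np.tile([0.01, 2.0, 3.0, 2.0, 0.5], (6000, 1))
        est = _make_estimate(theta)
        norm = baseline_normalize(est, duration=10.0,
                                  baseline_window=(-50.0, -20.0))
        assert np.allclose(norm.percent, 0.0)
        assert norm.usable.all()

    def test_fifty_percent_change(self):
        theta = np.tile([0.01, 2.0, 3.0, 2.0, 0.5], (6000, 1))
        theta[3000:, 1] = 3.0          # alpha_ep 2 -> 3
        est = _make_estimate(theta)
        norm = baseline_normalize(est, duration=20.0,
                                  baseline_window=(-50.0, -20.0))
        assert norm.percent[-1, 1] == pytest.approx(50.0)

    def test_negative_baseline_convention(self):
        """With baseline -2 and value -3 the change is -50% (|.| divisor)."""
        theta = np.tile([0.01, -2.0, 3.0, 2.0, 0.5], (6000, 1))
        theta[3000:, 1] = -3.0
        est = _make_estimate(theta)
        norm = baseline_normalize(est, duration=20.0,
                                  baseline_window=(-50.0, -20.0))
        assert norm.percent[-1, 1] == pytest.approx(-50.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        theta = np.abs(rng.normal(2.0, 0.2, (3000, 5))) + 0.5
        est1 = _make_estimate(theta)
        est5 = _make_estimate(5.0 * theta)
        n1 = baseline_normalize(est1, 5.0, (-50.0, -20.0))
        n5 = baseline_normalize(est5, 5.0, (-50.0, -20.0))
        assert np.allclose(n1.percent, n5.percent, atol=1e-9)

    def test_zero_baseline_flagged(self):
        theta = np.tile([0.0, 2.0, 3.0, 2.0, 0.5], (6000, 1))
        est = _make_estimate(theta)
        norm = baseline_normalize(est, 10.0, (-50.0, -20.0))
        assert not norm.usable[0]
        assert norm.usable[1:].all()

    def test_missing_baseline_window(self):
        est = _make_estimate(np.ones((100, 5)), t0=0.0)
        with pytest.raises(ValueError, match="baseline"):
            baseline_normalize(est, 1.0, (-120.0, -60.0))


def _norm(time, percent, duration, sid="s", channel=0):
    return NormalizedTrajectory(time=time, percent=percent,
                                usable=np.ones(5, dtype=bool),
                                duration=duration, seizure_id=sid,
                                channel=channel)


class TestSummarizeTrajectories:
    def test_identical_seizures_zero_ci(self):
        t = np.linspace(-10, 20, 601)
        pct = np.tile(np.sin(t)[:, None], (1, 5)) * 10
        norms = [_norm(t, pct.copy(), 20.0, sid=f"s{i}") for i in range(5)]
        summ = summarize_trajectories(norms, t_start=-10.0, dt=0.5)
        assert np.allclose(summ.ci_halfwidth, 0.0, atol=1e-12)
        expect = np.interp(summ.time, t, pct[:, 0])
        assert np.allclose(summ.mean[:, 0], expect, atol=1e-9)

    def test_ongoing_only_averaging(self):
        t = np.linspace(-5, 30, 701)
        norms = [_norm(t, np.zeros((701, 5)), d, sid=f"s{d}")
                 for d in (10.0, 30.0)]
        summ = summarize_trajectories(norms, t_start=0.0, dt=1.0)
        n_at = dict(zip(summ.time, summ.n))
        assert n_at[5.0] == 2
        assert n_at[20.0] == 1

    def test_minmax_attains_extremes(self):
        rng = np.random.default_rng(0)
        t = np.linspace(-10, 10, 401)
        norms = [_norm(t, rng.normal(0, 5, (401, 5)), 10.0, sid=f"s{i}")
                 for i in range(4)]
        summ = summarize_trajectories(norms, t_start=-10.0, dt=0.05,
                                      with_minmax=True)
        assert summ.minmax is not None
        assert np.nanmax(np.abs(summ.minmax)) <= 1.0 + 1e-12

    def test_designed_motif_flags(self):
        """A decrease-then-increase motif plus noise yields a contiguous
        decrease epoch then an increase epoch in the significance flags."""
        rng = np.random.default_rng(5)
        t = np.linspace(-10, 20, 601)
        shape = np.zeros_like(t)
        shape[(t >= 0) & (t < 10)] = -20.0
        shape[(t >= 12) & (t <= 18)] = +15.0
        norms = []
        for i in range(50):
            pct = np.zeros((t.size, 5))
            pct[:, 1] = shape + rng.normal(0, 5, t.size)
            norms.append(_norm(t, pct, 20.0, sid=f"s{i}"))
        summ = summarize_trajectories(norms, t_start=-10.0, dt=0.5)
        f = summ.flag[:, 1]
        tt = summ.time
        ictal = tt >= 0          # per-time tests carry ~5% false flags
        dec = tt[(f == -1) & ictal]
        inc = tt[(f == +1) & ictal]
        assert dec.size >= 10 and inc.size >= 5
        assert np.median(dec) < np.median(inc)
        assert np.mean((dec > -1) & (dec < 11)) >= 0.9
        assert np.mean((inc > 11) & (inc < 19)) >= 0.9

    def test_empty_input(self):
        with pytest.raises(ValueError):
            summarize_trajectories([])


class TestCompareLongShort:
    def _cluster(self, n_short, n_long):
        from seizurepath.stats import ClusterResult
        return ClusterResult(
            optimal_k=2, optimal_k_gmm=2,
            assignments=np.array([0] * n_short + [1] * n_long),
            gap_values={}, gap_se={}, method_agreement=True,
            long_short_boundary=30.0)

    def test_identical_groups_no_flags(self):
        t = np.linspace(-5, 15, 401)
        pct = np.tile(np.cos(t)[:, None], (1, 5))
        norms = [_norm(t, pct.copy(), 15.0, sid=f"s{i}") for i in range(8)]
        df, overall = compare_long_short(norms, self._cluster(4, 4),
                                         t_start=-5.0, dt=1.0)
        assert not df.significant.any()
        assert np.allclose(overall.overall_mean_difference, 0.0, atol=1e-12)

    def test_null_flag_rate_bounded(self):
        """Same-generator groups flag at most ~alpha of time points."""
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = np.linspace(-5, 15, 201)
            norms = [_norm(t, rng.normal(0, 5, (201, 5)), 15.0, sid=f"s{i}")
                     for i in range(40)]
            df, _ = compare_long_short(norms, self._cluster(20, 20),
                                       t_start=-5.0, dt=0.5)
            rates.append(df.significant.mean())
        assert np.mean(rates) <= 0.10

    def test_designed_offset_difference_located(self):
        rng = np.random.default_rng(1)
        t = np.linspace(-5, 15, 401)
        norms = []
        for i in range(30):
            pct = rng.normal(0, 2, (401, 5))
            if i >= 15:                       # long group diverges after t=10
                pct[t >= 10, 1] += 25.0
            norms.append(_norm(t, pct, 15.0, sid=f"s{i}"))
        df, _ = compare_long_short(norms, self._cluster(15, 15),
                                   t_start=-5.0, dt=0.5)
        sig = df[(df.parameter == "alpha_ep") & df.significant]
        assert (sig.time_s >= 10).mean() > 0.9

    def test_needs_two_clusters(self):
        from seizurepath.stats import ClusterResult
        res = ClusterResult(1, 1, np.zeros(4, dtype=int), {}, {}, True, None)
        with pytest.raises(ValueError):
            compare_long_short([], res)


class TestCorrelateDuration:
    def _estimates(self, values, durations, window="offset"):
        """Build estimates whose chosen-window mean equals `values` (n, 5)."""
        ests, durs = {}, {}
        for i, (v, d) in enumerate(zip(values, durations)):
            theta = np.tile(np.asarray(v, dtype=float), (int(50 * (d + 70)), 1))
            est = _make_estimate(theta, fs=50.0, t0=-60.0, seizure_id=f"s{i}")
            ests[f"s{i}"] = [est]
            durs[f"s{i}"] = float(d)
        return ests, durs

    def test_exact_proportionality(self):
        durations = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        values = np.tile(durations[:, None] * 0.01, (1, 5))
        ests, durs = self._estimates(values, durations)
        res = correlate_duration(ests, durs, "offset", bonferroni_m=5)
        assert np.allclose(res.table.r, 1.0)
        assert res.table.significant.all()

    def test_constant_parameter_not_computable(self):
        durations = np.array([10.0, 20.0, 30.0, 40.0])
        values = np.ones((4, 5))
        ests, durs = self._estimates(values, durations)
        res = correlate_duration(ests, durs, "onset", bonferroni_m=5)
        assert not res.table.computable.any()
        assert not res.table.significant.any()

    def test_ordering_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        durations = rng.uniform(10, 60, 12)
        values = rng.normal(2.0, 0.3, (12, 5))
        ests, durs = self._estimates(values, durations)
        res1 = correlate_duration(ests, durs, "offset", bonferroni_m=5)
        # shuffle ids
        perm = rng.permutation(12)
        ests2 = {f"s{i}": ests[f"s{j}"] for i, j in enumerate(perm)}
        durs2 = {f"s{i}": durs[f"s{j}"] for i, j in enumerate(perm)}
        for sid, lst in ests2.items():
            for e in lst:
                e.seizure_id = sid
        res2 = correlate_duration(ests2, durs2, "offset", bonferroni_m=5)
        assert np.allclose(np.sort(res1.table.r), np.sort(res2.table.r))
        # affine duration rescaling preserves r
        durs3 = {k: 3.0 * v + 7.0 for k, v in durs.items()}
        vals3 = np.stack([
            np.mean([window_theta_means(e, durs[s], "offset")
                     for e in ests[s]], axis=0) for s in sorted(ests)])
        # correlate manually against rescaled durations
        from scipy.stats import pearsonr
        d0 = np.array([durs[s] for s in sorted(ests)])
        d3 = 3.0 * d0 + 7.0
        for j in range(5):
            r0 = pearsonr(vals3[:, j], d0).statistic
            r3 = pearsonr(vals3[:, j], d3).statistic
            assert r0 == pytest.approx(r3, abs=1e-12)

    def test_minimum_seizures(self):
        ests, durs = self._estimates(np.ones((2, 5)), [10.0, 20.0])
        with pytest.raises(ValueError):
            correlate_duration(ests, durs)

    def test_window_means_extraction(self):
        theta = np.tile(np.arange(5, dtype=float), (5000, 1))
        theta[:500] = 99.0      # t in [-60, -50): outside both windows
        est = _make_estimate(theta, fs=50.0, t0=-60.0)
        on = window_theta_means(est, duration=30.0, window="onset")
        assert np.allclose(on, np.arange(5))
        off = window_theta_means(est, duration=30.0, window="offset")
        assert np.allclose(off, np.arange(5))
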