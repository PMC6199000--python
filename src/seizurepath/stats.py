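"""Seizure statistics: duration bimodality, trajectory summaries, correlations.

The pipeline mirrors a model-inversion seizure study:

* duration clustering — k-means and Gaussian-mixture fits on log durations for
  k = 1..3, with the gap statistic (uniform reference) choosing k per method;
* baseline normalization — connectivity estimates expressed as percent change
  from the pre-ictal window (default 2 to 1 minutes before onset);
* trajectory summaries — across-seizure means with 95% CIs and per-time
  one-sample significance flags (a display statistic, uncorrected);
* long/short contrasts — per-time Welch tests between duration clusters;
* duration correlations — Pearson correlation between duration and the
  channel-averaged parameter mean over the 5-s window before onset or offset,
  Bonferroni-corrected over patients x parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .adf import TrajectoryEstimate
from .model import N_THETA, THETA_LABELS

__all__ = [
    "DurationCatalog", "ClusterResult", "NormalizedTrajectory",
    "TrajectorySummary", "CorrelationResult", "bonferroni_divisor",
    "cluster_durations", "baseline_normalize", "summarize_trajectories",
    "compare_long_short", "correlate_duration", "window_theta_means",
]

MIN_SEIZURES = 20


def bonferroni_divisor(n_patients: int, n_params: int = N_THETA) -> int:
    """Multiple-comparison divisor for the duration-correlation analysis.

    One test per patient per connectivity parameter, so the 0.05 level is
    divided by ``n_patients * n_params`` (60 for a 12-patient, 5-parameter
    cohort).
    """
    if n_patients < 1 or n_params < 1:
        raise ValueError("counts must be positive")
    return int(n_patients) * int(n_params)


@dataclass
class DurationCatalog:
    """Per-patient seizure durations in seconds."""

    patient_id: str
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float).ravel()
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")

    @property
    def log_durations(self) -> np.ndarray:
        return np.log(self.durations)

    @property
    def n(self) -> int:
        return self.durations.size


@dataclass
class ClusterResult:
    """Cluster-number selection on log durations."""

    optimal_k: int                      # gap choice on the k-means path
    optimal_k_gmm: int                  # gap choice on the mixture path
    assignments: np.ndarray             # k-means labels at optimal_k (0 = short)
    gap_values: dict[int, float]        # k-means path gap per k
    gap_se: dict[int, float]
    method_agreement: bool
    long_short_boundary: float | None   # seconds, defined when optimal_k == 2


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lbl in np.unique(labels):
        pts = x[labels == lbl]
        w += float(np.sum((pts - pts.mean()) ** 2))
    return w


def _fit_labels(x: np.ndarray, k: int, method: str, seed: int) -> np.ndarray:
    if k == 1:
        return np.zeros(x.size, dtype=int)
    X = x.reshape(-1, 1)
    if method == "kmeans":
        return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    return GaussianMixture(n_components=k, n_init=3,
                           random_state=seed).fit(X).predict(X)


def _gap_curve(x: np.ndarray, method: str, seed: int, ks=(1, 2, 3),
               n_ref: int = 100):
    """Gap statistic per k with a uniform reference over the observed range."""
    rng = np.random.default_rng(seed)
    lo, hi = float(x.min()), float(x.max())
    log_w = {}
    for k in ks:
        labels = _fit_labels(x, k, method, seed)
        log_w[k] = np.log(max(_within_dispersion(x, labels), 1e-300))
    gaps, ses = {}, {}
    ref_log_w = {k: np.empty(n_ref) for k in ks}
    for b in range(n_ref):
        xb = rng.uniform(lo, hi, x.size)
        for k in ks:
            labels = _fit_labels(xb, k, method, seed)
            ref_log_w[k][b] = np.log(max(_within_dispersion(xb, labels), 1e-300))
    for k in ks:
        gaps[k] = float(ref_log_w[k].mean() - log_w[k])
        ses[k] = float(ref_log_w[k].std(ddof=1) * np.sqrt(1.0 + 1.0 / n_ref))
    return gaps, ses


def _select_k(gaps: dict[int, float], ses: dict[int, float], ks=(1, 2, 3)) -> int:
    """First-max rule with the one-standard-error tolerance."""
    for k in ks[:-1]:
        if gaps[k] >= gaps[k + 1] - ses[k + 1]:
            return k
    return ks[-1]


def cluster_durations(cat: DurationCatalog, seed: int = 0,
                      n_ref: int = 100,
                      min_seizures: int = MIN_SEIZURES) -> ClusterResult:
    """Test a patient's log durations for one, two or three populations.

    Runs both k-means and Gaussian-mixture clustering for k = 1..3 and picks
    k per method by the gap statistic (uniform reference over the observed
    log-duration range, ``n_ref`` reference draws, first-max selection with a
    one-SE tolerance).  The long/short boundary, defined when k = 2, is the
    midpoint of the two cluster means on the log scale, reported in seconds.
    """
    if cat.n < min_seizures:
        raise ValueError(
            f"patient excluded: fewer than {min_seizures} seizures (n={cat.n})")
    x = cat.log_durations
    if np.ptp(x) == 0:
        return ClusterResult(optimal_k=1, optimal_k_gmm=1,
                             assignments=np.zeros(cat.n, dtype=int),
                             gap_values={1: 0.0}, gap_se={1: 0.0},
                             method_agreement=True, long_short_boundary=None)
    gaps_km, ses_km = _gap_curve(x, "kmeans", seed, n_ref=n_ref)
    gaps_gm, ses_gm = _gap_curve(x, "gmm", seed + 1, n_ref=n_ref)
    k_km = _select_k(gaps_km, ses_km)
    k_gm = _select_k(gaps_gm, ses_gm)

    labels = _fit_labels(x, max(k_km, 1), "kmeans", seed)
    boundary = None
    if k_km == 2:
        means = np.array([x[labels == l].mean() for l in (0, 1)])
        # relabel so 0 = short
        if means[0] > means[1]:
            labels = 1 - labels
            means = means[::-1]
        boundary = float(np.exp(means.mean()))
    return ClusterResult(optimal_k=k_km, optimal_k_gmm=k_gm,
                         assignments=labels, gap_values=gaps_km, gap_se=ses_km,
                         method_agreement=bool(k_km == k_gm),
                         long_short_boundary=boundary)


@dataclass
class NormalizedTrajectory:
    """Percent change of each parameter from its pre-ictal baseline mean.

    A value of 0 means no change from baseline; for negative baselines the
    change is divided by |baseline| so the direction is preserved.
    """

    time: np.ndarray                    # seconds relative to onset
    percent: np.ndarray                 # (T, 5)
    usable: np.ndarray                  # (5,) bool, False if |baseline| ~ 0
    duration: float                     # seizure duration, seconds
    seizure_id: str | None = None
    channel: int | str | None = None
    baseline_window: tuple[float, float] = (-120.0, -60.0)


def baseline_normalize(est: TrajectoryEstimate, duration: float,
                       baseline_window: tuple[float, float] = (-120.0, -60.0),
                       eps: float = 1e-12) -> NormalizedTrajectory:
    """Express a parameter trajectory as percent change from baseline.

    The baseline is the mean over ``baseline_window`` (seconds relative to
    onset).  percent = 100 (theta(t) - baseline) / |baseline|.
    """
    if not est.valid:
        raise ValueError("estimate is invalid (filter instability)")
    mask = (est.time >= baseline_window[0]) & (est.time < baseline_window[1])
    if not np.any(mask):
        raise ValueError("estimate does not cover the baseline window")
    theta = est.theta
    base = theta[mask].mean(axis=0)
    usable = np.abs(base) > eps
    denom = np.where(usable, np.abs(base), 1.0)
    percent = 100.0 * (theta - base) / denom
    return NormalizedTrajectory(time=est.time, percent=percent, usable=usable,
                                duration=float(duration),
                                seizure_id=est.seizure_id, channel=est.channel,
                                baseline_window=baseline_window)


@dataclass
class TrajectorySummary:
    """Across-seizure mean trajectory with CIs and per-time significance."""

    time: np.ndarray                    # common grid, seconds rel. onset
    mean: np.ndarray                    # (T, 5) mean percent change
    ci_halfwidth: np.ndarray            # (T, 5) 1.96 SE
    p_value: np.ndarray                 # (T, 5) one-sample t vs 0
    flag: np.ndarray                    # (T, 5) int: +1 increase, -1 decrease, 0 ns
    n: np.ndarray                       # (T,) seizures contributing per time
    minmax: np.ndarray | None = None    # (T, 5) min-max normalized to [-1, 1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, lbl in enumerate(THETA_LABELS):
            rows.append(pd.DataFrame({
                "time_s": self.time, "parameter": lbl,
                "mean_pct": self.mean[:, j],
                "ci95_halfwidth": self.ci_halfwidth[:, j],
                "p_value": self.p_value[:, j], "flag": self.flag[:, j],
                "n": self.n}))
        return pd.concat(rows, ignore_index=True)


def _resample(norm: NormalizedTrajectory, grid: np.ndarray,
              align: str = "onset") -> np.ndarray:
    """Sample the trajectory on the grid; NaN where the grid leaves its span
    or (past onset) exceeds the seizure's own duration.

    With ``align="offset"`` the grid is in seconds relative to seizure offset
    and samples before the seizure's own onset are excluded.
    """
    out = np.full((grid.size, N_THETA), np.nan)
    t = norm.time if align == "onset" else norm.time - norm.duration
    if align == "onset":
        within = (grid >= t[0]) & (grid <= t[-1]) & ~(grid > norm.duration)
    else:
        within = (grid >= t[0]) & (grid <= t[-1]) & ~(grid < -norm.duration)
    for j in range(N_THETA):
        out[within, j] = np.interp(grid[within], t, norm.percent[:, j])
    return out


def summarize_trajectories(norms, align: str = "onset", t_start: float = -30.0,
                           t_stop: float | None = None, dt: float = 0.25,
                           alpha: float = 0.05,
                           with_minmax: bool = False) -> TrajectorySummary:
    """Average normalized trajectories over seizures on a common time grid.

    With onset alignment (the default), time runs relative to seizure onset
    and, at each time past onset, only seizures still ongoing (duration >= t)
    contribute — the summary never mixes ictal and post-ictal samples.  With
    ``align="offset"``, time runs relative to seizure offset (termination
    epochs line up) and only samples after each seizure's own onset
    contribute.  Per-time two-sided one-sample t-tests against 0 flag
    significant increases (+1) and decreases (-1); this matches a per-time
    display convention and applies no multiplicity correction.
    """
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    norms = list(norms)
    if not norms:
        raise ValueError("no trajectories to summarize")
    if t_stop is None:
        t_stop = max(n.duration for n in norms) if align == "onset" else 0.0
    grid = np.arange(t_start, t_stop + 1e-9, dt)
    stack = np.stack([_resample(n, grid, align) for n in norms])  # (S, T, 5)
    n_t = np.sum(~np.isnan(stack[:, :, 0]), axis=0)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    se = sd / np.sqrt(np.maximum(n_t, 1))[:, None]
    ci = 1.96 * se
    p = np.ones_like(mean)
    tt = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
    for j in range(N_THETA):
        dfree = np.maximum(n_t - 1, 1)
        p[:, j] = 2.0 * sps.t.sf(np.abs(tt[:, j]), dfree)
    degenerate = (se == 0) & (np.abs(mean) > 0) & (n_t[:, None] >= 2)
    p[degenerate] = 0.0          # identical nonzero values: trivially significant
    p[n_t < 2] = 1.0
    flag = np.zeros_like(mean, dtype=int)
    flag[(p < alpha) & (mean > 0)] = 1
    flag[(p < alpha) & (mean < 0)] = -1
    minmax = None
    if with_minmax:
        lo = np.nanmin(stack, axis=(0, 1))
        hi = np.nanmax(stack, axis=(0, 1))
        half = np.maximum(np.maximum(np.abs(lo), np.abs(hi)), 1e-300)
        minmax = mean / half
    return TrajectorySummary(time=grid, mean=mean, ci_halfwidth=ci, p_value=p,
                             flag=flag, n=n_t, minmax=minmax)


def compare_long_short(norms, split: ClusterResult, t_start: float = -30.0,
                       t_stop: float | None = None, dt: float = 0.25,
                       alpha: float = 0.05):
    """Per-time Welch tests between long- and short-cluster trajectories.

    Returns a DataFrame keyed by time and parameter with the group means,
    the two-sample p-value, a significance flag (uncorrected per-time
    display convention), and the overall-average contrast per parameter.
    """
    if split.optimal_k != 2:
        raise ValueError("long/short contrast needs optimal_k == 2")
    norms = list(norms)
    labels = np.asarray(split.assignments)
    if len(norms) != labels.size:
        raise ValueError("assignments must align with trajectories")
    short = [n for n, l in zip(norms, labels) if l == 0]
    long_ = [n for n, l in zip(norms, labels) if l == 1]
    if len(short) < 2 or len(long_) < 2:
        raise ValueError("each duration group needs at least 2 seizures")
    if t_stop is None:
        t_stop = max(n.duration for n in norms)
    grid = np.arange(t_start, t_stop + 1e-9, dt)
    s_stack = np.stack([_resample(n, grid) for n in short])
    l_stack = np.stack([_resample(n, grid) for n in long_])
    rows = []
    for j, lbl in enumerate(THETA_LABELS):
        for i, t in enumerate(grid):
            a = s_stack[:, i, j]
            b = l_stack[:, i, j]
            a = a[~np.isnan(a)]
            b = b[~np.isnan(b)]
            if a.size < 2 or b.size < 2:
                p = np.nan
            elif np.array_equal(np.sort(a), np.sort(b)):
                p = 1.0
            elif a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                p = 0.0 if a.mean() != b.mean() else 1.0
            else:
                p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
            rows.append({"time_s": t, "parameter": lbl,
                         "mean_short": a.mean() if a.size else np.nan,
                         "mean_long": b.mean() if b.size else np.nan,
                         "p_value": p,
                         "significant": bool(p < alpha) if np.isfinite(p) else False})
    df = pd.DataFrame(rows)
    overall = (df.groupby("parameter", sort=False)
               .apply(lambda g: g.mean_long.mean() - g.mean_short.mean(),
                      include_groups=False)
               .rename("overall_mean_difference").reset_index())
    return df, overall


def window_theta_means(est: TrajectoryEstimate, duration: float,
                       window: str = "onset", window_s: float = 5.0) -> np.ndarray:
    """Mean raw parameter estimates over the 5-s window before onset or offset."""
    if window == "onset":
        mask = (est.time >= -window_s) & (est.time < 0.0)
    elif window == "offset":
        mask = (est.time >= duration - window_s) & (est.time < duration)
    else:
        raise ValueError("window must be 'onset' or 'offset'")
    if not np.any(mask):
        raise ValueError(f"estimate does not cover the pre-{window} window")
    return est.theta[mask].mean(axis=0)


@dataclass
class CorrelationResult:
    """Duration-connectivity correlations for one patient and window."""

    window: str                          # "onset" or "offset"
    table: pd.DataFrame                  # parameter, r, p, significant, computable
    bonferroni_m: int
    alpha: float = 0.05


def correlate_duration(estimates, durations, window: str = "onset",
                       bonferroni_m: int = N_THETA, alpha: float = 0.05,
                       per_channel: bool = False) -> CorrelationResult:
    """Correlate seizure duration with pre-onset/pre-offset connectivity.

    ``estimates`` maps seizure_id -> list of per-channel TrajectoryEstimate;
    ``durations`` maps seizure_id -> duration (s).  For each parameter, the
    mean estimate over the 5-s window (averaged across channels) is Pearson-
    correlated against duration; significance applies the Bonferroni divisor.
    With ``per_channel`` the table carries one row per channel and parameter.
    """
    sids = sorted(set(estimates) & set(durations))
    if len(sids) < 3:
        raise ValueError("need at least 3 seizures with estimates")
    dur = np.array([durations[s] for s in sids])

    def corr_rows(values: np.ndarray, channel=None):
        rows = []
        for j, lbl in enumerate(THETA_LABELS):
            v = values[:, j]
            if np.ptp(v) == 0 or np.ptp(dur) == 0:
                rows.append({"parameter": lbl, "channel": channel,
                             "r": np.nan, "p": np.nan, "significant": False,
                             "computable": False})
                continue
            r, p = sps.pearsonr(v, dur)
            rows.append({"parameter": lbl, "channel": channel,
                         "r": float(r), "p": float(p),
                         "significant": bool(p < alpha / bonferroni_m),
                         "computable": True})
        return rows

    rows = []
    if per_channel:
        channels = sorted({e.channel for s in sids for e in estimates[s]},
                          key=str)
        for ch in channels:
            vals = np.stack([
                np.mean([window_theta_means(e, durations[s], window)
                         for e in estimates[s] if e.channel == ch], axis=0)
                for s in sids])
            rows += corr_rows(vals, channel=ch)
    else:
        vals = np.stack([
            np.mean([window_theta_means(e, durations[s], window)
                     for e in estimates[s]], axis=0)
            for s in sids])
        rows += corr_rows(vals)
    table = pd.DataFrame(rows)
    if not per_channel:
        table = table.drop(columns=["channel"])
    return CorrelationResult(window=window, table=table,
                             bonferroni_m=bonferroni_m, alpha=alpha)
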