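"""Per-bin significance tests and effect-onset (latency) measures.

An effect latency is the earliest time bin at which looks show a reliable
preference.  Four measures are implemented, all built on a per-bin test of
"probability of target looks above chance":

``consecutive``
    start of the first run of ``k`` consecutive significant bins.
``consecutive_threshold``
    as above, but every bin of the run must also exceed a minimal effect
    size (default 0.2 log-odds, i.e. about 55% target looks).
``holm``
    first bin significant after Holm-Bonferroni step-down correction over
    all bins in the window (with a positive estimate).
``holm_threshold``
    as ``holm`` plus the effect-size threshold.

Two per-bin tests are available.  For trial-level binarized data the test
is an intercept-only logistic regression pooled over all trials of the
group in the bin; with ``s`` successes out of ``n`` this fit has the closed
form ``b = log(p/(1-p))``, Wald ``SE = 1/sqrt(n p (1-p))``, so no iterative
fitting is needed.  Complete separation (``s`` = 0 or ``n``) collapses the
Wald test, so those bins fall back to an exact binomial test against 0.5.
For participant-averaged proportion data (e.g. shared word-recognition
datasets) the test is a one-sample t-test of the relative proportion
competitor / (competitor + unrelated) against 0.5, with a raw
proportion-difference threshold (default 0.03).

When no bin qualifies, the latency is *censored* at the end of the window
rather than dropped, which keeps resampling distributions at fixed length;
the censored fraction is carried along as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .data_model import BinnedCounts, BinningConfig, ConfigError, ParticipantProportions

MEASURES = ("consecutive", "consecutive_threshold", "holm", "holm_threshold")

@dataclass(frozen=True)
class LatencyConfig:
    """Parameters of the latency measures.

    ``logodds_threshold`` applies to the pooled logistic test (0.2 log-odds
    is ~55% target probability); ``prop_diff_threshold`` applies to the
    relative-proportion t-test (raw competitor-minus-unrelated difference).
    """

    measure: str = "consecutive_threshold"
    k_consecutive: int = 5
    alpha: float = 0.05
    logodds_threshold: float = 0.2
    prop_diff_threshold: float = 0.03
    bin_test: str = "pooled_logistic"

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ConfigError(f"measure must be one of {MEASURES}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")
        if self.k_consecutive < 1:
            raise ConfigError("k_consecutive must be >= 1")
        if self.logodds_threshold < 0 or self.prop_diff_threshold < 0:
            raise ConfigError("effect-size thresholds must be >= 0")
        if self.bin_test not in ("pooled_logistic", "relative_proportion_ttest"):
            raise ConfigError("unknown bin_test")

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "k_consecutive": self.k_consecutive,
            "alpha": self.alpha,
            "logodds_threshold": self.logodds_threshold,
            "prop_diff_threshold": self.prop_diff_threshold,
            "bin_test": self.bin_test,
        }

    @classmethod
    def from_dict(cls, d) -> "LatencyConfig":
        return cls(**dict(d))


@dataclass
class BinTestResult:
    bin_index: int
    estimate: float
    n_obs: int
    p_value: float
    significant_positive: bool
    exceeds_threshold: bool
    flag: str | None = None


@dataclass
class LatencyEstimate:
    group: str | None
    measure: str
    latency_ms: float
    censored: bool
    source_bin_index: int | None


@dataclass
class LatencyDifference:
    """Shifted-minus-baseline latency difference with censoring provenance."""

    difference_ms: float
    censored: bool
    shifted: LatencyEstimate | None = None
    baseline: LatencyEstimate | None = None

    def __float__(self) -> float:
        return float(self.difference_ms)


@dataclass
class BinTests:
    """Vectorized per-bin test results over the whole window."""

    estimate: np.ndarray
    p_value: np.ndarray
    n_obs: np.ndarray
    significant_positive: np.ndarray
    exceeds_threshold: np.ndarray
    positive: np.ndarray


# ---------------------------------------------------------------------------
# Per-bin tests
# ---------------------------------------------------------------------------

def wald_logistic_tests(
    s, n, alpha: float = 0.05, logodds_threshold: float = 0.2
) -> BinTests:
    """Closed-form pooled logistic test for arrays of per-bin counts.

    Wald z on the intercept for interior counts; exact binomial two-sided
    p (= min(1, 2 * 0.5**n) at p0 = 0.5) under complete separation, with
    the estimate reported as +/-inf as a sign carrier.  Bins with no data
    get p = 1 and no flags set.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    est = np.full(s.shape, np.nan)
    p = np.ones(s.shape)
    pos = np.zeros(s.shape, dtype=bool)
    exc = np.zeros(s.shape, dtype=bool)
    has = n > 0
    interior = has & (s > 0) & (s < n)
    if interior.any():
        ph = s[interior] / n[interior]
        b = np.log(ph / (1.0 - ph))
        se = 1.0 / np.sqrt(n[interior] * ph * (1.0 - ph))
        z = np.abs(b / se)
        p[interior] = special.erfc(z / np.sqrt(2.0))  # two-sided normal tail
        est[interior] = b
        pos[interior] = b > 0
        exc[interior] = b > logodds_threshold
    all1 = has & (s == n)
    all0 = has & (s == 0)
    sep = all1 | all0
    if sep.any():
        p[sep] = np.minimum(1.0, 2.0 * 0.5 ** n[sep])
        est[all1] = np.inf
        est[all0] = -np.inf
        pos[all1] = True
        exc[all1] = True
    sig = (p < alpha) & pos
    return BinTests(
        estimate=est, p_value=p, n_obs=n, significant_positive=sig,
        exceeds_threshold=exc, positive=pos,
    )


def pooled_logistic_bin_test(
    values, alpha: float = 0.05, logodds_threshold: float = 0.2, bin_index: int = 0
) -> BinTestResult:
    """Intercept-only pooled logistic test of one group x bin of binary values."""
    values = np.asarray(values, dtype=float)
    n = int(values.size)
    if n == 0:
        return BinTestResult(
            bin_index=bin_index, estimate=float("nan"), n_obs=0, p_value=1.0,
            significant_positive=False, exceeds_threshold=False, flag="no_data",
        )
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("values must be binary 0/1")
    s = float(values.sum())
    t = wald_logistic_tests(s, n, alpha=alpha, logodds_threshold=logodds_threshold)
    flag = "separation" if s in (0.0, float(n)) else None
    return BinTestResult(
        bin_index=bin_index,
        estimate=float(t.estimate[0]),
        n_obs=n,
        p_value=float(t.p_value[0]),
        significant_positive=bool(t.significant_positive[0]),
        exceeds_threshold=bool(t.exceeds_threshold[0]),
        flag=flag,
    )


def relative_proportion_tests(
    competitor: np.ndarray,
    unrelated: np.ndarray,
    alpha: float = 0.05,
    prop_diff_threshold: float = 0.03,
) -> BinTests:
    """Per-bin one-sample t-tests of relative competitor proportion vs 0.5.

    ``competitor`` and ``unrelated`` are (participants x bins) arrays; NaN
    marks missing participant-bin cells.  Cells where both proportions are
    zero have an undefined relative proportion and are excluded from that
    bin's test.  Zero-variance bins are degenerate and never significant.
    """
    comp = np.asarray(competitor, dtype=float)
    unrel = np.asarray(unrelated, dtype=float)
    denom = comp + unrel
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(denom > 0, comp / np.where(denom > 0, denom, 1.0), np.nan)
    count = np.sum(~np.isnan(rel), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(rel), np.nan, rel), axis=0) if rel.size else np.full(rel.shape[1], np.nan)
    sd = np.full(rel.shape[1], np.nan)
    ok = count >= 2
    if ok.any():
        sd[ok] = np.sqrt(np.nansum((rel[:, ok] - mean[ok]) ** 2, axis=0) / (count[ok] - 1.0))
    p = np.ones(rel.shape[1])
    tstat = np.zeros(rel.shape[1])
    valid = ok & (sd > 1e-12)  # numerically zero variance counts as degenerate
    if valid.any():
        tstat[valid] = (mean[valid] - 0.5) / (sd[valid] / np.sqrt(count[valid]))
        p[valid] = 2.0 * stats.t.sf(np.abs(tstat[valid]), count[valid] - 1.0)
    diff = np.nanmean(np.where(np.isnan(comp) | np.isnan(unrel), np.nan, comp - unrel), axis=0)
    pos = np.nan_to_num(mean, nan=0.0) > 0.5
    sig = (p < alpha) & pos
    exc = np.nan_to_num(diff, nan=-np.inf) > prop_diff_threshold
    return BinTests(
        estimate=mean, p_value=p, n_obs=count, significant_positive=sig,
        exceeds_threshold=exc, positive=pos,
    )


def relative_proportion_bin_test(
    p_competitor,
    p_unrelated,
    alpha: float = 0.05,
    prop_diff_threshold: float = 0.03,
    bin_index: int = 0,
) -> BinTestResult:
    """t-test of per-participant relative competitor proportions for one bin."""
    comp = np.asarray(p_competitor, dtype=float).reshape(-1, 1)
    unrel = np.asarray(p_unrelated, dtype=float).reshape(-1, 1)
    t = relative_proportion_tests(
        comp, unrel, alpha=alpha, prop_diff_threshold=prop_diff_threshold
    )
    n = int(t.n_obs[0])
    flag = None
    if n < 2:
        flag = "insufficient_data"
    elif t.p_value[0] == 1.0 and not np.isclose(t.estimate[0], 0.5):
        flag = "degenerate"
    return BinTestResult(
        bin_index=bin_index,
        estimate=float(t.estimate[0]),
        n_obs=n,
        p_value=float(t.p_value[0]),
        significant_positive=bool(t.significant_positive[0]),
        exceeds_threshold=bool(t.exceeds_threshold[0]),
        flag=flag,
    )


# ---------------------------------------------------------------------------
# Multiple-comparison correction
# ---------------------------------------------------------------------------

def holm_correct(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm-Bonferroni step-down rejection flags over one family of bins.

    Sorts ascending (stable, so ties break by bin order), rejects while
    ``p_(i) <= alpha / (m - i + 1)`` and stops at the first failure.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresh = alpha / (m - np.arange(m))
    ok = p[order] <= thresh
    k = int(np.argmin(ok)) if not ok.all() else m
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone non-decreasing in rank)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate(np.minimum(1.0, (m - np.arange(m)) * p[order]))
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Latency measures
# ---------------------------------------------------------------------------

def _first_run(flags: np.ndarray, k: int) -> int:
    """Index of the first run of k consecutive True values, or -1."""
    f = np.asarray(flags, dtype=bool)
    if k < 1:
        raise ConfigError("k must be >= 1")
    if f.size < k:
        return -1
    w = np.convolve(f.astype(np.int32), np.ones(k, dtype=np.int32), mode="valid")
    hits = np.nonzero(w == k)[0]
    return int(hits[0]) if hits.size else -1


def measure_onset_indices(tests: BinTests, cfg: LatencyConfig) -> dict:
    """First qualifying bin index per measure (-1 when censored)."""
    sig = tests.significant_positive
    exc = tests.exceeds_threshold
    k = cfg.k_consecutive
    rej = holm_correct(tests.p_value, cfg.alpha) & tests.positive
    first = lambda flags: int(np.argmax(flags)) if flags.any() else -1
    return {
        "consecutive": _first_run(sig, k),
        "consecutive_threshold": _first_run(sig & exc, k),
        "holm": first(rej),
        "holm_threshold": first(rej & exc),
    }


def estimate_latency(
    bin_results: Sequence[BinTestResult],
    cfg: LatencyConfig,
    binning: BinningConfig,
    group: str | None = None,
) -> LatencyEstimate:
    """Onset latency under ``cfg.measure`` from ordered per-bin results.

    Bins missing from ``bin_results`` are treated as not significant.  If no
    bin qualifies the estimate is censored at the end of the window.
    """
    m = binning.n_bins
    est = np.full(m, np.nan)
    p = np.ones(m)
    n = np.zeros(m)
    sig = np.zeros(m, dtype=bool)
    exc = np.zeros(m, dtype=bool)
    pos = np.zeros(m, dtype=bool)
    for r in bin_results:
        i = r.bin_index
        if not (0 <= i < m):
            raise ValueError(f"bin index {i} outside 0..{m - 1}")
        est[i], p[i], n[i] = r.estimate, r.p_value, r.n_obs
        sig[i], exc[i] = r.significant_positive, r.exceeds_threshold
        null_value = 0.5 if cfg.bin_test == "relative_proportion_ttest" else 0.0
        pos[i] = bool(r.estimate > null_value)  # NaN compares False
    tests = BinTests(estimate=est, p_value=p, n_obs=n, significant_positive=sig,
                     exceeds_threshold=exc, positive=pos)
    idx = measure_onset_indices(tests, cfg)[cfg.measure]
    if idx < 0:
        return LatencyEstimate(group=group, measure=cfg.measure,
                               latency_ms=binning.end_ms, censored=True,
                               source_bin_index=None)
    return LatencyEstimate(group=group, measure=cfg.measure,
                           latency_ms=binning.bin_start(idx), censored=False,
                           source_bin_index=idx)


def latency_difference(shifted: LatencyEstimate, baseline: LatencyEstimate) -> LatencyDifference:
    """Shifted minus baseline latency; censored operands enter at window end."""
    if shifted.measure != baseline.measure:
        raise ValueError("latency measures differ between groups")
    return LatencyDifference(
        difference_ms=shifted.latency_ms - baseline.latency_ms,
        censored=shifted.censored or baseline.censored,
        shifted=shifted,
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
# The latency-difference statistic used by resampling and simulation
# ---------------------------------------------------------------------------

class LatencyDifferenceStatistic:
    """Maps a two-group dataset to latency difference(s) between the groups.

    Calling the statistic returns the scalar difference under
    ``cfg.measure``; :meth:`evaluate` returns the differences under all four
    measures at once together with censoring flags, which lets resampling
    code obtain every measure from a single pass over the bins.
    """

    measures = MEASURES

    def __init__(
        self,
        latency_cfg: LatencyConfig,
        binning: BinningConfig,
        baseline: str = "baseline",
        shifted: str = "shifted",
    ):
        self.cfg = latency_cfg
        self.binning = binning
        self.baseline = baseline
        self.shifted = shifted

    # -- per-group machinery -------------------------------------------

    def bin_tests(self, data, group) -> BinTests:
        if isinstance(data, BinnedCounts):
            if self.cfg.bin_test != "pooled_logistic":
                raise ConfigError("binned count data require the pooled_logistic bin test")
            s, n = data.pooled(group)
            return wald_logistic_tests(
                s, n, alpha=self.cfg.alpha, logodds_threshold=self.cfg.logodds_threshold
            )
        if isinstance(data, ParticipantProportions):
            gp = data.groups[group]
            return relative_proportion_tests(
                gp.competitor, gp.unrelated,
                alpha=self.cfg.alpha, prop_diff_threshold=self.cfg.prop_diff_threshold,
            )
        raise TypeError(f"unsupported data container {type(data).__name__}")

    def onset_indices(self, data, group) -> dict:
        return measure_onset_indices(self.bin_tests(data, group), self.cfg)

    def group_estimates(self, data) -> dict:
        """Per-group LatencyEstimate for every measure."""
        out = {}
        for g in data.groups:
            idx = self.onset_indices(data, g)
            out[g] = {
                meas: (
                    LatencyEstimate(g, meas, self.binning.bin_start(i), False, i)
                    if i >= 0
                    else LatencyEstimate(g, meas, self.binning.end_ms, True, None)
                )
                for meas, i in idx.items()
            }
        return out

    # -- statistic protocol --------------------------------------------

    def evaluate(self, data) -> tuple[np.ndarray, np.ndarray]:
        """(differences over MEASURES, censored flags over MEASURES)."""
        idx_s = self.onset_indices(data, self.shifted)
        idx_b = self.onset_indices(data, self.baseline)
        vals = np.empty(len(self.measures))
        cens = np.zeros(len(self.measures), dtype=bool)
        end = self.binning.end_ms
        for j, meas in enumerate(self.measures):
            a, b = idx_s[meas], idx_b[meas]
            la = self.binning.bin_start(a) if a >= 0 else end
            lb = self.binning.bin_start(b) if b >= 0 else end
            vals[j] = la - lb
            cens[j] = (a < 0) or (b < 0)
        return vals, cens

    def __call__(self, data) -> float:
        vals, _ = self.evaluate(data)
        return float(vals[self.measures.index(self.cfg.measure)])
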