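"""Participant-level resampling: bootstrap, permutation, and interval methods.

Two bootstrap schemes are provided.  The *by-participant* bootstrap redraws
whole participants with replacement within each group (preserving all
within-participant dependencies and propagating between-participant
variability into the bootstrap distribution).  The *stratified* bootstrap
keeps every participant and redraws trial-level values with replacement
within each participant x time-bin stratum, which breaks within-trial
autocorrelation and understates between-participant variability -- it is
included so that its anti-conservative behaviour can be measured.

The permutation test reassigns whole participants to groups (all of a
participant's data move together), building the null distribution of the
latency difference; the p-value is the plain proportion of null values at
least as extreme in absolute value as the observed difference.

Five bootstrap confidence-interval constructions are implemented:
percentile, normal (bias-corrected normal approximation), empirical (a.k.a.
basic / backwards percentile), bias-corrected (BC), and accelerated
bias-corrected (BCa, with leave-one-participant-out jackknife
acceleration).  Wilson score intervals summarise Monte Carlo proportion
estimates such as power and Type I error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .data_model import ConfigError

CI_METHODS = ("percentile", "normal", "empirical", "bc", "bca")
BOOTSTRAP_SCHEMES = ("by_participant", "stratified")


@dataclass(frozen=True)
class ResamplingConfig:
    n_bootstrap: int = 2000
    n_permutation: int = 1000
    ci_level: float = 0.95
    ci_methods: tuple[str, ...] = CI_METHODS
    bootstrap_schemes: tuple[str, ...] = ("by_participant",)
    stratify_by_condition: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.n_bootstrap < 1 or self.n_permutation < 1:
            raise ConfigError("n_bootstrap and n_permutation must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigError("ci_level must be in (0, 1)")
        bad = set(self.ci_methods) - set(CI_METHODS)
        if bad:
            raise ConfigError(f"unknown CI method(s) {sorted(bad)}")
        bad = set(self.bootstrap_schemes) - set(BOOTSTRAP_SCHEMES)
        if bad:
            raise ConfigError(f"unknown bootstrap scheme(s) {sorted(bad)}")

    def to_dict(self) -> dict:
        return {
            "n_bootstrap": self.n_bootstrap,
            "n_permutation": self.n_permutation,
            "ci_level": self.ci_level,
            "ci_methods": list(self.ci_methods),
            "bootstrap_schemes": list(self.bootstrap_schemes),
            "stratify_by_condition": self.stratify_by_condition,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d) -> "ResamplingConfig":
        d = dict(d)
        for key in ("ci_methods", "bootstrap_schemes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ResampleDistribution:
    """B (or P) resampled statistic values with provenance.

    ``values`` has shape (B,) for scalar statistics or (B, K) when the
    statistic reports several measures at once.
    """

    values: np.ndarray
    kind: str  # "bootstrap" | "permutation_null"
    observed: np.ndarray | float | None = None
    censored_fraction: float | np.ndarray | None = None
    scheme: str | None = None


@dataclass
class PermutationResult:
    distribution: ResampleDistribution
    p_value: np.ndarray | float
    observed: np.ndarray | float


@dataclass
class IntervalResult:
    method: str
    lower_ms: float
    upper_ms: float
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# statistic evaluation helpers
# ---------------------------------------------------------------------------

def _evaluate(statistic, data):
    """Returns (values array, censored flags or None) for one dataset."""
    if hasattr(statistic, "evaluate"):
        vals, cens = statistic.evaluate(data)
        return np.atleast_1d(np.asarray(vals, dtype=float)), np.atleast_1d(cens)
    return np.atleast_1d(np.asarray(statistic(data), dtype=float)), None


def _collect(rows, cens_rows):
    values = np.vstack(rows)
    if values.shape[1] == 1:
        values = values[:, 0]
    censored = None
    if cens_rows and cens_rows[0] is not None:
        cmat = np.vstack(cens_rows)
        censored = cmat.mean(axis=0)
        if censored.size == 1:
            censored = float(censored[0])
    return values, censored


def _draw_group_indices(rng, n, conditions, stratify):
    if not stratify:
        return rng.integers(0, n, size=n)
    idx = np.empty(n, dtype=int)
    pos = 0
    for c in dict.fromkeys(conditions):  # preserves first-seen order
        members = np.nonzero(conditions == c)[0]
        draw = members[rng.integers(0, len(members), size=len(members))]
        idx[pos : pos + len(members)] = draw
        pos += len(members)
    return idx


# ---------------------------------------------------------------------------
# Resampling procedures
# ---------------------------------------------------------------------------

def bootstrap_by_participant(
    data, cfg: ResamplingConfig, statistic, rng: np.random.Generator | None = None
) -> ResampleDistribution:
    """By-participant bootstrap distribution of ``statistic``.

    Each of ``cfg.n_bootstrap`` resamples draws n participants per group
    with replacement (within condition strata when
    ``cfg.stratify_by_condition``); all of a drawn participant's records
    are included, and clones weight pooled counts once per draw.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    for g in data.groups:
        if data.n_participants(g) == 0:
            raise ConfigError(f"group {g!r} has no participants")
    rows, cens_rows = [], []
    for _ in range(cfg.n_bootstrap):
        indices = {
            g: _draw_group_indices(
                rng,
                data.n_participants(g),
                data.groups[g].conditions,
                cfg.stratify_by_condition,
            )
            for g in data.groups
        }
        vals, cens = _evaluate(statistic, data.take(indices))
        rows.append(vals)
        cens_rows.append(cens)
    values, censored = _collect(rows, cens_rows)
    return ResampleDistribution(
        values=values, kind="bootstrap", censored_fraction=censored, scheme="by_participant"
    )


def bootstrap_stratified(
    data, cfg: ResamplingConfig, statistic, rng: np.random.Generator | None = None
) -> ResampleDistribution:
    """Stratified bootstrap: resample trial values within participant x bin.

    Every resample keeps the full participant roster; per-stratum record
    counts are preserved exactly.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if not hasattr(data, "resample_within_strata"):
        raise ConfigError("stratified bootstrap requires trial-level binned count data")
    rows, cens_rows = [], []
    for _ in range(cfg.n_bootstrap):
        vals, cens = _evaluate(statistic, data.resample_within_strata(rng))
        rows.append(vals)
        cens_rows.append(cens)
    values, censored = _collect(rows, cens_rows)
    return ResampleDistribution(
        values=values, kind="bootstrap", censored_fraction=censored, scheme="stratified"
    )


def permutation_test(
    data, cfg: ResamplingConfig, statistic, rng: np.random.Generator | None = None
) -> PermutationResult:
    """Participant-label permutation test of the group difference.

    ``p = #{|null| >= |observed|} / P`` exactly (the observed value is not
    added to the null set), so p lies on the grid {0, 1/P, ..., 1}.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    observed, obs_cens = _evaluate(statistic, data)
    rows, cens_rows = [], []
    for _ in range(cfg.n_permutation):
        permuted = data.permute_groups(rng, stratify_by_condition=cfg.stratify_by_condition)
        vals, cens = _evaluate(statistic, permuted)
        rows.append(vals)
        cens_rows.append(cens)
    values, censored = _collect(rows, cens_rows)
    null = values if values.ndim == 2 else values[:, None]
    p = (np.abs(null) >= np.abs(observed)[None, :]).mean(axis=0)
    obs_out: np.ndarray | float = observed if observed.size > 1 else float(observed[0])
    p_out: np.ndarray | float = p if p.size > 1 else float(p[0])
    dist = ResampleDistribution(
        values=values, kind="permutation_null", observed=obs_out, censored_fraction=censored
    )
    return PermutationResult(distribution=dist, p_value=p_out, observed=obs_out)


def jackknife_by_participant(data, statistic) -> np.ndarray:
    """Leave-one-participant-out statistics, concatenated across groups.

    Used to estimate the BCa acceleration constant; the participant -- the
    resampling unit -- is what gets left out.
    """
    rows = []
    for g in data.groups:
        n = data.n_participants(g)
        for i in range(n):
            idx = np.delete(np.arange(n), i)
            vals, _ = _evaluate(statistic, data.take({g: idx}))
            rows.append(vals)
    out = np.vstack(rows)
    return out[:, 0] if out.shape[1] == 1 else out


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def _quantile(values, q):
    return float(np.quantile(values, q))  # linear interpolation of order stats


def bootstrap_ci(
    dist,
    observed: float,
    method: str,
    level: float = 0.95,
    jackknife_values: Sequence[float] | None = None,
) -> IntervalResult:
    """One bootstrap confidence interval from a (scalar) bootstrap distribution.

    ``dist`` may be a :class:`ResampleDistribution` or a plain value array.
    ``jackknife_values`` (leave-one-participant-out statistics) are required
    for ``bca``.
    """
    values = dist.values if isinstance(dist, ResampleDistribution) else np.asarray(dist, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("bootstrap_ci expects a 1-D distribution; slice multi-measure values first")
    if values.size == 0:
        raise ConfigError("empty bootstrap distribution")
    if method not in CI_METHODS:
        raise ConfigError(f"unknown CI method {method!r}")
    B = values.size
    boot_mean = float(values.mean())
    boot_sd = float(values.std(ddof=1)) if B > 1 else 0.0
    diag: dict = {"boot_mean": boot_mean, "boot_sd": boot_sd}
    if values.max() == values.min():
        c = float(values[0])
        diag["degenerate"] = True
        return IntervalResult(method=method, lower_ms=c, upper_ms=c, diagnostics=diag)
    alpha = 1.0 - level
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if method == "percentile":
        lo, hi = _quantile(values, alpha / 2.0), _quantile(values, 1.0 - alpha / 2.0)
    elif method == "normal":
        bias = boot_mean - observed
        center = observed - bias
        lo, hi = center - z * boot_sd, center + z * boot_sd
    elif method == "empirical":
        lo = 2.0 * observed - _quantile(values, 1.0 - alpha / 2.0)
        hi = 2.0 * observed - _quantile(values, alpha / 2.0)
    else:  # bc / bca
        below = int(np.sum(values < observed))  # ties with observed excluded
        if below in (0, B):
            edge = stats.norm.ppf(1.0 / (B + 1.0))
            z0 = edge if below == 0 else -edge
            diag["z0_clamped"] = True
        else:
            z0 = stats.norm.ppf(below / B)
        diag["z0"] = float(z0)
        a = 0.0
        if method == "bca":
            if jackknife_values is None:
                raise ConfigError("bca requires leave-one-participant-out jackknife values")
            jk = np.asarray(jackknife_values, dtype=float)
            d = jk.mean() - jk
            denom = np.sum(d**2) ** 1.5
            a = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0
        diag["a"] = a
        zl, zh = z0 - z, z0 + z
        lo_level = stats.norm.cdf(z0 + zl / (1.0 - a * zl))
        hi_level = stats.norm.cdf(z0 + zh / (1.0 - a * zh))
        lo, hi = _quantile(values, lo_level), _quantile(values, hi_level)
        diag["levels"] = (float(lo_level), float(hi_level))
    if lo > hi:
        lo, hi = hi, lo
    return IntervalResult(method=method, lower_ms=float(lo), upper_ms=float(hi), diagnostics=diag)


def wilson_interval(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if trials < 1:
        raise ConfigError("trials must be >= 1")
    if not (0 <= successes <= trials):
        raise ConfigError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - level, method="wilson")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))
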