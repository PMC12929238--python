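"""Monte Carlo evaluation of the latency comparison procedures.

A :class:`SimulationPlan` enumerates cells over a grid of group sizes,
true latency shifts and per-participant timing-noise levels.  Each
simulation assembles a two-group dataset (fresh synthetic participants, or
a subsample of a seed gaze/proportion table), injects the cell's true
shift into the "shifted" group, optionally adds per-participant Gaussian
timing noise, computes all four latency measures, and runs the requested
resampling procedures: by-participant (and optionally stratified)
bootstrap with all configured CI methods, and the participant-label
permutation test.

Aggregation turns the per-simulation records of one cell into power
(true shift > 0) or Type I error (shift = 0) per test x measure, coverage
per CI method, and latency-distribution summaries, each with a Wilson
interval.  Because a rigid time shift translates the whole bootstrap
distribution without changing its shape, records from shift-0 cells can
also be re-scored at any hypothetical shift by translating the stored CI
bounds, pooling precision across effect sizes.

Child seeds are derived deterministically from ``(master_seed, cell,
simulation)``, so cells can run in any order with identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    BinnedCounts,
    BinningConfig,
    ConfigError,
    ParticipantProportions,
    add_participant_noise,
    bin_series,
    shift_group_time,
    shift_proportion_table,
)
from .latency import MEASURES, LatencyConfig, LatencyDifferenceStatistic
from .resampling import (
    ResamplingConfig,
    bootstrap_by_participant,
    bootstrap_ci,
    bootstrap_stratified,
    jackknife_by_participant,
    permutation_test,
    wilson_interval,
)
from .synthetic import SyntheticSpec, generate_gaze, generate_proportion_table

PROCEDURES = ("bootstrap", "permutation")
GROUPS = ("baseline", "shifted")


@dataclass
class SimulationCell:
    index: int
    n: int
    delta_ms: float
    noise_sd_ms: float


@dataclass
class PlanReport:
    """Planned totals: simulations, resampled datasets and bin-level fits."""

    n_cells: int
    n_simulations: int
    n_resamples: int
    n_bin_fits: int


@dataclass
class SimulationPlan:
    group_sizes: Sequence[int] = (24,)
    effect_sizes: Sequence[float] = (0.0,)
    noise_sds: Sequence[float] = (0.0,)
    n_sims: int = 1000
    sample_with_replacement: bool = False
    condition_balanced: bool = False
    procedures: tuple[str, ...] = ("bootstrap", "permutation")
    latency_cfg: LatencyConfig = field(default_factory=LatencyConfig)
    resampling_cfg: ResamplingConfig = field(default_factory=ResamplingConfig)
    binning_cfg: BinningConfig = field(default_factory=BinningConfig)
    master_seed: int = 0
    cells: list = field(default_factory=list)
    report: PlanReport | None = None


def build_plan(plan: SimulationPlan | dict) -> SimulationPlan:
    """Enumerate cells and compute the plan's resource accounting.

    Resamples per simulation = B per bootstrap scheme (when the bootstrap
    procedure is on) + P (when the permutation test is on); bin-level test
    fits = resamples x bins x 2 groups.
    """
    if isinstance(plan, dict):
        plan = plan_from_dict(plan)
    if not plan.group_sizes or not plan.effect_sizes or not plan.noise_sds:
        raise ConfigError("group_sizes, effect_sizes and noise_sds must be nonempty")
    bad = set(plan.procedures) - set(PROCEDURES)
    if bad:
        raise ConfigError(f"unknown procedure(s) {sorted(bad)}")
    cells = [
        SimulationCell(index=i, n=int(n), delta_ms=float(d), noise_sd_ms=float(s))
        for i, (n, d, s) in enumerate(
            itertools.product(plan.group_sizes, plan.effect_sizes, plan.noise_sds)
        )
    ]
    r = plan.resampling_cfg
    per_sim = 0
    if "bootstrap" in plan.procedures:
        per_sim += r.n_bootstrap * len(r.bootstrap_schemes)
    if "permutation" in plan.procedures:
        per_sim += r.n_permutation
    n_sims = plan.n_sims * len(cells)
    n_resamples = n_sims * per_sim
    plan.cells = cells
    plan.report = PlanReport(
        n_cells=len(cells),
        n_simulations=n_sims,
        n_resamples=n_resamples,
        n_bin_fits=n_resamples * plan.binning_cfg.n_bins * 2,
    )
    return plan


def plan_from_dict(d: dict) -> SimulationPlan:
    d = dict(d)
    if "latency" in d:
        d["latency_cfg"] = LatencyConfig.from_dict(d.pop("latency"))
    if "resampling" in d:
        d["resampling_cfg"] = ResamplingConfig.from_dict(d.pop("resampling"))
    if "binning" in d:
        d["binning_cfg"] = BinningConfig.from_dict(d.pop("binning"))
    if "procedures" in d:
        d["procedures"] = tuple(d["procedures"])
    return SimulationPlan(**d)


# ---------------------------------------------------------------------------
# one simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationRecord:
    n: int
    delta_ms: float
    noise_sd_ms: float
    sim_index: int
    observed: dict            # measure -> latency difference (ms)
    observed_censored: dict   # measure -> bool
    baseline_latency: dict    # measure -> (latency_ms, censored)
    shifted_latency: dict
    permutation_p: dict | None          # measure -> p
    intervals: dict                     # scheme -> method -> measure -> (lo, hi)
    censored_fraction: dict             # scheme -> mean over resamples/measures


def _child_rngs(master_seed: int, cell_index: int, sim_index: int, n: int):
    ss = np.random.SeedSequence([int(master_seed), int(cell_index), int(sim_index)])
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def _sample_pool(pool: pd.DataFrame, n: int, rng, with_replacement: bool, balanced: bool):
    """Draw 2n participants from a seed table and split them into two groups."""
    meta = pool[["participant", "condition"]].drop_duplicates("participant")
    participants = meta["participant"].to_numpy()
    conditions = meta["condition"].to_numpy()
    if balanced:
        conds = pd.unique(conditions)
        k = len(conds)
        if (2 * n) % k:
            raise ConfigError("2n must be divisible by the number of conditions")
        per = 2 * n // k
        if per % 2:
            raise ConfigError("n must be divisible by the number of conditions")
        chosen = []
        for c in conds:
            members = participants[conditions == c]
            if not with_replacement and len(members) < per:
                raise ConfigError(f"condition {c!r} has too few participants")
            idx = rng.choice(len(members), size=per, replace=with_replacement)
            chosen.append(members[idx])
        # split each condition's draw in half so both groups stay balanced
        chosen = np.stack(chosen)  # (k, per)
        drawn = chosen[:, : per // 2].ravel(), chosen[:, per // 2 :].ravel()
    else:
        if not with_replacement and len(participants) < 2 * n:
            raise ConfigError(
                f"seed pool has {len(participants)} participants; 2n = {2 * n} required"
            )
        idx = rng.choice(len(participants), size=2 * n, replace=with_replacement)
        drawn = participants[idx][:n], participants[idx][n:]
    frames = []
    for g, members in zip(GROUPS, drawn):
        counts: dict = {}
        for p in members:
            counts[p] = counts.get(p, 0) + 1
            sub = pool[pool["participant"] == p].copy()
            # per-group relabeling keeps with-replacement clones (and the
            # same seed participant drawn into both groups) distinct
            label = f"{g}:{p}" if counts[p] == 1 else f"{g}:{p}~clone{counts[p]}"
            sub["participant"] = label
            sub["group"] = g
            frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def _assemble_counts(seed_data, cell: SimulationCell, plan: SimulationPlan, rng):
    """Build the resampling container for one simulation."""
    binning = plan.binning_cfg
    if cell.noise_sd_ms and plan.latency_cfg.bin_test == "relative_proportion_ttest":
        raise ConfigError("participant timing noise is not representable on pre-binned proportions")
    if isinstance(seed_data, SyntheticSpec):
        spec = replace(seed_data, n_participants=cell.n, delta_group_ms=0.0, seed=None)
        if plan.latency_cfg.bin_test == "relative_proportion_ttest":
            table, _ = generate_proportion_table(spec, rng=rng)
            if cell.delta_ms:
                table = shift_proportion_table(table, GROUPS[1], cell.delta_ms, binning.bin_width_ms)
            return ParticipantProportions.from_proportion_table(table, binning)
        gaze, _ = generate_gaze(spec, rng=rng)
    elif "p_competitor" in seed_data.columns:
        table = _sample_pool(
            seed_data, cell.n, rng, plan.sample_with_replacement, plan.condition_balanced
        )
        if cell.delta_ms:
            table = shift_proportion_table(table, GROUPS[1], cell.delta_ms, binning.bin_width_ms)
        return ParticipantProportions.from_proportion_table(table, binning)
    else:
        gaze = _sample_pool(
            seed_data, cell.n, rng, plan.sample_with_replacement, plan.condition_balanced
        )
    if cell.delta_ms:
        gaze = shift_group_time(gaze, GROUPS[1], cell.delta_ms)
    if cell.noise_sd_ms:
        gaze = add_participant_noise(gaze, cell.noise_sd_ms, rng)
    return BinnedCounts.from_binned_series(bin_series(gaze, binning), binning)


def run_simulation(
    seed_data, cell: SimulationCell, plan: SimulationPlan, sim_index: int = 0
) -> SimulationRecord:
    """Execute one full simulated experiment and all requested tests."""
    rng_data, rng_boot, rng_strat, rng_perm = _child_rngs(
        plan.master_seed, cell.index, sim_index, 4
    )
    data = _assemble_counts(seed_data, cell, plan, rng_data)
    stat = LatencyDifferenceStatistic(plan.latency_cfg, plan.binning_cfg, *GROUPS)
    estimates = stat.group_estimates(data)
    obs_vals, obs_cens = stat.evaluate(data)
    observed = dict(zip(MEASURES, map(float, obs_vals)))
    observed_censored = dict(zip(MEASURES, map(bool, obs_cens)))
    rcfg = plan.resampling_cfg
    intervals: dict = {}
    censored_fraction: dict = {}
    if "bootstrap" in plan.procedures:
        jack = None
        if "bca" in rcfg.ci_methods:
            jack = jackknife_by_participant(data, stat)
        for scheme in rcfg.bootstrap_schemes:
            if scheme == "by_participant":
                dist = bootstrap_by_participant(data, rcfg, stat, rng=rng_boot)
            else:
                dist = bootstrap_stratified(data, rcfg, stat, rng=rng_strat)
            per_method: dict = {}
            for method in rcfg.ci_methods:
                per_measure = {}
                for j, meas in enumerate(MEASURES):
                    jk = jack[:, j] if (jack is not None and method == "bca") else None
                    res = bootstrap_ci(
                        dist.values[:, j], observed[meas], method,
                        level=rcfg.ci_level, jackknife_values=jk,
                    )
                    per_measure[meas] = (res.lower_ms, res.upper_ms)
                per_method[method] = per_measure
            intervals[scheme] = per_method
            cf = dist.censored_fraction
            censored_fraction[scheme] = float(np.mean(cf)) if cf is not None else 0.0
    permutation_p = None
    if "permutation" in plan.procedures:
        res = permutation_test(data, rcfg, stat, rng=rng_perm)
        permutation_p = dict(zip(MEASURES, map(float, np.atleast_1d(res.p_value))))
    return SimulationRecord(
        n=cell.n,
        delta_ms=cell.delta_ms,
        noise_sd_ms=cell.noise_sd_ms,
        sim_index=sim_index,
        observed=observed,
        observed_censored=observed_censored,
        baseline_latency={
            m: (e.latency_ms, e.censored) for m, e in estimates[GROUPS[0]].items()
        },
        shifted_latency={
            m: (e.latency_ms, e.censored) for m, e in estimates[GROUPS[1]].items()
        },
        permutation_p=permutation_p,
        intervals=intervals,
        censored_fraction=censored_fraction,
    )


def run_cell(seed_data, cell, plan, progress=None) -> list[SimulationRecord]:
    records = []
    for i in range(plan.n_sims):
        records.append(run_simulation(seed_data, cell, plan, sim_index=i))
        if progress is not None:
            progress(cell, i)
    return records


def run_plan(seed_data, plan: SimulationPlan, progress=None) -> list[SimulationRecord]:
    """Run every cell of the plan; returns the flat list of records."""
    if not plan.cells:
        plan = build_plan(plan)
    out = []
    for cell in plan.cells:
        out.extend(run_cell(seed_data, cell, plan, progress=progress))
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class CellSummary:
    n: int
    delta_ms: float
    noise_sd_ms: float
    n_sims: int
    kind: str                     # "power" or "type_i"
    tests: pd.DataFrame           # per test x measure rates with Wilson CIs
    coverage: pd.DataFrame        # per scheme x method x measure
    latency: pd.DataFrame         # latency-distribution summaries per measure


def _rate_row(hits: int, total: int, level: float = 0.95):
    lo, hi = wilson_interval(hits, total, level)
    return hits / total, lo, hi


def aggregate_cell(
    records: Sequence[SimulationRecord],
    alpha: float = 0.05,
    true_delta: float | None = None,
    ci_level: float = 0.95,
) -> CellSummary:
    """Summarise one cell's records into power / Type I, coverage and spreads.

    Bootstrap-based tests reject when the CI excludes 0 (power counts a
    strictly positive lower bound; Type I counts exclusion on either side).
    The permutation test rejects at ``p < alpha``; its power additionally
    requires a positive observed difference.  Coverage is the proportion of
    CIs containing the true shift.  Censored latencies enter the summaries
    at the window end and their frequency is reported, not hidden.
    """
    if not records:
        raise ConfigError("no records to aggregate")
    first = records[0]
    if true_delta is None:
        true_delta = first.delta_ms
    total = len(records)
    kind = "power" if true_delta > 0 else "type_i"
    rows = []
    if first.permutation_p is not None:
        for meas in MEASURES:
            if kind == "power":
                hits = sum(
                    1
                    for r in records
                    if r.permutation_p[meas] < alpha and r.observed[meas] > 0
                )
            else:
                hits = sum(1 for r in records if r.permutation_p[meas] < alpha)
            rate, lo, hi = _rate_row(hits, total, ci_level)
            rows.append(("permutation", "", meas, rate, lo, hi))
    cov_rows = []
    for scheme in first.intervals:
        for method in first.intervals[scheme]:
            for meas in MEASURES:
                bounds = [r.intervals[scheme][method][meas] for r in records]
                if kind == "power":
                    hits = sum(1 for lo_, hi_ in bounds if lo_ > 0)
                else:
                    hits = sum(1 for lo_, hi_ in bounds if lo_ > 0 or hi_ < 0)
                rate, lo, hi = _rate_row(hits, total, ci_level)
                rows.append((f"bootstrap_{scheme}", method, meas, rate, lo, hi))
                chits = sum(1 for lo_, hi_ in bounds if lo_ <= true_delta <= hi_)
                crate, clo, chi_ = _rate_row(chits, total, ci_level)
                cov_rows.append((scheme, method, meas, crate, clo, chi_))
    lat_rows = []
    for meas in MEASURES:
        base = np.asarray([r.baseline_latency[meas][0] for r in records])
        diffs = np.asarray([r.observed[meas] for r in records])
        cens = np.mean([r.observed_censored[meas] for r in records])
        lat_rows.append(
            (
                meas,
                float(base.mean()),
                float(base.std(ddof=1)) if total > 1 else 0.0,
                float(diffs.mean()),
                float(diffs.std(ddof=1)) if total > 1 else 0.0,
                float(cens),
            )
        )
    return CellSummary(
        n=first.n,
        delta_ms=first.delta_ms,
        noise_sd_ms=first.noise_sd_ms,
        n_sims=total,
        kind=kind,
        tests=pd.DataFrame(
            rows, columns=["test", "ci_method", "measure", "rate", "wilson_low", "wilson_high"]
        ),
        coverage=pd.DataFrame(
            cov_rows,
            columns=["scheme", "ci_method", "measure", "coverage", "wilson_low", "wilson_high"],
        ),
        latency=pd.DataFrame(
            lat_rows,
            columns=[
                "measure", "baseline_mean", "baseline_sd", "diff_mean", "diff_sd",
                "censored_fraction",
            ],
        ),
    )


def pooled_shift_estimates(
    records: Sequence[SimulationRecord], effect_sizes: Sequence[float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-score shift-0 bootstrap CIs at translated effect sizes and pool.

    A rigid shift of one group's time axis translates the bootstrap
    distribution of the latency difference without changing its shape, so a
    CI computed at shift 0 becomes the CI at shift ``delta`` by adding
    ``delta`` to both bounds.  For each requested shift the translated CI is
    re-scored (rejection = interval excludes 0, which at shift 0 reproduces
    the directly estimated Type I error exactly; coverage = interval
    contains the shift).  Pooled rates average over the shift grid.
    """
    if any(r.delta_ms != 0 for r in records):
        raise ConfigError("pooled shift estimates require records simulated at shift 0")
    total = len(records)
    per_rows = []
    pooled_rows = []
    first = records[0]
    for scheme in first.intervals:
        for method in first.intervals[scheme]:
            for meas in MEASURES:
                bounds = np.asarray(
                    [r.intervals[scheme][method][meas] for r in records]
                )  # (R, 2)
                powers = []
                covers = []
                for delta in effect_sizes:
                    lo = bounds[:, 0] + delta
                    hi = bounds[:, 1] + delta
                    power = float(np.mean((lo > 0) | (hi < 0)))
                    cover = float(np.mean((lo <= delta) & (delta <= hi)))
                    per_rows.append((scheme, method, meas, float(delta), power, cover))
                    powers.append(power)
                    covers.append(cover)
                pooled_rows.append(
                    (scheme, method, meas, float(np.mean(powers)), float(np.mean(covers)))
                )
    per = pd.DataFrame(
        per_rows, columns=["scheme", "ci_method", "measure", "delta_ms", "power", "coverage"]
    )
    pooled = pd.DataFrame(
        pooled_rows, columns=["scheme", "ci_method", "measure", "power", "coverage"]
    )
    return per, pooled


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[SimulationRecord]) -> pd.DataFrame:
    """Flatten records to one row per simulation x measure for CSV export."""
    rows = []
    for r in records:
        for meas in MEASURES:
            row = {
                "n": r.n,
                "delta_ms": r.delta_ms,
                "noise_sd_ms": r.noise_sd_ms,
                "sim_index": r.sim_index,
                "measure": meas,
                "observed_diff_ms": r.observed[meas],
                "observed_censored": r.observed_censored[meas],
                "baseline_latency_ms": r.baseline_latency[meas][0],
                "baseline_censored": r.baseline_latency[meas][1],
                "shifted_latency_ms": r.shifted_latency[meas][0],
                "shifted_censored": r.shifted_latency[meas][1],
                "permutation_p": (r.permutation_p or {}).get(meas),
            }
            for scheme, methods in r.intervals.items():
                for method, per_measure in methods.items():
                    lo, hi = per_measure[meas]
                    row[f"{scheme}_{method}_low"] = lo
                    row[f"{scheme}_{method}_high"] = hi
            rows.append(row)
    return pd.DataFrame(rows)
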