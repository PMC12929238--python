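"""Synthetic visual-world gaze data with known ground-truth onsets.

The generator emulates the two experimental regimes the latency procedures
are meant for:

* a two-picture *target preference* design (sentence processing): each
  participant looks at chance before their personal effect onset, then
  ramps to a lasting target-preference plateau;
* a four-picture *competitor transient* design (word recognition): the
  cohort competitor enjoys a small, temporary advantage over unrelated
  items that decays once the target is identified.

Participant onsets are ``tau_base + delta_group + Normal(0, sigma_subj)``;
trials jitter around the participant onset with SD ``sigma_trial``.  Gaze
samples follow a two-state persistent chain: with probability ``rho`` a
sample repeats the previous gaze state, otherwise it is redrawn from the
marginal target probability at that time -- this reproduces the strong
within-trial autocorrelation of real eye-tracking series, which is exactly
what distinguishes the by-participant from the stratified bootstrap.
Sampling is either at a fixed rate (infrared trackers, e.g. 120 Hz) or with
lognormal inter-sample gaps around a low mean rate (webcam trackers,
typically 1-50 Hz with irregular timing).

Every generated table comes with a ground-truth sidecar of per-participant
onsets, so parameter-recovery and calibration tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import ConfigError


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth model of a two-group visual-world experiment.

    Defaults describe an infrared-tracked sentence-processing experiment:
    24 participants per group, 24 trials each, 120 Hz sampling, an effect
    onset 600 ms after cue onset with 60 ms between-participant SD, a
    200-ms linear ramp from chance (0.5) to a 0.95 target-preference
    plateau, gaze-state persistence 0.9 and 5% off-screen looks.
    """

    n_participants: int = 24          # per group
    n_trials: int = 24
    tau_base_ms: float = 600.0        # population effect onset
    delta_group_ms: float = 0.0       # true shift of the "shifted" group
    sigma_subj_ms: float = 60.0       # between-participant onset SD
    sigma_trial_ms: float = 50.0      # within-participant trial jitter SD
    p_pre: float = 0.5                # pre-onset target probability (chance)
    p_max: float = 0.95               # post-ramp plateau
    ramp_ms: float = 200.0
    rho: float = 0.9                  # gaze-state persistence
    p_whitespace: float = 0.05
    sampling: Mapping = field(default_factory=lambda: {"fixed_hz": 120.0})
    trial_length_ms: float = 2400.0
    effect_mode: str = "target_preference"   # or "competitor_transient"
    effect_duration_ms: float = 400.0        # transient-mode plateau length
    # competitor/proportion-table parameters
    bin_width_ms: float = 40.0
    pre_window_ms: float = 400.0      # margin generated before cue onset
    comp_effect_size: float = 0.10    # peak competitor-minus-unrelated difference
    n_conditions: int = 1
    groups: tuple[str, str] = ("baseline", "shifted")
    seed: int | None = None

    def __post_init__(self):
        for name in ("p_pre", "p_max", "rho", "p_whitespace"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.rho >= 1.0:
            raise ConfigError("rho must be < 1")
        if min(self.sigma_subj_ms, self.sigma_trial_ms, self.ramp_ms) < 0:
            raise ConfigError("SDs and ramp must be >= 0")
        if self.n_participants < 1 or self.n_trials < 1:
            raise ConfigError("n_participants and n_trials must be >= 1")
        if self.effect_mode not in ("target_preference", "competitor_transient"):
            raise ConfigError("unknown effect_mode")
        if self.tau_base_ms + self.ramp_ms > self.trial_length_ms:
            raise ConfigError("effect ramp extends beyond the trial")
        if "fixed_hz" in self.sampling:
            if self.sampling["fixed_hz"] <= 0:
                raise ConfigError("fixed sampling rate must be > 0")
        elif "webcam" in self.sampling:
            if self.sampling["webcam"].get("mean_hz", 0) <= 0:
                raise ConfigError("webcam mean rate must be > 0")
        else:
            raise ConfigError("sampling must declare 'fixed_hz' or 'webcam'")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["sampling"] = dict(self.sampling)
        d["groups"] = list(self.groups)
        return d

    @classmethod
    def from_dict(cls, d) -> "SyntheticSpec":
        d = dict(d)
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        return cls(**d)


# ---------------------------------------------------------------------------
# marginal target probability
# ---------------------------------------------------------------------------

def target_marginal(t: np.ndarray, onset: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Marginal target probability at time ``t`` for trials with ``onset``."""
    x = t - onset
    if spec.ramp_ms > 0:
        up = np.clip(x / spec.ramp_ms, 0.0, 1.0)
    else:
        up = (x >= 0).astype(float)
    p = spec.p_pre + (spec.p_max - spec.p_pre) * up
    if spec.effect_mode == "competitor_transient":
        x2 = x - spec.ramp_ms - spec.effect_duration_ms
        if spec.ramp_ms > 0:
            down = np.clip(x2 / spec.ramp_ms, 0.0, 1.0)
        else:
            down = (x2 >= 0).astype(float)
        p = p - (spec.p_max - spec.p_pre) * down
    return p


# ---------------------------------------------------------------------------
# gaze tables
# ---------------------------------------------------------------------------

def _condition_labels(spec: SyntheticSpec, n: int) -> np.ndarray:
    if spec.n_conditions <= 1:
        return np.asarray(["c1"] * n, dtype=object)
    labels = [f"c{1 + i % spec.n_conditions}" for i in range(n)]
    return np.asarray(labels, dtype=object)


def _chain_states(rng, p: np.ndarray, rho: float) -> np.ndarray:
    """Persistent binary chain along the last axis with marginal profile p."""
    n_series, n_samples = p.shape
    states = np.empty((n_series, n_samples), dtype=bool)
    draw = rng.random((n_series, n_samples)) < p
    persist = rng.random((n_series, n_samples)) < rho
    states[:, 0] = draw[:, 0]
    for j in range(1, n_samples):
        states[:, j] = np.where(persist[:, j], states[:, j - 1], draw[:, j])
    return states


def _sample_times_fixed(hz: float, length_ms: float) -> np.ndarray:
    step = 1000.0 / hz
    return np.arange(0.0, length_ms, step)


def _sample_times_webcam(rng, mean_hz: float, jitter: float, length_ms: float) -> np.ndarray:
    """Lognormal inter-sample gaps with the requested mean rate."""
    mean_gap = 1000.0 / mean_hz
    mu = np.log(mean_gap) - 0.5 * jitter**2
    times = []
    t = float(rng.lognormal(mu, jitter))
    while t < length_ms:
        times.append(t)
        t += float(rng.lognormal(mu, jitter))
    return np.asarray(times)


def generate_gaze(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a two-group gaze table plus its ground-truth onsets.

    Returns ``(gaze_table, ground_truth)`` where the ground truth holds one
    row per participant with the participant's true onset in ms.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    frames = []
    truth_rows = []
    for g in spec.groups:
        offset = spec.delta_group_ms if g == spec.groups[1] else 0.0
        nP, nT = spec.n_participants, spec.n_trials
        pid = np.asarray([f"{g}_p{i:03d}" for i in range(nP)], dtype=object)
        cond = _condition_labels(spec, nP)
        tau = spec.tau_base_ms + offset + rng.normal(0.0, spec.sigma_subj_ms, size=nP)
        onsets = tau[:, None] + rng.normal(0.0, spec.sigma_trial_ms, size=(nP, nT))
        for i in range(nP):
            truth_rows.append((pid[i], g, cond[i], float(tau[i])))
        if "fixed_hz" in spec.sampling:
            times = _sample_times_fixed(spec.sampling["fixed_hz"], spec.trial_length_ms)
            S = times.size
            flat_onsets = onsets.reshape(-1, 1)                     # (nP*nT, 1)
            p = target_marginal(times[None, :], flat_onsets, spec)  # (nP*nT, S)
            states = _chain_states(rng, p, spec.rho)
            t_all = np.broadcast_to(times, (nP * nT, S)).ravel()
            part_all = np.repeat(pid, nT * S)
            cond_all = np.repeat(cond, nT * S)
            trial_ids = np.asarray([f"t{j:03d}" for j in range(nT)], dtype=object)
            trial_all = np.tile(np.repeat(trial_ids, S), nP)
            state_all = states.ravel()
        else:
            wc = spec.sampling["webcam"]
            t_parts, part_parts, cond_parts, trial_parts, state_parts = [], [], [], [], []
            for i in range(nP):
                for j in range(nT):
                    times = _sample_times_webcam(
                        rng, wc["mean_hz"], wc.get("jitter", 0.6), spec.trial_length_ms
                    )
                    if times.size == 0:
                        continue
                    p = target_marginal(times[None, :], np.asarray([[onsets[i, j]]]), spec)
                    states = _chain_states(rng, p, spec.rho)[0]
                    t_parts.append(times)
                    part_parts.append(np.repeat(pid[i], times.size))
                    cond_parts.append(np.repeat(cond[i], times.size))
                    trial_parts.append(np.repeat(f"t{j:03d}", times.size))
                    state_parts.append(states)
            t_all = np.concatenate(t_parts)
            part_all = np.concatenate(part_parts)
            cond_all = np.concatenate(cond_parts)
            trial_all = np.concatenate(trial_parts)
            state_all = np.concatenate(state_parts)
        aoi = np.where(state_all, "target", "competitor").astype(object)
        if spec.p_whitespace > 0:
            white = rng.random(aoi.size) < spec.p_whitespace
            aoi[white] = "whitespace"
        frames.append(
            pd.DataFrame(
                {
                    "participant": part_all,
                    "group": g,
                    "condition": cond_all,
                    "trial": trial_all,
                    "time_ms": t_all,
                    "aoi": aoi,
                }
            )
        )
    gaze = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=["participant", "group", "condition", "true_onset_ms"])
    return gaze, truth


# ---------------------------------------------------------------------------
# proportion tables (pre-averaged, word-recognition style)
# ---------------------------------------------------------------------------

def _aoi_probabilities(t: np.ndarray, onset: float, spec: SyntheticSpec, effect_scale: float):
    """(target, competitor, each-unrelated) probabilities over bin centers.

    All four pictures start at 0.25.  The competitor advantage follows a
    trapezoid (ramp up over ``ramp_ms``, hold ``effect_duration_ms``, ramp
    back down); once the transient is over the target rises toward
    ``p_max`` with the rest of the mass split evenly.
    """
    ramp = max(spec.ramp_ms, 1e-9)
    d_peak = spec.comp_effect_size * effect_scale
    up = np.clip((t - onset) / ramp, 0.0, 1.0)
    down = np.clip((t - onset - spec.ramp_ms - spec.effect_duration_ms) / ramp, 0.0, 1.0)
    d = d_peak * (up - down)
    gain = (spec.p_max - 0.25) * np.clip(
        (t - onset - spec.ramp_ms - spec.effect_duration_ms) / ramp, 0.0, 1.0
    )
    p_target = 0.25 + gain
    p_comp = 0.25 + d - gain / 3.0
    p_unrel = 0.25 - d / 2.0 - gain / 3.0
    if (p_comp < 0).any() or (p_unrel < 0).any() or (p_target > 1).any():
        raise ConfigError("infeasible AOI probabilities; reduce comp_effect_size or p_max")
    return p_target, p_comp, p_unrel


def generate_proportion_table(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant x bin AOI proportions for the competitor-transient design.

    Each participant x bin cell averages ``n_trials`` independent AOI draws
    from the model marginals, as in shared datasets that publish only
    participant-level means.  Condition labels scale the competitor effect
    (evenly spaced multipliers around 1), emulating between-condition
    differences in effect size.  Returns ``(table, ground_truth)``.
    """
    if spec.effect_mode != "competitor_transient":
        raise ConfigError("proportion tables require effect_mode='competitor_transient'")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    bins = np.arange(-spec.pre_window_ms, spec.trial_length_ms, spec.bin_width_ms)
    centers = bins + spec.bin_width_ms / 2.0
    scales = (
        np.linspace(0.5, 1.5, spec.n_conditions) if spec.n_conditions > 1 else np.asarray([1.0])
    )
    rows = []
    truth_rows = []
    for g in spec.groups:
        offset = spec.delta_group_ms if g == spec.groups[1] else 0.0
        cond = _condition_labels(spec, spec.n_participants)
        tau = spec.tau_base_ms + offset + rng.normal(0.0, spec.sigma_subj_ms, size=spec.n_participants)
        for i in range(spec.n_participants):
            pid = f"{g}_p{i:03d}"
            truth_rows.append((pid, g, cond[i], float(tau[i])))
            scale = scales[int(cond[i][1:]) - 1] if spec.n_conditions > 1 else 1.0
            p_t, p_c, p_u = _aoi_probabilities(centers, tau[i], spec, scale)
            probs = np.stack([p_t, p_c, p_u, p_u], axis=1)
            counts = np.stack([rng.multinomial(spec.n_trials, pr) for pr in probs])
            rows.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "group": g,
                        "condition": cond[i],
                        "bin_start_ms": bins,
                        "p_target": counts[:, 0] / spec.n_trials,
                        "p_competitor": counts[:, 1] / spec.n_trials,
                        "p_unrelated": (counts[:, 2] + counts[:, 3]) / (2.0 * spec.n_trials),
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=["participant", "group", "condition", "true_onset_ms"])
    return table, truth
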