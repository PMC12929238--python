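"""Core data structures and transforms for visual-world gaze time courses.

The package works with two long-format tables, both held as plain
:class:`pandas.DataFrame` objects with a documented schema:

``GazeTable``
    one row per gaze sample, with columns ``participant``, ``group``,
    ``condition``, ``trial``, ``time_ms`` (real, relative to the onset of
    the disambiguating cue) and ``aoi`` (area-of-interest label such as
    ``target``, ``competitor`` or ``whitespace``).

``ProportionTable``
    one row per participant x time bin for designs where only
    participant-averaged fixation proportions are available, with columns
    ``participant``, ``condition``, ``bin_start_ms``, ``p_target``,
    ``p_competitor`` and ``p_unrelated`` (plus an optional ``group``).

Binning restricts samples to a region of interest (ROI), assigns them to
fixed-width time bins, computes per-trial target proportions and optionally
binarizes them.  The module also provides the two time transforms used by
the Monte Carlo engine -- a rigid shift of one group's time axis (the
injected true latency difference) and per-participant Gaussian timing noise
-- and the aggregated count/proportion containers that the resampling code
operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GAZE_COLUMNS = ("participant", "group", "condition", "trial", "time_ms", "aoi")
PROPORTION_COLUMNS = (
    "participant",
    "condition",
    "bin_start_ms",
    "p_target",
    "p_competitor",
    "p_unrelated",
)


class SchemaError(ValueError):
    """A required column is missing or mis-typed in an input table."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names the offending row."""


class ConfigError(ValueError):
    """An invalid configuration value."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def validate_gaze_table(df: pd.DataFrame, aoi_vocabulary: Iterable[str] | None = None) -> pd.DataFrame:
    """Validate schema and types of a gaze table; returns a normalized copy.

    ``time_ms`` is coerced to float; a non-numeric entry raises
    :class:`ParseError` naming the row.  Unknown AOI labels (relative to
    ``aoi_vocabulary``, when given) are reported with a warning, not an
    error, so that exploratory data with extra regions still loads.
    """
    for col in GAZE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"gaze table is missing required column {col!r}")
    out = df.loc[:, list(GAZE_COLUMNS)].copy()
    times = pd.to_numeric(out["time_ms"], errors="coerce")
    bad = ~np.isfinite(times.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        row = int(np.nonzero(bad)[0][0])
        raise ParseError(f"non-numeric or non-finite time_ms at row {row}")
    out["time_ms"] = times.astype(float)
    if aoi_vocabulary is not None:
        vocab = set(aoi_vocabulary)
        unknown = sorted(set(out["aoi"].astype(str)) - vocab)
        if unknown:
            warnings.warn(f"unknown AOI labels present: {unknown}", stacklevel=2)
    return out


def read_gaze_table(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    aoi_vocabulary: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read a delimited gaze table.

    Parameters
    ----------
    column_map
        optional mapping from the canonical field names (``participant``,
        ``group``, ``condition``, ``trial``, ``time_ms``, ``aoi``) to the
        column names used in the file.
    delimiter
        field separator; inferred from the file when omitted.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if column_map:
        rename = {src: dst for dst, src in column_map.items()}
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise SchemaError(f"file is missing mapped column(s) {missing}")
        df = df.rename(columns=rename)
    return validate_gaze_table(df, aoi_vocabulary=aoi_vocabulary)


def write_gaze_table(df: pd.DataFrame, path) -> None:
    validate_gaze_table(df).to_csv(path, index=False)


def read_proportion_table(path, delimiter: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    for col in PROPORTION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"proportion table is missing required column {col!r}")
    for col in ("p_target", "p_competitor", "p_unrelated"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals > 1).any():
            raise ParseError(f"column {col!r} contains values outside [0, 1]")
        df[col] = vals.astype(float)
    df["bin_start_ms"] = pd.to_numeric(df["bin_start_ms"]).astype(float)
    return df


def write_proportion_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c in PROPORTION_COLUMNS + ("group",)]
    df.loc[:, cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinningConfig:
    """Region-of-interest and time-bin geometry.

    ``roi_start_ms``/``roi_end_ms`` delimit the analysis window relative to
    the cue onset; ``saccade_offset_ms`` (default 200 ms, the typical time
    needed to program and execute a saccade) is added to *both* boundaries,
    so the effective window is ``[roi_start + offset, roi_end + offset)``.
    Bins are half-open ``[start, start + width)`` intervals laid end to end;
    the window span must be an integer multiple of ``bin_width_ms``.
    """

    roi_start_ms: float = 0.0
    roi_end_ms: float = 2000.0
    bin_width_ms: float = 50.0
    saccade_offset_ms: float = 200.0
    target_aoi: str = "target"
    exclude_aois: tuple[str, ...] = ("whitespace",)
    binarize: bool = True

    def __post_init__(self):
        if self.bin_width_ms <= 0:
            raise ConfigError("bin_width_ms must be > 0")
        span = self.roi_end_ms - self.roi_start_ms
        if span <= 0:
            raise ConfigError("roi_end_ms must exceed roi_start_ms")
        n = span / self.bin_width_ms
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("ROI span must be an integer multiple of bin_width_ms")

    @property
    def n_bins(self) -> int:
        return int(round((self.roi_end_ms - self.roi_start_ms) / self.bin_width_ms))

    @property
    def start_ms(self) -> float:
        """Effective window start (ROI start plus saccade offset)."""
        return self.roi_start_ms + self.saccade_offset_ms

    @property
    def end_ms(self) -> float:
        return self.roi_end_ms + self.saccade_offset_ms

    @property
    def bin_starts(self) -> np.ndarray:
        return self.start_ms + self.bin_width_ms * np.arange(self.n_bins)

    def bin_start(self, index: int) -> float:
        return self.start_ms + self.bin_width_ms * index

    def to_dict(self) -> dict:
        return {
            "roi_start_ms": self.roi_start_ms,
            "roi_end_ms": self.roi_end_ms,
            "bin_width_ms": self.bin_width_ms,
            "saccade_offset_ms": self.saccade_offset_ms,
            "target_aoi": self.target_aoi,
            "exclude_aois": list(self.exclude_aois),
            "binarize": self.binarize,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BinningConfig":
        d = dict(d)
        if "exclude_aois" in d:
            d["exclude_aois"] = tuple(d["exclude_aois"])
        return cls(**d)


def bin_series(gaze: pd.DataFrame, cfg: BinningConfig) -> pd.DataFrame:
    """Bin a gaze table into per participant x trial x bin target values.

    Samples whose AOI is in ``cfg.exclude_aois`` are dropped before
    proportions are computed, so the denominator of each bin is the number
    of *retained* samples.  A sample at time ``t`` goes to bin
    ``floor((t - start) / width)`` iff ``start <= t < end``.  Cells with no
    retained samples emit no record.  With ``binarize``, proportions
    >= 0.5 become 1 and the rest 0.
    """
    gaze = validate_gaze_table(gaze)
    t = gaze["time_ms"].to_numpy()
    keep = (t >= cfg.start_ms) & (t < cfg.end_ms)
    keep &= ~gaze["aoi"].isin(cfg.exclude_aois).to_numpy()
    if not keep.any():
        return pd.DataFrame(
            columns=["participant", "group", "condition", "trial", "bin_index", "bin_start_ms", "value"]
        )
    sub = gaze.loc[keep]
    bin_index = np.floor((sub["time_ms"].to_numpy() - cfg.start_ms) / cfg.bin_width_ms).astype(int)
    is_target = (sub["aoi"] == cfg.target_aoi).astype(float)
    out = (
        pd.DataFrame(
            {
                "participant": sub["participant"].to_numpy(),
                "group": sub["group"].to_numpy(),
                "condition": sub["condition"].to_numpy(),
                "trial": sub["trial"].to_numpy(),
                "bin_index": bin_index,
                "value": is_target.to_numpy(),
            }
        )
        .groupby(["participant", "group", "condition", "trial", "bin_index"], sort=True, observed=True)["value"]
        .mean()
        .reset_index()
    )
    if cfg.binarize:
        out["value"] = (out["value"] >= 0.5).astype(float)
    out.insert(5, "bin_start_ms", cfg.start_ms + out["bin_index"] * cfg.bin_width_ms)
    return out


# ---------------------------------------------------------------------------
# Time transforms
# ---------------------------------------------------------------------------

def shift_group_time(gaze: pd.DataFrame, group, delta_ms: float) -> pd.DataFrame:
    """Add ``delta_ms`` to every time stamp of one group; all else unchanged."""
    if group not in set(gaze["group"]):
        raise KeyError(f"group {group!r} not present in gaze table")
    out = gaze.copy()
    mask = out["group"] == group
    out.loc[mask, "time_ms"] = out.loc[mask, "time_ms"] + delta_ms
    return out


def add_participant_noise(gaze: pd.DataFrame, sd_ms: float, rng: np.random.Generator) -> pd.DataFrame:
    """Add one Normal(0, sd) offset per participant to all of their samples.

    Emulates between-participant variability in response timing: each
    participant's entire time course moves rigidly by their own draw.
    """
    if sd_ms < 0:
        raise ConfigError("sd_ms must be >= 0")
    out = gaze.copy()
    participants = pd.unique(out["participant"])
    offsets = rng.normal(0.0, sd_ms, size=len(participants))
    lookup = dict(zip(participants, offsets))
    out["time_ms"] = out["time_ms"] + out["participant"].map(lookup).astype(float)
    return out


def shift_proportion_table(table: pd.DataFrame, group, delta_ms: float, bin_width_ms: float) -> pd.DataFrame:
    """Shift a pre-binned proportion table right in time for one group.

    Because the data are already binned, only shifts that are integer
    multiples of the bin width are representable.
    """
    if "group" not in table.columns:
        raise SchemaError("proportion table needs a 'group' column to shift one group")
    steps = delta_ms / bin_width_ms
    if abs(steps - round(steps)) > 1e-9:
        raise ConfigError("delta_ms must be an integer multiple of the bin width for pre-binned data")
    out = table.copy()
    mask = out["group"] == group
    out.loc[mask, "bin_start_ms"] = out.loc[mask, "bin_start_ms"] + delta_ms
    return out


# ---------------------------------------------------------------------------
# Aggregated containers used by the resampling machinery
# ---------------------------------------------------------------------------

@dataclass
class GroupCounts:
    """Per-participant success/total counts over bins for one group.

    ``S[p, b]`` is the number of trials of participant ``p`` whose
    (binarized) value in bin ``b`` is 1, ``N[p, b]`` the number of trials
    with any data in that cell.  Duplicated rows (bootstrap clones) weight
    the pooled counts correctly by construction.
    """

    participants: np.ndarray
    conditions: np.ndarray
    S: np.ndarray
    N: np.ndarray

    def take(self, idx: np.ndarray) -> "GroupCounts":
        return GroupCounts(
            participants=self.participants[idx],
            conditions=self.conditions[idx],
            S=self.S[idx],
            N=self.N[idx],
        )


@dataclass
class BinnedCounts:
    """Two-group (or multi-group) binned trial counts, the unit of resampling.

    Built from a binarized ``BinnedSeries`` table.  The participant is the
    exchangeable unit: bootstrap and permutation operate on whole rows.
    """

    binning: BinningConfig
    groups: dict

    kind = "counts"

    @classmethod
    def from_binned_series(cls, binned: pd.DataFrame, binning: BinningConfig) -> "BinnedCounts":
        m = binning.n_bins
        groups: dict[str, GroupCounts] = {}
        for g, sub in binned.groupby("group", sort=True, observed=True):
            parts = pd.unique(sub["participant"])
            index = {p: i for i, p in enumerate(parts)}
            P = len(parts)
            S = np.zeros((P, m))
            N = np.zeros((P, m))
            rows = sub["participant"].map(index).to_numpy()
            cols = sub["bin_index"].to_numpy()
            vals = sub["value"].to_numpy(dtype=float)
            np.add.at(S, (rows, cols), vals)
            np.add.at(N, (rows, cols), 1.0)
            conditions = sub.groupby("participant", sort=False, observed=True)["condition"].first()
            cond = np.asarray([conditions[p] for p in parts], dtype=object)
            groups[g] = GroupCounts(
                participants=np.asarray(parts, dtype=object), conditions=cond, S=S, N=N
            )
        return cls(binning=binning, groups=groups)

    # -- resampling primitives ------------------------------------------

    def n_participants(self, group) -> int:
        return len(self.groups[group].participants)

    def pooled(self, group) -> tuple[np.ndarray, np.ndarray]:
        gc = self.groups[group]
        return gc.S.sum(axis=0), gc.N.sum(axis=0)

    def take(self, indices: Mapping) -> "BinnedCounts":
        groups = {
            g: (gc.take(np.asarray(indices[g])) if g in indices else gc)
            for g, gc in self.groups.items()
        }
        return BinnedCounts(binning=self.binning, groups=groups)

    def resample_within_strata(self, rng: np.random.Generator) -> "BinnedCounts":
        """Stratified bootstrap: redraw trial values within participant x bin.

        For binarized trial values, drawing ``n`` values with replacement
        from a stratum holding ``s`` ones out of ``n`` is distributionally
        identical to drawing the new success count from Binomial(n, s/n);
        stratum sizes are preserved exactly and every participant stays in
        every resample.
        """
        groups = {}
        for g, gc in self.groups.items():
            n = gc.N.astype(int)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(n > 0, gc.S / np.where(n > 0, n, 1), 0.0)
            S = rng.binomial(n, p).astype(float)
            groups[g] = GroupCounts(
                participants=gc.participants, conditions=gc.conditions, S=S, N=gc.N
            )
        return BinnedCounts(binning=self.binning, groups=groups)

    def permute_groups(self, rng: np.random.Generator, stratify_by_condition: bool = False) -> "BinnedCounts":
        """Randomly reassign whole participants to groups, preserving sizes.

        With ``stratify_by_condition`` the reassignment happens within each
        condition stratum, so per-condition counts in each group are kept.
        """
        labels = list(self.groups)
        sizes = [self.n_participants(g) for g in labels]
        all_parts = np.concatenate([self.groups[g].participants for g in labels])
        all_cond = np.concatenate([self.groups[g].conditions for g in labels])
        all_S = np.vstack([self.groups[g].S for g in labels])
        all_N = np.vstack([self.groups[g].N for g in labels])
        assignment = _permuted_assignment(
            rng,
            labels,
            sizes,
            np.concatenate([np.repeat(i, s) for i, s in enumerate(sizes)]),
            all_cond,
            stratify_by_condition,
        )
        groups = {}
        for i, g in enumerate(labels):
            idx = np.nonzero(assignment == i)[0]
            groups[g] = GroupCounts(
                participants=all_parts[idx], conditions=all_cond[idx], S=all_S[idx], N=all_N[idx]
            )
        return BinnedCounts(binning=self.binning, groups=groups)


@dataclass
class GroupProportions:
    """Per-participant competitor/unrelated proportions over bins (NaN = missing)."""

    participants: np.ndarray
    conditions: np.ndarray
    competitor: np.ndarray
    unrelated: np.ndarray

    def take(self, idx: np.ndarray) -> "GroupProportions":
        return GroupProportions(
            participants=self.participants[idx],
            conditions=self.conditions[idx],
            competitor=self.competitor[idx],
            unrelated=self.unrelated[idx],
        )


@dataclass
class ParticipantProportions:
    """Two-group participant-by-bin proportion data (pre-averaged designs).

    The per-bin test on this container is a one-sample t-test on the
    relative proportion competitor / (competitor + unrelated) against 0.5.
    """

    binning: BinningConfig
    groups: dict

    kind = "proportions"

    @classmethod
    def from_proportion_table(cls, table: pd.DataFrame, binning: BinningConfig) -> "ParticipantProportions":
        if "group" not in table.columns:
            raise SchemaError("proportion table needs a 'group' column for group comparison")
        m = binning.n_bins
        starts = binning.bin_starts
        groups = {}
        for g, sub in table.groupby("group", sort=True, observed=True):
            parts = pd.unique(sub["participant"])
            index = {p: i for i, p in enumerate(parts)}
            comp = np.full((len(parts), m), np.nan)
            unrel = np.full((len(parts), m), np.nan)
            rows = sub["participant"].map(index).to_numpy()
            rel = (sub["bin_start_ms"].to_numpy() - binning.start_ms) / binning.bin_width_ms
            cols = np.round(rel).astype(int)
            ok = (np.abs(rel - cols) < 1e-6) & (cols >= 0) & (cols < m)
            comp[rows[ok], cols[ok]] = sub["p_competitor"].to_numpy()[ok]
            unrel[rows[ok], cols[ok]] = sub["p_unrelated"].to_numpy()[ok]
            conditions = sub.groupby("participant", sort=False, observed=True)["condition"].first()
            cond = np.asarray([conditions[p] for p in parts], dtype=object)
            groups[g] = GroupProportions(
                participants=np.asarray(parts, dtype=object),
                conditions=cond,
                competitor=comp,
                unrelated=unrel,
            )
        _ = starts  # geometry checked via column mapping above
        return cls(binning=binning, groups=groups)

    def n_participants(self, group) -> int:
        return len(self.groups[group].participants)

    def take(self, indices: Mapping) -> "ParticipantProportions":
        groups = {
            g: (gp.take(np.asarray(indices[g])) if g in indices else gp)
            for g, gp in self.groups.items()
        }
        return ParticipantProportions(binning=self.binning, groups=groups)

    def permute_groups(self, rng: np.random.Generator, stratify_by_condition: bool = False) -> "ParticipantProportions":
        labels = list(self.groups)
        sizes = [self.n_participants(g) for g in labels]
        all_parts = np.concatenate([self.groups[g].participants for g in labels])
        all_cond = np.concatenate([self.groups[g].conditions for g in labels])
        all_comp = np.vstack([self.groups[g].competitor for g in labels])
        all_unrel = np.vstack([self.groups[g].unrelated for g in labels])
        assignment = _permuted_assignment(
            rng,
            labels,
            sizes,
            np.concatenate([np.repeat(i, s) for i, s in enumerate(sizes)]),
            all_cond,
            stratify_by_condition,
        )
        groups = {}
        for i, g in enumerate(labels):
            idx = np.nonzero(assignment == i)[0]
            groups[g] = GroupProportions(
                participants=all_parts[idx],
                conditions=all_cond[idx],
                competitor=all_comp[idx],
                unrelated=all_unrel[idx],
            )
        return ParticipantProportions(binning=self.binning, groups=groups)


def _permuted_assignment(rng, labels, sizes, current, conditions, stratify_by_condition):
    """Shuffle group membership indices, optionally within condition strata."""
    total = int(np.sum(sizes))
    assignment = np.empty(total, dtype=int)
    if stratify_by_condition:
        for c in pd.unique(conditions):
            idx = np.nonzero(conditions == c)[0]
            assignment[idx] = rng.permutation(current[idx])
    else:
        assignment[:] = rng.permutation(current)
    return assignment
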