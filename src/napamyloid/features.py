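"""Automated marking of NAP traces: twelve abstracted parameters per
waveform, stimulus-response ratios and baseline normalization.

All half-level crossings are located by linear interpolation between the
bracketing samples; fixed-offset voltages (0.08 ms / 0.16 ms) are read at
fractional sample positions, never rounded to the grid. Degenerate traces
yield missing values that propagate as excluded cases, not zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateWaveformError, InvalidConfigError, UndefinedRatioError
from .simulate import ExperimentDesign, WaveformDataset

__all__ = [
    "MarkingConfig",
    "NapFeatureVector",
    "PARAMETERS",
    "mark_peak_trough",
    "extract_features",
    "compute_srr",
    "extract_feature_table",
    "normalize_to_baseline",
]

#: canonical order of the 12 abstracted parameters
PARAMETERS = [
    "peak_to_peak_amplitude",
    "peak_amplitude",
    "trough_amplitude",
    "velocity",
    "duration",
    "decline_latency",
    "rise_latency",
    "decline_amplitude",
    "rise_amplitude",
    "recovery_latency",
    "recovery_amplitude",
    "srr",
]


@dataclass(frozen=True)
class MarkingConfig:
    artifact_samples: int = 10
    baseline_samples: int = 10  # baseline window = [artifact, artifact + this)
    slope_offset_rise_decline: float = 0.08  # ms
    slope_offset_recovery: float = 0.16  # ms

    def __post_init__(self) -> None:
        if self.artifact_samples < 0 or self.baseline_samples < 1:
            raise InvalidConfigError("invalid marking windows")
        if self.slope_offset_rise_decline <= 0 or self.slope_offset_recovery <= 0:
            raise InvalidConfigError("slope offsets must be positive")


@dataclass
class NapFeatureVector:
    """The 12 parameters abstracted from one NAP; missing values are NaN.

    Amplitudes are baseline-subtracted voltages; latencies and duration in
    ms; velocity in m/s; srr is unset (NaN) until the whole stimulus set is
    available.
    """

    peak_to_peak_amplitude: float
    peak_amplitude: float
    trough_amplitude: float
    velocity: float
    duration: float
    decline_latency: float
    rise_latency: float
    decline_amplitude: float
    rise_amplitude: float
    recovery_latency: float
    recovery_amplitude: float
    srr: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _baseline(samples: np.ndarray, cfg: MarkingConfig) -> float:
    lo = cfg.artifact_samples
    hi = min(lo + cfg.baseline_samples, len(samples))
    return float(np.mean(samples[lo:hi]))


def mark_peak_trough(
    samples: np.ndarray, cfg: MarkingConfig = MarkingConfig()
) -> tuple[float, float, float, float]:
    """Locate the NAP peak and trough.

    Returns ``(peak_index, trough_index, peak_voltage, trough_voltage)``.
    The peak is the maximum voltage after the artifact region, the trough
    the minimum after the peak; ties break to the earliest sample and
    voltages are baseline-subtracted.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) <= cfg.artifact_samples + 4:
        raise DegenerateWaveformError("window shorter than artifact region + 4")
    w = samples - _baseline(samples, cfg)
    post = w[cfg.artifact_samples:]
    if np.ptp(post) == 0:
        raise DegenerateWaveformError("flat post-artifact trace")
    peak_i = cfg.artifact_samples + int(np.argmax(post))
    after = w[peak_i + 1:]
    if len(after) == 0:
        raise DegenerateWaveformError("empty trough search window")
    trough_i = peak_i + 1 + int(np.argmin(after))
    return float(peak_i), float(trough_i), float(w[peak_i]), float(w[trough_i])


def _value_at(w: np.ndarray, idx: float) -> float:
    """Voltage at a fractional sample index; NaN outside the window."""
    if idx < 0 or idx > len(w) - 1:
        return math.nan
    return float(np.interp(idx, np.arange(len(w)), w))


def _cross_down_after(w: np.ndarray, start: int, level: float) -> float:
    """First fractional index >= start where w falls through ``level``."""
    for m in range(start, len(w) - 1):
        if w[m] >= level > w[m + 1]:
            return m + (w[m] - level) / (w[m] - w[m + 1])
        if w[m] == level:
            return float(m)
    return math.nan


def _cross_up_before(w: np.ndarray, stop: int, lo: int, level: float) -> float:
    """Last fractional index in [lo, stop) where w rises through ``level``."""
    for m in range(stop - 1, lo - 1, -1):
        if w[m] < level <= w[m + 1]:
            return m + (level - w[m]) / (w[m + 1] - w[m])
    return math.nan


def _cross_toward_after(w: np.ndarray, start: int, level: float, rising: bool) -> float:
    """First fractional index >= start where w crosses ``level`` moving
    toward baseline (direction given by ``rising``)."""
    for m in range(start, len(w) - 1):
        if rising and w[m] <= level < w[m + 1]:
            return m + (level - w[m]) / (w[m + 1] - w[m])
        if not rising and w[m] >= level > w[m + 1]:
            return m + (w[m] - level) / (w[m] - w[m + 1])
    return math.nan


def extract_features(
    samples: np.ndarray,
    cfg: MarkingConfig = MarkingConfig(),
    electrode_distance: float = 1.0,
    sample_rate: float = 99_000.0,
) -> NapFeatureVector:
    """Abstract the 12 parameters (srr left unset) from one trace.

    ``electrode_distance`` is in cm; latencies come out in ms and velocity
    in m/s. Features whose defining crossing never occurs inside the window
    are NaN.
    """
    samples = np.asarray(samples, dtype=float)
    peak_i, trough_i, peak_v, trough_v = mark_peak_trough(samples, cfg)
    w = samples - _baseline(samples, cfg)
    ms_per_sample = 1e3 / sample_rate

    peak_t = peak_i * ms_per_sample
    duration = (trough_i - peak_i) * ms_per_sample
    velocity = (electrode_distance / 100.0) / (peak_t / 1e3)

    half = 0.5 * (peak_v + trough_v)
    dcross = _cross_down_after(w, int(peak_i), half)
    decline_latency = (dcross - peak_i) * ms_per_sample if not math.isnan(dcross) else math.nan
    ucross = _cross_up_before(w, int(peak_i), cfg.artifact_samples, half)
    rise_latency = (peak_i - ucross) * ms_per_sample if not math.isnan(ucross) else math.nan

    rec_half = 0.5 * trough_v  # halfway between trough and (zeroed) baseline
    rcross = _cross_toward_after(w, int(trough_i), rec_half, rising=trough_v < 0)
    recovery_latency = (rcross - trough_i) * ms_per_sample if not math.isnan(rcross) else math.nan

    off = cfg.slope_offset_rise_decline / ms_per_sample
    off_rec = cfg.slope_offset_recovery / ms_per_sample
    decline_amplitude = peak_v - _value_at(w, peak_i + off)
    rise_amplitude = peak_v - _value_at(w, peak_i - off)
    recovery_amplitude = _value_at(w, trough_i + off_rec) - trough_v

    return NapFeatureVector(
        peak_to_peak_amplitude=peak_v - trough_v,
        peak_amplitude=peak_v,
        trough_amplitude=trough_v,
        velocity=velocity,
        duration=duration,
        decline_latency=decline_latency,
        rise_latency=rise_latency,
        decline_amplitude=decline_amplitude,
        rise_amplitude=rise_amplitude,
        recovery_latency=recovery_latency,
        recovery_amplitude=recovery_amplitude,
    )


def compute_srr(pp_by_seq: Mapping[int, float], stim_set: int) -> dict[int, float]:
    """Stimulus-response ratio per seq within one 7-stimulus set.

    Set 0 divides by the last (largest-current) response, set 1 by the
    first (longest-interval) response.
    """
    if sorted(pp_by_seq) != list(range(1, 8)):
        raise InvalidConfigError("all 7 seq positions are required")
    if stim_set == 0:
        ref = pp_by_seq[7]
    elif stim_set == 1:
        ref = pp_by_seq[1]
    else:
        raise InvalidConfigError(f"stim_set must be 0 or 1, got {stim_set}")
    if not ref > 0:
        raise UndefinedRatioError(f"reference peak-to-peak amplitude {ref} <= 0")
    return {k: pp_by_seq[k] / ref for k in pp_by_seq}


def extract_feature_table(
    dataset: WaveformDataset,
    cfg: MarkingConfig = MarkingConfig(),
    design: ExperimentDesign | None = None,
) -> pd.DataFrame:
    """Feature-extract every record of a dataset into a tidy long table.

    Columns: nerve, conc, expttime, stim_set, seq, parameter, value. The
    srr parameter is filled per (nerve, expttime, set) when all 7 seq
    positions are present (NaN otherwise). Unmarkable records yield NaN
    for every parameter.
    """
    design = design or dataset.design
    if design is None:
        raise InvalidConfigError("an ExperimentDesign is required (dataset has none)")
    rows: list[dict[str, float]] = []
    key_rows = dataset.keys.to_dict("records")
    for key, trace in zip(key_rows, dataset.samples):
        try:
            fv = extract_features(
                trace, cfg,
                electrode_distance=design.electrode_distance,
                sample_rate=design.sample_rate,
            ).as_dict()
        except DegenerateWaveformError:
            fv = {p: math.nan for p in PARAMETERS}
        rows.append({**key, **fv})
    wide = pd.DataFrame(rows)

    # fill srr set-wise from peak-to-peak amplitudes; a missing (degenerate)
    # non-reference response stays NaN without spoiling the rest of the set
    def _fill_srr(group: pd.DataFrame) -> pd.DataFrame:
        pp = dict(zip(group["seq"], group["peak_to_peak_amplitude"]))
        if sorted(pp) != list(range(1, 8)):
            return group
        ref = pp[7] if int(group["stim_set"].iloc[0]) == 0 else pp[1]
        if np.isfinite(ref) and ref > 0:
            group = group.copy()
            group["srr"] = group["seq"].map({k: v / ref for k, v in pp.items()})
        return group

    wide = (
        wide.groupby(["nerve", "expttime", "stim_set"], group_keys=False)[wide.columns]
        .apply(_fill_srr)
    )
    table = wide.melt(
        id_vars=WaveformDataset.KEY_COLUMNS, value_vars=PARAMETERS,
        var_name="parameter", value_name="value",
    )
    return table.reset_index(drop=True)


def batch_peak_to_peak(
    dataset: WaveformDataset, cfg: MarkingConfig = MarkingConfig()
) -> pd.DataFrame:
    """Vectorized peak-to-peak amplitude for every record of a dataset.

    Fast path for amplitude-only Monte-Carlo analyses; matches
    :func:`mark_peak_trough` exactly (baseline subtraction cancels in the
    peak-to-peak difference, peak before trough, earliest-tie convention).
    Returns the key table with a ``peak_to_peak_amplitude`` column.
    """
    post = dataset.samples[:, cfg.artifact_samples:]
    peak_pos = np.argmax(post, axis=1)
    peak_v = post[np.arange(len(post)), peak_pos]
    # minimum over samples strictly after each record's peak
    suffix_min = np.minimum.accumulate(post[:, ::-1], axis=1)[:, ::-1]
    after = np.minimum(peak_pos + 1, post.shape[1] - 1)
    trough_v = suffix_min[np.arange(len(post)), after]
    out = dataset.keys.copy()
    out["peak_to_peak_amplitude"] = peak_v - trough_v
    return out


def normalize_to_baseline(
    table: pd.DataFrame,
    baseline_segment: int = 3,
    analysis_segments: range | None = None,
) -> pd.DataFrame:
    """Divide each parameter by its own baseline-segment value per
    (nerve, set, seq, parameter) and keep only the analysis segments.

    A zero or missing baseline marks the parameter missing for that key
    (never infinity). ``analysis_segments`` defaults to every segment after
    ``baseline_segment``.
    """
    if baseline_segment not in set(table["expttime"]):
        raise InvalidConfigError(f"baseline segment {baseline_segment} absent from table")
    keys = ["nerve", "stim_set", "seq", "parameter"]
    base = (
        table[table["expttime"] == baseline_segment]
        .groupby(keys)["value"].mean().rename("baseline")
    )
    out = table.merge(base, on=keys, how="left")
    denom = out["baseline"].where(out["baseline"] != 0)
    out["normalized_value"] = out["value"] / denom
    if analysis_segments is None:
        segs = [j for j in sorted(set(out["expttime"])) if j > baseline_segment]
    else:
        segs = list(analysis_segments)
    return out[out["expttime"].isin(segs)].drop(columns="baseline").reset_index(drop=True)
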