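"""Synthetic compound nerve action potential (NAP) experiments.

Generates seeded, reproducible datasets with the statistical structure the
downstream analyses assume: a population of axon classes with lognormal
conduction velocities and recruitment thresholds, a biphasic unit kernel,
refractory availability at short inter-stimulus intervals, slow Wallerian
amplitude decline across 30-minute segments, and a non-monotonic
concentration-dependent depression that ramps in after drug onset.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

__all__ = [
    "StimulusProtocol",
    "ExperimentDesign",
    "AxonPopulationModel",
    "DrugEffectModel",
    "WaveformRecord",
    "WaveformDataset",
    "simulate_nap",
    "simulate_experiment",
    "write_dataset",
    "read_dataset",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """The two interleaved seven-stimulus sets delivered each cycle.

    Set 0 ramps the stimulus current at a fixed inter-stimulus interval;
    set 1 holds a supramaximal current and shortens the interval.
    """

    set0_currents: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 6.0, 10.0, 15.0)
    set0_isi: float = 4.0
    set1_current: float = 15.0
    set1_isis: tuple[float, ...] = (166.0, 8.0, 4.0, 3.0, 2.0, 1.5, 1.0)
    sets_per_cycle: int = 2
    cycle_period: float = 8.0

    def __post_init__(self) -> None:
        if len(self.set0_currents) != 7:
            raise InvalidConfigError("set0_currents must have exactly 7 entries")
        if len(self.set1_isis) != 7:
            raise InvalidConfigError("set1_isis must have exactly 7 entries")
        if any(c <= 0 for c in self.set0_currents) or self.set1_current <= 0:
            raise InvalidConfigError("stimulus currents must be positive")
        if any(i <= 0 for i in self.set1_isis) or self.set0_isi <= 0:
            raise InvalidConfigError("inter-stimulus intervals must be positive")
        if list(self.set0_currents) != sorted(set(self.set0_currents)):
            raise InvalidConfigError("set0_currents must be strictly increasing")
        if list(self.set1_isis) != sorted(set(self.set1_isis), reverse=True):
            raise InvalidConfigError("set1_isis must be strictly decreasing")

    def stimulus(self, stim_set: int, seq: int) -> tuple[float, float | None]:
        """Return (current_mA, preceding_isi_ms) for stimulus ``seq`` (1-based).

        The first stimulus of set 0 follows a multi-second gap and has no
        meaningful preceding interval (returned as ``None`` = fully recovered).
        """
        if seq < 1 or seq > 7:
            raise InvalidConfigError(f"seq must be in 1..7, got {seq}")
        if stim_set == 0:
            isi = None if seq == 1 else self.set0_isi
            return self.set0_currents[seq - 1], isi
        if stim_set == 1:
            return self.set1_current, self.set1_isis[seq - 1]
        raise InvalidConfigError(f"stim_set must be 0 or 1, got {stim_set}")


#: default ordinal-concentration map: ordinal -> (molar concentration, n nerves)
DEFAULT_CONC_GROUPS: dict[int, tuple[float, int]] = {
    0: (0.0, 40),
    1: (70e-12, 8),
    2: (700e-12, 8),
    3: (7e-9, 8),
    4: (70e-9, 8),
    5: (700e-9, 8),
    6: (7e-6, 8),
    7: (70e-6, 8),
    8: (700e-6, 16),
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Group sizes, segment schedule and acquisition geometry."""

    conc_groups: Mapping[int, tuple[float, int]] = field(
        default_factory=lambda: dict(DEFAULT_CONC_GROUPS)
    )
    n_segments: int = 36
    drug_onset_segment: int = 4
    baseline_segment: int = 3
    sample_rate: float = 99_000.0
    window_samples: int = 512
    electrode_distance: float = 1.0  # cm

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.drug_onset_segment < 1:
            raise InvalidConfigError("segment counts must be positive")
        if self.sample_rate <= 0 or self.window_samples < 16:
            raise InvalidConfigError("invalid acquisition settings")
        if self.electrode_distance <= 0:
            raise InvalidConfigError("electrode_distance must be positive")
        for conc, (molar, n) in self.conc_groups.items():
            if n <= 0:
                raise InvalidConfigError(f"group {conc} has non-positive size {n}")
            if molar < 0:
                raise InvalidConfigError(f"group {conc} has negative concentration")

    @property
    def n_nerves(self) -> int:
        return sum(n for _, n in self.conc_groups.values())

    @property
    def analysis_segments(self) -> range:
        """Segments entering the statistical analyses (post-onset)."""
        return range(self.drug_onset_segment, self.n_segments + 1)

    def nerve_conc(self) -> dict[int, int]:
        """Map 1-based nerve id -> ordinal concentration, ids assigned in
        ascending ordinal order."""
        out: dict[int, int] = {}
        nid = 1
        for conc in sorted(self.conc_groups):
            for _ in range(self.conc_groups[conc][1]):
                out[nid] = conc
                nid += 1
        return out


@dataclass(frozen=True)
class AxonPopulationModel:
    """Mechanistic knobs of the synthetic nerve.

    An excised nerve is modelled as ``n_classes`` axon classes. Each class
    has a lognormal conduction velocity and recruitment threshold, and
    contributes a biphasic difference-of-Gaussians kernel delayed by
    electrode_distance / velocity. A stimulus recruits the classes whose
    (possibly drug-elevated) threshold it exceeds; a preceding stimulus at
    interval ISI leaves the fraction 1 - exp(-ISI/refractory_tau) available.
    """

    n_classes: int = 30
    velocity_median: float = 40.0  # m/s
    velocity_sigma: float = 0.25  # lognormal shape
    threshold_median: float = 3.0  # mA
    threshold_sigma: float = 0.5
    pos_width: float = 0.10  # ms, positive lobe s.d.
    neg_width: float = 0.22  # ms, negative lobe s.d.
    lobe_ratio: float = 0.55  # negative/positive lobe amplitude, in (0, 1]
    neg_delay: float = 0.30  # ms between lobe centres
    onset_delay: float = 0.30  # ms fixed stimulus-to-response latency offset
    refractory_tau: float = 1.5  # ms
    wallerian_tau: float = 60.0  # segments
    noise_sd: float = 0.02  # fraction of baseline peak-to-peak
    gain_jitter: float = 0.01  # lognormal sigma of per-record gain drift
    latency_jitter: float = 0.02  # ms, per-record onset drift s.d.
    artifact_amplitude: float = 0.5

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise InvalidConfigError("n_classes must be >= 1")
        for name in ("velocity_median", "threshold_median", "pos_width",
                     "neg_width", "neg_delay", "onset_delay", "refractory_tau",
                     "wallerian_tau"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if not 0.0 < self.lobe_ratio <= 1.0:
            raise InvalidConfigError("lobe_ratio must be in (0, 1]")
        if self.noise_sd < 0 or self.gain_jitter < 0 or self.latency_jitter < 0:
            raise InvalidConfigError("noise and jitter magnitudes must be >= 0")

    def availability(self, isi_ms: float | None, refractory_scale: float = 1.0) -> float:
        """Fraction of recruited axons recovered from the preceding stimulus."""
        if isi_ms is None or math.isinf(isi_ms):
            return 1.0
        if isi_ms <= 0:
            raise InvalidConfigError("preceding_isi must be positive")
        return 1.0 - math.exp(-isi_ms / (self.refractory_tau * refractory_scale))


@dataclass(frozen=True)
class DrugEffectModel:
    """Concentration-dependent depression of the compound response.

    ``effect_by_conc`` is the maximal fractional amplitude depression per
    ordinal concentration; the default is non-monotonic with its maximum at
    ordinal 4 and near-zero values at the two highest ordinals. The effect
    ramps in after drug onset along a logistic in segments; full expression
    takes 10-15 segments. Depression is accompanied by a recruitment-
    threshold elevation and a refractory-tau elongation, which makes the
    effect larger at low currents and short inter-stimulus intervals.
    """

    effect_by_conc: Mapping[int, float] = field(
        default_factory=lambda: {
            0: 0.0, 1: 0.08, 2: 0.12, 3: 0.20, 4: 0.30,
            5: 0.22, 6: 0.10, 7: 0.02, 8: 0.0,
        }
    )
    ramp_midpoint: float = 5.0  # segments after onset
    ramp_width: float = 1.8  # segments
    threshold_shift_gain: float = 1.0
    refractory_gain: float = 1.5

    def __post_init__(self) -> None:
        if self.effect_by_conc.get(0, 0.0) != 0.0:
            raise InvalidConfigError("effect_by_conc[0] must be 0 (no-drug group)")
        if self.ramp_width <= 0:
            raise InvalidConfigError("ramp_width must be positive")
        for conc, eff in self.effect_by_conc.items():
            if not 0.0 <= eff < 1.0:
                raise InvalidConfigError(f"effect_by_conc[{conc}] outside [0, 1)")

    def ramp(self, segment: int, onset_segment: int) -> float:
        """Fraction of the maximal effect expressed during ``segment``."""
        if segment < onset_segment:
            return 0.0
        x = (segment - onset_segment - self.ramp_midpoint) / self.ramp_width
        return 1.0 / (1.0 + math.exp(-x))

    def effect(self, conc: int, segment: int, onset_segment: int) -> float:
        return self.effect_by_conc.get(conc, 0.0) * self.ramp(segment, onset_segment)


@dataclass(frozen=True)
class WaveformRecord:
    """One averaged NAP trace with its provenance keys."""

    nerve: int
    conc: int
    expttime: int  # 30-min segment index, 1-based
    stim_set: int  # 0 = increasing current, 1 = decreasing ISI
    seq: int  # position within the 7-stimulus set, 1-based
    samples: np.ndarray


# ---------------------------------------------------------------------------
# internal nerve realization
# ---------------------------------------------------------------------------

class _NerveState:
    """Per-nerve draw from the axon population: velocities, thresholds and
    the fixed (n_classes, window) kernel matrix."""

    def __init__(
        self,
        population: AxonPopulationModel,
        rng: np.random.Generator,
        *,
        sample_rate: float,
        window_samples: int,
        electrode_distance: float,
    ) -> None:
        self.population = population
        n = population.n_classes
        self.velocities = population.velocity_median * np.exp(
            population.velocity_sigma * rng.standard_normal(n)
        )
        self.thresholds = population.threshold_median * np.exp(
            population.threshold_sigma * rng.standard_normal(n)
        )
        t_ms = np.arange(window_samples) / sample_rate * 1e3
        # arrival delay over electrode_distance cm at v m/s, in ms, plus a
        # fixed onset offset that keeps the pre-response baseline clean
        delay = population.onset_delay + 10.0 * electrode_distance / self.velocities
        dt = t_ms[None, :] - delay[:, None]
        pos = np.exp(-0.5 * (dt / population.pos_width) ** 2)
        neg = np.exp(-0.5 * ((dt - population.neg_delay) / population.neg_width) ** 2)
        self.kernels = (pos - population.lobe_ratio * neg) / n
        # reference supramaximal response sets the noise scale
        ref = self.kernels.sum(axis=0)
        self.baseline_pp = float(ref.max() - ref.min())

    def recruited(self, current: float, threshold_scale: float) -> np.ndarray:
        return (self.thresholds * threshold_scale <= current).astype(float)

    def compound(
        self,
        current: float,
        preceding_isi: float | None,
        amplitude_scale: float,
        threshold_scale: float,
        refractory_scale: float = 1.0,
    ) -> np.ndarray:
        avail = self.population.availability(preceding_isi, refractory_scale)
        w = self.recruited(current, threshold_scale) * avail * amplitude_scale
        return w @ self.kernels


def _artifact(window_samples: int, amplitude: float, current: float) -> np.ndarray:
    """Deterministic damped oscillation confined to samples 0-9."""
    out = np.zeros(window_samples)
    i = np.arange(10)
    out[:10] = amplitude * (current / 15.0) * np.exp(-i / 3.0) * np.cos(np.pi * i / 2.0)
    return out


def _apply_drift(
    block: np.ndarray,
    population: AxonPopulationModel,
    rng: np.random.Generator,
    sample_rate: float,
) -> np.ndarray:
    """Per-record physiological drift: a small lognormal gain factor and a
    fractional-sample onset shift (linear resampling). Emulates the slow
    perfusion/electrode variability of real sweep averages; without it the
    segment-mean features would be implausibly quantized."""
    if population.gain_jitter == 0 and population.latency_jitter == 0:
        return block
    n_rec, width = block.shape
    gains = np.exp(population.gain_jitter * rng.standard_normal(n_rec))
    shifts = (population.latency_jitter * sample_rate / 1e3
              * rng.standard_normal(n_rec))
    idx = np.arange(width)
    out = np.empty_like(block)
    for i in range(n_rec):
        if shifts[i] != 0.0:
            out[i] = gains[i] * np.interp(idx - shifts[i], idx, block[i])
        else:
            out[i] = gains[i] * block[i]
    return out


def _nerve_rng(root_seed: int, nerve: int) -> np.random.Generator:
    # fixed per-nerve stream: reproducible regardless of simulation order
    return np.random.default_rng(np.random.SeedSequence((int(root_seed), int(nerve))))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_nap(
    population: AxonPopulationModel,
    current: float,
    preceding_isi: float | None,
    amplitude_scale: float = 1.0,
    threshold_scale: float = 1.0,
    rng_seed: int = 0,
    *,
    refractory_scale: float = 1.0,
    sample_rate: float = 99_000.0,
    window_samples: int = 512,
    electrode_distance: float = 1.0,
) -> np.ndarray:
    """Simulate a single averaged NAP trace.

    Draws one nerve realization from ``population`` (deterministically from
    ``rng_seed``) and returns the compound waveform: recruited axon classes,
    scaled by refractory availability at ``preceding_isi`` and by
    ``amplitude_scale``, plus a stimulus artifact in samples 0-9 and
    additive Gaussian noise.
    """
    if current <= 0:
        raise InvalidConfigError("current must be positive")
    if preceding_isi is not None and not math.isinf(preceding_isi) and preceding_isi <= 0:
        raise InvalidConfigError("preceding_isi must be positive")
    rng = np.random.default_rng(rng_seed)
    state = _NerveState(
        population, rng,
        sample_rate=sample_rate,
        window_samples=window_samples,
        electrode_distance=electrode_distance,
    )
    samples = state.compound(
        current, preceding_isi, amplitude_scale, threshold_scale, refractory_scale
    )
    samples = _apply_drift(samples[None, :], population, rng, sample_rate)[0]
    samples = samples + _artifact(window_samples, population.artifact_amplitude, current)
    if population.noise_sd > 0:
        samples = samples + (
            population.noise_sd * state.baseline_pp * rng.standard_normal(window_samples)
        )
    return samples


class WaveformDataset:
    """A collection of waveform records stored as a key table plus a dense
    (n_records, window_samples) sample matrix."""

    KEY_COLUMNS = ["nerve", "conc", "expttime", "stim_set", "seq"]

    def __init__(self, keys: pd.DataFrame, samples: np.ndarray,
                 design: ExperimentDesign | None = None) -> None:
        if len(keys) != samples.shape[0]:
            raise InvalidConfigError("keys and samples disagree in length")
        self.keys = keys.reset_index(drop=True)
        self.samples = np.asarray(samples, dtype=float)
        self.design = design

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def window_samples(self) -> int:
        return self.samples.shape[1]

    def records(self) -> Iterator[WaveformRecord]:
        for i, row in enumerate(self.keys.itertuples(index=False)):
            yield WaveformRecord(
                nerve=int(row.nerve), conc=int(row.conc), expttime=int(row.expttime),
                stim_set=int(row.stim_set), seq=int(row.seq), samples=self.samples[i],
            )

    def select(self, **conditions: object) -> "WaveformDataset":
        """Subset by equality (scalar) or membership (list/tuple/set) on key
        columns, e.g. ``select(stim_set=1, expttime=[3, 36])``."""
        mask = np.ones(len(self.keys), dtype=bool)
        for col, val in conditions.items():
            if col not in self.KEY_COLUMNS:
                raise InvalidConfigError(f"unknown key column {col!r}")
            if isinstance(val, (list, tuple, set, range, np.ndarray)):
                mask &= self.keys[col].isin(list(val)).to_numpy()
            else:
                mask &= (self.keys[col] == val).to_numpy()
        return WaveformDataset(self.keys[mask], self.samples[mask], self.design)

    def get(self, nerve: int, expttime: int, stim_set: int, seq: int) -> np.ndarray:
        sub = self.select(nerve=nerve, expttime=expttime, stim_set=stim_set, seq=seq)
        if len(sub) != 1:
            raise InvalidConfigError(
                f"expected exactly one record for nerve={nerve}, expttime={expttime}, "
                f"stim_set={stim_set}, seq={seq}; found {len(sub)}"
            )
        return sub.samples[0]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (record, sample_index)."""
        n_rec, width = self.samples.shape
        keys = self.keys.loc[self.keys.index.repeat(width)].reset_index(drop=True)
        keys["sample_index"] = np.tile(np.arange(width), n_rec)
        keys["voltage"] = self.samples.ravel()
        return keys


def simulate_experiment(
    design: ExperimentDesign,
    protocol: StimulusProtocol,
    population: AxonPopulationModel,
    drug: DrugEffectModel,
    rng_seed: int = 0,
    *,
    segments: Sequence[int] | None = None,
    stim_sets: Sequence[int] = (0, 1),
    seqs: Sequence[int] = (1, 2, 3, 4, 5, 6, 7),
    nerves: Sequence[int] | None = None,
) -> WaveformDataset:
    """Simulate one segment-mean waveform per (nerve, segment, set, seq).

    Per-segment amplitude scale is ``exp(-(j-1)/wallerian_tau) *
    (1 - effect_by_conc(conc) * ramp(j))``; the drug additionally elevates
    recruitment thresholds and elongates the refractory time constant.
    ``segments``/``stim_sets``/``seqs``/``nerves`` restrict the simulated
    subset (used to scale Monte-Carlo studies down).
    """
    seg_list = list(segments) if segments is not None else list(range(1, design.n_segments + 1))
    if any(j < 1 or j > design.n_segments for j in seg_list):
        raise InvalidConfigError("segments outside 1..n_segments")
    combos = [
        (j, l, k)
        for j in seg_list
        for l in stim_sets
        for k in seqs
    ]
    stim_lookup = {(l, k): protocol.stimulus(l, k) for l in stim_sets for k in seqs}

    nerve_conc = design.nerve_conc()
    nerve_ids = list(nerves) if nerves is not None else sorted(nerve_conc)
    for n in nerve_ids:
        if n not in nerve_conc:
            raise InvalidConfigError(f"unknown nerve id {n}")

    n_combo = len(combos)
    j_arr = np.array([j for j, _, _ in combos])
    current_arr = np.array([stim_lookup[(l, k)][0] for _, l, k in combos])
    isi_arr = np.array([
        np.inf if stim_lookup[(l, k)][1] is None else stim_lookup[(l, k)][1]
        for _, l, k in combos
    ])
    wallerian = np.exp(-(j_arr - 1) / population.wallerian_tau)
    ramp_arr = np.array([
        drug.ramp(j, design.drug_onset_segment) for j in j_arr
    ])
    artifacts = np.stack([
        _artifact(design.window_samples, population.artifact_amplitude, c)
        for c in current_arr
    ])

    all_keys: list[pd.DataFrame] = []
    blocks: list[np.ndarray] = []
    for nerve in nerve_ids:
        conc = nerve_conc[nerve]
        rng = _nerve_rng(rng_seed, nerve)
        state = _NerveState(
            population, rng,
            sample_rate=design.sample_rate,
            window_samples=design.window_samples,
            electrode_distance=design.electrode_distance,
        )
        eff = drug.effect_by_conc.get(conc, 0.0) * ramp_arr  # (n_combo,)
        amp = wallerian * (1.0 - eff)
        thr_scale = 1.0 + drug.threshold_shift_gain * eff
        refr_scale = 1.0 + drug.refractory_gain * eff
        avail = np.where(
            np.isinf(isi_arr), 1.0,
            1.0 - np.exp(-isi_arr / (population.refractory_tau * refr_scale)),
        )
        recruited = (
            state.thresholds[None, :] * thr_scale[:, None] <= current_arr[:, None]
        ).astype(float)
        weights = recruited * (avail * amp)[:, None]
        block = weights @ state.kernels
        block = _apply_drift(block, population, rng, design.sample_rate)
        block = block + artifacts
        if population.noise_sd > 0:
            block += (
                population.noise_sd * state.baseline_pp
                * rng.standard_normal(block.shape)
            )
        blocks.append(block)
        all_keys.append(pd.DataFrame({
            "nerve": nerve,
            "conc": conc,
            "expttime": j_arr,
            "stim_set": [l for _, l, _ in combos],
            "seq": [k for _, _, k in combos],
        }))

    keys = pd.concat(all_keys, ignore_index=True)
    return WaveformDataset(keys, np.vstack(blocks), design)


def write_dataset(
    dataset: WaveformDataset,
    path: str | os.PathLike,
    *,
    config: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> None:
    """Write the long-format CSV plus a JSON sidecar echoing config and seed."""
    if len(dataset) == 0:
        raise InvalidConfigError("refusing to write an empty dataset")
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "seed": seed,
        "n_records": len(dataset),
        "window_samples": dataset.window_samples,
        "config": _jsonable(config) if config is not None else None,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_dataset(path: str | os.PathLike) -> WaveformDataset:
    """Read a long-format CSV written by :func:`write_dataset`."""
    frame = pd.read_csv(path)
    required = set(WaveformDataset.KEY_COLUMNS) | {"sample_index", "voltage"}
    missing = required - set(frame.columns)
    if missing:
        raise InvalidConfigError(f"dataset file missing columns: {sorted(missing)}")
    frame = frame.sort_values(
        WaveformDataset.KEY_COLUMNS + ["sample_index"], kind="stable"
    )
    width = int(frame["sample_index"].max()) + 1
    if len(frame) % width:
        raise InvalidConfigError("dataset rows do not tile into fixed-width records")
    keys = frame[WaveformDataset.KEY_COLUMNS].iloc[::width].reset_index(drop=True)
    samples = frame["voltage"].to_numpy().reshape(-1, width)
    return WaveformDataset(keys, samples)


def _jsonable(obj: object) -> object:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
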