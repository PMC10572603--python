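"""Waveform normalization against an exemplar template.

Each nerve's trace is matched to the template by a four-parameter
transform — amplitude scale ``a``, time-scale ``b``, latency shift ``c``
(samples) and voltage offset ``d`` — fitted once per (nerve, seq, set) on
the first-segment waveform and then applied unchanged to every segment.
The fit minimizes a weighted mean-square difference whose weights vanish
over the stimulus-artifact samples and taper away over the late tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import (
    FitFailureError,
    InvalidConfigError,
    UnregistrableRecordError,
)
from .simulate import WaveformDataset

__all__ = [
    "WeightVector",
    "RegistrationParams",
    "build_weights",
    "transform",
    "objective",
    "fit",
    "register_experiment",
]


@dataclass(frozen=True)
class WeightVector:
    values: np.ndarray
    zero_prefix: int
    plateau_end: int
    taper_tau: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RegistrationParams:
    a: float  # amplitude scale
    b: float  # duration (time-scale) index
    c: float  # latency shift, samples
    d: float  # voltage offset
    objective: float = math.nan
    nerve: int | None = None
    stim_set: int | None = None
    seq: int | None = None

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise InvalidConfigError("a and b must be positive")


def build_weights(
    window_samples: int,
    zero_prefix: int = 10,
    plateau_end: int = 100,
    taper_tau: float = 20.0,
) -> WeightVector:
    """Zero over the artifact prefix, one over the main response, then an
    exponential taper ``exp(-(i - plateau_end)/taper_tau)``."""
    if not 0 <= zero_prefix < plateau_end < window_samples:
        raise InvalidConfigError(
            "require 0 <= zero_prefix < plateau_end < window_samples"
        )
    if taper_tau <= 0:
        raise InvalidConfigError("taper_tau must be positive")
    i = np.arange(window_samples, dtype=float)
    v = np.ones(window_samples)
    v[:zero_prefix] = 0.0
    tail = i >= plateau_end
    v[tail] = np.exp(-(i[tail] - plateau_end) / taper_tau)
    return WeightVector(v, zero_prefix, plateau_end, taper_tau)


def transform(samples: np.ndarray, params: RegistrationParams) -> np.ndarray:
    """Apply ``out(i) = a * samples(b*i + c) - d`` with linear interpolation;
    queries outside the window clamp to the edge values."""
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    query = params.b * np.arange(n) + params.c
    return params.a * np.interp(query, np.arange(n), samples) - params.d


def objective(
    params: RegistrationParams,
    waveform: np.ndarray,
    template: np.ndarray,
    weights: WeightVector | np.ndarray,
) -> float:
    """Weighted mean-square difference between the transformed waveform and
    the template (divided by the number of points)."""
    w = weights.values if isinstance(weights, WeightVector) else np.asarray(weights)
    waveform = np.asarray(waveform, dtype=float)
    template = np.asarray(template, dtype=float)
    if not len(waveform) == len(template) == len(w):
        raise InvalidConfigError("waveform, template and weights must share a length")
    diff = transform(waveform, params) - template
    return float(np.sum(w * diff * diff) / len(w))


def _peak_to_peak(x: np.ndarray, skip: int = 10) -> float:
    body = np.asarray(x, dtype=float)[skip:]
    return float(body.max() - body.min())


def fit(
    waveform: np.ndarray,
    template: np.ndarray,
    weights: WeightVector | np.ndarray,
    init: RegistrationParams | None = None,
    *,
    ftol: float = 1e-10,
    max_iter: int = 500,
) -> RegistrationParams:
    """Fit (a, b, c, d) by Nelder-Mead simplex minimization of
    :func:`objective`.

    Initialized at a = pp(template)/pp(waveform), b = 1, c = 0 and d
    matching the early-baseline offset; converges on relative objective
    change below ``ftol`` or ``max_iter`` iterations.
    """
    waveform = np.asarray(waveform, dtype=float)
    template = np.asarray(template, dtype=float)
    w = weights.values if isinstance(weights, WeightVector) else np.asarray(weights)
    pp = _peak_to_peak(waveform)
    if pp == 0:
        raise UnregistrableRecordError("waveform has zero peak-to-peak amplitude")
    if init is None:
        a0 = _peak_to_peak(template) / pp
        base_w = float(np.mean(waveform[10:20]))
        base_t = float(np.mean(template[10:20]))
        init = RegistrationParams(a=a0, b=1.0, c=0.0, d=a0 * base_w - base_t)

    def cost(x: np.ndarray) -> float:
        a, b, c, d = x
        if a <= 0 or b <= 0:
            return np.inf
        diff = a * np.interp(
            b * np.arange(len(waveform)) + c, np.arange(len(waveform)), waveform
        ) - d - template
        return float(np.sum(w * diff * diff) / len(w))

    res = minimize(
        cost,
        x0=[init.a, init.b, init.c, init.d],
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "fatol": ftol * max(cost([init.a, init.b, init.c, init.d]), 1e-30),
            "xatol": 1e-8,
        },
    )
    a, b, c, d = res.x
    value = float(res.fun)
    if not np.isfinite(value):
        raise FitFailureError("non-finite objective at optimum")
    if a <= 0 or b <= 0:
        raise FitFailureError(f"optimizer left the valid domain: a={a}, b={b}")
    return RegistrationParams(a=float(a), b=float(b), c=float(c), d=float(d),
                              objective=value)


def register_experiment(
    dataset: WaveformDataset,
    template_nerve: int | None = None,
    *,
    fit_segment: int = 1,
    weights: WeightVector | None = None,
    ftol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[WaveformDataset, pd.DataFrame]:
    """Register every nerve of a dataset against an exemplar nerve.

    For each (nerve, set, seq), the transform is fitted on the
    ``fit_segment`` waveform against the exemplar's ``fit_segment``
    waveform for the same stimulus, then applied to all segments of that
    key. Returns the registered dataset and a parameter table with columns
    nerve, stim_set, seq, a, b, c, d, objective.
    """
    if weights is None:
        weights = build_weights(dataset.window_samples)
    nerve_ids = sorted(dataset.keys["nerve"].unique())
    if template_nerve is None:
        template_nerve = nerve_ids[0]  # arbitrary exemplar: first nerve id
    if template_nerve not in nerve_ids:
        raise InvalidConfigError(f"template nerve {template_nerve} not in dataset")

    combos = (
        dataset.keys[["stim_set", "seq"]].drop_duplicates().itertuples(index=False)
    )
    registered = dataset.samples.copy()
    param_rows: list[dict[str, float]] = []
    for stim_set, seq in combos:
        template = dataset.get(template_nerve, fit_segment, stim_set, seq)
        for nerve in nerve_ids:
            trace = dataset.get(nerve, fit_segment, stim_set, seq)
            params = fit(trace, template, weights, ftol=ftol, max_iter=max_iter)
            param_rows.append({
                "nerve": nerve, "stim_set": stim_set, "seq": seq,
                "a": params.a, "b": params.b, "c": params.c, "d": params.d,
                "objective": params.objective,
            })
            mask = (
                (dataset.keys["nerve"] == nerve)
                & (dataset.keys["stim_set"] == stim_set)
                & (dataset.keys["seq"] == seq)
            ).to_numpy()
            for idx in np.flatnonzero(mask):
                registered[idx] = transform(dataset.samples[idx], params)
    out = WaveformDataset(dataset.keys.copy(), registered, dataset.design)
    return out, pd.DataFrame(param_rows)
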