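"""Pointwise analysis of registered NAP waveforms.

Correlates the voltage at every waveform time point with the ordinal drug
concentration across nerves (Spearman), applies raw-p and BH-FDR
significance masks, compares the |R| profile with the template voltage
profile, and tests whether significant points cluster at particular
latencies with a chi-square over time bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import InsufficientDataError, InvalidConfigError
from .param_stats import Chi2Result, StatsConfig, bh_fdr
from .simulate import WaveformDataset

__all__ = [
    "CorrelationMap",
    "ProfileCorrelation",
    "pointwise_spearman_arrays",
    "pointwise_spearman",
    "r_vs_voltage_profile",
    "timepoint_chi2",
]


@dataclass(frozen=True)
class CorrelationMap:
    """Per-sample Spearman R/p against concentration for one
    (set, seq, expttime) slice, with significance masks."""

    stim_set: int
    seq: int
    expttime: int
    n_nerves: int
    conc_subset: tuple[int, ...]
    rho: np.ndarray
    p: np.ndarray
    sig_raw: np.ndarray
    sig_fdr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stim_set": self.stim_set,
            "seq": self.seq,
            "expttime": self.expttime,
            "sample": np.arange(len(self.rho)),
            "rho": self.rho,
            "p": self.p,
            "sig_raw": self.sig_raw,
            "sig_fdr": self.sig_fdr,
        })


class ProfileCorrelation(NamedTuple):
    rho: float
    p: float
    n_points: int


def pointwise_spearman_arrays(
    voltages: np.ndarray, conc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman rank correlation of each column of ``voltages``
    (nerves x samples) against ``conc`` (nerves,).

    Uses mid-ranks for ties and the t-distribution approximation for the
    p-value (the same approximation scipy uses). Columns with zero rank
    variance come back NaN.
    """
    voltages = np.asarray(voltages, dtype=float)
    conc = np.asarray(conc, dtype=float)
    n = len(conc)
    if voltages.shape[0] != n:
        raise InvalidConfigError("voltages rows must match conc length")
    if n < 3:
        raise InsufficientDataError("need >= 3 nerves for a correlation")
    rv = sps.rankdata(voltages, axis=0)
    rc = sps.rankdata(conc)
    rv = rv - rv.mean(axis=0)
    rc = rc - rc.mean()
    denom = np.sqrt((rv**2).sum(axis=0) * (rc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, (rv * rc[:, None]).sum(axis=0) / denom, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(
        np.isnan(rho), np.nan,
        np.where(np.abs(rho) == 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), n - 2)),
    )
    return rho, p


def pointwise_spearman(
    registered: WaveformDataset,
    stim_set: int,
    seq: int,
    expttime: int,
    cfg: StatsConfig = StatsConfig(),
) -> CorrelationMap:
    """Correlation map for one slice of a registered dataset, restricted to
    the configured low-concentration subset."""
    sub = registered.select(stim_set=stim_set, seq=seq, expttime=expttime)
    sub = WaveformDataset(
        sub.keys[sub.keys["conc"] <= cfg.conc_subset_max_ordinal],
        sub.samples[(sub.keys["conc"] <= cfg.conc_subset_max_ordinal).to_numpy()],
        sub.design,
    )
    conc = sub.keys["conc"].to_numpy()
    if len(np.unique(conc)) < 3:
        raise InsufficientDataError("need >= 3 distinct concentration groups")
    rho, p = pointwise_spearman_arrays(sub.samples, conc)
    sig_raw = np.where(np.isfinite(p), p < cfg.raw_p_threshold, False)
    sig_fdr = bh_fdr(p, cfg.fdr_q)
    return CorrelationMap(
        stim_set=stim_set, seq=seq, expttime=expttime, n_nerves=len(conc),
        conc_subset=tuple(sorted(np.unique(conc).astype(int))),
        rho=rho, p=p, sig_raw=sig_raw, sig_fdr=sig_fdr,
    )


def r_vs_voltage_profile(
    cmap: CorrelationMap,
    template: np.ndarray,
    *,
    use_abs: bool = True,
    skip_samples: int = 10,
    weights: np.ndarray | None = None,
    min_weight: float = 0.05,
) -> ProfileCorrelation:
    """Spearman correlation between the per-sample |R| profile and the
    template voltage profile (artifact samples excluded).

    A multiplicative (amplitude-only) drug effect makes the two profiles
    agree; shape-changing effects break the agreement. When ``weights``
    (the registration weight vector) is given, the comparison is restricted
    to samples with weight >= ``min_weight`` — the part of the window that
    actually carries the response — so the long noise-ranked tail cannot
    dilute the correlation. ``use_abs=False`` correlates signed R with the
    template instead.
    """
    template = np.asarray(template, dtype=float)
    if len(template) != len(cmap.rho):
        raise InvalidConfigError("template length must match the correlation map")
    r = np.abs(cmap.rho) if use_abs else cmap.rho
    r = r[skip_samples:]
    v = np.abs(template[skip_samples:]) if use_abs else template[skip_samples:]
    ok = np.isfinite(r) & np.isfinite(v)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(cmap.rho):
            raise InvalidConfigError("weights length must match the correlation map")
        ok &= w[skip_samples:] >= min_weight
    if ok.sum() < 3:
        raise InsufficientDataError("fewer than 3 defined profile points")
    if np.ptp(r[ok]) == 0 or np.ptp(v[ok]) == 0:
        raise InsufficientDataError("constant profile: correlation undefined")
    res = sps.spearmanr(r[ok], v[ok])
    return ProfileCorrelation(float(res.statistic), float(res.pvalue), int(ok.sum()))


def timepoint_chi2(
    sig_counts: np.ndarray,
    *,
    n_bins: int = 8,
    skip_samples: int = 10,
    min_expected: float = 5.0,
) -> tuple[Chi2Result, np.ndarray]:
    """Goodness-of-fit chi-square of significant-count uniformity over time
    bins.

    ``sig_counts[i]`` counts the EXPTTIME values with p below threshold at
    sample i. Post-artifact samples are split into ``n_bins`` equal-width
    bins; adjacent bins are merged until every expected count reaches
    ``min_expected``. Returns the test and the binned counts.
    """
    sig_counts = np.asarray(sig_counts, dtype=float)
    body = sig_counts[skip_samples:]
    total = body.sum()
    if total == 0:
        return Chi2Result(math.nan, 0, math.nan, applicable=False), np.array([])
    edges = np.linspace(0, len(body), n_bins + 1).astype(int)
    binned = np.array([body[lo:hi].sum() for lo, hi in zip(edges[:-1], edges[1:])])
    # merge adjacent bins until expected count per bin >= min_expected
    while len(binned) > 1 and total / len(binned) < min_expected:
        i = int(np.argmin(binned))
        j = i - 1 if i > 0 else 1
        merged = binned[min(i, j)] + binned[max(i, j)]
        binned = np.delete(binned, max(i, j))
        binned[min(i, j)] = merged
    if len(binned) < 2:
        raise InsufficientDataError("chi-square needs >= 2 time bins (df >= 1)")
    stat, p = sps.chisquare(binned)
    return Chi2Result(float(stat), len(binned) - 1, float(p), applicable=True), binned


def correlation_maps(
    registered: WaveformDataset,
    stim_set: int,
    seq: int,
    expttimes: Sequence[int],
    cfg: StatsConfig = StatsConfig(),
) -> list[CorrelationMap]:
    """Correlation maps across several segments for one stimulus."""
    return [
        pointwise_spearman(registered, stim_set, seq, j, cfg) for j in expttimes
    ]


def significance_count_profile(maps: Sequence[CorrelationMap]) -> np.ndarray:
    """Per-sample count, over segments, of raw-p significant correlations."""
    if not maps:
        raise InsufficientDataError("no correlation maps supplied")
    return np.sum([m.sig_raw for m in maps], axis=0)
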