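"""Statistics on the abstracted NAP parameters.

Endpoint concentration-effect tests (one-way ANOVA with Bonferroni-
corrected levels, confirmatory Kruskal-Wallis, quadratic regression on the
ordinal concentration), balanced split-plot repeated-measures ANOVA,
Benjamini-Hochberg step-up FDR over Spearman screens, and significance-
count tables with a chi-square test of parameter-by-stimulus independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .errors import InsufficientDataError, InvalidConfigError, UnbalancedPanelError
from .features import PARAMETERS

__all__ = [
    "StatsConfig",
    "AnovaResult",
    "KruskalResult",
    "Chi2Result",
    "CountTableResult",
    "endpoint_anova",
    "endpoint_kruskal",
    "quadratic_regression",
    "repeated_measures",
    "bh_fdr",
    "spearman_screen",
    "build_count_table",
]


@dataclass(frozen=True)
class StatsConfig:
    family_alpha_anova: float = 0.05
    n_tests: int = 12
    family_alpha_kw: float = 0.1
    fdr_q: float = 0.05
    raw_p_threshold: float = 0.01
    conc_subset_max_ordinal: int = 4  # correlation analyses use CONC <= this

    def __post_init__(self) -> None:
        for name in ("family_alpha_anova", "family_alpha_kw", "fdr_q",
                     "raw_p_threshold"):
            if not 0 < getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must lie in (0, 1)")
        if self.n_tests < 1:
            raise InvalidConfigError("n_tests must be >= 1")

    @property
    def per_test_alpha_anova(self) -> float:
        """Bonferroni per-test level for the endpoint ANOVAs."""
        return self.family_alpha_anova / self.n_tests

    @property
    def per_test_alpha_kw(self) -> float:
        """Per-test level for the confirmatory Kruskal-Wallis tests."""
        return self.family_alpha_kw / self.n_tests


class AnovaResult(NamedTuple):
    F: float
    df_between: int
    df_within: int
    p: float


class KruskalResult(NamedTuple):
    H: float
    df: int
    p: float


class Chi2Result(NamedTuple):
    chi2: float
    df: int
    p: float
    applicable: bool = True


class CountTableResult(NamedTuple):
    counts: pd.DataFrame  # parameters x seq
    chi2: Chi2Result
    significance: str  # "fdr" or "raw_p"


def _endpoint_groups(
    table: pd.DataFrame,
    parameter: str,
    expttime: int,
    seq: int,
    stim_set: int,
) -> list[np.ndarray]:
    sub = table[
        (table["parameter"] == parameter)
        & (table["expttime"] == expttime)
        & (table["seq"] == seq)
        & (table["stim_set"] == stim_set)
    ]
    groups = [
        g["normalized_value"].dropna().to_numpy()
        for _, g in sub.groupby("conc")
    ]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError(
            "endpoint test needs >= 2 groups with >= 2 observations each"
        )
    return groups


def endpoint_anova(
    table: pd.DataFrame,
    parameter: str,
    expttime: int = 36,
    seq: int = 1,
    stim_set: int = 1,
) -> AnovaResult:
    """One-way fixed-effects ANOVA of a normalized parameter across the
    concentration groups at one (endpoint) stimulus."""
    groups = _endpoint_groups(table, parameter, expttime, seq, stim_set)
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return AnovaResult(float(f), k - 1, n - k, float(p))


def endpoint_kruskal(
    table: pd.DataFrame,
    parameter: str,
    expttime: int = 36,
    seq: int = 1,
    stim_set: int = 1,
) -> KruskalResult:
    """Confirmatory rank-based Kruskal-Wallis across concentration groups."""
    groups = _endpoint_groups(table, parameter, expttime, seq, stim_set)
    h, p = sps.kruskal(*groups)
    return KruskalResult(float(h), len(groups) - 1, float(p))


def quadratic_regression(
    table: pd.DataFrame,
    parameter: str,
    expttime: int = 36,
    seq: int = 1,
    stim_set: int = 1,
) -> pd.DataFrame:
    """OLS of the normalized parameter on the ordinal concentration and its
    square; returns a coefficient table (term, coef, se, t, p)."""
    sub = table[
        (table["parameter"] == parameter)
        & (table["expttime"] == expttime)
        & (table["seq"] == seq)
        & (table["stim_set"] == stim_set)
    ].dropna(subset=["normalized_value"])
    if len(sub) < 4:
        raise InsufficientDataError("quadratic regression needs >= 4 observations")
    conc = sub["conc"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(conc), conc, conc**2])
    if np.linalg.matrix_rank(X) < 3:
        raise InsufficientDataError("design matrix is rank deficient")
    model = sm.OLS(sub["normalized_value"].to_numpy(), X).fit()
    return pd.DataFrame({
        "term": ["intercept", "conc", "conc_sq"],
        "coef": model.params,
        "se": model.bse,
        "t": model.tvalues,
        "p": model.pvalues,
    })


# ---------------------------------------------------------------------------
# split-plot repeated measures
# ---------------------------------------------------------------------------

def _panel_array(
    sub: pd.DataFrame, within_a: str, within_b: str
) -> tuple[np.ndarray, np.ndarray, list, list, list]:
    """Pivot a long table into (subjects, A-levels, B-levels) with a group
    label per subject; raise if any cell is missing or duplicated."""
    a_levels = sorted(sub[within_a].unique())
    b_levels = sorted(sub[within_b].unique())
    subjects = sorted(sub["nerve"].unique())
    pivot = sub.pivot_table(
        index="nerve", columns=[within_a, within_b], values="normalized_value",
        aggfunc="count", fill_value=0,
    )
    if (pivot.to_numpy() != 1).any() or pivot.shape[1] != len(a_levels) * len(b_levels):
        raise UnbalancedPanelError(
            "repeated-measures panel is incomplete or has duplicate cells"
        )
    wide = sub.pivot_table(
        index="nerve", columns=[within_a, within_b], values="normalized_value"
    )
    cols = pd.MultiIndex.from_product([a_levels, b_levels])
    y = wide[cols].to_numpy().reshape(len(subjects), len(a_levels), len(b_levels))
    if not np.all(np.isfinite(y)):
        raise UnbalancedPanelError("missing values in the repeated-measures panel")
    group_of = sub.drop_duplicates("nerve").set_index("nerve")["conc"]
    groups = group_of.loc[subjects].to_numpy()
    return y, groups, subjects, a_levels, b_levels


def repeated_measures(
    table: pd.DataFrame,
    within_factor: str,
    parameter: str = "peak_to_peak_amplitude",
    cfg: StatsConfig = StatsConfig(),
    *,
    protocol_levels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Split-plot ANOVA: concentration group between subjects, segment
    (EXPTTIME) and the stimulus factor within subjects.

    ``within_factor`` is ``"isi"`` (stimulus set 1, all 7 positions) or
    ``"current"`` (stimulus set 0; the lowest, frequently sub-threshold
    current is dropped, leaving 6 levels). Concentrations are restricted to
    the configured low-concentration subset. Requires a complete panel —
    unbalanced data raise rather than being imputed.

    Returns an ANOVA table with one row per effect: conc, expttime,
    within, and all interactions, with sum_sq, df, F and p; each within-
    stratum effect is tested against its own subject-interaction error.
    """
    if within_factor == "isi":
        stim_set, seqs = 1, list(range(1, 8))
    elif within_factor == "current":
        stim_set, seqs = 0, list(range(2, 8))
    else:
        raise InvalidConfigError("within_factor must be 'isi' or 'current'")
    if protocol_levels is not None:
        seqs = list(protocol_levels)
    if len(seqs) < 2:
        raise InsufficientDataError("within factor needs >= 2 levels")

    sub = table[
        (table["parameter"] == parameter)
        & (table["stim_set"] == stim_set)
        & (table["seq"].isin(seqs))
        & (table["conc"] <= cfg.conc_subset_max_ordinal)
    ]
    if sub.empty:
        raise InsufficientDataError("no data after subsetting")
    y, groups, _, a_levels, b_levels = _panel_array(sub, "expttime", "seq")
    if len(a_levels) < 2:
        raise InsufficientDataError("need >= 2 EXPTTIME levels")

    n_subj, p, q = y.shape
    uniq, gidx = np.unique(groups, return_inverse=True)
    G = len(uniq)
    if G < 2:
        raise InsufficientDataError("need >= 2 concentration groups")
    n_g = np.bincount(gidx)

    m = y.mean()
    subj_mean = y.mean(axis=(1, 2))  # (n_subj,)
    grp_mean = np.array([subj_mean[gidx == g].mean() for g in range(G)])
    ya = y.mean(axis=(0, 2))  # (p,)
    yb = y.mean(axis=(0, 1))  # (q,)
    yab = y.mean(axis=0)  # (p, q)
    yga = np.stack([y[gidx == g].mean(axis=(0, 2)) for g in range(G)])  # (G,p)
    ygb = np.stack([y[gidx == g].mean(axis=(0, 1)) for g in range(G)])  # (G,q)
    ygab = np.stack([y[gidx == g].mean(axis=0) for g in range(G)])  # (G,p,q)
    ysa = y.mean(axis=2)  # (n_subj, p)
    ysb = y.mean(axis=1)  # (n_subj, q)

    ss = {}
    ss["conc"] = p * q * float(np.sum(n_g * (grp_mean - m) ** 2))
    ss["subject"] = p * q * float(np.sum((subj_mean - grp_mean[gidx]) ** 2))
    ss["expttime"] = n_subj * q * float(np.sum((ya - m) ** 2))
    ss["conc:expttime"] = q * float(
        np.sum(n_g[:, None] * (yga - grp_mean[:, None] - ya[None, :] + m) ** 2)
    )
    ss["expttime:subject"] = q * float(
        np.sum((ysa - subj_mean[:, None] - yga[gidx] + grp_mean[gidx, None]) ** 2)
    )
    ss["within"] = n_subj * p * float(np.sum((yb - m) ** 2))
    ss["conc:within"] = p * float(
        np.sum(n_g[:, None] * (ygb - grp_mean[:, None] - yb[None, :] + m) ** 2)
    )
    ss["within:subject"] = p * float(
        np.sum((ysb - subj_mean[:, None] - ygb[gidx] + grp_mean[gidx, None]) ** 2)
    )
    ab_dev = yab - ya[:, None] - yb[None, :] + m
    ss["expttime:within"] = n_subj * float(np.sum(ab_dev**2))
    gab_dev = (
        ygab - yga[:, :, None] - ygb[:, None, :] + grp_mean[:, None, None]
        - ab_dev[None, :, :]
    )
    ss["conc:expttime:within"] = float(np.sum(n_g[:, None, None] * gab_dev**2))
    resid = (
        y - ysa[:, :, None] - ysb[:, None, :] + subj_mean[:, None, None]
        - (ygab - yga[:, :, None] - ygb[:, None, :] + grp_mean[:, None, None])[gidx]
    )
    ss["residual"] = float(np.sum(resid**2))

    df = {
        "conc": G - 1,
        "subject": n_subj - G,
        "expttime": p - 1,
        "conc:expttime": (G - 1) * (p - 1),
        "expttime:subject": (n_subj - G) * (p - 1),
        "within": q - 1,
        "conc:within": (G - 1) * (q - 1),
        "within:subject": (n_subj - G) * (q - 1),
        "expttime:within": (p - 1) * (q - 1),
        "conc:expttime:within": (G - 1) * (p - 1) * (q - 1),
        "residual": (n_subj - G) * (p - 1) * (q - 1),
    }
    error_of = {
        "conc": "subject",
        "expttime": "expttime:subject",
        "conc:expttime": "expttime:subject",
        "within": "within:subject",
        "conc:within": "within:subject",
        "expttime:within": "residual",
        "conc:expttime:within": "residual",
    }
    rows = []
    for effect, err in error_of.items():
        if df[err] <= 0:
            raise InsufficientDataError(f"no error df for effect {effect}")
        ms_e = ss[effect] / df[effect]
        ms_r = ss[err] / df[err]
        f = ms_e / ms_r if ms_r > 0 else math.inf
        pval = float(sps.f.sf(f, df[effect], df[err])) if math.isfinite(f) else 0.0
        rows.append({
            "effect": effect, "sum_sq": ss[effect], "df": df[effect],
            "error": err, "error_df": df[err], "F": f, "p": pval,
        })
    for err in ("subject", "expttime:subject", "within:subject", "residual"):
        rows.append({
            "effect": err, "sum_sq": ss[err], "df": df[err],
            "error": None, "error_df": None, "F": math.nan, "p": math.nan,
        })
    out = pd.DataFrame(rows)
    out.attrs["within_factor"] = within_factor
    return out


# ---------------------------------------------------------------------------
# FDR and count tables
# ---------------------------------------------------------------------------

def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask.

    Rejects all p <= p_(k*) with k* = max{k : p_(k) <= k q / m}; m counts
    the non-missing p-values, and missing entries are never rejected.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    mask = np.zeros(p.shape, dtype=bool)
    m = int(finite.sum())
    if m == 0:
        return mask
    ps = np.sort(p[finite])
    k = np.arange(1, m + 1)
    passed = ps <= k * q / m
    if not passed.any():
        return mask
    cutoff = ps[np.nonzero(passed)[0][-1]]
    mask[finite] = p[finite] <= cutoff
    return mask


def spearman_screen(
    table: pd.DataFrame,
    stim_set: int,
    cfg: StatsConfig = StatsConfig(),
    expttimes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of every (parameter, seq, expttime) cell of one
    stimulus set against the ordinal concentration, restricted to the
    configured low-concentration subset.

    Returns a long table: parameter, seq, expttime, n, rho, p.
    """
    sub = table[
        (table["stim_set"] == stim_set)
        & (table["conc"] <= cfg.conc_subset_max_ordinal)
    ].dropna(subset=["normalized_value"])
    if expttimes is not None:
        sub = sub[sub["expttime"].isin(list(expttimes))]
    rows = []
    for (parameter, seq, expttime), g in sub.groupby(["parameter", "seq", "expttime"]):
        if (g["conc"].nunique() < 3 or len(g) < 4
                or g["normalized_value"].nunique() < 2):
            rho, pval = math.nan, math.nan
        else:
            res = sps.spearmanr(g["conc"], g["normalized_value"])
            rho, pval = float(res.statistic), float(res.pvalue)
        rows.append({
            "parameter": parameter, "seq": int(seq), "expttime": int(expttime),
            "n": len(g), "rho": rho, "p": pval,
        })
    return pd.DataFrame(rows)


def _chi2_independence(counts: np.ndarray, df: int) -> Chi2Result:
    """Pearson chi-square of independence with a fixed df; zero-margin
    cells (expected 0, observed 0) contribute nothing."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return Chi2Result(math.nan, df, math.nan, applicable=False)
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = float(cells.sum())
    return Chi2Result(chi2, df, float(sps.chi2.sf(chi2, df)), applicable=True)


def build_count_table(
    table: pd.DataFrame,
    stim_set: int,
    cfg: StatsConfig = StatsConfig(),
    significance: str = "fdr",
    screen: pd.DataFrame | None = None,
) -> CountTableResult:
    """12 x 7 table counting, per (parameter, seq), the analysis segments
    whose concentration Spearman screen is significant, plus the chi-square
    test of parameter-by-stimulus independence (df = 11 x 6 = 66).

    ``significance`` selects the criterion: "fdr" applies the BH step-up at
    ``cfg.fdr_q`` over the whole stimulus-set family; "raw_p" thresholds at
    ``cfg.raw_p_threshold``.
    """
    if significance not in ("fdr", "raw_p"):
        raise InvalidConfigError("significance must be 'fdr' or 'raw_p'")
    if screen is None:
        screen = spearman_screen(table, stim_set, cfg)
    screen = screen.copy()
    if significance == "fdr":
        screen["significant"] = bh_fdr(screen["p"].to_numpy(), cfg.fdr_q)
    else:
        screen["significant"] = screen["p"].to_numpy() < cfg.raw_p_threshold

    seqs = list(range(1, 8))
    counts = (
        screen[screen["significant"]]
        .groupby(["parameter", "seq"]).size()
        .unstack(fill_value=0)
        .reindex(index=PARAMETERS, columns=seqs, fill_value=0)
        .fillna(0).astype(int)
    )
    df = (len(PARAMETERS) - 1) * (len(seqs) - 1)
    chi2 = _chi2_independence(counts.to_numpy(), df)
    return CountTableResult(counts, chi2, significance)
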