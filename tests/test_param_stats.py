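import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from napamyloid.errors import (
    InsufficientDataError,
    InvalidConfigError,
    UnbalancedPanelError,
)
from napamyloid.features import PARAMETERS
from napamyloid.param_stats import (
    StatsConfig,
    bh_fdr,
    build_count_table,
    endpoint_anova,
    endpoint_kruskal,
    quadratic_regression,
    repeated_measures,
    spearman_screen,
)


def make_table(values_by_conc, parameter="peak_to_peak_amplitude",
               expttime=36, seq=1, stim_set=1):
    """Build a minimal normalized feature table from per-group value lists."""
    rows = []
    nerve = 1
    for conc, values in values_by_conc.items():
        for v in values:
            rows.append({
                "nerve": nerve, "conc": conc, "expttime": expttime,
                "stim_set": stim_set, "seq": seq, "parameter": parameter,
                "value": v, "normalized_value": v,
            })
            nerve += 1
    return pd.DataFrame(rows)


class TestStatsConfig:
    def test_bonferroni_levels(self):
        cfg = StatsConfig()
        assert round(cfg.per_test_alpha_anova, 3) == 0.004
        assert round(cfg.per_test_alpha_kw, 3) == 0.008

    def test_invalid(self):
        with pytest.raises(InvalidConfigError):
            StatsConfig(fdr_q=0.0)
        with pytest.raises(InvalidConfigError):
            StatsConfig(n_tests=0)


class TestEndpointAnova:
    def test_hand_computed_two_groups(self):
        # groups {1,2,3} vs {4,5,6}: SSB = 13.5, MSW = 1 -> F = 13.5
        t = make_table({0: [1, 2, 3], 1: [4, 5, 6]})
        res = endpoint_anova(t, "peak_to_peak_amplitude")
        assert res.F == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p == pytest.approx(float(sps.f.sf(13.5, 1, 4)))

    def test_full_design_df(self, rng):
        groups = {c: rng.normal(size=n)
                  for c, n in zip(range(9), [40, 8, 8, 8, 8, 8, 8, 8, 16])}
        res = endpoint_anova(make_table(groups), "peak_to_peak_amplitude")
        assert (res.df_between, res.df_within) == (8, 103)

    def test_null_median_p(self, rng):
        # equal group means, tiny iid noise: p approximately uniform
        ps = []
        for _ in range(200):
            groups = {c: 1.0 + 1e-6 * rng.standard_normal(5) for c in range(4)}
            ps.append(endpoint_anova(make_table(groups),
                                     "peak_to_peak_amplitude").p)
        assert 0.35 < np.median(ps) < 0.65

    def test_insufficient_groups(self):
        t = make_table({0: [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            endpoint_anova(t, "peak_to_peak_amplitude")


class TestEndpointKruskal:
    def test_hand_computed(self):
        # groups {1,2} and {3,4}: ranks 1,2 | 3,4
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 = 12/20 * 4 = 2.4
        t = make_table({0: [1, 2], 1: [3, 4]})
        res = endpoint_kruskal(t, "peak_to_peak_amplitude")
        assert res.H == pytest.approx(2.4)
        assert res.df == 1

    def test_null_rejection_rate(self, rng):
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            groups = {c: rng.standard_normal(6) for c in range(3)}
            res = endpoint_kruskal(make_table(groups), "peak_to_peak_amplitude")
            rejections += res.p < 0.05
        # H is discrete at these sizes; allow generous calibration slack
        assert rejections / n_sims < 0.09

    def test_single_group_errors(self):
        with pytest.raises(InsufficientDataError):
            endpoint_kruskal(make_table({0: [1, 2, 3]}),
                             "peak_to_peak_amplitude")


class TestQuadraticRegression:
    def test_exact_interpolation(self):
        conc = np.repeat(np.arange(9), 3)
        y = 1.0 - 0.1 * conc + 0.01 * conc**2
        t = make_table({c: y[conc == c] for c in range(9)})
        res = quadratic_regression(t, "peak_to_peak_amplitude")
        coef = res.set_index("term")["coef"]
        assert coef["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert coef["conc"] == pytest.approx(-0.1, abs=1e-10)
        assert coef["conc_sq"] == pytest.approx(0.01, abs=1e-10)

    def test_u_shape_positive_quadratic(self, rng):
        means = {c: 1.0 - 0.08 * c + 0.012 * (c - 4) ** 2 for c in range(9)}
        groups = {c: means[c] + 0.01 * rng.standard_normal(8) for c in range(9)}
        res = quadratic_regression(make_table(groups), "peak_to_peak_amplitude")
        assert res.set_index("term").loc["conc_sq", "coef"] > 0

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(300):
            groups = {c: rng.standard_normal(6) for c in range(5)}
            res = quadratic_regression(make_table(groups),
                                       "peak_to_peak_amplitude")
            ps.append(res.set_index("term").loc["conc", "p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.001


class TestBhFdr:
    def test_hand_applied_step_up(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.9])
        mask = bh_fdr(p, q=0.05)
        assert mask.tolist() == [True, True, True, True, False]

    def test_all_ones(self):
        assert not bh_fdr(np.ones(10), 0.05).any()

    def test_all_zeros(self):
        assert bh_fdr(np.zeros(10), 0.05).all()

    def test_nan_never_rejected(self):
        mask = bh_fdr(np.array([0.001, np.nan, 0.002]), 0.05)
        assert mask.tolist() == [True, False, True]

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests
        p = np.array(pvals)
        ours = bh_fdr(p, 0.05)
        theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert np.array_equal(ours, theirs)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50), st.floats(min_value=0.01, max_value=0.2))
    @settings(max_examples=50, deadline=None)
    def test_dominates_bonferroni(self, pvals, q):
        p = np.array(pvals)
        bonferroni = p <= q / len(p)
        bh = bh_fdr(p, q)
        assert np.all(bh[bonferroni])


def make_panel(rng, n_per_group=4, groups=(0, 1, 2), expttimes=(4, 5, 6),
               seqs=(1, 2, 3, 4, 5, 6, 7), stim_set=1, effect=0.0):
    rows = []
    nerve = 1
    for g in groups:
        for _ in range(n_per_group):
            subj_off = rng.standard_normal() * 0.1
            for j in expttimes:
                for k in seqs:
                    y = (1.0 + subj_off - effect * g * k / len(seqs)
                         + 0.05 * rng.standard_normal())
                    rows.append({
                        "nerve": nerve, "conc": g, "expttime": j,
                        "stim_set": stim_set, "seq": k,
                        "parameter": "peak_to_peak_amplitude",
                        "value": y, "normalized_value": y,
                    })
            nerve += 1
    return pd.DataFrame(rows)


class TestRepeatedMeasures:
    def test_ss_decomposition_total(self, rng):
        t = make_panel(rng, n_per_group=3)
        res = repeated_measures(t, "isi")
        y = t["normalized_value"].to_numpy()
        total = float(np.sum((y - y.mean()) ** 2))
        assert res["sum_sq"].sum() == pytest.approx(total, rel=1e-9)
        assert res["df"].sum() == len(t) - 1

    def test_against_pingouin_mixed_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        t = make_panel(rng, n_per_group=5, effect=0.3)
        res = repeated_measures(t, "isi").set_index("effect")
        # averaging over the other within factor reduces the design to a
        # one-within/one-between mixed ANOVA with identical F ratios
        agg = (t.groupby(["nerve", "conc", "seq"])["normalized_value"]
               .mean().reset_index())
        pg = pingouin.mixed_anova(agg, dv="normalized_value", within="seq",
                                  subject="nerve", between="conc")
        pg = pg.set_index("Source")
        assert res.loc["conc", "F"] == pytest.approx(pg.loc["conc", "F"], rel=1e-6)
        assert res.loc["within", "F"] == pytest.approx(pg.loc["seq", "F"], rel=1e-6)
        assert res.loc["conc:within", "F"] == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-6)

    def test_detects_isi_dependent_effect(self, rng):
        detected = 0
        for _ in range(20):
            t = make_panel(rng, n_per_group=5, effect=0.4)
            res = repeated_measures(t, "isi").set_index("effect")
            detected += res.loc["conc:within", "p"] < 0.05
        assert detected >= 16

    def test_null_calibration(self, rng):
        rejections = 0
        n_sims = 100
        for _ in range(n_sims):
            t = make_panel(rng, n_per_group=4, effect=0.0)
            res = repeated_measures(t, "isi").set_index("effect")
            rejections += res.loc["conc", "p"] < 0.05
        assert rejections / n_sims < 0.12

    def test_unbalanced_panel_errors(self, rng):
        t = make_panel(rng).iloc[:-1]  # drop one cell
        with pytest.raises(UnbalancedPanelError):
            repeated_measures(t, "isi")

    def test_single_within_level_errors(self, rng):
        t = make_panel(rng)
        with pytest.raises(InsufficientDataError):
            repeated_measures(t, "isi", protocol_levels=[2])

    def test_current_factor_drops_lowest(self, rng):
        t = make_panel(rng, stim_set=0)
        res = repeated_measures(t, "current").set_index("effect")
        # 6 current levels (seq 2..7) -> within df = 5
        assert res.loc["within", "df"] == 5


class TestCountTable:
    def _screen(self, sig_cells):
        rows = []
        for parameter in PARAMETERS:
            for seq in range(1, 8):
                for j in range(4, 37):
                    sig = (parameter, seq) in sig_cells and j <= 4 + sig_cells[
                        (parameter, seq)] - 1
                    rows.append({
                        "parameter": parameter, "seq": seq, "expttime": j,
                        "n": 72, "rho": -0.5 if sig else 0.0,
                        "p": 1e-6 if sig else 0.5,
                    })
        return pd.DataFrame(rows)

    def test_counts_and_df(self):
        screen = self._screen({("peak_to_peak_amplitude", 1): 10,
                               ("peak_amplitude", 3): 5})
        res = build_count_table(pd.DataFrame(), 1, significance="raw_p",
                                screen=screen)
        assert res.counts.loc["peak_to_peak_amplitude", 1] == 10
        assert res.counts.loc["peak_amplitude", 3] == 5
        assert res.counts.to_numpy().sum() == 15
        assert res.chi2.df == 66
        assert res.counts.shape == (12, 7)

    def test_cells_bounded_by_segments(self):
        screen = self._screen({("duration", 2): 33})
        res = build_count_table(pd.DataFrame(), 1, significance="raw_p",
                                screen=screen)
        assert res.counts.to_numpy().max() <= 33

    def test_chi2_matches_scipy_on_dense_table(self, rng):
        # dense random screen -> compare the independence statistic to scipy
        screen = self._screen({})
        screen["p"] = rng.uniform(0, 0.02, size=len(screen))
        res = build_count_table(pd.DataFrame(), 1, significance="raw_p",
                                screen=screen)
        counts = res.counts.to_numpy()
        if counts.sum() and (counts.sum(axis=0) > 0).all() \
                and (counts.sum(axis=1) > 0).all():
            chi2, p, df, _ = sps.chi2_contingency(counts, correction=False)
            assert res.chi2.chi2 == pytest.approx(chi2)
            assert res.chi2.df == df
            assert res.chi2.p == pytest.approx(p)

    def test_all_zero_not_applicable(self):
        screen = self._screen({})
        res = build_count_table(pd.DataFrame(), 1, significance="fdr",
                                screen=screen)
        assert not res.chi2.applicable

    def test_invalid_mode(self):
        with pytest.raises(InvalidConfigError):
            build_count_table(pd.DataFrame(), 1, significance="bogus",
                              screen=self._screen({}))


class TestSpearmanScreen:
    def test_perfect_anticorrelation(self):
        rows = []
        nerve = 1
        for conc in range(5):
            for _ in range(4):
                rows.append({
                    "nerve": nerve, "conc": conc, "expttime": 36,
                    "stim_set": 1, "seq": 1,
                    "parameter": "peak_to_peak_amplitude",
                    "value": -conc, "normalized_value": -float(conc) - 0.001 * nerve,
                })
                nerve += 1
        screen = spearman_screen(pd.DataFrame(rows), 1)
        assert screen["rho"].iloc[0] == pytest.approx(-1.0, abs=0.05)

    def test_conc_subset_respected(self):
        rows = []
        for conc in range(9):
            for n in range(3):
                rows.append({
                    "nerve": conc * 10 + n, "conc": conc, "expttime": 36,
                    "stim_set": 1, "seq": 1, "parameter": "duration",
                    "value": 1.0, "normalized_value": float(n),
                })
        screen = spearman_screen(pd.DataFrame(rows), 1,
                                 StatsConfig(conc_subset_max_ordinal=4))
        assert screen["n"].iloc[0] == 15  # 5 groups x 3 nerves
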