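"""Multivariate analysis of pre-estimated parameters (SRTM vectors)."""

import numpy as np
import pandas as pd
import pytest

from hierpet.contrasts import group_contrasts, rn_vs_projection
from hierpet.inference import InferenceSettings
from hierpet.pumba import build_pumba_model, fit_pumba
from hierpet.simba import HierarchicalModelSpec


def make_pumba_cohort(rng, n_per_group=12, regions=("DLPFC", "MPFC", "RN"),
                      gamma=None, resid_sd=(0.08, 0.10, 0.15)):
    """Generate log (R1, k2prime, BPND) tables directly from the PuMBA
    generative model (multivariate-normal response, known effects)."""
    mu = np.array([np.log(0.9), np.log(0.15), np.log(2.5)])
    region_off = {r: rng.normal(0, 0.1, 3) for r in regions}
    rows, meta = [], []
    for g in ("HV", "NRM", "AE"):
        for i in range(n_per_group):
            sid = f"{g}{i:02d}"
            age = float(rng.normal(40, 12))
            sex = "F" if rng.uniform() < 0.5 else "M"
            subj = rng.normal(0, [0.1, 0.12, 0.2])
            meta.append((sid, g, age, sex))
            for r in regions:
                y = mu + region_off[r] + subj + rng.normal(0, resid_sd)
                if gamma is not None:
                    y[2] += gamma.get((g, r), 0.0)
                for pname, val in zip(("R1", "k2prime", "BPND"), y):
                    rows.append((sid, r, "srtm", "bpnd", pname, val,
                                 0.05, True, 0.0))
    tab = pd.DataFrame(rows, columns=[
        "subject_id", "region", "model", "variant", "parameter",
        "estimate_log", "se_log", "converged", "rss"])
    metadata = pd.DataFrame(meta, columns=["subject_id", "group", "age",
                                           "sex"])
    return tab, metadata


class TestRecovery:
    def test_injected_rn_effect_recovered_within_interval(self):
        rng = np.random.default_rng(0)
        tab, meta = make_pumba_cohort(
            rng, n_per_group=15,
            gamma={("NRM", "RN"): 0.25})
        fit = fit_pumba(tab, meta,
                        settings=InferenceSettings(seed=0, draws=400,
                                                   chains=2))
        cons = {c.region: c for c in group_contrasts(
            fit, comparisons=("NRM-HV",))}
        c = cons["RN"]
        want = 100 * np.expm1(0.25)
        assert c.lo95 < want and c.percent > 5.0
        assert c.p_positive > 0.9
        # null regions stay near zero
        assert abs(cons["DLPFC"].percent) < 15

    def test_single_region_degrades_to_multivariate_regression(self):
        rng = np.random.default_rng(1)
        tab, meta = make_pumba_cohort(rng, regions=("RN",),
                                      gamma={("NRM", "RN"): 0.3})
        fit = fit_pumba(tab, meta,
                        settings=InferenceSettings(seed=1, draws=300,
                                                   chains=2))
        c = group_contrasts(fit, comparisons=("NRM-HV",))[0]
        assert c.region == "RN"
        assert c.p_positive > 0.8

    def test_missing_metadata_subject_rejected(self):
        rng = np.random.default_rng(2)
        tab, meta = make_pumba_cohort(rng, n_per_group=3)
        with pytest.raises(ValueError, match="missing subjects"):
            build_pumba_model(tab, meta.iloc[1:])

    def test_incomplete_parameter_table_rejected(self):
        rng = np.random.default_rng(3)
        tab, meta = make_pumba_cohort(rng, n_per_group=3)
        with pytest.raises(ValueError, match="lacks"):
            build_pumba_model(tab[tab.parameter != "BPND"], meta)


class TestRnVsProjection:
    def _fit(self, gamma, seed):
        rng = np.random.default_rng(seed)
        tab, meta = make_pumba_cohort(
            rng, n_per_group=15,
            regions=("DLPFC", "MPFC", "PCC", "HIP", "RN"), gamma=gamma)
        spec = HierarchicalModelSpec(contrast_mode="rn_projection")
        return fit_pumba(tab, meta, spec=spec,
                         settings=InferenceSettings(seed=seed, draws=400,
                                                    chains=2))

    def test_equal_effects_give_symmetric_probability(self):
        gamma = {("NRM", r): 0.15
                 for r in ("DLPFC", "MPFC", "PCC", "HIP", "RN")}
        fit = self._fit(gamma, seed=4)
        res = rn_vs_projection(None, fit=fit)
        assert 0.1 < res["p_rn_gt_proj"] < 0.9

    def test_raphe_dominant_effect_detected(self):
        gamma = {("NRM", "RN"): 0.35}
        for r in ("DLPFC", "MPFC", "PCC", "HIP"):
            gamma[("NRM", r)] = 0.05
        fit = self._fit(gamma, seed=5)
        res = rn_vs_projection(None, fit=fit)
        assert res["p_rn_gt_proj"] > 0.9
        assert res["rn"].percent > res["projection_mean"].percent

    def test_homogeneous_projections_give_small_slope_sd(self):
        gamma = {("NRM", r): 0.1
                 for r in ("DLPFC", "MPFC", "PCC", "HIP")}
        fit = self._fit(gamma, seed=6)
        res = rn_vs_projection(None, fit=fit)
        assert res["slope_sd_mean"] < 0.1


class TestEfficiencyVersusUnivariate:
    def test_pumba_intervals_narrower_than_lme_on_matched_data(self):
        from hierpet.contrasts import fit_univariate_lme
        rng = np.random.default_rng(7)
        tab, meta = make_pumba_cohort(rng, n_per_group=12,
                                      gamma={("NRM", "RN"): 0.15})
        fit = fit_pumba(tab, meta,
                        settings=InferenceSettings(seed=7, draws=400,
                                                   chains=2))
        cp = {c.region: c for c in group_contrasts(
            fit, comparisons=("NRM-HV",))}
        w = tab[tab.parameter == "BPND"].merge(meta, on="subject_id")
        w = w.rename(columns={"estimate_log": "value"})
        cl = {c.region: c for c in fit_univariate_lme(
            w, comparisons=("NRM-HV",))["contrasts"]}
        widths_p = [cp[r].hi95 - cp[r].lo95 for r in cp]
        widths_l = [cl[r].hi95 - cl[r].lo95 for r in cl]
        assert np.mean(widths_p) < np.mean(widths_l)


class TestSubgroupCorrelations:
    def _group_fit(self, rng, corr_sign=1.0, n=60, seed=0):
        """Fit one subgroup generated with a known individual-level
        correlation structure between k2prime and BPND."""
        from hierpet.inference import InferenceSettings
        import pandas as pd
        rows, meta = [], []
        mu = np.array([np.log(0.9), np.log(0.15), np.log(2.5)])
        cov = np.array([[0.10**2, 0.0, 0.0],
                        [0.0, 0.15**2, corr_sign * 0.7 * 0.15 * 0.25],
                        [0.0, corr_sign * 0.7 * 0.15 * 0.25, 0.25**2]])
        L = np.linalg.cholesky(cov)
        for i in range(n):
            sid = f"s{i:02d}"
            subj = L @ rng.standard_normal(3)
            meta.append((sid, "HV", float(rng.normal(40, 10)), "F"))
            for r in ("DLPFC", "MPFC", "RN"):
                y = mu + subj + rng.normal(0, 0.05, 3)
                for pname, val in zip(("R1", "k2prime", "BPND"), y):
                    rows.append((sid, r, "srtm", "bpnd", pname, val,
                                 0.05, True, 0.0))
        tab = pd.DataFrame(rows, columns=[
            "subject_id", "region", "model", "variant", "parameter",
            "estimate_log", "se_log", "converged", "rss"])
        metadata = pd.DataFrame(meta, columns=["subject_id", "group",
                                               "age", "sex"])
        return fit_pumba(tab, metadata,
                         settings=InferenceSettings(seed=seed, draws=200,
                                                    chains=2))

    def test_identical_configs_agree_and_diagonal_is_one(self):
        from hierpet.contrasts import subgroup_correlations
        rng = np.random.default_rng(10)
        fits = {"A": self._group_fit(rng, 1.0, seed=1),
                "B": self._group_fit(rng, 1.0, seed=2)}
        res = subgroup_correlations(fits)
        for C in res["matrices"].values():
            np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-9)
        # sampling noise of a correlation difference at n=60 is ~0.18 SD
        assert res["max_abs_diff"] < 0.3
        # the strong k2prime-BP correlation is present in both
        for C in res["matrices"].values():
            assert C[1, 2] > 0.4

    def test_antithetic_correlations_flagged_as_different(self):
        from hierpet.contrasts import subgroup_correlations
        rng = np.random.default_rng(11)
        fits = {"A": self._group_fit(rng, 1.0, seed=3),
                "B": self._group_fit(rng, -1.0, seed=4)}
        res = subgroup_correlations(fits)
        assert res["max_abs_diff"] > 0.5


def test_posterior_contraction_with_sample_size():
    """Doubling the number of subjects shrinks the raphe-contrast interval
    by roughly sqrt(2)."""
    widths = {}
    for n in (12, 24):
        rng = np.random.default_rng(42)
        tab, meta = make_pumba_cohort(rng, n_per_group=n,
                                      gamma={("NRM", "RN"): 0.1})
        fit = fit_pumba(tab, meta,
                        settings=InferenceSettings(seed=n, draws=600,
                                                   chains=2))
        c = [k for k in group_contrasts(fit, comparisons=("NRM-HV",))
             if k.region == "RN"][0]
        widths[n] = np.log1p(c.hi95 / 100) - np.log1p(c.lo95 / 100)
    ratio = widths[12] / widths[24]
    assert np.sqrt(2) * 0.75 < ratio < np.sqrt(2) * 1.35


def test_fit_persists_draws_csv_and_summary(tmp_path):
    """Fits persist as a long draws table (draw, chain, parameter, value)
    plus a JSON summary with means, intervals and split R-hat."""
    import json
    rng = np.random.default_rng(9)
    tab, meta = make_pumba_cohort(rng, n_per_group=5)
    fit = fit_pumba(tab, meta,
                    settings=InferenceSettings(seed=9, draws=100, chains=2))
    fit.to_files(tmp_path)
    dr = pd.read_csv(tmp_path / "draws.csv")
    assert list(dr.columns) == ["draw", "chain", "parameter", "value"]
    assert set(dr["chain"]) == {0, 1}
    assert any(p.startswith("gamma[NRM:RN]") for p in dr["parameter"])
    s = json.loads((tmp_path / "summary.json").read_text())
    g = s["parameters"]["gamma[NRM:RN]"]
    assert g["q2.5"] <= g["mean"] <= g["q97.5"]
    assert 0.8 < g["rhat"] < 1.2
    assert s["diagnostics"]["method"] == "map_laplace_ecm"
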