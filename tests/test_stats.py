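import numpy as np
import pandas as pd
import pytest

from limbictex.stats import (
    GroupTimeInteraction,
    fdr_adjust,
    fit_interaction_model,
    rmcorr,
    run_stats_stage,
)
from limbictex.synthetic import simulate_feature_table

from oracles import bh_adjust, change_score_ttest


def build_table(ect_changes, med_changes, baselines=None, **covars):
    """Two-timepoint long table from per-subject change scores."""
    rows = []
    rng = np.random.default_rng(0)
    for grp, changes in (("ECT", ect_changes), ("MED", med_changes)):
        for i, d in enumerate(changes):
            base = baselines[grp][i] if baselines else rng.normal()
            cov = {k: v[grp][i] if isinstance(v, dict) else v for k, v in covars.items()}
            for tp, val in (("baseline", base), ("followup", base + d)):
                rows.append({"subject_id": f"{grp}{i}", "group": grp,
                             "timepoint": tp, "roi": "r", "feature": "f",
                             "value": val, **cov})
    return pd.DataFrame(rows)


class TestInteractionModel:
    def test_noiseless_contrast_recovers_effect_exactly(self):
        c = 0.73
        t = build_table([c] * 6, [0.0] * 6)
        res = fit_interaction_model(t, covariates=())
        assert res.beta == pytest.approx(c, abs=1e-8)

    def test_equivalence_with_change_score_ttest(self, rng):
        """Without covariates the mixed model reproduces the two-sample
        t-test on change scores (the analytic 2-timepoint equivalence)."""
        for _ in range(5):
            tbl, _ = simulate_feature_table(n_ect=20, n_med=15, delta=0.4, rng=rng)
            res = fit_interaction_model(tbl, covariates=())
            est, t, df, p = change_score_ttest(tbl)
            assert res.p == pytest.approx(p, abs=1e-6)
            assert res.beta == pytest.approx(est, abs=1e-6)
            assert res.df == df

    def test_covariate_adjustment_runs_and_matches_sign(self, rng):
        tbl, true_beta = simulate_feature_table(delta=1.2, rng=rng)
        res = fit_interaction_model(tbl)
        assert res.method == "mixed"
        assert np.sign(res.beta) == np.sign(true_beta)
        assert res.p < 0.05

    def test_constant_covariate_named_in_error(self, rng):
        tbl, _ = simulate_feature_table(rng=rng)
        tbl["oz_dose"] = 5.0
        with pytest.raises(ValueError, match="oz_dose"):
            fit_interaction_model(tbl)

    def test_missing_timepoint_rejected(self, rng):
        tbl, _ = simulate_feature_table(rng=rng)
        with pytest.raises(ValueError, match="timepoint"):
            fit_interaction_model(tbl[tbl.timepoint == "baseline"], covariates=())

    def test_too_few_subjects_rejected(self):
        t = build_table([1.0] * 3, [0.0] * 6)
        with pytest.raises(ValueError, match="4 subjects"):
            fit_interaction_model(t, covariates=())

    def test_change_score_fallback_flagged(self, rng):
        tbl, _ = simulate_feature_table(rng=rng)
        res = fit_interaction_model(tbl, method="change_score")
        assert res.method == "change_score_ols"
        assert np.isfinite(res.p)

    def test_estimator_class_fits_per_roi_feature(self, rng):
        tables = []
        for roi in ("r1", "r2"):
            t, _ = simulate_feature_table(n_ect=10, n_med=10, rng=rng, roi=roi)
            tables.append(t)
        est = GroupTimeInteraction(covariates=("age",)).fit(pd.concat(tables))
        assert len(est.results_) == 2
        assert {"beta", "se", "p", "p_fdr"} <= set(est.results_.columns)
        assert (est.results_["p_fdr"] >= est.results_["p"] - 1e-15).all()


class TestFDR:
    def test_hand_bh_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037]) == pytest.approx([0.037])

    def test_all_ones(self):
        assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            fdr_adjust([-0.1])

    def test_matches_hand_bh_on_random_inputs(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            assert fdr_adjust(p) == pytest.approx(bh_adjust(p), rel=1e-12)

    def test_monotone_in_order_statistics(self, rng):
        """Adjusted values preserve the input order statistics and always
        dominate the raw p-values, capped at 1."""
        for _ in range(10):
            p = rng.random(20)
            adj = np.array(fdr_adjust(p))
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()
            assert (adj >= p - 1e-15).all()
            assert (adj <= 1.0).all()


class TestRmcorr:
    def _paired(self, deltas_x, deltas_y, rng):
        subj, xs, ys = [], [], []
        for i, (dx, dy) in enumerate(zip(deltas_x, deltas_y)):
            x0 = rng.normal()
            y0 = rng.normal()
            subj += [i, i]
            xs += [x0, x0 + dx]
            ys += [y0, y0 + dy]
        return subj, xs, ys

    def test_perfect_positive_collinearity(self, rng):
        dx = rng.normal(size=6)
        subj, xs, ys = self._paired(dx, 2 * dx, rng)
        res = rmcorr(subj, xs, ys)
        assert res.r == pytest.approx(1.0)
        assert res.df == 5  # N - 1 for two visits

    def test_perfect_negative_collinearity(self, rng):
        dx = rng.normal(size=6)
        subj, xs, ys = self._paired(dx, -dx, rng)
        assert rmcorr(subj, xs, ys).r == pytest.approx(-1.0)

    def test_shift_invariance(self, rng):
        dx = rng.normal(size=8)
        dy = 0.5 * dx + rng.normal(size=8) * 0.3
        subj, xs, ys = self._paired(dx, dy, rng)
        base = rmcorr(subj, xs, ys)
        shifts = {s: rng.normal() * 10 for s in set(subj)}
        xs2 = [x + shifts[s] for s, x in zip(subj, xs)]
        ys2 = [y - 3 * shifts[s] for s, y in zip(subj, ys)]
        shifted = rmcorr(subj, xs2, ys2)
        assert shifted.r == pytest.approx(base.r, rel=1e-9)
        assert shifted.p == pytest.approx(base.p, rel=1e-9)

    def test_zero_x_change_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            rmcorr([0, 0, 1, 1, 2, 2], [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
                   [0.0, 1.0, 0.0, 1.0, 0.0, 1.0])

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            rmcorr([0, 0, 1, 1], [0, 1, 0, 2], [0, 1, 1, 0])

    def test_unequal_visits_rejected(self):
        with pytest.raises(ValueError, match="exactly 2"):
            rmcorr([0, 0, 0, 1, 1], [0, 1, 2, 0, 1], [0, 1, 2, 0, 1])

    def test_simulation_tracks_analytic_correlation(self, rng):
        """Mean r over replicates approaches β·sd(Δx)/sd(Δy)."""
        beta, sd_dx, sd_eps, n = 0.8, 1.0, 0.6, 36
        target = beta * sd_dx / np.sqrt(beta**2 * sd_dx**2 + sd_eps**2)
        rs = []
        for _ in range(120):
            dx = rng.normal(0, sd_dx, size=n)
            dy = beta * dx + rng.normal(0, sd_eps, size=n)
            subj, xs, ys = self._paired(dx, dy, rng)
            rs.append(rmcorr(subj, xs, ys).r)
        assert np.mean(rs) == pytest.approx(target, abs=0.05)


@pytest.fixture(scope="module")
def stage_inputs():
    rng = np.random.default_rng(5)
    tex_rows = []
    clinical_rows = []
    subj_cov = {}
    for grp, n in (("ECT", 16), ("MED", 14)):
        for i in range(n):
            sid = f"{grp}{i}"
            subj_cov[sid] = {
                "group": grp, "age": rng.normal(33, 7),
                "sex": "M" if rng.random() < 0.5 else "F",
                "oz_dose": abs(rng.normal(30, 10)), "etiv": rng.normal(1.5e6, 1e5),
            }
    # texture: effect planted only in roi "hit", feature "lae"
    for roi in ("hit", "null"):
        for feat in ("lae", "other"):
            for sid, cov in subj_cov.items():
                base = rng.normal()
                eff = 1.8 if (roi, feat) == ("hit", "lae") and cov["group"] == "ECT" else 0.0
                for tp, v in (("baseline", base),
                              ("followup", base + eff + rng.normal(0, 0.5))):
                    tex_rows.append({"subject_id": sid, "group": cov["group"],
                                     "timepoint": tp, "roi": roi, "feature": feat,
                                     "value": v})
    texture = pd.DataFrame(tex_rows)
    volumes = texture[texture["feature"] == "other"].assign(feature="volume")
    wide = texture[(texture.roi == "hit") & (texture.feature == "lae")].pivot_table(
        index="subject_id", columns="timepoint", values="value")
    for sid, cov in subj_cov.items():
        dx = wide.loc[sid, "followup"] - wide.loc[sid, "baseline"]
        base_p = rng.normal(75, 15)
        coupled = -6 * dx + rng.normal(0, 4) if cov["group"] == "ECT" else rng.normal(0, 6)
        for tp, v in (("baseline", base_p), ("followup", base_p + coupled)):
            clinical_rows.append({"subject_id": sid, "timepoint": tp, **cov,
                                  "panss_total": v, "panss_pos": v / 4,
                                  "panss_neg": rng.normal(18, 4),
                                  "panss_gen": v / 2, "cgi_s": 4.5})
    clinical = pd.DataFrame(clinical_rows)
    return texture, volumes, clinical


class TestRunStatsStage:
    def test_families_and_contracts(self, stage_inputs):
        texture, volumes, clinical = stage_inputs
        out = run_stats_stage(texture, volumes, clinical,
                              selected_features=["lae", "other"])
        assert len(out["volume"]) == 2  # one per ROI
        assert len(out["texture"]) == 4  # 2 features x 2 ROIs, one BH family
        tex = out["texture"].set_index(["roi", "outcome"])
        assert tex.loc[("hit", "lae"), "p_fdr"] < 0.05
        assert (out["texture"]["p_fdr"] >= out["texture"]["p"] - 1e-15).all()
        # rmcorr only on significant pairs, per patient group, 5 clinical vars
        assert set(out["rmcorr"]["group"]) == {"ECT", "MED"}
        assert set(out["rmcorr"]["roi"]) == {"hit"}
        ect = out["rmcorr"].query("group == 'ECT' and clinical_var == 'panss_total'")
        assert (ect["r"] < 0).all()  # planted negative coupling
        assert (ect["p_fdr"] < 0.05).all()

    def test_selected_feature_filter(self, stage_inputs):
        texture, volumes, clinical = stage_inputs
        out = run_stats_stage(texture, volumes, clinical, selected_features=["lae"])
        assert set(out["texture"]["outcome"]) == {"lae"}
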