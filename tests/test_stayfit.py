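import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

from twostep import stayfit
from twostep.stayfit import (ConvergenceError, HierFit, build_stay_design,
                             extract_mbi, fit_comparison, fit_hierarchical,
                             fit_hit_model, fit_pointwise, pointwise_table)
from twostep.taskmodel import InvalidArgument, TrialRecord, trials_to_frame

from conftest import hybrid_cohort


def make_trial(subject, block, trial, choice, transition, reward,
               missed=False, hit=None, session=1):
    colour = None
    if not missed:
        majority = {"left": "purple", "right": "pink"}[choice]
        minority = {"left": "pink", "right": "purple"}[choice]
        colour = majority if transition == "common" else minority
    return TrialRecord(subject, session, block, trial,
                       None if missed else choice,
                       None if missed else transition, colour,
                       None if missed else reward, hit, "easy", missed)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

class TestBuildStayDesign:
    def test_three_trial_toy(self):
        recs = [
            make_trial("a", 1, 0, "left", "common", 1),
            make_trial("a", 1, 1, "left", "rare", 0),
            make_trial("a", 1, 2, "right", "common", 1),
        ]
        rows = build_stay_design(recs)
        assert len(rows) == 2
        assert rows.loc[0, ["stay", "prev_reward", "prev_transition"]].tolist() \
            == [1, 1, 1]
        assert rows.loc[1, ["stay", "prev_reward", "prev_transition"]].tolist() \
            == [0, -1, -1]

    def test_single_trial_session(self):
        rows = build_stay_design([make_trial("a", 1, 0, "left", "common", 1)])
        assert len(rows) == 0

    def test_row_count_is_trials_minus_blocks(self):
        trials = hybrid_cohort(3, w=0.5, seed=0)
        rows = build_stay_design(trials)
        # brute-force count of adjacent non-missed pairs within blocks
        expected = 0
        for _, sub in trials.groupby(["subject", "session", "block"]):
            expected += len(sub) - 1
        assert len(rows) == expected == 3 * (200 - 2)

    def test_missed_trial_breaks_chain(self):
        recs = [
            make_trial("a", 1, 0, "left", "common", 1),
            make_trial("a", 1, 1, None, None, None, missed=True),
            make_trial("a", 1, 2, "right", "common", 1),
            make_trial("a", 1, 3, "right", "rare", 0),
        ]
        rows = build_stay_design(recs)
        # only the (2, 3) pair survives
        assert len(rows) == 1
        assert rows.loc[0, "trial"] == 3

    def test_rows_never_cross_blocks(self):
        recs = [
            make_trial("a", 1, 0, "left", "common", 1),
            make_trial("a", 2, 1, "left", "common", 1),
        ]
        rows = build_stay_design(trials_to_frame(recs))
        assert len(rows) == 0

    def test_unsorted_input_rejected(self):
        recs = [
            make_trial("a", 1, 1, "left", "common", 1),
            make_trial("a", 1, 0, "left", "common", 1),
        ]
        with pytest.raises(InvalidArgument, match="sorted"):
            build_stay_design(recs)

    def test_prev_hit_coding(self):
        recs = [
            make_trial("a", 1, 0, "left", "common", 1, hit=1),
            make_trial("a", 1, 1, "left", "common", 0),
            make_trial("a", 1, 2, "left", "common", 1, hit=0),
            make_trial("a", 1, 3, "left", "common", 1),
        ]
        rows = build_stay_design(recs, include_hit=True)
        # hit -> +1; no-hit and unrewarded -> -1
        assert rows["prev_hit"].tolist() == [1, -1, -1]

    def test_all_missed_subject_gives_empty_output(self):
        recs = [make_trial("a", 1, t, None, None, None, missed=True)
                for t in range(5)]
        rows = build_stay_design(recs)
        assert len(rows) == 0


# ---------------------------------------------------------------------------
# pointwise fits vs a brute-force oracle
# ---------------------------------------------------------------------------

def random_stay_rows(n_rows, rng, subject="s", coefs=(0.5, 0.3, 0.0, 0.2)):
    r = rng.choice([-1, 1], n_rows)
    t = rng.choice([-1, 1], n_rows, p=[0.2, 0.8])
    eta = coefs[0] + coefs[1] * r + coefs[2] * t + coefs[3] * r * t
    stay = (rng.random(n_rows) < expit(eta)).astype(int)
    return pd.DataFrame({"subject": subject, "session": 1, "block": 1,
                         "trial": np.arange(1, n_rows + 1), "stay": stay,
                         "prev_reward": r, "prev_transition": t})


def brute_force_logit(rows, ridge):
    """Independent oracle: coarse grid search then Nelder-Mead polish."""
    r = rows["prev_reward"].to_numpy(float)
    t = rows["prev_transition"].to_numpy(float)
    X = np.column_stack([np.ones_like(r), r, t, r * t])
    y = rows["stay"].to_numpy(float)

    def nll(theta):
        eta = X @ theta
        return -(y @ eta - np.logaddexp(0, eta).sum()) \
            + 0.5 * ridge * theta @ theta

    grid = np.linspace(-2, 2, 9)
    best, best_val = None, np.inf
    for a in grid:
        for b in grid:
            for c in grid:
                for d in grid:
                    v = nll(np.array([a, b, c, d]))
                    if v < best_val:
                        best, best_val = np.array([a, b, c, d]), v
    res = optimize.minimize(nll, best, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000, "maxfev": 20000})
    return res.x


class TestPointwise:
    def test_balanced_design_gives_zero_coefficients(self):
        cells = [(r, t) for r in (-1, 1) for t in (-1, 1)]
        rows = pd.DataFrame([
            {"subject": "a", "session": 1, "block": 1, "trial": i,
             "stay": s, "prev_reward": r, "prev_transition": t}
            for i, ((r, t), s) in enumerate(
                [(c, s) for c in cells for s in (0, 1)])])
        fit = fit_pointwise(rows)
        assert fit.as_array() == pytest.approx(np.zeros(4), abs=1e-10)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        rows = random_stay_rows(50, rng)
        fit = fit_pointwise(rows, ridge=1e-3)
        oracle = brute_force_logit(rows, ridge=1e-3)
        assert fit.as_array() == pytest.approx(oracle, abs=1e-4)

    def test_separation_flag_with_ridge(self):
        rows = random_stay_rows(30, np.random.default_rng(1))
        rows["stay"] = 1
        fit = fit_pointwise(rows, ridge=1e-3)
        assert fit.separation_flag
        assert np.all(np.isfinite(fit.as_array()))

    def test_separation_without_ridge_raises(self):
        rows = random_stay_rows(30, np.random.default_rng(2))
        rows["stay"] = 1
        with pytest.raises(ConvergenceError, match="separation"):
            fit_pointwise(rows, ridge=0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgument):
            fit_pointwise(pd.DataFrame(columns=["subject", "stay",
                                                "prev_reward",
                                                "prev_transition"]))

    def test_coding_symmetry(self):
        rng = np.random.default_rng(3)
        rows = random_stay_rows(80, rng)
        flipped = rows.assign(prev_reward=-rows.prev_reward,
                              prev_transition=-rows.prev_transition)
        a = fit_pointwise(rows)
        b = fit_pointwise(flipped)
        assert b.mbi == pytest.approx(a.mbi, abs=1e-8)
        assert b.mfi == pytest.approx(-a.mfi, abs=1e-8)
        assert b.transition_effect == pytest.approx(-a.transition_effect,
                                                    abs=1e-8)
        assert b.stay_tendency == pytest.approx(a.stay_tendency, abs=1e-8)


# ---------------------------------------------------------------------------
# hierarchical fits
# ---------------------------------------------------------------------------

def simulate_mixed_rows(n_subjects, n_rows, fixed, sds, rng, group=None):
    """Rows drawn directly from the mixed logistic model (ground truth)."""
    frames = []
    fixed = np.asarray(fixed, float)
    for i in range(n_subjects):
        b = rng.normal(0, sds)
        coefs = fixed[:4] + b
        g = None
        if group is not None:
            g = group[i]
            coefs = coefs + g * fixed[4:]
        r = rng.choice([-1, 1], n_rows)
        t = rng.choice([-1, 1], n_rows, p=[0.2, 0.8])
        eta = coefs[0] + coefs[1] * r + coefs[2] * t + coefs[3] * r * t
        stay = (rng.random(n_rows) < expit(eta)).astype(int)
        frames.append(pd.DataFrame({
            "subject": f"s{i:04d}", "session": 1, "block": 1,
            "trial": np.arange(1, n_rows + 1), "stay": stay,
            "prev_reward": r, "prev_transition": t}))
    return pd.concat(frames, ignore_index=True)


class TestHierarchical:
    def test_recovers_generative_fixed_effects(self):
        rng = np.random.default_rng(7)
        truth = (1.3, 0.4, 0.0, 0.3)
        rows = simulate_mixed_rows(200, 150, truth, [0.5] * 4, rng)
        fit = fit_hierarchical(rows)
        assert fit.converged
        for term, value in zip(stayfit.BASE_TERMS, truth):
            est = fit.fixed.loc[term]
            assert abs(est["estimate"] - value) < 2 * est["se"], term

    def test_identical_subjects_collapse_to_pooled_fit(self):
        rng = np.random.default_rng(8)
        one = random_stay_rows(120, rng, subject="template")
        rows = pd.concat(
            [one.assign(subject=f"s{i}") for i in range(12)],
            ignore_index=True)
        fit = fit_hierarchical(rows)
        pooled = fit_pointwise(one, ridge=0.0)
        assert np.sqrt(np.diag(fit.ranef_cov)).max() < 0.05
        assert fit.fixed["estimate"].to_numpy() == pytest.approx(
            pooled.as_array(), abs=0.02)

    def test_subject_coefficients_are_fixed_plus_modes(self):
        rng = np.random.default_rng(9)
        rows = simulate_mixed_rows(30, 80, (0.8, 0.3, 0.0, 0.3), [0.4] * 4, rng)
        fit = fit_hierarchical(rows)
        coefs = fit.subject_coefficients()
        manual = (fit.fixed["estimate"][stayfit.BASE_TERMS].to_numpy()
                  + fit.subject_effects.to_numpy())
        assert coefs.to_numpy() == pytest.approx(manual)

    def test_ranef_cov_is_symmetric_psd(self):
        rng = np.random.default_rng(10)
        rows = simulate_mixed_rows(60, 60, (0.8, 0.3, 0.0, 0.3), [0.4] * 4, rng)
        fit = fit_hierarchical(rows)
        cov = fit.ranef_cov
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_needs_two_subjects(self):
        rows = random_stay_rows(50, np.random.default_rng(11))
        with pytest.raises(InvalidArgument):
            fit_hierarchical(rows)

    def test_shrinkage_reduces_variance(self, recovery_rows):
        hier = extract_mbi(fit_hierarchical(recovery_rows))
        point = extract_mbi(pointwise_table(recovery_rows))
        assert hier.var() <= point.var()

    def test_pointwise_hierarchical_agreement(self, recovery_rows):
        hier = extract_mbi(fit_hierarchical(recovery_rows))
        point = extract_mbi(pointwise_table(recovery_rows))
        r = np.corrcoef(hier, point.reindex(hier.index))[0, 1]
        assert r > 0.7

    def test_mean_subject_mbi_near_fixed_effect(self, recovery_rows):
        fit = fit_hierarchical(recovery_rows)
        mbi = extract_mbi(fit)
        assert abs(mbi.mean() - fit.fixed.loc["reward_x_transition",
                                              "estimate"]) < 0.02


class TestComparisonModel:
    def test_exchangeable_groups_have_null_interactions(self):
        rng = np.random.default_rng(12)
        group = np.array([1] * 50 + [-1] * 50)
        rows = simulate_mixed_rows(
            100, 100, (1.0, 0.4, 0.0, 0.3, 0, 0, 0, 0), [0.4] * 4, rng,
            group=group)
        codes = pd.Series(group, index=[f"s{i:04d}" for i in range(100)])
        fit = fit_comparison(rows, codes)
        for term in ("group", "reward_x_group", "transition_x_group",
                     "reward_x_transition_x_group"):
            est = fit.fixed.loc[term]
            assert abs(est["estimate"]) < 2.5 * est["se"], term

    def test_group_contrast_detected_with_matching_sign(self):
        rng = np.random.default_rng(13)
        group = np.array([1] * 50 + [-1] * 50)
        # +1 group has larger interaction: fixed three-way term = +0.25
        rows = simulate_mixed_rows(
            100, 100, (1.0, 0.4, 0.0, 0.4, 0, 0, 0, 0.25), [0.3] * 4, rng,
            group=group)
        codes = pd.Series(group, index=[f"s{i:04d}" for i in range(100)])
        fit = fit_comparison(rows, codes)
        est = fit.fixed.loc["reward_x_transition_x_group"]
        assert est["estimate"] > 0
        assert est["p"] < 0.05

    def test_single_group_rejected(self):
        rows = simulate_mixed_rows(10, 30, (1.0, 0.4, 0.0, 0.3), [0.3] * 4,
                                   np.random.default_rng(14))
        codes = pd.Series(1, index=rows["subject"].unique())
        with pytest.raises(InvalidArgument):
            fit_comparison(rows, codes)


class TestHitModel:
    @staticmethod
    def _hit_cohort(distraction, seed):
        from twostep.taskmodel import default_config
        cfg = default_config()
        cfg.hit_rates = {"easy": 0.5, "medium": 0.5, "hard": 0.5}
        return hybrid_cohort(80, w=0.6, seed=seed, config=cfg,
                             hit_distraction=distraction)

    def test_inert_hits_have_null_interactions(self):
        trials = self._hit_cohort(1.0, seed=15)
        rows = build_stay_design(trials, include_hit=True)
        fit = fit_hit_model(rows)
        for term in ("reward_x_hit", "reward_x_transition_x_hit"):
            est = fit.fixed.loc[term]
            assert abs(est["estimate"]) < 2.5 * est["se"], term

    def test_distraction_reduces_reward_effect_after_hits(self):
        trials = self._hit_cohort(0.15, seed=16)
        rows = build_stay_design(trials, include_hit=True)
        fit = fit_hit_model(rows)
        est = fit.fixed.loc["reward_x_hit"]
        assert est["estimate"] < 0
        assert est["p"] < 0.05

    def test_constant_hit_column_rejected(self):
        rows = random_stay_rows(50, np.random.default_rng(17))
        rows["prev_hit"] = -1
        with pytest.raises(InvalidArgument, match="constant"):
            fit_hit_model(rows)

    def test_rows_without_hit_rejected(self):
        rows = random_stay_rows(50, np.random.default_rng(18))
        with pytest.raises(InvalidArgument, match="include_hit"):
            fit_hit_model(rows)


class TestExtractMbi:
    def test_zero_deviations_give_fixed_effect(self):
        fixed = pd.DataFrame(
            {"estimate": [1.0, 0.3, 0.0, 0.42], "se": [0.1] * 4,
             "z": [1.0] * 4, "p": [0.5] * 4},
            index=pd.Index(stayfit.BASE_TERMS, name="term"))
        effects = pd.DataFrame(
            np.zeros((3, 4)), index=pd.Index(["a", "b", "c"], name="subject"),
            columns=[f"d_{t}" for t in stayfit.BASE_TERMS])
        fit = HierFit(fixed=fixed, ranef_cov=np.eye(4),
                      subject_effects=effects, n_subjects=3, n_rows=100,
                      loglik=0.0, converged=True)
        mbi = extract_mbi(fit)
        assert np.all(mbi == 0.42)
        assert list(mbi.index) == ["a", "b", "c"]

    def test_accepts_coefficient_list(self):
        coefs = [stayfit.SubjectCoefficients("b", 1, 2, 3, 4),
                 stayfit.SubjectCoefficients("a", 1, 2, 3, 5)]
        mbi = extract_mbi(coefs)
        assert mbi.tolist() == [5, 4]  # sorted by subject id


class TestIO:
    def test_stay_csv_round_trip(self, tmp_path):
        rows = random_stay_rows(40, np.random.default_rng(19))
        path = tmp_path / "rows.csv"
        stayfit.write_stay_csv(rows, path)
        back = stayfit.read_stay_csv(path)
        assert back.shape[0] == 40
        assert back["prev_reward"].isin([-1, 1]).all()

    def test_hierfit_json_export(self, tmp_path, recovery_rows):
        fit = fit_hierarchical(recovery_rows)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        import json
        payload = json.loads(path.read_text())
        assert set(payload["fixed"]) == set(stayfit.BASE_TERMS)
        assert payload["converged"] is True
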