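from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from pitchsub.mixed_models import (
    fit_pitch_lmm,
    fit_pitch_lmm_reduced,
    fit_singing_lmm,
    greedy_pairing,
    per_bird_test,
    pitch_change_table,
    random_pairings,
    singing_rate_table,
)
from pitchsub.synthetic import default_cohort, simulate_cohort


@pytest.fixture(scope="module")
def cohort_changes():
    design = default_cohort(n_subs=6, n_unsubs=6, n_lo=0, n_nolo=0, n_subs_rand=0)
    design = [replace(p, renditions_per_day_mean=120.0) for p in design]
    table = simulate_cohort(design, seed=77)
    return pitch_change_table(table)


class TestPitchChangeTable:
    def test_indicators_partition_observations(self, cohort_changes):
        ch = cohort_changes
        active = (ch["vartheta"] != 0) + (ch["theta"] != 0) + (ch["phi"] != 0)
        assert (active == 1).all()
        # baseline pairs exist for every bird; boundary pairs are dropped
        assert set(ch.groupby("bird_id")["vartheta"].sum()) == {4.0}

    def test_phi_sign_follows_target_side(self, cohort_changes):
        stim = cohort_changes[cohort_changes["phi"] != 0]
        assert ((stim["target_side"] == "high") == (stim["phi"] > 0)).all()


class TestFitPitchLmm:
    def test_recovers_injected_fixed_effect(self, cohort_changes):
        fit = fit_pitch_lmm(cohort_changes)
        d = fit["d"]
        assert abs(d.estimate - 0.19) < 3 * d.se
        assert d.pvalue < 0.001
        assert abs(fit["b"].estimate) < 3 * fit["b"].se
        assert d.df == len(cohort_changes) - 3

    def test_all_zero_response_gives_zero_effects(self, cohort_changes):
        ch = cohort_changes.copy()
        ch["dprime"] = 0.0
        fit = fit_pitch_lmm(ch)
        for name in ("b", "a", "d"):
            assert fit[name].estimate == pytest.approx(0.0, abs=1e-8)

    def test_relabeling_birds_leaves_fixed_effects_unchanged(self, cohort_changes):
        fit = fit_pitch_lmm(cohort_changes)
        relabeled = cohort_changes.copy()
        mapping = {
            b: f"z{i}" for i, b in enumerate(sorted(relabeled["bird_id"].unique())[::-1])
        }
        relabeled["bird_id"] = relabeled["bird_id"].map(mapping)
        fit2 = fit_pitch_lmm(relabeled)
        for name in ("b", "a", "d"):
            assert fit2[name].estimate == pytest.approx(fit[name].estimate, abs=1e-6)

    def test_singular_design_rejected(self, cohort_changes):
        only_subs = cohort_changes[cohort_changes["group"] == "subs"]
        with pytest.raises(ValueError, match="singular"):
            fit_pitch_lmm(only_subs)

    def test_reduced_model_keeps_reinforcement_effect(self, cohort_changes):
        """Collapsing baseline and control-drift terms into one leaves the
        sign and significance of the reinforcement term unchanged."""
        full = fit_pitch_lmm(cohort_changes)
        reduced = fit_pitch_lmm_reduced(cohort_changes)
        assert np.sign(reduced["d"].estimate) == np.sign(full["d"].estimate)
        assert reduced["d"].pvalue < 0.05 and full["d"].pvalue < 0.05

    def test_zero_random_variance_equals_ols(self, rng):
        """On balanced data with no bird-level heterogeneity the ML mixed fit
        coincides with ordinary least squares."""
        n_birds, n_days = 8, 10
        rows = []
        for b in range(n_birds):
            phi = 1.0 if b % 2 == 0 else -1.0
            for day in range(n_days):
                vartheta = 1.0 if day < 5 else 0.0
                rows.append(
                    dict(
                        bird_id=f"b{b}", dprime=0.3 * phi * (1 - vartheta)
                        + 0.05 * vartheta + rng.normal(0, 0.05),
                        vartheta=vartheta, theta=0.0,
                        phi=phi * (1 - vartheta),
                    )
                )
        df = pd.DataFrame(rows)
        df.loc[df["phi"] == 0, "theta"] = 0.0
        X = df[["vartheta", "phi"]].to_numpy()
        beta_ols = np.linalg.lstsq(X, df["dprime"].to_numpy(), rcond=None)[0]
        sub = df[["bird_id", "dprime", "vartheta", "theta", "phi"]].copy()
        sub["theta"] = 0.0
        # drop the theta column from the design by folding it into vartheta=0 rows
        from pitchsub.mixed_models import _fit_mixed

        fit = _fit_mixed(
            sub["dprime"].to_numpy(), X, sub["bird_id"].to_numpy(), ["b", "d"]
        )
        # the ML variance estimate sits at (or numerically near) the zero
        # boundary, so the GLS weights collapse to OLS up to that residue
        assert fit.random_effect_var < 0.01 * np.var(sub["dprime"])
        assert fit["b"].estimate == pytest.approx(beta_ols[0], abs=0.01)
        assert fit["d"].estimate == pytest.approx(beta_ols[1], abs=0.01)


class TestSingingRateLmm:
    @staticmethod
    def synth_rates(rng, interaction=0.6, lo_main=0.0, n_per_cell=6):
        rows = []
        k = 0
        for deaf in (0.0, 1.0):
            for lo in (0.0, 1.0):
                for _ in range(n_per_cell):
                    k += 1
                    for day in (1, 2, 3):
                        rate = (
                            1.0 + lo_main * lo + interaction * deaf * lo
                            + rng.normal(0, 0.05)
                        )
                        rows.append(
                            dict(bird_id=f"s{k}", day=day, rate=rate, deaf=deaf, lo=lo)
                        )
        return pd.DataFrame(rows)

    def test_identical_response_gives_pure_offset(self, rng):
        df = self.synth_rates(rng, interaction=0.0, lo_main=0.0)
        df["rate"] = 0.8
        fit = fit_singing_lmm(df)
        assert fit["c"].estimate == pytest.approx(0.8, abs=1e-6)
        for name in ("a", "b", "d"):
            assert fit[name].estimate == pytest.approx(0.0, abs=1e-6)

    def test_interaction_only_effect_recovered(self, rng):
        fit = fit_singing_lmm(self.synth_rates(rng, interaction=0.6))
        assert abs(fit["d"].estimate - 0.6) < 3 * fit["d"].se
        assert fit["d"].pvalue < 0.001
        assert abs(fit["b"].estimate) < 3 * fit["b"].se

    def test_missing_factor_level_rejected(self, rng):
        df = self.synth_rates(rng)
        with pytest.raises(ValueError, match="factor level"):
            fit_singing_lmm(df[df["deaf"] == 1.0])

    def test_singing_rate_table_normalizes_by_baseline(self):
        counts = pd.DataFrame(
            dict(
                bird_id="b1", group="subs",
                day=list(range(1, 17)),
                count=[100] * 5 + [125] * 11,
            )
        )
        rates = singing_rate_table(counts)
        assert len(rates) == 3
        assert rates["rate"].tolist() == pytest.approx([1.25] * 3)
        assert rates["deaf"].iloc[0] == 1.0 and rates["lo"].iloc[0] == 1.0


class TestPerBirdTest:
    def test_identical_samples_not_significant(self):
        x = np.array([0.1, 0.2, 0.0, 0.15])
        res = per_bird_test(x, x)
        assert not res["significant"]
        assert res["p"] == pytest.approx(1.0)

    def test_matches_pooled_formula(self):
        x = np.array([0.5, 0.7, 0.6, 0.4, 0.8])
        y = np.array([0.1, 0.0, 0.2, -0.1])
        res = per_bird_test(x, y)
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        assert res["t"] == pytest.approx(t_hand, rel=1e-10)
        assert res["df"] == nx + ny - 2


class TestRandomPairings:
    def test_single_feasible_matching_is_constant(self):
        allowed = {"c1": ["t1"], "c2": ["t2"]}
        seen = []

        def test_fn(pairs):
            seen.append(tuple(sorted(pairs)))
            return 0.01

        res = random_pairings(["t1", "t2"], ["c1", "c2"], allowed, test_fn,
                              n_replicates=50, seed=4)
        assert res["fraction_significant"] == 1.0
        assert len(set(seen)) == 1

    def test_null_fraction_near_alpha(self, rng):
        from scipy import stats

        treated = {f"t{i}": rng.normal(0, 1, 12) for i in range(8)}
        controls = {f"c{i}": rng.normal(0, 1, 12) for i in range(8)}
        allowed = {c: list(treated) for c in controls}

        def test_fn(pairs):
            diffs = [treated[t].mean() - controls[c].mean() for t, c in pairs]
            return stats.ttest_1samp(diffs, 0.0).pvalue

        res = random_pairings(list(treated), list(controls), allowed, test_fn,
                              n_replicates=200, seed=8)
        assert res["fraction_significant"] < 0.3

    def test_strong_effect_always_significant(self, rng):
        treated = {f"t{i}": rng.normal(1.0, 0.2, 10) for i in range(5)}
        controls = {f"c{i}": rng.normal(0.0, 0.2, 10) for i in range(5)}
        allowed = {c: list(treated) for c in controls}

        def test_fn(pairs):
            x = np.concatenate([treated[t] for t, _ in pairs])
            y = np.concatenate([controls[c] for _, c in pairs])
            return per_bird_test(x, y)["p"]

        res = random_pairings(list(treated), list(controls), allowed, test_fn,
                              n_replicates=100, seed=2)
        assert res["fraction_significant"] == 1.0

    def test_scarcity_first_respects_constraints(self, rng):
        allowed = {"c1": ["t1"], "c2": ["t1", "t2"], "c3": ["t1", "t2", "t3"]}
        pairs = greedy_pairing(["t1", "t2", "t3"], ["c1", "c2", "c3"], allowed, rng)
        matched = dict((c, t) for t, c in pairs)
        assert matched["c1"] == "t1"
        assert matched["c2"] == "t2"
        assert matched["c3"] == "t3"

    def test_surplus_controls_matched_with_replacement(self, rng):
        treated = ["t1", "t2"]
        controls = ["c1", "c2", "c3", "c4"]
        allowed = {c: treated for c in controls}
        pairs = greedy_pairing(treated, controls, allowed, rng)
        assert len(pairs) == 4
        used = [t for t, _ in pairs]
        assert set(used) == {"t1", "t2"}  # every treated bird used at least once

    def test_infeasible_constraints_rejected(self, rng):
        with pytest.raises(ValueError):
            greedy_pairing(["t1"], ["c1"], {"c1": []}, rng)
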