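import numpy as np
import pytest

from feedval.energy import estimate_ingredient_energies, treatment_energy_summary
from feedval.exceptions import ConfigError, DesignError, SchemaError
from feedval.ileal import EndogenousLossTable, digestibility_table
from feedval.synthetic import (
    BASAL_DIET_ID,
    N_FREE_DIET_ID,
    NoiseModel,
    SyntheticTruth,
    estimate_endogenous_losses,
    generate_design,
    recovery_report,
    simulate_balance_trial,
    simulate_ileal_trial,
)

NO_NOISE = NoiseModel(0.0, 0.0, 0.0)


class TestDesign:
    @pytest.mark.parametrize(
        "n_pigs, n_diets, n_periods, reps",
        [(22, 11, 3, 6), (10, 10, 6, 6), (2, 2, 1, 1)],
    )
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_combinatorial_guarantees(self, n_pigs, n_diets, n_periods, reps, seed):
        plan = generate_design(n_pigs, n_diets, n_periods, reps, seed=seed)
        assert len(plan.allocation) == n_pigs * n_periods
        counts = plan.replicate_counts()
        assert set(counts.values()) == {reps}
        for pig in plan.pigs:
            diets = [plan.allocation[(pig, j + 1)] for j in range(n_periods)]
            assert len(set(diets)) == n_periods  # no pig repeats a diet

    def test_invariants_hold_across_many_seeds(self):
        for seed in range(100):
            plan = generate_design(10, 10, 6, 6, seed=seed)
            assert set(plan.replicate_counts().values()) == {6}

    @pytest.mark.parametrize(
        "args", [(10, 10, 6, 5), (9, 10, 6, 6), (10, 10, 11, 11), (21, 11, 3, 6)]
    )
    def test_infeasible_counts_rejected(self, args):
        with pytest.raises(DesignError):
            generate_design(*args)

    def test_same_seed_same_plan(self):
        a = generate_design(22, 11, 3, 6, seed=5)
        b = generate_design(22, 11, 3, 6, seed=5)
        assert a == b
        c = generate_design(22, 11, 3, 6, seed=6)
        assert a != c


class TestBalanceTrial:
    def test_feed_intake_is_four_percent_of_body_weight(self, energy_truth, energy_plan):
        recs = simulate_balance_trial(energy_truth, energy_plan, NO_NOISE,
                                      bw_kg=36.47)
        rec = next(r for r in recs if r.diet_id == "ESBM 1")
        dm = energy_truth.diet_dm_pct["ESBM 1"]
        # 0.04 * 36.47 = 1.459 kg as-fed daily; DM intake over 5 days
        assert rec.feed_intake_kg_dm == pytest.approx(1.459 * 5 * dm / 100, abs=2e-3)

    def test_zero_noise_recovers_truth_exactly(self, energy_truth, energy_plan):
        recs = simulate_balance_trial(energy_truth, energy_plan, NO_NOISE, seed=3)
        est = estimate_ingredient_energies(recs, BASAL_DIET_ID)
        summary = treatment_energy_summary(est)
        for ing, de in energy_truth.true_de.items():
            assert summary.loc[ing, "de"] == pytest.approx(de, abs=1e-9)
            assert summary.loc[ing, "me"] == pytest.approx(
                energy_truth.true_me[ing], abs=1e-9
            )

    def test_same_seed_identical_records(self, energy_truth, energy_plan):
        noise = NoiseModel(2.0, 2.0, 5.0)
        a = simulate_balance_trial(energy_truth, energy_plan, noise, seed=9)
        b = simulate_balance_trial(energy_truth, energy_plan, noise, seed=9)
        assert a == b

    def test_estimator_nearly_unbiased_at_low_noise(self, energy_truth, energy_plan):
        """Across 200 replicate trials at 2% assay noise the mean error of
        ingredient DE stays well inside 0.05 MJ/kg."""
        noise = NoiseModel(2.0, 2.0, 5.0)
        errors = []
        for seed in range(200):
            recs = simulate_balance_trial(energy_truth, energy_plan, noise,
                                          seed=10_000 + seed)
            est = estimate_ingredient_energies(recs, BASAL_DIET_ID)
            summary = treatment_energy_summary(est)
            errors.append(
                np.mean([summary.loc[i, "de"] - energy_truth.true_de[i]
                         for i in energy_truth.true_de])
            )
        assert abs(float(np.mean(errors))) < 0.05

    def test_missing_truth_rejected(self, energy_truth):
        plan = generate_design(2, 2, 1, 1, seed=0, diet_ids=["nope", "other"])
        with pytest.raises(ConfigError):
            simulate_balance_trial(energy_truth, plan, NO_NOISE)


class TestIlealTrial:
    def test_zero_noise_recovers_sid_exactly(self, ileal_truth, ileal_plan):
        recs, profiles = simulate_ileal_trial(ileal_truth, ileal_plan, NO_NOISE)
        table = digestibility_table(recs, profiles, ileal_truth.endogenous)
        per = table[table.diet_id != "mean"].set_index(["diet_id", "amino_acid"])
        for diet, sids in ileal_truth.true_sid.items():
            for aa, sid in sids.items():
                assert per.loc[(diet, aa), "sid_pct"] == pytest.approx(sid, abs=1e-9)

    def test_sid_aid_gap_is_exactly_the_endogenous_term(self, ileal_truth, ileal_plan):
        recs, profiles = simulate_ileal_trial(ileal_truth, ileal_plan, NO_NOISE)
        table = digestibility_table(recs, profiles, ileal_truth.endogenous)
        prof = {p.diet_id: p for p in profiles}
        per = table[table.diet_id != "mean"]
        for _, row in per.head(40).iterrows():
            aa2_g = prof[row.diet_id].aa_mg_per_kg[row.amino_acid] / 1000.0
            gap = 100.0 * ileal_truth.endogenous.loss(row.amino_acid) / aa2_g
            assert row.sid_pct - row.aid_pct == pytest.approx(gap, rel=1e-9)

    def test_endogenous_losses_recovered_from_n_free_records(
        self, ileal_truth, ileal_plan
    ):
        recs, profiles = simulate_ileal_trial(
            ileal_truth, ileal_plan, NO_NOISE, include_n_free=True
        )
        n_free = next(p for p in profiles if p.is_nitrogen_free)
        est = estimate_endogenous_losses(recs, n_free)
        for aa, loss in ileal_truth.endogenous.iaa_g_per_kg_dmi.items():
            assert est.loss(aa) == pytest.approx(loss, rel=1e-9)

    def test_constructed_aid_from_sid_and_endogenous_loss(self):
        # SID 70% with a loss of half the diet content implies AID 20%
        truth = SyntheticTruth(
            true_sid={"d": {"Trp": 70.0}},
            endogenous=EndogenousLossTable({"Trp": 0.63}),
            diet_aa_g_per_kg_dm={"d": {"Trp": 1.26}},
        )
        plan = generate_design(1, 1, 1, 1, seed=0, diet_ids=["d"])
        recs, profiles = simulate_ileal_trial(truth, plan, NO_NOISE)
        table = digestibility_table(recs, profiles, truth.endogenous)
        row = table[table.diet_id == "d"].iloc[0]
        assert row.aid_pct == pytest.approx(20.0, abs=1e-9)
        assert row.sid_pct == pytest.approx(70.0, abs=1e-9)

    def test_fully_digestible_without_loss_leaves_no_residue(self):
        truth = SyntheticTruth(
            true_sid={"d": {"Lys": 100.0}},
            endogenous=EndogenousLossTable({"Lys": 0.0}),
            diet_aa_g_per_kg_dm={"d": {"Lys": 10.0}},
        )
        plan = generate_design(1, 1, 1, 1, seed=0, diet_ids=["d"])
        recs, _ = simulate_ileal_trial(truth, plan, NO_NOISE)
        assert recs[0].aa_mg_per_kg["Lys"] == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_records(self, ileal_truth, ileal_plan):
        noise = NoiseModel(2.0, 2.0, 5.0)
        a, _ = simulate_ileal_trial(ileal_truth, ileal_plan, noise, seed=4,
                                    include_n_free=True)
        b, _ = simulate_ileal_trial(ileal_truth, ileal_plan, noise, seed=4,
                                    include_n_free=True)
        assert a == b


class TestRecoveryReport:
    def test_perfect_estimates(self):
        out = recovery_report({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
        assert out["bias"] == 0.0 and out["rmse"] == 0.0

    def test_constant_offset(self):
        out = recovery_report({"a": 2.0, "b": 3.0}, {"a": 1.0, "b": 2.0})
        assert out["bias"] == 1.0 and out["rmse"] == 1.0

    def test_coverage_with_standard_errors(self):
        out = recovery_report(
            {"a": 1.1, "b": 5.0}, {"a": 1.0, "b": 2.0},
            se={"a": 0.1, "b": 0.1},
        )
        assert out["coverage"] == 0.5

    def test_key_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            recovery_report({"a": 1.0}, {"b": 1.0})

    def test_empirical_se_matches_error_propagation(self, energy_truth, energy_plan):
        """Monte-Carlo spread of the ingredient-DE estimator agrees with
        first-order (delta-method) propagation of the assay noise."""
        noise = NoiseModel(2.0, 0.0, 0.0)
        x, frac = 0.30, 0.97
        est_de = []
        for seed in range(300):
            recs = simulate_balance_trial(energy_truth, energy_plan, noise,
                                          seed=50_000 + seed)
            est = estimate_ingredient_energies(recs, BASAL_DIET_ID)
            summary = treatment_energy_summary(est)
            est_de.append(summary.loc["ESBM 1", "de"])
        empirical_se = float(np.std(est_de, ddof=1))
        # per-observation: de_d = ge - (ge - de_d)*eps, sd = (ge - de_d)*cv
        ge = energy_truth.diet_ge["ESBM 1"]
        de_dc = energy_truth.basal_diet_de / frac
        de_d = x * energy_truth.true_de["ESBM 1"] + (1 - x) * de_dc
        sd_diet = (ge - de_d) * 0.02 / np.sqrt(6)  # 6 replicates
        sd_basal = (energy_truth.basal_diet_ge - energy_truth.basal_diet_de) \
            * 0.02 / np.sqrt(6) / frac
        analytic_se = np.sqrt(sd_diet**2 + ((1 - x) * sd_basal) ** 2) / x
        assert empirical_se == pytest.approx(analytic_se, rel=0.15)
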