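"""Cox/log-rank primitives against lifelines, scans, synergy, signatures."""
import numpy as np
import pandas as pd
import pytest

from mthetero.simulate import (SimulationConfig, simulate_cohort,
                               outcomes_frame, true_feature_carriage)
from mthetero.survival import (CONFLICT_RULES, _classify, cox_binary,
                               feature_cox_scan, fixed_signature,
                               km_survival_at, logrank_binary, logrank_many,
                               loocv_signature, multivariable_cox,
                               synergy_groups)


def random_survival(rng, n=150, p_group=0.3, hr=1.0):
    x = (rng.uniform(size=n) < p_group).astype(float)
    lam = 0.01 * hr ** x
    time = rng.exponential(1 / lam)
    censor = rng.uniform(0, 150, n)
    event = (time <= censor).astype(int)
    return np.minimum(time, censor), event, x


class TestPrimitivesAgainstLifelines:
    @pytest.mark.parametrize("hr", [0.4, 1.0, 2.5])
    def test_cox_binary_matches_lifelines(self, hr):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(int(hr * 10))
        time, event, x = random_survival(rng, hr=hr)
        beta, se, flags = cox_binary(time, event, x)
        df = pd.DataFrame({"t": time, "e": event, "x": x})
        cph = CoxPHFitter().fit(df, "t", "e")
        # Breslow vs lifelines' Efron tie handling: identical without ties,
        # compare at solver tolerance
        assert beta == pytest.approx(float(cph.params_.iloc[0]), abs=1e-3)
        assert se == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-3)

    @pytest.mark.parametrize("hr", [0.4, 1.0, 2.5])
    def test_logrank_matches_lifelines(self, hr):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(int(hr * 100) + 1)
        time, event, x = random_survival(rng, hr=hr)
        z, p = logrank_binary(time, event, x)
        ref = logrank_test(time[x == 1], time[x == 0],
                           event[x == 1], event[x == 0])
        assert p == pytest.approx(ref.p_value, rel=1e-6)
        # direction: positive z means excess hazard in the x=1 group
        if hr > 1:
            assert z > 0
        if hr < 1:
            assert z < 0

    def test_logrank_many_matches_scalar(self):
        rng = np.random.default_rng(9)
        time, event, _ = random_survival(rng)
        X = (rng.uniform(size=(len(time), 5)) < 0.3).astype(float)
        z_many, p_many = logrank_many(time, event, X)
        for j in range(X.shape[1]):
            z, p = logrank_binary(time, event, X[:, j])
            assert z_many[j] == pytest.approx(z, rel=1e-9)
            assert p_many[j] == pytest.approx(p, rel=1e-9)

    def test_separation_flagged(self):
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1, 1, 0, 0, 0])  # all events in group 1
        beta, se, flags = cox_binary(time, event, x)
        assert "separated" in flags


class TestFeatureCoxScan:
    def test_recovery_and_min_mutated(self, annotation):
        config = SimulationConfig(n_patients=1200, seed=21, noise_sd=0.0,
                                  censoring_rate=0.0,
                                  baseline_hazard=-np.log(0.3) / 120,
                                  hazard_by_feature={"OHR": 2.5, "HV1": 0.3})
        cohort = simulate_cohort(config, annotation)
        rows = []
        for p in cohort.patients:
            carried = true_feature_carriage(p, annotation)
            rows.append({"OHR": int("OHR" in carried),
                         "HV1": int("HV1" in carried),
                         "rare": 0})
        matrix = pd.DataFrame(rows, index=[p.patient_id for p in cohort.patients])
        matrix.index.name = "patient_id"
        matrix.loc[matrix.index[0], "rare"] = 1  # single carrier
        outcomes = outcomes_frame(cohort.patients)
        results = {r.feature: r for r in feature_cox_scan(matrix, outcomes)}
        assert "rare" not in results  # min_mutated rule
        assert 2.0 <= results["OHR"].hazard_ratio <= 3.0
        assert 0.2 <= results["HV1"].hazard_ratio <= 0.45
        assert results["OHR"].ci_low <= results["OHR"].hazard_ratio <= \
            results["OHR"].ci_high
        assert results["OHR"].ten_year_survival_change < 0
        assert results["HV1"].ten_year_survival_change > 0

    def test_derived_dichotomies_added(self, small_cohort):
        _, _, matrix, outcomes = small_cohort
        results = feature_cox_scan(matrix, outcomes, min_mutated=1)
        names = {r.feature for r in results}
        assert "MCN_high" in names and "mtSNV_any" in names

    def test_no_events_rejected(self, small_cohort):
        _, _, matrix, outcomes = small_cohort
        dead = outcomes.copy()
        dead["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            feature_cox_scan(matrix, dead)


class TestMultivariableCox:
    @staticmethod
    def _clinical_frame(rng, n, confounded):
        age = rng.uniform(45, 75, n)
        if confounded:
            x = (rng.uniform(size=n) < (age - 45) / 30 * 0.5).astype(float)
            lam = 0.008 * np.exp(0.05 * (age - 60))  # age drives hazard, x inert
        else:
            x = (rng.uniform(size=n) < 0.3).astype(float)
            lam = 0.008 * 2.0 ** x
        time = rng.exponential(1 / lam)
        event = (time <= 120).astype(int)
        time = np.minimum(time, 120)
        matrix = pd.DataFrame({
            "feat": x, "age": age,
            "psa": rng.lognormal(2, 0.5, n),
            "t_category": rng.choice(["T1", "T2", "T3"], n),
            "gleason": rng.choice([6, 7, 8], n)},
            index=pd.Index([f"p{i}" for i in range(n)], name="patient_id"))
        outcomes = pd.DataFrame({"patient_id": matrix.index,
                                 "time": time, "event": event})
        return matrix, outcomes

    def test_confounded_effect_vanishes_after_adjustment(self):
        rng = np.random.default_rng(31)
        matrix, outcomes = self._clinical_frame(rng, 1500, confounded=True)
        adjusted = multivariable_cox("feat", matrix, outcomes)
        assert adjusted.ci_low <= 1.0 <= adjusted.ci_high

    def test_unconfounded_matches_univariate(self):
        rng = np.random.default_rng(32)
        matrix, outcomes = self._clinical_frame(rng, 2000, confounded=False)
        adjusted = multivariable_cox("feat", matrix, outcomes)
        beta, _, _ = cox_binary(outcomes["time"], outcomes["event"],
                                matrix["feat"].to_numpy())
        ratio = adjusted.hazard_ratio / np.exp(beta)
        assert 0.8 <= ratio <= 1.25

    def test_single_level_adjuster_dropped(self):
        rng = np.random.default_rng(33)
        matrix, outcomes = self._clinical_frame(rng, 200, confounded=False)
        matrix["gleason"] = 7
        with pytest.warns(UserWarning, match="single level"):
            result = multivariable_cox("feat", matrix, outcomes)
        assert result.hazard_ratio > 0


class TestSynergyGroups:
    def test_partition_exhaustive_disjoint(self, small_cohort):
        _, _, matrix, outcomes = small_cohort
        out = synergy_groups(matrix, outcomes)
        assert len(out["groups"]) == len(matrix)
        assert set(out["groups"].unique()) <= {"neither", "either", "both"}

    def test_all_negative_single_group(self, small_cohort):
        _, _, matrix, outcomes = small_cohort
        m = matrix.copy()
        m["MYC_gain"] = 0
        m["OHR"] = 0
        out = synergy_groups(m, outcomes)
        assert (out["groups"] == "neither").all()
        assert out["km"]["both"] is None

    def test_multiplicative_hazards_rank_groups(self, annotation):
        config = SimulationConfig(n_patients=1500, seed=41, noise_sd=0.0,
                                  censoring_rate=0.0,
                                  baseline_hazard=-np.log(0.5) / 120,
                                  hazard_by_feature={"OHR": 2.0, "MYC_gain": 2.0})
        cohort = simulate_cohort(config, annotation)
        rows = []
        for p in cohort.patients:
            carried = true_feature_carriage(p, annotation)
            rows.append({"OHR": int("OHR" in carried),
                         "MYC_gain": p.nuclear_features["MYC_gain"]})
        matrix = pd.DataFrame(rows, index=[p.patient_id for p in cohort.patients])
        matrix.index.name = "patient_id"
        outcomes = outcomes_frame(cohort.patients)
        out = synergy_groups(matrix, outcomes)
        surv = {}
        for g in ("neither", "either", "both"):
            km = out["km"][g]
            below = km[km["time"] <= 60.0]
            surv[g] = below["survival"].iloc[-1]
        assert surv["both"] < surv["either"] < surv["neither"]
        assert out["pairwise_logrank_p"][("neither", "both")] < 0.01

    def test_unknown_feature_rejected(self, small_cohort):
        _, _, matrix, outcomes = small_cohort
        with pytest.raises(ValueError):
            synergy_groups(matrix, outcomes, mito_feature="nope")


class TestClassification:
    @pytest.mark.parametrize("rule,expected", [
        ("high_dominates", "high"), ("low_dominates", "low"),
        ("exclude", "intermediate")])
    def test_conflict_rules(self, rule, expected):
        assert _classify(True, True, rule) == expected

    def test_unmixed_cases(self):
        for rule in CONFLICT_RULES:
            assert _classify(False, False, rule) == "intermediate"
            assert _classify(True, False, rule) == "low"
            assert _classify(False, True, rule) == "high"

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            _classify(True, False, "coin_flip")


def planted_signature_cohort(annotation, n=1200, seed=51):
    config = SimulationConfig(n_patients=n, seed=seed, noise_sd=0.0,
                              censoring_rate=0.0,
                              baseline_hazard=-np.log(0.3) / 120,
                              hazard_by_feature={"OHR": 2.5, "HV1": 0.3})
    cohort = simulate_cohort(config, annotation)
    features = ["HV1", "OHR", "CO3", "ND5", "CYB", "RNR2", "CO1", "tRNA"]
    rows = []
    for p in cohort.patients:
        carried = true_feature_carriage(p, annotation)
        trna = {r.name for r in annotation.regions if r.region_class == "tRNA"}
        rows.append({f: int(f in carried or
                            (f == "tRNA" and bool(carried & trna)))
                     for f in features})
    matrix = pd.DataFrame(rows, index=[p.patient_id for p in cohort.patients])
    matrix.index.name = "patient_id"
    return matrix, outcomes_frame(cohort.patients)


class TestSignatures:
    def test_fixed_signature_directions(self, annotation):
        matrix, outcomes = planted_signature_cohort(annotation)
        sig = fixed_signature(matrix, outcomes, low={"HV1"}, high={"OHR"})
        assert set(sig.classes.unique()) == {"low", "intermediate", "high"}
        assert sig.low_vs_intermediate.hazard_ratio < 1
        assert sig.high_vs_intermediate.hazard_ratio > 1

    def test_fixed_signature_patient_order_invariant(self, annotation):
        matrix, outcomes = planted_signature_cohort(annotation, n=300, seed=52)
        sig1 = fixed_signature(matrix, outcomes)
        perm = matrix.sample(frac=1.0, random_state=0)
        sig2 = fixed_signature(perm, outcomes)
        assert sig1.classes.sort_index().equals(sig2.classes.sort_index())

    def test_fixed_signature_unknown_feature(self, annotation):
        matrix, outcomes = planted_signature_cohort(annotation, n=200, seed=53)
        with pytest.raises(ValueError, match="unknown"):
            fixed_signature(matrix, outcomes, low={"nope"}, high={"OHR"})

    def test_loocv_partitions_and_recovers(self, annotation):
        matrix, outcomes = planted_signature_cohort(annotation)
        sig = loocv_signature(matrix, outcomes)
        assert len(sig.classes) == len(matrix)
        assert set(sig.classes.unique()) <= {"low", "intermediate", "high"}
        # planted protective/adverse features dominate the consensus sets
        assert "HV1" in sig.consensus_low
        assert "OHR" in sig.consensus_high
        assert sig.low_vs_intermediate.hazard_ratio < 1
        assert sig.high_vs_intermediate.hazard_ratio > 1

    def test_loocv_no_mtsnv_patient_is_intermediate(self, annotation):
        matrix, outcomes = planted_signature_cohort(annotation)
        empty = matrix.index[matrix.sum(axis=1) == 0]
        sig = loocv_signature(matrix, outcomes)
        assert (sig.classes.loc[empty] == "intermediate").all()

    def test_loocv_deterministic(self, annotation):
        matrix, outcomes = planted_signature_cohort(annotation, n=250, seed=54)
        a = loocv_signature(matrix, outcomes)
        b = loocv_signature(matrix, outcomes)
        assert a.classes.equals(b.classes)

    def test_loocv_conflict_rule_applied(self, annotation):
        matrix, outcomes = planted_signature_cohort(annotation)
        both = matrix.index[(matrix["HV1"] == 1) & (matrix["OHR"] == 1)]
        if len(both):
            high_rule = loocv_signature(matrix, outcomes,
                                        conflict_rule="high_dominates")
            low_rule = loocv_signature(matrix, outcomes,
                                       conflict_rule="low_dominates")
            assert (high_rule.classes.loc[both] == "high").all()
            assert (low_rule.classes.loc[both] == "low").all()
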