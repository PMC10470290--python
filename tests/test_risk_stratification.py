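import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from plasma_subtyper import (
    RiskRule,
    SimulationConfig,
    apply_risk_rule,
    biomarker_cascade,
    generate_cohort,
    hans_classify,
    identification_metrics,
    roc_auc,
    train_subtype_classifier,
)
from plasma_subtyper.risk_stratification import DEFAULT_MARKER_CUTOFF, apply_risk_rule_vector


class TestHansClassify:
    @pytest.mark.parametrize(
        "cd10, bcl6, mum1, expected",
        [
            (1, 0, 0, "GCB"),       # CD10 alone positive
            (1, 1, 1, "GCB"),       # CD10 positive dominates
            (0, 0, 0, "nonGCB"),    # both CD10 and BCL6 negative
            (0, 0, 1, "nonGCB"),
            (0, 1, 0, "GCB"),       # BCL6+, MUM1- -> GCB
            (0, 1, 1, "nonGCB"),    # BCL6+, MUM1+ -> nonGCB
        ],
    )
    def test_decision_table(self, cd10, bcl6, mum1, expected):
        assert hans_classify(cd10, bcl6, mum1) == expected

    def test_unknown_propagates(self):
        assert hans_classify(np.nan, 1, 0) == "unknown"
        assert hans_classify(0, np.nan, 1) == "unknown"
        assert hans_classify(0, 1, None) == "unknown"
        # but CD10+ decides regardless of the others
        assert hans_classify(1, None, None) == "GCB"


class TestApplyRiskRule:
    def test_exhaustive_truth_table(self):
        rule = RiskRule()
        eps = 1e-9
        for ipi in range(6):
            for marker in (DEFAULT_MARKER_CUTOFF - eps, DEFAULT_MARKER_CUTOFF + eps):
                expected = "high" if (ipi >= 3 or marker > DEFAULT_MARKER_CUTOFF) else "low"
                assert apply_risk_rule(rule, ipi, marker) == expected

    def test_boundary_equality_is_low(self):
        assert apply_risk_rule(RiskRule(), 1, DEFAULT_MARKER_CUTOFF) == "low"

    @pytest.mark.parametrize("ipi, marker, expected", [
        (4, 10.0, "high"),          # high-IPI branch
        (2, 200.0, "high"),         # low IPI, marker above cutoff
        (1, 150.0, "low"),
    ])
    def test_stated_cases(self, ipi, marker, expected):
        assert apply_risk_rule(RiskRule(), ipi, marker) == expected

    def test_invalid_ipi_rejected(self):
        with pytest.raises(ValueError, match="IPI"):
            apply_risk_rule(RiskRule(), 7, 100.0)

    def test_third_quartile_policy_uses_low_ipi_subgroup(self):
        rule = RiskRule(marker_cutoff=1.0, cutoff_policy="third_quartile")
        ipi = np.array([0, 1, 2, 2, 1, 0, 4, 5])
        marker = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 0.5, 0.5])
        flags = apply_risk_rule_vector(rule, ipi, marker)
        q3 = np.quantile(marker[:6], 0.75)
        expected = np.where((ipi >= 3) | (marker > q3), "high", "low")
        np.testing.assert_array_equal(flags, expected)


class TestIdentificationMetrics:
    def _clinical(self, times, events):
        return pd.DataFrame({"pfs_time": times, "pfs_event": events,
                             "os_time": times, "os_event": events})

    def test_worked_improvement_example(self):
        # 25 relapse patients: combined flags 16 (0.640), IPI alone 10 (0.400)
        n = 25
        clin = self._clinical([6.0] * n, [1] * n)
        combined = np.array(["high"] * 16 + ["low"] * 9)
        ipi_alone = np.array(["high"] * 10 + ["low"] * 15)
        m = identification_metrics({"combined": combined, "ipi_alone": ipi_alone}, clin)
        assert m.identified_fraction["combined"] == pytest.approx(0.640)
        assert m.identified_fraction["ipi_alone"] == pytest.approx(0.400)
        assert m.improvement_points == pytest.approx(24.0)

    def test_flagging_everyone_gives_one(self):
        clin = self._clinical([3.0] * 10, [1] * 10)
        m = identification_metrics(
            {"combined": ["high"] * 10, "ipi_alone": ["low"] * 10}, clin
        )
        assert m.identified_fraction["combined"] == 1.0

    def test_simple_counting(self):
        clin = self._clinical([2.0] * 10 + [100.0], [1] * 10 + [0])
        flags = np.array(["high"] * 7 + ["low"] * 3 + ["low"])
        m = identification_metrics({"combined": flags, "ipi_alone": flags}, clin)
        assert m.n_event == 10
        assert m.identified_fraction["combined"] == pytest.approx(0.7)

    def test_combined_superset_implies_nonnegative_improvement(self, rng):
        # the combined rule only adds patients to the IPI-high set
        for _ in range(20):
            n = 50
            ipi = rng.integers(0, 6, size=n)
            marker = rng.uniform(0, 400, size=n)
            combined = apply_risk_rule_vector(RiskRule(), ipi, marker)
            ipi_alone = np.where(ipi >= 3, "high", "low")
            clin = self._clinical(rng.uniform(1, 11, size=n), rng.integers(0, 2, size=n))
            if not ((clin["pfs_event"] == 1) & (clin["pfs_time"] <= 12)).any():
                continue
            m = identification_metrics({"combined": combined, "ipi_alone": ipi_alone}, clin)
            assert m.improvement_points >= 0.0

    def test_event_horizon_respected(self):
        clin = self._clinical([6.0, 13.0], [1, 1])
        m = identification_metrics(
            {"combined": ["high", "high"], "ipi_alone": ["low", "low"]},
            clin, "relapse_within_12mo",
        )
        assert m.n_event == 1

    def test_no_events_rejected(self):
        clin = self._clinical([100.0] * 5, [0] * 5)
        with pytest.raises(ValueError, match="no event"):
            identification_metrics({"combined": ["low"] * 5, "ipi_alone": ["low"] * 5}, clin)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_chance(self):
        assert roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_pair_counting_example(self):
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


def cascade_inputs(seed, mediated=False):
    """Small direct simulation for the cascade: 1 planted marker + 9 nulls."""
    r = np.random.default_rng(seed)
    n = 150
    ids = [f"c{i}" for i in range(9)] + ["MARKER"]
    X = r.lognormal(mean=8.0, sigma=0.5, size=(10, n))
    ipi = r.integers(0, 6, size=n)
    if mediated:
        # marker reflects IPI only; hazard driven by IPI
        X[-1] = np.exp(0.6 * ipi + r.normal(0, 0.3, size=n) + 7)
        risk = 0.5 * (ipi - ipi.mean())
    else:
        risk = np.log(3.0) * (np.log(X[-1]) - np.log(X[-1]).mean()) / np.log(X[-1]).std()
        risk = risk + 0.2 * (ipi - ipi.mean())
    rate = 0.04 * np.exp(risk)
    t = r.exponential(1.0 / rate)
    c = r.uniform(12, 60, size=n)
    e = (t <= c).astype(int)
    t = np.minimum(t, c)
    resp = np.where(r.uniform(size=n) < 1 / (1 + np.exp(-(0.2 + 1.2 * (risk - risk.mean())))), "NR", "R")
    matrix = pd.DataFrame(X, index=ids, columns=[f"s{i}" for i in range(n)])
    clinical = pd.DataFrame({
        "sample_id": matrix.columns, "response": resp, "ipi": ipi,
        "pfs_time": t, "pfs_event": e, "os_time": t * 1.2, "os_event": e,
    })
    return matrix, clinical, ids


class TestBiomarkerCascade:
    def test_empty_candidates_empty_output(self):
        matrix, clinical, _ = cascade_inputs(0)
        out = biomarker_cascade(matrix, clinical, [])
        assert out.empty

    def test_planted_marker_survives(self):
        hits = 0
        for seed in range(5):
            matrix, clinical, ids = cascade_inputs(seed)
            out = biomarker_cascade(matrix, clinical, ids)
            hits += "MARKER" in set(out["protein_id"])
        assert hits >= 4

    def test_ipi_mediated_marker_mostly_removed(self):
        removed = 0
        for seed in range(5):
            matrix, clinical, ids = cascade_inputs(seed, mediated=True)
            out = biomarker_cascade(matrix, clinical, ids)
            if "MARKER" not in set(out["protein_id"]):
                removed += 1
            else:
                row = out[out["protein_id"] == "MARKER"].iloc[0]
                # survived stage 1/2 but the IPI-adjusted effect should be weak
                removed += row["p_multi_pfs"] > 1e-4
        assert removed >= 3

    def test_output_subset_of_candidates(self):
        matrix, clinical, ids = cascade_inputs(1)
        out = biomarker_cascade(matrix, clinical, ids[:4])
        assert set(out["protein_id"]) <= set(ids[:4])


class TestTrainSubtypeClassifier:
    def _features(self, seed, shifted=True):
        r = np.random.default_rng(seed)
        n = 150
        labels = (r.uniform(size=n) < 0.2).astype(int)
        X = r.normal(size=(n, 3))
        if shifted:
            X[labels == 1] += 1.5
        return pd.DataFrame(X, columns=["m1", "m2", "m3"]), labels

    def test_planted_subtype_learnable(self):
        aucs = []
        for seed in range(5):
            X, y = self._features(seed)
            _, _, test_auc = train_subtype_classifier(X, y, seed=seed)
            aucs.append(test_auc)
        assert np.mean(aucs) >= 0.75

    def test_permuted_labels_chance_level(self):
        aucs = []
        for seed in range(10):
            X, y = self._features(seed)
            r = np.random.default_rng(seed + 100)
            _, _, test_auc = train_subtype_classifier(X, r.permutation(y), seed=seed)
            aucs.append(test_auc)
        assert 0.35 < np.mean(aucs) < 0.65

    def test_deterministic_under_seed(self):
        X, y = self._features(3)
        a = train_subtype_classifier(X, y, seed=11)
        b = train_subtype_classifier(X, y, seed=11)
        assert a[1] == b[1] and a[2] == b[2]


class TestCohortLevelMarker:
    def test_marker_elevated_in_nonresponders(self):
        """The planted marker separates R from NR in the generated cohort."""
        from plasma_subtyper.differential import rank_sum_test

        ms, ab, clinical, truth = generate_cohort(SimulationConfig(seed=5))
        union = pd.concat([ms.values, ab.values.loc[~ab.values.index.isin(ms.values.index)]])
        dl = clinical[clinical["group"] == "DLBCL"]
        vals = union.loc[truth.marker_protein_id, dl["sample_id"]].to_numpy()
        nr = vals[(dl["response"] == "NR").to_numpy()]
        r = vals[(dl["response"] == "R").to_numpy()]
        _, p = rank_sum_test(nr, r)
        assert p < 0.01
        assert nr.mean() > r.mean()
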