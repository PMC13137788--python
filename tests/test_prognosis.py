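import numpy as np
import pandas as pd
import pytest

from midriver import prognosis, synthetic
from midriver.prognosis import (
    CMPSModel,
    SurvivalRecord,
    cmps_score,
    fit_cmps_model,
    logrank,
    stratify_by_median,
)


def _model(coefs):
    return CMPSModel(cancer_type="LUAD", coefficients=coefs)


class TestScore:
    def test_direct_substitution(self):
        m = _model({"g1": 0.5, "g2": -0.2})
        expr = pd.DataFrame({"P1": [2.0, 1.0]}, index=["g1", "g2"])
        assert cmps_score(m, expr)["P1"] == pytest.approx(0.8)

    def test_zero_expression_scores_zero(self):
        m = _model({"g1": 0.5, "g2": -0.2})
        expr = pd.DataFrame(np.zeros((2, 3)), index=["g1", "g2"],
                            columns=["P1", "P2", "P3"])
        assert np.allclose(cmps_score(m, expr), 0.0)

    def test_linearity_in_coefficients(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(2, 5)), index=["g1", "g2"])
        s1 = cmps_score(_model({"g1": 0.5, "g2": -0.2}), expr)
        s2 = cmps_score(_model({"g1": 1.0, "g2": -0.4}), expr)
        assert np.allclose(2 * s1, s2)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(3, 6)), index=["a", "b", "c"],
                            columns=[f"P{i}" for i in range(6)])
        m = _model({"a": 1.0, "b": -0.5, "c": 0.25})
        s = cmps_score(m, expr)
        shuffled = expr.iloc[::-1, ::-1]
        assert np.allclose(cmps_score(m, shuffled)[s.index], s)

    def test_missing_gene_named(self):
        m = _model({"gX": 1.0})
        expr = pd.DataFrame({"P1": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="gX"):
            cmps_score(m, expr)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            CMPSModel(cancer_type="x", coefficients={})
        with pytest.raises(ValueError):
            CMPSModel(cancer_type="x", coefficients={"g": 0.0})


class TestStratify:
    def test_even_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        g = stratify_by_median(s)
        assert set(g[g == "low"].index) == {"a", "b"}
        assert set(g[g == "high"].index) == {"c", "d"}

    def test_median_ties_go_low(self):
        s = pd.Series([1.0, 2.0, 2.0, 4.0], index=list("abcd"))
        g = stratify_by_median(s)
        assert set(g[g == "low"].index) == {"a", "b", "c"}
        assert set(g[g == "high"].index) == {"d"}

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_median(pd.Series([1.0]))

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            stratify_by_median(pd.Series([2.0, 2.0, 2.0]))


class TestLogrank:
    def test_identical_groups_null(self):
        recs = [
            SurvivalRecord("A1", 5, 1), SurvivalRecord("A2", 8, 0),
            SurvivalRecord("B1", 5, 1), SurvivalRecord("B2", 8, 0),
        ]
        groups = pd.Series(["high", "high", "low", "low"],
                           index=["A1", "A2", "B1", "B2"])
        stat, p = logrank(groups, recs)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_oe_table(self):
        """Six-patient fixture: the statistic equals the manually summed
        (O-E)^2/V over distinct event times."""
        recs = [
            SurvivalRecord("a", 1, 1), SurvivalRecord("b", 3, 1),
            SurvivalRecord("c", 5, 0), SurvivalRecord("d", 2, 1),
            SurvivalRecord("e", 4, 1), SurvivalRecord("f", 6, 1),
        ]
        groups = pd.Series(
            ["high", "high", "high", "low", "low", "low"],
            index=["a", "b", "c", "d", "e", "f"],
        )
        # manual Mantel-Haenszel table over event times of the "high" group
        times = {r.patient_id: r.time for r in recs}
        events = {r.patient_id: r.event for r in recs}
        o_minus_e, var = 0.0, 0.0
        for t in sorted({times[p] for p in times if events[p]}):
            at_risk = [p for p in times if times[p] >= t]
            d = sum(1 for p in at_risk if times[p] == t and events[p])
            n = len(at_risk)
            n1 = sum(1 for p in at_risk if groups[p] == "high")
            d1 = sum(
                1 for p in at_risk
                if groups[p] == "high" and times[p] == t and events[p]
            )
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_stat = o_minus_e**2 / var
        stat, p = logrank(groups, recs)
        assert stat == pytest.approx(expected_stat, rel=1e-9)

    def test_label_symmetric(self):
        rng = np.random.default_rng(5)
        recs = [
            SurvivalRecord(f"P{i}", float(rng.exponential(10) + 0.1),
                           int(rng.random() < 0.7))
            for i in range(30)
        ]
        groups = pd.Series(
            ["high" if i < 15 else "low" for i in range(30)],
            index=[f"P{i}" for i in range(30)],
        )
        flipped = groups.map({"high": "low", "low": "high"})
        assert logrank(groups, recs)[0] == pytest.approx(logrank(flipped, recs)[0])

    def test_no_events_rejected(self):
        recs = [SurvivalRecord("a", 1, 0), SurvivalRecord("b", 2, 0)]
        groups = pd.Series(["high", "low"], index=["a", "b"])
        with pytest.raises(ValueError, match="events"):
            logrank(groups, recs)

    def test_null_calibration_under_permutation(self):
        """Exchangeable survival with random group labels gives a roughly
        uniform log-rank p (coarse check on 200 label permutations)."""
        rng = np.random.default_rng(8)
        recs = [
            SurvivalRecord(f"P{i}", float(rng.exponential(10) + 0.01),
                           int(rng.random() < 0.7))
            for i in range(40)
        ]
        ids = [r.patient_id for r in recs]
        ps = []
        for _ in range(200):
            labels = np.array(["high"] * 20 + ["low"] * 20)
            rng.shuffle(labels)
            ps.append(logrank(pd.Series(labels, index=ids), recs)[1])
        ps = np.asarray(ps)
        assert 0.30 < (ps < 0.5).mean() < 0.70


class TestFit:
    def test_recovers_planted_gene(self):
        """One gene with unit log-hazard effect among 9 noise genes is
        selected with a positive sign in at least 18/20 seeds (n=300)."""
        genes = [f"G{i}" for i in range(10)]
        hits = 0
        for seed in range(20):
            expr, recs, _ = synthetic.simulate_survival(
                300, genes, {"G0": 1.0}, seed=seed
            )
            model = fit_cmps_model(expr, recs, seed=seed)
            if model.coefficients.get("G0", 0) > 0:
                hits += 1
        assert hits >= 18

    def test_score_reproduces_fit_scale(self):
        genes = [f"G{i}" for i in range(5)]
        expr, recs, _ = synthetic.simulate_survival(200, genes, {"G0": 1.0}, seed=3)
        model = fit_cmps_model(expr, recs, seed=3)
        scores = cmps_score(model, expr)
        assert scores.index.equals(expr.columns)
        assert scores.std() > 0

    def test_all_censored_rejected(self):
        genes = ["G0", "G1"]
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(2, 30)), index=genes,
                            columns=[f"P{i}" for i in range(30)])
        recs = [SurvivalRecord(f"P{i}", 10.0, 0) for i in range(30)]
        with pytest.raises(ValueError, match="censored"):
            fit_cmps_model(expr, recs)

    def test_missing_patient_rejected(self):
        genes = ["G0"]
        expr = pd.DataFrame([[1.0]], index=genes, columns=["P0"])
        recs = [SurvivalRecord("P1", 5.0, 1)]
        with pytest.raises(ValueError, match="missing patients"):
            fit_cmps_model(expr, recs)

    def test_model_json_round_trip(self):
        m = _model({"g1": 0.5, "g2": -0.2})
        assert CMPSModel.from_dict(m.to_dict()).coefficients == m.coefficients
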