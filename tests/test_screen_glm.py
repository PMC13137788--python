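import numpy as np
import pandas as pd
import pytest

from midriver import screen_glm, synthetic
from midriver.screen_glm import (
    GRNAEffect,
    ScreenDataset,
    day0_frequencies,
    fit_grna_glm,
    qc_filter,
    run_screen,
    screen_results,
)


def _cells(rows):
    df = pd.DataFrame(
        rows, columns=["barcode", "n_genes", "n_umis", "mito_pct", "assigned_grnas"]
    )
    return df


BOUNDARY_CELLS = [
    # (genes, umis, mito, grnas) straddling every strict threshold
    ("c_pass", 600, 400, 5.0, ["g1"]),
    ("c_multi", 600, 400, 5.0, ["g1", "g2"]),
    ("c_genes", 500, 400, 5.0, ["g1"]),   # boundary 500 excluded
    ("c_umis", 600, 300, 5.0, ["g1"]),    # boundary 300 excluded
    ("c_mito", 600, 400, 10.0, ["g1"]),   # boundary 10 excluded
]


class TestQcFilter:
    def test_boundary_fixture_bit_exact(self):
        cells = _cells(BOUNDARY_CELLS)
        passed, report = qc_filter(cells)
        assert list(passed["barcode"]) == ["c_pass"]
        assert report == {
            "input": 5, "passed": 1, "low_genes": 1, "low_umis": 1,
            "high_mito": 1, "multi_grna": 1,
        }

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(0)
        rows = [
            (
                f"c{i}",
                int(rng.integers(200, 5000)),
                int(rng.integers(100, 2000)),
                float(rng.uniform(0, 20)),
                ["g"] * int(rng.integers(0, 3)),
            )
            for i in range(200)
        ]
        passed, _ = qc_filter(_cells(rows))
        brute = {
            b for b, g, u, m, gr in rows
            if g > 500 and u > 300 and m < 10 and len(gr) == 1
        }
        assert set(passed["barcode"]) == brute

    def test_multi_reason_cells_counted_per_reason(self):
        cells = _cells([("bad", 100, 100, 50.0, [])])
        _, report = qc_filter(cells)
        assert (
            report["low_genes"] == report["low_umis"]
            == report["high_mito"] == report["multi_grna"] == 1
        )


class TestDay0Frequencies:
    def test_simple_normalization(self):
        f = day0_frequencies(pd.Series({"a": 10, "b": 30}))
        assert f["a"] == pytest.approx(0.25) and f["b"] == pytest.approx(0.75)

    def test_uniform(self):
        f = day0_frequencies(pd.Series({f"g{i}": 7 for i in range(5)}))
        assert np.allclose(f, 0.2)

    def test_pseudocount(self):
        f = day0_frequencies(pd.Series({"a": 0, "b": 3}), pseudocount=1)
        assert f["a"] == pytest.approx(0.2) and f["b"] == pytest.approx(0.8)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            day0_frequencies(pd.Series({"a": 0.0}))


def _dataset(assignments, controls=("c1", "c2"), targets=("t1",), day0=None):
    cells = pd.DataFrame(
        {"barcode": [f"b{i}" for i in range(len(assignments))], "grna": assignments}
    )
    grnas = list(targets) + list(controls)
    gmap = pd.DataFrame(
        {
            "gene": [f"GENE_{g}" for g in targets] + ["ctrl"] * len(controls),
            "is_control": [False] * len(targets) + [True] * len(controls),
        },
        index=pd.Index(grnas, name="grna"),
    )
    if day0 is None:
        day0 = pd.Series(100.0, index=grnas)
    return ScreenDataset(cells=cells, grna_map=gmap, day0_counts=day0)


class TestDatasetValidation:
    def test_unmapped_grna_rejected(self):
        with pytest.raises(ValueError, match="unmapped"):
            _dataset(["t1", "zzz"])

    def test_control_required(self):
        cells = pd.DataFrame({"barcode": ["b0"], "grna": ["t1"]})
        gmap = pd.DataFrame(
            {"gene": ["X"], "is_control": [False]},
            index=pd.Index(["t1"], name="grna"),
        )
        with pytest.raises(ValueError, match="control"):
            ScreenDataset(cells=cells, grna_map=gmap,
                          day0_counts=pd.Series({"t1": 10.0}))

    def test_day0_freq_sums_to_one(self):
        ds = _dataset(["t1", "c1", "c2"])
        assert ds.day0_freq.sum() == pytest.approx(1.0, abs=1e-12)


class TestFitGrnaGlm:
    def test_low_cells_flag(self):
        ds = _dataset(["t1"] * 5 + ["c1"] * 5 + ["c2"] * 5)
        eff = fit_grna_glm(ds, "t1", min_cells=50)
        assert eff.flag == "low_cells" and eff.p is None

    def test_absent_target_flags_separation_depleting(self):
        spec = synthetic.ScreenSpec(n_grnas=3, n_controls=20, n_cells=4000,
                                    fitness={"sg000": 0.0}, seed=5)
        cells, day0, gmap, _ = synthetic.simulate_screen(spec)
        ds = ScreenDataset.from_tables(cells, gmap, day0)
        eff = fit_grna_glm(ds, "sg000")
        assert eff.flag == "separation"
        assert eff.log2fc < 0  # reported as depleting

    def test_control_grna_rejected(self):
        ds = _dataset(["t1"] * 30 + ["c1"] * 30 + ["c2"] * 30)
        with pytest.raises(ValueError, match="control"):
            fit_grna_glm(ds, "c1")

    def test_log2fc_is_beta1_over_ln2(self):
        ds = _dataset(
            ["t1"] * 40 + ["c1"] * 80 + ["c2"] * 20 + ["c3"] * 30,
            controls=("c1", "c2", "c3"),
        )
        eff = fit_grna_glm(ds, "t1")
        assert eff.log2fc == pytest.approx(eff.beta1 / np.log(2))

    def test_methods_agree_in_sign(self):
        spec = synthetic.ScreenSpec(n_grnas=2, n_controls=20, n_cells=5000,
                                    fitness={"sg000": 0.5, "sg001": 2.0}, seed=6)
        cells, day0, gmap, _ = synthetic.simulate_screen(spec)
        ds = ScreenDataset.from_tables(cells, gmap, day0)
        for g in ("sg000", "sg001"):
            signs = {
                np.sign(fit_grna_glm(ds, g, method=m).beta1)
                for m in ("covariate", "linear", "offset")
            }
            assert len(signs) == 1


class TestScreenResults:
    def _eff(self, grna, p, log2fc, flag="ok"):
        return GRNAEffect(grna=grna, gene=f"G_{grna}", beta1=log2fc * np.log(2),
                          log2fc=log2fc, lrt_stat=1.0, p=p, flag=flag)

    def test_classification_rules(self):
        effects = [
            self._eff("a", 1e-5, -2.0),
            self._eff("b", 1e-5, 1.0),
            self._eff("c", 0.8, -3.0),
        ]
        res = screen_results(effects).set_index("grna")
        assert res.loc["a", "class"] == "lethal"
        assert res.loc["b", "class"] == "enriched"
        assert res.loc["c", "class"] == "neutral"

    def test_low_cells_excluded_from_family(self):
        effects = [
            self._eff("a", 0.01, -1.0),
            GRNAEffect(grna="x", gene="G_x", beta1=None, log2fc=None,
                       lrt_stat=None, p=None, flag="low_cells"),
        ]
        res = screen_results(effects).set_index("grna")
        assert res.loc["x", "class"] == "untested"
        assert res.loc["a", "fdr"] == pytest.approx(0.01)  # family of one

    def test_bh_matches_oracle(self):
        rng = np.random.default_rng(7)
        ps = rng.uniform(size=30)
        effects = [self._eff(f"g{i}", float(p), 1.0) for i, p in enumerate(ps)]
        res = screen_results(effects)
        m = len(ps)
        order = np.argsort(ps)
        naive = np.empty(m)
        for i in range(m):
            naive[order[i]] = min(m * ps[order[k]] / (k + 1) for k in range(i, m))
        assert np.allclose(res["fdr"].to_numpy(), np.minimum(naive, 1.0))

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            screen_results([GRNAEffect(grna="x", gene="g", beta1=None,
                                       log2fc=None, lrt_stat=None, p=None,
                                       flag="low_cells")])


class TestDeterminism:
    def test_identical_dataset_identical_results(self):
        spec = synthetic.ScreenSpec(n_grnas=5, n_controls=10, n_cells=2000,
                                    fitness={"sg000": 0.5}, seed=11)
        frames = []
        for _ in range(2):
            cells, day0, gmap, _ = synthetic.simulate_screen(spec)
            ds = ScreenDataset.from_tables(cells, gmap, day0)
            frames.append(run_screen(ds))
        pd.testing.assert_frame_equal(frames[0], frames[1])
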