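"""Moderated-t enrichment selection: shrinkage, BH, fold filter, presets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from capri.enrichment import (
    PRESETS,
    IntensityMatrix,
    bh_adjust,
    fit_f_dist,
    fold_filter,
    moderated_t,
    preprocess,
    read_maxquant_table,
    run_contrast,
)

SAMPLES = [f"xl{i}" for i in range(1, 5)] + [f"ctrl{i}" for i in range(1, 5)]
GROUPS = {s: ("crosslinked" if s.startswith("xl") else "control") for s in SAMPLES}


def make_matrix(values, metadata=None, ids=None):
    df = pd.DataFrame(values, columns=SAMPLES, index=ids)
    return IntensityMatrix(df, dict(GROUPS), metadata)


class TestPreprocess:
    def test_no_missing_is_identity(self):
        vals = np.full((3, 8), 1000.0)
        raw, log2 = preprocess(make_matrix(vals))
        assert (raw.to_numpy() == 1000.0).all()
        assert np.allclose(log2.to_numpy(), np.log2(1000.0))

    def test_missing_imputed_with_global_minimum(self):
        vals = np.full((2, 8), 5000.0)
        vals[0, 0] = 0.0
        vals[1, 3] = 1000.0
        raw, _ = preprocess(make_matrix(vals))
        assert raw.iloc[0, 0] == 1000.0

    def test_contaminants_dropped(self):
        vals = np.full((3, 8), 1000.0)
        meta = pd.DataFrame({"contaminant": [False, True, False], "reverse": [False, False, True]})
        raw, _ = preprocess(make_matrix(vals, metadata=meta))
        assert list(raw.index) == [0]

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            preprocess(make_matrix(np.zeros((2, 8))))


class TestModeratedT:
    def test_prior_at_sample_variance_is_shrinkage_fixed_point(self, rng):
        """With s0^2 equal to the common sample variance, shrinkage is a
        no-op: s~^2 = s^2 and t~ equals the ordinary pooled t (larger df
        aside, the statistic itself is unchanged)."""
        base = rng.normal(20, 1, size=50)
        noise = rng.standard_normal(8)  # same residuals every row -> same s2
        data = base[:, None] + noise[None, :]
        df = pd.DataFrame(data, columns=SAMPLES)
        v = float(moderated_t(df, GROUPS, prior=(4.0, 1.0))["s2"].iloc[0])
        res = moderated_t(df, GROUPS, prior=(4.0, v))
        assert np.allclose(res["s2_post"], res["s2"], rtol=1e-9)
        t_ref = np.array(
            [stats.ttest_ind(row[:4], row[4:], equal_var=True).statistic for row in data]
        )
        assert np.allclose(res["t"], t_ref, rtol=1e-6)

    def test_frozen_limma_reference(self):
        """Agreement with the Bioconductor limma eBayes implementation.

        Reference values computed once with limma 3.58.1 on the matrix below
        (30 features, 4+4 design, first 5 shifted by +3) and frozen here.
        """
        rng = np.random.default_rng(20240917)
        base = rng.normal(20.0, 1.5, size=30)
        data = base[:, None] + rng.normal(0.0, 0.4, size=(30, 8))
        data[:5, :4] += 3.0
        res = moderated_t(pd.DataFrame(data, columns=SAMPLES), GROUPS)
        assert res.attrs["d0"] == pytest.approx(20.9992841265, rel=1e-6)
        assert res.attrs["s02"] == pytest.approx(0.1064499912, rel=1e-6)
        T = [15.2082, 11.6167, 13.2689, 12.2018, 13.83, 0.883975, -1.01311,
             -0.396682, 0.630775, -1.03766, 0.936761, 0.852316, 2.07532,
             -0.771236, 0.204238, 0.792834, 0.20092, -0.944809, -2.67939,
             -0.0790357, -1.39059, -0.673567, 0.45094, 0.242617, 0.0573371,
             -1.17889, 0.944719, 1.47636, 0.773651, -2.00224]
        P = [9.21875e-15, 5.19912e-12, 2.40737e-13, 1.69342e-12, 9.03779e-14,
             0.384514, 0.320003, 0.69472, 0.533491, 0.308632, 0.357186,
             0.401536, 0.04761, 0.447265, 0.839699, 0.434787, 0.842267,
             0.353135, 0.0124085, 0.937587, 0.175707, 0.506313, 0.655634,
             0.810136, 0.954699, 0.248726, 0.35318, 0.151416, 0.445859,
             0.0553968]
        np.testing.assert_allclose(res["t"], T, rtol=1e-4)
        np.testing.assert_allclose(res["p"], P, rtol=1e-3)

    def test_d0_infinite_limit_uses_prior_only(self, rng):
        """Identical sample variances across features (log-variance spread
        zero) force d0 = inf; every posterior variance collapses to s0^2."""
        mu = rng.normal(20, 2, size=(40, 1))
        noise = rng.normal(0, 0.5, size=(1, 8))
        data = mu + noise  # same residuals in every row -> identical s2
        with pytest.warns(RuntimeWarning):
            res = moderated_t(pd.DataFrame(data, columns=SAMPLES), GROUPS)
        assert not np.isfinite(res.attrs["d0"])
        assert np.allclose(res["s2_post"], res.attrs["s02"])

    def test_parameter_recovery(self):
        """Method-of-moments recovers (d0, s02) within 20% at 2000 features."""
        rng = np.random.default_rng(7)
        d0_true, s02_true, dg = 6.0, 0.25, 6
        s2 = s02_true * d0_true / rng.chisquare(d0_true, size=2000)
        sample_s2 = s2 * rng.chisquare(dg, size=2000) / dg
        d0_hat, s02_hat = fit_f_dist(sample_s2, dg)
        assert d0_hat == pytest.approx(d0_true, rel=0.2)
        assert s02_hat == pytest.approx(s02_true, rel=0.2)

    def test_requires_two_replicates(self):
        df = pd.DataFrame(np.ones((3, 3)), columns=["xl1", "xl2", "ctrl1"])
        with pytest.raises(ValueError):
            moderated_t(df, {"xl1": "crosslinked", "xl2": "crosslinked", "ctrl1": "control"})


def brute_force_bh(p):
    """Textbook step-up: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestFoldFilter:
    def make_raw(self, xl_mean, ctrl_mean):
        vals = np.column_stack([np.full((1, 4), xl_mean), np.full((1, 4), ctrl_mean)])
        return pd.DataFrame(vals.reshape(1, 8), columns=SAMPLES)

    def test_strict_inequality(self):
        assert fold_filter(self.make_raw(9000, 1000), GROUPS).iloc[0]
        assert not fold_filter(self.make_raw(8000, 1000), GROUPS).iloc[0]

    def test_threshold_one(self):
        assert fold_filter(self.make_raw(1001, 1000), GROUPS, threshold=1).iloc[0]

    def test_zero_control_mean_errors(self):
        with pytest.raises(ValueError):
            fold_filter(self.make_raw(100, 0), GROUPS)


class TestRunContrast:
    def spike_matrix(self, seed=11, n=500, n_spiked=50, fold=16.0, sigma=0.3):
        rng = np.random.default_rng(seed)
        base = rng.normal(20, 1.5, size=n)
        log2 = base[:, None] + rng.normal(0, sigma, size=(n, 8))
        log2[:n_spiked, :4] += np.log2(fold)
        ids = [f"f{i:04d}" for i in range(n)]
        return make_matrix(np.exp2(log2), ids=ids), set(ids[:n_spiked])

    def test_adj_preset_recovers_spike(self):
        matrix, spiked = self.spike_matrix()
        res = run_contrast(matrix, "ADJ")
        selected = set(res.index[res["selected"]])
        recall = len(selected & spiked) / len(spiked)
        fdr = len(selected - spiked) / max(1, len(selected))
        assert recall >= 0.9
        assert fdr <= 0.1

    def test_fourfold_spike_blocked_by_fold_filter(self):
        matrix, spiked = self.spike_matrix(fold=4.0)
        res = run_contrast(matrix, "ADJ")
        assert not (res.loc[sorted(spiked), "pass_fold"]).any()

    def test_selection_monotone_in_thresholds(self):
        matrix, _ = self.spike_matrix(seed=3, n=200, n_spiked=30)
        from capri.enrichment import ContrastPreset

        tight = run_contrast(matrix, ContrastPreset("t", fdr=0.01, fold=8))
        loose = run_contrast(matrix, ContrastPreset("l", fdr=0.10, fold=2))
        assert set(tight.index[tight["selected"]]) <= set(loose.index[loose["selected"]])

    def test_fadom_requires_two_crosslinked_detections(self):
        matrix, _ = self.spike_matrix(seed=5, n=100, n_spiked=10)
        vals = matrix.intensities.copy()
        vals.loc["f0000", ["xl2", "xl3", "xl4"]] = 0.0  # detected once only
        matrix = IntensityMatrix(vals, matrix.groups)
        res = run_contrast(matrix, "FAdom")
        assert "f0000" not in res.index
        assert "f0001" in res.index

    def test_rbpome_requires_unique_peptides(self):
        matrix, _ = self.spike_matrix(seed=6, n=50, n_spiked=5)
        meta = pd.DataFrame(
            {"unique_peptides": [1] * 10 + [5] * 40}, index=matrix.intensities.index
        )
        matrix = IntensityMatrix(matrix.intensities, matrix.groups, meta)
        res = run_contrast(matrix, "RBPome")
        assert len(res) == 40

    def test_unknown_preset(self):
        matrix, _ = self.spike_matrix(seed=2, n=20, n_spiked=2)
        with pytest.raises(ValueError, match="preset"):
            run_contrast(matrix, "nope")


def test_read_maxquant_table(tmp_path):
    path = tmp_path / "peptides.txt"
    rows = ["Sequence\tProteins\tIntensity xl1\tIntensity xl2\tIntensity ctrl1\t"
            "Intensity ctrl2\tPotential contaminant\tReverse"]
    rows.append("PEPTIDEK\tP1\t100\t110\t10\t11\t\t")
    rows.append("CONTAMK\tCON1\t50\t55\t50\t52\t+\t")
    path.write_text("\n".join(rows) + "\n")
    groups = {"xl1": "crosslinked", "xl2": "crosslinked", "ctrl1": "control", "ctrl2": "control"}
    matrix = read_maxquant_table(path, groups)
    assert list(matrix.intensities.columns) == ["xl1", "xl2", "ctrl1", "ctrl2"]
    raw, _ = preprocess(matrix)
    assert list(raw.index) == ["PEPTIDEK"]  # contaminant removed
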