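import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from ecoassembly.drivers import (correlate_axes, dbrda_forward, pca, pcnm,
                                 pcoa, rda_stats, shift_to_nonnegative)
from ecoassembly.drivers import AxisSet


class TestPcnm:
    def test_transect_axes_are_sinusoid_like(self):
        """On an evenly spaced transect the eigenvectors behave like
        discretized sinusoids: later axes oscillate faster."""
        coords = np.column_stack([np.arange(10.0), np.zeros(10)])
        axes = pcnm(coords)
        s = axes.scores.to_numpy()
        assert s.shape[1] >= 2

        def sign_changes(v):
            sg = np.sign(v[np.abs(v) > 1e-12])
            return int((sg[1:] != sg[:-1]).sum())

        assert sign_changes(s[:, 0]) < sign_changes(s[:, 1])

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 100, size=(25, 2))
        s = pcnm(coords).scores.to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * max(np.diag(gram).max(), 1)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pcnm(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="identical"):
            pcnm(np.zeros((5, 2)))


class TestPca:
    def test_perfectly_correlated_pair(self):
        x = np.linspace(0, 1, 30)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        axes = pca(df)
        ev = axes.explained_variance
        assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 5)),
                          columns=list("abcde"))
        axes = pca(df)
        z = (df - df.mean()) / df.std(ddof=1)
        recon = axes.scores.to_numpy() @ axes.loadings.to_numpy().T
        assert np.allclose(recon, z.to_numpy(), atol=1e-10)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            pca(df)

    def test_recovers_block_structure(self):
        """Loadings separate two planted correlated variable blocks."""
        rng = np.random.default_rng(5)
        n = 200
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        df = pd.DataFrame({
            "a1": f1 + 0.1 * rng.normal(size=n),
            "a2": f1 + 0.1 * rng.normal(size=n),
            "b1": f2 + 0.1 * rng.normal(size=n),
            "b2": f2 + 0.1 * rng.normal(size=n),
        })
        lo = pca(df).loadings
        for axis in ["PCA1", "PCA2"]:
            v = lo[axis]
            same_block = abs(v["a1"] * v["a2"]) + abs(v["b1"] * v["b2"])
            cross = abs(v["a1"] * v["b1"])
            assert same_block > cross

    def test_missing_values_refused(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [1, 2.0]})
        with pytest.raises(ValueError, match="missing"):
            pca(df)


class TestPcoa:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 2))
        d = squareform(pdist(pts))
        axes = pcoa(d)
        _, _, disparity = procrustes(pts, axes.scores.to_numpy()[:, :2])
        assert disparity < 1e-8

    def test_zero_matrix(self):
        axes = pcoa(np.zeros((4, 4)))
        assert axes.scores.shape[1] == 0

    def test_negative_eigenvalues_reported(self):
        # Bray-Curtis-like semimetric produces negative eigenvalues
        rng = np.random.default_rng(3)
        x = rng.random((10, 6))
        d = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                d[i, j] = np.abs(x[i] - x[j]).sum() / (x[i] + x[j]).sum()
        axes = pcoa(d)
        assert axes.negative_eigenvalues is not None
        assert np.isfinite(axes.scores.to_numpy()).all()


def _axis_set(scores: pd.DataFrame) -> AxisSet:
    return AxisSet(kind="PCA", scores=scores)


class TestDbrda:
    def test_euclidean_equals_classical_rda(self):
        """dbRDA on Euclidean distances reproduces the classical RDA
        pseudo-F computed directly on the raw data."""
        rng = np.random.default_rng(4)
        n = 25
        x = pd.DataFrame({"A": rng.normal(size=n), "B": rng.normal(size=n)})
        y = np.column_stack([
            x["A"] + 0.3 * rng.normal(size=n),
            rng.normal(size=n), rng.normal(size=n)])
        d = squareform(pdist(y))
        from ecoassembly.drivers import _response_matrix
        y_emb, _ = _response_matrix(d)
        xc = x.to_numpy() - x.to_numpy().mean(axis=0)
        r2_db, f_db = rda_stats(y_emb, xc)
        r2_cl, f_cl = rda_stats(y - y.mean(axis=0), xc)
        assert f_db == pytest.approx(f_cl, abs=1e-8)
        assert r2_db == pytest.approx(r2_cl, abs=1e-10)

    def test_planted_signal_selected_first(self):
        rng = np.random.default_rng(6)
        n = 40
        scores = pd.DataFrame(rng.normal(size=(n, 4)),
                              columns=["A1", "A2", "A3", "A4"])
        y = np.column_stack([scores["A3"], scores["A3"]])
        sel = dbrda_forward(y, _axis_set(scores), alpha=0.05,
                            n_perm=199, seed=0)
        assert sel.selected[0] == "A3"
        assert sel.steps.iloc[0]["p"] == pytest.approx(1 / 200)

    def test_adjusted_r2_nondecreasing_and_deterministic(self):
        rng = np.random.default_rng(7)
        n = 40
        scores = pd.DataFrame(rng.normal(size=(n, 5)),
                              columns=[f"A{i}" for i in range(5)])
        y = (scores[["A0"]].to_numpy() + 0.5 * scores[["A2"]].to_numpy()
             + 0.2 * rng.normal(size=(n, 1)))
        a = dbrda_forward(y, _axis_set(scores), n_perm=99, seed=1)
        b = dbrda_forward(y, _axis_set(scores), n_perm=99, seed=1)
        pd.testing.assert_frame_equal(a.steps, b.steps)
        cum = a.steps["adj_r2_cum"].to_numpy()
        assert np.all(np.diff(cum) >= -1e-12)

    def test_alpha_resolution_guard(self):
        scores = pd.DataFrame(np.eye(5), columns=list("abcde"))
        with pytest.raises(ValueError, match="resolve"):
            dbrda_forward(np.eye(5), _axis_set(scores), alpha=0.001,
                          n_perm=9)


class TestShift:
    def test_shift_to_nonnegative(self):
        v = np.array([[0.0, -3.0, 1.0], [-3.0, 0.0, 2.0], [1.0, 2.0, 0.0]])
        s = shift_to_nonnegative(v)
        off = s[~np.eye(3, dtype=bool)]
        assert off.min() == 0.0
        assert np.all(np.diag(s) == 0)


class TestCorrelateAxes:
    def test_monotone_pairs(self):
        x = pd.DataFrame({"u": np.arange(10.0)})
        up = pd.DataFrame({"v": np.exp(np.arange(10.0))})
        down = pd.DataFrame({"w": -np.arange(10.0) ** 3})
        assert correlate_axes(x, up)["rho"].iloc[0] == pytest.approx(1.0)
        assert correlate_axes(x, down)["rho"].iloc[0] == pytest.approx(-1.0)

    def test_bonferroni_family(self):
        rng = np.random.default_rng(8)
        a = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x1", "x2"])
        b = pd.DataFrame(rng.normal(size=(30, 3)), columns=["y1", "y2", "y3"])
        tab = correlate_axes(a, b)
        assert len(tab) == 6
        expected = np.minimum(1.0, tab["p"] * 6)
        assert np.allclose(tab["p_bonferroni"], expected)

    def test_constant_column_rejected(self):
        a = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        b = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            correlate_axes(a, b)

    def test_noise_calibration(self):
        """Independent noise pairs: raw p < 0.05 about once in 20 tests,
        Bonferroni-adjusted essentially never."""
        rng = np.random.default_rng(9)
        hits_raw = hits_adj = 0
        for rep in range(20):
            a = pd.DataFrame({"x": rng.normal(size=40)})
            b = pd.DataFrame({"y": rng.normal(size=40)})
            tab = correlate_axes(a, b, family=20)
            hits_raw += int(tab["p"].iloc[0] < 0.05)
            hits_adj += int(tab["p_bonferroni"].iloc[0] < 0.05)
        assert hits_raw <= 5
        assert hits_adj == 0
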