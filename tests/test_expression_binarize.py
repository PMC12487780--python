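"""Cell filtering, Gaussian-mixture binarization and observable series."""

import numpy as np
import pandas as pd
import pytest

import frustnet as fn


def _expr_from_bits(bits, genes, samples, spec, seed=0):
    values = fn.synthetic_expression(bits, spec, seed=seed)
    return fn.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples)
    )


class TestFilterCells:
    def test_identity_band(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.random((10, 20)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"c{i}" for i in range(20)],
        )
        expr = fn.ExpressionMatrix(values=df)
        out = fn.filter_cells(expr, 0.0, 1.0)
        assert out.values.shape == df.shape

    def test_quantile_band_on_known_counts(self):
        # cell k expresses exactly k+1 genes (counts 1..100)
        n = 100
        mat = np.zeros((n, n))
        for k in range(n):
            mat[: k + 1, k] = 1.0
        expr = fn.ExpressionMatrix(
            values=pd.DataFrame(
                mat,
                index=[f"g{i}" for i in range(n)],
                columns=[f"c{i}" for i in range(n)],
            )
        )
        out = fn.filter_cells(expr, 0.05, 0.95)
        counts = (out.values.to_numpy() > 0).sum(axis=0)
        # linear-interpolation quantiles of 1..100: q05 = 5.95, q95 = 95.05
        assert counts.min() == 6
        assert counts.max() == 95
        assert out.values.shape[1] == 90

    def test_empty_cell_removed(self):
        mat = np.ones((5, 4))
        mat[:, 0] = 0.0
        expr = fn.ExpressionMatrix(
            values=pd.DataFrame(
                mat, index=list("abcde"), columns=list("wxyz")
            )
        )
        out = fn.filter_cells(expr, 0.3, 1.0)
        assert "w" not in out.values.columns

    def test_annotations_follow_filter(self):
        mat = np.ones((3, 4))
        mat[:, 0] = 0.0
        ann = pd.DataFrame({"time": [0, 1, 2, 3]}, index=list("wxyz"))
        expr = fn.ExpressionMatrix(
            values=pd.DataFrame(mat, index=list("abc"), columns=list("wxyz")),
            annotations=ann,
        )
        out = fn.filter_cells(expr, 0.3, 1.0)
        assert list(out.annotations.index) == ["x", "y", "z"]


class TestGmmBinarize:
    def test_well_separated_recovery(self):
        rng = np.random.default_rng(1)
        bits = rng.integers(0, 2, size=(30, 200), dtype=np.uint8)
        spec = fn.SyntheticSpec(mu_off=0.0, mu_on=10.0, sigma=1.0)
        expr = _expr_from_bits(
            bits, [f"g{i}" for i in range(30)],
            [f"c{i}" for i in range(200)], spec,
        )
        out = fn.gmm_binarize(expr, seed=0)
        assert (out.to_numpy() == bits).mean() >= 0.99

    def test_recovery_with_dropout(self):
        """At >=5 sigma separation and dropout up to 0.3, bits of the
        observed (non-dropped) entries are recovered at >=95%."""
        rng = np.random.default_rng(2)
        bits = rng.integers(0, 2, size=(30, 300), dtype=np.uint8)
        spec = fn.SyntheticSpec(
            mu_off=1.0, mu_on=6.0, sigma=1.0, dropout=0.3
        )
        values = fn.synthetic_expression(bits, spec, seed=3)
        expr = fn.ExpressionMatrix(
            values=pd.DataFrame(
                values,
                index=[f"g{i}" for i in range(30)],
                columns=[f"c{i}" for i in range(300)],
            )
        )
        out = fn.gmm_binarize(expr, seed=0).to_numpy()
        observed = values > 0
        assert (out[observed] == bits[observed]).mean() >= 0.95

    def test_constant_gene_all_silent(self):
        df = pd.DataFrame(
            np.vstack([np.full(50, 3.0), np.r_[np.zeros(25), np.full(25, 8.0)]]),
            index=["flat", "bimodal"],
            columns=[f"c{i}" for i in range(50)],
        )
        out = fn.gmm_binarize(fn.ExpressionMatrix(values=df), seed=0)
        assert (out.loc["flat"] == 0).all()
        assert out.loc["bimodal"].sum() == 25

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        bits = rng.integers(0, 2, size=(10, 80), dtype=np.uint8)
        spec = fn.SyntheticSpec(mu_off=1.0, mu_on=6.0, sigma=1.0)
        genes = [f"g{i}" for i in range(10)]
        samples = [f"c{i}" for i in range(80)]
        expr = _expr_from_bits(bits, genes, samples, spec)
        perm = rng.permutation(80)
        shuffled = fn.ExpressionMatrix(values=expr.values.iloc[:, perm])
        a = fn.gmm_binarize(expr, seed=0)
        b = fn.gmm_binarize(shuffled, seed=0)
        assert np.array_equal(
            a.iloc[:, perm].to_numpy(), b.to_numpy()
        )

    def test_approximate_scale_equivariance(self):
        """Rescaling a gene's expression by a positive constant leaves the
        classification essentially unchanged (the pseudo-log transform makes
        this approximate rather than exact)."""
        rng = np.random.default_rng(5)
        bits = rng.integers(0, 2, size=(10, 150), dtype=np.uint8)
        spec = fn.SyntheticSpec(mu_off=1.0, mu_on=8.0, sigma=1.0)
        genes = [f"g{i}" for i in range(10)]
        samples = [f"c{i}" for i in range(150)]
        expr = _expr_from_bits(bits, genes, samples, spec)
        scaled = fn.ExpressionMatrix(values=expr.values * 16.0)
        a = fn.gmm_binarize(expr, seed=0).to_numpy()
        b = fn.gmm_binarize(scaled, seed=0).to_numpy()
        assert (a == b).mean() >= 0.95

    def test_determinism(self):
        rng = np.random.default_rng(6)
        bits = rng.integers(0, 2, size=(8, 60), dtype=np.uint8)
        spec = fn.SyntheticSpec(mu_off=1.0, mu_on=6.0, sigma=1.0, dropout=0.1)
        expr = _expr_from_bits(
            bits, [f"g{i}" for i in range(8)], [f"c{i}" for i in range(60)], spec
        )
        assert fn.gmm_binarize(expr, seed=9).equals(fn.gmm_binarize(expr, seed=9))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fn.gmm_binarize(pd.DataFrame())


class TestTrajectoryObservables:
    def _series(self, standin, n_steps=6, n_per_step=8, seed=0):
        """Synthetic time course morphing the SM anchor into the PE anchor."""
        grn, anchors = standin
        rng = np.random.default_rng(seed)
        sm, pe = anchors["SM"], anchors["PE"]
        samples, times = [], []
        for t in range(n_steps):
            frac = t / (n_steps - 1)
            for r in range(n_per_step):
                flip = rng.random(grn.n_genes) < frac
                samples.append(np.where(flip, pe, sm))
                times.append(t)
        binary = pd.DataFrame(
            np.array(samples, dtype=np.uint8).T,
            index=list(grn.genes),
            columns=[f"s{i}" for i in range(len(samples))],
        )
        ann = pd.DataFrame({"time": times}, index=binary.columns)
        return binary, ann

    def test_all_zero_sample(self, standin):
        grn, _ = standin
        binary = pd.DataFrame(
            np.zeros((grn.n_genes, 1), dtype=np.uint8),
            index=list(grn.genes),
            columns=["s0"],
        )
        series = fn.trajectory_observables(binary, grn, fn.BUILTIN_MARKERS)
        row = series.observables.iloc[0]
        assert row["phi_ps"] == 0 and row["phi_em"] == 0
        zero = np.zeros(grn.n_genes, dtype=np.uint8)
        assert row["driving_force"] == fn.driving_force(grn, zero)

    def test_fixed_point_has_zero_driving_force(self, standin, standin_ensemble):
        grn, _ = standin
        state = standin_ensemble.states[0]
        binary = pd.DataFrame(
            state[:, None], index=list(grn.genes), columns=["s0"]
        )
        series = fn.trajectory_observables(binary, grn, fn.BUILTIN_MARKERS)
        assert series.observables["driving_force"].iloc[0] == 0

    def test_morphing_series_trends(self, standin):
        """A series morphing SM -> PE shows a rising PS score and a falling
        mean driving force toward the ordered end states."""
        grn, _ = standin
        binary, ann = self._series(standin)
        series = fn.trajectory_observables(
            binary, grn, fn.BUILTIN_MARKERS, annotations=ann
        )
        by_time = series.observables.groupby("time").mean()
        ps = by_time["phi_ps"].to_numpy()
        assert ps[0] < 0 < ps[-1]
        assert (np.diff(ps) >= 0).all()  # monotone rise
        df = by_time["driving_force"].to_numpy()
        assert df[-1] < df.max()  # order re-established at the end
        assert series.adjacent_tests is not None
        assert (series.adjacent_tests["p_value"].dropna() >= 0).all()

    def test_common_gene_subnetwork(self, standin):
        grn, anchors = standin
        keep = list(grn.genes)[:40]
        binary = pd.DataFrame(
            anchors["SM"][:40][:, None], index=keep, columns=["s0"]
        )
        series = fn.trajectory_observables(binary, grn, fn.BUILTIN_MARKERS)
        assert series.subnetwork.n_genes == 40
        assert series.subnetwork.n_edges < grn.n_edges

    def test_empty_intersection_rejected(self, standin):
        grn, _ = standin
        binary = pd.DataFrame(
            np.zeros((2, 1), dtype=np.uint8), index=["x", "y"], columns=["s0"]
        )
        with pytest.raises(ValueError):
            fn.trajectory_observables(binary, grn, fn.BUILTIN_MARKERS)

    def test_embedding_coordinates_attached(self, standin, standin_ensemble):
        grn, _ = standin
        model = fn.fit_embedding(
            standin_ensemble.states.astype(float), components=(1, 2)
        )
        binary = pd.DataFrame(
            standin_ensemble.states[:5].T,
            index=list(grn.genes),
            columns=[f"s{i}" for i in range(5)],
        )
        series = fn.trajectory_observables(
            binary, grn, fn.BUILTIN_MARKERS, model=model
        )
        assert series.coordinates.shape == (5, 2)
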