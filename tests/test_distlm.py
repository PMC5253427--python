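"""Distance-based linear models: traces, pseudo-F, permutation schemes."""

import numpy as np
import pandas as pd
import pytest

from landgenkit.core_data import DistanceMatrix, PopulationAttributes
from landgenkit.distlm import (
    PredictorSet,
    distlm_conditional,
    distlm_forward,
    distlm_marginal,
    distlm_population_level,
    gower_center,
    migration_to_distance,
)
from landgenkit.errors import ValidationError


def euclid_dm(y, labels=None):
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix(
        labels=labels or [f"u{k}" for k in range(len(y))], values=d, kind="euclidean"
    )


class TestGowerCenter:
    def test_one_dimensional_identity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        G = gower_center(euclid_dm(y))
        yc = y - y.mean()
        assert np.allclose(G, np.outer(yc, yc), atol=1e-9)

    def test_zero_matrix(self):
        D = DistanceMatrix(labels=list("abcd"), values=np.zeros((4, 4)))
        assert np.allclose(gower_center(D), 0.0)

    def test_row_sums_zero_and_trace_nonnegative(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(15, 3))
        G = gower_center(euclid_dm(pts))
        assert np.allclose(G.sum(axis=0), 0.0, atol=1e-9)
        assert np.trace(G) >= 0
        # Euclidean-embeddable: eigenvalues non-negative
        assert np.linalg.eigvalsh(G).min() > -1e-9


class TestMarginal:
    def test_reduces_to_classical_regression_f(self):
        rng = np.random.default_rng(1)
        n = 30
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        D = euclid_dm(y)
        preds = PredictorSet(data=pd.DataFrame({"x": x}), unit_labels=D.labels)
        row = distlm_marginal(D, preds, n_perm=49, seed=0)[0]
        # classical F computed from first principles
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        ssr = ((X @ beta - y.mean()) ** 2).sum()
        sse = (resid**2).sum()
        F = (ssr / 1) / (sse / (n - 2))
        assert row.pseudo_F == pytest.approx(F, abs=1e-9)
        assert row.pct_var == pytest.approx(100 * ssr / (ssr + sse), abs=1e-9)

    def test_categorical_matches_skbio_permanova(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix as SkDM

        rng = np.random.default_rng(2)
        n = 24
        groups = ["g1"] * 8 + ["g2"] * 8 + ["g3"] * 8
        y = rng.normal(size=(n, 2)) + np.array([[0, 0]] * 8 + [[1, 0]] * 8 + [[0, 2]] * 8)
        D = euclid_dm(y)
        preds = PredictorSet(data=pd.DataFrame({"grp": groups}), unit_labels=D.labels)
        row = distlm_marginal(D, preds, n_perm=49, seed=0)[0]
        res = skbio_stats.permanova(SkDM(D.values, ids=D.labels), grouping=groups, permutations=9)
        assert row.pseudo_F == pytest.approx(res["test statistic"], abs=1e-9)

    def test_constant_predictor_rejected(self):
        D = euclid_dm(np.arange(6.0))
        preds = PredictorSet(data=pd.DataFrame({"c": np.ones(6)}), unit_labels=D.labels)
        with pytest.raises(ValidationError, match="singular"):
            distlm_marginal(D, preds, n_perm=9, seed=0)

    def test_variance_decomposition_conservation(self):
        rng = np.random.default_rng(3)
        n = 20
        y = rng.normal(size=(n, 2))
        x = rng.normal(size=n)
        D = euclid_dm(y)
        G = gower_center(D)
        from landgenkit.distlm import _hat, _trace_prod

        H = _hat(x[:, None])
        I = np.eye(n)
        explained = _trace_prod(H, G)
        residual = float(((I - H) * ((I - H) @ G)).sum())
        assert explained + residual == pytest.approx(np.trace(G), abs=1e-9)


class TestConditional:
    def test_predictor_equal_to_covariate_is_singular(self):
        rng = np.random.default_rng(4)
        n = 15
        x = rng.normal(size=n)
        D = euclid_dm(rng.normal(size=n))
        preds = PredictorSet(
            data=pd.DataFrame({"x": x, "x_copy": x}), unit_labels=D.labels
        )
        with pytest.raises(ValidationError, match="singular"):
            distlm_conditional(D, preds, covariates="x", n_perm=9, seed=0)

    def test_noise_predictor_explains_nothing_given_coordinates(self):
        rng = np.random.default_rng(6)
        n = 100
        coords = rng.normal(size=(n, 2))
        D = euclid_dm(coords @ np.array([1.0, 0.7]))
        preds = PredictorSet(
            data=pd.DataFrame(
                {"cx": coords[:, 0], "cy": coords[:, 1], "noise": rng.normal(size=n)}
            ),
            unit_labels=D.labels,
            groups={"coordinates": ["cx", "cy"]},
        )
        rows = distlm_conditional(D, preds, covariates="coordinates", n_perm=49, seed=0)
        noise_row = next(r for r in rows if r.predictor == "noise")
        assert abs(noise_row.pct_var) < 2.0

    def test_trace_arithmetic_oracle(self):
        rng = np.random.default_rng(7)
        n = 12
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = x + 0.5 * z + rng.normal(size=n)
        D = euclid_dm(y)
        preds = PredictorSet(data=pd.DataFrame({"x": x, "z": z}), unit_labels=D.labels)
        row = next(
            r
            for r in distlm_conditional(D, preds, covariates="z", n_perm=9, seed=0)
            if r.predictor == "x"
        )
        # independent trace arithmetic with explicit projections
        G = gower_center(D)
        ones = np.ones((n, 1))
        Xc = np.hstack([ones, z[:, None]])
        Xf = np.hstack([ones, z[:, None], x[:, None]])
        Hc = Xc @ np.linalg.inv(Xc.T @ Xc) @ Xc.T
        Hf = Xf @ np.linalg.inv(Xf.T @ Xf) @ Xf.T
        added = np.trace(Hf @ G @ Hf) - np.trace(Hc @ G @ Hc)
        resid = np.trace((np.eye(n) - Hf) @ G @ (np.eye(n) - Hf))
        F = (added / 1) / (resid / (n - 2 - 1))
        assert row.pseudo_F == pytest.approx(F, abs=1e-9)
        assert row.pct_var == pytest.approx(100 * added / np.trace(G), abs=1e-9)


class TestForward:
    def test_duplicate_predictor_adds_nothing(self):
        rng = np.random.default_rng(8)
        n = 15
        x = rng.normal(size=n)
        D = euclid_dm(2 * x + rng.normal(scale=0.1, size=n))
        preds = PredictorSet(
            data=pd.DataFrame({"x": x, "x_dup": x}), unit_labels=D.labels
        )
        rows = distlm_forward(D, preds, n_perm=9, seed=0)
        assert rows[0].predictor in ("x", "x_dup")
        assert rows[1].pct_var == pytest.approx(0.0, abs=1e-9) or np.isnan(rows[1].pseudo_F)

    def test_ordering_recovery(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n = 60
            coords = rng.normal(size=(n, 2))
            elev = rng.normal(size=n)
            signal = coords @ np.array([1.0, 1.0]) + 0.45 * elev
            D = euclid_dm(signal + rng.normal(scale=0.3, size=n))
            preds = PredictorSet(
                data=pd.DataFrame(
                    {
                        "cx": coords[:, 0],
                        "cy": coords[:, 1],
                        "elevation": elev,
                        "noise": rng.normal(size=n),
                    }
                ),
                unit_labels=D.labels,
                groups={"coordinates": ["cx", "cy"]},
            )
            rows = distlm_forward(D, preds, n_perm=9, seed=seed)
            order = [r.predictor for r in rows]
            if order[0] == "coordinates" and order[1] == "elevation":
                hits += 1
        assert hits >= int(0.8 * n_seeds)

    def test_sequential_decomposition_identity(self):
        rng = np.random.default_rng(9)
        n = 18
        data = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": rng.normal(size=n),
            }
        )
        y = data["a"] + 0.3 * data["b"] - 0.7 * data["c"] + rng.normal(size=n)
        D = euclid_dm(y.to_numpy())
        preds = PredictorSet(data=data, unit_labels=D.labels)
        rows = distlm_forward(D, preds, n_perm=9, seed=0)
        total_added = sum(r.pct_var for r in rows)
        # full model explained fraction
        G = gower_center(D)
        X = data.to_numpy()
        from landgenkit.distlm import _hat, _trace_prod

        full = 100 * _trace_prod(_hat(X), G) / np.trace(G)
        assert total_added == pytest.approx(full, abs=1e-9)


class TestPopulationLevel:
    def _inputs(self, k=5, seed=0):
        rng = np.random.default_rng(seed)
        labels = [f"pop{i}" for i in range(k)]
        fst = euclid_dm(rng.uniform(size=k), labels=labels)
        m = rng.uniform(0, 0.1, size=(k, k))
        np.fill_diagonal(m, 0.0)
        np.fill_diagonal(m, 1 - m.sum(axis=1))
        m1 = migration_to_distance(m, labels, "upper")
        m2 = migration_to_distance(m, labels, "lower")
        attrs = PopulationAttributes(
            population_ids=labels,
            n_census=rng.integers(50, 400, size=k).astype(float),
            n_effective=rng.uniform(20, 150, size=k),
            centroid_x=rng.uniform(0, 1e5, size=k),
            centroid_y=rng.uniform(0, 1e5, size=k),
        )
        geo = euclid_dm(
            np.column_stack([attrs.centroid_x, attrs.centroid_y]), labels=labels
        )
        return fst, m1, m2, attrs, geo

    def test_delegation_identity_with_marginal(self):
        fst, m1, m2, attrs, geo = self._inputs()
        res = distlm_population_level(fst, m1, m2, attrs, geo, n_perm=49, seed=3)
        # recompute the N_e marginal row directly
        labels = fst.labels
        mean_geo = geo.values.sum(axis=1) / (len(labels) - 1)
        data = pd.DataFrame(
            {
                "n_effective": attrs.n_effective,
                "n_census": attrs.n_census,
                "mean_geo_distance": mean_geo,
            }
        )
        preds = PredictorSet(data=data, unit_labels=labels)
        direct = distlm_marginal(fst, preds, n_perm=49, seed=0)
        ne_direct = next(r for r in direct if r.predictor == "n_effective")
        ne_pop = next(r for r in res["fst"]["marginal"] if r.predictor == "n_effective")
        assert ne_pop.pseudo_F == pytest.approx(ne_direct.pseudo_F, abs=1e-9)

    def test_migration_to_distance_directions(self):
        labels = ["a", "b", "c"]
        m = np.array([[0.9, 0.06, 0.04], [0.01, 0.97, 0.02], [0.03, 0.05, 0.92]])
        m1 = migration_to_distance(m, labels, "upper")
        m2 = migration_to_distance(m, labels, "lower")
        assert m1.values[0, 1] == pytest.approx(1 - 0.06)
        assert m2.values[0, 1] == pytest.approx(1 - 0.01)
        assert m1.values[1, 2] == pytest.approx(1 - 0.02)

    def test_too_few_populations_rejected(self):
        fst, m1, m2, attrs, geo = self._inputs(k=3)
        with pytest.raises(ValidationError, match="4 populations"):
            distlm_population_level(fst, m1, m2, attrs, geo, n_perm=9, seed=0)

    def test_constant_ne_is_singular(self):
        fst, m1, m2, attrs, geo = self._inputs()
        attrs.n_effective = np.full_like(attrs.n_effective, 50.0)
        with pytest.raises(ValidationError, match="singular"):
            distlm_population_level(fst, m1, m2, attrs, geo, n_perm=9, seed=0)
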