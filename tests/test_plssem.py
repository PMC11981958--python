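import numpy as np
import pandas as pd
import pytest

from ednariver.plssem import (
    PathModel,
    default_model,
    effects_decomposition,
    fit_plspm,
    permutation_test,
)
from ednariver.synthetic import (
    DEFAULT_PATH_COEFFICIENTS,
    SimConfig,
    indicators_from_latents,
    simulate_structural,
)


def _two_latent_model():
    return PathModel(
        latents=["X", "Y"],
        blocks={"X": ["x"], "Y": ["y"]},
        edges=[("X", "Y")],
    )


class TestSingleIndicatorCollapse:
    def test_exact_slope_recovered(self, rng):
        x = rng.normal(size=200)
        data = pd.DataFrame({"x": x, "y": 0.8 * x})
        res = fit_plspm(data, _two_latent_model())
        assert res.path("X", "Y") == pytest.approx(0.8 * x.std(ddof=1) / (0.8 * x).std(ddof=1), abs=1e-10)
        assert res.path("X", "Y") == pytest.approx(1.0, abs=1e-10)  # standardized slope of exact line
        assert res.converged

    def test_collapses_to_standardized_ols_path_analysis(self, rng):
        """With single-indicator blocks every path coefficient equals the
        partial regression coefficient from a normal-equations oracle."""
        n = 300
        e = rng.normal(size=n)
        f = -0.5 * e + rng.normal(0, 0.8, n)
        w = 0.4 * e + 0.5 * f + rng.normal(0, 0.7, n)
        b = -0.7 * e - 0.2 * f - 0.1 * w + rng.normal(0, 0.6, n)
        data = pd.DataFrame({"elevation": e, "footprint": f, "wq": w, "biodiv": b})
        model = PathModel(
            latents=["elevation", "footprint", "wq", "biodiv"],
            blocks={k: [k2] for k, k2 in zip(
                ["elevation", "footprint", "wq", "biodiv"],
                ["elevation", "footprint", "wq", "biodiv"],
            )},
            edges=[
                ("elevation", "footprint"),
                ("elevation", "wq"),
                ("footprint", "wq"),
                ("elevation", "biodiv"),
                ("footprint", "biodiv"),
                ("wq", "biodiv"),
            ],
        )
        res = fit_plspm(data, model)

        def ols_beta(y, cols):
            Z = (data[cols] - data[cols].mean()) / data[cols].std(ddof=1)
            yv = (data[y] - data[y].mean()) / data[y].std(ddof=1)
            return np.linalg.lstsq(Z.values, yv.values, rcond=None)[0]

        for target, preds in [
            ("footprint", ["elevation"]),
            ("wq", ["elevation", "footprint"]),
            ("biodiv", ["elevation", "footprint", "wq"]),
        ]:
            oracle = ols_beta(target, preds)
            for pred, b_hat in zip(preds, oracle):
                assert res.path(pred, target) == pytest.approx(b_hat, abs=1e-8)

    def test_row_duplication_invariance(self, rng):
        x = rng.normal(size=80)
        data = pd.DataFrame({"x": x, "y": 0.6 * x + rng.normal(0, 0.5, 80)})
        res1 = fit_plspm(data, _two_latent_model())
        res2 = fit_plspm(pd.concat([data, data], ignore_index=True), _two_latent_model())
        assert res1.path("X", "Y") == pytest.approx(res2.path("X", "Y"), abs=1e-9)


class TestFormativeBlocks:
    def test_sign_flip_of_indicator_leaves_paths_unchanged(self, rng):
        cfg = SimConfig(seed=5)
        lat = simulate_structural(cfg, 800, rng)
        data = indicators_from_latents(lat, cfg, rng)
        model = default_model()
        res1 = fit_plspm(data, model)
        flipped = data.copy()
        flipped["TP"] = -flipped["TP"]
        res2 = fit_plspm(flipped, model)
        for r in res1.paths.itertuples(index=False):
            assert abs(res2.path(r.source, r.target)) == pytest.approx(
                abs(r.coefficient), abs=0.02
            )

    def test_schemes_agree_on_strong_structure(self, rng):
        cfg = SimConfig(seed=9)
        lat = simulate_structural(cfg, 2000, rng)
        data = indicators_from_latents(lat, cfg, rng)
        res_c = fit_plspm(data, default_model(scheme="centroid"))
        res_f = fit_plspm(data, default_model(scheme="factorial"))
        res_p = fit_plspm(data, default_model(scheme="path"))
        for r in res_c.paths.itertuples(index=False):
            assert res_f.path(r.source, r.target) == pytest.approx(r.coefficient, abs=0.02)
            assert res_p.path(r.source, r.target) == pytest.approx(r.coefficient, abs=0.02)

    def test_constant_indicator_raises(self, rng):
        data = pd.DataFrame({"x": np.ones(50), "y": rng.normal(size=50)})
        with pytest.raises(ValueError, match="constant"):
            fit_plspm(data, _two_latent_model())

    def test_zero_disturbance_limit_recovers_exactly(self):
        """With no structural disturbance and no indicator noise the path
        model is deterministic and PLS recovers it to numerical tolerance."""
        rng = np.random.default_rng(3)
        n = 400
        e = rng.normal(size=n)
        f = -0.5452 * e
        w = 0.4739 * e + 0.5485 * f
        b = -0.7056 * e - 0.1779 * f - 0.0626 * w
        data = pd.DataFrame(
            {"elevation": e, "footprint": f, "TP": w, "TN": w, "BOD5": w, "TOC": w,
             "TD": b, "FD": b, "GD": -b}
        )
        res = fit_plspm(data, default_model())
        # deterministic chain: footprint, wq are exact functions of elevation,
        # so only the first path is identified without collinearity issues
        assert abs(res.path("elevation", "footprint")) == pytest.approx(1.0, abs=1e-6)


class TestEffects:
    def _result_with(self, coefs, model):
        rows = [
            {"source": s, "target": t, "coefficient": c} for (s, t), c in coefs.items()
        ]
        from ednariver.plssem import PLSResult

        return PLSResult(
            model=model,
            outer_weights={},
            loadings={},
            scores=pd.DataFrame(),
            paths=pd.DataFrame(rows),
            r_squared={},
            iterations=1,
            converged=True,
        )

    def test_chain_indirect_is_product(self):
        model = PathModel(
            latents=["A", "B", "C"],
            blocks={"A": ["a"], "B": ["b"], "C": ["c"]},
            edges=[("A", "B"), ("B", "C")],
        )
        res = self._result_with({("A", "B"): 0.5, ("B", "C"): 0.4}, model)
        eff = effects_decomposition(res, model)
        row = eff[eff.relation == "A -> C"].iloc[0]
        assert row.direct == 0.0
        assert row.indirect == pytest.approx(0.2)
        assert row.total == pytest.approx(0.2)

    def test_reference_topology_with_unit_coefficients(self):
        model = default_model()
        coefs = {edge: 1.0 for edge in model.edges}
        res = self._result_with(coefs, model)
        eff = effects_decomposition(res, model)
        row = eff[eff.relation == "elevation -> biodiversity"].iloc[0]
        # three indirect routes: via footprint, via WQ, via footprint→WQ
        assert row.indirect == pytest.approx(3.0)
        assert row.total == pytest.approx(4.0)

    def test_no_multi_step_paths_means_zero_indirect(self):
        model = _two_latent_model()
        res = self._result_with({("X", "Y"): 0.7}, model)
        eff = effects_decomposition(res, model)
        assert (eff.indirect == 0).all()


class TestPermutation:
    def test_deterministic_under_seed(self, rng):
        cfg = SimConfig(seed=2)
        lat = simulate_structural(cfg, 60, rng)
        data = indicators_from_latents(lat, cfg, rng)
        p1 = permutation_test(data, default_model(), n_perm=30, seed=7)
        p2 = permutation_test(data, default_model(), n_perm=30, seed=7)
        pd.testing.assert_frame_equal(p1, p2)

    def test_strong_signal_reaches_minimum_p(self, rng):
        cfg = SimConfig(seed=4, indicator_noise_sd=0.05, facet_noise_sd=0.05)
        lat = simulate_structural(cfg, 100, rng)
        data = indicators_from_latents(lat, cfg, rng)
        p = permutation_test(data, default_model(), n_perm=100, seed=1)
        row = p[(p.source == "elevation") & (p.target == "biodiversity")].iloc[0]
        assert row.p_perm == pytest.approx(1 / 101)

    def test_null_data_gives_large_p_for_exogenous_paths(self, rng):
        n = 80
        data = pd.DataFrame(
            rng.normal(size=(n, 9)),
            columns=["elevation", "footprint", "TP", "TN", "BOD5", "TOC", "TD", "FD", "GD"],
        )
        p = permutation_test(data, default_model(), n_perm=60, seed=3)
        elev_paths = p[p.source == "elevation"]
        assert (elev_paths.p_perm > 0.05).mean() >= 2 / 3
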