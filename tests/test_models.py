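import numpy as np
import pandas as pd
import pytest

import boxnet as bn
from boxnet import metrics as met
from boxnet import models as mod
from boxnet.models import (
    LocationScaleModel,
    ModelSpec,
    build_response_table,
    design_matrices,
    fit_community_model,
    fit_location_scale,
    permutation_effect_test,
    standardize,
)
from boxnet.permutation import apply_swaps_synchronized, generate_swap_chain


def simulate_ls(
    seed, n_groups=80, per_group=6, beta=(1.0, -0.5, 0.8), gamma=(0.0, 0.4), tau=0.7
):
    """Self-generated location-scale data with known parameters."""
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x1, x2])
    Z = np.column_stack([np.ones(n), x1])
    groups = np.repeat(np.arange(n_groups), per_group)
    u = rng.normal(scale=tau, size=n_groups)
    sigma = np.exp(Z @ np.asarray(gamma))
    y = X @ np.asarray(beta) + u[groups] + rng.normal(scale=sigma)
    return y, X, Z, groups


# ---------------------------------------------------------------------------
# helpers


def test_standardize():
    z = standardize(pd.Series([1.0, 2.0, 3.0]))
    assert z.mean() == pytest.approx(0.0)
    assert z.std(ddof=0) == pytest.approx(1.0, rel=1e-6) or z.std() == pytest.approx(1.0, rel=1e-6)
    # constant input does not blow up
    z0 = standardize(np.array([2.0, 2.0, 2.0]))
    assert np.all(np.isfinite(z0))


def test_build_response_table(small_response_table):
    t = small_response_table
    for col in ("individual_id", "window", "phase", "d_degree", "d_strength",
                "sociality_z", "loss_z"):
        assert col in t.columns
    per_ind = t.drop_duplicates("individual_id")
    assert per_ind["sociality_z"].mean() == pytest.approx(0.0, abs=1e-9)
    assert abs(per_ind["sociality_z"].std() - 1.0) < 0.05
    # attribute constant within individual
    assert (t.groupby("individual_id")["loss_z"].nunique() == 1).all()


def test_design_matrices_interaction(small_response_table):
    spec = ModelSpec(response="d_degree", variant="interaction")
    X, names, Z, z_names = design_matrices(small_response_table, spec)
    n_windows = small_response_table["window"].nunique()
    n_t = n_windows - 1
    assert names[0] == "Intercept"
    assert len(names) == 1 + n_t + 3 + 3 * n_t
    assert X.shape == (len(small_response_table), len(names))
    assert z_names == ["scale_Intercept", "scale_sociality_z", "scale_loss_z",
                       "scale_sociality_z:loss_z"]
    # interaction column really is the product
    k_soc = names.index("sociality_z")
    k_loss = names.index("loss_z")
    k_int = names.index("sociality_z:loss_z")
    assert np.allclose(X[:, k_int], X[:, k_soc] * X[:, k_loss])


def test_design_matrices_additive(small_response_table):
    spec = ModelSpec(variant="additive")
    X, names, _, _ = design_matrices(small_response_table, spec)
    assert not any(":" in n and n.startswith("t") for n in names)
    assert "sociality_z:loss_z" in names


def test_reference_window_is_first_post(small_response_table):
    spec = ModelSpec()
    _, names, _, _ = design_matrices(small_response_table, spec)
    first_post = sorted(
        small_response_table.loc[small_response_table["phase"] == "post", "window"]
    )[0]
    assert f"t{first_post}" not in names


# ---------------------------------------------------------------------------
# the model itself


def test_intercept_only_recovers_sample_mean():
    rng = np.random.default_rng(0)
    y = rng.normal(loc=3.0, scale=2.0, size=400)
    X = np.ones((400, 1))
    Z = np.ones((400, 1))
    model = LocationScaleModel(y, X, Z, None, ["Intercept"], ["scale_Intercept"])
    res = model.fit()
    assert res.converged
    assert res.params["Intercept"] == pytest.approx(y.mean(), abs=1e-6)
    assert np.exp(res.scale_params["scale_Intercept"]) == pytest.approx(
        y.std(ddof=0), rel=1e-4
    )


def test_analytic_gradient_matches_numeric():
    from scipy.optimize import check_grad

    y, X, Z, groups = simulate_ls(1, n_groups=30, per_group=5)
    model = LocationScaleModel(
        y, X, Z, groups, ["b0", "b1", "b2"], ["g0", "g1"]
    )
    theta0 = model._start() + 0.05
    err = check_grad(
        lambda th: model._nll_grad(th)[0],
        lambda th: model._nll_grad(th)[1],
        theta0,
    )
    assert err < 1e-4 * max(1.0, np.linalg.norm(model._nll_grad(theta0)[1]))


def test_parameter_recovery_single_replicate():
    y, X, Z, groups = simulate_ls(2, n_groups=200, per_group=10)
    model = LocationScaleModel(y, X, Z, groups, ["b0", "b1", "b2"], ["g0", "g1"])
    res = model.fit()
    assert res.converged
    beta_hat = res.params.to_numpy()
    se = res.bse.to_numpy()[:3]
    for k, true in enumerate([1.0, -0.5, 0.8]):
        assert abs(beta_hat[k] - true) < 4 * se[k]
    assert res.tau == pytest.approx(0.7, abs=0.15)
    assert res.scale_params["g1"] == pytest.approx(0.4, abs=0.1)


def test_matches_statsmodels_mixedlm():
    """With constant scale, the model reduces to a random-intercept LMM."""
    import statsmodels.api as sm

    y, X, _, groups = simulate_ls(3, n_groups=60, per_group=6, gamma=(0.2, 0.0))
    Z = np.ones((len(y), 1))
    model = LocationScaleModel(y, X, Z, groups, ["b0", "b1", "b2"], ["g0"])
    res = model.fit()
    ml = sm.MixedLM(y, X, groups=groups).fit(reml=False)
    assert np.allclose(res.params.to_numpy(), ml.fe_params, atol=1e-4)
    tau2 = float(np.asarray(ml.cov_re)[0, 0])
    sigma2 = np.exp(2 * res.scale_params["g0"])
    assert sigma2 == pytest.approx(ml.scale, rel=1e-3)
    assert res.tau ** 2 == pytest.approx(tau2, rel=2e-3, abs=1e-4)
    assert res.llf == pytest.approx(ml.llf, abs=1e-4)


def test_results_api(small_response_table):
    res = fit_location_scale(small_response_table, ModelSpec(variant="interaction"))
    assert res.converged
    tab = res.coefficient_table()
    assert {"estimate", "se", "lower", "upper"} <= set(tab.columns)
    ci = res.conf_int()
    mean_ci = ci.loc[res.params.index]
    assert (mean_ci["lower"] <= res.params + 1e-12).all()
    assert (res.params <= mean_ci["upper"] + 1e-12).all()
    text = res.summary()
    assert "Intercept" in text and "tau" in text
    X = res.model.X
    pred = res.predict_mean(X)
    assert pred.shape == (X.shape[0],)


def test_fit_on_all_responses(small_response_table):
    for response in ("d_degree", "d_strength", "d_betweenness"):
        res = fit_location_scale(small_response_table, ModelSpec(response=response))
        assert res.converged


# ---------------------------------------------------------------------------
# permutation effect test: two routes, one answer


def test_permutation_routes_agree(small_scenario, small_stacks, small_response_table):
    sc = small_scenario
    full, surv = small_stacks
    table = small_response_table
    pool = sorted(set(table["individual_id"]))
    chain = generate_swap_chain(pool, burn_in=50, swaps_per_emission=5,
                                n_emissions=4, seed=9)
    spec = ModelSpec(response="d_degree", variant="additive")
    observed, rand = permutation_effect_test(table, spec, chain)

    attrs = bn.loss_attributes(full[sc.schedule.last_pre_index], sc.roster.missing)
    for r in range(chain.n_emissions):
        rnd = apply_swaps_synchronized(surv, chain, r)
        delta_r = met.delta_from_baseline(rnd.stack)
        table_r = build_response_table(delta_r, attrs)
        table_r = table_r[table_r["individual_id"].isin(surv.common_nodes)]
        res_r = fit_location_scale(table_r, spec)
        fast = rand.iloc[r][res_r.params.index].to_numpy(dtype=float)
        # routes share one likelihood optimum; tolerance covers the two
        # optimizers' differing termination points
        assert np.allclose(fast, res_r.params.to_numpy(), atol=5e-4)


def test_permutation_pvalues_attached(small_response_table):
    pool = sorted(set(small_response_table["individual_id"]))
    chain = generate_swap_chain(pool, 20, 5, 9, seed=1)
    observed, rand = permutation_effect_test(
        small_response_table, ModelSpec(variant="additive"), chain
    )
    assert len(rand) == 9
    ps = observed.empirical_pvalues
    for name, p in ps.items():
        assert 0.0 < p <= 1.0
        assert p == pytest.approx((1 + np.sum(
            np.abs(rand[name]) >= abs(
                observed.params.get(name, observed.scale_params.get(name))
            )
        )) / 10)


def test_pool_must_match_table(small_response_table):
    chain = generate_swap_chain(["nope1", "nope2"], 5, 1, 2, seed=0)
    with pytest.raises(ValueError):
        permutation_effect_test(small_response_table, ModelSpec(), chain)


# ---------------------------------------------------------------------------
# community-level model


def community_stats(seed, n_comm=12, slope=-3.0):
    """Scripted community stats: d_size declines with prop_missing."""
    rng = np.random.default_rng(seed)
    base_rows, post_rows = [], []
    prop = rng.uniform(0.0, 0.8, size=n_comm)
    size0 = rng.integers(8, 25, size=n_comm)
    stats = {}
    base = pd.DataFrame({
        "community": [f"C{k}" for k in range(n_comm)],
        "window": 2, "size": size0,
        "within_density": rng.uniform(0.3, 0.6, size=n_comm),
        "prop_missing": prop, "pre_size": size0,
    })
    stats[2] = base
    for w in (3, 4):
        stats[w] = pd.DataFrame({
            "community": base["community"],
            "window": w,
            "size": size0 + slope * prop * 4 + rng.normal(scale=0.5, size=n_comm),
            "within_density": base["within_density"],
            "prop_missing": prop, "pre_size": size0,
        })
    return stats


def test_community_table_and_model_sign():
    stats = community_stats(5)
    table = mod.build_community_table(stats, baseline_window=2)
    assert set(table["window"]) == {3, 4}
    res = fit_community_model(table, ModelSpec(response="d_size", variant="additive",
                                               scale_terms=()))
    assert res.converged
    # loss_z slot carries standardized prop_missing; slope must be negative
    assert res.params["loss_z"] < 0


def test_single_community_fallback_warns():
    # degenerate input: one community cannot support a random effect, and
    # its standardized predictors are constant — the model must warn and
    # return finite estimates rather than crash
    stats = community_stats(6, n_comm=1)
    table = mod.build_community_table(stats, baseline_window=2)
    with pytest.warns(RuntimeWarning):
        res = fit_community_model(table, ModelSpec(response="d_size",
                                                   variant="additive", scale_terms=()))
    assert np.all(np.isfinite(res.params.to_numpy()))
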