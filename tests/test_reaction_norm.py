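"""Kernel algebra and Gibbs-sampler behavior of the reaction-norm benchmark."""

import numpy as np
import pandas as pd
import pytest

from metml import reaction_norm as rn
from metml.synthetic import SimulationConfig, simulate_met_data


def small_design(n_geno=8, n_env=4, p=30, q=6, seed=0):
    rng = np.random.default_rng(seed)
    markers = pd.DataFrame(
        rng.binomial(2, 0.4, size=(n_geno, p)).astype(float),
        index=[f"G{i}" for i in range(n_geno)],
        columns=[f"M{j}" for j in range(p)],
    )
    markers.index.name = "genotype_id"
    ecs = pd.DataFrame(
        rng.normal(size=(n_env, q)),
        index=pd.Index([f"L{e}_2000" for e in range(n_env)], name="env_id"),
        columns=[f"ec_{j}_1" for j in range(q)],
    )
    pheno = pd.DataFrame(
        [(g, e) for g in markers.index for e in ecs.index],
        columns=["genotype_id", "env_id"],
    )
    return markers, ecs, pheno


# ---------------------------------------------------------------------------
# kernel algebra
# ---------------------------------------------------------------------------

def test_interaction_kernel_matches_brute_force_double_loop():
    markers, ecs, pheno = small_design()
    ks = rn.build_kernels(markers, ecs, pheno)
    n = len(pheno)
    assert n <= 50
    geno_idx = {g: i for i, g in enumerate(ks.genotype_ids)}
    env_idx = {e: i for i, e in enumerate(ks.env_ids)}
    for u in range(n):
        for v in range(n):
            gu = geno_idx[pheno.loc[u, "genotype_id"]]
            gv = geno_idx[pheno.loc[v, "genotype_id"]]
            eu = env_idx[pheno.loc[u, "env_id"]]
            ev = env_idx[pheno.loc[v, "env_id"]]
            expected = ks.G[gu, gv] * ks.omega[eu, ev]
            assert ks.K_gw[u, v] == pytest.approx(expected, abs=1e-12)


def test_all_ones_omega_reduces_interaction_to_genomic_kernel():
    markers, ecs, pheno = small_design(seed=1)
    ones = np.ones((ecs.shape[0], ecs.shape[0]))
    ks = rn.build_kernels(markers, ecs, pheno, omega_override=ones)
    assert np.array_equal(ks.K_gw, ks.K_g)


def test_identical_ec_rows_give_zero_environmental_kernel():
    markers, ecs, pheno = small_design(seed=2)
    ecs.loc[:, :] = 1.7  # no environmental contrast
    with pytest.raises(ValueError, match="zero-variance"):
        rn.build_kernels(markers, ecs, pheno)
    # one informative column, identical across environments after centering
    ecs["ec_var_1"] = [3.0, 3.0, 3.0, 3.0]
    ecs["ec_real_1"] = [1.0, 1.0, 1.0, 1.0]
    ecs.iloc[0, -1] = 1.0  # still constant: builds must reject
    with pytest.raises(ValueError, match="zero-variance"):
        rn.build_kernels(markers, ecs, pheno)


def test_mean_diagonal_of_genomic_kernel_near_one():
    rng = np.random.default_rng(3)
    markers = pd.DataFrame(
        rng.binomial(2, rng.uniform(0.1, 0.5, 200), size=(50, 200)).astype(float),
        index=[f"G{i}" for i in range(50)],
        columns=[f"M{j}" for j in range(200)],
    )
    ecs = pd.DataFrame(
        rng.normal(size=(3, 5)),
        index=pd.Index(["A_1", "B_1", "C_1"], name="env_id"),
        columns=[f"e{j}" for j in range(5)],
    )
    pheno = pd.DataFrame(
        [(g, e) for g in markers.index for e in ecs.index],
        columns=["genotype_id", "env_id"],
    )
    ks = rn.build_kernels(markers, ecs, pheno)
    assert np.mean(np.diag(ks.G)) == pytest.approx(1.0, abs=0.05)


def test_missing_ec_row_errors():
    markers, ecs, pheno = small_design(seed=4)
    with pytest.raises(ValueError, match="lacks rows"):
        rn.build_kernels(markers, ecs.iloc[1:], pheno)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_constant_response_gives_zero_variance_components():
    markers, ecs, pheno = small_design(seed=5)
    y = np.full(len(pheno), 7.3)
    ks = rn.build_kernels(markers, ecs, pheno)
    res = rn.fit_reaction_norm(y, ks, iterations=800, burn_in=100, seed=0)
    assert res.mu == pytest.approx(7.3, abs=0.02)
    for k in ("g", "w", "gw"):
        assert res.varcomps[k] < 0.01


def test_seeded_chains_are_identical():
    markers, ecs, pheno = small_design(seed=6)
    rng = np.random.default_rng(0)
    y = rng.normal(size=len(pheno))
    ks = rn.build_kernels(markers, ecs, pheno)
    a = rn.fit_reaction_norm(y, ks, iterations=500, burn_in=50, seed=42)
    b = rn.fit_reaction_norm(y, ks, iterations=500, burn_in=50, seed=42)
    assert a.mu == b.mu
    assert a.varcomps == b.varcomps
    assert np.array_equal(a.u_g, b.u_g)


def test_genetic_signal_ratio_recovered_and_cv1_predictive():
    """y = g + e with sigma2_g / sigma2_e = 2: ratio and CV1 accuracy recovered."""
    cfg = SimulationConfig(
        n_genotypes=100, p_markers=60, years=(2014,), locations=("Ames", "Lincoln",
                                                                 "Columbia", "Guelph"),
        v_g=2 / 3, v_w=0.0, v_gw=0.0, v_e=1 / 3, seed=99,
    )
    met, truth = simulate_met_data(cfg)
    assert len(met.pheno) == 400
    model = rn.ReactionNormModel.from_met_data(met, "trait")
    res = model.fit(iterations=2000, burn_in=200, seed=1)
    ratio = res.varcomps["g"] / res.varcomps["e"]
    assert 1.2 <= ratio <= 3.2

    # CV1: hold out a third of the genotypes, predict from marker similarity
    geno = sorted(met.markers.index)
    test_geno = set(geno[::3])
    pheno = met.pheno
    train = pheno[~pheno["genotype_id"].isin(test_geno)].reset_index(drop=True)
    test = pheno[pheno["genotype_id"].isin(test_geno)].reset_index(drop=True)
    ks = rn.build_kernels(met.markers, met.ecs, train)
    fit = rn.ReactionNormModel(train["trait"].to_numpy(), ks).fit(
        iterations=2000, burn_in=200, seed=2
    )
    pred = fit.predict(met.markers, met.ecs, test)
    r = np.corrcoef(pred, test["trait"])[0, 1]
    assert r > 0.5


def test_prediction_of_training_observation_matches_fitted_value():
    markers, ecs, pheno = small_design(n_geno=10, n_env=4, seed=7)
    rng = np.random.default_rng(1)
    y = rng.normal(size=len(pheno))
    ks = rn.build_kernels(markers, ecs, pheno)
    res = rn.fit_reaction_norm(y, ks, iterations=1500, burn_in=200, seed=3)
    pred = res.predict(markers, ecs, pheno)
    sd = y.std()
    assert np.abs(pred - res.fitted_values).max() < 0.05 * sd


def test_new_environment_at_training_mean_has_zero_w_contribution():
    markers, ecs, pheno = small_design(seed=8)
    ks = rn.build_kernels(markers, ecs, pheno)
    new_ecs = pd.DataFrame(
        [ecs.mean(axis=0)], index=pd.Index(["New_2001"], name="env_id")
    )
    pheno_new = pd.DataFrame(
        {"genotype_id": [markers.index[0]], "env_id": ["New_2001"]}
    )
    _, Kw_c, Kgw_c = ks.cross_kernels(markers, new_ecs, pheno_new)
    assert np.allclose(Kw_c, 0.0, atol=1e-10)
    assert np.allclose(Kgw_c, 0.0, atol=1e-10)


def test_predictions_invariant_to_observation_ordering():
    markers, ecs, pheno = small_design(seed=9)
    rng = np.random.default_rng(2)
    y = rng.normal(size=len(pheno))
    perm = rng.permutation(len(pheno))
    ks_a = rn.build_kernels(markers, ecs, pheno)
    res_a = rn.fit_reaction_norm(y, ks_a, iterations=1200, burn_in=200, seed=11)
    pheno_p = pheno.iloc[perm].reset_index(drop=True)
    ks_b = rn.build_kernels(markers, ecs, pheno_p)
    res_b = rn.fit_reaction_norm(y[perm], ks_b, iterations=1200, burn_in=200, seed=11)
    probe = pheno.iloc[:6]
    pa = res_a.predict(markers, ecs, probe)
    pb = res_b.predict(markers, ecs, probe)
    # same posterior geometry up to Monte-Carlo noise
    assert np.allclose(pa, pb, atol=0.12 * y.std())


def test_too_few_observations_rejected():
    markers, ecs, pheno = small_design(n_geno=3, n_env=2)
    ks = rn.build_kernels(markers, ecs, pheno)
    with pytest.raises(ValueError, match="20 observations"):
        rn.ReactionNormModel(np.zeros(len(pheno)), ks)


def test_summary_reports_components_and_settings():
    markers, ecs, pheno = small_design(seed=10)
    y = np.random.default_rng(3).normal(size=len(pheno))
    ks = rn.build_kernels(markers, ecs, pheno)
    res = rn.fit_reaction_norm(y, ks, iterations=600, burn_in=100, seed=0)
    text = res.summary()
    assert "sigma2_gw" in text and "burn-in" in text
    props = res.variance_proportions()
    assert sum(props.values()) == pytest.approx(1.0)
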