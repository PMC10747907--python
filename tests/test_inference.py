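"""Tests of priors, parameter layout, likelihood algebra and the posterior."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from skinperm.core import ScalingSet, total_permeability
from skinperm.datasets import TrainingDataSet, build_group_datasets
from skinperm.inference import (
    DatasetModel,
    ParameterLayout,
    ParameterVector,
    default_priors,
    diagnostics,
    log_likelihood,
    log_prior,
    record_context,
    run_mcmc,
    sample_posterior,
)
from skinperm.mcmc import MCMCConfig


@pytest.fixture(scope="module")
def b1():
    return build_group_datasets("B", 7)[0]


@pytest.fixture(scope="module")
def layout(b1):
    return ParameterLayout.from_dataset(b1)


@pytest.fixture(scope="module")
def model(b1, layout):
    return DatasetModel(b1, layout)


# ---------------------------------------------------------------------------
# Priors and layout
# ---------------------------------------------------------------------------


def test_prior_bounds_match_table(layout):
    pri = default_priors()
    assert pri.bounds["dlog10_ktrans_cmp"] == (-0.54, 0.54)
    assert pri.bounds["dlog10_Klipw_cmp"] == (-0.43, 0.43)
    assert pri.bounds["dlog10_Kinfw_cmp"] == (-1.0, 1.0)
    assert pri.bounds["hSC_site"][1] == pytest.approx(math.log10(1.5))
    assert pri.bounds["Nf_site"][1] == pytest.approx(math.log10(1.25))
    with pytest.raises(ValueError):
        default_priors(nu2_bounds=(1.0, 0.1))


def test_layout_contents(b1, layout):
    # one site scaling per site, one individual block per donor, 3 compound
    # perturbations per compound, plus the error variance
    expected_dim = 3 * len(b1.compounds) + 2 * len(b1.sites) + 4 * len(b1.individuals) + 1
    assert layout.dim == expected_dim
    classes = {b.name.split(":")[0] for b in layout.blocks()}
    assert classes == {"compound", "site", "individual", "nu"}
    # blocks partition the coordinates
    covered = sorted(i for b in layout.blocks() for i in b.indices)
    assert covered == list(range(layout.dim))
    with pytest.raises(KeyError):
        layout.index("hSC_site", "forearm")


def test_scaling_set_roundtrip_is_lossless(layout):
    rng = np.random.default_rng(1)
    v = layout.lo + (layout.hi - layout.lo) * rng.random(layout.dim)
    c, s, i = layout.compounds[0], layout.sites[1], layout.individuals[2]
    ss = layout.scaling_set(v, c, s, i)
    v2 = layout.set_scalings(v, ss, c, s, i)
    assert np.allclose(v, v2, atol=1e-14)
    ss2 = layout.scaling_set(v2, c, s, i)
    assert ss == ss2 or all(
        getattr(ss, f) == pytest.approx(getattr(ss2, f)) for f in ScalingSet.__dataclass_fields__
    )


def test_log_prior_support(layout):
    mid = layout.mid_vector()
    assert log_prior(mid, layout) == 0.0
    bad = mid.copy()
    bad[layout.index("hSC_site", layout.sites[0])] = math.log10(1.6)  # > 1.5 bound
    assert log_prior(bad, layout) == -math.inf
    # flatness: two in-support vectors differing only in a perturbation
    other = mid.copy()
    other[layout.index("dlog10_Kinfw_cmp", layout.compounds[0])] = 0.7
    assert log_prior(other, layout) == log_prior(mid, layout)


# ---------------------------------------------------------------------------
# Likelihood algebra
# ---------------------------------------------------------------------------


def _perfect_fit_dataset(b1, layout, values):
    """Data set whose observations equal the model predictions exactly."""
    model = DatasetModel(b1, layout)
    preds = model.predict(values)
    from dataclasses import replace

    recs = tuple(
        replace(r, P_mean=float(p)) for r, p in zip(b1.records, preds)
    )
    return TrainingDataSet(b1.group, b1.dataset_id, recs)


def test_perfect_fit_likelihood_value(b1, layout):
    nu = 0.25
    v = layout.identity_vector(nu=nu)
    ds = _perfect_fit_dataset(b1, layout, v)
    model = DatasetModel(ds, layout)
    n = len(ds.records)
    expected = -(n / 2.0) * math.log(2.0 * math.pi * nu**2)
    assert log_likelihood(v, model) == pytest.approx(expected, rel=1e-12)


def test_single_record_one_sigma_residual(b1, layout):
    nu = 0.3
    v = layout.identity_vector(nu=nu)
    model = DatasetModel(b1, layout)
    pred0 = model.predict(v)[0]
    from dataclasses import replace

    rec = replace(b1.records[0], P_mean=float(pred0 * math.exp(nu)))
    toy = TrainingDataSet(b1.group, "toy", (rec,) * 12)  # 12 copies, residual nu each
    toy_model = DatasetModel(toy, layout)
    expected = 12 * (-0.5 * math.log(2.0 * math.pi * nu**2) - 0.5)
    assert log_likelihood(v, toy_model) == pytest.approx(expected, rel=1e-10)


def test_likelihood_matches_bruteforce_sum(b1, layout, model):
    """Term-by-term independent re-summation on random vectors."""
    rng = np.random.default_rng(4)
    for _ in range(5):
        v = layout.lo + (layout.hi - layout.lo) * rng.random(layout.dim)
        nu2 = math.exp(v[layout.index("log_nu2")])
        brute = 0.0
        for r in b1.records:
            s = layout.scaling_set(v, r.compound, r.site, r.individual_id)
            f = total_permeability(record_context(r), s).P_tot_w
            brute += -0.5 * math.log(2 * math.pi * nu2) - (
                math.log(f) - math.log(r.P_mean)
            ) ** 2 / (2 * nu2)
        assert log_likelihood(v, model) == pytest.approx(brute, rel=1e-10)


def test_vectorized_model_equals_engine_per_record(b1, layout, model):
    rng = np.random.default_rng(9)
    v = layout.lo + (layout.hi - layout.lo) * rng.random(layout.dim)
    vec = model.predict(v)
    for k, r in enumerate(b1.records):
        s = layout.scaling_set(v, r.compound, r.site, r.individual_id)
        direct = total_permeability(record_context(r), s).P_tot_w
        assert vec[k] == pytest.approx(direct, rel=1e-12)


def test_posterior_is_prior_plus_likelihood(b1, layout, model):
    rng = np.random.default_rng(2)
    for _ in range(100):
        v = layout.lo + (layout.hi - layout.lo) * rng.random(layout.dim)
        lp = log_prior(v, layout)
        assert lp == 0.0  # flat inside support
        assert np.isfinite(log_likelihood(v, model))
    outside = layout.mid_vector()
    outside[0] = layout.hi[0] + 1.0
    assert log_prior(outside, layout) == -math.inf


# ---------------------------------------------------------------------------
# Sampling behaviour
# ---------------------------------------------------------------------------


def test_prior_only_marginals_match_priors(b1):
    """Prior-only MCMC marginals pass KS tests against every prior family."""
    draws = run_mcmc(
        b1, config=MCMCConfig(n_iter=24000, n_chains=2, seed=21), prior_only=True
    )
    lay = draws.layout
    flat = draws.flat()[::40]  # thin against residual autocorrelation
    for j, (base, ent) in enumerate(lay.entries):
        lo, hi = lay.lo[j], lay.hi[j]
        u = (flat[:, j] - lo) / (hi - lo)  # uniform in sampling coords
        p = stats.kstest(u, "uniform").pvalue
        assert p > 0.01, f"{base}[{ent}]: KS p={p:.4f}"
    # spot-check a multiplicative scaling on its natural (log-uniform) scale
    hsc = 10.0 ** flat[:, lay.index("hSC_site", lay.sites[0])]
    assert hsc.min() >= 1 / 1.5 - 1e-9 and hsc.max() <= 1.5 + 1e-9


def test_mcmc_determinism_and_support(b1):
    cfg = MCMCConfig(n_iter=600, n_chains=2, seed=33)
    a = run_mcmc(b1, config=cfg)
    b = run_mcmc(b1, config=cfg)
    assert np.array_equal(a.samples, b.samples)
    assert a.layout.in_support(a.flat())
    nch, nit, _ = a.samples.shape
    assert nch == 2 and nit == 600 - cfg.resolved_burn_in()


def test_record_permutation_leaves_posterior_unchanged(b1, layout):
    """The posterior density is invariant to the ordering of records."""
    recs = list(b1.records)
    rng = np.random.default_rng(0)
    perm = tuple(recs[i] for i in rng.permutation(len(recs)))
    shuffled = TrainingDataSet(b1.group, b1.dataset_id, perm)
    m1, m2 = DatasetModel(b1, layout), DatasetModel(shuffled, layout)
    for _ in range(20):
        v = layout.lo + (layout.hi - layout.lo) * rng.random(layout.dim)
        assert log_likelihood(v, m1) == pytest.approx(log_likelihood(v, m2), rel=1e-12)
    # and the sampled posterior is statistically indistinguishable
    cfg = MCMCConfig(n_iter=3000, n_chains=1, seed=17)
    a = run_mcmc(b1, config=cfg)
    b = run_mcmc(shuffled, config=cfg)
    ma, mb = a.flat().mean(axis=0), b.flat().mean(axis=0)
    sd = a.flat().std(axis=0) + 1e-12
    assert np.all(np.abs(ma - mb) < 6.0 * sd)


def test_sample_posterior_properties(synthetic_b_draws):
    draws = synthetic_b_draws
    flat = draws.flat()
    n_all = flat.shape[0]
    # fixed seed reproducibility
    s1 = sample_posterior(draws, 50, seed=5)
    s2 = sample_posterior(draws, 50, seed=5)
    assert all(np.array_equal(a.values, b.values) for a, b in zip(s1, s2))
    with pytest.raises(ValueError):
        sample_posterior(draws, 0)
    # joint resampling preserves cross-parameter correlation
    lay = draws.layout
    j1 = lay.index("dlog10_ktrans_cmp", lay.compounds[0])
    j2 = lay.index("dlog10_Klipw_cmp", lay.compounds[0])
    rho_chain = np.corrcoef(flat[:, j1], flat[:, j2])[0, 1]
    big = np.array([pv.values for pv in sample_posterior(draws, 4000, seed=2)])
    rho_res = np.corrcoef(big[:, j1], big[:, j2])[0, 1]
    assert abs(rho_res - rho_chain) < 0.08
    # full-size resample without replacement is not required; multiset
    # equality holds for the identity index permutation path
    rows = {tuple(np.round(v, 12)) for v in flat}
    assert all(tuple(np.round(pv.values, 12)) in rows for pv in s1)


def test_diagnostics_output(synthetic_b_draws):
    diag = diagnostics(synthetic_b_draws, ess_floor=10.0)
    assert set(diag.columns) >= {"parameter", "rhat", "ess", "flagged"}
    assert len(diag) == synthetic_b_draws.layout.dim
    assert np.isfinite(diag["rhat"]).all()
    assert "accept_rates" in diag.attrs


def test_diagnostics_single_chain_warns(b1):
    draws = run_mcmc(b1, config=MCMCConfig(n_iter=300, n_chains=1, seed=2))
    with pytest.warns(UserWarning, match="single chain"):
        diag = diagnostics(draws)
    assert diag["rhat"].isna().all()


def test_save_load_roundtrip(tmp_path, synthetic_b_draws):
    synthetic_b_draws.save(tmp_path / "chains")
    from skinperm.inference import PosteriorDraws

    back = PosteriorDraws.load(tmp_path / "chains")
    assert back.layout.entries == synthetic_b_draws.layout.entries
    assert np.allclose(back.samples, synthetic_b_draws.samples)


def test_empty_dataset_rejected():
    with pytest.raises((ValueError, TypeError)):
        run_mcmc(None)
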