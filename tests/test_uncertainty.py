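"""Chi-square acceptance range, Monte-Carlo refits and bootstrap summaries."""

import numpy as np
import pytest

import emuflux as ef
from emuflux import estimation, uncertainty
from emuflux import fixtures as fx


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def test_gof_range_known_quantiles():
    # df = 12: upper bound prints as 21
    r = ef.gof_range(18, 6)
    assert r.df == 12
    assert r.upper == pytest.approx(21.026, abs=1e-3)
    # df = 5: acceptable range 1.15 - 11.07
    r = ef.gof_range(29, 24)
    assert (round(r.lower, 2), round(r.upper, 2)) == (1.15, 11.07)
    # df = 1 at the (0.05, 0.95) quantiles
    r = ef.gof_range(2, 1)
    assert r.lower == pytest.approx(0.00393, abs=1e-5)
    assert r.upper == pytest.approx(3.841, abs=1e-3)


def test_gof_range_halved_convention():
    r = ef.gof_range(18, 6, alpha=0.05, halved=True)
    from scipy.stats import chi2
    assert r.lower == pytest.approx(chi2.ppf(0.025, 12))
    assert r.upper == pytest.approx(chi2.ppf(0.975, 12))


def test_gof_range_monotone_in_df():
    uppers = [ef.gof_range(n, 1).upper for n in range(2, 30)]
    lowers = [ef.gof_range(n, 1).lower for n in range(2, 30)]
    assert all(a < b for a, b in zip(uppers, uppers[1:]))
    assert all(a < b for a, b in zip(lowers, lowers[1:]))
    assert all(l < u for l, u in zip(lowers, uppers))


def test_gof_range_requires_positive_df():
    with pytest.raises(ValueError):
        ef.gof_range(5, 5)


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def split_mc(split_fit):
    problem, result, v_true = split_fit
    samples = uncertainty.monte_carlo(problem, result, n_sets=30, seed=5)
    return problem, result, samples


def test_monte_carlo_is_reproducible(split_fit):
    problem, result, _ = split_fit
    s1 = uncertainty.monte_carlo(problem, result, n_sets=10, seed=2)
    s2 = uncertainty.monte_carlo(problem, result, n_sets=10, seed=2)
    assert np.array_equal(s1, s2)


def test_monte_carlo_degenerate_noise_reproduces_base(split_fit):
    """With vanishing measurement SDs every perturbed refit lands back on
    the base optimum."""
    problem, result, v_true = split_fit
    import dataclasses
    tiny = [dataclasses.replace(f, sd=np.full_like(f.sd, 1e-12))
            for f in problem.measurements]
    prob2 = dataclasses.replace(problem, measurements=tiny)
    base = estimation.fit(prob2, start=result.v_free[problem.adjustable])
    samples = uncertainty.monte_carlo(prob2, base, n_sets=5, seed=0)
    assert np.abs(samples - base.v).max() < 1e-6


def test_monte_carlo_basis_column_constant(split_mc):
    problem, result, samples = split_mc
    j = result.reaction_ids.index(problem.model.basis_reaction_id)
    assert np.allclose(samples[:, j], 1.0)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_constant_column():
    samples = np.full((50, 2), 0.7)
    summ = ef.bootstrap_summary(samples, ["A", "B"], n_boot=50, seed=0)
    assert np.allclose(summ.medians, 0.7)


def test_bootstrap_percentile_oracle_linear_interpolation():
    x = np.arange(1, 101, dtype=float)
    assert np.percentile(x, 2.5) == pytest.approx(3.475)
    assert np.percentile(x, 97.5) == pytest.approx(97.525)
    # medians of bootstrap percentiles stay near the direct percentiles
    summ = ef.bootstrap_summary(x[:, None], ["A"], n_boot=400, seed=1)
    assert summ.row("A")[2] == pytest.approx(np.median(x), abs=3 * np.std(x) / 10)


def test_bootstrap_medians_monotone_and_within_range(split_mc):
    _, result, samples = split_mc
    summ = ef.bootstrap_summary(samples, result.reaction_ids, n_boot=200, seed=3)
    for j, rid in enumerate(result.reaction_ids):
        row = summ.row(rid)
        assert (np.diff(row) >= -1e-12).all()
        assert samples[:, j].min() - 1e-12 <= row[0]
        assert row[-1] <= samples[:, j].max() + 1e-12


def test_bootstrap_symmetric_sample_median():
    rng = np.random.default_rng(0)
    x = rng.normal(0.5, 0.1, size=400)
    summ = ef.bootstrap_summary(x[:, None], ["A"], n_boot=300, seed=2)
    se = np.std(x) / np.sqrt(len(x))
    assert abs(summ.row("A")[2] - np.median(x)) < 3 * se


def test_bootstrap_requires_samples():
    with pytest.raises(ValueError):
        ef.bootstrap_summary(np.zeros((1, 3)), ["a", "b", "c"])
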