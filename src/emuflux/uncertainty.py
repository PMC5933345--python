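"""Goodness of fit and Monte-Carlo / bootstrap flux uncertainty.

Under a correct model and well-estimated measurement errors the minimized
SSR follows a chi-square distribution with ``n - p`` degrees of freedom, so
the fit is accepted when the SSR falls between two chi-square quantiles.

Flux confidence intervals are estimated by Monte Carlo: perturbed copies of
the measured MIDs (Gaussian noise at the measured SD, clipped at zero, not
renormalized) are each refit, giving an empirical flux distribution per
reaction.  Bootstrap resampling of those Monte-Carlo solutions yields
percentile estimates (2.5/16/50/84/97.5); the median of each percentile over
the bootstrap replicates is reported as the corresponding confidence bound.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import chi2

from . import estimation
from .estimation import FitProblem, FitResult  # noqa: F401
from .model_io import MeasuredFragment

__all__ = ["GOFRange", "MonteCarloSummary", "gof_range", "monte_carlo",
           "bootstrap_summary"]

PERCENTILES = (2.5, 16.0, 50.0, 84.0, 97.5)


@dataclass
class GOFRange:
    n: int
    p: int
    alpha: float
    lower: float
    upper: float

    def accepts(self, ssr: float) -> bool:
        return self.lower <= ssr <= self.upper

    @property
    def df(self) -> int:
        return self.n - self.p


def gof_range(n: int, p: int, alpha: float = 0.05,
              halved: bool = False) -> GOFRange:
    """Chi-square acceptance range for the SSR at ``n - p`` degrees of
    freedom.

    By default the bounds are the ``alpha`` and ``1 - alpha`` quantiles
    (e.g. 1.15–11.07 at df 5, upper bound 21.0 at df 12 for alpha 0.05);
    ``halved=True`` uses the two-sided ``alpha/2`` / ``1 - alpha/2``
    convention instead.
    """
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    lo_q = alpha / 2 if halved else alpha
    hi_q = 1 - alpha / 2 if halved else 1 - alpha
    df = n - p
    return GOFRange(n=n, p=p, alpha=alpha,
                    lower=float(chi2.ppf(lo_q, df)),
                    upper=float(chi2.ppf(hi_q, df)))


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

def _perturb(measurements: list[MeasuredFragment],
             rng: np.random.Generator) -> list[MeasuredFragment]:
    out = []
    for f in measurements:
        mid = np.clip(f.mid + rng.normal(0.0, f.sd), 0.0, None)
        out.append(replace(f, mid=mid))
    return out


def monte_carlo(problem: FitProblem, base_fit: FitResult,
                n_sets: int = 500, seed: int | None = None,
                max_failure_fraction: float = 0.2) -> np.ndarray:
    """Refit ``n_sets`` noise-perturbed datasets; one flux vector per row.

    Each refit starts from the base optimum (single start per set).  Failed
    sets are dropped; more than ``max_failure_fraction`` failures raises.
    """
    rng = np.random.default_rng(seed)
    theta0 = base_fit.v_free[problem.adjustable]
    rows, failures = [], 0
    for _ in range(n_sets):
        perturbed = _perturb(problem.measurements, rng)
        try:
            res = estimation.fit(problem, measurements=perturbed, start=theta0)
            rows.append(res.v)
        except Exception:
            failures += 1
    if failures > max_failure_fraction * n_sets:
        raise RuntimeError(
            f"{failures}/{n_sets} Monte-Carlo refits failed "
            f"(> {max_failure_fraction:.0%} allowed)")
    return np.array(rows)


@dataclass
class MonteCarloSummary:
    reaction_ids: list[str]
    percentiles: tuple[float, ...]
    medians: np.ndarray           # (n_reactions, n_percentiles)
    samples: np.ndarray           # (n_sets, n_reactions)
    n_sets: int
    n_boot: int

    def row(self, rid: str) -> np.ndarray:
        return self.medians[self.reaction_ids.index(rid)]


def bootstrap_summary(samples: np.ndarray, reaction_ids: list[str],
                      n_boot: int = 1000, seed: int | None = None,
                      percentiles: tuple[float, ...] = PERCENTILES
                      ) -> MonteCarloSummary:
    """Bootstrap the Monte-Carlo flux samples.

    Draws ``n_boot`` resamples with replacement of the sample rows, computes
    the requested percentiles per resample (linear interpolation between
    order statistics) and reports the median of each percentile.
    """
    samples = np.asarray(samples, float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need a (n_sets, n_reactions) matrix with >= 2 rows")
    rng = np.random.default_rng(seed)
    n_sets = samples.shape[0]
    percs = np.empty((n_boot, samples.shape[1], len(percentiles)))
    for b in range(n_boot):
        idx = rng.integers(0, n_sets, size=n_sets)
        percs[b] = np.percentile(samples[idx], percentiles, axis=0).T
    medians = np.median(percs, axis=0)
    return MonteCarloSummary(
        reaction_ids=list(reaction_ids), percentiles=tuple(percentiles),
        medians=medians, samples=samples, n_sets=n_sets, n_boot=n_boot)
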