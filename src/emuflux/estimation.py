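"""Weighted least-squares flux fitting with multi-start bounded optimization.

The free fluxes are the parameters; the full flux vector follows from the
null-space parameterization.  The objective is the variance-weighted sum of
squared residuals between corrected simulated and measured MIDs,

    SSR = sum over measured entries of (MID_calc - MID_measured)^2 / Error^2.

Measured fluxes contribute no residual term: they enter as free parameters
box-bounded to mean +/- 3 SD, so the data-point count ``n`` comes from MID
entries alone and the parameter count ``p`` is the number of adjustable free
fluxes (the basis flux is frozen at its fixed value).

Each start draws the free fluxes uniformly within their bounds (resampling
until the dependent fluxes are nonnegative, with the LP-feasible point as
fallback) and runs a bounded trust-region Levenberg-Marquardt-type solver.
Nonnegativity of dependent fluxes — not expressible as a box on the free
fluxes — is enforced by a quadratic exterior penalty added to the residual
vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import correction, emu_engine, network_math
from .emu_engine import EMU, SimulationError
from .model_io import (CorrectionSpec, MeasuredFragment, MetabolicModel,
                       ModelError, SubstrateSpec)

__all__ = ["FitProblem", "FitResult", "StartRecord", "build_problem",
           "objective", "fit", "weighted_ssr"]

#: exterior penalty weight on negative dependent fluxes
PENALTY_WEIGHT = 1e6

#: residual magnitude substituted when the EMU system cannot be solved
FAILURE_RESIDUAL = 1e3

MAX_NFEV = 2000
FEASIBILITY_DRAWS = 1000


@dataclass
class FitProblem:
    """Everything needed to evaluate the objective for a model + dataset."""

    model: MetabolicModel
    substrates: list[SubstrateSpec]
    corrections: dict[str, CorrectionSpec]
    measurements: list[MeasuredFragment]
    nb: network_math.NullBasis
    bounds: network_math.FluxBounds
    decomp: emu_engine.EMUDecomposition
    basis_value: float
    lp_start: np.ndarray               # feasible full flux vector
    free_lower: np.ndarray             # bounds of all free fluxes
    free_upper: np.ndarray
    basis_free_pos: int                # index of the frozen basis flux
    fragment_emus: dict[str, EMU] = field(default_factory=dict)

    @property
    def adjustable(self) -> np.ndarray:
        """Free-flux positions that are actual fit parameters."""
        return np.array([k for k in range(self.nb.n_free)
                         if k != self.basis_free_pos], dtype=int)

    @property
    def n_data(self) -> int:
        return sum(f.n_points for f in self.measurements)

    @property
    def n_params(self) -> int:
        return len(self.adjustable)

    def free_template(self) -> np.ndarray:
        v_free = self.nb.free_from_fluxes(self.lp_start)
        v_free[self.basis_free_pos] = self.basis_value
        return v_free

    def simulate_corrected(self, v_free: np.ndarray,
                           measurements: list[MeasuredFragment] | None = None
                           ) -> dict[str, np.ndarray]:
        """Corrected, truncated MID per fragment at the given free fluxes."""
        ms = self.measurements if measurements is None else measurements
        v = np.clip(self.nb.fluxes_from_free(v_free), 0.0, None)
        mids = emu_engine.simulate(self.decomp, v, self.substrates)
        out = {}
        for frag in ms:
            emu = self.fragment_emus[frag.fragment_id]
            out[frag.fragment_id] = correction.apply_correction(
                mids[emu], self.corrections[frag.fragment_id])
        return out


def build_problem(model: MetabolicModel,
                  substrates: list[SubstrateSpec],
                  corrections_list: list[CorrectionSpec],
                  measurements: list[MeasuredFragment],
                  preferences: list[str] | None = None,
                  basis_value: float = 1.0,
                  cap: float = network_math.FLUX_CAP,
                  lp_seed: int | None = 0) -> FitProblem:
    """Assemble matrix, ordering, kernel, bounds and EMU decomposition."""
    nb = network_math.null_basis_for_model(model, preferences)
    bounds, v0 = network_math.feasible_bounds_and_start(
        model, nb, seed=lp_seed, basis_value=basis_value, cap=cap)
    fragment_emus = {f.fragment_id: EMU(f.metabolite, f.positions)
                     for f in measurements}
    decomp = emu_engine.decompose(model, sorted(set(fragment_emus.values())))
    lo, hi = network_math.free_bounds(bounds, nb)
    basis_pos = nb.free_reaction_ids.index(model.basis_reaction_id)
    corr = {c.fragment_id: c for c in corrections_list}
    missing = [f.fragment_id for f in measurements if f.fragment_id not in corr]
    if missing:
        raise ModelError(f"fragments without correction entry: {missing}")
    return FitProblem(
        model=model, substrates=substrates, corrections=corr,
        measurements=measurements, nb=nb, bounds=bounds, decomp=decomp,
        basis_value=basis_value, lp_start=v0,
        free_lower=lo, free_upper=hi, basis_free_pos=basis_pos,
        fragment_emus=fragment_emus)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def weighted_ssr(calc: np.ndarray, measured: np.ndarray, sd: np.ndarray) -> float:
    """Variance-weighted sum of squared residuals for one vector pair."""
    r = (np.asarray(calc, float) - np.asarray(measured, float)) / np.asarray(sd, float)
    return float(r @ r)


def _residuals(problem: FitProblem, v_free: np.ndarray,
               measurements: list[MeasuredFragment]) -> np.ndarray:
    """Measurement residuals followed by dependent-flux penalty residuals."""
    n_meas = sum(f.n_points for f in measurements)
    v = problem.nb.fluxes_from_free(v_free)
    penalty = np.sqrt(PENALTY_WEIGHT) * np.clip(-v, 0.0, None)
    try:
        calc = problem.simulate_corrected(v_free, measurements)
        res = np.concatenate([
            (calc[f.fragment_id] - f.mid) / f.sd for f in measurements])
    except SimulationError:
        res = np.full(n_meas, FAILURE_RESIDUAL)
    return np.concatenate([res, penalty])


def objective(v_free: np.ndarray, problem: FitProblem,
              measurements: list[MeasuredFragment] | None = None) -> float:
    """SSR at the given free fluxes (simulation failure returns a large
    finite penalty instead of raising)."""
    ms = problem.measurements if measurements is None else measurements
    r = _residuals(problem, np.asarray(v_free, float), ms)
    n_meas = sum(f.n_points for f in ms)
    return float(np.sum(r[:n_meas] ** 2))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class StartRecord:
    start: np.ndarray     # free fluxes at the start (full free vector)
    ssr: float            # measurement SSR at the converged point
    cost: float           # penalized SSR used for ranking
    n_evaluations: int
    success: bool


@dataclass
class FitResult:
    v: np.ndarray                     # input-order mass-balance fluxes
    v_free: np.ndarray
    ssr: float
    mids: dict[str, np.ndarray]       # corrected calculated MIDs per fragment
    starts: list[StartRecord]
    n: int                            # measured data points
    p: int                            # adjustable free fluxes
    reaction_ids: list[str]
    free_reaction_ids: list[str]

    @property
    def degrees_of_freedom(self) -> int:
        return self.n - self.p


def _draw_start(problem: FitProblem, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw of the adjustable free fluxes, resampled until the
    dependent fluxes are feasible; falls back to the LP-feasible point."""
    adj = problem.adjustable
    template = problem.free_template()
    lo, hi = problem.free_lower[adj], problem.free_upper[adj]
    for _ in range(FEASIBILITY_DRAWS):
        theta = rng.uniform(lo, hi)
        v_free = template.copy()
        v_free[adj] = theta
        if (problem.nb.fluxes_from_free(v_free) >= -1e-8).all():
            return theta
    return template[adj]


def fit(problem: FitProblem, n_starts: int = 10, seed: int | None = None,
        measurements: list[MeasuredFragment] | None = None,
        start: np.ndarray | None = None) -> FitResult:
    """Multi-start bounded least-squares fit of the free fluxes.

    ``start`` (adjustable free fluxes) forces a single deterministic start,
    used by the Monte-Carlo refits.  Identical seed and inputs give an
    identical result.
    """
    ms = problem.measurements if measurements is None else measurements
    n_meas = sum(f.n_points for f in ms)
    rng = np.random.default_rng(seed)
    adj = problem.adjustable
    template = problem.free_template()
    lo, hi = problem.free_lower[adj], problem.free_upper[adj]

    def fun(theta: np.ndarray) -> np.ndarray:
        v_free = template.copy()
        v_free[adj] = theta
        return _residuals(problem, v_free, ms)

    if start is not None:
        start_points = [np.clip(np.asarray(start, float), lo, hi)]
    else:
        start_points = [_draw_start(problem, rng) for _ in range(n_starts)]

    records: list[StartRecord] = []
    best = None
    for theta0 in start_points:
        try:
            sol = least_squares(fun, theta0, bounds=(lo, hi), method="trf",
                                ftol=1e-10, xtol=1e-10, gtol=1e-10,
                                max_nfev=MAX_NFEV)
        except Exception:
            records.append(StartRecord(theta0, np.inf, np.inf, 0, False))
            continue
        r = sol.fun
        ssr = float(np.sum(r[:n_meas] ** 2))
        cost = float(np.sum(r ** 2))
        records.append(StartRecord(theta0, ssr, cost, sol.nfev, True))
        if best is None or cost < best[0]:
            best = (cost, sol.x)
    if best is None:
        raise RuntimeError(
            "all optimization starts failed; per-start diagnostics: "
            + "; ".join(f"start {i}: ssr={rec.ssr}" for i, rec in enumerate(records)))

    v_free = template.copy()
    v_free[adj] = best[1]
    v = np.clip(problem.nb.fluxes_from_free(v_free), 0.0, None)
    mids = problem.simulate_corrected(v_free, ms)
    ssr = sum(weighted_ssr(mids[f.fragment_id], f.mid, f.sd) for f in ms)
    return FitResult(
        v=v, v_free=v_free, ssr=float(ssr), mids=mids, starts=records,
        n=n_meas, p=len(adj),
        reaction_ids=list(problem.bounds.reaction_ids),
        free_reaction_ids=list(problem.nb.free_reaction_ids))
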