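"""Stoichiometry, null-space flux parameterization and feasible bounds.

At metabolic steady state the flux vector satisfies ``S @ v = 0`` with ``S``
the stoichiometric matrix over balanced metabolites.  Any steady-state flux
distribution can therefore be written ``v = N @ v_free`` where the columns of
``N`` span the kernel of ``S`` and ``v_free`` collects the free fluxes.

Which fluxes end up free is controlled by arranging the reaction columns in
blocks before taking the reduced row echelon form (rref):

    [ reversible-forward | irreversible | user-preferred | basis & measured |
      reversible-reverse ]

rref assigns pivots to the left-most independent columns, so reactions placed
late in the ordering (basis, measured, reverse/exchange fluxes) become free
fluxes whenever the network allows it.  This is what lets measured fluxes be
treated directly as bounded parameters of the fit.

Feasible box bounds are derived from the basis flux (default 15x cap) and
from measured values (mean +/- 3 SD), and an initial feasible flux
distribution is produced by linear programming with a seeded random
objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel, ModelError

__all__ = [
    "NullBasis",
    "FluxBounds",
    "build_stoichiometric_matrix",
    "order_reactions",
    "null_basis",
    "feasible_bounds_and_start",
]

#: relative pivot tolerance of the numeric rref
RREF_TOL = 1e-10

#: default cap on non-basis fluxes, in units of the basis flux
FLUX_CAP = 15.0


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Stoichiometric matrix of the mass-balance (F/FR/R/B) reactions.

    Rows follow ``model.balanced_metabolites``, columns follow the input
    order of the mass-balance reactions.  S-type reactions and unbalanced
    source/sink metabolites are excluded.
    """
    mets = model.balanced_metabolites
    if not mets:
        raise ModelError("model has no balanced metabolites")
    row = {m: i for i, m in enumerate(mets)}
    rxns = model.mass_balance_reactions
    S = np.zeros((len(mets), len(rxns)))
    for j, rxn in enumerate(rxns):
        for ref in rxn.reactants:
            if ref.metabolite in row:
                S[row[ref.metabolite], j] -= ref.coef
        for ref in rxn.products:
            if ref.metabolite in row:
                S[row[ref.metabolite], j] += ref.coef
    return S


# ---------------------------------------------------------------------------
# block ordering
# ---------------------------------------------------------------------------

def order_reactions(model: MetabolicModel,
                    preferences: list[str] | None = None) -> np.ndarray:
    """Stable block permutation of the mass-balance reaction columns.

    Returns ``perm`` such that column ``k`` of the ordered system is column
    ``perm[k]`` of the input-order system.  Blocks: reversible-forward,
    irreversible (and B), preferred free, basis & measured, reversible-
    reverse; input order is preserved within each block.
    """
    rxns = model.mass_balance_reactions
    if preferences is None:
        preferences = [r.id for r in rxns if r.prefer_free]
    pref_rank = {rid: k for k, rid in enumerate(preferences)}

    fwd, irrev, pref, pinned, rev = [], [], [], [], []
    for j, r in enumerate(rxns):
        if r.rtype == "R":
            rev.append(j)
        elif r.is_basis or r.measured is not None:
            pinned.append(j)
        elif r.id in pref_rank:
            pref.append(j)
        elif r.rtype == "FR":
            fwd.append(j)
        else:  # F or B
            irrev.append(j)
    pref.sort(key=lambda j: pref_rank[rxns[j].id])
    return np.array(fwd + irrev + pref + pinned + rev, dtype=int)


# ---------------------------------------------------------------------------
# rref and null-space basis
# ---------------------------------------------------------------------------

def _rref(A: np.ndarray, tol_rel: float = RREF_TOL):
    """Numeric reduced row echelon form with partial pivoting.

    Returns ``(R, pivot_columns)``.  A column is pivotless when its working
    entries are below ``tol_rel`` relative to the largest entry of the
    working column.
    """
    R = np.array(A, dtype=float)
    m, n = R.shape
    pivots: list[int] = []
    r = 0
    scale = max(np.abs(R).max(), 1.0)
    for c in range(n):
        if r >= m:
            break
        i = r + int(np.argmax(np.abs(R[r:, c])))
        if np.abs(R[i, c]) <= tol_rel * scale:
            R[r:, c] = 0.0
            continue
        if i != r:
            R[[r, i]] = R[[i, r]]
        R[r] = R[r] / R[r, c]
        mask = np.arange(m) != r
        R[mask] -= np.outer(R[mask, c], R[r])
        pivots.append(c)
        r += 1
    return R, pivots


@dataclass
class NullBasis:
    """Null-space parameterization of the ordered flux system."""

    S: np.ndarray                 # input-order stoichiometric matrix
    ordering: np.ndarray          # ordered position k -> input-order column
    N: np.ndarray                 # ordered fluxes = N @ v_free
    free_indices: np.ndarray      # ordered positions of the free fluxes
    rank: int
    reaction_ids: list[str]       # input-order mass-balance reaction ids

    @property
    def n_free(self) -> int:
        return len(self.free_indices)

    @property
    def free_reaction_ids(self) -> list[str]:
        return [self.reaction_ids[self.ordering[k]] for k in self.free_indices]

    def fluxes_from_free(self, v_free: np.ndarray) -> np.ndarray:
        """Full flux vector in input order for the given free fluxes."""
        v_ordered = self.N @ np.asarray(v_free, float)
        v = np.empty_like(v_ordered)
        v[self.ordering] = v_ordered
        return v

    def free_from_fluxes(self, v: np.ndarray) -> np.ndarray:
        """Free-flux coordinates of a full input-order flux vector."""
        return np.asarray(v, float)[self.ordering[self.free_indices]]


def null_basis(S: np.ndarray, ordering: np.ndarray) -> NullBasis:
    """Kernel basis of ``S`` with free fluxes chosen by rref on the ordered
    columns: non-pivot columns become the free fluxes."""
    S = np.asarray(S, float)
    if S.size == 0:
        raise ModelError("empty stoichiometric matrix")
    ordering = np.asarray(ordering, int)
    R, pivots = _rref(S[:, ordering])
    rank = len(pivots)
    if rank == 0:
        raise ModelError("stoichiometric matrix has rank zero")
    n = S.shape[1]
    free = np.array([c for c in range(n) if c not in set(pivots)], dtype=int)
    N = np.zeros((n, len(free)))
    for k, c in enumerate(free):
        N[c, k] = 1.0
        for i, p in enumerate(pivots):
            N[p, k] = -R[i, c]
    return NullBasis(S=S, ordering=ordering, N=N, free_indices=free,
                     rank=rank, reaction_ids=[])


def null_basis_for_model(model: MetabolicModel,
                         preferences: list[str] | None = None) -> NullBasis:
    """Convenience wrapper: matrix, ordering and kernel for a model.

    Emits a :class:`ModelError` if a basis or measured reaction fails to
    come out as a free flux (a structurally over-determined model).
    """
    S = build_stoichiometric_matrix(model)
    perm = order_reactions(model, preferences)
    nb = null_basis(S, perm)
    nb.reaction_ids = [r.id for r in model.mass_balance_reactions]
    pinned = {r.id for r in model.mass_balance_reactions
              if r.is_basis or r.measured is not None}
    missing = pinned - set(nb.free_reaction_ids)
    if missing:
        raise ModelError(
            f"basis/measured reactions {sorted(missing)} could not be "
            f"assigned as free fluxes; the network pins their values")
    return nb


# ---------------------------------------------------------------------------
# bounds and initial feasible point
# ---------------------------------------------------------------------------

@dataclass
class FluxBounds:
    """Per-reaction (lower, upper) bounds, input order, basis-flux units."""

    lower: np.ndarray
    upper: np.ndarray
    reaction_ids: list[str]

    def as_pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.lower, self.upper))


def feasible_bounds_and_start(model: MetabolicModel,
                              nb: NullBasis,
                              seed: int | None = 0,
                              basis_value: float = 1.0,
                              cap: float = FLUX_CAP):
    """Box bounds plus an initial feasible flux distribution.

    All directional fluxes are bounded to ``[0, cap * basis_value]``; the
    basis flux is fixed at ``basis_value``; measured reactions are bounded to
    mean +/- 3 SD intersected with the cap.  Reverse (exchange) fluxes share
    the cap so the optimizer has finite box bounds.  The start point solves
    ``S v = 0`` within bounds by linear programming under a seeded
    uniform(-1, 1) random objective.
    """
    rxns = model.mass_balance_reactions
    n = len(rxns)
    lower = np.zeros(n)
    upper = np.full(n, cap * basis_value)
    for j, r in enumerate(rxns):
        if r.is_basis:
            lower[j] = upper[j] = basis_value
        elif r.measured is not None:
            mean, sd = r.measured
            lower[j] = max(0.0, mean - 3.0 * sd)
            upper[j] = min(cap * basis_value, mean + 3.0 * sd)
            if lower[j] > upper[j]:
                raise ModelError(
                    f"reaction {r.id}: measured bounds "
                    f"[{mean - 3 * sd:g}, {mean + 3 * sd:g}] do not intersect "
                    f"[0, {cap * basis_value:g}]")
    bounds = FluxBounds(lower, upper, [r.id for r in rxns])

    rng = np.random.default_rng(seed)
    c = rng.uniform(-1.0, 1.0, size=n)
    res = linprog(c, A_eq=nb.S, b_eq=np.zeros(nb.S.shape[0]),
                  bounds=bounds.as_pairs(), method="highs")
    if not res.success:
        pinned = [f"{r.id} in [{lower[j]:g}, {upper[j]:g}]"
                  for j, r in enumerate(rxns)
                  if r.is_basis or r.measured is not None]
        raise ModelError(
            "no feasible flux distribution satisfies S v = 0 with the given "
            "bounds; fixed/measured constraints: " + "; ".join(pinned))
    return bounds, res.x


def free_bounds(bounds: FluxBounds, nb: NullBasis):
    """Bounds of the free fluxes (ordered-system free positions)."""
    idx = nb.ordering[nb.free_indices]
    return bounds.lower[idx], bounds.upper[idx]
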