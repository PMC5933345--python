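"""EMU decomposition and mass-isotopomer simulation.

An elementary metabolite unit (EMU) is a specific subset of a metabolite's
carbon atoms.  Starting from the measured fragments, the atom-transition
network is traced backwards: each EMU's producing reactions are rewritten as
elementary EMU reactions whose sources are the reactant EMUs contributing
those carbons.  A condensation (two reactant molecules each contributing
carbons) yields a source pair whose mass isotopomer distributions (MIDs)
convolve.  Grouping EMUs by size gives a cascade of *linear* systems — one
per size, solved in ascending order — which reproduces the full nonlinear
isotopomer model exactly while tracking only the EMUs the measurements
actually need.

For independent verification the module also contains a brute-force
simulator that iterates the complete isotopomer balance (all ``2^k`` labeling
states per metabolite) to a fixed point and marginalizes to mass groups; it
shares no code path with the EMU cascade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model_io import (MetabolicModel, ModelError, Reaction, SpeciesRef,
                       SubstrateSpec)

__all__ = [
    "EMU",
    "ElementaryEMUReaction",
    "EMULevel",
    "EMUDecomposition",
    "SimulationError",
    "decompose",
    "substrate_mids",
    "simulate",
    "convolve_mids",
    "simulate_by_isotopomer_enumeration",
]


class SimulationError(RuntimeError):
    """Raised when an EMU system cannot be solved at the given fluxes."""


@dataclass(frozen=True, order=True)
class EMU:
    """A metabolite id plus a sorted tuple of 1-based carbon positions."""

    metabolite: str
    positions: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(sorted(self.positions)))
        if len(set(self.positions)) != len(self.positions):
            raise ModelError(f"EMU {self}: repeated carbon positions")

    @property
    def size(self) -> int:
        return len(self.positions)

    def __repr__(self) -> str:
        return f"{self.metabolite}{{{','.join(map(str, self.positions))}}}"


@dataclass(frozen=True)
class ElementaryEMUReaction:
    """One EMU-level transition: flux-weighted production of ``product``
    from one source EMU or an ordered tuple whose MIDs convolve."""

    product: EMU
    sources: tuple[EMU, ...]
    rxn_index: int   # position in model.reactions
    coef: float      # stoichiometric coefficient of the product occurrence

    def __post_init__(self):
        if sum(s.size for s in self.sources) != self.product.size:
            raise ModelError(
                f"elementary reaction {self.sources} -> {self.product}: "
                f"source sizes do not add up to the product size")


@dataclass
class EMULevel:
    """All unknown EMUs of one size and the reactions producing them."""

    size: int
    internal: list[EMU]
    reactions: list[ElementaryEMUReaction]


@dataclass
class EMUDecomposition:
    model: MetabolicModel
    levels: list[EMULevel]
    inputs: list[EMU]          # substrate EMUs (metabolites never produced)
    measured: list[EMU]

    @property
    def n_unknown_mids(self) -> int:
        """Total number of unknown MID entries across all levels."""
        return sum((lv.size + 1) * len(lv.internal) for lv in self.levels)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _producer_index(model: MetabolicModel):
    """met -> list of (reaction index, product occurrence, reaction).

    S-type reactions define only their fragment species: their product
    occurrences are skipped for metabolites that take part in the mass
    balance (e.g. CO2 released during amino-acid formation), so the
    unit-flux pseudo-reactions never feed network metabolite balances.
    """
    mb_mets = {ref.metabolite
               for rxn in model.mass_balance_reactions
               for ref in rxn.reactants + rxn.products}
    producers: dict[str, list[tuple[int, SpeciesRef, Reaction]]] = {}
    for idx, rxn in enumerate(model.reactions):
        for ref in rxn.products:
            if not ref.atoms:
                continue
            if rxn.rtype == "S" and ref.metabolite in mb_mets:
                continue
            producers.setdefault(ref.metabolite, []).append((idx, ref, rxn))
    return producers


def input_metabolites(model: MetabolicModel) -> frozenset[str]:
    """Traced metabolites never produced by an atom-mapped reaction
    (the substrate entry points of the labeling network)."""
    producers = _producer_index(model)
    return frozenset(m for m in model.carbon_counts if m not in producers)


def _source_emus(rxn: Reaction, pref: SpeciesRef, positions: tuple[int, ...]):
    """Source EMU(s) supplying the given product carbons, reactant order."""
    symbols = [pref.atoms[p - 1] for p in positions]
    per_reactant: dict[int, list[int]] = {}
    for sym in symbols:
        for i, ref in enumerate(rxn.reactants):
            if ref.atoms and sym in ref.atoms:
                per_reactant.setdefault(i, []).append(ref.atoms.index(sym) + 1)
                break
        else:
            raise ModelError(
                f"reaction {rxn.id}: product atom {sym!r} has no reactant source")
    return tuple(EMU(rxn.reactants[i].metabolite, tuple(sorted(ps)))
                 for i, ps in sorted(per_reactant.items()))


def decompose(model: MetabolicModel, measured_emus: list[EMU]) -> EMUDecomposition:
    """Trace the atom-transition network backwards from the measured EMUs.

    Returns size-ordered levels containing only EMUs that are ancestors of a
    measured EMU.  Symmetric products written as fractional-coefficient twins
    yield one elementary reaction per atom-map variant, each carrying the
    fractional flux.
    """
    producers = _producer_index(model)
    inputs_mets = input_metabolites(model)

    for emu in measured_emus:
        if emu.metabolite not in model.carbon_counts:
            raise ModelError(
                f"measured EMU {emu}: metabolite has no atom maps in the model")
        nc = model.carbon_counts[emu.metabolite]
        if any(p < 1 or p > nc for p in emu.positions):
            raise ModelError(
                f"measured EMU {emu}: position outside 1..{nc}")

    elementary: dict[EMU, list[ElementaryEMUReaction]] = {}
    inputs: set[EMU] = set()
    stack = list(measured_emus)
    seen: set[EMU] = set()
    while stack:
        emu = stack.pop()
        if emu in seen:
            continue
        seen.add(emu)
        if emu.metabolite in inputs_mets:
            inputs.add(emu)
            continue
        if emu.metabolite not in producers:
            raise ModelError(f"orphan EMU {emu}: no producing reaction")
        ers = []
        for idx, pref, rxn in producers[emu.metabolite]:
            sources = _source_emus(rxn, pref, emu.positions)
            ers.append(ElementaryEMUReaction(emu, sources, idx, pref.coef))
            stack.extend(sources)
        elementary[emu] = ers

    sizes = sorted({e.size for e in elementary})
    levels = []
    for n in sizes:
        internal = sorted(e for e in elementary if e.size == n)
        rxns = [er for e in internal for er in elementary[e]]
        levels.append(EMULevel(size=n, internal=internal, reactions=rxns))
    return EMUDecomposition(model=model, levels=levels,
                            inputs=sorted(inputs), measured=list(measured_emus))


# ---------------------------------------------------------------------------
# substrate MIDs
# ---------------------------------------------------------------------------

def _position_mid(spec: SubstrateSpec, pattern: str, enrichment: float,
                  position: int) -> np.ndarray:
    labeled = pattern == "U" or pattern[position - 1] == "1"
    p13 = enrichment if labeled else spec.natural_abundance
    return np.array([1.0 - p13, p13])


def convolve_mids(mids) -> np.ndarray:
    out = np.array([1.0])
    for m in mids:
        out = np.convolve(out, np.asarray(m, float))
    return out


def substrate_mids(spec: SubstrateSpec, emu: EMU) -> np.ndarray:
    """Mixture-weighted MID of a substrate EMU.

    Labeled positions contribute the species enrichment, unlabeled positions
    the residual natural 13C abundance; positions combine by convolution and
    species by molar-fraction mixture.
    """
    if emu.metabolite != spec.metabolite:
        raise ModelError(f"EMU {emu} does not belong to substrate {spec.metabolite}")
    out = np.zeros(emu.size + 1)
    for pattern, frac, enr in spec.species:
        if pattern != "U" and any(p > len(pattern) for p in emu.positions):
            raise ModelError(
                f"EMU {emu}: position outside the {len(pattern)}-carbon "
                f"substrate {spec.metabolite}")
        out += frac * convolve_mids(
            _position_mid(spec, pattern, enr, p) for p in emu.positions)
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _model_flux_vector(model: MetabolicModel, v: np.ndarray) -> np.ndarray:
    """Expand mass-balance fluxes to all reactions (S-type get unit flux).

    S-type reactions are outside the mass balance and carry no flux
    variable; for a fragment with a single forming reaction the weight
    cancels in the balance, so unit flux is used.
    """
    v = np.asarray(v, float)
    if (v < -1e-9).any():
        bad = [model.mass_balance_reactions[j].id for j in np.flatnonzero(v < -1e-9)]
        raise SimulationError(f"negative fluxes for reactions {bad}")
    full = np.ones(len(model.reactions))
    for k, j in enumerate(model.mass_balance_indices):
        full[j] = max(v[k], 0.0)
    return full


def simulate(decomp: EMUDecomposition, v: np.ndarray,
             substrate_specs: list[SubstrateSpec]) -> dict[EMU, np.ndarray]:
    """Solve the EMU cascade at flux vector ``v`` (input-order mass-balance
    fluxes) and return the MID of every EMU in the decomposition.

    Per size level the flux-weighted balance ``A(v) X = B(v) Y`` is
    assembled over internal (X) and already-known (Y) EMU MIDs and solved by
    dense LU.  Condensation sources enter as convolutions of already-solved
    MIDs.  Internal EMUs with zero total inflow are reported as dead ends.
    """
    model = decomp.model
    flux = _model_flux_vector(model, v)
    specs = {s.metabolite: s for s in substrate_specs}

    solved: dict[EMU, np.ndarray] = {}
    for emu in decomp.inputs:
        if emu.metabolite not in specs:
            raise SimulationError(
                f"substrate metabolite {emu.metabolite} has no labeling spec")
        solved[emu] = substrate_mids(specs[emu.metabolite], emu)

    for level in decomp.levels:
        index = {e: i for i, e in enumerate(level.internal)}
        k = len(level.internal)
        A = np.zeros((k, k))
        B = np.zeros((k, level.size + 1))
        for er in level.reactions:
            f = flux[er.rxn_index] * er.coef
            if f <= 0.0:
                continue
            i = index[er.product]
            A[i, i] += f
            if len(er.sources) == 1 and er.sources[0] in index:
                A[i, index[er.sources[0]]] -= f
            else:
                B[i] += f * convolve_mids(solved[s] for s in er.sources)
        dead = [level.internal[i] for i in range(k) if A[i, i] <= 0.0]
        if dead:
            raise SimulationError(
                f"dead-end EMUs with zero inflow at this flux vector: {dead}")
        try:
            X = scipy.linalg.solve(A, B)
        except scipy.linalg.LinAlgError as exc:
            raise SimulationError(f"singular EMU balance at size {level.size}: {exc}")
        for e, i in index.items():
            solved[e] = X[i]
    return solved


# ---------------------------------------------------------------------------
# brute-force isotopomer oracle
# ---------------------------------------------------------------------------

def _substrate_iso_dist(spec: SubstrateSpec, nc: int) -> np.ndarray:
    d = np.zeros(2 ** nc)
    for pattern, frac, enr in spec.species:
        probs = [_position_mid(spec, pattern, enr, p + 1)[1] for p in range(nc)]
        for mask in range(2 ** nc):
            p = frac
            for q in range(nc):
                p *= probs[q] if (mask >> q) & 1 else 1.0 - probs[q]
            d[mask] += p
    return d


def simulate_by_isotopomer_enumeration(
        model: MetabolicModel, v: np.ndarray,
        substrate_specs: list[SubstrateSpec],
        emus: list[EMU],
        tol: float = 1e-13, max_iter: int = 200_000) -> dict[EMU, np.ndarray]:
    """Reference simulator over the complete isotopomer state space.

    Tracks the joint labeling distribution of every traced metabolite (all
    ``2^k`` positional isotopomers) and iterates the flux-weighted balance to
    a fixed point, then marginalizes to the mass groups of the requested
    EMUs.  Exponential in per-metabolite carbon count — meant for small
    networks and cross-checks only.
    """
    producers = _producer_index(model)
    inputs = input_metabolites(model)
    flux = _model_flux_vector(model, v)
    specs = {s.metabolite: s for s in substrate_specs}

    dists: dict[str, np.ndarray] = {}
    for met, nc in model.carbon_counts.items():
        if met in inputs:
            if met not in specs:
                raise SimulationError(f"substrate {met} has no labeling spec")
            dists[met] = _substrate_iso_dist(specs[met], nc)
        else:
            d = np.zeros(2 ** nc)
            d[0] = 1.0
            dists[met] = d

    internal = [m for m in model.carbon_counts if m not in inputs]
    for _ in range(max_iter):
        delta = 0.0
        new: dict[str, np.ndarray] = {}
        for met in internal:
            nc = model.carbon_counts[met]
            num = np.zeros(2 ** nc)
            denom = 0.0
            for idx, pref, rxn in producers.get(met, []):
                f = flux[idx] * pref.coef
                if f <= 0.0:
                    continue
                denom += f
                num += f * _instance_product_dist(rxn, pref, dists)
            if denom <= 0.0:
                raise SimulationError(f"metabolite {met} has zero inflow")
            new[met] = num / denom
            delta = max(delta, np.abs(new[met] - dists[met]).max())
        dists.update(new)
        if delta < tol:
            break
    else:
        raise SimulationError("isotopomer fixed point did not converge")

    out = {}
    for emu in emus:
        d = dists[emu.metabolite]
        mid = np.zeros(emu.size + 1)
        bits = [p - 1 for p in emu.positions]
        for mask in range(len(d)):
            k = sum((mask >> b) & 1 for b in bits)
            mid[k] += d[mask]
        out[emu] = mid
    return out


def _instance_product_dist(rxn: Reaction, pref: SpeciesRef,
                           dists: dict[str, np.ndarray]) -> np.ndarray:
    """Isotopomer distribution of one product occurrence given reactant
    distributions (independence across distinct reactant molecules)."""
    sources = []  # per product carbon: (reactant instance no., reactant bit)
    reactant_ids = []
    for q, sym in enumerate(pref.atoms):
        for i, ref in enumerate(rxn.reactants):
            if ref.atoms and sym in ref.atoms:
                if i not in reactant_ids:
                    reactant_ids.append(i)
                sources.append((reactant_ids.index(i), ref.atoms.index(sym)))
                break
    r_dists = [dists[rxn.reactants[i].metabolite] for i in reactant_ids]
    out = np.zeros(2 ** len(pref.atoms))
    for masks in np.ndindex(*(len(d) for d in r_dists)):
        p = 1.0
        for d, m in zip(r_dists, masks):
            p *= d[m]
        if p == 0.0:
            continue
        pmask = 0
        for q, (ri, bit) in enumerate(sources):
            if (masks[ri] >> bit) & 1:
                pmask |= 1 << q
        out[pmask] += p
    return out
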