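"""Reading and writing the four delimited input files of a flux-analysis run.

A model is described by four comma-separated text files, editable in any
spreadsheet:

* ``model.csv`` — one row per reaction: id, stoichiometric equation,
  atom-transition equation, reaction type, basis marker, optional measured
  value and standard deviation, optional free-flux preference.
* ``substrate_input.csv`` — labeled-substrate mixtures: per substrate a list
  of positional isotopomer species with molar fractions.
* ``corr_file.csv`` — elemental composition of the non-traced atoms of each
  measured fragment (for natural-isotope correction) and the number of mass
  isotopomers reported for that fragment.
* ``measurements.csv`` — measured mass isotopomer distributions (MIDs) with
  standard deviations.

Reaction types follow the common convention of 13C-MFA model files:
``F`` irreversible, ``FR``/``R`` the forward/reverse directions of a
reversible reaction (listed as two rows, paired in file order), ``B``
metabolite-balance-only reactions (no atom map), and ``S`` isotopomer-balance
reactions (e.g. amino-acid formation from precursors) which carry atom maps
but are excluded from the mass balance.  Metabolites that do not take part in
isotopomer balancing are written ``X`` in the atom-transition equation.  The
basis reaction — typically substrate uptake — is marked ``*``.

Lines starting with ``#`` are comments; a comment of the form
``# unbalanced: MET1 MET2`` forces the listed metabolites out of the mass
balance regardless of the automatic source/sink classification.

All parse functions accept a filesystem path or, for convenience, a string
containing the file content itself (recognised by an embedded newline).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelError",
    "SpeciesRef",
    "Reaction",
    "MetabolicModel",
    "SubstrateSpec",
    "CorrectionSpec",
    "MeasuredFragment",
    "parse_model",
    "parse_substrates",
    "parse_corrections",
    "parse_measurements",
    "write_model",
    "write_measurements",
]

MASS_BALANCE_TYPES = ("F", "FR", "R", "B")
REACTION_TYPES = MASS_BALANCE_TYPES + ("S",)

#: default residual fractional 13C abundance of unlabeled carbon positions
NATURAL_13C = 0.0107

_SUM_TOL = 1e-9


class ModelError(ValueError):
    """Raised for any structural defect in an input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesRef:
    """One metabolite occurrence on one side of a reaction.

    ``atoms`` assigns a distinct letter to each carbon of this occurrence, or
    is ``None`` for untraced occurrences (written ``X`` in the file).
    """

    metabolite: str
    coef: float
    atoms: str | None = None


@dataclass
class Reaction:
    id: str
    rtype: str
    reactants: list[SpeciesRef]
    products: list[SpeciesRef]
    is_basis: bool = False
    measured: tuple[float, float] | None = None  # (mean, sd)
    prefer_free: bool = False
    pair_id: str | None = None  # partner id for FR/R pairs

    @property
    def traced(self) -> bool:
        return any(s.atoms for s in self.reactants + self.products)


@dataclass
class MetabolicModel:
    reactions: list[Reaction]
    balanced_metabolites: list[str]
    unbalanced_metabolites: frozenset[str]
    basis_reaction_id: str
    carbon_counts: dict[str, int]

    @property
    def mass_balance_indices(self) -> list[int]:
        """Positions (in ``reactions``) of the F/FR/R/B reactions, file order."""
        return [i for i, r in enumerate(self.reactions)
                if r.rtype in MASS_BALANCE_TYPES]

    @property
    def mass_balance_reactions(self) -> list[Reaction]:
        return [self.reactions[i] for i in self.mass_balance_indices]

    @property
    def s_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.rtype == "S"]

    @property
    def traced_metabolites(self) -> frozenset[str]:
        return frozenset(self.carbon_counts)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def reaction_index(self, rid: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == rid:
                return i
        raise KeyError(rid)


@dataclass
class SubstrateSpec:
    """Mixture of positional labeling species for one substrate.

    Each species is ``(pattern, molar_fraction, enrichment)`` where the
    pattern is a string of ``0``/``1`` over carbon positions (or ``U`` for
    uniformly labeled).  A ``1`` position carries the species' enrichment as
    its 13C fraction; a ``0`` position carries the residual natural
    abundance.
    """

    metabolite: str
    species: list[tuple[str, float, float]]
    natural_abundance: float = NATURAL_13C

    def __post_init__(self) -> None:
        total = sum(f for _, f, _ in self.species)
        if abs(total - 1.0) > _SUM_TOL:
            raise ModelError(
                f"substrate {self.metabolite}: molar fractions sum to "
                f"{total:g}, expected 1")
        for pat, _, enr in self.species:
            if not (0.0 <= enr <= 1.0):
                raise ModelError(
                    f"substrate {self.metabolite}: enrichment {enr} outside [0, 1]")
            if pat != "U" and set(pat) - {"0", "1"}:
                raise ModelError(
                    f"substrate {self.metabolite}: bad species pattern {pat!r}")


@dataclass
class CorrectionSpec:
    """Natural-isotope composition of a fragment's non-traced atoms."""

    fragment_id: str
    elements: list[tuple[tuple[float, ...], int]]  # (abundance vector, atom count)
    n_measured: int

    def __post_init__(self) -> None:
        if self.n_measured < 1:
            raise ModelError(
                f"fragment {self.fragment_id}: n_measured must be >= 1")
        for vec, count in self.elements:
            if count < 0:
                raise ModelError(
                    f"fragment {self.fragment_id}: negative atom count {count}")
            a = np.asarray(vec, float)
            if (a < 0).any() or abs(a.sum() - 1.0) > _SUM_TOL:
                raise ModelError(
                    f"fragment {self.fragment_id}: abundance vector must be "
                    f"nonnegative and sum to 1 (got sum {a.sum()!r})")


@dataclass
class MeasuredFragment:
    fragment_id: str
    metabolite: str
    positions: tuple[int, ...]  # 1-based carbons of the measured EMU
    mid: np.ndarray
    sd: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.mid)

    def __eq__(self, other) -> bool:  # ndarray-aware equality
        return (isinstance(other, MeasuredFragment)
                and self.fragment_id == other.fragment_id
                and self.metabolite == other.metabolite
                and self.positions == other.positions
                and np.array_equal(self.mid, other.mid)
                and np.array_equal(self.sd, other.sd))


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _open_rows(src) -> tuple[list[list[str]], list[str]]:
    """Return (data rows, comment lines) from a path or CSV text."""
    if hasattr(src, "read"):
        text = src.read()
    elif isinstance(src, str) and "\n" in src:
        text = src
    else:
        with open(os.fspath(src), newline="") as fh:
            text = fh.read()
    rows, comments = [], []
    for line in text.splitlines():
        if line.strip().startswith("#"):
            comments.append(line.strip())
            continue
        if not line.strip():
            continue
        rows.append([c.strip() for c in next(csv.reader([line]))])
    return rows, comments


def _parse_side(side: str) -> list[tuple[str, float]]:
    terms = []
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ModelError(f"empty term in equation side {side!r}")
        parts = term.split()
        if len(parts) == 2:
            coef = float(parts[0])
            met = parts[1]
        elif len(parts) == 1:
            coef, met = 1.0, parts[0]
        else:
            raise ModelError(f"cannot parse equation term {term!r}")
        if coef <= 0:
            raise ModelError(f"nonpositive coefficient in term {term!r}")
        terms.append((met, coef))
    return terms


def _parse_atoms(side: str) -> list[str | None]:
    out: list[str | None] = []
    for term in side.split("+"):
        term = term.strip()
        out.append(None if term in ("X", "x", "") else term)
    return out


def _build_side(eq_terms, atom_terms, rid, side_name) -> list[SpeciesRef]:
    if atom_terms is not None and len(atom_terms) != len(eq_terms):
        raise ModelError(
            f"reaction {rid}: atom transition has {len(atom_terms)} "
            f"{side_name} terms but the equation has {len(eq_terms)}")
    refs = []
    for k, (met, coef) in enumerate(eq_terms):
        atoms = atom_terms[k] if atom_terms is not None else None
        refs.append(SpeciesRef(met, coef, atoms))
    return refs


def _check_atom_balance(rxn: Reaction) -> None:
    """Every product-side atom symbol must map to exactly one reactant atom."""
    source: dict[str, tuple[int, int]] = {}
    for i, ref in enumerate(rxn.reactants):
        if not ref.atoms:
            continue
        for j, sym in enumerate(ref.atoms):
            if sym in source:
                raise ModelError(
                    f"reaction {rxn.id}: atom symbol {sym!r} appears more "
                    f"than once on the reactant side")
            source[sym] = (i, j)
    for ref in rxn.products:
        if not ref.atoms:
            continue
        if len(set(ref.atoms)) != len(ref.atoms):
            raise ModelError(
                f"reaction {rxn.id}: repeated atom symbol within product "
                f"map {ref.atoms!r}")
        for sym in ref.atoms:
            if sym not in source:
                raise ModelError(
                    f"reaction {rxn.id}: product atom symbol {sym!r} has no "
                    f"source on the reactant side")


# ---------------------------------------------------------------------------
# model parsing
# ---------------------------------------------------------------------------

def parse_model(src) -> MetabolicModel:
    """Parse a model file into a validated :class:`MetabolicModel`.

    Raises :class:`ModelError` naming the offending reaction for unknown type
    codes, missing/duplicate basis markers, atom-map length mismatches and
    unpaired FR/R rows.
    """
    rows, comments = _open_rows(src)
    if not rows:
        raise ModelError("model file contains no rows")
    rows = rows[1:]  # header

    forced_unbalanced: set[str] = set()
    forced_balanced: set[str] = set()
    for c in comments:
        body = c.lstrip("#").strip()
        if body.lower().startswith("unbalanced:"):
            forced_unbalanced.update(body.split(":", 1)[1].split())
        elif body.lower().startswith("balanced:"):
            forced_balanced.update(body.split(":", 1)[1].split())

    reactions: list[Reaction] = []
    seen_ids: set[str] = set()
    for row in rows:
        row = row + [""] * (8 - len(row))
        rid, eq, atoms, rtype, basis, mval, msd, pref = row[:8]
        if not rid:
            raise ModelError(f"row without a reaction id: {row}")
        if rid in seen_ids:
            raise ModelError(f"duplicate reaction id {rid}")
        seen_ids.add(rid)
        if rtype not in REACTION_TYPES:
            raise ModelError(
                f"reaction {rid}: unknown type code {rtype!r} "
                f"(expected one of {'/'.join(REACTION_TYPES)})")
        if "->" not in eq:
            raise ModelError(f"reaction {rid}: equation lacks '->'")
        lhs, rhs = eq.split("->", 1)
        eq_l, eq_r = _parse_side(lhs), _parse_side(rhs)
        if atoms:
            if "->" not in atoms:
                raise ModelError(f"reaction {rid}: atom transition lacks '->'")
            at_l, at_r = atoms.split("->", 1)
            atoms_l, atoms_r = _parse_atoms(at_l), _parse_atoms(at_r)
        else:
            if rtype != "B":
                raise ModelError(
                    f"reaction {rid}: atom transition required for type {rtype}")
            atoms_l = atoms_r = None

        measured = None
        if mval:
            if not msd:
                raise ModelError(f"reaction {rid}: measured value without SD")
            measured = (float(mval), float(msd))
            if measured[1] <= 0:
                raise ModelError(f"reaction {rid}: measured SD must be > 0")

        rxn = Reaction(
            id=rid, rtype=rtype,
            reactants=_build_side(eq_l, atoms_l, rid, "reactant"),
            products=_build_side(eq_r, atoms_r, rid, "product"),
            is_basis=(basis == "*"),
            measured=measured,
            prefer_free=bool(pref),
        )
        _check_atom_balance(rxn)
        reactions.append(rxn)

    basis_ids = [r.id for r in reactions if r.is_basis]
    if len(basis_ids) != 1:
        raise ModelError(
            f"exactly one basis reaction ('*') required, found {basis_ids or 'none'}")

    _pair_reversible(reactions)
    carbon_counts = _collect_carbon_counts(reactions)
    balanced, unbalanced = _classify_metabolites(
        reactions, forced_unbalanced, forced_balanced)
    return MetabolicModel(
        reactions=reactions,
        balanced_metabolites=balanced,
        unbalanced_metabolites=frozenset(unbalanced),
        basis_reaction_id=basis_ids[0],
        carbon_counts=carbon_counts,
    )


def _pair_reversible(reactions: list[Reaction]) -> None:
    fwd = [r for r in reactions if r.rtype == "FR"]
    rev = [r for r in reactions if r.rtype == "R"]
    if len(fwd) != len(rev):
        raise ModelError(
            f"unpaired reversible reactions: {len(fwd)} FR vs {len(rev)} R "
            f"(FR ids {[r.id for r in fwd]}, R ids {[r.id for r in rev]})")
    for f, r in zip(fwd, rev):
        _check_pair_stoichiometry(f, r)
        f.pair_id, r.pair_id = r.id, f.id


def _net_coefs(refs: list[SpeciesRef]) -> dict[str, float]:
    out: dict[str, float] = {}
    for ref in refs:
        out[ref.metabolite] = out.get(ref.metabolite, 0.0) + ref.coef
    return out


def _check_pair_stoichiometry(f: Reaction, r: Reaction) -> None:
    if (_net_coefs(f.reactants) != _net_coefs(r.products)
            or _net_coefs(f.products) != _net_coefs(r.reactants)):
        raise ModelError(
            f"reversible pair {f.id}/{r.id}: reverse stoichiometry does not "
            f"mirror the forward reaction")


def _collect_carbon_counts(reactions: list[Reaction]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rxn in reactions:
        for ref in rxn.reactants + rxn.products:
            if not ref.atoms:
                continue
            n = len(ref.atoms)
            prev = counts.setdefault(ref.metabolite, n)
            if prev != n:
                raise ModelError(
                    f"reaction {rxn.id}: atom map length {n} for "
                    f"{ref.metabolite} conflicts with carbon count {prev} "
                    f"seen elsewhere")
    return counts


def _classify_metabolites(reactions, forced_unbalanced,
                          forced_balanced=frozenset()):
    """Split metabolites into balanced rows and unbalanced sources/sinks.

    A metabolite that, over all mass-balance reactions, appears only as a
    reactant or only as a product is a source/sink and is excluded from the
    stoichiometric matrix; explicit ``# unbalanced:`` / ``# balanced:``
    lists override the automatic classification.
    """
    consumed: set[str] = set()
    produced: set[str] = set()
    order: list[str] = []
    for rxn in reactions:
        if rxn.rtype not in MASS_BALANCE_TYPES:
            continue
        for ref in rxn.reactants:
            consumed.add(ref.metabolite)
            if ref.metabolite not in order:
                order.append(ref.metabolite)
        for ref in rxn.products:
            produced.add(ref.metabolite)
            if ref.metabolite not in order:
                order.append(ref.metabolite)
    balanced = [m for m in order
                if ((m in consumed and m in produced) or m in forced_balanced)
                and m not in forced_unbalanced]
    unbalanced = [m for m in order if m not in balanced]
    return balanced, set(unbalanced) | set(forced_unbalanced)


# ---------------------------------------------------------------------------
# substrate, correction and measurement parsing
# ---------------------------------------------------------------------------

def parse_substrates(src, model: MetabolicModel | None = None) -> list[SubstrateSpec]:
    """Parse a substrate-mixture file.

    Columns: metabolite, species pattern (``0``/``1`` per position or ``U``),
    molar fraction, optional enrichment (default 1), optional residual
    natural 13C abundance (default 0.0107).  When *model* is given, substrate
    ids and pattern lengths are validated against it.
    """
    rows, _ = _open_rows(src)
    if not rows:
        raise ModelError("substrate file contains no rows")
    grouped: dict[str, list[tuple[str, float, float]]] = {}
    natural: dict[str, float] = {}
    for row in rows[1:]:
        row = row + [""] * (5 - len(row))
        met, pattern, frac, enr, nat = row[:5]
        grouped.setdefault(met, []).append(
            (pattern, float(frac), float(enr) if enr else 1.0))
        if nat:
            prev = natural.setdefault(met, float(nat))
            if prev != float(nat):
                raise ModelError(
                    f"substrate {met}: conflicting natural-abundance values")
    specs = []
    for met, species in grouped.items():
        total = sum(f for _, f, _ in species)
        if abs(total - 1.0) > _SUM_TOL:
            raise ModelError(
                f"substrate {met}: molar fractions sum to {total:g}, expected 1")
        specs.append(SubstrateSpec(met, species, natural.get(met, NATURAL_13C)))
    if model is not None:
        for spec in specs:
            if spec.metabolite not in model.carbon_counts:
                raise ModelError(
                    f"substrate {spec.metabolite} is not a traced metabolite "
                    f"of the model")
            nc = model.carbon_counts[spec.metabolite]
            for pat, _, _ in spec.species:
                if pat != "U" and len(pat) != nc:
                    raise ModelError(
                        f"substrate {spec.metabolite}: pattern {pat!r} has "
                        f"{len(pat)} positions, metabolite has {nc} carbons")
    return specs


def parse_corrections(src) -> list[CorrectionSpec]:
    """Parse a correction file.

    Columns: fragment id, element label, semicolon-separated natural
    abundance vector, atom count, number of measured mass isotopomers.
    Multiple rows per fragment add elements; n_measured must agree.
    """
    rows, _ = _open_rows(src)
    if not rows:
        raise ModelError("correction file contains no rows")
    elements: dict[str, list[tuple[tuple[float, ...], int]]] = {}
    n_meas: dict[str, int] = {}
    for row in rows[1:]:
        row = row + [""] * (5 - len(row))
        frag, _label, vec, count, nm = row[:5]
        count = int(count) if count else 0
        if vec:
            abundances = tuple(float(x) for x in vec.split(";"))
            elements.setdefault(frag, []).append((abundances, count))
        else:
            elements.setdefault(frag, [])
        if nm:
            prev = n_meas.setdefault(frag, int(nm))
            if prev != int(nm):
                raise ModelError(f"fragment {frag}: conflicting n_measured values")
    specs = []
    for frag, elems in elements.items():
        if frag not in n_meas:
            raise ModelError(f"fragment {frag}: n_measured not specified")
        specs.append(CorrectionSpec(frag, elems, n_meas[frag]))
    return specs


def parse_measurements(src, corrections: list[CorrectionSpec]) -> list[MeasuredFragment]:
    """Parse measured fragment MIDs, validated against the correction specs.

    Columns: fragment id, source metabolite, carbon-position indicator
    (e.g. ``11111``), semicolon-separated MID, semicolon-separated SDs.
    Vectors are trimmed to the fragment's n_measured entries.
    """
    by_id = {c.fragment_id: c for c in corrections}
    rows, _ = _open_rows(src)
    if not rows:
        raise ModelError("measurement file contains no rows")
    fragments = []
    for row in rows[1:]:
        row = row + [""] * (5 - len(row))
        frag, met, posind, mid_s, sd_s = row[:5]
        if frag not in by_id:
            raise ModelError(f"fragment {frag} has no entry in the correction file")
        spec = by_id[frag]
        positions = tuple(i + 1 for i, ch in enumerate(posind) if ch == "1")
        if not positions:
            raise ModelError(f"fragment {frag}: empty carbon-position indicator")
        if spec.n_measured > len(positions) + 1:
            raise ModelError(
                f"fragment {frag}: n_measured {spec.n_measured} exceeds "
                f"carbon count + 1 = {len(positions) + 1}")
        mid = np.array([float(x) for x in mid_s.split(";")])
        sd = np.array([float(x) for x in sd_s.split(";")])
        if len(mid) < spec.n_measured or len(sd) < spec.n_measured:
            raise ModelError(
                f"fragment {frag}: expected {spec.n_measured} MID/SD entries, "
                f"got {len(mid)}/{len(sd)}")
        mid, sd = mid[:spec.n_measured], sd[:spec.n_measured]
        if (mid < 0).any():
            raise ModelError(f"fragment {frag}: negative MID entry")
        if (sd <= 0).any():
            raise ModelError(f"fragment {frag}: standard deviations must be > 0")
        fragments.append(MeasuredFragment(frag, met, positions, mid, sd))
    return fragments


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _format_side(refs: list[SpeciesRef]) -> str:
    return " + ".join(
        (f"{ref.coef:g} {ref.metabolite}" if ref.coef != 1.0 else ref.metabolite)
        for ref in refs)


def _format_atoms(refs: list[SpeciesRef]) -> str:
    return " + ".join(ref.atoms if ref.atoms else "X" for ref in refs)


def write_model(model: MetabolicModel, path) -> None:
    """Write a model back to the file dialect read by :func:`parse_model`."""
    lines = ["id,equation,atom transition,type,basis,measured value,measured SD,free-flux preference"]
    explicit = sorted(
        m for m in model.unbalanced_metabolites
        if m in _auto_balanced_candidates(model))
    if explicit:
        lines.insert(0, "# unbalanced: " + " ".join(explicit))
    for r in model.reactions:
        eq = f"{_format_side(r.reactants)} -> {_format_side(r.products)}"
        atoms = ""
        if r.traced or r.rtype != "B":
            atoms = f"{_format_atoms(r.reactants)} -> {_format_atoms(r.products)}"
        mval = f"{r.measured[0]:g}" if r.measured else ""
        msd = f"{r.measured[1]:g}" if r.measured else ""
        lines.append(",".join([
            r.id, f'"{eq}"', f'"{atoms}"', r.rtype,
            "*" if r.is_basis else "", mval, msd,
            "1" if r.prefer_free else ""]))
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _auto_balanced_candidates(model: MetabolicModel) -> set[str]:
    consumed, produced = set(), set()
    for rxn in model.mass_balance_reactions:
        consumed.update(ref.metabolite for ref in rxn.reactants)
        produced.update(ref.metabolite for ref in rxn.products)
    return consumed & produced


def write_measurements(fragments: list[MeasuredFragment], path) -> None:
    lines = ["fragment,metabolite,positions,mid,sd"]
    for f in fragments:
        nmax = max(f.positions)
        indicator = "".join("1" if i + 1 in f.positions else "0" for i in range(nmax))
        lines.append(",".join([
            f.fragment_id, f.metabolite, indicator,
            ";".join(f"{x:.17g}" for x in f.mid),
            ";".join(f"{x:.17g}" for x in f.sd)]))
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")
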