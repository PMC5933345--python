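"""Stoichiometric matrix, block ordering, null space and LP bounds."""

import numpy as np
import pytest
import scipy.linalg

import emuflux as ef
from emuflux import fixtures as fx
from emuflux import network_math as nm

HEADER = "id,equation,atom transition,type,basis,measured value,measured SD,free-flux preference\n"


def test_single_reaction_column():
    m = ef.parse_model("# balanced: A B\n" + HEADER + "R1, A -> B, ab -> ab, F, *\n")
    S = ef.build_stoichiometric_matrix(m)
    rows = {met: i for i, met in enumerate(m.balanced_metabolites)}
    assert S.shape == (2, 1)
    assert S[rows["A"], 0] == -1 and S[rows["B"], 0] == 1


def test_tca_nullity_is_seven(tca):
    model, _, _ = tca
    S = ef.build_stoichiometric_matrix(model)
    assert S.shape == (11, 18)
    nullity = S.shape[1] - np.linalg.matrix_rank(S)
    assert nullity == 7


def test_tca_block_ordering(tca):
    model, _, _ = tca
    rxns = model.mass_balance_reactions
    ids = [r.id for r in rxns]
    perm = ef.order_reactions(model)
    ordered = [ids[j] for j in perm]
    assert ordered[0] == "V07"           # reversible forward first
    assert ordered[-1] == "V08"          # reversible reverse last
    assert ordered[-5:-1] == ["V01", "V16", "V17", "V18"]  # basis & measured


def test_ordering_preference_stability():
    m = ef.parse_model(HEADER + "\n".join([
        "R0, S -> A, a -> a, F, *",
        "Va, A -> B, a -> a, F,,,,",
        "Vb, A -> B, a -> a, F,,,,",
        "R3, B -> C, a -> a, F,,,,",
        "R4, C -> C_OUT, a -> X, F,,,,",
    ]) + "\n")
    ids = [r.id for r in m.mass_balance_reactions]
    perm = ef.order_reactions(m, preferences=["Vb", "Va"])
    ordered = [ids[j] for j in perm]
    # preferred free fluxes keep the user's relative order, before the basis
    assert ordered.index("Vb") < ordered.index("Va") < ordered.index("R0")


def test_no_reversible_reactions_ordering():
    m = ef.parse_model(HEADER + "R1, A -> B, ab -> ab, F, *\nR2, B -> C, ab -> ab, F,\n")
    perm = ef.order_reactions(m)
    ids = [r.id for r in m.mass_balance_reactions]
    assert [ids[j] for j in perm] == ["R2", "R1"]


def test_tca_free_fluxes_include_basis_and_measured(tca):
    model, _, _ = tca
    nb = ef.null_basis_for_model(model)
    assert nb.n_free == 7
    assert {"V01", "V16", "V17", "V18", "V08"} <= set(nb.free_reaction_ids)
    assert nb.rank == 11


def test_chain_null_basis():
    m = ef.parse_model(HEADER + "R1, A -> M, a -> a, F, *\nR2, M -> B, a -> X, F,\n")
    S = ef.build_stoichiometric_matrix(m)
    nb = ef.null_basis(S, ef.order_reactions(m))
    nb.reaction_ids = [r.id for r in m.mass_balance_reactions]
    assert nb.rank == 1 and nb.n_free == 1
    v = nb.fluxes_from_free(np.array([2.5]))
    assert np.allclose(v, [2.5, 2.5])


@pytest.mark.parametrize("seed", range(10))
def test_random_kernel_against_svd(seed):
    """rref-based kernel spans the same space as an SVD null space and
    satisfies S @ N = 0; pivot count agrees with the numeric rank."""
    rng = np.random.default_rng(seed)
    m, n = rng.integers(2, 8), rng.integers(3, 12)
    S = np.where(rng.random((m, n)) < 0.6, 0.0, rng.integers(-2, 3, (m, n)))
    if np.abs(S).sum() == 0:
        S[0, 0] = 1.0
    nb = ef.null_basis(S, np.arange(n))
    assert nb.rank == np.linalg.matrix_rank(S)
    if nb.N.size:
        assert np.abs(S @ nb.N).max() < 1e-9
    kernel = scipy.linalg.null_space(S)
    assert nb.N.shape[1] == kernel.shape[1]
    # every rref kernel vector lies in the SVD kernel
    if kernel.size:
        proj = kernel @ (kernel.T @ nb.N)
        assert np.abs(proj - nb.N).max() < 1e-9


@pytest.mark.parametrize("seed", range(5))
def test_steady_state_for_random_free_fluxes(tca, seed):
    model, _, _ = tca
    nb = ef.null_basis_for_model(model)
    S = nb.S
    rng = np.random.default_rng(seed)
    for _ in range(20):
        v = nb.fluxes_from_free(rng.uniform(-5, 5, nb.n_free))
        assert np.abs(S @ v).max() < 1e-9


def test_nullity_invariant_under_ordering(tca):
    model, _, _ = tca
    S = ef.build_stoichiometric_matrix(model)
    rng = np.random.default_rng(0)
    baseline = ef.null_basis(S, np.arange(S.shape[1])).n_free
    for _ in range(5):
        perm = rng.permutation(S.shape[1])
        assert ef.null_basis(S, perm).n_free == baseline


def test_bounds_and_feasible_start(tca):
    model, _, _ = tca
    nb = ef.null_basis_for_model(model)
    bounds, v0 = ef.feasible_bounds_and_start(model, nb, seed=0)
    by_id = dict(zip(bounds.reaction_ids, bounds.as_pairs()))
    assert by_id["V01"] == (1.0, 1.0)
    # measured mean 0.20, SD 0.01 -> mean +/- 3 SD
    assert by_id["V16"] == pytest.approx((0.17, 0.23))
    for rid, (lo, hi) in by_id.items():
        if rid not in ("V01", "V16", "V17", "V18"):
            assert (lo, hi) == (0.0, 15.0)
    assert np.abs(nb.S @ v0).max() < 1e-9
    assert (v0 >= bounds.lower - 1e-9).all() and (v0 <= bounds.upper + 1e-9).all()


def test_contradictory_measured_bounds_raise():
    m = ef.parse_model(HEADER + "\n".join([
        "R1, S -> A, a -> a, F, *",
        "R2, A -> B, a -> X, F,,20.0,0.1,",
        "R3, A -> C, a -> a, F,,,,",
        "R4, C -> C_OUT, a -> X, F,,,,",
    ]) + "\n")
    nb = ef.null_basis_for_model(m)
    with pytest.raises(ef.ModelError, match="R2"):
        ef.feasible_bounds_and_start(m, nb, seed=0)
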