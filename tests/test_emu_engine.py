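"""EMU decomposition, substrate MIDs and simulation vs the isotopomer oracle."""

import numpy as np
import pytest

import emuflux as ef
from emuflux import fixtures as fx
from emuflux.emu_engine import EMU, SimulationError

HEADER = "id,equation,atom transition,type,basis,measured value,measured SD,free-flux preference\n"


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def test_decompose_linear_chain():
    model, _, (measured,) = fx.toy_chain()
    decomp = ef.decompose(model, [measured])
    assert len(decomp.levels) == 1
    level = decomp.levels[0]
    assert level.size == 2
    assert set(level.internal) == {EMU("B", (1, 2)), EMU("C", (1, 2))}
    assert decomp.inputs == [EMU("A", (1, 2))]


def test_measured_substrate_emu_needs_no_levels():
    model, subs, _ = fx.toy_chain()
    emu = EMU("A", (1, 2))
    decomp = ef.decompose(model, [emu])
    assert decomp.levels == [] and decomp.inputs == [emu]
    mids = ef.simulate(decomp, np.ones(3), subs)
    assert np.allclose(mids[emu], [0.5, 0.5, 0.0])


def test_decompose_rejects_untraced_and_orphan():
    model, _, _ = fx.toy_chain()
    with pytest.raises(ef.ModelError, match="atom maps"):
        ef.decompose(model, [EMU("C_OUT", (1,))])
    with pytest.raises(ef.ModelError, match="outside"):
        ef.decompose(model, [EMU("C", (1, 5))])


def test_tca_decomposition_is_smaller_than_isotopomer_model(tca):
    model, _, _ = tca
    emus = [EMU(met, pos) for _, met, pos in fx.tca_fragments()]
    decomp = ef.decompose(model, emus)
    n_iso = sum(2 ** nc for nc in model.carbon_counts.values())
    assert 0 < decomp.n_unknown_mids < n_iso


# ---------------------------------------------------------------------------
# substrate MIDs
# ---------------------------------------------------------------------------

def test_substrate_mid_uniform_label():
    spec = ef.SubstrateSpec("S", [("U", 1.0, 1.0)], natural_abundance=0.0)
    assert np.allclose(ef.substrate_mids(spec, EMU("S", (1, 2, 3))), [0, 0, 0, 1])


def test_substrate_mid_positional_mixture():
    spec = ef.SubstrateSpec("S", [("100", 0.5, 1.0), ("000", 0.5, 1.0)],
                            natural_abundance=0.0)
    assert np.allclose(ef.substrate_mids(spec, EMU("S", (1,))), [0.5, 0.5])


def test_substrate_mid_natural_abundance_binomial():
    a = 0.011
    spec = ef.SubstrateSpec("S", [("00", 1.0, 1.0)], natural_abundance=a)
    mid = ef.substrate_mids(spec, EMU("S", (1, 2)))
    assert np.allclose(mid, [0.978121, 0.021758, 0.000121], atol=1e-12)


def test_substrate_mid_position_out_of_range():
    spec = ef.SubstrateSpec("S", [("10", 1.0, 1.0)])
    with pytest.raises(ef.ModelError, match="outside"):
        ef.substrate_mids(spec, EMU("S", (3,)))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _feasible_fluxes(model, seed):
    nb = ef.null_basis_for_model(model)
    _, v0 = ef.feasible_bounds_and_start(model, nb, seed=seed)
    return v0


def test_unlabeled_network_gives_monoisotopic_mids():
    model, _, emus = fx.toy_symmetric_cycle()
    subs = [ef.SubstrateSpec("S_EX", [("00", 1.0, 1.0)], natural_abundance=0.0)]
    decomp = ef.decompose(model, emus)
    mids = ef.simulate(decomp, _feasible_fluxes(model, 0), subs)
    for emu in emus:
        expected = np.zeros(emu.size + 1)
        expected[0] = 1.0
        assert np.allclose(mids[emu], expected, atol=1e-12)


@pytest.mark.parametrize("toy", sorted(fx.TOY_BUILDERS))
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_emu_matches_brute_force_enumeration(toy, seed):
    """EMU cascade equals the full isotopomer fixed point on every bundled
    toy network, at random feasible flux distributions."""
    model, subs, emus = fx.TOY_BUILDERS[toy]()
    v = _feasible_fluxes(model, seed)
    decomp = ef.decompose(model, emus)
    mids = ef.simulate(decomp, v, subs)
    oracle = ef.simulate_by_isotopomer_enumeration(model, v, subs, emus)
    for emu in emus:
        assert np.abs(mids[emu] - oracle[emu]).max() < 1e-9


def test_tca_matches_brute_force_enumeration(tca, tca_truth):
    model, subs, _ = tca
    _, v = tca_truth
    emus = [EMU(met, pos) for _, met, pos in fx.tca_fragments()]
    decomp = ef.decompose(model, emus)
    mids = ef.simulate(decomp, v, subs)
    oracle = ef.simulate_by_isotopomer_enumeration(model, v, subs, emus)
    for emu in emus:
        assert np.abs(mids[emu] - oracle[emu]).max() < 1e-9


@pytest.mark.parametrize("toy", sorted(fx.TOY_BUILDERS))
def test_simulated_mids_are_distributions(toy):
    model, subs, emus = fx.TOY_BUILDERS[toy]()
    decomp = ef.decompose(model, emus)
    mids = ef.simulate(decomp, _feasible_fluxes(model, 7), subs)
    for mid in mids.values():
        assert mid.sum() == pytest.approx(1.0, abs=1e-9)
        assert (mid >= -1e-12).all() and (mid <= 1 + 1e-12).all()


def test_flux_scaling_invariance(tca, tca_truth):
    model, subs, _ = tca
    _, v = tca_truth
    emus = [EMU(met, pos) for _, met, pos in fx.tca_fragments()]
    decomp = ef.decompose(model, emus)
    base = ef.simulate(decomp, v, subs)
    for scale in (0.1, 3.7, 250.0):
        scaled = ef.simulate(decomp, scale * v, subs)
        assert max(np.abs(base[e] - scaled[e]).max() for e in emus) < 1e-12


def test_condensation_source_order_is_symmetric():
    """Writing the condensing reactants in either order gives the same MID."""
    common = "R1, S1 -> A, ab -> ab, F, *\nR2, S2 -> B, cd -> cd, F,\n"
    m1 = ef.parse_model(HEADER + common
                        + "R3, A + B -> C, ab + cd -> acbd, F,\n"
                        + "R4, C -> C_OUT, abcd -> X, F,\n")
    m2 = ef.parse_model(HEADER + common
                        + "R3, B + A -> C, cd + ab -> acbd, F,\n"
                        + "R4, C -> C_OUT, abcd -> X, F,\n")
    subs = [ef.SubstrateSpec("S1", [("10", 1.0, 1.0)], natural_abundance=0.0),
            ef.SubstrateSpec("S2", [("01", 0.5, 0.8), ("00", 0.5, 0.8)],
                             natural_abundance=0.011)]
    emu = EMU("C", (1, 2, 3, 4))
    v = np.ones(4)
    out = []
    for m in (m1, m2):
        decomp = ef.decompose(m, [emu])
        out.append(ef.simulate(decomp, v, subs)[emu])
    assert np.allclose(out[0], out[1], atol=1e-12)


def test_dead_end_and_negative_flux_errors():
    model, subs, emus = fx.toy_chain()
    decomp = ef.decompose(model, emus)
    with pytest.raises(SimulationError, match="dead-end"):
        ef.simulate(decomp, np.array([1.0, 0.0, 1.0]), subs)
    with pytest.raises(SimulationError, match="negative"):
        ef.simulate(decomp, np.array([1.0, -0.5, 1.0]), subs)


def test_missing_substrate_spec_raises():
    model, _, emus = fx.toy_chain()
    decomp = ef.decompose(model, emus)
    with pytest.raises(SimulationError, match="labeling spec"):
        ef.simulate(decomp, np.ones(3), [])
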