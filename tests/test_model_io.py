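"""Parsing, validation and round-trip of the four input file formats."""

import numpy as np
import pytest

import emuflux as ef
from emuflux import fixtures as fx
from emuflux.model_io import ModelError

HEADER = "id,equation,atom transition,type,basis,measured value,measured SD,free-flux preference\n"


def test_minimal_single_reaction_model():
    m = ef.parse_model(HEADER + "R1, A -> B, ab -> ab, F, *\n")
    assert len(m.reactions) == 1
    assert m.basis_reaction_id == "R1"
    assert {r.metabolite for ref in m.reactions for r in ref.reactants + ref.products} == {"A", "B"}
    assert m.carbon_counts == {"A": 2, "B": 2}


def test_tca_model_structure(tca):
    model, _, _ = tca
    assert len(model.mass_balance_reactions) == 18
    assert len(model.s_reactions) == 3
    assert model.basis_reaction_id == "V01"
    # reversible pair is wired both ways
    assert model.reaction("V07").pair_id == "V08"
    assert model.reaction("V08").pair_id == "V07"
    # sources/sinks excluded from the balance
    assert "PYR_EX" in model.unbalanced_metabolites
    assert "OAA_B" in model.unbalanced_metabolites
    assert "PYR" in model.balanced_metabolites


@pytest.mark.parametrize("row, message", [
    ("R1, A -> B, ab -> ab, Q, *", "unknown type code"),
    ("R1, A -> B, ab -> ab, F, ", "basis"),
    ("R1, A -> B, ab -> ab + cd, F, *", "atom transition"),
    ("R1, A -> B, abc -> abc, FR, *", "unpaired"),
    ("R1, A -> B, ab -> ac, F, *", "no source"),
    ("R1, A -> B, ab -> aa, F, *", "repeated atom symbol"),
    ("R1, A -> B + B, ab -> ab + X, F, *, 0.5,", "SD"),
])
def test_model_rejections(row, message):
    with pytest.raises(ModelError, match=message):
        ef.parse_model(HEADER + row + "\n")


def test_duplicate_basis_rejected():
    text = HEADER + "R1, A -> B, ab -> ab, F, *\nR2, B -> A, ab -> ab, F, *\n"
    with pytest.raises(ModelError, match="basis"):
        ef.parse_model(text)


def test_atom_map_length_consistency_across_reactions():
    text = HEADER + "R1, A -> B, ab -> ab, F, *\nR2, B -> C, abc -> abc, F,\n"
    with pytest.raises(ModelError, match="carbon count"):
        ef.parse_model(text)


def test_model_round_trip(tmp_path, tca):
    model, _, _ = tca
    path = tmp_path / "model.csv"
    ef.write_model(model, path)
    assert ef.parse_model(path) == model


def test_substrate_parsing_and_rejections():
    specs = ef.parse_substrates(
        "metabolite,pattern,fraction,enrichment,natural_13c\n"
        "PYR,100,0.4,0.99,0.011\nPYR,U,0.6,1.0,0.011\n")
    (spec,) = specs
    assert spec.metabolite == "PYR"
    assert spec.species == [("100", 0.4, 0.99), ("U", 0.6, 1.0)]
    assert spec.natural_abundance == 0.011

    with pytest.raises(ModelError, match="1.2"):
        ef.parse_substrates(
            "metabolite,pattern,fraction\nGLC,100000,0.6\nGLC,U,0.6\n")

    model = fx.builtin_tca_model()
    with pytest.raises(ModelError, match="not a traced metabolite"):
        ef.parse_substrates("metabolite,pattern,fraction\nNOPE,10,1.0\n", model)
    with pytest.raises(ModelError, match="carbons"):
        ef.parse_substrates("metabolite,pattern,fraction\nPYR_EX,10,1.0\n", model)


def test_single_unlabeled_substrate():
    (spec,) = ef.parse_substrates("metabolite,pattern,fraction\nGLC,000000,1.0\n")
    assert spec.species == [("000000", 1.0, 1.0)]


def test_correction_parsing(tca):
    corr = fx.builtin_tca_corrections()
    by_id = {c.fragment_id: c for c in corr}
    assert by_id["VALX"].n_measured == 6
    assert by_id["LYSX"].n_measured == 7
    assert by_id["ASPX"].n_measured == 5
    assert all(len(c.elements) == 2 for c in corr)

    with pytest.raises(ModelError, match="sum to 1"):
        ef.parse_corrections(
            "fragment,element,abundances,count,n_measured\nF1,C,0.9;0.2,1,2\n")
    with pytest.raises(ModelError, match="negative"):
        ef.parse_corrections(
            "fragment,element,abundances,count,n_measured\nF1,C,0.99;0.01,-1,2\n")


def test_measurement_parsing_counts_and_rejections(tca, tca_truth, tmp_path):
    model, subs, corr = tca
    _, v_true = tca_truth
    ds = fx.generate(model, subs, corr, fx.tca_fragments(), v_true,
                     noise_sd=0.0, seed=0, out_path=tmp_path / "meas.csv")
    frags = ef.parse_measurements(tmp_path / "meas.csv", corr)
    # data-point count equals the sum of n_measured over fragments
    assert sum(f.n_points for f in frags) == 18
    assert sum(c.n_measured for c in corr) == 18
    assert frags == ds.measurements

    with pytest.raises(ModelError, match="no entry in the correction file"):
        ef.parse_measurements(
            "fragment,metabolite,positions,mid,sd\nZZ,OAA,1111,1;0;0;0;0,0.01;0.01;0.01;0.01;0.01\n",
            corr)
    with pytest.raises(ModelError, match="> 0"):
        ef.parse_measurements(
            "fragment,metabolite,positions,mid,sd\n"
            "ASPX,ASPX,1111,1;0;0;0;0,0.01;0;0.01;0.01;0.01\n", corr)
    with pytest.raises(ModelError, match="expected 5"):
        ef.parse_measurements(
            "fragment,metabolite,positions,mid,sd\nASPX,ASPX,1111,1;0,0.01;0.01\n",
            corr)
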