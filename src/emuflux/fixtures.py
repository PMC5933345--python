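"""Bundled example networks and a seeded synthetic-data generator.

The centerpiece is a small tricarboxylic-acid (TCA) cycle network: 18
mass-balance reactions (two substrate inputs — pyruvate and glutamate — one
reversible pair represented as two directional reactions, three reactions
with measured values relative to the pyruvate uptake basis fixed at 1) plus
three isotopomer-balance reactions forming the measured amino-acid
fragments VALX, LYSX and ASPX.  Its stoichiometry gives seven free fluxes.

The atom-transition maps bundled here are a synthetic reconstruction from
canonical central-carbon biochemistry (citrate synthase / isocitrate
dehydrogenase carbon fates, succinate symmetry as fractional-coefficient
twins, valine from two pyruvates, lysine from oxaloacetate plus pyruvate
via the diaminopimelate route); they were not transcribed from any published
model file.  The substrate mixture (1-13C and U-13C pyruvate plus 1-13C
glutamate) and the GC-MS correction compositions are likewise plausible
synthetic defaults.  The fixture is therefore suited to closure and
parameter-recovery experiments, not to reproducing published flux tables.

Smaller toy networks (linear chain, branch split, symmetric condensation
cycle, reversible scrambling pair; each at most 12 traced carbons in total)
exercise every structural feature of the EMU engine and are small enough
for brute-force isotopomer cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import correction as _correction
from . import emu_engine, model_io, network_math
from .emu_engine import EMU
from .model_io import (CorrectionSpec, MeasuredFragment, MetabolicModel,
                       SubstrateSpec, parse_corrections, parse_model,
                       parse_substrates)

__all__ = [
    "builtin_tca_model", "builtin_tca_substrates", "builtin_tca_corrections",
    "tca_fragments", "tca_reference_fluxes",
    "toy_chain", "toy_split", "toy_symmetric_cycle", "toy_reversible",
    "TOY_BUILDERS", "SyntheticDataset", "generate",
]

# ---------------------------------------------------------------------------
# TCA cycle fixture
# ---------------------------------------------------------------------------

TCA_MODEL_CSV = """\
id,equation,atom transition,type,basis,measured value,measured SD,free-flux preference
V01,PYR_EX -> PYR,abc -> abc,F,*,,,
V02,GLU_EX -> AKG,abcde -> abcde,F,,,,
V03,"PYR -> ACCOA + CO_2_ + NADH","abc -> bc + a + X",F,,,,
V04,"ACCOA + OAA -> ICI","ab + cdef -> fedbac",F,,,,
V05,"ICI -> AKG + CO_2_ + NADH","abcdef -> abcde + f + X",F,,,,
V06,"AKG -> 0.5 SUC + 0.5 SUC + CO_2_ + NADH + ATP","abcde -> bcde + edcb + a + X + X",F,,,,
V07,"SUC -> OAA + FADH2 + NADH","abcd -> abcd + X + X",FR,,,,
V08,"OAA + FADH2 + NADH -> 0.5 SUC + 0.5 SUC","abcd + X + X -> abcd + dcba",R,,,,
V09,"OAA -> PYR + CO_2_","abcd -> abc + d",F,,,,
V10,"PYR + CO_2_ + ATP -> OAA","abc + d + X -> abcd",F,,,,
V11,"2 NADH + O_2_ -> 4 ATP",,B,,,,
V12,"2 FADH2 + O_2_ -> 2 ATP",,B,,,,
V13,O_2__EX -> O_2_,,B,,,,
V14,CO_2_ -> CO_2__EX,a -> X,F,,,,
V15,ATP -> ATPM,,B,,,,
V16,PYR -> PYR_B,abc -> X,F,,0.20,0.01,
V17,AKG -> AKG_B,abcde -> X,F,,0.23,0.01,
V18,OAA -> OAA_B,abcd -> X,F,,0.15,0.01,
SV1,"PYR + PYR -> VALX + CO_2_","abc + def -> abcef + d",S,,,,
SV2,"OAA + PYR -> LYSX + CO_2_","abcd + efg -> abcdfg + e",S,,,,
SV3,OAA -> ASPX,abcd -> abcd,S,,,,
"""

TCA_SUBSTRATES_CSV = """\
metabolite,pattern,fraction,enrichment,natural_13c
PYR_EX,100,0.5,1.0,0.0107
PYR_EX,U,0.5,1.0,0.0107
GLU_EX,10000,1.0,1.0,0.0107
"""

# TBDMS-derivative-like compositions: derivative carbons + two silicons.
TCA_CORRECTIONS_CSV = """\
fragment,element,abundances,count,n_measured
VALX,C,0.9893;0.0107,8,6
VALX,Si,0.92223;0.04685;0.03092,2,6
LYSX,C,0.9893;0.0107,8,7
LYSX,Si,0.92223;0.04685;0.03092,2,7
ASPX,C,0.9893;0.0107,8,5
ASPX,Si,0.92223;0.04685;0.03092,2,5
"""

#: Reference steady-state flux values used as the generating "truth" of the
#: synthetic TCA datasets (basis V01 = 1; free fluxes taken from this table,
#: dependent fluxes recomputed exactly from the null-space basis).
TCA_REFERENCE_TARGETS = {
    "V01": 1.00, "V02": 0.20, "V03": 0.62, "V04": 0.62, "V05": 0.62,
    "V06": 0.59, "V07": 2.62, "V08": 2.02, "V09": 0.30, "V10": 0.48,
    "V11": 1.21, "V12": 0.30, "V13": 1.51, "V14": 1.65, "V15": 5.56,
    "V16": 0.20, "V17": 0.23, "V18": 0.15,
}


def builtin_tca_model() -> MetabolicModel:
    return parse_model(TCA_MODEL_CSV)


def builtin_tca_substrates() -> list[SubstrateSpec]:
    return parse_substrates(TCA_SUBSTRATES_CSV)


def builtin_tca_corrections() -> list[CorrectionSpec]:
    return parse_corrections(TCA_CORRECTIONS_CSV)


def tca_fragments() -> list[tuple[str, str, tuple[int, ...]]]:
    """(fragment id, source metabolite, measured carbon positions)."""
    return [("VALX", "VALX", (1, 2, 3, 4, 5)),
            ("LYSX", "LYSX", (1, 2, 3, 4, 5, 6)),
            ("ASPX", "ASPX", (1, 2, 3, 4))]


def tca_reference_fluxes(model: MetabolicModel | None = None,
                         nb: network_math.NullBasis | None = None) -> np.ndarray:
    """Exactly balanced flux vector closest to the reference targets.

    Free fluxes are set to their target values and all dependent fluxes are
    recomputed through the null-space basis, so ``S v = 0`` holds to
    machine precision.
    """
    if model is None:
        model = builtin_tca_model()
    if nb is None:
        nb = network_math.null_basis_for_model(model)
    v_free = np.array([TCA_REFERENCE_TARGETS[rid] for rid in nb.free_reaction_ids])
    return nb.fluxes_from_free(v_free)


# ---------------------------------------------------------------------------
# toy networks (each returns model, substrates, measured EMUs)
# ---------------------------------------------------------------------------

def toy_chain():
    """Two-carbon linear chain A -> B -> C with A as the labeled substrate."""
    model = parse_model("""\
id,equation,atom transition,type,basis,measured value,measured SD,free-flux preference
R1,A -> B,ab -> ab,F,*,,,
R2,B -> C,ab -> ab,F,,,,
R3,C -> C_OUT,ab -> X,F,,,,
""")
    subs = [SubstrateSpec("A", [("10", 0.5, 1.0), ("00", 0.5, 1.0)],
                          natural_abundance=0.0)]
    return model, subs, [EMU("C", (1, 2))]


def toy_split():
    """Branch point whose split ratio is identifiable from the B fragment:
    route R2 passes carbons 1-2 of a 1-13C substrate, route R3 carbons 2-3."""
    model = parse_model("""\
id,equation,atom transition,type,basis,measured value,measured SD,free-flux preference
R1,S -> A,abc -> abc,F,*,,,
R2,A -> B + C,abc -> ab + c,F,,,,
R3,A -> B + C,abc -> bc + a,F,,,,
R4,B -> B_OUT,ab -> X,F,,,,
R5,C -> C_OUT,a -> X,F,,,,
""")
    subs = [SubstrateSpec("S", [("100", 1.0, 1.0)], natural_abundance=0.0)]
    return model, subs, [EMU("B", (1, 2))]


def toy_symmetric_cycle():
    """Condensation of the substrate with a recycled one-carbon unit into a
    symmetric intermediate, exercising convolution sources,
    fractional-coefficient twins and a labeling cycle (11 traced carbons)."""
    model = parse_model("""\
id,equation,atom transition,type,basis,measured value,measured SD,free-flux preference
R1,S_EX + E -> C,ab + c -> abc,F,*,,,
R2,"C -> 0.5 D + 0.5 D","abc -> abc + cba",F,,,,
R3,D -> E + F,abc -> c + ab,F,,,,
R4,F -> F_OUT,ab -> X,F,,,,
""")
    subs = [SubstrateSpec("S_EX", [("10", 0.5, 1.0), ("11", 0.3, 1.0),
                                   ("00", 0.2, 1.0)],
                          natural_abundance=0.0107)]
    return model, subs, [EMU("F", (1, 2)), EMU("D", (1, 2, 3))]


def toy_reversible():
    """Reversible pair with positional scrambling on the reverse step."""
    model = parse_model("""\
id,equation,atom transition,type,basis,measured value,measured SD,free-flux preference
R1,S_EX -> M1,ab -> ab,F,*,,,
R2,M1 -> M2,ab -> ab,FR,,,,
R3,M2 -> M1,ab -> ba,R,,,,
R4,M2 -> M2_OUT,ab -> X,F,,,,
""")
    subs = [SubstrateSpec("S_EX", [("10", 0.7, 1.0), ("00", 0.3, 1.0)],
                          natural_abundance=0.0)]
    return model, subs, [EMU("M2", (1,)), EMU("M2", (1, 2)), EMU("M1", (1,))]


TOY_BUILDERS = {
    "chain": toy_chain,
    "split": toy_split,
    "symmetric_cycle": toy_symmetric_cycle,
    "reversible": toy_reversible,
}


# ---------------------------------------------------------------------------
# synthetic data generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    true_v: np.ndarray
    substrates: list[SubstrateSpec]
    noise_sd: float
    seed: int | None
    measurements: list[MeasuredFragment]


def generate(model: MetabolicModel,
             substrates: list[SubstrateSpec],
             corrections: list[CorrectionSpec],
             fragments: list[tuple[str, str, tuple[int, ...]]],
             true_v: np.ndarray,
             noise_sd: float = 0.0,
             seed: int | None = None,
             default_sd: float = 0.01,
             out_path=None) -> SyntheticDataset:
    """Simulate, correct, truncate and perturb MIDs at a known flux vector.

    ``true_v`` is the full input-order mass-balance flux vector.  Gaussian
    noise of standard deviation ``noise_sd`` is added per entry (clipped at
    zero); the emitted SD column equals ``noise_sd`` when positive, else
    ``default_sd``.  At zero noise the emitted MIDs equal the corrected
    simulated MIDs exactly.  With ``out_path`` the measurements are also
    written in the measurement-file dialect.
    """
    true_v = np.asarray(true_v, float)
    S = network_math.build_stoichiometric_matrix(model)
    if np.abs(S @ true_v).max() > 1e-6:
        raise model_io.ModelError("true fluxes violate the mass balance")
    if (true_v < -1e-9).any():
        raise model_io.ModelError("true fluxes must be nonnegative")

    by_id = {c.fragment_id: c for c in corrections}
    emus = [EMU(met, pos) for _, met, pos in fragments]
    decomp = emu_engine.decompose(model, emus)
    mids = emu_engine.simulate(decomp, true_v, substrates)

    rng = np.random.default_rng(seed)
    sd_value = noise_sd if noise_sd > 0 else default_sd
    out = []
    for (frag, met, pos), emu in zip(fragments, emus):
        vec = _correction.apply_correction(mids[emu], by_id[frag])
        if noise_sd > 0:
            vec = np.clip(vec + rng.normal(0.0, noise_sd, size=vec.shape), 0.0, None)
        out.append(MeasuredFragment(frag, met, tuple(pos), vec,
                                    np.full(vec.shape, sd_value)))
    if out_path is not None:
        model_io.write_measurements(out, out_path)
    return SyntheticDataset(true_v=true_v, substrates=substrates,
                            noise_sd=noise_sd, seed=seed, measurements=out)
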