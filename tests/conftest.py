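import numpy as np
import pytest

import emuflux as ef
from emuflux import estimation
from emuflux import fixtures as fx

TCA_PREFERENCES = ["V02", "V09"]


@pytest.fixture(scope="session")
def tca():
    """(model, substrates, corrections) of the bundled TCA fixture."""
    return (fx.builtin_tca_model(), fx.builtin_tca_substrates(),
            fx.builtin_tca_corrections())


@pytest.fixture(scope="session")
def tca_truth(tca):
    """Null basis (with informative free-flux preferences) and the exactly
    balanced reference flux vector of the TCA fixture."""
    model, _, _ = tca
    nb = ef.null_basis_for_model(model, preferences=TCA_PREFERENCES)
    return nb, fx.tca_reference_fluxes(model, nb)


@pytest.fixture(scope="session")
def tca_noiseless_problem(tca, tca_truth):
    """Fit problem built from a zero-noise synthetic TCA dataset."""
    model, subs, corr = tca
    nb, v_true = tca_truth
    ds = fx.generate(model, subs, corr, fx.tca_fragments(), v_true,
                     noise_sd=0.0, seed=0)
    problem = estimation.build_problem(model, subs, corr, ds.measurements,
                                       preferences=TCA_PREFERENCES)
    return problem, v_true


@pytest.fixture(scope="session")
def split_fit():
    """Converged fit of a zero-noise dataset on the branch-split toy.

    Truth: split flux R3 = 0.3 of a unit basis.
    """
    model, subs, _ = fx.toy_split()
    nb = ef.null_basis_for_model(model)
    v_free = np.array([0.3 if rid == "R3" else 1.0
                       for rid in nb.free_reaction_ids])
    v_true = nb.fluxes_from_free(v_free)
    corr = ef.parse_corrections(
        "fragment,element,abundances,count,n_measured\nFB,,,0,3\n")
    ds = fx.generate(model, subs, corr, [("FB", "B", (1, 2))], v_true,
                     noise_sd=0.0, seed=0)
    problem = estimation.build_problem(model, subs, corr, ds.measurements)
    result = estimation.fit(problem, n_starts=4, seed=11)
    return problem, result, v_true
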