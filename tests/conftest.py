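import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mini_helix(tmp_path_factory):
    """Ideal-geometry helical mini-protein written to disk once per session."""
    from loopmc.fixtures import make_mini_protein

    path = tmp_path_factory.mktemp("pdb") / "mini_helix.pdb"
    model, state, spec = make_mini_protein(path, n_residues=12, loop_start=4,
                                           loop_end=9, kind="helix", seed=0)
    return {"path": path, "model": model, "state": state, "spec": spec}


@pytest.fixture(scope="session")
def helix_system(mini_helix):
    """The mini-helix loaded back through the PDB reader."""
    from loopmc.backbone import load_state_from_pdb

    system, state = load_state_from_pdb(mini_helix["path"], mini_helix["spec"])
    return {"system": system, "state": state}


@pytest.fixture(scope="session")
def toy_priors():
    from loopmc.fixtures import make_toy_priors

    grid, lib = make_toy_priors(seed=0)
    return {"grid": grid, "rotamers": lib}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
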