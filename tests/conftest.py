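import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from crystalgp import synthetic as syn


@pytest.fixture(scope="session")
def helix_structure():
    """12-residue helix-like toy structure with a mix of residue classes."""
    from crystalgp.pdb import parse_structure

    layout = syn.helix_layout("GKEALVSTNDFY")
    return parse_structure(syn.generate_toy_structure(layout))


@pytest.fixture(scope="session")
def small_screen():
    """A small synthetic screen shared by the slower integration tests."""
    spec = syn.SyntheticScreenSpec(n_proteins=60, n_cocktails=250, seed=11)
    proteins, cocktails_tab, outcomes, truth = syn.generate_screen(spec)
    return proteins, cocktails_tab, outcomes, truth


@pytest.fixture(scope="session")
def recovery_fit():
    """One ARD recovery problem and its fitted GPR model (reused across tests)."""
    from crystalgp import gpr

    X, y, relevant = syn.generate_ard_recovery_problem(n=150, d=20, n_relevant=5, seed=1)
    model = gpr.train_restarts(X, y, n_restarts=30, seed=1)
    return X, y, relevant, model
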