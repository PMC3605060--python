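import numpy as np
import pytest

from knotfold.chain_core import Conformation
from knotfold.cg_forcefield import ForceFieldParams, build_forcefield
from knotfold.contact_maps import ContactMapParams, build_native_structure
from knotfold.knot_topology import ClosureSpec
from knotfold.synthetic_data import ToyNativeSpec, build_toy_native


@pytest.fixture(scope="session")
def toy_native():
    """Default 48-bead shallow-trefoil native (topology-verified at build)."""
    return build_toy_native(ToyNativeSpec())


@pytest.fixture(scope="session")
def rich_native(toy_native):
    """Same toy reference with a denser contact set (cutoff 9.5 A)."""
    return build_native_structure(
        toy_native.reference, params=ContactMapParams(cutoff=9.5),
        annotated_regions=toy_native.annotated_regions)


@pytest.fixture(scope="session")
def soft_ff_params():
    """Force-field constants used by the dynamic (campaign-scale) tests."""
    return ForceFieldParams(k_bond=50.0, k_angle=10.0, native_eps=2.0,
                            ev_cap=15.0)


@pytest.fixture(scope="session")
def toy_ff(rich_native, soft_ff_params):
    return build_forcefield(rich_native, params=soft_ff_params)


@pytest.fixture(scope="session")
def fast_closure():
    return ClosureSpec(n_closures=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def square_conformation():
    return Conformation(np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0],
                                  [3.8, 3.8, 0.0], [0.0, 3.8, 0.0]]))
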