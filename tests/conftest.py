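import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def harmonic_bead_system():
    """12 independent beads in a harmonic restraint well (E = k d², k = 10)."""
    from glycodyn.system import BeadSystem, RestraintSet

    n = 12
    system = BeadSystem(
        labels=[f"p{i}" for i in range(n)],
        masses=np.full(n, 100.0),
        positions=np.zeros((n, 3)),
    ).finalize()
    restraints = RestraintSet(indices=np.arange(n), r0=np.zeros((n, 3)), k=10.0)
    return system, restraints


@pytest.fixture(scope="session")
def toy_complexes():
    """Minimized nonfucosylated and fucosylated toy complexes."""
    from glycodyn.system import minimize
    from glycodyn.toy import ToyComplexSpec, build_toy_complex

    out = {}
    for fuc in (False, True):
        toy = build_toy_complex(ToyComplexSpec(fc_fucosylated=fuc))
        coords, _ = minimize(toy.system, toy.restraints, toy.system.positions, max_steps=300)
        out[fuc] = (toy, coords)
    return out


@pytest.fixture(scope="session")
def glycan_fixture_pdb(tmp_path_factory):
    """Fucosylated decasaccharide fixture attached at an Asn sequon."""
    from glycodyn.synth import fixture_glycan_model, gen_fixture_pdb

    path = tmp_path_factory.mktemp("pdb") / "glycan.pdb"
    model = gen_fixture_pdb(fixture_glycan_model(fucosylated=True), path)
    return path, model
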