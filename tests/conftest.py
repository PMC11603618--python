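import numpy as np
import pytest

from crystalfit.crystal import (
    Crystal,
    CrystalSystem,
    Lattice,
    RigidMolecule,
    SymmetryOp,
)
from crystalfit.latmin import LMOptions
from crystalfit.synthetic import (
    ToySpec,
    default_true_potentials,
    generate_reference_set,
)


@pytest.fixture(scope="session")
def lm_opts():
    return LMOptions(cutoff=10.0)


@pytest.fixture(scope="session")
def fit_pots():
    """FIT-magnitude explicit Buckingham set for two types, A and C free."""
    return default_true_potentials()


@pytest.fixture(scope="session")
def bent_p1():
    """A packed (unrelaxed) bent-triatomic P1 toy crystal."""
    from crystalfit.synthetic import make_toy_crystal

    return make_toy_crystal(ToySpec(template="bent3", space_group="P1"), seed=5)


@pytest.fixture(scope="session")
def refset2(fit_pots, lm_opts):
    """Two relaxed reference structures generated at the true parameters."""
    specs = [
        ToySpec(template="bent3", space_group="P1"),
        ToySpec(template="quad4", space_group="P1"),
    ]
    return generate_reference_set(specs, fit_pots, seed=11, lm_opts=lm_opts)


def random_lattice(rng) -> Lattice:
    """A random valid triclinic lattice."""
    while True:
        a, b, c = rng.uniform(4.0, 12.0, size=3)
        al, be, ga = rng.uniform(70.0, 110.0, size=3)
        try:
            lat = Lattice(a, b, c, al, be, ga, CrystalSystem.TRICLINIC)
        except Exception:
            continue
        if lat.volume > 10.0:
            return lat


def toy_dimer_crystal(charged=True, system=CrystalSystem.TRICLINIC):
    """Two bent molecules in a P1 cell; handy for derivative checks."""
    if system is CrystalSystem.TRICLINIC:
        lat = Lattice(6.0, 6.5, 7.0, 85.0, 95.0, 92.0, system)
    else:
        lat = Lattice(6.0, 6.0, 7.0, 90.0, 100.0, 90.0, system)
    raw = np.array([[0.9, 0.0, 0.0], [-0.9, 0.0, 0.0], [0.0, 0.7, 0.0]])
    local = raw - raw.mean(axis=0)
    q = [0.2, 0.2, -0.4] if charged else [0.0, 0.0, 0.0]
    m1 = RigidMolecule.create(
        ["C", "C", "O"], ["T1", "T1", "T2"], local, q, [0.1, 0.2, 0.3],
        quaternion=[0.9, 0.1, 0.3, 0.2],
    )
    m2 = RigidMolecule.create(
        ["C", "C", "O"], ["T1", "T1", "T2"], local, q, [0.6, 0.7, 0.8],
        quaternion=[0.8, -0.2, 0.1, 0.4],
    )
    return Crystal.create(lat, [SymmetryOp.identity()], [m1, m2], "dimer")
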