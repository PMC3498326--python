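import numpy as np
import pytest

from contactprefs import fragments as fr
from contactprefs import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cutoffs():
    return fr.DistanceCutoffs(hbond=3.3, dispersion=4.0, halogen=3.6)


@pytest.fixture
def one_comp_spec():
    """A single hydrogen-bond-like contact cluster with known parameters."""
    return sd.CloudSpec(
        components=[
            sd.ComponentSpec(
                weight=1.0, mu_theta=0.6, kappa=12.0, mu_r=2.9, var_r=0.04,
                azimuthal=[sd.AzimuthalSpec(1.0, 3.0, 0.3)],
            )
        ],
        r_max=4.0, n=2000, seed=5,
    )


@pytest.fixture
def two_comp_spec():
    """Two well-separated polar clusters (e.g. in-plane and below-plane)."""
    return sd.CloudSpec(
        components=[
            sd.ComponentSpec(
                weight=0.6, mu_theta=0.5, kappa=12.0, mu_r=2.9, var_r=0.04,
                theta_lo=0.0, theta_hi=1.5,
                azimuthal=[sd.AzimuthalSpec(1.0, 2.0, 0.2)],
            ),
            sd.ComponentSpec(
                weight=0.4, mu_theta=2.5, kappa=12.0, mu_r=3.3, var_r=0.04,
                theta_lo=1.5, theta_hi=np.pi,
                azimuthal=[sd.AzimuthalSpec(1.0, 4.0, 0.2)],
            ),
        ],
        r_max=4.5, n=2000, seed=6,
    )


@pytest.fixture
def one_comp_cloud(one_comp_spec):
    return sd.gen_cloud(one_comp_spec)


def make_ligand(atoms):
    """Build a StructureModel from (element, name, xyz) HETATM triples."""
    return fr.StructureModel(
        atoms=[
            fr.Atom(i + 1, name, el, "LIG", 900, "B", np.array(pos, dtype=float), True)
            for i, (el, name, pos) in enumerate(atoms)
        ],
        resolution=2.0,
        source_id="synthetic",
    )


@pytest.fixture
def benzene():
    ring = np.linspace(0, 2 * np.pi, 7)[:-1]
    return make_ligand(
        [("C", f"C{i+1}", (1.39 * np.cos(a), 1.39 * np.sin(a), 0.0))
         for i, a in enumerate(ring)]
    )


@pytest.fixture
def phenol():
    ring = np.linspace(0, 2 * np.pi, 7)[:-1]
    atoms = [("C", f"C{i+1}", (1.39 * np.cos(a), 1.39 * np.sin(a), 0.0))
             for i, a in enumerate(ring)]
    atoms.append(("O", "O1", (2.75, 0.0, 0.0)))
    return make_ligand(atoms)


@pytest.fixture
def acetamide():
    return make_ligand(
        [("C", "C1", (0.0, 0.0, 0.0)), ("C", "C2", (1.51, 0.0, 0.0)),
         ("O", "O1", (2.13, 1.06, 0.0)), ("N", "N1", (2.2, -1.15, 0.0))]
    )
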