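"""Shared fixtures: bundled synthetic systems sized so the whole suite
runs comfortably on one CPU."""

import numpy as np
import pytest

from trps import (ChainSystem, ContinuousSystem, CutPlanes, EngineConfig,
                  TSRegion, make_double_well)


@pytest.fixture(scope="session")
def double_well():
    """Symmetric quartic double well: minima at ±1, barrier 5 kBT."""
    return make_double_well(barrier=5.0, x_min_sep=2.0)


@pytest.fixture(scope="session")
def dw_system(double_well):
    return ContinuousSystem(double_well)


@pytest.fixture(scope="session")
def dw_config():
    return EngineConfig(dt=1e-3, temperature=1.0, friction=1.0, mass=1.0,
                        seed=0)


@pytest.fixture(scope="session")
def dw_planes():
    return CutPlanes(qa=-1.0, qb=1.0)


@pytest.fixture(scope="session")
def dw_ts():
    return TSRegion(-0.2, 0.2)


@pytest.fixture(scope="session")
def chain30(double_well):
    """30-state discretisation of the double well (barrier ~5 kBT)."""
    xs = np.linspace(-1.5, 1.5, 30)
    return ChainSystem(double_well.energy(xs))


@pytest.fixture(scope="session")
def chain30_planes(chain30):
    E = chain30.energies
    sa = int(np.argmin(E[:15]))
    sb = 15 + int(np.argmin(E[15:]))
    return CutPlanes(qa=sa, qb=sb)


@pytest.fixture(scope="session")
def chain30_ts():
    return TSRegion(14, 15)


@pytest.fixture(scope="session")
def chain_config():
    """Chain engines advance one state per step: dt = 1."""
    return EngineConfig(dt=1.0, temperature=1.0, seed=0)


@pytest.fixture(scope="session")
def synthetic_pdb_text():
    """Synthetic 5-residue horseshoe with exactly one engineered contact
    between residues 1 and 5 (CB atoms 4.0 Å apart; all other pairs at
    sequence separation >= 4 are far)."""
    atoms = [
        # resseq, name, x, y, z
        (1, "CA", 0.0, 0.0, 0.0), (1, "CB", 0.0, 1.3, 0.5),
        (2, "CA", 3.8, 0.0, 0.0), (2, "CB", 4.6, -1.0, 0.3),
        (3, "CA", 5.7, 3.3, 0.0), (3, "CB", 7.0, 3.9, 0.4),
        (4, "CA", 3.8, 6.6, 0.0), (4, "CB", 4.6, 7.7, 0.3),
        (5, "CA", 0.0, 6.6, 0.0), (5, "CB", 0.0, 5.3, 0.5),
    ]
    lines = []
    for serial, (resseq, name, x, y, z) in enumerate(atoms, start=1):
        lines.append(
            f"ATOM  {serial:5d}  {name:<3s}ALA A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def go_fixture_topology():
    """8-bead curved chain with three native contacts, used for the
    energetic/force tests (synthetic stand-in for a real fold)."""
    from trps.go_model import GoTopology

    t = np.arange(8)
    coords = np.c_[np.cos(t * 0.6) * 3.2, np.sin(t * 0.6) * 3.2, t * 1.8]
    contacts = [(0, 5), (1, 6), (0, 7)]
    r0 = [float(np.linalg.norm(coords[i] - coords[j])) for i, j in contacts]
    return GoTopology(native_coords=coords, contacts=contacts, contact_r0=r0)
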