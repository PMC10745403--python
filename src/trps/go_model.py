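"""Coarse-grained Cα structure-based (Gō-type) protein model.

Each residue is one bead at its Cα position.  Only contacts present in
the native structure attract, which biases the energy landscape toward
the experimental fold; the native-contact count Q is the reaction
coordinate for folding kinetics.  The functional form is the standard
Clementi-Onuchic parameterization:

* harmonic bonds       Kb (r - r0)^2,          Kb = 100 eps/A^2
* harmonic angles      Ka (theta - theta0)^2,  Ka = 20 eps/rad^2
* dihedrals            Kd1 [1 - cos(phi-phi0)] + Kd3 [1 - cos 3(phi-phi0)]
* native contacts      eps [5 (r0/r)^12 - 6 (r0/r)^10]
* non-native repulsion eps (sigma/r)^12,       sigma = 4 A

Reduced units: eps = 1, kB = 1, so temperatures read directly in eps/kB.
All constants are overridable on the topology.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from .dynamics import EngineConfig


class StructureError(ValueError):
    """The PDB structure cannot supply the needed atoms."""


class CutoffError(ValueError):
    """The contact cutoff produced no native contacts."""


class GeometryError(RuntimeError):
    """Non-finite energy/forces."""


@dataclass
class GoTopology:
    """Native topology: bead coordinates, bonded reference values, and
    the native contact map with its Cα distances (Å)."""

    native_coords: np.ndarray           # (n, 3)
    contacts: np.ndarray                # (m, 2) residue index pairs, i<j
    contact_r0: np.ndarray              # (m,) native Cα-Cα distances
    bond_r0: np.ndarray = field(default=None)
    angle_t0: np.ndarray = field(default=None)
    dihedral_p0: np.ndarray = field(default=None)
    epsilon: float = 1.0
    k_bond: float = 100.0
    k_angle: float = 20.0
    k_dihedral_1: float = 1.0
    k_dihedral_3: float = 0.5
    sigma_rep: float = 4.0
    nonnative_min_sep: int = 4

    def __post_init__(self):
        self.native_coords = np.asarray(self.native_coords, dtype=float)
        self.contacts = np.asarray(self.contacts, dtype=int).reshape(-1, 2)
        self.contact_r0 = np.asarray(self.contact_r0, dtype=float)
        x = self.native_coords
        if self.bond_r0 is None:
            self.bond_r0 = np.linalg.norm(np.diff(x, axis=0), axis=1)
        if self.angle_t0 is None:
            self.angle_t0 = _angles(x)
        if self.dihedral_p0 is None:
            self.dihedral_p0 = _dihedrals(x)
        n = self.n_residues
        # non-native repulsive pairs: |i-j| >= nonnative_min_sep, not a contact
        cset = {tuple(c) for c in self.contacts}
        pairs = [(i, j) for i in range(n)
                 for j in range(i + self.nonnative_min_sep, n)
                 if (i, j) not in cset]
        self._rep_pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)

    @property
    def n_residues(self) -> int:
        return self.native_coords.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.contacts.shape[0]

    def to_json(self, path) -> None:
        data = {
            "native_coords": self.native_coords.tolist(),
            "contacts": self.contacts.tolist(),
            "contact_r0": self.contact_r0.tolist(),
            "epsilon": self.epsilon, "k_bond": self.k_bond,
            "k_angle": self.k_angle, "k_dihedral_1": self.k_dihedral_1,
            "k_dihedral_3": self.k_dihedral_3, "sigma_rep": self.sigma_rep,
            "nonnative_min_sep": self.nonnative_min_sep,
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path) -> "GoTopology":
        with open(path) as fh:
            data = json.load(fh)
        return cls(native_coords=np.array(data["native_coords"]),
                   contacts=np.array(data["contacts"]),
                   contact_r0=np.array(data["contact_r0"]),
                   epsilon=data["epsilon"], k_bond=data["k_bond"],
                   k_angle=data["k_angle"],
                   k_dihedral_1=data["k_dihedral_1"],
                   k_dihedral_3=data["k_dihedral_3"],
                   sigma_rep=data["sigma_rep"],
                   nonnative_min_sep=data["nonnative_min_sep"])


def _angles(x: np.ndarray) -> np.ndarray:
    u = x[:-2] - x[1:-1]
    v = x[2:] - x[1:-1]
    c = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.arccos(np.clip(c, -1.0, 1.0))


def _dihedrals(x: np.ndarray) -> np.ndarray:
    b1 = x[1:-2] - x[:-3]
    b2 = x[2:-1] - x[1:-2]
    b3 = x[3:] - x[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    y = np.einsum("ij,ij->i", m, n2)
    c = np.einsum("ij,ij->i", n1, n2)
    return np.arctan2(y, c)


def build_from_pdb(pdb_text: str, contact_cutoff: float = 4.5,
                   chain_id: str | None = None, min_seq_sep: int = 4,
                   epsilon: float = 1.0) -> GoTopology:
    """Build the topology from PDB-format text.

    Uses the first model; native contacts are residue pairs at sequence
    separation >= ``min_seq_sep`` with any heavy-atom pair within
    ``contact_cutoff`` Å.  The contact potential acts on the native
    Cα-Cα distance of each pair.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", io.StringIO(pdb_text))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise StructureError(f"chain {chain_id!r} not found")
    chain = chains[0]
    residues = [r for r in chain.get_residues() if r.id[0] == " "]
    if not residues:
        raise StructureError("no standard residues in the selected chain")
    missing = [r.get_resname() + str(r.id[1]) for r in residues
               if "CA" not in r]
    if missing:
        raise StructureError(f"residues without CA atoms: {missing}")
    ca = np.array([r["CA"].get_coord() for r in residues], dtype=float)
    heavy = [np.array([a.get_coord() for a in r.get_atoms()
                       if a.element != "H"], dtype=float) for r in residues]
    n = len(residues)
    contacts = []
    r0 = []
    for i in range(n):
        for j in range(i + min_seq_sep, n):
            d = np.linalg.norm(heavy[i][:, None, :] - heavy[j][None, :, :],
                               axis=2)
            if d.min() < contact_cutoff:
                contacts.append((i, j))
                r0.append(np.linalg.norm(ca[i] - ca[j]))
    if not contacts:
        raise CutoffError(
            f"no native contacts at cutoff {contact_cutoff} Å")
    return GoTopology(native_coords=ca, contacts=np.array(contacts),
                      contact_r0=np.array(r0), epsilon=epsilon)


def energy_forces(top: GoTopology, coords: np.ndarray,
                  ) -> tuple[float, np.ndarray]:
    """Total energy (units of eps) and forces = -dE/dx (eps/Å)."""
    x = np.asarray(coords, dtype=float).reshape(-1, 3)
    if x.shape[0] != top.n_residues:
        raise GeometryError("coordinate count does not match topology")
    f = np.zeros_like(x)
    e = 0.0

    # bonds
    d = x[1:] - x[:-1]
    r = np.linalg.norm(d, axis=1)
    dr = r - top.bond_r0
    e += top.k_bond * np.sum(dr**2)
    g = (2.0 * top.k_bond * dr / r)[:, None] * d   # dE/dx_{i+1}
    np.add.at(f, np.arange(1, top.n_residues), -g)
    np.add.at(f, np.arange(0, top.n_residues - 1), g)

    # angles
    if top.n_residues >= 3:
        u = x[:-2] - x[1:-1]
        v = x[2:] - x[1:-1]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        s = np.sqrt(np.maximum(1.0 - c**2, 1e-12))
        theta = np.arccos(c)
        dtheta = theta - top.angle_t0
        e += top.k_angle * np.sum(dtheta**2)
        dE = 2.0 * top.k_angle * dtheta
        g1 = (c[:, None] * uh - vh) / (nu * s)[:, None]   # dtheta/dr1
        g3 = (c[:, None] * vh - uh) / (nv * s)[:, None]   # dtheta/dr3
        np.add.at(f, np.arange(0, top.n_residues - 2), -dE[:, None] * g1)
        np.add.at(f, np.arange(2, top.n_residues), -dE[:, None] * g3)
        np.add.at(f, np.arange(1, top.n_residues - 1),
                  dE[:, None] * (g1 + g3))

    # dihedrals
    if top.n_residues >= 4:
        b1 = x[1:-2] - x[:-3]
        b2 = x[2:-1] - x[1:-2]
        b3 = x[3:] - x[2:-1]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m = np.cross(n1, b2 / nb2[:, None])
        phi = np.arctan2(np.einsum("ij,ij->i", m, n2),
                         np.einsum("ij,ij->i", n1, n2))
        dphi = phi - top.dihedral_p0
        e += np.sum(top.k_dihedral_1 * (1.0 - np.cos(dphi))
                    + top.k_dihedral_3 * (1.0 - np.cos(3.0 * dphi)))
        dE = (top.k_dihedral_1 * np.sin(dphi)
              + 3.0 * top.k_dihedral_3 * np.sin(3.0 * dphi))
        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        gp1 = (nb2 / n1sq)[:, None] * n1                  # dphi/dr1
        gp4 = -(nb2 / n2sq)[:, None] * n2                 # dphi/dr4
        t = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
        s2 = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
        gp2 = -(1.0 + t) * gp1 + s2 * gp4
        gp3 = t * gp1 - (1.0 + s2) * gp4
        idx = np.arange(top.n_residues - 3)
        np.add.at(f, idx, -dE[:, None] * gp1)
        np.add.at(f, idx + 1, -dE[:, None] * gp2)
        np.add.at(f, idx + 2, -dE[:, None] * gp3)
        np.add.at(f, idx + 3, -dE[:, None] * gp4)

    # native contacts: eps [5 (r0/r)^12 - 6 (r0/r)^10]
    if top.n_contacts:
        i, j = top.contacts[:, 0], top.contacts[:, 1]
        d = x[j] - x[i]
        r = np.linalg.norm(d, axis=1)
        rr = top.contact_r0 / r
        e += top.epsilon * np.sum(5.0 * rr**12 - 6.0 * rr**10)
        # dE/dr = eps (-60 r0^12/r^13 + 60 r0^10/r^11)
        dEdr = top.epsilon * 60.0 * (rr**10 - rr**12) / r
        g = (dEdr / r)[:, None] * d
        np.add.at(f, j, -g)
        np.add.at(f, i, g)

    # non-native repulsion
    if top._rep_pairs.size:
        i, j = top._rep_pairs[:, 0], top._rep_pairs[:, 1]
        d = x[j] - x[i]
        r = np.linalg.norm(d, axis=1)
        sr = top.sigma_rep / r
        e += top.epsilon * np.sum(sr**12)
        dEdr = -12.0 * top.epsilon * sr**12 / r
        g = (dEdr / r)[:, None] * d
        np.add.at(f, j, -g)
        np.add.at(f, i, g)

    if not (np.isfinite(e) and np.all(np.isfinite(f))):
        raise GeometryError("non-finite energy or forces")
    return float(e), f


def contact_energy(top: GoTopology, coords: np.ndarray) -> float:
    """The native-contact term alone (equals -eps * n_contacts natively)."""
    x = np.asarray(coords, dtype=float).reshape(-1, 3)
    i, j = top.contacts[:, 0], top.contacts[:, 1]
    r = np.linalg.norm(x[j] - x[i], axis=1)
    rr = top.contact_r0 / r
    return float(top.epsilon * np.sum(5.0 * rr**12 - 6.0 * rr**10))


def count_Q(top: GoTopology, coords: np.ndarray,
            tol_factor: float = 1.2) -> int:
    """Number of native contacts currently formed: pairs whose Cα distance
    is below tol_factor times the native distance."""
    x = np.asarray(coords, dtype=float).reshape(-1, 3)
    i, j = top.contacts[:, 0], top.contacts[:, 1]
    r = np.linalg.norm(x[j] - x[i], axis=1)
    return int(np.count_nonzero(r < tol_factor * top.contact_r0))


def run_underdamped_cartesian(top: GoTopology, coords0: np.ndarray,
                              n_steps: int, config: EngineConfig,
                              seed: int, stride: int = 1,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """BAOAB Langevin dynamics on the bead coordinates.

    Returns (coordinate snapshots every ``stride`` steps, Q per snapshot).
    Small systems only — this is a plain numpy loop.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(coords0, dtype=float).copy()
    m = config.mass
    v = rng.normal(0.0, np.sqrt(config.temperature / m), size=x.shape)
    dt = config.dt
    c1 = np.exp(-config.friction * dt)
    c2 = np.sqrt(config.temperature / m * (1.0 - c1 * c1))
    _, f = energy_forces(top, x)
    snaps = []
    qs = []
    for step in range(n_steps):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        _, f = energy_forces(top, x)
        v += 0.5 * dt * f / m
        if (step + 1) % stride == 0:
            snaps.append(x.copy())
            qs.append(count_Q(top, x))
    return np.array(snaps), np.array(qs)
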