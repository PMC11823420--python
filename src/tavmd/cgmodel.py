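"""Toy coarse-grained C-alpha bead chain.

A polypeptide is reduced to the trace of its C-alpha atoms: an ordered set of
beads linked by virtual bonds of equilibrium length ``b0`` (3.8 A for a trans
peptide bond).  The backbone geometry is described by virtual-bond angles
theta (vertex at bead i) and virtual-bond dihedral angles gamma (axis through
beads i and i+1), the standard internal coordinates of C-alpha-trace models.

The bead force field here is a declared stand-in for a real coarse-grained
protein potential: harmonic virtual bonds, harmonic virtual-bond angles, a
cosine torsion series with a chiral sine term, and a purely repulsive
excluded-volume potential.  It exists so that the restraint and
time-averaging machinery can be exercised on realistic chain dynamics; it
makes no claim to protein energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import toy_energy_forces_kernel

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 0.001987204259

#: Natural time unit of the (amu, A, kcal/mol) unit system, in femtoseconds:
#: sqrt(1 amu * 1 A^2 / (1 kcal/mol)).  Velocities are A per this unit.
TIME_UNIT_FS = 48.8884


class ChainSizeError(ValueError):
    """Chain too short for the requested operation."""


class GenerationError(RuntimeError):
    """Random-chain build-up exhausted its retry budget."""


@dataclass
class ChainTopology:
    """Residue-level topology of a C-alpha trace."""

    n_beads: int
    labels: list[str] = field(default_factory=list)
    b0: float = 3.8
    mass: float = 110.0

    def __post_init__(self):
        if self.n_beads < 2:
            raise ChainSizeError("a chain needs at least 2 beads")
        if self.b0 <= 0 or self.mass <= 0:
            raise ValueError("b0 and mass must be positive")
        if not self.labels:
            self.labels = ["ALA"] * self.n_beads
        if len(self.labels) != self.n_beads:
            raise ValueError("labels length must equal n_beads")

    @property
    def masses(self) -> np.ndarray:
        return np.full(self.n_beads, self.mass)


@dataclass
class Conformation:
    """Ordered 3-D bead coordinates of one chain conformation (Angstrom)."""

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_beads, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy())


@dataclass
class InternalCoords:
    """Virtual-bond angles and dihedrals of a conformation, in degrees.

    ``theta[k]`` is the angle with vertex at bead k+2 (1-based residue k+2);
    ``gamma[k]`` is the signed dihedral about the bond between beads k+2 and
    k+3 (1-based), wrapped to (-180, 180].  Dihedrals whose defining triples
    are collinear are degenerate: ``gamma`` holds NaN there and
    ``gamma_ok`` is False.
    """

    theta: np.ndarray
    gamma: np.ndarray
    gamma_ok: np.ndarray


@dataclass
class ToyForceField:
    """Stand-in bead force field (kcal/mol, Angstrom, degrees).

    Constants are chosen for stability at the production time step of
    4.89 fs (bond omega*dt ~ 0.1) rather than to mimic any real protein
    potential.  ``c1s`` is the chiral torsion coefficient: distance
    information alone cannot distinguish a fold from its mirror image, so the
    backbone torsion term is given a handedness, as in real protein models.
    """

    k_bond: float = 25.0
    b0: float = 3.8
    theta0: float = 105.0
    k_theta: float = 0.01
    c1: float = 0.2
    c3: float = 0.3
    c1s: float = 0.3
    eps_ev: float = 0.5
    sigma_ev: float = 4.5
    ev_min_sep: int = 3

    def __post_init__(self):
        if self.eps_ev < 0 or self.sigma_ev <= 0:
            raise ValueError("eps_ev must be >= 0 and sigma_ev > 0")
        for v in (self.k_bond, self.b0, self.theta0, self.k_theta,
                  self.c1, self.c3, self.c1s):
            if not np.isfinite(v):
                raise ValueError("force-field constants must be finite")


def wrap_angle(a):
    """Wrap an angle in degrees to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return w if w.ndim else float(w)


def internal_coords(conf: Conformation) -> InternalCoords:
    """theta/gamma internal coordinates of a conformation.

    Requires at least 4 beads (the shortest chain with a dihedral).
    """
    c = conf.coords
    n = conf.n_beads
    if n < 4:
        raise ChainSizeError("internal coordinates need at least 4 beads")
    b = c[1:] - c[:-1]                      # (n-1, 3) virtual bonds
    nb = np.linalg.norm(b, axis=1)
    if np.any(nb < 1e-10):
        raise ValueError("coincident consecutive beads")
    u = -b[:-1]                             # bead j-1 relative to vertex j
    v = b[1:]
    ct = np.einsum("ij,ij->i", u, v) / (nb[:-1] * nb[1:])
    theta = np.degrees(np.arccos(np.clip(ct, -1.0, 1.0)))

    b1, b2, b3 = b[:-2], b[1:-1], b[2:]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.einsum("ij,ij->i", n1, n2)
    y = nb[1:-1] * np.einsum("ij,ij->i", b1, n2)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    ok = (n1sq > 1e-14) & (n2sq > 1e-14)
    gamma = np.degrees(np.arctan2(y, x))
    gamma = wrap_angle(np.where(ok, gamma, np.nan))
    return InternalCoords(theta=theta, gamma=gamma, gamma_ok=ok)


def toy_energy_forces(conf: Conformation, ff: ToyForceField):
    """Toy-field energy (kcal/mol) and forces (kcal/mol/A) of a conformation.

    Forces are the exact negative gradient of the energy.
    """
    c = conf.coords
    if c.shape[0] >= 2:
        bl = np.linalg.norm(c[1:] - c[:-1], axis=1)
        if np.any(bl < 1e-8):
            raise ValueError("coincident bonded beads: angle geometry undefined")
    eb, ea, ed, ev, forces = toy_energy_forces_kernel(
        c, ff.k_bond, ff.b0, ff.k_theta, ff.theta0,
        ff.c1, ff.c3, ff.c1s, ff.eps_ev, ff.sigma_ev, ff.ev_min_sep)
    return eb + ea + ed + ev, forces


def place_next_bead(r_prev3, b0, theta_deg, gamma_deg) -> np.ndarray:
    """Append a bead at bond length b0, angle theta and dihedral gamma.

    ``r_prev3`` holds the last three bead positions (oldest first); the new
    bead closes the dihedral r1-r2-r3-r4 = gamma with angle theta at r3.
    """
    r1, r2, r3 = r_prev3
    th = np.radians(theta_deg)
    ga = np.radians(gamma_deg)
    bc = r3 - r2
    bc = bc / np.linalg.norm(bc)
    ab = r2 - r1
    nrm = np.cross(ab, bc)
    nn = np.linalg.norm(nrm)
    if nn < 1e-12:
        raise ValueError("collinear support: dihedral frame undefined")
    nrm = nrm / nn
    m = np.cross(nrm, bc)
    d = b0 * (-np.cos(th) * bc + np.sin(th) * (np.cos(ga) * m + np.sin(ga) * nrm))
    return r3 + d


def generate_random_chain(n: int, seed: int, ff: ToyForceField,
                          clash_cutoff: float = 4.0,
                          build_temperature: float = 300.0,
                          max_total_retries: int = 200_000) -> Conformation:
    """Random-chain build-up from the N-terminus.

    Residues are appended one at a time: the torsion gamma is drawn uniformly
    on [-180, 180) deg and the angle theta from the Boltzmann weight of the
    toy angle term at ``build_temperature``, i.e. a normal distribution of
    mean ``theta0`` and standard deviation sqrt(kB*T/k_theta) truncated to
    (0, 180).  A candidate clashing with any earlier bead (sequence
    separation >= 2, distance < ``clash_cutoff``) is retried up to 100 times,
    after which the build-up backtracks one residue.  The same seed yields a
    bitwise-identical chain.
    """
    if n < 2:
        raise ChainSizeError("cannot generate a chain of fewer than 2 beads")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(KB * build_temperature / ff.k_theta)

    def draw_theta():
        while True:
            t = rng.normal(ff.theta0, sd)
            if 0.0 < t < 180.0:
                return t

    coords = np.zeros((n, 3))
    coords[1] = (ff.b0, 0.0, 0.0)
    k = 2  # next bead index to place
    total = 0
    while k < n:
        placed = False
        for _ in range(100):
            total += 1
            if total > max_total_retries:
                raise GenerationError(
                    f"chain generation exhausted {max_total_retries} retries")
            th = draw_theta()
            if k == 2:
                thr = np.radians(th)
                # in-plane placement; global orientation is arbitrary
                cand = coords[1] + ff.b0 * np.array(
                    [-np.cos(thr), np.sin(thr), 0.0])
            else:
                ga = rng.uniform(-180.0, 180.0)
                cand = place_next_bead(coords[k - 3:k], ff.b0, th, ga)
            prior = coords[:k - 1]  # separation >= 2
            if prior.size and np.min(
                    np.linalg.norm(prior - cand, axis=1)) < clash_cutoff:
                continue
            coords[k] = cand
            k += 1
            placed = True
            break
        if not placed:
            k = max(2, k - 1)  # backtrack one residue and retry it
    return Conformation(coords)


# ---------------------------------------------------------------------------
# PDB I/O (C-alpha trace, one MODEL per conformation)

def write_pdb(path, conformations, labels=None) -> None:
    """Write conformations as a multi-model C-alpha-trace PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    confs = ([conformations] if isinstance(conformations, Conformation)
             else list(conformations))
    if not confs:
        raise ValueError("no conformations to write")
    n = confs[0].n_beads
    if labels is None:
        labels = ["ALA"] * n
    arrays = []
    for conf in confs:
        if conf.n_beads != n:
            raise ValueError("all models must have the same bead count")
        atoms = struc.AtomArray(n)
        atoms.coord = np.asarray(conf.coords, dtype=np.float32)
        atoms.chain_id = np.full(n, "A")
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.asarray(labels)
        atoms.atom_name = np.full(n, "CA")
        atoms.element = np.full(n, "C")
        atoms.hetero = np.zeros(n, dtype=bool)
        atoms.set_annotation("occupancy", np.ones(n, dtype=np.float32))
        atoms.set_annotation("b_factor", np.zeros(n, dtype=np.float32))
        arrays.append(atoms)
    stack = struc.stack(arrays)
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


def read_pdb(path) -> list[Conformation]:
    """Read every model of a PDB file as a C-alpha-trace conformation."""
    from biotite.structure.io.pdb import PDBFile

    pdbf = PDBFile.read(str(path))
    stack = pdbf.get_structure(model=None)
    ca = stack[:, stack.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"no CA atoms in {path}")
    return [Conformation(np.asarray(ca.coord[i], dtype=float))
            for i in range(ca.stack_depth())]
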