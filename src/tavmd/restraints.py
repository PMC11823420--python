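"""NMR-style restraints on a C-alpha-bead chain.

Distance restraints use a flat-bottomed well: the penalty is a constant -A
between the lower and upper bounds d_l and d_u, rises along Gaussian walls of
width sigma on both sides, and above the upper bound additionally carries a
linear tail of slope kappa so that a far-violated restraint keeps pulling
with a small constant force.  kappa defaults to 0.01 kcal/(mol A): strong
enough to drive toward the bounds, weak enough not to force mutually
contradictory restraints.  Angle (theta) and dihedral (gamma) restraints use
the same flat-bottom/Gaussian-wall shape without a linear tail; the dihedral
version measures distance to its bound interval on the circle and is
360-degree periodic.

Restrained distances support equivalent-site groups (e.g. the protons of a
methyl group, mapped here to bead groups): the measured quantity is the
equal-weight r^-6 combination over all cross pairs.  Time/ensemble averaging
conventions: distances average with exponent m = 3 (of y^-m, the
NOE-intensity convention), angles with m = -1 (direct averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cgmodel import Conformation, internal_coords, wrap_angle

__all__ = [
    "DistanceRestraint", "AngleRestraint", "DihedralRestraint",
    "RestraintSet", "MeasuredValues",
    "eval_distance_penalty", "eval_theta_penalty", "eval_gamma_penalty",
    "restraint_energy", "measure", "synthesize_restraints",
    "read_restraint_table", "write_restraint_table",
]


@dataclass(frozen=True)
class DistanceRestraint:
    """Flat-bottom distance restraint between two equivalent-site groups."""

    group_i: tuple
    group_j: tuple
    d_l: float
    d_u: float
    A: float = 5.0
    sigma: float = 1.0
    kappa: float = 0.01

    def __post_init__(self):
        gi, gj = tuple(self.group_i), tuple(self.group_j)
        object.__setattr__(self, "group_i", gi)
        object.__setattr__(self, "group_j", gj)
        if not gi or not gj:
            raise ValueError("equivalent-site groups must be non-empty")
        if set(gi) & set(gj):
            raise ValueError(
                f"intra-residue distance restraint rejected: groups "
                f"{gi} and {gj} share a residue")
        if not (0 <= self.d_l <= self.d_u):
            raise ValueError("need 0 <= d_l <= d_u")
        if self.sigma <= 0 or self.A < 0 or self.kappa < 0:
            raise ValueError("need sigma > 0, A >= 0, kappa >= 0")


@dataclass(frozen=True)
class AngleRestraint:
    """Flat-bottom restraint on a virtual-bond angle theta (degrees)."""

    vertex: int
    theta_l: float
    theta_u: float
    A_theta: float = 1.0
    sigma_theta: float = 10.0

    def __post_init__(self):
        if not (0 < self.theta_l <= self.theta_u < 180):
            raise ValueError("need 0 < theta_l <= theta_u < 180")
        if self.A_theta < 0 or self.sigma_theta <= 0:
            raise ValueError("need A_theta >= 0 and sigma_theta > 0")


@dataclass(frozen=True)
class DihedralRestraint:
    """Flat-bottom periodic restraint on a virtual-bond dihedral (degrees).

    The bound interval runs from gamma_l to gamma_u counterclockwise on the
    circle, so gamma_l may numerically exceed gamma_u for intervals crossing
    +-180.
    """

    bond: int
    gamma_l: float
    gamma_u: float
    A_gamma: float = 5.0
    sigma_gamma: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "gamma_l", wrap_angle(self.gamma_l))
        object.__setattr__(self, "gamma_u", wrap_angle(self.gamma_u))
        if self.A_gamma < 0 or self.sigma_gamma <= 0:
            raise ValueError("need A_gamma >= 0 and sigma_gamma > 0")


#: Averaging exponents per restraint kind (y^-m enters the memory integral)
M_DISTANCE = 3
M_ANGLE = -1


@dataclass
class MeasuredValues:
    """Per-restraint instantaneous (or averaged) quantities."""

    dist: np.ndarray    # group-combined distances, A
    theta: np.ndarray   # degrees
    gamma: np.ndarray   # degrees, NaN where degenerate


@dataclass
class RestraintSet:
    distance: list = field(default_factory=list)
    angle: list = field(default_factory=list)
    dihedral: list = field(default_factory=list)
    m_distance: int = M_DISTANCE
    m_angle: int = M_ANGLE

    def __post_init__(self):
        self._compiled = None

    @property
    def n_distance(self):
        return len(self.distance)

    @property
    def n_angle(self):
        return len(self.angle)

    @property
    def n_dihedral(self):
        return len(self.dihedral)

    def validate_for_chain(self, n_beads: int) -> None:
        """Check that every 1-based residue index fits the chain."""
        for r in self.distance:
            for idx in (*r.group_i, *r.group_j):
                if not 1 <= idx <= n_beads:
                    raise IndexError(f"residue {idx} outside chain of "
                                     f"{n_beads} beads")
        for r in self.angle:
            if not 2 <= r.vertex <= n_beads - 1:
                raise IndexError(f"theta vertex {r.vertex} needs interior bead")
        for r in self.dihedral:
            if not 2 <= r.bond <= n_beads - 2:
                raise IndexError(f"gamma bond {r.bond} needs interior bond")

    def compiled(self):
        """Flattened index arrays for vectorized measurement/forces."""
        if self._compiled is None:
            pi, pj, rid = [], [], []
            npairs = np.zeros(self.n_distance)
            for k, r in enumerate(self.distance):
                for a in r.group_i:
                    for b in r.group_j:
                        pi.append(a - 1)
                        pj.append(b - 1)
                        rid.append(k)
                npairs[k] = len(r.group_i) * len(r.group_j)
            self._compiled = dict(
                pair_i=np.asarray(pi, dtype=np.int64),
                pair_j=np.asarray(pj, dtype=np.int64),
                pair_rid=np.asarray(rid, dtype=np.int64),
                npairs=npairs,
                d_l=np.array([r.d_l for r in self.distance]),
                d_u=np.array([r.d_u for r in self.distance]),
                A=np.array([r.A for r in self.distance]),
                sigma=np.array([r.sigma for r in self.distance]),
                kappa=np.array([r.kappa for r in self.distance]),
                th_vertex=np.array([r.vertex for r in self.angle],
                                   dtype=np.int64),
                th_l=np.array([r.theta_l for r in self.angle]),
                th_u=np.array([r.theta_u for r in self.angle]),
                th_A=np.array([r.A_theta for r in self.angle]),
                th_sigma=np.array([r.sigma_theta for r in self.angle]),
                ga_bond=np.array([r.bond for r in self.dihedral],
                                 dtype=np.int64),
                ga_l=np.array([r.gamma_l for r in self.dihedral]),
                ga_u=np.array([r.gamma_u for r in self.dihedral]),
                ga_A=np.array([r.A_gamma for r in self.dihedral]),
                ga_sigma=np.array([r.sigma_gamma for r in self.dihedral]),
            )
        return self._compiled


# ---------------------------------------------------------------------------
# penalty potentials

def _flat_bottom(x, lo, hi, A, sigma):
    """Flat bottom of depth A on [lo, hi] with Gaussian walls; no tail."""
    x = np.asarray(x, dtype=float)
    below = x < lo
    above = x > hi
    dev = np.where(below, x - lo, np.where(above, x - hi, 0.0))
    g = np.exp(-dev * dev / (2.0 * sigma**2))
    V = -A * g
    dV = A * dev / sigma**2 * g
    return V, dV


def eval_distance_penalty(d, r: DistanceRestraint):
    """Distance penalty and its exact derivative dV/dd.

    V = -A on [d_l, d_u]; Gaussian walls of width sigma on both sides; a
    linear tail kappa*(d - d_u) is added above the upper bound.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    V, dV = _flat_bottom(d, r.d_l, r.d_u, r.A, r.sigma)
    above = d > r.d_u
    V = V + np.where(above, r.kappa * (d - r.d_u), 0.0)
    dV = dV + np.where(above, r.kappa, 0.0)
    if V.ndim == 0:
        return float(V), float(dV)
    return V, dV


def eval_theta_penalty(theta, r: AngleRestraint):
    """Virtual-bond-angle penalty and dV/dtheta (per degree)."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta <= 0) | (theta >= 180)):
        raise ValueError("theta must lie in (0, 180)")
    V, dV = _flat_bottom(theta, r.theta_l, r.theta_u, r.A_theta, r.sigma_theta)
    if V.ndim == 0:
        return float(V), float(dV)
    return V, dV


def eval_gamma_penalty(gamma, r: DihedralRestraint):
    """Periodic virtual-bond-dihedral penalty and dV/dgamma (per degree).

    The argument is measured by its circular distance to the bound interval
    [gamma_l, gamma_u] (taken counterclockwise); V(gamma) = V(gamma + 360).
    """
    gamma = np.asarray(wrap_angle(gamma), dtype=float)
    span = np.mod(r.gamma_u - r.gamma_l, 360.0)
    pos = np.mod(gamma - r.gamma_l, 360.0)
    inside = pos <= span
    d_above = pos - span          # circular distance past the upper bound
    d_below = 360.0 - pos         # circular distance below the lower bound
    use_above = d_above <= d_below
    dev = np.where(inside, 0.0, np.where(use_above, d_above, -d_below))
    g = np.exp(-dev * dev / (2.0 * r.sigma_gamma**2))
    V = -r.A_gamma * g
    dV = r.A_gamma * dev / r.sigma_gamma**2 * g
    if V.ndim == 0:
        return float(V), float(dV)
    return V, dV


def distance_penalty_vec(d, comp):
    """Vectorized distance penalty over a compiled restraint set."""
    dev = np.where(d < comp["d_l"], d - comp["d_l"],
                   np.where(d > comp["d_u"], d - comp["d_u"], 0.0))
    g = np.exp(-dev * dev / (2.0 * comp["sigma"]**2))
    above = d > comp["d_u"]
    V = -comp["A"] * g + np.where(above, comp["kappa"] * (d - comp["d_u"]), 0.0)
    dV = comp["A"] * dev / comp["sigma"]**2 * g + np.where(above,
                                                           comp["kappa"], 0.0)
    return V, dV


def theta_penalty_vec(theta, comp):
    """Vectorized virtual-bond-angle penalty over a compiled set."""
    dev = np.where(theta < comp["th_l"], theta - comp["th_l"],
                   np.where(theta > comp["th_u"], theta - comp["th_u"], 0.0))
    g = np.exp(-dev * dev / (2.0 * comp["th_sigma"]**2))
    return -comp["th_A"] * g, comp["th_A"] * dev / comp["th_sigma"]**2 * g


def gamma_penalty_vec(gamma, comp):
    """Vectorized periodic dihedral penalty; NaN input yields zero term."""
    span = np.mod(comp["ga_u"] - comp["ga_l"], 360.0)
    pos = np.mod(gamma - comp["ga_l"], 360.0)
    d_above = pos - span
    d_below = 360.0 - pos
    dev = np.where(pos <= span, 0.0,
                   np.where(d_above <= d_below, d_above, -d_below))
    bad = np.isnan(dev)
    dev = np.where(bad, 0.0, dev)
    g = np.exp(-dev * dev / (2.0 * comp["ga_sigma"]**2))
    V = np.where(bad, 0.0, -comp["ga_A"] * g)
    dV = np.where(bad, 0.0, comp["ga_A"] * dev / comp["ga_sigma"]**2 * g)
    return V, dV


def restraint_energy(values: MeasuredValues, rset: RestraintSet):
    """Total penalty energy and the per-restraint terms.

    Dihedral entries flagged degenerate (NaN) are skipped.  Returns
    (V_total, {"dist": ..., "theta": ..., "gamma": ...}).
    """
    if (len(values.dist) != rset.n_distance
            or len(values.theta) != rset.n_angle
            or len(values.gamma) != rset.n_dihedral):
        raise ValueError("value/restraint count mismatch")
    v_dist = np.array([eval_distance_penalty(d, r)[0]
                       for d, r in zip(values.dist, rset.distance)])
    v_theta = np.array([eval_theta_penalty(t, r)[0]
                        for t, r in zip(values.theta, rset.angle)])
    v_gamma = np.array([0.0 if np.isnan(g) else eval_gamma_penalty(g, r)[0]
                        for g, r in zip(values.gamma, rset.dihedral)])
    total = float(v_dist.sum() + v_theta.sum() + v_gamma.sum())
    return total, {"dist": v_dist, "theta": v_theta, "gamma": v_gamma}


# ---------------------------------------------------------------------------
# measurement and Cartesian gradients

_DEG = 180.0 / np.pi


def measure_cached(conf: Conformation, rset: RestraintSet):
    """As :func:`measure`, but also return geometry reused by the forces."""
    rset.validate_for_chain(conf.n_beads)
    comp = rset.compiled()
    cache = {}
    if rset.n_distance:
        dvec = conf.coords[comp["pair_j"]] - conf.coords[comp["pair_i"]]
        dpair = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        if np.any(dpair < 1e-10):
            raise ValueError("coincident restrained beads")
        acc = np.zeros(rset.n_distance)
        np.add.at(acc, comp["pair_rid"], dpair**-6.0)
        dist = (acc / comp["npairs"]) ** (-1.0 / 6.0)
        cache["dvec"], cache["dpair"] = dvec, dpair
    else:
        dist = np.zeros(0)
    theta = np.zeros(0)
    gamma = np.zeros(0)
    if rset.n_angle or rset.n_dihedral:
        ic = internal_coords(conf)
        if rset.n_angle:
            theta = ic.theta[comp["th_vertex"] - 2]
        if rset.n_dihedral:
            gamma = ic.gamma[comp["ga_bond"] - 2]
    return MeasuredValues(dist=dist, theta=theta, gamma=gamma), cache


def apply_restraint_gradients(conf: Conformation, rset: RestraintSet,
                              g_dist, g_theta, g_gamma, cache=None):
    """Cartesian forces from per-restraint scalar gradients.

    ``g_*`` is dV/dy evaluated at whatever argument the penalty was given
    (momentary or time-averaged), per A for distances and per degree for
    angles; the returned array is the force, i.e. minus the gradient.
    NaN entries in ``g_gamma`` (degenerate dihedrals) contribute nothing.
    """
    comp = rset.compiled()
    coords = conf.coords
    forces = np.zeros_like(coords)

    if rset.n_distance:
        if cache is None:
            _, cache = measure_cached(conf, rset)
        dvec, dpair = cache["dvec"], cache["dpair"]
        acc = np.zeros(rset.n_distance)
        np.add.at(acc, comp["pair_rid"], dpair**-6.0)
        dgroup = (acc / comp["npairs"]) ** (-1.0 / 6.0)
        # d(group)/d(pair) = (1/P) (d_g / d_p)^7
        rid = comp["pair_rid"]
        ddg = (dgroup[rid] / dpair) ** 7 / comp["npairs"][rid]
        pref = (g_dist[rid] * ddg / dpair)[:, None] * dvec
        np.add.at(forces, comp["pair_j"], -pref)
        np.add.at(forces, comp["pair_i"], pref)

    if rset.n_angle and np.any(g_theta):
        v = comp["th_vertex"] - 1          # 0-based vertex bead
        u = coords[v - 1] - coords[v]
        w = coords[v + 1] - coords[v]
        nu = np.linalg.norm(u, axis=1)
        nw = np.linalg.norm(w, axis=1)
        ct = np.clip(np.einsum("ij,ij->i", u, w) / (nu * nw),
                     -1 + 1e-12, 1 - 1e-12)
        st = np.sqrt(1.0 - ct * ct)
        gi = (ct[:, None] * u / nu[:, None] - w / nw[:, None]) \
            / (nu * st)[:, None]
        gk = (ct[:, None] * w / nw[:, None] - u / nu[:, None]) \
            / (nw * st)[:, None]
        pref = (g_theta * _DEG)[:, None]   # dV per radian
        np.add.at(forces, v - 1, -pref * gi)
        np.add.at(forces, v + 1, -pref * gk)
        np.add.at(forces, v, pref * (gi + gk))

    if rset.n_dihedral:
        gg = np.where(np.isnan(g_gamma), 0.0, g_gamma)
        if np.any(gg):
            a = comp["ga_bond"] - 2        # 0-based first bead of the quad
            b1 = coords[a + 1] - coords[a]
            b2 = coords[a + 2] - coords[a + 1]
            b3 = coords[a + 3] - coords[a + 2]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            n1sq = np.einsum("ij,ij->i", n1, n1)
            n2sq = np.einsum("ij,ij->i", n2, n2)
            ok = (n1sq > 1e-14) & (n2sq > 1e-14)
            n1sq = np.where(ok, n1sq, 1.0)
            n2sq = np.where(ok, n2sq, 1.0)
            b2n = np.linalg.norm(b2, axis=1)
            g1 = -(b2n / n1sq)[:, None] * n1
            g4 = (b2n / n2sq)[:, None] * n2
            d12 = (np.einsum("ij,ij->i", b1, b2) / b2n**2)[:, None]
            d32 = (np.einsum("ij,ij->i", b3, b2) / b2n**2)[:, None]
            g2 = -g1 - d12 * g1 + d32 * g4
            g3 = -g4 + d12 * g1 - d32 * g4
            pref = (np.where(ok, gg, 0.0) * _DEG)[:, None]
            np.add.at(forces, a, -pref * g1)
            np.add.at(forces, a + 1, -pref * g2)
            np.add.at(forces, a + 2, -pref * g3)
            np.add.at(forces, a + 3, -pref * g4)

    return forces


def instantaneous_restraint_forces(conf: Conformation, rset: RestraintSet):
    """Penalty energy and forces evaluated on momentary quantities."""
    values, cache = measure_cached(conf, rset)
    comp = rset.compiled()
    energy = 0.0
    g_dist = np.zeros(rset.n_distance)
    g_theta = np.zeros(rset.n_angle)
    g_gamma = np.zeros(rset.n_dihedral)
    if rset.n_distance:
        V, g_dist = distance_penalty_vec(values.dist, comp)
        energy += V.sum()
    if rset.n_angle:
        V, g_theta = theta_penalty_vec(values.theta, comp)
        energy += V.sum()
    if rset.n_dihedral:
        V, g_gamma = gamma_penalty_vec(values.gamma, comp)
        energy += V.sum()
    forces = apply_restraint_gradients(conf, rset, g_dist, g_theta, g_gamma,
                                       cache=cache)
    return float(energy), forces


def group_r6_distance(distances, weights=None):
    """Equal- (or given-) weight r^-6 combination of distances."""
    d = np.asarray(distances, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    w = (np.full(d.shape, 1.0 / d.shape[-1]) if weights is None
         else np.asarray(weights, dtype=float))
    return float(np.sum(w * d**-6.0, axis=-1) ** (-1.0 / 6.0)) \
        if d.ndim == 1 else np.sum(w * d**-6.0, axis=-1) ** (-1.0 / 6.0)


def measure(conf: Conformation, rset: RestraintSet) -> MeasuredValues:
    """Instantaneous restrained quantities of one conformation.

    Group distances are r^-6 combined with equal weights within the
    conformation; degenerate dihedrals are flagged NaN.
    """
    values, _ = measure_cached(conf, rset)
    return values


def synthesize_restraints(refs, weights=None, cutoff: float = 8.0,
                          pad: float = 0.5, min_separation: int = 2,
                          A: float = 5.0, sigma: float = 1.0,
                          kappa: float = 0.01) -> RestraintSet:
    """Distance restraints from one or more reference conformations.

    For every bead pair (i, j) with sequence separation >= ``min_separation``
    whose weighted r^-6-average distance over the references is <= ``cutoff``,
    a restraint with bounds [max(0, dbar - pad), dbar + pad] is emitted,
    ordered by (i, j).
    """
    refs = [refs] if isinstance(refs, Conformation) else list(refs)
    if not refs:
        raise ValueError("need at least one reference conformation")
    n = refs[0].n_beads
    if any(r.n_beads != n for r in refs):
        raise ValueError("references must have equal bead counts")
    if weights is None:
        weights = np.full(len(refs), 1.0 / len(refs))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(refs) or np.any(weights < 0) \
            or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    stack = np.stack([r.coords for r in refs])     # (L, n, 3)
    out = []
    for i in range(n):
        for j in range(i + min_separation, n):
            d = np.linalg.norm(stack[:, j] - stack[:, i], axis=1)
            dbar = float(np.sum(weights * d**-6.0) ** (-1.0 / 6.0))
            if dbar <= cutoff:
                out.append(DistanceRestraint(
                    group_i=(i + 1,), group_j=(j + 1,),
                    d_l=max(0.0, dbar - pad), d_u=dbar + pad,
                    A=A, sigma=sigma, kappa=kappa))
    return RestraintSet(distance=out)


# ---------------------------------------------------------------------------
# restraint-table I/O (tab-separated, 1-based residue indices)

def _parse_group(token: str):
    try:
        return tuple(int(t) for t in token.split(","))
    except ValueError as exc:
        raise ValueError(
            f"unparseable residue group {token!r}; ambiguous-NOE syntax "
            f"beyond comma-joined equivalent-site groups is not supported"
        ) from exc


def read_restraint_table(path) -> RestraintSet:
    """Read a tab/whitespace-separated restraint table.

    Records: ``DIST i_group j_group d_l d_u [A sigma kappa]``,
    ``THETA vertex theta_l theta_u [A_theta sigma_theta]``,
    ``GAMMA bond gamma_l gamma_u [A_gamma sigma_gamma]``.
    Lines starting with ``#`` are ignored.
    """
    dist, ang, dih = [], [], []
    with open(path, "r", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            try:
                kind = tok[0].upper()
                if kind == "DIST":
                    opts = [float(x) for x in tok[5:8]]
                    dist.append(DistanceRestraint(
                        _parse_group(tok[1]), _parse_group(tok[2]),
                        float(tok[3]), float(tok[4]), *opts))
                elif kind == "THETA":
                    opts = [float(x) for x in tok[4:6]]
                    ang.append(AngleRestraint(
                        int(tok[1]), float(tok[2]), float(tok[3]), *opts))
                elif kind == "GAMMA":
                    opts = [float(x) for x in tok[4:6]]
                    dih.append(DihedralRestraint(
                        int(tok[1]), float(tok[2]), float(tok[3]), *opts))
                else:
                    raise ValueError(f"unknown record kind {tok[0]!r}")
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}, line {ln}: {exc}") from exc
    return RestraintSet(distance=dist, angle=ang, dihedral=dih)


def write_restraint_table(path, rset: RestraintSet) -> None:
    """Write a restraint table; write->read round-trips losslessly."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# tavmd restraint table\n")
        fh.write("# DIST i_group j_group d_l d_u A sigma kappa\n")
        for r in rset.distance:
            fh.write("DIST\t%s\t%s\t%.17g\t%.17g\t%.17g\t%.17g\t%.17g\n" % (
                ",".join(map(str, r.group_i)), ",".join(map(str, r.group_j)),
                r.d_l, r.d_u, r.A, r.sigma, r.kappa))
        for r in rset.angle:
            fh.write("THETA\t%d\t%.17g\t%.17g\t%.17g\t%.17g\n" % (
                r.vertex, r.theta_l, r.theta_u, r.A_theta, r.sigma_theta))
        for r in rset.dihedral:
            fh.write("GAMMA\t%d\t%.17g\t%.17g\t%.17g\t%.17g\n" % (
                r.bond, r.gamma_l, r.gamma_u, r.A_gamma, r.sigma_gamma))
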