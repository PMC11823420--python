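"""Ensemble post-processing: r^-6 averaging, violation statistics,
structural similarity, clustering, distribution summaries.

The NOE-consistent ensemble average of a distance over weighted
conformations is <d^-6>^(-1/6).  Upper-bound violations are summarized by
rho_u+, the root mean square of the positive excesses of the
ensemble-averaged distances over their upper bounds, together with the
count of violated restraints and the count violated by 2 A or more.
Structural similarity uses C-alpha RMSD at the optimal proper-rotation
superposition (Kabsch) and GDT_TS, the mean percentage of beads within
1/2/4/8 A of the reference after a single all-bead superposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cgmodel import Conformation
from .restraints import RestraintSet, measure

__all__ = ["ViolationReport", "ClusterResult", "r6_ensemble_average",
           "violation_report", "kabsch_rmsd", "superpose", "gdt_ts",
           "cluster_ensemble", "rmsd_distributions",
           "per_conformation_violation"]


@dataclass
class ViolationReport:
    d_avg: np.ndarray          # ensemble-averaged distances, A
    d_upper: np.ndarray        # upper bounds, A
    excess: np.ndarray         # max(d_avg - d_upper, 0)
    rho_u_plus: float          # RMS of the positive excesses, A
    n_violated: int
    n_violated_2A: int

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"restraint": np.arange(len(self.d_avg)),
                             "d_avg": self.d_avg, "d_upper": self.d_upper,
                             "excess": self.excess})


@dataclass
class ClusterResult:
    assignment: np.ndarray     # family index (0-based) per conformation
    family_weight: np.ndarray  # cumulative weight per family
    ranked_families: np.ndarray  # family indices, heaviest first
    representatives: np.ndarray  # conformation index per family


def _normalized_weights(weights, n):
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return w


def r6_ensemble_average(distances, weights=None):
    """<d^-6>^(-1/6) over conformations, per restraint.

    ``distances`` has shape (n_conformations, n_restraints) (a 1-D array is
    treated as a single restraint's values).
    """
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    w = _normalized_weights(weights, d.shape[0])
    return (w @ d**-6.0) ** (-1.0 / 6.0)


def violation_report(d_avg, d_upper, threshold: float = 2.0):
    """rho_u+ and violation counts of averaged distances vs upper bounds."""
    d_avg = np.asarray(d_avg, dtype=float)
    d_upper = np.asarray(d_upper, dtype=float)
    if d_avg.shape != d_upper.shape:
        raise ValueError("distance/bound length mismatch")
    if d_avg.size == 0:
        raise ValueError("empty restraint list: rho_u+ undefined")
    excess = np.maximum(d_avg - d_upper, 0.0)
    rho = float(np.sqrt(np.mean(excess**2)))
    return ViolationReport(
        d_avg=d_avg, d_upper=d_upper, excess=excess, rho_u_plus=rho,
        n_violated=int(np.sum(excess > 0)),
        n_violated_2A=int(np.sum(excess >= threshold)))


def per_conformation_violation(conf: Conformation, rset: RestraintSet):
    """rho_u+ of a single conformation's own distances (no averaging)."""
    values = measure(conf, rset)
    d_upper = np.array([r.d_u for r in rset.distance])
    return violation_report(values.dist, d_upper).rho_u_plus


def superpose(mobile: Conformation, target: Conformation):
    """Optimal proper-rotation superposition of mobile onto target.

    Returns (superposed coordinates, rmsd).
    """
    A = np.asarray(mobile.coords, dtype=float)
    B = np.asarray(target.coords, dtype=float)
    if A.shape != B.shape or A.shape[0] < 3:
        raise ValueError("need equal bead counts >= 3")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # Kabsch: SVD of the covariance with a determinant correction so the
    # optimum is a proper rotation (no reflection)
    U, _, Vt = np.linalg.svd(A0.T @ B0)
    d = np.sign(np.linalg.det(U @ Vt))
    R = (U @ np.diag([1.0, 1.0, d]) @ Vt).T
    moved = A0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B0) ** 2, axis=1))))
    return moved + cb, rmsd


def kabsch_rmsd(a: Conformation, b: Conformation) -> float:
    """Minimal C-alpha RMSD over rigid rotations and translations (A)."""
    return superpose(a, b)[1]


def gdt_ts(a_superposed, b, cutoffs=(1.0, 2.0, 4.0, 8.0)) -> float:
    """GDT_TS of already-superposed coordinates, in [0, 100].

    Single all-bead superposition variant (a lower bound on the
    multi-superposition search of assessment tools).
    """
    A = np.asarray(a_superposed.coords if isinstance(a_superposed, Conformation)
                   else a_superposed, dtype=float)
    B = np.asarray(b.coords if isinstance(b, Conformation) else b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("bead count mismatch")
    dev = np.linalg.norm(A - B, axis=1)
    return float(np.mean([100.0 * np.mean(dev <= c) for c in cutoffs]))


def cluster_ensemble(conformations, weights=None, k: int = 5,
                     rset: RestraintSet | None = None) -> ClusterResult:
    """Ward clustering of an ensemble on its pairwise-RMSD matrix.

    Families are ranked by cumulative weight (heaviest first, ties by lowest
    family index); the representative of a family is its member with the
    lowest per-conformation restraint violation (lowest index wins ties), or
    its highest-weight member when no restraint set is given.
    """
    confs = list(conformations)
    n = len(confs)
    if k < 1:
        raise ValueError("need k >= 1")
    if k > n:
        raise ValueError("more families than conformations")
    w = _normalized_weights(weights, n)
    if n == 1 or k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = kabsch_rmsd(confs[i], confs[j])
        Z = linkage(squareform(dm, checks=False), method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    n_fam = labels.max() + 1
    fam_w = np.array([w[labels == f].sum() for f in range(n_fam)])
    ranked = np.argsort(-fam_w, kind="stable")
    reps = np.zeros(n_fam, dtype=int)
    for f in range(n_fam):
        members = np.flatnonzero(labels == f)
        if rset is not None and rset.n_distance:
            scores = [per_conformation_violation(confs[i], rset)
                      for i in members]
            reps[f] = members[int(np.argmin(scores))]
        else:
            reps[f] = members[int(np.argmax(w[members]))]
    return ClusterResult(assignment=labels, family_weight=fam_w,
                         ranked_families=ranked, representatives=reps)


def rmsd_distributions(conformations, refs, bin_width: float = 0.5,
                       weights=None, rmsd_max: float | None = None):
    """Weighted RMSD histogram(s) against one or two references.

    Returns (edges, hist): 1-D for one reference, 2-D (with a pair of edge
    arrays) for two.  Histogram masses sum to 1.
    """
    confs = list(conformations)
    if not confs:
        raise ValueError("empty ensemble")
    refs = [refs] if isinstance(refs, Conformation) else list(refs)
    if not 1 <= len(refs) <= 2:
        raise ValueError("need one or two references")
    w = _normalized_weights(weights, len(confs))
    r = np.array([[kabsch_rmsd(c, ref) for ref in refs] for c in confs])
    hi = rmsd_max if rmsd_max is not None else max(r.max() + bin_width, bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    if len(refs) == 1:
        hist, edges = np.histogram(r[:, 0], bins=edges, weights=w)
        return edges, hist
    hist, ex, ey = np.histogram2d(r[:, 0], r[:, 1], bins=(edges, edges),
                                  weights=w)
    return (ex, ey), hist
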