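"""Backbone dihedrals, the delta twist statistic, and helical geometry.

The handedness of the cross-beta sheet twist can be read off the
Ramachandran plot: for residues in the beta region, pairs on the right of
the -Phi = Psi diagonal (delta = Psi + Phi > 0) indicate a left-hand sheet
twist, pairs on the left (delta < 0) a right-hand twist.  Independently,
the overall fibril handedness follows from the sign of the per-layer twist
obtained by superposing consecutive molecular layers.  Both routes are
implemented here so their concordance can be checked on any model.

Conventions
-----------
* Angles in degrees, wrapped to (-180, 180].
* The fibril axis is oriented so the rise is positive; the twist is the
  signed rotation per layer about that axis (right-hand rule), so
  twist > 0 means a right-handed helix.
* crossover = (180/|twist|) * rise is the axial distance over which the
  fibril rotates half a turn; pitch = 2 * crossover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.transform import Rotation

from .model import FibrilModel

log = logging.getLogger(__name__)

PEPTIDE_BOND_MAX_A = 2.0  # C(i)-N(i+1) beyond this is a chain break


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    w = np.asarray(deg, dtype=float) % 360.0
    w = np.where(w > 180.0, w - 360.0, w)
    return float(w) if np.isscalar(deg) or np.ndim(deg) == 0 else w


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention:
    looking from p1 to p2, the angle from the p0 side to the p3 side,
    clockwise positive)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class DihedralRecord:
    """Backbone dihedrals of one residue.

    ``delta_deg`` is Psi + Phi wrapped to (-180, 180], undefined (None)
    whenever either angle is undefined (chain termini and breaks).
    """

    chain_id: str
    residue_number: int
    residue_name: str
    phi_deg: float | None
    psi_deg: float | None
    delta_deg: float | None
    is_beta: bool = False


@dataclass
class TwistSummary:
    """Summary of the delta statistic over a residue subset."""

    delta_mean_deg: float
    delta_sd_deg: float
    n_residues: int
    right_side_fraction: float
    handedness_call: str  # left | right | indeterminate


@dataclass
class HelicalParams:
    """Helical symmetry of a layered fibril model."""

    twist_deg_per_layer: float
    rise_A: float
    crossover_nm: float
    pitch_nm: float
    handedness: str
    per_step_values: list
    rmsd_A: float


def backbone_dihedrals(model: FibrilModel, chain_id: str) -> list[DihedralRecord]:
    """Phi/Psi/delta for every residue of one chain.

    Residues missing any of N, CA, C are skipped with a logged warning.
    Consecutive residues whose C-N distance exceeds 2 A are treated as a
    chain break (angles across the break are undefined).
    """
    sub = model.chain_atoms(chain_id)
    residues = []
    for resnum, grp in sub.groupby("residue_number", sort=True):
        pos = {row.atom_name: np.array([row.x, row.y, row.z])
               for row in grp.itertuples()}
        if not {"N", "CA", "C"} <= set(pos):
            log.warning("chain %s residue %s: incomplete backbone, skipped",
                        chain_id, resnum)
            continue
        residues.append((int(resnum), str(grp["residue_name"].iloc[0]), pos))

    bonded_prev = [False] * len(residues)
    for i in range(1, len(residues)):
        d = np.linalg.norm(residues[i][2]["N"] - residues[i - 1][2]["C"])
        bonded_prev[i] = d < PEPTIDE_BOND_MAX_A

    records = []
    for i, (resnum, resname, pos) in enumerate(residues):
        phi = psi = None
        if i > 0 and bonded_prev[i]:
            prev = residues[i - 1][2]
            phi = dihedral_deg(prev["C"], pos["N"], pos["CA"], pos["C"])
        if i + 1 < len(residues) and bonded_prev[i + 1]:
            nxt = residues[i + 1][2]
            psi = dihedral_deg(pos["N"], pos["CA"], pos["C"], nxt["N"])
        delta = wrap_angle(phi + psi) if phi is not None and psi is not None else None
        records.append(DihedralRecord(chain_id, resnum, resname, phi, psi, delta))
    return records


def delta_statistic(records: Iterable[DihedralRecord],
                    subset: str | Callable[[DihedralRecord], bool] = "beta",
                    ) -> TwistSummary:
    """Mean and SD of delta = Psi + Phi over a residue subset.

    ``subset`` is ``"beta"`` (records flagged as beta-sheet), ``"all"``
    (every record with a defined delta), or a predicate.  The mean is the
    arithmetic mean of the wrapped values; the SD uses the n-1
    denominator (0 is reported when n = 1).
    """
    if subset == "beta":
        pred = lambda r: r.is_beta
    elif subset == "all":
        pred = lambda r: True
    else:
        pred = subset
    deltas = np.array([r.delta_deg for r in records
                       if pred(r) and r.delta_deg is not None])
    if deltas.size == 0:
        raise ValueError("subset selects no residues with a defined delta")
    mean = float(deltas.mean())
    sd = float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0
    frac = float((deltas > 0).sum() / deltas.size)
    return TwistSummary(delta_mean_deg=mean, delta_sd_deg=sd,
                        n_residues=int(deltas.size),
                        right_side_fraction=frac,
                        handedness_call=_call(mean, frac))


def _call(mean: float, frac: float) -> str:
    if mean > 0 and frac > 0.5:
        return "left"
    if mean < 0 and frac < 0.5:
        return "right"
    return "indeterminate"


def ramachandran_side(records: Iterable[DihedralRecord]) -> TwistSummary:
    """Which side of the -Phi = Psi Ramachandran diagonal the residues
    fall on.  Residues with delta exactly 0 sit on the diagonal: they are
    counted in n but in neither side's numerator."""
    return delta_statistic(records, subset="all")


# ---------------------------------------------------------------------------
# helical parameters


def helical_parameters(model: FibrilModel,
                       axis_tolerance_deg: float = 10.0) -> HelicalParams:
    """Signed per-layer twist and rise from consecutive-layer superpositions.

    For every stack and every consecutive layer pair, the shared-residue
    C-alpha atoms of layer i are superposed onto layer i+1 by least
    squares (Kabsch).  The rotation must be about the fibril axis (within
    ``axis_tolerance_deg``); its signed angle and the axial translation
    give the per-step twist and rise, averaged over all steps.
    """
    if model.n_layers < 2:
        raise ValueError("helical parameters need at least 2 layers")
    axis = model.axis
    steps = []
    residuals = []
    layers = sorted(set(model.layer_of.values()))
    for stack in (model.stacks or ["A"]):
        for la, lb in zip(layers[:-1], layers[1:]):
            ca_chain = model.chain_for(la, stack)
            cb_chain = model.chain_for(lb, stack)
            if ca_chain is None or cb_chain is None:
                continue
            twist, rise, rmsd = _step_transform(model, ca_chain, cb_chain,
                                                axis, axis_tolerance_deg)
            steps.append((twist, rise))
            residuals.append(rmsd)
    if not steps:
        raise ValueError("no consecutive-layer chain pairs with shared residues")
    twists = np.array([s[0] for s in steps])
    rises = np.array([s[1] for s in steps])
    twist = float(twists.mean())
    rise = float(rises.mean())
    if rise < 0:
        # axis orientation convention: rise positive
        twist, rise = -twist, -rise
    if twist == 0:
        crossover = float("inf")
    else:
        crossover = (180.0 / abs(twist)) * rise / 10.0
    return HelicalParams(
        twist_deg_per_layer=twist,
        rise_A=rise,
        crossover_nm=crossover,
        pitch_nm=2.0 * crossover,
        handedness="right" if twist > 0 else "left",
        per_step_values=[(float(t), float(r)) for t, r in steps],
        rmsd_A=float(np.mean(residuals)),
    )


def _step_transform(model, chain_a, chain_b, axis, axis_tolerance_deg):
    """Twist/rise of the rigid transform mapping chain_a onto chain_b.

    The transform is fitted with the rotation constrained to be about the
    fibril axis (2D Procrustes in the cross-section plus the mean axial
    shift), which keeps the estimate well conditioned for noisy,
    nearly planar chains where a free 3D superposition has a poorly
    determined out-of-plane component.  The free Kabsch fit is still
    computed as a sanity check: when it fits decisively better than the
    axis-constrained one, the step is not a rotation about the stated
    axis and an error is raised.
    """
    ra, xa = model.ca_coords(chain_a)
    rb, xb = model.ca_coords(chain_b)
    shared = np.intersect1d(ra, rb)
    if len(shared) < 3:
        raise ValueError(
            f"chains {chain_a}/{chain_b} share fewer than 3 residues")
    pa = xa[np.isin(ra, shared)] * 1.0
    pb = xb[np.isin(rb, shared)] * 1.0
    da = pa - pa.mean(axis=0)
    db = pb - pb.mean(axis=0)

    # axis-constrained fit
    u = _perp(axis)
    v = np.cross(axis, u)
    qa = np.column_stack([da @ u, da @ v])
    qb = np.column_stack([db @ u, db @ v])
    num = float((qa[:, 0] * qb[:, 1] - qa[:, 1] * qb[:, 0]).sum())
    den = float((qa * qb).sum())
    theta = np.arctan2(num, den)
    rot_c = Rotation.from_rotvec(theta * axis)
    rmsd_c = float(np.sqrt(np.mean(
        np.sum((rot_c.apply(da) - db) ** 2, axis=1))))

    # free fit for the axis-sanity check
    rot_f, rssd = Rotation.align_vectors(db, da)
    rmsd_f = float(rssd / np.sqrt(len(shared)))
    rotvec = rot_f.as_rotvec()
    angle = np.linalg.norm(rotvec)
    dev = (np.degrees(np.arccos(np.clip(
        abs(np.dot(rotvec / angle, axis)), 0, 1))) if angle > 1e-9 else 0.0)
    # a near-rigid free fit determines its rotation axis reliably; with
    # appreciable residuals the residual comparison is the robust test
    bad_rigid = rmsd_f < 0.05 and dev > axis_tolerance_deg
    bad_noisy = rmsd_c > max(2.0 * rmsd_f, rmsd_f + 0.5)
    if bad_rigid or bad_noisy:
        raise ValueError(
            f"superposition rotation axis deviates {dev:.1f} deg from the "
            f"fibril axis (constrained rmsd {rmsd_c:.2f} A vs free "
            f"{rmsd_f:.2f} A); model is not a simple helix about the "
            "stated axis")

    twist = float(np.degrees(theta))
    rise = float((pb - pa).mean(axis=0) @ axis)
    return twist, rise, rmsd_c


def model_width(model: FibrilModel, atom_radius_A: float = 1.7) -> float:
    """Fibril width in nm: the maximum pairwise heavy-atom distance in the
    cross-section (the plane perpendicular to the axis) plus an atomic
    radius margin on each side.

    Model-derived widths are lower bounds on micrograph widths, which
    include disordered regions invisible in the model.
    """
    xyz = model.atoms[["x", "y", "z"]].to_numpy(dtype=float)
    axis = model.axis
    cross = xyz - np.outer(xyz @ axis, axis)
    # reduce to 2D in-plane coordinates
    u = _perp(axis)
    v = np.cross(axis, u)
    pts = np.column_stack([cross @ u, cross @ v])
    d = _max_pairwise(pts)
    return (d + 2.0 * atom_radius_A) / 10.0


def _perp(axis):
    a = np.eye(3)[int(np.argmin(np.abs(axis)))]
    u = np.cross(axis, a)
    return u / np.linalg.norm(u)


def _max_pairwise(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    uniq = np.unique(np.round(pts, 9), axis=0)
    if len(uniq) < 2:
        return 0.0
    if len(uniq) > 3:
        try:
            uniq = uniq[ConvexHull(uniq).vertices]
        except QhullError:
            pass  # degenerate (collinear) point sets: brute force below
    diff = uniq[:, None, :] - uniq[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=-1)).max())


def flag_beta(records: Sequence[DihedralRecord], flags: Sequence[bool]):
    """Return copies of ``records`` with is_beta set from ``flags``."""
    return [replace(r, is_beta=bool(f)) for r, f in zip(records, flags)]
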