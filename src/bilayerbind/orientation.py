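"""Helix axis fitting, rotational phase, and the four binding-orientation
classes of a membrane-bound amphipathic helix.

The rotational phase psi is the azimuth, about the fitted helix axis, of
the molecule-fixed anchor face -- the mean radial direction of the
anchor-residue side chains (R11, F15, S19 by default, the face that is
membrane-buried in the Fd pose) -- measured from the membrane-facing
("down") direction by right-hand rule about the axis.  psi is only
meaningful for a membrane-engaged pose, so a flat core-helix side-chain
depth profile (no membrane-facing asymmetry) is rejected.  The four
orientation classes are psi quadrants anchored
at Fd = 0 degrees (the pose with R11/F15/S19 membrane-facing), in the
cyclic order Fd -> Fa -> Fb -> Fc under successive +90 degree rotations.
The attachment of the Fa/Fb/Fc labels to particular helix faces is a
package convention; only the Fd anchor and the cyclic order are fixed by
the class definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AtomGroup, Frame, Trajectory, min_image_distance_matrix
from .geometry import (DEFAULT_Z_THRESHOLD, BilayerReference,
                       bilayer_reference, depth_profile,
                       relative_z, residue_centroid_z)

CORE_HELIX_RANGE = (8, 19)
CLASS_CYCLE = ("Fd", "Fa", "Fb", "Fc")   # +90 degrees advances one step
DEFAULT_WINDOW = 20.0                     # ns, classification window


@dataclass
class HelixFrame:
    """Fitted helix axis and per-residue side-chain azimuths about it."""

    axis: np.ndarray                 # unit vector, N- to C-terminal sense
    point: np.ndarray                # a point on the axis (nm)
    residue_range: tuple[int, int]
    resids: np.ndarray
    azimuths: np.ndarray             # degrees in [0, 360), from "down"


@dataclass
class OrientationResult:
    psi: float                       # degrees, circular mean over window
    label: str                       # Fa | Fb | Fc | Fd | unbound
    window: tuple[float, float]      # ns
    confidence: float                # circular resultant length in [0, 1]


def class_of_psi(psi: float) -> str:
    """Quadrant class of a phase angle; boundaries at 45/135/225/315."""
    return CLASS_CYCLE[int(np.floor(((psi + 45.0) % 360.0) / 90.0))]


def fit_helix_axis(frame: Frame, peptide: AtomGroup,
                   residue_range: tuple[int, int] = CORE_HELIX_RANGE
                   ) -> HelixFrame:
    """Helix axis through the core-helix C-alpha atoms.

    The direction comes from second differences of consecutive C-alpha
    positions: for helical geometry each second difference points
    radially inward, so cross products of successive ones lie along the
    axis exactly (a least-squares line through a fractional number of
    turns is systematically tilted).  The axis sign points from lower to
    higher residue index.  Side-chain azimuths are measured from the
    downward direction (-z projected off the axis), increasing by
    right-hand rule about the axis.
    """
    top = peptide.topology
    lo, hi = residue_range
    names = top.names[peptide.indices].astype(str)
    resids = top.resids[peptide.indices]
    ca_mask = (names == "CA") & (resids >= lo) & (resids <= hi)
    ca_idx = peptide.indices[ca_mask]
    if len(ca_idx) < 4:
        raise ValueError("need at least four C-alpha atoms to fit a helix "
                         "axis")
    ca_resids = top.resids[ca_idx]
    order = np.argsort(ca_resids)
    ca_idx = ca_idx[order]
    pts = frame.coordinates[ca_idx]
    center = pts.mean(axis=0)
    w = np.diff(pts, n=2, axis=0)             # radial second differences
    # the axis is the direction all second differences are normal to:
    # the smallest principal direction of their scatter
    _, svals, vt = np.linalg.svd(w)
    if svals[1] < 1e-9:
        raise ValueError("degenerate C-alpha geometry: cannot determine "
                         "a helix axis")
    axis = vt[-1]
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    # downward reference direction perpendicular to the axis
    down = np.array([0.0, 0.0, -1.0])
    d0 = down - np.dot(down, axis) * axis
    n0 = np.linalg.norm(d0)
    if n0 < 1e-9:
        raise ValueError("helix axis is parallel to the membrane normal; "
                         "no in-plane 'down' direction exists")
    d0 /= n0
    d90 = np.cross(axis, d0)
    res_list, azimuths = [], []
    for rid, z in zip(*residue_centroid_z(frame, peptide, "sidechain")):
        if not (lo <= rid <= hi) or np.isnan(z):
            continue
        idx = peptide.indices[(top.resids[peptide.indices] == rid)]
        mask = _sidechain_mask(top, idx)
        if not mask.any():
            continue
        sc = frame.coordinates[idx[mask]].mean(axis=0)
        radial = sc - center
        radial -= np.dot(radial, axis) * axis
        phi = np.degrees(np.arctan2(np.dot(radial, d90), np.dot(radial, d0)))
        res_list.append(int(rid))
        azimuths.append(phi % 360.0)
    return HelixFrame(axis=axis, point=center, residue_range=residue_range,
                      resids=np.array(res_list),
                      azimuths=np.array(azimuths))


def _sidechain_mask(top, idx: np.ndarray) -> np.ndarray:
    names = top.names[idx].astype(str)
    return (~np.isin(names, ("N", "CA", "C", "O"))
            & ~top.is_hydrogen()[idx])


ANCHOR_RESIDUES = (11, 15, 19)


def rotational_phase(frame: Frame, helix: HelixFrame,
                     depths: pd.DataFrame,
                     anchor_residues: tuple = ANCHOR_RESIDUES) -> float:
    """Phase psi (degrees): azimuth of the anchor face from "down".

    The anchor face is the mean radial direction of the anchor residues'
    side chains, so psi = 0 when that face points straight at the
    membrane (the Fd pose) and a rigid +90 degree roll about the axis
    shifts psi by +90.  Requires a binding-competent pose: the helix axis
    within 60 degrees of the membrane plane, and a non-flat core-helix
    side-chain depth profile (otherwise there is no membrane-facing
    asymmetry to orient against).
    """
    if abs(helix.axis[2]) > np.sin(np.radians(60.0)):
        raise ValueError("helix axis tilted more than 60 degrees out of "
                         "the membrane plane")
    lo, hi = helix.residue_range
    sub = depths[(depths["resid"] >= lo) & (depths["resid"] <= hi)]
    zv = sub.set_index("resid")["sidechain_z"].reindex(
        helix.resids).to_numpy(dtype=float)
    w = np.maximum(0.0, np.nanmean(zv) - zv)
    w[np.isnan(zv)] = 0.0
    if not np.any(w > 1e-12):
        raise ValueError("no membrane-facing asymmetry: side-chain depth "
                         "profile is flat")
    in_anchor = np.isin(helix.resids, anchor_residues)
    if not in_anchor.any():
        raise ValueError("no anchor residues found in the fitted range")
    phi = np.radians(helix.azimuths[in_anchor])
    x = float(np.sum(np.cos(phi)))
    y = float(np.sum(np.sin(phi)))
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def _circular_mean(angles_deg: np.ndarray) -> tuple[float, float]:
    a = np.radians(angles_deg)
    x, y = np.mean(np.cos(a)), np.mean(np.sin(a))
    return float(np.degrees(np.arctan2(y, x)) % 360.0), float(np.hypot(x, y))


def classify_orientation(traj: Trajectory, peptide: AtomGroup,
                         phosphorus: AtomGroup,
                         window: float = DEFAULT_WINDOW,
                         residue_range: tuple[int, int] = CORE_HELIX_RANGE,
                         z_threshold: float = DEFAULT_Z_THRESHOLD,
                         anchor_residues: tuple = ANCHOR_RESIDUES
                         ) -> OrientationResult:
    """Orientation class over the trajectory's final time window.

    psi is computed per frame and combined by circular mean; the resultant
    length is reported as the confidence.  If no residue centroid comes
    within ``z_threshold`` of the proximal phosphorus plane during the
    window, the peptide is reported as unbound.
    """
    t_end = traj.times[-1]
    sub = traj.window(t_end - window, t_end)
    psis = []
    bound = False
    for fr in sub:
        ref = bilayer_reference(fr, phosphorus, peptide)
        _, z = residue_centroid_z(fr, peptide, "whole")
        z_rel = relative_z(z, ref.proximal_mean_z, fr.box[2])
        if ref.proximal == "lower":
            z_rel = -z_rel
        if np.nanmin(z_rel) < z_threshold:
            bound = True
        helix = fit_helix_axis(fr, peptide, residue_range)
        depths = depth_profile(fr, peptide, ref, "phosphorus_plane")
        psis.append(rotational_phase(fr, helix, depths, anchor_residues))
    t_window = (float(sub.times[0]), float(sub.times[-1]))
    mean_psi, resultant = _circular_mean(np.array(psis))
    if not bound:
        return OrientationResult(mean_psi, "unbound", t_window, resultant)
    return OrientationResult(mean_psi, class_of_psi(mean_psi), t_window,
                             resultant)


def orientation_table(runs: list[tuple[Trajectory, AtomGroup, AtomGroup]],
                      labels: list[str],
                      **kwargs) -> tuple[pd.DataFrame, pd.Series]:
    """Classify many runs; returns (table, class frequencies).

    ``runs`` holds (trajectory, peptide, phosphorus) triples; ``labels``
    names each run's initial state.  Unbound runs appear in the table but
    are excluded from the frequency summary.
    """
    if not runs:
        raise ValueError("need at least one run")
    rows = []
    for label, (traj, pep, phos) in zip(labels, runs):
        res = classify_orientation(traj, pep, phos, **kwargs)
        rows.append((label, res.label, res.psi, res.confidence))
    table = pd.DataFrame(rows, columns=["initial_state", "orientation",
                                        "psi", "confidence"])
    bound = table[table["orientation"] != "unbound"]
    freq = (bound["orientation"].value_counts(normalize=True)
            if len(bound) else pd.Series(dtype=float))
    return table, freq


# ---------------------------------------------------------------------------
# construction of rotated initial states
# ---------------------------------------------------------------------------

def rotate_about_axis(coords: np.ndarray, axis: np.ndarray,
                      point: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of coordinates about a line (point, axis)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    rel = np.atleast_2d(coords - point)
    out = (point + rel * np.cos(th)
           + np.cross(axis, rel) * np.sin(th)
           + axis[None, :] * (rel @ axis)[:, None] * (1 - np.cos(th)))
    return out.reshape(np.shape(coords))


def build_initial_states(peptide_top, peptide_frame: Frame,
                         bilayer_top, bilayer_frame: Frame,
                         separation: float = 1.4,
                         rotations: tuple = (0, 90, 180, 270),
                         reference_resid: int = 1,
                         residue_range: tuple[int, int] = CORE_HELIX_RANGE):
    """Four rotated starting configurations of the peptide over the bilayer.

    The helix axis is aligned with x (parallel to the membrane plane); the
    zero-rotation state has the reference residue's side chain pointing at
    the membrane; each state keeps a minimum peptide-lipid heavy-atom
    distance of at least ``separation``.  Returns (combined topology,
    list of Frames), deterministic in its inputs.
    """
    from .core import concatenate_topologies

    all_pep = AtomGroup(peptide_top, np.arange(peptide_top.n_atoms))
    coords = peptide_frame.coordinates.copy()
    box = bilayer_frame.box.copy()

    # orient the helix axis along +x
    helix = fit_helix_axis(Frame(coords, peptide_frame.box), all_pep,
                           residue_range)
    target = np.array([1.0, 0.0, 0.0])
    v = np.cross(helix.axis, target)
    s = np.linalg.norm(v)
    c = float(np.dot(helix.axis, target))
    if s > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        coords = (coords - helix.point) @ rot.T + helix.point
    elif c < 0:
        coords[:, 1:] = 2 * helix.point[1:] - coords[:, 1:]

    # roll about the axis until the reference side chain points down
    helix = fit_helix_axis(Frame(coords, peptide_frame.box), all_pep,
                           residue_range)
    idx = np.flatnonzero(peptide_top.resids == reference_resid)
    mask = _sidechain_mask(peptide_top, idx)
    if not mask.any():
        raise ValueError(f"reference residue {reference_resid} has no "
                         "side-chain atoms")
    sc = coords[idx[mask]].mean(axis=0)
    radial = sc - helix.point
    radial -= np.dot(radial, helix.axis) * helix.axis
    d0 = np.array([0.0, 0.0, -1.0])
    d0 -= np.dot(d0, helix.axis) * helix.axis
    d0 /= np.linalg.norm(d0)
    d90 = np.cross(helix.axis, d0)
    phi = np.degrees(np.arctan2(np.dot(radial, d90), np.dot(radial, d0)))
    coords = rotate_about_axis(coords, helix.axis, helix.point, -phi)

    # place the peptide centroid over the box center, above the upper leaflet
    bil_heavy = AtomGroup(bilayer_top, np.flatnonzero(
        ~bilayer_top.is_hydrogen()))
    bil_pos = bil_heavy.positions(bilayer_frame)
    pep_heavy_mask = ~peptide_top.is_hydrogen()
    center_xy = np.array([box[0] / 2, box[1] / 2])
    coords[:, :2] += center_xy - coords[pep_heavy_mask, :2].mean(axis=0)
    z_top = bil_pos[:, 2].max()
    coords[:, 2] += (z_top + separation) - coords[pep_heavy_mask, 2].min()
    # raise further until the true 3D minimum distance clears the separation
    for _ in range(50):
        d = min_image_distance_matrix(coords[pep_heavy_mask], bil_pos, box)
        gap = d.min()
        if gap >= separation:
            break
        coords[:, 2] += separation - gap
    if coords[pep_heavy_mask, 2].max() >= box[2]:
        raise ValueError("bilayer box too small to hold the peptide at the "
                         "requested separation")

    helix = fit_helix_axis(Frame(coords, box), all_pep, residue_range)
    frames = []
    combined = concatenate_topologies(peptide_top, bilayer_top)
    for ang in rotations:
        rc = rotate_about_axis(coords, helix.axis, helix.point, float(ang))
        # re-establish the clearance for this rotated copy
        for _ in range(50):
            d = min_image_distance_matrix(rc[pep_heavy_mask], bil_pos, box)
            gap = d.min()
            if gap >= separation:
                break
            rc = rc + np.array([0.0, 0.0, separation - gap + 1e-6])
        if rc[pep_heavy_mask, 2].max() >= box[2]:
            raise ValueError("bilayer box too small to hold the peptide at "
                             "the requested separation")
        frames.append(Frame(np.vstack([rc, bilayer_frame.coordinates]),
                            box, time=0.0))
    return combined, frames
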