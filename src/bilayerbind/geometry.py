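"""Depth coordinates, leaflet assignment, adsorption timelines, contacts.

The bilayer normal is assumed to be the z axis throughout.  Depths are
measured relative either to the proximal leaflet's mean phosphorus plane
(the convention used for per-residue depth profiles) or to the bilayer
midplane (used for density profiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (AtomGroup, Frame, Topology, Trajectory,
                   min_image_distance_matrix, min_image_vector,
                   periodic_mean, unwrap_molecules)

MAINCHAIN_NAMES = ("N", "CA", "C", "O")

#: operational adsorption definition: residue centroid within this height
#: above the proximal phosphorus plane, sustained for at least this long
DEFAULT_Z_THRESHOLD = 0.3   # nm
DEFAULT_DWELL = 1.0         # ns

#: heavy-atom contact cutoff (a common literature convention)
DEFAULT_CONTACT_CUTOFF = 0.45  # nm


@dataclass
class BilayerReference:
    """Leaflet assignment and the z = 0 conventions for one frame."""

    upper_mean_z: float
    lower_mean_z: float
    midplane_z: float
    proximal: str                      # "upper" | "lower"
    leaflet_of_molecule: dict[int, str]

    @property
    def proximal_mean_z(self) -> float:
        return self.upper_mean_z if self.proximal == "upper" else self.lower_mean_z

    def reference_z(self, convention: str) -> float:
        if convention == "phosphorus_plane":
            return self.proximal_mean_z
        if convention == "bilayer_center":
            return self.midplane_z
        raise ValueError(f"unknown depth convention {convention!r}")


def _split_leaflets(z: np.ndarray, box_lz: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Split phosphorus z values into two leaflets by the largest gap.

    Values are first recentred with a periodic mean so a bilayer wrapped
    across the z boundary is handled.  Returns boolean masks (upper, lower).
    """
    center = periodic_mean(z, box_lz)
    zr = center + min_image_vector(center, z, np.asarray(box_lz))
    order = np.argsort(zr)
    zs = zr[order]
    gaps = np.diff(zs)
    if len(gaps) == 0 or gaps.max() < 0.3:
        raise ValueError(
            "cannot separate two leaflets from phosphorus z positions "
            "(all phosphorus atoms appear to lie in one plane)")
    k = int(np.argmax(gaps))
    lower = np.zeros(len(z), dtype=bool)
    lower[order[: k + 1]] = True
    return ~lower, lower


def bilayer_reference(frame: Frame, phosphorus: AtomGroup,
                      peptide: AtomGroup) -> BilayerReference:
    """Leaflet means, midplane, and which leaflet the peptide is nearest.

    Lipid molecules are unwrapped along z before assignment so a molecule
    split across the periodic boundary cannot corrupt the plane estimate.
    """
    if len(phosphorus) < 2:
        raise ValueError("need at least two phosphorus atoms")
    top = phosphorus.topology
    coords = unwrap_molecules(frame, top, axis=2)
    pz = coords[phosphorus.indices, 2]
    upper, lower = _split_leaflets(pz, frame.box[2])
    # recenter both leaflets consistently with the periodic mean used above
    center = periodic_mean(pz, frame.box[2])
    pz = center + min_image_vector(center, pz, np.asarray(frame.box[2]))
    zu = float(pz[upper].mean())
    zl = float(pz[lower].mean())
    if zu < zl:
        zu, zl = zl, zu
        upper, lower = lower, upper
    mid = 0.5 * (zu + zl)
    mols = top.molids[phosphorus.indices]
    leaflet_of_molecule = {int(m): ("upper" if u else "lower")
                           for m, u in zip(mols, upper)}
    pep_z = float(np.mean(coords[peptide.indices, 2])) if len(peptide) else mid
    # compare with minimum-image separation in z
    du = abs(min_image_vector(zu, pep_z, np.asarray(frame.box[2])))
    dl = abs(min_image_vector(zl, pep_z, np.asarray(frame.box[2])))
    proximal = "upper" if du <= dl else "lower"
    return BilayerReference(upper_mean_z=zu, lower_mean_z=zl, midplane_z=mid,
                            proximal=proximal,
                            leaflet_of_molecule=leaflet_of_molecule)


# ---------------------------------------------------------------------------
# residue centroids and depth profiles
# ---------------------------------------------------------------------------

def _residue_indices(peptide: AtomGroup) -> list[tuple[int, np.ndarray]]:
    top = peptide.topology
    resids = top.resids[peptide.indices]
    out = []
    for rid in np.unique(resids):
        out.append((int(rid), peptide.indices[resids == rid]))
    return out


def _part_mask(top: Topology, idx: np.ndarray, part: str) -> np.ndarray:
    names = top.names[idx].astype(str)
    is_h = top.is_hydrogen()[idx]
    if part == "mainchain":
        return np.isin(names, MAINCHAIN_NAMES)
    if part == "sidechain":
        return ~np.isin(names, MAINCHAIN_NAMES) & ~is_h
    if part == "whole":
        return np.ones(len(idx), dtype=bool)
    raise ValueError(f"unknown residue part {part!r}")


def residue_centroid_z(frame: Frame, peptide: AtomGroup, part: str
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(resids, centroid z) for each peptide residue; unweighted centroid.

    Residues with no atom of the requested part (e.g. glycine side chains)
    get NaN.
    """
    top = peptide.topology
    resids, zvals = [], []
    for rid, idx in _residue_indices(peptide):
        mask = _part_mask(top, idx, part)
        resids.append(rid)
        zvals.append(float(frame.coordinates[idx[mask], 2].mean())
                     if mask.any() else np.nan)
    return np.array(resids), np.array(zvals)


def relative_z(z, z0: float, box_lz: float) -> np.ndarray:
    """Minimum-image z offset from a reference plane (handles the plane
    and the atoms sitting in different periodic images)."""
    return min_image_vector(z0, np.asarray(z, dtype=float),
                            np.asarray(box_lz))


def depth_profile(frame: Frame, peptide: AtomGroup, ref: BilayerReference,
                  convention: str = "phosphorus_plane") -> pd.DataFrame:
    """Per-residue depth table: mainchain/side-chain centroid and Cα z (nm)
    relative to the chosen reference plane."""
    z0 = ref.reference_z(convention)
    resids, main_z = residue_centroid_z(frame, peptide, "mainchain")
    _, side_z = residue_centroid_z(frame, peptide, "sidechain")
    top = peptide.topology
    ca_z = np.full(len(resids), np.nan)
    for i, rid in enumerate(resids):
        idx = peptide.indices[(top.resids[peptide.indices] == rid)
                              & (top.names[peptide.indices].astype(str) == "CA")]
        if len(idx):
            ca_z[i] = frame.coordinates[idx[0], 2]
    lz = frame.box[2]
    return pd.DataFrame({
        "resid": resids,
        "mainchain_z": relative_z(main_z, z0, lz),
        "sidechain_z": relative_z(side_z, z0, lz),
        "ca_z": relative_z(ca_z, z0, lz),
        "convention": convention,
    })


def closest_residue(frame: Frame, peptide: AtomGroup, ref: BilayerReference,
                    part: str = "whole") -> int:
    """Residue whose centroid sits lowest (closest to the bilayer surface).

    Ties break toward the lower residue index.  Assumes the water side of
    the proximal leaflet is at positive z relative to its phosphorus plane.
    """
    resids, z = residue_centroid_z(frame, peptide, part)
    z = relative_z(z, ref.proximal_mean_z, frame.box[2])
    if ref.proximal == "lower":
        z = -z
    valid = ~np.isnan(z)
    zv = np.where(valid, z, np.inf)
    return int(resids[int(np.argmin(zv))])


def closest_residue_timeline(traj: Trajectory, peptide: AtomGroup,
                             phosphorus: AtomGroup, part: str = "whole"
                             ) -> pd.DataFrame:
    rows = []
    for fr in traj:
        ref = bilayer_reference(fr, phosphorus, peptide)
        rows.append((fr.time, closest_residue(fr, peptide, ref, part)))
    return pd.DataFrame(rows, columns=["time", "closest_resid"])


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contact_count(frame: Frame, group_a: AtomGroup, group_b: AtomGroup,
                  cutoff: float = DEFAULT_CONTACT_CUTOFF) -> int:
    """Number of heavy-atom pairs (a in A, b in B) closer than ``cutoff``
    under minimum-image distances."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if group_a.overlaps(group_b):
        raise ValueError("contact groups must not overlap")
    a = group_a.heavy()
    b = group_b.heavy()
    if not len(a) or not len(b):
        return 0
    d = min_image_distance_matrix(a.positions(frame), b.positions(frame),
                                  frame.box)
    return int(np.count_nonzero(d < cutoff))


def contact_timeseries(traj: Trajectory, group_a: AtomGroup,
                       group_b: AtomGroup,
                       cutoff: float = DEFAULT_CONTACT_CUTOFF) -> pd.DataFrame:
    rows = [(fr.time, contact_count(fr, group_a, group_b, cutoff))
            for fr in traj]
    return pd.DataFrame(rows, columns=["time", "contacts"])


# ---------------------------------------------------------------------------
# adsorption
# ---------------------------------------------------------------------------

N_TERMINAL_RANGE = (1, 19)
C_TERMINAL_RANGE = (20, 37)


@dataclass
class AdsorptionReport:
    """First sustained-surface-contact time per residue plus which terminal
    region initiated adsorption."""

    first_adsorption_time: pd.Series    # indexed by resid; NaN = never
    initiating_region: str              # "N-terminal" | "C-terminal" | "none"
    z_threshold: float
    dwell: float


def _first_sustained_time(times: np.ndarray, below: np.ndarray,
                          dwell: float) -> float:
    """Start time of the first run of True spanning at least ``dwell``."""
    i = 0
    n = len(times)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if times[j] - times[i] >= dwell:
                return float(times[i])
            i = j + 1
        else:
            i += 1
    return np.nan


def adsorption_report(traj: Trajectory, peptide: AtomGroup,
                      phosphorus: AtomGroup, part: str = "whole",
                      z_threshold: float = DEFAULT_Z_THRESHOLD,
                      dwell: float = DEFAULT_DWELL) -> AdsorptionReport:
    """Detect per-residue adsorption: centroid z below ``z_threshold`` above
    the proximal phosphorus plane, sustained for at least ``dwell`` ns."""
    times = traj.times
    if times[-1] - times[0] < dwell:
        raise ValueError("trajectory shorter than the dwell requirement")
    z_rel = []
    resids = None
    for fr in traj:
        ref = bilayer_reference(fr, phosphorus, peptide)
        r, z = residue_centroid_z(fr, peptide, part)
        z = relative_z(z, ref.proximal_mean_z, fr.box[2])
        if ref.proximal == "lower":
            z = -z
        resids = r
        z_rel.append(z)
    z_rel = np.array(z_rel)                      # (n_frames, n_residues)
    below = z_rel < z_threshold
    first = np.array([_first_sustained_time(times, below[:, j], dwell)
                      for j in range(len(resids))])
    series = pd.Series(first, index=pd.Index(resids, name="resid"),
                       name="first_adsorption_time")
    if np.all(np.isnan(first)):
        region = "none"
    else:
        # earliest adsorbed residue; ties toward the lower residue index
        t_min = np.nanmin(first)
        rid = int(resids[np.flatnonzero(first == t_min)[0]])
        region = ("N-terminal"
                  if N_TERMINAL_RANGE[0] <= rid <= N_TERMINAL_RANGE[1]
                  else "C-terminal")
    return AdsorptionReport(series, region, z_threshold, dwell)
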