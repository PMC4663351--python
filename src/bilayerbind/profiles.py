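"""Bilayer-level observables: electron density, S_CD, thickness, area/lipid.

Electron density bins atom electron counts (atomic number plus implicit
hydrogens; CH2 -> 8, CH3 -> 9) along z relative to the per-frame bilayer
midplane.  The acyl-chain order parameter is

    S_CD = 0.5 < 3 cos^2(theta) - 1 >,

theta being the angle between a C-H bond vector and the bilayer normal,
averaged over both hydrogens, lipids, and frames.  For united-atom chains
the two C-H directions of each CH2 are reconstructed assuming ideal
tetrahedral geometry from the two neighbouring chain carbons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (AtomGroup, Frame, Topology, Trajectory,
                   min_image_distance_matrix, min_image_vector)
from .geometry import bilayer_reference

DEFAULT_BIN_WIDTH = 0.05  # nm

#: half the ideal tetrahedral H-C-H angle
_TETRAHEDRAL_HALF = np.radians(109.47122063449069 / 2.0)


# ---------------------------------------------------------------------------
# electron density
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    bin_centers: np.ndarray        # nm, relative to bilayer center
    density: np.ndarray            # e nm^-3, frame-averaged
    label: str
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.bin_centers,
                             "electron_density": self.density,
                             "group": self.label})


def electron_density(traj: Trajectory, group: AtomGroup,
                     phosphorus: AtomGroup,
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     label: str | None = None) -> DensityProfile:
    """Electron density of ``group`` along z, bilayer center at z = 0.

    Each atom contributes its full electron count to the bin containing
    its midplane-relative z, so the profile integrates exactly to the
    group's total electrons divided by the lateral area.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if not len(group):
        raise ValueError("empty atom group")
    top = traj.topology
    electrons = top.electrons()[group.indices]
    lz_max = max(fr.box[2] for fr in traj)
    k = int(np.ceil(0.5 * lz_max / bin_width)) + 1
    edges = np.arange(-k, k + 1) * bin_width
    acc = np.zeros(len(edges) - 1)
    for fr in traj:
        ref = bilayer_reference(fr, phosphorus, AtomGroup(top, np.array([], int)))
        z = fr.coordinates[group.indices, 2]
        z_rel = min_image_vector(ref.midplane_z, z, np.asarray(fr.box[2]))
        hist, _ = np.histogram(z_rel, bins=edges, weights=electrons)
        area = fr.box[0] * fr.box[1]
        acc += hist / (area * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, acc / traj.n_frames,
                          label if label is not None else group.label,
                          bin_width)


# ---------------------------------------------------------------------------
# order parameter
# ---------------------------------------------------------------------------

def scd_from_vectors(vectors: np.ndarray) -> float:
    """S_CD of a set of C-H bond vectors against the z axis."""
    v = np.asarray(vectors, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    cos2 = (v[:, 2] / np.linalg.norm(v, axis=1)) ** 2
    return float(0.5 * np.mean(3.0 * cos2 - 1.0))


def reconstruct_ch_cos2(prev: np.ndarray, this: np.ndarray,
                        nxt: np.ndarray, box: np.ndarray) -> np.ndarray:
    """cos^2(theta) of the two reconstructed C-H vectors of a CH2 carbon.

    Input arrays are (n, 3) positions of the previous, central, and next
    chain carbons; the hydrogens are placed in the plane perpendicular to
    the C(i-1)->C(i+1) direction, opposite the bond bisector, at ideal
    tetrahedral angles.
    """
    u = min_image_vector(prev, nxt, box)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    b1 = min_image_vector(this, prev, box)
    b2 = min_image_vector(this, nxt, box)
    v = b1 + b2
    # remove any component along the chain direction, then normalize
    v -= np.einsum("ij,ij->i", v, u)[:, None] * u
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("collinear chain carbons: cannot reconstruct C-H")
    a = -v / norm
    w = np.cross(u, a)
    h1 = np.cos(_TETRAHEDRAL_HALF) * a + np.sin(_TETRAHEDRAL_HALF) * w
    h2 = np.cos(_TETRAHEDRAL_HALF) * a - np.sin(_TETRAHEDRAL_HALF) * w
    return np.concatenate([h1[:, 2] ** 2, h2[:, 2] ** 2])


@dataclass
class OrderParameterProfile:
    carbon_index: np.ndarray     # 1-based position along the chain
    scd: np.ndarray              # NaN where not computable (terminal carbons)
    n_samples: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"carbon": self.carbon_index, "scd": self.scd,
                             "n_samples": self.n_samples})


def tail_chain_map(topology: Topology, prefix: str = "C",
                   kind: str = "lipid") -> np.ndarray:
    """Per-lipid ordered tail-carbon index array, matching names like C1,
    C2, ... within each lipid molecule."""
    chains = []
    for mol in np.unique(topology.molids[topology.molkinds == kind]):
        idx = np.flatnonzero(topology.molids == mol)
        carbons = [(int(str(topology.names[i])[len(prefix):]), i)
                   for i in idx
                   if str(topology.names[i]).startswith(prefix)
                   and str(topology.names[i])[len(prefix):].isdigit()]
        if carbons:
            chains.append([i for _, i in sorted(carbons)])
    if not chains:
        raise ValueError("no tail chains found")
    lengths = {len(c) for c in chains}
    if len(lengths) != 1:
        raise ValueError("tail chains have unequal lengths")
    return np.array(chains, dtype=int)


def order_parameter(traj: Trajectory, chain_map: np.ndarray,
                    hydrogens: str = "reconstructed",
                    near_group: AtomGroup | None = None,
                    near_cutoff: float = 1.0) -> OrderParameterProfile:
    """sn-1 chain order parameter per carbon position.

    ``chain_map`` is (n_lipids, n_carbons) of atom indices, ordered from
    the glycerol end.  With ``near_group`` set, only lipids whose minimum
    heavy-atom distance to that group's heavy atoms is below
    ``near_cutoff`` contribute (the "lipids near the peptide" filter).
    Terminal carbons, which lack a reconstruction neighbour, are reported
    as NaN with zero samples, not as zero.
    """
    chain_map = np.asarray(chain_map, dtype=int)
    n_lipids, n_carbons = chain_map.shape
    if n_carbons < 3:
        raise ValueError("chains need at least three carbons for "
                         "C-H reconstruction")
    if hydrogens not in ("reconstructed", "explicit"):
        raise ValueError(f"unknown hydrogen mode {hydrogens!r}")
    top = traj.topology
    sum_cos2 = np.zeros(n_carbons)
    counts = np.zeros(n_carbons, dtype=int)
    for fr in traj:
        rows = np.arange(n_lipids)
        if near_group is not None:
            heavy = near_group.heavy()
            keep = []
            for li in range(n_lipids):
                mol = top.molids[chain_map[li, 0]]
                lip_idx = np.flatnonzero((top.molids == mol)
                                         & ~top.is_hydrogen())
                dmin = min_image_distance_matrix(
                    fr.coordinates[lip_idx], heavy.positions(fr),
                    fr.box).min()
                if dmin < near_cutoff:
                    keep.append(li)
            rows = np.array(keep, dtype=int)
            if not len(rows):
                continue
        coords = fr.coordinates
        if hydrogens == "reconstructed":
            for ci in range(1, n_carbons - 1):
                cos2 = reconstruct_ch_cos2(coords[chain_map[rows, ci - 1]],
                                           coords[chain_map[rows, ci]],
                                           coords[chain_map[rows, ci + 1]],
                                           fr.box)
                sum_cos2[ci] += cos2.sum()
                counts[ci] += len(cos2)
        else:
            is_h = top.is_hydrogen()
            for ci in range(n_carbons):
                for li in rows:
                    c = chain_map[li, ci]
                    hs = np.flatnonzero((top.molids == top.molids[c])
                                        & (top.resids == top.resids[c])
                                        & is_h)
                    for h in hs:
                        v = min_image_vector(coords[c], coords[h], fr.box)
                        r = np.linalg.norm(v)
                        if r <= 0.125:
                            sum_cos2[ci] += (v[2] / r) ** 2
                            counts[ci] += 1
    scd = np.full(n_carbons, np.nan)
    ok = counts > 0
    scd[ok] = 0.5 * (3.0 * sum_cos2[ok] / counts[ok] - 1.0)
    return OrderParameterProfile(np.arange(1, n_carbons + 1), scd, counts)


# ---------------------------------------------------------------------------
# thickness and area per lipid
# ---------------------------------------------------------------------------

@dataclass
class ThicknessResult:
    thickness: float               # nm, frame-averaged P-P distance
    cutoff: float | None           # nm from peptide, None = all lipids
    mean_lipid_count: float


def thickness(traj: Trajectory, phosphorus: AtomGroup,
              peptide: AtomGroup | None = None,
              cutoff: float | None = None) -> ThicknessResult:
    """Mean phosphorus-to-phosphorus bilayer thickness.

    With a cutoff, only lipids whose minimum *lateral* (xy) heavy-atom
    distance to any peptide heavy atom is below ``cutoff`` enter the
    leaflet means (local thickness under the peptide's footprint); the
    lateral metric keeps the distal leaflet selectable, which a 3D
    distance from a surface-bound peptide would not.  Each leaflet must
    keep at least one lipid.
    """
    if cutoff is not None and peptide is None:
        raise ValueError("local thickness needs a peptide group")
    top = traj.topology
    total = 0.0
    total_count = 0.0
    for fr in traj:
        ref = bilayer_reference(fr, phosphorus,
                                peptide if peptide is not None
                                else AtomGroup(top, np.array([], int)))
        p_idx = phosphorus.indices
        include = np.ones(len(p_idx), dtype=bool)
        if cutoff is not None:
            pep_heavy = peptide.heavy()
            pep_xy = np.column_stack([pep_heavy.positions(fr)[:, :2],
                                      np.zeros(len(pep_heavy))])
            for k, pi in enumerate(p_idx):
                mol = top.molids[pi]
                lip_idx = np.flatnonzero((top.molids == mol)
                                         & ~top.is_hydrogen())
                lip_xy = np.column_stack([fr.coordinates[lip_idx, :2],
                                          np.zeros(len(lip_idx))])
                dmin = min_image_distance_matrix(lip_xy, pep_xy,
                                                 fr.box).min()
                include[k] = dmin < cutoff
        leaflets = np.array([ref.leaflet_of_molecule[int(top.molids[pi])]
                             for pi in p_idx])
        # re-image each P onto the midplane's side of the box
        z = ref.midplane_z + min_image_vector(
            ref.midplane_z, fr.coordinates[p_idx, 2], np.asarray(fr.box[2]))
        up = include & (leaflets == "upper")
        lo = include & (leaflets == "lower")
        if not up.any() or not lo.any():
            raise ValueError(
                "a leaflet has no lipids within the cutoff; use a larger "
                "cutoff")
        total += float(z[up].mean() - z[lo].mean())
        total_count += int(include.sum())
    return ThicknessResult(total / traj.n_frames, cutoff,
                           total_count / traj.n_frames)


def area_per_lipid(traj: Trajectory, lipids_per_leaflet: int) -> float:
    """Time-averaged lateral box area per lipid (nm^2)."""
    if lipids_per_leaflet <= 0:
        raise ValueError("lipids_per_leaflet must be positive")
    areas = np.array([fr.box[0] * fr.box[1] for fr in traj])
    return float(areas.mean() / lipids_per_leaflet)
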