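"""Geometric hydrogen-bond detection and aggregation by lipid group.

A hydrogen bond D-H...A is counted when, simultaneously,

* the donor-acceptor heavy-atom distance is below 0.35 nm,
* the hydrogen-acceptor distance is below 0.25 nm, and
* the D-H...A angle (vertex at the hydrogen) exceeds 150 degrees,

all under minimum-image distances.  Donor and acceptor capability comes
from per-atom flags in the parameter sidecar, so both peptide-donor and
lipid-donor bonds are countable.  Note the angle vertex: GROMACS's hbond
tool uses a donor-vertex angle convention, so exact parity with it is not
claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AtomGroup, Frame, Trajectory, min_image_vector

#: maximum covalent D-H bond length used to attach hydrogens to donors
MAX_DH_BOND = 0.125  # nm


@dataclass(frozen=True)
class HBondCriterion:
    """Distance/angle thresholds of the geometric criterion."""

    max_da_distance: float = 0.35   # nm, donor-acceptor heavy atoms
    max_ha_distance: float = 0.25   # nm, hydrogen-acceptor
    min_dha_angle: float = 150.0    # degrees, vertex at hydrogen

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.max_ha_distance <= 0:
            raise ValueError("distance thresholds must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle threshold must lie in (0, 180]")


@dataclass(frozen=True)
class HBondRecord:
    time: float
    donor: int
    hydrogen: int
    acceptor: int
    donor_resid: int
    acceptor_label: str = ""


def donor_hydrogen_pairs(frame: Frame, group: AtomGroup
                         ) -> list[tuple[int, int]]:
    """(donor, hydrogen) index pairs for donor-capable heavy atoms.

    Hydrogens are attached geometrically: element-H atoms of the same
    residue within ``MAX_DH_BOND`` of the donor.  A donor-flagged heavy
    atom with no attached hydrogen is an error (the criterion cannot be
    evaluated for it).
    """
    top = group.topology
    is_h = top.is_hydrogen()
    donors = group.indices[top.donor[group.indices]
                           & ~is_h[group.indices]]
    hydrogens = group.indices[is_h[group.indices]]
    pairs: list[tuple[int, int]] = []
    for d in donors:
        same_res = hydrogens[(top.molids[hydrogens] == top.molids[d])
                             & (top.resids[hydrogens] == top.resids[d])]
        attached = []
        for h in same_res:
            v = min_image_vector(frame.coordinates[d], frame.coordinates[h],
                                 frame.box)
            if np.linalg.norm(v) <= MAX_DH_BOND:
                attached.append(int(h))
        if not attached:
            raise ValueError(
                f"donor atom {top.names[d]} (index {d}, residue "
                f"{top.resnames[d]}{top.resids[d]}) has no attached hydrogen")
        pairs.extend((int(d), h) for h in attached)
    return pairs


def detect_hbonds(frame: Frame, donors: AtomGroup, acceptors: AtomGroup,
                  criterion: HBondCriterion = HBondCriterion(),
                  acceptor_label: str = "") -> list[HBondRecord]:
    """All (D, H, A) triples satisfying the geometric criterion.

    ``donors`` supplies donor-capable heavy atoms together with their
    hydrogens; ``acceptors`` supplies acceptor-capable heavy atoms.
    """
    top = donors.topology
    acc = acceptors.indices[top.acceptor[acceptors.indices]
                            & ~top.is_hydrogen()[acceptors.indices]]
    pairs = donor_hydrogen_pairs(frame, donors)
    if not pairs or not len(acc):
        return []
    d_idx = np.array([p[0] for p in pairs])
    h_idx = np.array([p[1] for p in pairs])
    coords = frame.coordinates
    box = frame.box
    # vector tables: (n_pairs, n_acceptors, 3)
    v_da = min_image_vector(coords[d_idx][:, None, :],
                            coords[acc][None, :, :], box)
    v_ha = min_image_vector(coords[h_idx][:, None, :],
                            coords[acc][None, :, :], box)
    v_hd = min_image_vector(coords[h_idx], coords[d_idx], box)
    r_da = np.linalg.norm(v_da, axis=-1)
    r_ha = np.linalg.norm(v_ha, axis=-1)
    r_hd = np.linalg.norm(v_hd, axis=-1)
    cos_angle = np.einsum("pk,pak->pa", v_hd, v_ha) / (
        r_hd[:, None] * np.where(r_ha > 0, r_ha, np.inf))
    angle = np.degrees(np.arccos(np.clip(cos_angle, -1.0, 1.0)))
    ok = ((r_da < criterion.max_da_distance)
          & (r_ha < criterion.max_ha_distance)
          & (angle > criterion.min_dha_angle)
          & (d_idx[:, None] != acc[None, :]))
    records = []
    for p, a in zip(*np.nonzero(ok)):
        records.append(HBondRecord(
            time=frame.time, donor=int(d_idx[p]), hydrogen=int(h_idx[p]),
            acceptor=int(acc[a]), donor_resid=int(top.resids[d_idx[p]]),
            acceptor_label=acceptor_label))
    return records


def count_hbonds_between(frame: Frame, group_a: AtomGroup,
                         group_b: AtomGroup,
                         criterion: HBondCriterion = HBondCriterion(),
                         directions: str = "both") -> int:
    """H-bonds between two groups, counting A-donor, B-donor, or both."""
    n = 0
    if directions in ("both", "a_donor"):
        n += len(detect_hbonds(frame, group_a, group_b, criterion))
    if directions in ("both", "b_donor"):
        n += len(detect_hbonds(frame, group_b, group_a, criterion))
    return n


def hbond_timeseries(traj: Trajectory, group_a: AtomGroup,
                     group_b: AtomGroup,
                     criterion: HBondCriterion = HBondCriterion(),
                     directions: str = "both") -> pd.DataFrame:
    rows = [(fr.time,
             count_hbonds_between(fr, group_a, group_b, criterion, directions))
            for fr in traj]
    return pd.DataFrame(rows, columns=["time", "hbonds"])


def hbonds_by_lipid_group(traj: Trajectory, peptide: AtomGroup,
                          group_map: dict[str, AtomGroup],
                          criterion: HBondCriterion = HBondCriterion(),
                          directions: str = "both") -> pd.DataFrame:
    """Mean H-bond count per frame, resolved by peptide residue and lipid
    chemical group (choline/glycerol, phosphate, ester).

    Both bonding directions (peptide donor and lipid donor) are included
    by default; a bond is attributed to the peptide residue involved.
    """
    labels = list(group_map)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            if group_map[la].overlaps(group_map[lb]):
                raise ValueError(
                    f"lipid groups {la!r} and {lb!r} overlap")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory window")
    top = peptide.topology
    resids = np.unique(top.resids[peptide.indices])
    counts = pd.DataFrame(0.0, index=pd.Index(resids, name="resid"),
                          columns=labels)
    for fr in traj:
        for label in labels:
            grp = group_map[label]
            if directions in ("both", "peptide_donor"):
                for rec in detect_hbonds(fr, peptide, grp, criterion, label):
                    counts.loc[rec.donor_resid, label] += 1
            if directions in ("both", "lipid_donor"):
                for rec in detect_hbonds(fr, grp, peptide, criterion, label):
                    rid = int(top.resids[rec.acceptor])
                    counts.loc[rid, label] += 1
    return counts / traj.n_frames
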