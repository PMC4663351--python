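"""Cutoff nonbonded interaction energies between atom groups.

For pairwise-additive potentials the group interaction energy
U_inter = U(A+B) - U(A) - U(B) equals the direct sum over cross-group
pairs, which is what these routines evaluate: plain-cutoff Coulomb
(no Ewald reciprocal term) plus C6/C12 Lennard-Jones, under minimum-image
distances.  Absolute magnitudes therefore differ from a PME engine's; the
decomposition is meant for signs, rankings, and time evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AtomGroup, Frame, Trajectory, min_image_vector

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_PREFACTOR = 138.935458

DEFAULT_COULOMB_CUTOFF = 1.2  # nm
DEFAULT_LJ_CUTOFF = 1.4       # nm


@dataclass(frozen=True)
class NonbondedSettings:
    coulomb_cutoff: float = DEFAULT_COULOMB_CUTOFF
    lj_cutoff: float = DEFAULT_LJ_CUTOFF
    coulomb_prefactor: float = COULOMB_PREFACTOR

    def __post_init__(self) -> None:
        if self.coulomb_cutoff <= 0 or self.lj_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class EnergyDecomposition:
    electrostatic: float   # kJ/mol
    vdw: float             # kJ/mol
    normalization: str = "raw"

    @property
    def total(self) -> float:
        return self.electrostatic + self.vdw

    def per_lipid(self, n_lipids: int) -> "EnergyDecomposition":
        if n_lipids <= 0:
            raise ValueError("per-lipid normalization needs at least one lipid")
        return EnergyDecomposition(self.electrostatic / n_lipids,
                                   self.vdw / n_lipids, "per-lipid")


def coulomb_pair(r: float, q1: float, q2: float,
                 settings: NonbondedSettings = NonbondedSettings()) -> float:
    """Point-charge Coulomb energy, zero beyond the cutoff."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r >= settings.coulomb_cutoff:
        return 0.0
    return settings.coulomb_prefactor * q1 * q2 / r


def lj_pair(r: float, c6: float, c12: float,
            settings: NonbondedSettings = NonbondedSettings()) -> float:
    """C6/C12 Lennard-Jones energy, zero beyond the cutoff."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r >= settings.lj_cutoff:
        return 0.0
    return c12 / r**12 - c6 / r**6


def group_interaction(frame: Frame, group_a: AtomGroup, group_b: AtomGroup,
                      settings: NonbondedSettings = NonbondedSettings()
                      ) -> EnergyDecomposition:
    """Cross-group pair sum of Coulomb and LJ terms (kJ/mol).

    Groups must be disjoint; no intramolecular or exclusion bookkeeping is
    needed because only cross pairs are summed.
    """
    if group_a.overlaps(group_b):
        raise ValueError("interaction groups must not overlap")
    top = group_a.topology
    pa = group_a.positions(frame)
    pb = group_b.positions(frame)
    if not len(pa) or not len(pb):
        return EnergyDecomposition(0.0, 0.0)
    d = min_image_vector(pa[:, None, :], pb[None, :, :], frame.box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    if np.any(r == 0):
        raise ValueError("coincident atoms across groups (r = 0)")
    qq = np.outer(top.charges[group_a.indices], top.charges[group_b.indices])
    elec = np.where(r < settings.coulomb_cutoff,
                    settings.coulomb_prefactor * qq / r, 0.0).sum()
    # Lorentz-Berthelot-style geometric combination of C6/C12
    c6 = np.sqrt(np.outer(top.c6[group_a.indices], top.c6[group_b.indices]))
    c12 = np.sqrt(np.outer(top.c12[group_a.indices], top.c12[group_b.indices]))
    inv6 = 1.0 / r**6
    vdw = np.where(r < settings.lj_cutoff,
                   c12 * inv6**2 - c6 * inv6, 0.0).sum()
    return EnergyDecomposition(float(elec), float(vdw))


def interaction_timeseries(traj: Trajectory, group_a: AtomGroup,
                           group_b: AtomGroup,
                           settings: NonbondedSettings = NonbondedSettings(),
                           normalization: str = "raw") -> pd.DataFrame:
    """Per-frame electrostatic/vdW/total energies (kJ/mol).

    ``normalization="per-lipid"`` divides by the number of lipid molecules
    in the topology (all of them, not only contacting ones).
    """
    top = traj.topology
    scale = 1.0
    if normalization == "per-lipid":
        n_lip = len(np.unique(top.molids[top.molkinds == "lipid"]))
        if n_lip == 0:
            raise ValueError("per-lipid normalization with zero lipids")
        scale = 1.0 / n_lip
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    rows = []
    for fr in traj:
        e = group_interaction(fr, group_a, group_b, settings)
        rows.append((fr.time, e.electrostatic * scale, e.vdw * scale,
                     e.total * scale))
    return pd.DataFrame(rows, columns=["time", "electrostatic", "vdw",
                                       "total"])
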