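"""Structure/trajectory I/O and the parameter sidecar.

File formats (GRO, PDB, XTC, TRR) are read and written through MDAnalysis;
this module converts to the package's internal nm/ns containers and merges
per-atom parameters from a YAML sidecar keyed by (residue name, atom name).

Sidecar layout::

    residues:
      POPC:
        kind: lipid
        atoms:
          P:  {element: P, charge: 0.8, c6: 0.0, c12: 0.0, nh: 0,
               donor: false, acceptor: false}
          ...

A lipid-group map is a second YAML file of label -> selection expression,
e.g. ``{phosphate: "lipid and name P OP1 OP2"}``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import yaml

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .core import AtomGroup, Frame, Topology, Trajectory, select

A_PER_NM = 10.0
PS_PER_NS = 1000.0

_STRUCTURE_SUFFIXES = {".gro", ".pdb"}
_BINARY_TRAJ_SUFFIXES = {".xtc", ".trr"}


# ---------------------------------------------------------------------------
# sidecar
# ---------------------------------------------------------------------------

def read_sidecar(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "residues" not in data:
        raise ValueError(f"sidecar {path} lacks a 'residues' section")
    return data


def write_sidecar(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _atom_params(sidecar: dict, resname: str, name: str) -> dict:
    res = sidecar["residues"].get(resname)
    if res is None:
        raise KeyError(f"residue {resname!r} not in parameter sidecar")
    par = res.get("atoms", {}).get(name)
    if par is None:
        raise KeyError(
            f"atom {name!r} of residue {resname!r} not in parameter sidecar")
    return par


def _assign_molids(resids: np.ndarray, resnames: np.ndarray,
                   kinds: np.ndarray) -> np.ndarray:
    """One molecule per residue, except contiguous peptide residues which
    form a single chain molecule."""
    molids = np.zeros(len(resids), dtype=int)
    mol = -1
    prev_key = None
    prev_kind = None
    for i, (rid, rn, kind) in enumerate(zip(resids, resnames, kinds)):
        key = (rid, rn)
        if key != prev_key:
            if not (kind == "peptide" and prev_kind == "peptide"):
                mol += 1
            prev_key = key
            prev_kind = kind
        molids[i] = mol
    return molids


def topology_from_atoms(names, resids, resnames, sidecar: dict) -> Topology:
    """Build a Topology by looking every atom up in the sidecar."""
    names = np.asarray(names, dtype=object)
    resids = np.asarray(resids, dtype=int)
    resnames = np.asarray(resnames, dtype=object)
    n = len(names)
    elements = np.empty(n, dtype=object)
    charges = np.zeros(n)
    c6 = np.zeros(n)
    c12 = np.zeros(n)
    nh = np.zeros(n, dtype=int)
    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    kinds = np.empty(n, dtype=object)
    for i in range(n):
        par = _atom_params(sidecar, resnames[i], names[i])
        elements[i] = str(par["element"])
        charges[i] = float(par.get("charge", 0.0))
        c6[i] = float(par.get("c6", 0.0))
        c12[i] = float(par.get("c12", 0.0))
        nh[i] = int(par.get("nh", 0))
        donor[i] = bool(par.get("donor", False))
        acceptor[i] = bool(par.get("acceptor", False))
        kinds[i] = sidecar["residues"][resnames[i]].get("kind", "solvent")
    molids = _assign_molids(resids, resnames, kinds)
    return Topology(names=names, elements=elements, resids=resids,
                    resnames=resnames, molids=molids, molkinds=kinds,
                    charges=charges, c6=c6, c12=c12, n_implicit_h=nh,
                    donor=donor, acceptor=acceptor)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _check_orthorhombic(dimensions) -> np.ndarray:
    if dimensions is None or np.all(dimensions[:3] == 0):
        raise ValueError("structure has no box information")
    if not np.allclose(dimensions[3:], 90.0, atol=1e-3):
        raise ValueError("only orthorhombic boxes are supported")
    return np.asarray(dimensions[:3], dtype=float) / A_PER_NM


def load_structure(path, params_path) -> tuple[Topology, Frame]:
    """Read a GRO or PDB structure plus its parameter sidecar.

    Returns the topology and one frame; coordinates are converted to nm
    (MDAnalysis reads both formats in Angstrom internally).
    """
    path = Path(path)
    if path.suffix.lower() not in _STRUCTURE_SUFFIXES:
        raise ValueError(f"unsupported structure format: {path.suffix}")
    sidecar = read_sidecar(params_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    top = topology_from_atoms(u.atoms.names, u.atoms.resids,
                              u.atoms.resnames, sidecar)
    box = _check_orthorhombic(u.dimensions)
    frame = Frame(u.atoms.positions.astype(float) / A_PER_NM, box, time=0.0)
    return top, frame


def write_structure(topology: Topology, frame: Frame, path) -> None:
    """Write a GRO or PDB structure (nm -> format's native unit)."""
    u = _as_universe(topology, frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _as_universe(topology: Topology, frame: Frame) -> "mda.Universe":
    resid_keys = list(dict.fromkeys(
        zip(topology.molids, topology.resids, topology.resnames)))
    res_index = {k: i for i, k in enumerate(resid_keys)}
    atom_resindex = np.array([
        res_index[(m, r, n)] for m, r, n in
        zip(topology.molids, topology.resids, topology.resnames)])
    u = mda.Universe.empty(topology.n_atoms, n_residues=len(resid_keys),
                           atom_resindex=atom_resindex, trajectory=True)
    u.add_TopologyAttr("names", topology.names.astype(str))
    u.add_TopologyAttr("resids", np.array([k[1] for k in resid_keys]))
    u.add_TopologyAttr("resnames", [str(k[2]) for k in resid_keys])
    u.atoms.positions = frame.coordinates * A_PER_NM
    u.dimensions = [*(frame.box * A_PER_NM), 90.0, 90.0, 90.0]
    return u


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def load_trajectory(path, topology: Topology,
                    stride_ns: float = 1.0) -> Trajectory:
    """Read an XTC/TRR or multi-frame PDB trajectory.

    ``stride_ns`` supplies frame times when the file carries none (PDB) or
    carries non-increasing times.
    """
    path = Path(path)
    frames: list[Frame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() in _BINARY_TRAJ_SUFFIXES:
            cls = (mda.coordinates.XTC.XTCReader
                   if path.suffix.lower() == ".xtc"
                   else mda.coordinates.TRR.TRRReader)
            reader = cls(str(path))
        elif path.suffix.lower() == ".pdb":
            reader = mda.Universe(str(path)).trajectory
        else:
            raise ValueError(f"unsupported trajectory format: {path.suffix}")
        for ts in reader:
            box = _check_orthorhombic(ts.dimensions)
            frames.append(Frame(ts.positions.astype(float) / A_PER_NM, box,
                                time=float(ts.time) / PS_PER_NS))
    if not frames:
        raise ValueError(f"empty trajectory: {path}")
    if frames[0].n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory has {frames[0].n_atoms} atoms but topology has "
            f"{topology.n_atoms}")
    times = np.array([fr.time for fr in frames])
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        for i, fr in enumerate(frames):
            fr.time = i * stride_ns
    return Trajectory(topology, frames)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write frames to XTC/TRR (binary) or multi-frame PDB (text)."""
    path = Path(path)
    u = _as_universe(traj.topology, traj.frames[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), traj.topology.n_atoms) as w:
            for fr in traj:
                u.atoms.positions = fr.coordinates * A_PER_NM
                u.dimensions = [*(fr.box * A_PER_NM), 90.0, 90.0, 90.0]
                u.trajectory.ts.time = fr.time * PS_PER_NS
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# lipid group map
# ---------------------------------------------------------------------------

def read_group_map(path, topology: Topology) -> dict[str, AtomGroup]:
    """Load a label -> selection YAML and resolve it against a topology."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"group map {path} must be a mapping")
    return {label: select(topology, expr, label=label)
            for label, expr in raw.items()}


def write_group_map(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(mapping, fh, sort_keys=False)
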