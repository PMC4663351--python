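"""Synthetic bilayer/peptide systems with analytic ground truth.

These generators stand in for molecular-dynamics trajectories: an
idealized planar two-leaflet bilayer of pseudo-lipids, an ideal
alpha-helical peptide with radial side-chain stubs, and scripted
kinematic trajectories (approach, tilt, roll, planted hydrogen bonds).
Every target parameter (area per lipid, P-P thickness, tail tilt and the
S_CD it implies, rotational phase, planted H-bond counts, adsorption
times) is recorded so the analysis modules can be checked against known
answers without running any dynamics.

Each pseudo-lipid is ~12-14 sites: one choline (PC) or glycerol (PG)
head site, the phosphorus with two phosphate oxygens, two ester oxygens,
and an all-trans united-atom sn-1 tail whose tilt from the bilayer
normal is drawn from the spec's distribution.  Tail zigzag planes are
laid out at equally spaced azimuths across a leaflet, which makes the
orientational average in S_CD exact for a fixed tilt angle:
S_CD(tau) = (1 - 3 cos^2 tau) / 4.

No water or ions are generated by default; the analyses in scope never
touch solvent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Frame, Topology, Trajectory
from .io import topology_from_atoms

HIAPP_SEQUENCE = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"

AA3 = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
       "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
       "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
       "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR"}

#: residues whose side-chain site is a hydroxyl/amine donor (carries HS)
_SC_DONOR = set("STYKR")
#: residues whose side-chain site accepts hydrogen bonds
_SC_ACCEPTOR = set("STYNQDEH")
#: side-chain site element by residue letter
_SC_ELEMENT = {**{a: "C" for a in AA3}, "K": "N", "R": "N", "H": "N",
               "S": "O", "T": "O", "Y": "O", "N": "O", "Q": "O",
               "D": "O", "E": "O", "C": "S"}
#: side-chain formal charge
_SC_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

# generic heavy-atom LJ parameters (kJ/mol nm^6, kJ/mol nm^12):
# minimum near 0.40 nm, well depth ~0.6 kJ/mol
_C6, _C12 = 0.005, 1.0e-5

_CC_BOND = 0.153      # nm
_TET = np.radians(109.47122063449069)
_RISE_PER_C = _CC_BOND * np.sin(_TET / 2.0)
_ZIGZAG_HALF = _CC_BOND * np.cos(_TET / 2.0)


def expected_scd(tilt_deg: float) -> float:
    """S_CD implied by a fixed all-trans chain tilt with azimuthally
    uniform zigzag planes."""
    return (1.0 - 3.0 * np.cos(np.radians(tilt_deg)) ** 2) / 4.0


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class BilayerSpec:
    """Target geometry of the synthetic bilayer (study-scale defaults:
    2 x 64 lipids, area per lipid 0.616 nm^2, P-P thickness 3.67 nm)."""

    lipids_per_leaflet: int = 64
    area_per_lipid: float = 0.616          # nm^2
    thickness: float = 3.67                # nm, P plane to P plane
    headgroup_jitter: float = 0.02         # nm, sigma of rigid z jitter
    lipid_type: str = "PC"                 # "PC" | "PG"
    head_offset: float | None = None       # nm above P plane; None = default
    ester_offset: float = -0.20            # nm (toward bilayer center)
    tail_carbons: int = 8
    tail_tilt_deg: float = 30.0
    tail_tilt_sigma_deg: float = 0.0
    dimple_depth: float = 0.0              # nm, local thinning under peptide
    dimple_radius: float = 0.75            # nm, gaussian sigma
    n_frames: int = 1
    stride_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lipids_per_leaflet < 1:
            raise ValueError("need at least one lipid per leaflet")
        if min(self.area_per_lipid, self.thickness, self.stride_ns) <= 0:
            raise ValueError("lengths and stride must be positive")
        if self.lipid_type not in ("PC", "PG"):
            raise ValueError("lipid_type must be 'PC' or 'PG'")
        if self.tail_carbons < 3:
            raise ValueError("tails need at least three carbons")

    @property
    def resname(self) -> str:
        return "LPC" if self.lipid_type == "PC" else "LPG"

    @property
    def head_offset_resolved(self) -> float:
        # PC: choline clearly outside the phosphate plane; PG: glycerol
        # nearly level with it
        if self.head_offset is not None:
            return self.head_offset
        return 0.10 if self.lipid_type == "PC" else 0.02

    @property
    def box(self) -> np.ndarray:
        L = np.sqrt(self.lipids_per_leaflet * self.area_per_lipid)
        return np.array([L, L, self.thickness + 6.0])


@dataclass
class PeptideSpec:
    """Ideal alpha-helix with radial side-chain stubs."""

    sequence: str = HIAPP_SEQUENCE
    helix_rise: float = 0.15               # nm per residue
    helix_twist: float = 100.0             # degrees per residue
    helical_range: tuple[int, int] = (5, 28)
    helix_radius: float = 0.23             # nm, C-alpha radius
    stub_length: float = 0.40              # nm, side-chain site from CA
    phase_deg: float = 0.0                 # rotational phase psi0
    axis_azimuth_deg: float = 0.0          # axis direction in the xy plane
    z_position: float = 0.0                # axis height offset in its box
    jitter: float = 0.0                    # nm, per-atom gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set(AA3)
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")
        lo, hi = self.helical_range
        if not (1 <= lo < hi <= len(self.sequence)):
            raise ValueError("helical range outside the sequence")


@dataclass
class ScriptSpec:
    """Frame-by-frame kinematics of the peptide over the bilayer.

    ``keyframes`` rows are (time ns, N-terminal-region z, C-terminal-region
    z, psi degrees); region heights are of the whole-residue-centroid mean
    of residues 1-19 / 20-37 relative to the upper phosphorus plane and
    are piecewise-linearly interpolated.  ``plant`` asks for that many
    ideal-geometry peptide->lipid H-bonds per frame to each lipid group.
    """

    n_frames: int = 60
    stride_ns: float = 1.0
    keyframes: tuple = ((0.0, 1.0, 1.0, 0.0), (11.0, 1.0, 0.35, 0.0),
                        (12.0, 1.0, 0.10, 0.0), (49.0, 0.35, 0.05, 0.0),
                        (50.0, 0.15, 0.05, 0.0), (1.0e9, 0.15, 0.05, 0.0))
    plant: dict = field(default_factory=dict)
    plant_start_time: float = 0.0
    psi_jitter_deg: float = 0.0
    adsorption_z_threshold: float = 0.3
    adsorption_dwell: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.stride_ns <= 0:
            raise ValueError("need at least one frame and a positive stride")
        times = [k[0] for k in self.keyframes]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("keyframe times must increase")
        if any(v < 0 for v in self.plant.values()):
            raise ValueError("planted H-bond counts must be >= 0")

    def targets_at(self, t: float) -> tuple[float, float, float]:
        """(z_nterm, z_cterm, psi) at time t by linear interpolation."""
        ks = self.keyframes
        if t <= ks[0][0]:
            return ks[0][1:]
        for (t1, *v1), (t2, *v2) in zip(ks, ks[1:]):
            if t1 <= t <= t2:
                f = (t - t1) / (t2 - t1)
                return tuple(a + f * (b - a) for a, b in zip(v1, v2))
        return ks[-1][1:]


# ---------------------------------------------------------------------------
# sidecar construction
# ---------------------------------------------------------------------------

def peptide_sidecar_entries(sequence: str) -> dict:
    """Sidecar residue entries for every amino-acid type in a sequence."""
    out = {}
    for i, letter in enumerate(sequence):
        res = AA3[letter]
        if res in out and i > 0:
            continue
        atoms = {
            "N": {"element": "N", "charge": 0.0, "c6": _C6, "c12": _C12,
                  "nh": 0, "donor": True, "acceptor": False},
            "H": {"element": "H", "charge": 0.0, "c6": 0.0, "c12": 0.0,
                  "nh": 0, "donor": False, "acceptor": False},
            "CA": {"element": "C", "charge": 0.0, "c6": _C6, "c12": _C12,
                   "nh": 1, "donor": False, "acceptor": False},
            "C": {"element": "C", "charge": 0.0, "c6": _C6, "c12": _C12,
                  "nh": 0, "donor": False, "acceptor": False},
            "O": {"element": "O", "charge": 0.0, "c6": _C6, "c12": _C12,
                  "nh": 0, "donor": False, "acceptor": True},
        }
        # charged, free N-terminus: distinct atom name NT
        atoms["NT"] = dict(atoms["N"], charge=1.0)
        if letter != "G":
            atoms["CB"] = {"element": "C", "charge": 0.0, "c6": _C6,
                           "c12": _C12, "nh": 2, "donor": False,
                           "acceptor": False}
            atoms["SC"] = {"element": _SC_ELEMENT[letter],
                           "charge": _SC_CHARGE.get(letter, 0.0),
                           "c6": _C6, "c12": _C12, "nh": 0,
                           "donor": letter in _SC_DONOR,
                           "acceptor": letter in _SC_ACCEPTOR}
            if letter in _SC_DONOR:
                atoms["HS"] = {"element": "H", "charge": 0.0, "c6": 0.0,
                               "c12": 0.0, "nh": 0, "donor": False,
                               "acceptor": False}
        out[res] = {"kind": "peptide", "atoms": atoms}
    return out


def lipid_sidecar_entries(lipid_type: str, tail_carbons: int) -> dict:
    head = ("CHL" if lipid_type == "PC" else "GLY")
    atoms = {
        head: {"element": "N" if lipid_type == "PC" else "O",
               "charge": 1.0 if lipid_type == "PC" else 0.0,
               "c6": _C6, "c12": _C12, "nh": 0,
               "donor": lipid_type == "PG",
               "acceptor": lipid_type == "PG"},
        "P": {"element": "P", "charge": 0.8, "c6": _C6, "c12": _C12,
              "nh": 0, "donor": False, "acceptor": False},
        "OP1": {"element": "O", "charge": -0.9, "c6": _C6, "c12": _C12,
                "nh": 0, "donor": False, "acceptor": True},
        "OP2": {"element": "O", "charge": -0.9, "c6": _C6, "c12": _C12,
                "nh": 0, "donor": False, "acceptor": True},
        "OE1": {"element": "O", "charge": 0.0, "c6": _C6, "c12": _C12,
                "nh": 0, "donor": False, "acceptor": True},
        "OE2": {"element": "O", "charge": 0.0, "c6": _C6, "c12": _C12,
                "nh": 0, "donor": False, "acceptor": True},
    }
    if lipid_type == "PG":
        atoms["HG"] = {"element": "H", "charge": 0.0, "c6": 0.0, "c12": 0.0,
                       "nh": 0, "donor": False, "acceptor": False}
    for k in range(1, tail_carbons + 1):
        atoms[f"C{k}"] = {"element": "C", "charge": 0.0, "c6": _C6,
                          "c12": _C12,
                          "nh": 3 if k == tail_carbons else 2,
                          "donor": False, "acceptor": False}
    resname = "LPC" if lipid_type == "PC" else "LPG"
    return {resname: {"kind": "lipid", "atoms": atoms}}


def build_sidecar(peptide: PeptideSpec | None,
                  bilayer: BilayerSpec | None) -> dict:
    residues = {}
    if peptide is not None:
        residues.update(peptide_sidecar_entries(peptide.sequence))
    if bilayer is not None:
        residues.update(lipid_sidecar_entries(bilayer.lipid_type,
                                              bilayer.tail_carbons))
    return {"residues": residues}


def default_group_map(lipid_type: str = "PC") -> dict[str, str]:
    head = "CHL" if lipid_type == "PC" else "GLY"
    label = "choline" if lipid_type == "PC" else "glycerol"
    return {label: f"lipid and name {head}",
            "phosphate": "lipid and name P OP1 OP2",
            "ester": "lipid and name OE1 OE2"}


# ---------------------------------------------------------------------------
# bilayer generator
# ---------------------------------------------------------------------------

def _lipid_grid(n: int, lx: float, ly: float) -> np.ndarray:
    nx = int(np.ceil(np.sqrt(n)))
    ny = int(np.ceil(n / nx))
    xs = (np.arange(nx) + 0.5) * lx / nx
    ys = (np.arange(ny) + 0.5) * ly / ny
    pts = np.array([(x, y) for x in xs for y in ys])
    return pts[:n]


def _tail_positions(start: np.ndarray, s: float, tilt: float, phi: float,
                    n_carbons: int) -> np.ndarray:
    """All-trans zigzag from ``start``, chain axis tilted ``tilt`` rad from
    the inward normal, zigzag plane at azimuth ``phi`` about the axis."""
    d = np.array([np.sin(tilt), 0.0, -s * np.cos(tilt)])
    a0 = np.array([np.cos(tilt), 0.0, s * np.sin(tilt)])
    w0 = np.cross(d, a0)
    a = np.cos(phi) * a0 + np.sin(phi) * w0
    k = np.arange(n_carbons)
    return (start[None, :] + np.outer(k * _RISE_PER_C, d)
            + np.outer(((-1.0) ** k) * 0.5 * _ZIGZAG_HALF, a))


def generate_bilayer(spec: BilayerSpec,
                     dimple_center: tuple[float, float] | None = None
                     ) -> tuple[Topology, Trajectory]:
    """Planar two-leaflet pseudo-lipid bilayer on a lateral grid.

    Deterministic for a given spec (all randomness from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    box = spec.box
    n = spec.lipids_per_leaflet
    grid = _lipid_grid(n, box[0], box[1])
    head_name = "CHL" if spec.lipid_type == "PC" else "GLY"
    mid = box[2] / 2.0
    if dimple_center is None:
        dimple_center = (box[0] / 2.0, box[1] / 2.0)

    names, resids, resnames = [], [], []
    template: list[str] = [head_name]
    if spec.lipid_type == "PG":
        template.append("HG")
    template += ["P", "OP1", "OP2", "OE1", "OE2"]
    template += [f"C{k}" for k in range(1, spec.tail_carbons + 1)]

    base_coords = []
    tilts = []
    rid = 0
    for leaflet, s in (("upper", 1.0), ("lower", -1.0)):
        for l in range(n):
            rid += 1
            x, y = grid[l]
            zp = mid + s * spec.thickness / 2.0
            if s > 0 and spec.dimple_depth > 0:
                rho2 = ((x - dimple_center[0]) ** 2
                        + (y - dimple_center[1]) ** 2)
                zp -= spec.dimple_depth * np.exp(
                    -rho2 / (2.0 * spec.dimple_radius ** 2))
            tilt = np.radians(spec.tail_tilt_deg
                              + (rng.normal(0.0, spec.tail_tilt_sigma_deg)
                                 if spec.tail_tilt_sigma_deg > 0 else 0.0))
            phi = 2.0 * np.pi * l / n
            pos = {
                head_name: (x + 0.05, y, zp + s * spec.head_offset_resolved),
                "P": (x, y, zp),
                "OP1": (x + 0.15, y, zp),
                "OP2": (x - 0.15, y, zp),
                "OE1": (x + 0.12, y, zp + s * spec.ester_offset),
                "OE2": (x - 0.12, y, zp + s * spec.ester_offset),
            }
            if spec.lipid_type == "PG":
                pos["HG"] = (x + 0.05, y + 0.10,
                             zp + s * spec.head_offset_resolved)
            start = np.array([x, y, zp + s * (spec.ester_offset - 0.10)])
            tail = _tail_positions(start, s, tilt, phi, spec.tail_carbons)
            lipid_xyz = [pos[nm] for nm in template[: len(template)
                                                    - spec.tail_carbons]]
            lipid_xyz += list(tail)
            base_coords.extend(lipid_xyz)
            names.extend(template)
            resids.extend([rid] * len(template))
            resnames.extend([spec.resname] * len(template))
            tilts.append(tilt)

    base_coords = np.array(base_coords)
    sidecar = build_sidecar(None, spec)
    top = topology_from_atoms(names, resids, resnames, sidecar)

    atoms_per_lipid = len(template)
    frames = []
    for f in range(spec.n_frames):
        coords = base_coords.copy()
        if spec.headgroup_jitter > 0:
            dz = rng.normal(0.0, spec.headgroup_jitter, size=2 * n)
            coords[:, 2] += np.repeat(dz, atoms_per_lipid)
        frames.append(Frame(coords, box.copy(), time=f * spec.stride_ns))
    return top, Trajectory(top, frames)


# ---------------------------------------------------------------------------
# peptide generator
# ---------------------------------------------------------------------------

def _build_helix(spec: PeptideSpec) -> tuple[list, list, list, np.ndarray]:
    """Base helix along +x; returns (names, resids, resnames, coords)."""
    names, resids, resnames, xyz = [], [], [], []
    twist = np.radians(spec.helix_twist)
    for i, letter in enumerate(spec.sequence):
        rid = i + 1
        res = AA3[letter]
        th = i * twist
        # radial unit vector; theta = 0 points down (-z)
        u = np.array([0.0, np.sin(th), -np.cos(th)])
        axis_pt = np.array([i * spec.helix_rise, 0.0, 0.0])
        ca = axis_pt + spec.helix_radius * u

        def put(name, p):
            names.append(name)
            resids.append(rid)
            resnames.append(res)
            xyz.append(p)

        put("NT" if i == 0 else "N", ca + np.array([-0.05, 0.0, 0.0]))
        put("H", xyz[-1] + 0.10 * u)
        put("CA", ca)
        put("C", ca + np.array([0.05, 0.0, 0.0]))
        put("O", xyz[-1] + 0.12 * u)
        if letter != "G":
            put("CB", ca + 0.4 * spec.stub_length * u)
            put("SC", ca + spec.stub_length * u)
            if letter in _SC_DONOR:
                put("HS", ca + (spec.stub_length + 0.10) * u)
    return names, resids, resnames, np.array(xyz)


def _face_azimuth(coords: np.ndarray, top: Topology,
                  residue_range: tuple[int, int] = (8, 19)) -> float:
    """Phase of the depth-weighted side-chain face, via the analysis code."""
    from .core import AtomGroup
    from .geometry import residue_centroid_z
    from .orientation import fit_helix_axis, rotational_phase

    frame = Frame(coords, np.array([100.0, 100.0, 100.0]))
    pep = AtomGroup(top, np.arange(top.n_atoms))
    helix = fit_helix_axis(frame, pep, residue_range)
    resids, z = residue_centroid_z(frame, pep, "sidechain")
    depths = pd.DataFrame({"resid": resids, "sidechain_z": z})
    return rotational_phase(frame, helix, depths)


def generate_peptide(spec: PeptideSpec) -> tuple[Topology, Frame]:
    """Ideal helical peptide in a generous box.

    The helix axis lies in the xy plane at azimuth ``axis_azimuth_deg``;
    the rotational phase is calibrated so the depth-weighted core-helix
    face (residues 8-19) sits at exactly ``phase_deg`` from the downward
    direction.
    """
    from .orientation import fit_helix_axis, rotate_about_axis
    from .core import AtomGroup

    names, resids, resnames, coords = _build_helix(spec)
    sidecar = build_sidecar(spec, None)
    top = topology_from_atoms(names, resids, resnames, sidecar)

    if len(spec.sequence) >= 12:
        psi_now = _face_azimuth(coords, top)
        pep = AtomGroup(top, np.arange(top.n_atoms))
        helix = fit_helix_axis(Frame(coords, np.array([100.0] * 3)), pep)
        coords = rotate_about_axis(coords, helix.axis, helix.point,
                                   spec.phase_deg - psi_now)
    if spec.axis_azimuth_deg:
        az = np.radians(spec.axis_azimuth_deg)
        rot = np.array([[np.cos(az), -np.sin(az), 0.0],
                        [np.sin(az), np.cos(az), 0.0],
                        [0.0, 0.0, 1.0]])
        center = coords.mean(axis=0)
        coords = (coords - center) @ rot.T + center
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.jitter, size=coords.shape)

    length = len(spec.sequence) * spec.helix_rise
    box = np.array([length + 4.0, 6.0, 6.0])
    center_target = np.array([box[0] / 2, box[1] / 2,
                              box[2] / 2 + spec.z_position])
    coords = coords - coords.mean(axis=0) + center_target
    return top, Frame(coords, box, time=0.0)


# ---------------------------------------------------------------------------
# scripted trajectories
# ---------------------------------------------------------------------------

@dataclass
class ScriptTruth:
    """Ground-truth record accompanying a scripted trajectory."""

    times: np.ndarray
    psi: np.ndarray                      # realized phase per frame (deg)
    planted: dict                        # label -> per-frame counts
    first_adsorption_time: pd.Series     # per resid, NaN = never
    initiating_region: str               # N-terminal | C-terminal | none
    z_threshold: float
    dwell: float


def _first_sustained(times: np.ndarray, below: np.ndarray,
                     dwell: float) -> float:
    run_start = None
    for i, b in enumerate(below):
        if b and run_start is None:
            run_start = i
        elif not b and run_start is not None:
            if times[i - 1] - times[run_start] >= dwell:
                return float(times[run_start])
            run_start = None
    if run_start is not None and times[-1] - times[run_start] >= dwell:
        return float(times[run_start])
    return np.nan


def generate_scripted_trajectory(
        bilayer: BilayerSpec, peptide: PeptideSpec, script: ScriptSpec
        ) -> tuple[Topology, Trajectory, ScriptTruth]:
    """Peptide + bilayer trajectory following the scripted kinematics.

    Per frame the rigid helix is rolled about its axis to the scheduled
    phase, tilted so the N-terminal (1-19) and C-terminal (20-37) region
    centroids hit their scheduled heights above the upper phosphorus
    plane, and requested H-bond geometries are planted by relocating
    lipid acceptor atoms onto ideal positions (D-A 0.30 nm, H-A 0.20 nm,
    angle 180 degrees) along peptide backbone N-H directions.
    """
    from .core import AtomGroup, concatenate_topologies
    from .orientation import fit_helix_axis, rotate_about_axis
    from .geometry import residue_centroid_z

    rng = np.random.default_rng(script.seed)
    bl_spec = dataclasses.replace(
        bilayer, n_frames=script.n_frames, stride_ns=script.stride_ns)
    bl_top, bl_traj = generate_bilayer(bl_spec)
    pep_spec = dataclasses.replace(peptide, phase_deg=0.0,
                                   axis_azimuth_deg=0.0, jitter=0.0)
    pep_top, pep_frame = generate_peptide(pep_spec)
    base = pep_frame.coordinates
    box = bl_traj[0].box
    n_res = len(peptide.sequence)
    seq = peptide.sequence

    top = concatenate_topologies(pep_top, bl_top)
    pep_group = AtomGroup(pep_top, np.arange(pep_top.n_atoms))
    upper_p_idx = np.flatnonzero(
        (bl_top.names.astype(str) == "P")
        & (bl_top.resids <= bilayer.lipids_per_leaflet))

    helix0 = fit_helix_axis(pep_frame, pep_group)

    # planted-bond bookkeeping: which lipid acceptor atom serves each slot
    plant_labels = list(script.plant)
    acceptor_name = {"phosphate": "OP1", "ester": "OE1",
                     "glycerol": "GLY" if bilayer.lipid_type == "PG" else None,
                     "choline": None}
    slots: dict[str, list[int]] = {}
    donor_resids: dict[str, list[int]] = {}
    lipid_cursor = 0
    donor_cursor = 2
    for label in plant_labels:
        aname = acceptor_name.get(label)
        if aname is None:
            raise ValueError(
                f"cannot plant H-bonds to group {label!r}: its atoms are "
                "not hydrogen-bond acceptors")
        k = script.plant[label]
        slot_idx, dres = [], []
        for _ in range(k):
            lipid_cursor += 1
            if lipid_cursor > bilayer.lipids_per_leaflet:
                raise ValueError("not enough upper-leaflet lipids to plant "
                                 "all requested H-bonds")
            cand = np.flatnonzero((bl_top.resids == lipid_cursor)
                                  & (bl_top.names.astype(str) == aname))
            slot_idx.append(int(cand[0]) + pep_top.n_atoms)
            while seq[donor_cursor - 1] == "P":   # proline has no amide H
                donor_cursor += 3
            dres.append(donor_cursor)
            donor_cursor += 3
            if donor_cursor > n_res:
                raise ValueError("not enough peptide donors for the "
                                 "requested planted H-bonds")
        slots[label] = slot_idx
        donor_resids[label] = dres

    times = np.arange(script.n_frames) * script.stride_ns
    frames = []
    psi_real = np.zeros(script.n_frames)
    planted = {label: np.zeros(script.n_frames, dtype=int)
               for label in plant_labels}
    res_z = np.zeros((script.n_frames, n_res))

    upper_p_by_frame = np.array([
        bl_traj[fi].coordinates[upper_p_idx, 2].mean()
        for fi in range(script.n_frames)])

    for fi, t in enumerate(times):
        upper_p_mean = upper_p_by_frame[fi]
        z_n, z_c, psi = script.targets_at(t)
        if script.psi_jitter_deg > 0:
            psi = psi + rng.uniform(-script.psi_jitter_deg,
                                    script.psi_jitter_deg)
        psi_real[fi] = psi % 360.0
        coords = rotate_about_axis(base.copy(), helix0.axis, helix0.point,
                                   psi)
        # region centroids (mean of per-residue whole centroids)
        fr_tmp = Frame(coords, box)
        resids_arr, zc = residue_centroid_z(fr_tmp, pep_group, "whole")
        _, xc = _residue_centroid_axis(fr_tmp, pep_group, axis=0)
        mask_n = resids_arr <= 19
        zbar_n, zbar_c = zc[mask_n].mean(), zc[~mask_n].mean()
        xbar_n, xbar_c = xc[mask_n].mean(), xc[~mask_n].mean()
        cx, cz = coords[:, 0].mean(), coords[:, 2].mean()
        # solve tilt theta about y and z-offset for the two region targets
        tz_n = upper_p_mean + z_n
        tz_c = upper_p_mean + z_c
        A = zbar_n - zbar_c
        B = xbar_n - xbar_c
        D = tz_n - tz_c
        R = np.hypot(A, B)
        if abs(D) > R:
            raise ValueError("script demands a steeper tilt than the helix "
                             "length allows")
        phi0 = np.arctan2(B, A)
        cand = [a - phi0 for a in (np.arccos(D / R), -np.arccos(D / R))]
        theta = min(cand, key=lambda a: abs((a + np.pi) % (2 * np.pi)
                                            - np.pi))
        ct, st = np.cos(theta), np.sin(theta)
        rel_x = coords[:, 0] - cx
        rel_z = coords[:, 2] - cz
        new_x = cx + ct * rel_x + st * rel_z
        new_z = cz - st * rel_x + ct * rel_z
        coords = np.column_stack([new_x, coords[:, 1], new_z])
        zb_n_now = cz - st * (xbar_n - cx) + ct * (zbar_n - cz)
        coords[:, 2] += tz_n - zb_n_now
        # center laterally in the box
        coords[:, :2] += (box[:2] / 2.0) - coords[:, :2].mean(axis=0)

        # side chains may bury below the P plane, but not into the tail core
        if np.min(coords[:, 2]) < upper_p_mean - 0.25 * bilayer.thickness:
            raise ValueError("script would embed the peptide inside the "
                             "lipid tail region")

        full = np.vstack([coords, bl_traj[fi].coordinates])

        if t >= script.plant_start_time:
            for label in plant_labels:
                for slot, dres in zip(slots[label], donor_resids[label]):
                    nm = "NT" if dres == 1 else "N"
                    d_idx = np.flatnonzero(
                        (pep_top.resids == dres)
                        & (pep_top.names.astype(str) == nm))[0]
                    h_idx = d_idx + 1          # amide H follows its N
                    u = full[h_idx] - full[d_idx]
                    u /= np.linalg.norm(u)
                    full[slot] = full[d_idx] + 0.30 * u
                planted[label][fi] = len(slots[label])

        frames.append(Frame(full, box.copy(), time=float(t)))
        fr_done = Frame(full, box)
        _, zdone = residue_centroid_z(
            fr_done, AtomGroup(top, np.arange(pep_top.n_atoms)), "whole")
        res_z[fi] = zdone - upper_p_mean

    below = res_z < script.adsorption_z_threshold
    first = np.array([_first_sustained(times, below[:, j],
                                       script.adsorption_dwell)
                      for j in range(n_res)])
    resid_index = pd.Index(np.arange(1, n_res + 1), name="resid")
    series = pd.Series(first, index=resid_index,
                       name="first_adsorption_time")
    if np.all(np.isnan(first)):
        region = "none"
    else:
        t_min = np.nanmin(first)
        rid = int(resid_index[np.flatnonzero(first == t_min)[0]])
        region = "N-terminal" if rid <= 19 else "C-terminal"
    truth = ScriptTruth(times=times, psi=psi_real, planted=planted,
                        first_adsorption_time=series,
                        initiating_region=region,
                        z_threshold=script.adsorption_z_threshold,
                        dwell=script.adsorption_dwell)
    return top, Trajectory(top, frames), truth


def _residue_centroid_axis(frame: Frame, group, axis: int):
    """Per-residue whole-atom centroid along one coordinate axis."""
    top = group.topology
    resids = top.resids[group.indices]
    out_r, out_v = [], []
    for rid in np.unique(resids):
        idx = group.indices[resids == rid]
        out_r.append(int(rid))
        out_v.append(float(frame.coordinates[idx, axis].mean()))
    return np.array(out_r), np.array(out_v)
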