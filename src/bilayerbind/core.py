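"""Core containers: Topology, Frame, Trajectory, AtomGroup, periodic geometry.

Internal unit conventions, used everywhere in this package:
lengths in nm, times in ns, energies in kJ/mol, angles in degrees,
charges in elementary charge units.  Angstrom appears only at I/O
boundaries (PDB files).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

MOLECULE_KINDS = ("peptide", "lipid", "solvent", "ion")

#: electrons per neutral atom, for electron-density profiles
ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "NA": 11, "P": 15, "S": 16, "CL": 17,
}


class SelectionError(ValueError):
    """Raised for malformed or unresolvable selection expressions."""


@dataclass
class Topology:
    """Static description of the system: names, residues, charges, LJ terms.

    All fields are parallel arrays over atoms, in file order.  ``c6``/``c12``
    are the attractive/repulsive Lennard-Jones coefficients in
    kJ mol^-1 nm^6 and kJ mol^-1 nm^12 (GROMOS/Berger convention).
    ``n_implicit_h`` counts aliphatic hydrogens folded into united atoms
    (CH2 -> 2, CH3 -> 3); it contributes to electron counts and flags
    carbons that need C-H reconstruction.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    molids: np.ndarray
    molkinds: np.ndarray
    charges: np.ndarray
    c6: np.ndarray
    c12: np.ndarray
    n_implicit_h: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "resids", "resnames", "molids", "molkinds",
                     "charges", "c6", "c12", "n_implicit_h", "donor",
                     "acceptor"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology field {attr!r} has wrong length")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("non-finite partial charges in topology")
        if np.any(self.c6 < 0) or np.any(self.c12 < 0):
            raise ValueError("negative Lennard-Jones coefficients")
        bad = set(np.unique(self.molkinds)) - set(MOLECULE_KINDS)
        if bad:
            raise ValueError(f"unknown molecule kinds: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def electrons(self) -> np.ndarray:
        """Electron count per atom: atomic number plus implicit hydrogens."""
        z = np.array([ATOMIC_NUMBERS[e.upper()] for e in self.elements],
                     dtype=float)
        return z + self.n_implicit_h

    def is_hydrogen(self) -> np.ndarray:
        return np.char.upper(self.elements.astype(str)) == "H"

    def select(self, expression: str) -> "AtomGroup":
        return select(self, expression)

    def subset(self, indices: np.ndarray) -> "Topology":
        """New topology restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return Topology(*(getattr(self, f)[idx] for f in (
            "names", "elements", "resids", "resnames", "molids", "molkinds",
            "charges", "c6", "c12", "n_implicit_h", "donor", "acceptor")))


def concatenate_topologies(a: Topology, b: Topology) -> Topology:
    """Stack two topologies (e.g. peptide + bilayer); molids of ``b`` are
    offset so molecules stay distinct."""
    offset = int(a.molids.max()) + 1 if a.n_atoms else 0
    fields = {}
    for f in ("names", "elements", "resids", "resnames", "molkinds",
              "charges", "c6", "c12", "n_implicit_h", "donor", "acceptor"):
        fields[f] = np.concatenate([getattr(a, f), getattr(b, f)])
    fields["molids"] = np.concatenate([a.molids, b.molids + offset])
    return Topology(
        names=fields["names"], elements=fields["elements"],
        resids=fields["resids"], resnames=fields["resnames"],
        molids=fields["molids"], molkinds=fields["molkinds"],
        charges=fields["charges"], c6=fields["c6"], c12=fields["c12"],
        n_implicit_h=fields["n_implicit_h"], donor=fields["donor"],
        acceptor=fields["acceptor"])


@dataclass
class Frame:
    """One coordinate set: positions (N, 3) in nm, orthorhombic box, time."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths (nm)")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.box.copy(), self.time)


@dataclass
class Trajectory:
    """Time-ordered frames over one topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty trajectory")
        for fr in self.frames:
            if fr.n_atoms != self.topology.n_atoms:
                raise ValueError(
                    f"frame has {fr.n_atoms} atoms, topology has "
                    f"{self.topology.n_atoms}")
        t = self.times
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def window(self, t_min: float, t_max: float) -> "Trajectory":
        """Sub-trajectory with t_min <= time <= t_max."""
        sel = [fr for fr in self.frames if t_min <= fr.time <= t_max]
        if not sel:
            raise ValueError("no frames in requested time window")
        return Trajectory(self.topology, sel)


@dataclass
class AtomGroup:
    """Ordered, duplicate-free set of atom indices into one topology."""

    topology: Topology
    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("duplicate atom indices in group")
        if len(self.indices) and (self.indices.min() < 0
                                  or self.indices.max() >= self.topology.n_atoms):
            raise ValueError("atom index out of range")

    def __len__(self) -> int:
        return len(self.indices)

    def positions(self, frame: Frame) -> np.ndarray:
        return frame.coordinates[self.indices]

    def heavy(self) -> "AtomGroup":
        """Subgroup of non-hydrogen atoms."""
        mask = ~self.topology.is_hydrogen()[self.indices]
        return AtomGroup(self.topology, self.indices[mask], self.label)

    def overlaps(self, other: "AtomGroup") -> bool:
        return bool(np.intersect1d(self.indices, other.indices).size)


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def min_image_vector(a: np.ndarray, b: np.ndarray,
                     box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement b - a in an orthorhombic box.

    Each component of the result lies in (-L/2, L/2]; works on single
    points or broadcastable arrays of points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = b - a
    return d - box * np.ceil(d / box - 0.5)


def min_image_distance_matrix(pa: np.ndarray, pb: np.ndarray,
                              box: np.ndarray) -> np.ndarray:
    """(len(pa), len(pb)) matrix of minimum-image distances."""
    d = min_image_vector(pa[:, None, :], pb[None, :, :], box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def wrap_coordinate(x: np.ndarray, box_length: float,
                    center: float = 0.0) -> np.ndarray:
    """Wrap scalar coordinate(s) into (center - L/2, center + L/2]."""
    return center + min_image_vector(center, x, np.asarray(box_length))


def periodic_mean(x: np.ndarray, box_length: float) -> float:
    """Mean of a periodic coordinate (circular mean mapped back to length)."""
    ang = np.asarray(x) * (2 * np.pi / box_length)
    m = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float(m * box_length / (2 * np.pi))


def unwrap_molecules(frame: Frame, topology: Topology,
                     axis: int = 2) -> np.ndarray:
    """Coordinates with each molecule made whole along one box axis.

    Atoms are shifted by box multiples so each lies within half a box
    length of its molecule's first atom.  Returns a new (N, 3) array.
    """
    coords = frame.coordinates.copy()
    L = frame.box[axis]
    for mol in np.unique(topology.molids):
        idx = np.flatnonzero(topology.molids == mol)
        ref = coords[idx[0], axis]
        x = coords[idx, axis]
        coords[idx, axis] = ref + min_image_vector(ref, x, np.asarray(L))
    return coords


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------
# grammar:   expr    := term ("or" term)*
#            term    := factor ("and" factor)*
#            factor  := "not" factor | "(" expr ")" | primitive
#            primitive := kind | "all" | "resid" ranges | "name" values
#                       | "resname" values | "element" values
# ranges accept "5", "8-19" and "8~19"; "residue" is an alias for "resid".

_KEYWORDS = {"and", "or", "not", "(", ")", "all", "resid", "residue",
             "name", "resname", "element"} | set(MOLECULE_KINDS)


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("missing closing parenthesis")
            return mask
        return self.primitive()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.next())
        if not vals:
            raise SelectionError("selection keyword needs at least one value")
        return vals

    def primitive(self) -> np.ndarray:
        tok = self.next()
        top = self.top
        if tok == "all":
            return np.ones(top.n_atoms, dtype=bool)
        if tok in MOLECULE_KINDS:
            return top.molkinds == tok
        if tok in ("resid", "residue"):
            mask = np.zeros(top.n_atoms, dtype=bool)
            for v in self._values():
                sep = "-" if "-" in v[1:] else ("~" if "~" in v else None)
                try:
                    if sep:
                        lo, hi = v.split(sep, 1)
                        mask |= ((top.resids >= int(lo))
                                 & (top.resids <= int(hi)))
                    else:
                        mask |= top.resids == int(v)
                except ValueError as err:
                    raise SelectionError(
                        f"bad residue id or range {v!r}") from err
            return mask
        if tok == "name":
            return np.isin(top.names, self._values())
        if tok == "resname":
            return np.isin(top.resnames, self._values())
        if tok == "element":
            vals = [v.upper() for v in self._values()]
            return np.isin(np.char.upper(top.elements.astype(str)), vals)
        raise SelectionError(f"unknown selection token {tok!r}")


def select(topology: Topology, expression: str, label: str | None = None
           ) -> AtomGroup:
    """Evaluate a selection expression to an order-preserving AtomGroup.

    Examples: ``"peptide and resid 20-37"``, ``"lipid and name P"``,
    ``"not element H"``.
    """
    mask = _Parser(_tokenize(expression), topology).parse()
    return AtomGroup(topology, np.flatnonzero(mask),
                     label if label is not None else expression)
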