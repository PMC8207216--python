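"""Ring geometry: signed dihedrals and endocyclic furanose torsions.

The five-membered furanose ring is traversed C1'-C2'-C3'-C4'-O4'. The five
endocyclic torsions follow the standard nucleic-acid convention::

    nu0 = C4'-O4'-C1'-C2'
    nu1 = O4'-C1'-C2'-C3'
    nu2 = C1'-C2'-C3'-C4'
    nu3 = C2'-C3'-C4'-O4'
    nu4 = C3'-C4'-O4'-C1'

All angles are reported in degrees; coordinates are in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .exceptions import DataQualityWarning, DegenerateGeometryError, MissingAtomError

RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")

#: atom quadruples defining nu0..nu4, in ring-atom labels
TORSION_DEFS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

# plausible covalent bond-length window for ring bonds, Angstrom
_BOND_MIN, _BOND_MAX = 1.2, 1.8


@dataclass(frozen=True)
class RingAtomSet:
    """Coordinates of one furanose ring in one conformer.

    Attributes
    ----------
    coords : dict mapping each of C1', C2', C3', C4', O4' to a 3-vector (A).
    model_index : 1-based model number (PDB MODEL record).
    chain_id, residue_number : residue provenance.
    altloc_id : alternate-location id, '' when unique.
    occupancy_used : occupancy of the selected conformer, in (0, 1].
    """

    coords: dict
    model_index: int = 1
    chain_id: str = "A"
    residue_number: int = 1
    altloc_id: str = ""
    occupancy_used: float = 1.0

    def __post_init__(self):
        missing = [name for name in RING_ATOMS if name not in self.coords]
        if missing:
            raise MissingAtomError(
                f"ring atom(s) {', '.join(missing)} missing for residue "
                f"{self.chain_id}{self.residue_number} (model {self.model_index})"
            )
        clean = {}
        for name in RING_ATOMS:
            xyz = np.asarray(self.coords[name], dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise MissingAtomError(
                    f"atom {name} has invalid coordinates {xyz!r}"
                )
            clean[name] = xyz
        object.__setattr__(self, "coords", clean)
        self._check_bond_lengths()

    def _check_bond_lengths(self):
        cyc = RING_ATOMS + (RING_ATOMS[0],)
        for a, b in zip(cyc[:-1], cyc[1:]):
            d = float(np.linalg.norm(self.coords[a] - self.coords[b]))
            if not (_BOND_MIN < d < _BOND_MAX):
                warnings.warn(
                    f"bond {a}-{b} length {d:.2f} A outside "
                    f"({_BOND_MIN}, {_BOND_MAX}) A for residue "
                    f"{self.chain_id}{self.residue_number}",
                    DataQualityWarning,
                    stacklevel=3,
                )

    def atom(self, name: str) -> np.ndarray:
        return self.coords[name]


@dataclass(frozen=True)
class TorsionSet:
    """The five endocyclic torsions nu0..nu4 in degrees, each in (-180, 180]."""

    v0: float
    v1: float
    v2: float
    v3: float
    v4: float

    def __post_init__(self):
        for name in ("v0", "v1", "v2", "v3", "v4"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"torsion {name} is not finite: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.v0, self.v1, self.v2, self.v3, self.v4])


def dihedral_angle(p1, p2, p3, p4, labels: Iterable[str] | None = None) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    Looking down the p2->p3 bond, a clockwise rotation of the far bond
    relative to the near bond is positive. The result lies in (-180, 180],
    is invariant under rigid motions and is negated by mirror reflection.

    Raises
    ------
    DegenerateGeometryError
        if three consecutive points are collinear or coincident.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-10 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        names = tuple(labels) if labels is not None else ("p1", "p2", "p3", "p4")
        raise DegenerateGeometryError(
            f"collinear or coincident points among {names}: "
            "dihedral undefined"
        )
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly onto +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def endocyclic_torsions(ring: RingAtomSet) -> TorsionSet:
    """Compute nu0..nu4 from ring coordinates, in the standard atom order."""
    values = []
    for quad in TORSION_DEFS:
        pts = [ring.atom(a) for a in quad]
        values.append(dihedral_angle(*pts, labels=quad))
    return TorsionSet(*values)
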