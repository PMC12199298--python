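"""Low-level geometry shared by all analysis stages.

Distances (optionally under periodic boundary conditions), signed dihedral
angles in degrees, and atom-group selection on coordinate frames.  All
lengths are nanometres; all angles are degrees wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomId",
    "AtomSelection",
    "DihedralSpec",
    "Frame",
    "GeometryError",
    "IdentifierError",
    "ValidationError",
    "dihedral",
    "dihedral_angle",
    "distance",
    "min_group_distance",
    "pair_distance",
    "wrap_angle",
]


class ValidationError(ValueError):
    """Invalid input (bad box, empty selection, malformed spec)."""


class IdentifierError(KeyError):
    """An atom identifier did not resolve to exactly one atom."""


class GeometryError(ValueError):
    """Degenerate geometry (e.g. collinear triple in a dihedral)."""


#: Atom identifier: (chain, residue number, residue name, atom name).
AtomId = tuple[str, int, str, str]


@dataclass(frozen=True)
class AtomSelection:
    """An ordered, non-empty group of atom identifiers on some frame/model."""

    atom_ids: tuple[AtomId, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.atom_ids) == 0:
            raise ValidationError("AtomSelection must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atom_ids)


@dataclass(frozen=True)
class DihedralSpec:
    """Four atoms defining a signed torsion; quartet order fixes the sign."""

    quartet: tuple[AtomId, AtomId, AtomId, AtomId]
    label: str

    def __post_init__(self) -> None:
        if len(set(self.quartet)) != 4:
            raise ValidationError(f"dihedral {self.label!r}: four distinct atoms required")


@dataclass
class Frame:
    """One coordinate set: atom identifiers, positions (nm) and optional box.

    The box, when present, is either three orthorhombic edge lengths or a
    3x3 matrix of row vectors (triclinic).
    """

    atom_ids: list[AtomId]
    coords: np.ndarray
    box: np.ndarray | None = None
    _index: dict[AtomId, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atom_ids), 3):
            raise ValidationError("coords must be (n_atoms, 3)")
        self._index = {}
        for i, aid in enumerate(self.atom_ids):
            if aid in self._index:
                raise ValidationError(f"duplicate atom id {aid}")
            self._index[aid] = i

    def index(self, atom_id: AtomId) -> int:
        try:
            return self._index[atom_id]
        except KeyError:
            raise IdentifierError(f"atom id {atom_id} not found in frame") from None

    def position(self, atom_id: AtomId) -> np.ndarray:
        return self.coords[self.index(atom_id)]

    def positions(self, selection: AtomSelection | Iterable[AtomId]) -> np.ndarray:
        ids = selection.atom_ids if isinstance(selection, AtomSelection) else tuple(selection)
        return self.coords[[self.index(a) for a in ids]]


def _box_matrix(box) -> np.ndarray:
    b = np.asarray(box, dtype=float)
    if b.shape == (3,):
        b = np.diag(b)
    if b.shape != (3, 3):
        raise ValidationError("box must be 3 edge lengths or a 3x3 matrix")
    if abs(np.linalg.det(b)) < 1e-12:
        raise ValidationError("degenerate periodic box (zero volume)")
    return b


# The 27 lattice shifts (-1, 0, 1)^3, used to resolve the minimum image in
# skewed boxes where rounding fractional coordinates alone is not sufficient.
_SHIFTS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=float
)


def _min_image_vectors(d: np.ndarray, box) -> np.ndarray:
    """Map displacement vectors d (n,3) to their minimum images."""
    h = _box_matrix(box)
    hinv = np.linalg.inv(h)
    base = -np.round(d @ hinv)
    # integer lattice shifts keep the zero-shift case bit-exact
    shifts = base[:, None, :] + _SHIFTS[None, :, :]
    cand = d[:, None, :] + shifts @ h
    norms = np.einsum("ijk,ijk->ij", cand, cand)
    best = np.argmin(norms, axis=1)
    rows = np.arange(len(d))
    out = cand[rows, best]
    exact = np.all(shifts[rows, best] == 0, axis=1)
    out[exact] = d[exact]
    return out


def distance(p1, p2, box=None) -> float:
    """Euclidean (or minimum-image, when box is given) distance in nm."""
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    if box is not None:
        d = _min_image_vectors(d.reshape(1, 3), box)[0]
    return float(np.linalg.norm(d))


def pair_distance(frame: Frame, a: AtomId, b: AtomId, box=None) -> float:
    """Distance between two atoms of a frame; minimum-image if box given."""
    return distance(frame.position(a), frame.position(b), box=box)


def cross_distances(pa: np.ndarray, pb: np.ndarray, box=None) -> np.ndarray:
    """All pairwise distances between two coordinate sets, (na, nb)."""
    pa = np.atleast_2d(np.asarray(pa, dtype=float))
    pb = np.atleast_2d(np.asarray(pb, dtype=float))
    d = pb[None, :, :] - pa[:, None, :]
    if box is not None:
        flat = _min_image_vectors(d.reshape(-1, 3), box)
        d = flat.reshape(d.shape)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def min_group_distance(frame: Frame, group_a: AtomSelection, group_b: AtomSelection, box=None) -> float:
    """Minimum distance over all cross pairs of two selections, in nm."""
    pa = frame.positions(group_a)
    pb = frame.positions(group_b)
    return float(cross_distances(pa, pb, box=box).min())


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = float(angle_deg) % 360.0
    if a > 180.0:
        a -= 360.0
    return a


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle of four points, degrees in (-180, 180].

    IUPAC convention: looking down the p1->p2 bond, the angle from the
    p0 side to the p3 side, positive clockwise.  Reversing the quartet
    leaves the angle unchanged.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear triple: dihedral undefined")
    b1u = b1 / np.linalg.norm(b1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1u))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def dihedral_angle(frame: Frame, spec: DihedralSpec) -> float:
    """Evaluate a DihedralSpec on a frame; degrees in (-180, 180]."""
    p = [frame.position(a) for a in spec.quartet]
    return dihedral(*p)
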