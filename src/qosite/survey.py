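"""Survey of Q_o_-site side-chain conformers across experimental model ensembles.

Classifies chi torsions of the conserved Y147/E295/Y297 (YEY) group plus
H276/D278 into t / g / -g conformers, tabulates joint torsional modes over an
ensemble of monomer models, counts resolved waters near chosen centres, and
measures the two substrate-binding distances (H152 Ne2 to Q O4, Y147 OH to
Q O1).  Models come from multi-model PDB/mmCIF files (one monomer model per
chain per model record) or from the synthetic generator.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from string import ascii_uppercase
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .geometry import (
    AtomId,
    AtomSelection,
    DihedralSpec,
    Frame,
    IdentifierError,
    ValidationError,
    cross_distances,
    dihedral_angle,
    pair_distance,
    wrap_angle,
)

__all__ = [
    "CHI_QUARTETS",
    "ConformerLabel",
    "ResidueMap",
    "StructureModel",
    "SurveyResult",
    "TorsionalMode",
    "WATER_RESNAMES",
    "classify_conformer",
    "conformer_center",
    "count_waters_near",
    "load_models",
    "load_residue_map",
    "qbound_distances",
    "survey_modes",
]

#: Residue names recognised as water; only their oxygen atoms are counted.
WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O"})

#: Side-chain torsion quartets by residue type (chi1 = N-CA-CB-CG throughout;
#: chi2 follows the conventional next-bond quartet for each type).
CHI_QUARTETS: dict[str, dict[str, tuple[str, str, str, str]]] = {
    "TYR": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD1")},
    "GLU": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD")},
    "HIS": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "ND1")},
    "ASP": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "OD1")},
}

#: Conformer well centres in degrees.
_CENTERS = {"t": 180.0, "g": 60.0, "-g": -60.0}

#: The four torsions whose joint conformer tuple defines a torsional mode,
#: in tabulation order.
MODE_TORSIONS: tuple[tuple[str, str], ...] = (
    ("Y147", "chi1"),
    ("E295", "chi1"),
    ("E295", "chi2"),
    ("Y297", "chi1"),
)

#: Expected residue type per surveyed role (used to pick chi quartets).
ROLE_RESTYPE = {
    "Y147": "TYR",
    "E295": "GLU",
    "Y297": "TYR",
    "H276": "HIS",
    "D278": "ASP",
    "H152": "HIS",
}

ConformerLabel = str  # one of "t", "g", "-g"


def classify_conformer(angle_deg: float) -> ConformerLabel:
    """Assign a chi angle (degrees) to its t / g / -g conformer.

    The circle is partitioned into three 120-degree bins centred on the
    well centres 180, +60 and -60: t for \\|angle\\| >= 120, g for
    [0, 120), -g for (-120, 0).
    """
    a = wrap_angle(angle_deg)
    if abs(a) >= 120.0:
        return "t"
    if a >= 0.0:
        return "g"
    return "-g"


def conformer_center(label: ConformerLabel) -> float:
    """Well-centre angle (degrees) of a conformer label."""
    try:
        return _CENTERS[label]
    except KeyError:
        raise ValidationError(f"unknown conformer label {label!r}") from None


@dataclass
class StructureModel:
    """One monomer model of the Q_o_ site.

    ``frame`` holds every selected atom (highest-occupancy altloc) with ids
    (chain, resid, resname, atom name); coordinates are in nm.
    """

    model_id: str
    frame: Frame
    method: str = "synthetic"
    has_waters: bool = False
    has_bound_q: bool = False

    def water_oxygens(self) -> list[AtomId]:
        return [
            aid
            for aid in self.frame.atom_ids
            if aid[2] in WATER_RESNAMES and aid[3].startswith("O")
        ]


class ResidueMap:
    """Role -> (chain, residue number) mapping, per model or as a default.

    A model id of ``"*"`` supplies the fallback mapping used for any model
    without its own entry (the synthetic ensembles use a single shared map).
    Roles explicitly absent for a model are recorded as None.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, tuple[str, int] | None]]):
        self.entries = {m: dict(roles) for m, roles in entries.items()}

    def lookup(self, model_id: str, role: str) -> tuple[str, int] | None:
        base_id = model_id.split("|")[0]
        for key in (model_id, base_id, "*"):
            if key in self.entries and role in self.entries[key]:
                return self.entries[key][role]
        return None


def load_residue_map(path: str | Path) -> ResidueMap:
    """Read a residue map TSV with columns model_id, role, chain, resid.

    A resid of ``-`` (or empty chain) marks the role as absent in that model.
    """
    entries: dict[str, dict[str, tuple[str, int] | None]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"model_id", "role", "chain", "resid"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(f"residue map must have columns {sorted(required)}")
        for row in reader:
            roles = entries.setdefault(row["model_id"], {})
            if row["resid"] in ("-", "") or row["chain"] == "":
                roles[row["role"]] = None
            else:
                roles[row["role"]] = (row["chain"], int(row["resid"]))
    return ResidueMap(entries)


# --- structure file reading -------------------------------------------------

_ANGSTROM_TO_NM = 0.1


def _best_altloc(residue: gemmi.Residue, name: str) -> gemmi.Atom | None:
    """Highest-occupancy altloc of a named atom, or None if absent."""
    best = None
    for atom in residue:
        if atom.name == name and (best is None or atom.occ > best.occ):
            best = atom
    return best


def _model_to_frame(model: gemmi.Model, chain_name: str | None = None) -> tuple[Frame, bool]:
    """Extract one Frame (nm) from a gemmi model, optionally one chain plus waters.

    Returns (frame, has_waters).  When a chain is named, its residues are
    taken from that chain but waters are collected from every chain (solvent
    often sits in its own chain).
    """
    ids: list[AtomId] = []
    coords: list[tuple[float, float, float]] = []
    has_waters = False
    seen: set[AtomId] = set()
    for chain in model:
        for residue in chain:
            is_water = residue.name in WATER_RESNAMES
            if chain_name is not None and chain.name != chain_name and not is_water:
                continue
            if is_water:
                has_waters = True
            names = sorted({a.name for a in residue})
            for name in names:
                atom = _best_altloc(residue, name)
                if atom is None:
                    continue
                aid: AtomId = (chain.name, residue.seqid.num, residue.name, name)
                if aid in seen:  # insertion-code duplicates: keep the first
                    continue
                seen.add(aid)
                ids.append(aid)
                coords.append(
                    (atom.pos.x * _ANGSTROM_TO_NM, atom.pos.y * _ANGSTROM_TO_NM, atom.pos.z * _ANGSTROM_TO_NM)
                )
    return Frame(ids, np.array(coords, dtype=float)), has_waters


def load_models(
    path: str | Path,
    chains: Sequence[str] | None = None,
    method: str = "x-ray",
    has_bound_q: bool = False,
) -> list[StructureModel]:
    """Load monomer StructureModels from a PDB or mmCIF file.

    Multi-model files expand to one StructureModel per model record; when
    ``chains`` is given (e.g. the two monomers of a dimer), each listed chain
    becomes its own model.  Model ids are ``<stem>|<model>|<chain>``.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    out: list[StructureModel] = []
    for model in st:
        chain_list = list(chains) if chains is not None else [None]
        for chain_name in chain_list:
            frame, has_waters = _model_to_frame(model, chain_name)
            suffix = f"|{model.num}" + (f"|{chain_name}" if chain_name else "")
            out.append(
                StructureModel(
                    model_id=f"{path.stem}{suffix}",
                    frame=frame,
                    method=method,
                    has_waters=has_waters,
                    has_bound_q=has_bound_q,
                )
            )
    return out


# --- torsion survey ---------------------------------------------------------


def model_chi(model: StructureModel, residue_map: ResidueMap, role: str, chi: str) -> float:
    """Chi angle (degrees) of a mapped role residue in one model."""
    loc = residue_map.lookup(model.model_id, role)
    if loc is None:
        raise IdentifierError(f"role {role} not mapped for model {model.model_id}")
    chain, resid = loc
    restype = ROLE_RESTYPE[role]
    quartet_names = CHI_QUARTETS[restype][chi]
    resname = _resname_at(model.frame, chain, resid)
    quartet = tuple((chain, resid, resname, nm) for nm in quartet_names)
    spec = DihedralSpec(quartet, label=f"{role}.{chi}")
    return dihedral_angle(model.frame, spec)


def _resname_at(frame: Frame, chain: str, resid: int) -> str:
    for aid in frame.atom_ids:
        if aid[0] == chain and aid[1] == resid and aid[2] not in WATER_RESNAMES:
            return aid[2]
    raise IdentifierError(f"no residue {chain}/{resid} in frame")


@dataclass(frozen=True)
class TorsionalMode:
    """A joint conformer tuple with its ensemble count and mode letter."""

    tuple: tuple[ConformerLabel, ...]
    count: int
    label: str


@dataclass
class SurveyResult:
    modes: list[TorsionalMode]
    assignments: pd.DataFrame  # per-model chi values, conformer tuple, mode letter
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (model_id, reason)


def _mode_letter(i: int) -> str:
    # A..Z, then AA, AB, ... for pathological ensembles
    letters = ""
    i0 = i
    while True:
        letters = ascii_uppercase[i0 % 26] + letters
        i0 = i0 // 26 - 1
        if i0 < 0:
            return letters


def survey_modes(models: Iterable[StructureModel], residue_map: ResidueMap) -> SurveyResult:
    """Tabulate joint (Y147 chi1, E295 chi1, E295 chi2, Y297 chi1) modes.

    Models where any of the four torsions cannot be computed are reported as
    skipped.  Modes are sorted by descending count with lexicographic
    tuple order breaking ties, and labelled A, B, C, ... in that order.
    """
    models = list(models)
    if not models:
        raise ValidationError("survey requires at least one model")
    rows = []
    skipped: list[tuple[str, str]] = []
    for model in models:
        chis: dict[str, float] = {}
        try:
            for role, chi in MODE_TORSIONS:
                chis[f"{role}.{chi}"] = model_chi(model, residue_map, role, chi)
        except (IdentifierError, ValidationError) as exc:
            skipped.append((model.model_id, str(exc)))
            continue
        labels = tuple(classify_conformer(chis[f"{role}.{chi}"]) for role, chi in MODE_TORSIONS)
        rows.append({"model_id": model.model_id, **chis, "conformer_tuple": labels})
    counts = Counter(r["conformer_tuple"] for r in rows)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    modes = [TorsionalMode(tup, n, _mode_letter(i)) for i, (tup, n) in enumerate(ordered)]
    letter_of = {m.tuple: m.label for m in modes}
    for r in rows:
        r["mode"] = letter_of[r["conformer_tuple"]]
    assignments = pd.DataFrame(
        rows, columns=["model_id", *(f"{r}.{c}" for r, c in MODE_TORSIONS), "conformer_tuple", "mode"]
    )
    return SurveyResult(modes=modes, assignments=assignments, skipped=skipped)


# --- hydration and binding distances ---------------------------------------


def count_waters_near(model: StructureModel, center: AtomSelection, radius: float) -> int:
    """Number of distinct water oxygens within ``radius`` nm of the centre group."""
    if not model.has_waters:
        raise ValidationError(f"model {model.model_id} has no resolved waters")
    if radius <= 0:
        raise ValidationError("radius must be positive")
    waters = model.water_oxygens()
    if not waters:
        return 0
    pw = model.frame.positions(waters)
    pc = model.frame.positions(center)
    dmin = cross_distances(pw, pc).min(axis=1)
    return int(np.sum(dmin < radius))


def qbound_distances(model: StructureModel, residue_map: ResidueMap) -> dict[str, float]:
    """The two substrate-anchoring distances of a Q-bound model, in nm.

    Returns ``{"H152Ne-QO4": d1, "Y147OH-QO1": d2}``.
    """
    if not model.has_bound_q:
        raise ValidationError(f"model {model.model_id} has no bound Q substrate")

    def atom_of(role: str, name: str) -> AtomId:
        loc = residue_map.lookup(model.model_id, role)
        if loc is None:
            raise IdentifierError(f"role {role} not mapped for model {model.model_id}")
        chain, resid = loc
        for aid in model.frame.atom_ids:
            if aid[0] == chain and aid[1] == resid and aid[3] == name:
                return aid
        raise IdentifierError(f"atom {name} of role {role} missing in model {model.model_id}")

    d1 = pair_distance(model.frame, atom_of("H152", "NE2"), atom_of("Q_head", "O4"))
    d2 = pair_distance(model.frame, atom_of("Y147", "OH"), atom_of("Q_head", "O1"))
    return {"H152Ne-QO4": d1, "Y147OH-QO1": d2}


def mode_summary_table(result: SurveyResult) -> pd.DataFrame:
    """Mode-summary DataFrame: mode letter, one column per torsion, count."""
    rows = []
    for m in result.modes:
        row = {"mode": m.label}
        for (role, chi), lab in zip(MODE_TORSIONS, m.tuple):
            row[f"{role}.{chi}"] = lab
        row["N"] = m.count
        rows.append(row)
    return pd.DataFrame(rows)
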