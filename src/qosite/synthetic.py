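"""Synthetic input generators with the statistical structure the pipeline assumes.

Four families of stand-ins for the real inputs:

* torsional time series sampled by Metropolis Monte Carlo from designed
  periodic potentials, optionally under a well-tempered metadynamics bias
  (height 0.6 kJ/mol, width 0.4 rad, bias factor 15, deposition every 1000
  sampler steps by default);
* binary contact series from a two-state telegraph process with known
  on/off rates;
* multi-model coordinate ensembles (PDB files) with planted chi angles,
  planted water placements and planted substrate distances;
* multiple sequence alignments with planted per-column residue frequencies
  and per-row gap fractions.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import gemmi
import numpy as np

from .geometry import ValidationError, wrap_angle
from .survey import conformer_center

__all__ = [
    "KT_310",
    "BiasPotential",
    "SyntheticModelSpec",
    "TelegraphSpec",
    "TorsionPotentialSpec",
    "TorsionSeries",
    "boltzmann_profile",
    "cosine_double_well",
    "harmonic_well",
    "make_model_ensemble",
    "make_msa",
    "sample_metadynamics",
    "sample_potential",
    "telegraph_series",
]

#: Gas constant in kJ/(mol K).
R_GAS = 0.008314462618
#: kT at the simulation temperature of 310 K, kJ/mol.
KT_310 = R_GAS * 310.0  # 2.5775 kJ/mol


# --- designed potentials ----------------------------------------------------


def cosine_double_well(barrier: float = 10.0, asymmetry: float = 3.0) -> Callable[[float], float]:
    """Periodic 1D double well on (-180, 180] degrees, in kJ/mol.

    U(x) = (barrier/2)(1 - cos 2x) + (asymmetry/2)(1 - cos x): wells at
    0 (depth 0) and 180 (depth = asymmetry), barrier near +-90.
    """

    def u(x: float) -> float:
        xr = math.radians(x)
        return 0.5 * barrier * (1.0 - math.cos(2.0 * xr)) + 0.5 * asymmetry * (1.0 - math.cos(xr))

    return u


def harmonic_well(kappa: float = 0.01, center: float = 0.0) -> Callable[[float], float]:
    """Harmonic well U = kappa/2 * (x - center)^2, kJ/mol per degree^2."""

    def u(x: float) -> float:
        d = wrap_angle(x - center)
        return 0.5 * kappa * d * d

    return u


def boltzmann_profile(
    potential: Callable[[float], float],
    edges: np.ndarray,
    kT: float = KT_310,
    points_per_bin: int = 64,
) -> np.ndarray:
    """Analytic free-energy profile by numerical Boltzmann integration.

    Integrates exp(-U/kT) over each bin by the trapezoid rule, normalises,
    and returns -kT ln p shifted so the minimum is zero.  This is the
    independent reference against which sampled profiles are judged.
    """
    edges = np.asarray(edges, dtype=float)
    masses = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        xs = np.linspace(edges[i], edges[i + 1], points_per_bin)
        ys = np.exp(-np.array([potential(x) for x in xs]) / kT)
        masses[i] = np.trapezoid(ys, xs)
    p = masses / masses.sum()
    g = -kT * np.log(p)
    return g - g.min()


# --- Metropolis sampling ----------------------------------------------------


@dataclass
class TorsionPotentialSpec:
    """Designed torsional potential plus sampler settings.

    ``potential`` maps an angle in degrees to an energy in kJ/mol and must be
    bounded below.  The Metropolis step is auto-tuned during burn-in toward a
    30-50% acceptance rate.
    """

    potential: Callable[[float], float]
    temperature: float = 310.0
    step_deg: float = 30.0
    burn_in: int = 2000
    start: float = 0.0
    seed: int = 0

    @property
    def kT(self) -> float:
        return R_GAS * self.temperature


@dataclass
class TorsionSeries:
    """A sampled dihedral time series in degrees, with frame spacing in ns."""

    values: np.ndarray
    dt: float = 0.002
    label: str = "chi"


def _metropolis_1d(
    potential: Callable[[float], float],
    kT: float,
    n: int,
    step0: float,
    burn_in: int,
    start: float,
    rng: np.random.Generator,
    bias: "_GridBias | None" = None,
    bias_h0: float = 0.0,
    bias_gamma: float = 0.0,
    bias_stride: int = 0,
) -> np.ndarray:
    """Core periodic 1D Metropolis walk; optionally deposits a WT-metadynamics bias."""
    if n < 1:
        raise ValidationError("need at least one sample")
    if step0 <= 0 or step0 > 180:
        raise ValidationError("step size must be in (0, 180] degrees")
    x = float(start)
    ux = potential(x) + (bias.value(x) if bias is not None else 0.0)
    step = float(step0)
    out = np.empty(n)
    total = burn_in + n
    # pre-drawn randomness in blocks keeps the loop cheap and reproducible
    props = rng.uniform(-1.0, 1.0, total)
    accs = rng.uniform(0.0, 1.0, total)
    acc_count = 0
    for i in range(total):
        y = x + step * props[i]
        if y > 180.0:
            y -= 360.0
        elif y <= -180.0:
            y += 360.0
        uy = potential(y) + (bias.value(y) if bias is not None else 0.0)
        if uy <= ux or accs[i] < math.exp((ux - uy) / kT):
            x, ux = y, uy
            acc_count += 1
        if i < burn_in:
            if (i + 1) % 100 == 0:  # auto-tune toward 30-50% acceptance
                rate = acc_count / 100.0
                if rate > 0.5:
                    step = min(step * 1.2, 180.0)
                elif rate < 0.3:
                    step = max(step / 1.2, 1e-3)
                acc_count = 0
        else:
            j = i - burn_in
            out[j] = x
            if bias is not None and bias_stride > 0 and (j + 1) % bias_stride == 0:
                v = bias.value(x)
                h = bias_h0 * math.exp(-v / ((bias_gamma - 1.0) * kT))
                bias.deposit(x, h)
                ux = potential(x) + bias.value(x)
    return out


def sample_potential(spec: TorsionPotentialSpec, n: int) -> TorsionSeries:
    """Draw n Metropolis samples from exp(-U/kT) on the periodic angle domain."""
    rng = np.random.default_rng(spec.seed)
    values = _metropolis_1d(
        spec.potential, spec.kT, n, spec.step_deg, spec.burn_in, spec.start, rng
    )
    return TorsionSeries(values=values, label="chi")


class _GridBias:
    """Accumulated metadynamics bias on a periodic angular grid (degrees)."""

    def __init__(self, sigma_deg: float, n_grid: int = 1440):
        self.sigma = sigma_deg
        self.n = n_grid
        self.grid = np.linspace(-180.0, 180.0, n_grid, endpoint=False)
        self.v = np.zeros(n_grid)
        self.centers: list[float] = []
        self.heights: list[float] = []

    def deposit(self, center: float, height: float) -> None:
        d = np.abs(self.grid - center)
        d = np.minimum(d, 360.0 - d)
        self.v += height * np.exp(-0.5 * (d / self.sigma) ** 2)
        self.centers.append(center)
        self.heights.append(height)

    def value(self, x: float) -> float:
        # periodic linear interpolation on the grid
        t = (x + 180.0) / 360.0 * self.n
        i0 = int(math.floor(t)) % self.n
        i1 = (i0 + 1) % self.n
        f = t - math.floor(t)
        return (1.0 - f) * self.v[i0] + f * self.v[i1]

    def values(self, xs: np.ndarray) -> np.ndarray:
        t = (np.asarray(xs, dtype=float) + 180.0) / 360.0 * self.n
        i0 = np.floor(t).astype(int) % self.n
        i1 = (i0 + 1) % self.n
        f = t - np.floor(t)
        return (1.0 - f) * self.v[i0] + f * self.v[i1]


@dataclass
class BiasPotential:
    """Final accumulated well-tempered bias: Gaussian records plus evaluator."""

    centers: np.ndarray
    heights: np.ndarray
    sigma_deg: float
    gamma: float
    _grid: _GridBias = field(repr=False, default=None)

    def evaluate(self, xs) -> np.ndarray:
        """Bias energy (kJ/mol) at angles xs, with periodic Gaussian images."""
        return self._grid.values(np.atleast_1d(np.asarray(xs, dtype=float)))


def sample_metadynamics(
    spec: TorsionPotentialSpec,
    n: int,
    h0: float = 0.6,
    sigma: float = 0.4,
    gamma: float = 15.0,
    stride: int = 1000,
) -> tuple[TorsionSeries, np.ndarray, BiasPotential]:
    """Well-tempered metadynamics sampling of a designed 1D potential.

    Gaussian hills of initial height ``h0`` kJ/mol and width ``sigma``
    (radians, as is conventional for torsional collective variables) are
    deposited every ``stride`` sampler steps with the well-tempered height
    schedule h_k = h0 exp(-V(s_k) / ((gamma-1) kT)).

    Returns the sampled series, the final accumulated bias evaluated at every
    sample (what reweighting consumes), and the final BiasPotential.
    """
    if gamma <= 1.0:
        raise ValidationError("bias factor gamma must exceed 1")
    if h0 <= 0 or sigma <= 0 or stride < 1:
        raise ValidationError("invalid metadynamics parameters")
    rng = np.random.default_rng(spec.seed)
    grid = _GridBias(sigma_deg=math.degrees(sigma))
    values = _metropolis_1d(
        spec.potential,
        spec.kT,
        n,
        spec.step_deg,
        spec.burn_in,
        spec.start,
        rng,
        bias=grid,
        bias_h0=h0,
        bias_gamma=gamma,
        bias_stride=stride,
    )
    bias = BiasPotential(
        centers=np.array(grid.centers),
        heights=np.array(grid.heights),
        sigma_deg=grid.sigma,
        gamma=gamma,
        _grid=grid,
    )
    bias_at_samples = grid.values(values)
    return TorsionSeries(values=values, label="chi"), bias_at_samples, bias


# --- telegraph (two-state) contact process ----------------------------------


@dataclass
class TelegraphSpec:
    """Discrete-time two-state chain: on/off rates in 1/ns, frame spacing in ns."""

    k_on: float
    k_off: float
    dt: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValidationError("telegraph rates must be positive")
        if self.dt <= 0 or self.n_frames < 1:
            raise ValidationError("dt must be positive and n_frames >= 1")
        if self.dt * max(self.k_on, self.k_off) > 0.1:
            raise ValidationError(
                "dt * max(rate) > 0.1: frame spacing too coarse for the discretisation"
            )


def telegraph_series(spec: TelegraphSpec) -> np.ndarray:
    """Boolean per-frame series with switch probabilities k*dt per frame.

    Stationary occupancy is k_on/(k_on+k_off); on-state dwell times are
    geometric with mean 1/(k_off dt) frames.
    """
    rng = np.random.default_rng(spec.seed)
    p_on = spec.k_on * spec.dt
    p_off = spec.k_off * spec.dt
    out = np.empty(spec.n_frames, dtype=bool)
    state = bool(rng.random() < spec.k_on / (spec.k_on + spec.k_off))
    i = 0
    while i < spec.n_frames:
        run = int(rng.geometric(p_off if state else p_on))
        j = min(i + run, spec.n_frames)
        out[i:j] = state
        i = j
        state = not state
    return out


# --- planted structure ensembles --------------------------------------------

# local frame offsets (nm) keeping the site residues well separated
_ROLE_OFFSET = {
    "Y147": (0.0, 0.0, 0.0),
    "E295": (3.0, 0.0, 0.0),
    "Y297": (6.0, 0.0, 0.0),
    "H276": (0.0, 3.0, 0.0),
    "D278": (3.0, 3.0, 0.0),
    "H152": (6.0, 3.0, 0.0),
}
_ROLE_CHAIN_RES = {
    "Y147": ("A", 147, "TYR"),
    "E295": ("A", 295, "GLU"),
    "Y297": ("A", 297, "TYR"),
    "H276": ("A", 276, "HIS"),
    "D278": ("A", 278, "ASP"),
    "H152": ("B", 152, "HIS"),
}
#: Centre atom used when planting waters around a role.
ROLE_CENTER_ATOM = {
    "PRA_bL": "O1A",
    "Y147": "OH",
    "Y297": "OH",
    "E295": "OE1",
    "D278": "OD1",
    "H276": "NE2",
    "H152": "NE2",
}


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates so that dihedral(a,b,c,d) = torsion.

    ``bond`` is the c-d distance, ``angle_deg`` the b-c-d angle.  Natural
    extension reference frame (NeRF) construction.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor), bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_residue(restype: str, chi1: float, chi2: float, origin) -> dict[str, np.ndarray]:
    """Backbone + side chain with the requested chi angles (degrees), nm."""
    o = np.asarray(origin, dtype=float)
    atoms: dict[str, np.ndarray] = {}
    atoms["N"] = o + np.array([0.0, 0.0, 0.0])
    atoms["CA"] = o + np.array([0.1458, 0.0, 0.0])
    # C at 111 deg to the CA->N direction, in the xy plane
    alpha = math.radians(180.0 - 111.0)
    atoms["C"] = atoms["CA"] + 0.1525 * np.array([math.cos(alpha), math.sin(alpha), 0.0])
    atoms["O"] = place_atom(atoms["N"], atoms["CA"], atoms["C"], 0.123, 121.0, 0.0)
    atoms["CB"] = place_atom(atoms["C"], atoms["N"], atoms["CA"], 0.153, 110.5, -122.0)
    atoms["CG"] = place_atom(atoms["N"], atoms["CA"], atoms["CB"], 0.152, 114.0, chi1)
    if restype == "GLU":
        atoms["CD"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 0.152, 114.0, chi2)
        atoms["OE1"] = place_atom(atoms["CB"], atoms["CG"], atoms["CD"], 0.125, 118.0, 0.0)
        atoms["OE2"] = place_atom(atoms["CB"], atoms["CG"], atoms["CD"], 0.125, 118.0, 180.0)
    elif restype == "TYR":
        atoms["CD1"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 0.139, 120.0, chi2)
        # para position across the ring, then the hydroxyl
        atoms["CZ"] = place_atom(atoms["CB"], atoms["CG"], atoms["CD1"], 0.278, 30.0, 180.0)
        atoms["OH"] = place_atom(atoms["CG"], atoms["CD1"], atoms["CZ"], 0.137, 150.0, 180.0)
    elif restype == "HIS":
        atoms["ND1"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 0.138, 122.0, chi2)
        atoms["CE1"] = place_atom(atoms["CB"], atoms["CG"], atoms["ND1"], 0.132, 108.0, 180.0)
        atoms["NE2"] = place_atom(atoms["CG"], atoms["ND1"], atoms["CE1"], 0.133, 109.0, 0.0)
    elif restype == "ASP":
        atoms["OD1"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 0.125, 118.0, chi2)
        atoms["OD2"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 0.125, 118.0, chi2 + 180.0)
    else:
        raise ValidationError(f"unsupported residue type {restype}")
    return atoms


@dataclass
class SyntheticModelSpec:
    """Design of a planted multi-model ensemble.

    ``mode_tuples`` lists one (Y147 chi1, E295 chi1, E295 chi2, Y297 chi1)
    entry per model; entries may be conformer labels ('t', 'g', '-g') or
    angles in degrees.  ``extra_chi`` optionally plants H276/D278 chi1.
    ``waters`` plants water oxygens at exact distances (nm) from the centre
    atom of a role.  ``jitter`` > 0 applies a random rigid rotation plus a
    Gaussian translation of that magnitude (nm) to each whole model, which
    leaves all planted internal geometry invariant.
    """

    mode_tuples: Sequence[Sequence[object]]
    extra_chi: Mapping[str, float | str] | None = None
    waters: Mapping[str, Sequence[float]] | None = None
    q_distances: tuple[float, float] | None = None  # (H152Ne-QO4, Y147OH-QO1)
    jitter: float = 0.0
    seed: int = 0

    def angles(self, entry: Sequence[object]) -> tuple[float, float, float, float]:
        vals = []
        for v in entry:
            vals.append(conformer_center(v) if isinstance(v, str) else float(v))
        if len(vals) != 4:
            raise ValidationError("each mode tuple needs 4 torsions")
        return tuple(vals)  # type: ignore[return-value]


def _element_of(name: str) -> gemmi.Element:
    for ch in name:
        if ch.isalpha():
            return gemmi.Element(ch)
    return gemmi.Element("X")


def _chi(value: float | str) -> float:
    return conformer_center(value) if isinstance(value, str) else float(value)


def _build_model_atoms(
    spec: SyntheticModelSpec, entry: Sequence[object], rng: np.random.Generator
) -> list[tuple[str, int, str, str, np.ndarray]]:
    """All atoms of one model as (chain, resid, resname, atom name, xyz nm)."""
    y147_chi1, e295_chi1, e295_chi2, y297_chi1 = spec.angles(entry)
    extra = dict(spec.extra_chi or {})
    chis = {
        "Y147": (y147_chi1, 75.0),
        "E295": (e295_chi1, e295_chi2),
        "Y297": (y297_chi1, 80.0),
        "H276": (_chi(extra.get("H276", 180.0)), 90.0),
        "D278": (_chi(extra.get("D278", -60.0)), 20.0),
        "H152": (180.0, 90.0),
    }
    atoms: list[tuple[str, int, str, str, np.ndarray]] = []
    placed: dict[str, dict[str, np.ndarray]] = {}
    for role, (chi1, chi2) in chis.items():
        chain, resid, restype = _ROLE_CHAIN_RES[role]
        res_atoms = _build_residue(restype, chi1, chi2, _ROLE_OFFSET[role])
        placed[role] = res_atoms
        for name, pos in res_atoms.items():
            atoms.append((chain, resid, restype, name, pos))
    # heme propionate-A stand-in: two carboxylate oxygens on a bare fragment
    pra_o1 = np.array([1.5, -2.0, 0.0])
    pra = {"CGA": pra_o1 + np.array([0.13, 0.0, 0.0]), "O1A": pra_o1, "O2A": pra_o1 + np.array([0.21, 0.11, 0.0])}
    placed["PRA_bL"] = pra
    for name, pos in pra.items():
        atoms.append(("A", 500, "HEM", name, pos))
    if spec.q_distances is not None:
        d_o4, d_o1 = spec.q_distances
        o4 = placed["H152"]["NE2"] + d_o4 * np.array([0.0, 0.0, 1.0])
        o1 = placed["Y147"]["OH"] + d_o1 * np.array([0.0, 0.0, 1.0])
        for name, pos in (("O1", o1), ("O4", o4)):
            atoms.append(("A", 600, "UQ1", name, pos))
    if spec.waters:
        wres = 900
        for role, distances in spec.waters.items():
            center_role = role if role in placed else role
            center = placed[center_role][ROLE_CENTER_ATOM[role]]
            for d in distances:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                atoms.append(("W", wres, "HOH", "O", center + d * u))
                wres += 1
    if spec.jitter > 0:
        rot = _random_rotation(rng)
        shift = rng.normal(scale=spec.jitter, size=3)
        atoms = [(c, r, rn, an, rot @ pos + shift) for c, r, rn, an, pos in atoms]
    return atoms


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_model_ensemble(spec: SyntheticModelSpec, out_dir: str | Path):
    """Write one PDB file per planted model; returns (paths, residue-map rows).

    The residue map is also written to ``residue_map.tsv`` in ``out_dir`` in
    the TSV dialect :func:`qosite.survey.load_residue_map` reads, with a
    wildcard entry covering every generated model.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    paths: list[Path] = []
    for i, entry in enumerate(spec.mode_tuples):
        atoms = _build_model_atoms(spec, entry, rng)
        st = gemmi.Structure()
        st.name = f"synthetic_{i:04d}"
        model = gemmi.Model(1)
        chains: dict[str, gemmi.Chain] = {}
        for chain_name, resid, resname, atom_name, pos in atoms:
            if chain_name not in chains:
                chains[chain_name] = gemmi.Chain(chain_name)
            chain = chains[chain_name]
            if len(chain) == 0 or chain[-1].seqid.num != resid or chain[-1].name != resname:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resid, " ")
                chain.add_residue(res)
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = _element_of(atom_name)
            atom.occ = 1.0
            atom.pos = gemmi.Position(pos[0] * 10.0, pos[1] * 10.0, pos[2] * 10.0)
            chain[-1].add_atom(atom)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
        path = out_dir / f"model_{i:04d}.pdb"
        st.write_pdb(str(path))
        paths.append(path)
    map_path = out_dir / "residue_map.tsv"
    with open(map_path, "w") as fh:
        fh.write("model_id\trole\tchain\tresid\n")
        for role, (chain, resid, _restype) in _ROLE_CHAIN_RES.items():
            fh.write(f"*\t{role}\t{chain}\t{resid}\n")
        fh.write("*\tPRA_bL\tA\t500\n")
        fh.write("*\tQ_head\tA\t600\n")
    return paths, map_path


# --- synthetic alignments ---------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def make_msa(
    n_rows: int,
    column_freqs: Sequence[Mapping[str, float]],
    gap_fractions: Sequence[float] | None = None,
    seed: int = 0,
    reference_id: str = "reference",
) -> list[tuple[str, str]]:
    """Multinomial-sampled alignment rows with planted column frequencies.

    ``column_freqs[j]`` maps residues to probabilities (summing to 1) for
    column j.  ``gap_fractions``, when given, plants an exact per-row gap
    fraction (rounded down to whole columns) in rows cycled through the list;
    the reference row (row 0) is always gap-free and carries each column's
    most probable residue.
    """
    if n_rows < 1:
        raise ValidationError("need at least one row")
    ncol = len(column_freqs)
    for j, freqs in enumerate(column_freqs):
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in freqs.values()):
            raise ValidationError(f"column {j}: frequencies must be a probability vector")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    ref = "".join(max(f, key=f.get) for f in column_freqs)
    rows.append((reference_id, ref))
    for i in range(1, n_rows):
        chars = []
        for freqs in column_freqs:
            residues = list(freqs.keys())
            probs = np.array([freqs[r] for r in residues])
            chars.append(residues[rng.choice(len(residues), p=probs / probs.sum())])
        if gap_fractions:
            gf = gap_fractions[(i - 1) % len(gap_fractions)]
            n_gaps = int(gf * ncol)
            for j in rng.choice(ncol, size=n_gaps, replace=False):
                chars[j] = "-"
        rows.append((f"seq{i:05d}", "".join(chars)))
    return rows


def write_fasta(rows: Sequence[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in rows:
            fh.write(f">{name}\n{seq}\n")
    return path
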