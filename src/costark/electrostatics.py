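"""Coulomb point-charge fields at a CO probe and redox/protonation field changes.

The electric field at a point r from partial charges q_i at positions r_i in
a homogeneous dielectric ε_r is

    E(r) = (1 / 4πε_r ε₀) Σ_i q_i (r − r_i) / |r − r_i|³ .

Units: charges in elementary charges e, distances in Å, fields in MV/cm.
With e/(4πε₀) = 14.39964 V·Å the prefactor is 1439.964 MV·Å²/(cm·e), so a
unit charge at 10 Å in ε_r = 4 produces 3.59991 MV/cm pointing away from it.

The probe is the bound CO ligand: fields are evaluated at the geometric
midpoint of the C–O bond and projected on the unit vector p from C to O
(the sign convention declared by this package; a charge increase on the iron
side of the probe gives a positive projection).  Field *changes* between two
named charge states — e.g. heme a Fe²⁺ → Fe³⁺, or protonation of a heme
propionate — are, by superposition, the field of the charge-difference
distribution.

:func:`place_co_probe` constructs idealized (linear Fe–C–O, d(Fe–C) = 1.70 Å)
or bent (169°, d(Fe–C) = 1.67 Å) CO geometries on a heme axis;
:func:`report_transitions` tabulates projected field changes per transition
and per probe geometry, with user-selected combined sums.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SingularityError, ValidationError

logger = logging.getLogger(__name__)

#: e/(4πε₀) in V·Å per elementary charge
COULOMB_V_ANGSTROM = 14.39964
#: the same constant expressed for fields in MV/cm with distances in Å
COULOMB_MV_CM = COULOMB_V_ANGSTROM * 100.0  # 1439.964
#: default homogeneous dielectric constant
DEFAULT_EPS_R = 4.0
#: default C–O bond length, Å
DEFAULT_D_CO = 1.13


class AtomID(NamedTuple):
    """Atom identifier: chain, residue name, residue number (with any insertion
    code), atom name."""

    chain: str
    resname: str
    resnum: str
    name: str

    def __str__(self) -> str:
        return f"{self.chain}/{self.resname}/{self.resnum}/{self.name}"


@dataclass(frozen=True)
class ChargedAtom:
    """An atom position (Å) that can carry state-dependent partial charges."""

    atom_id: AtomID
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,) or not np.isfinite(pos).all():
            raise ValidationError(f"{self.atom_id}: position must be a finite 3-vector")


class ChargedStructure:
    """An ordered set of atoms addressable by :class:`AtomID`."""

    def __init__(self, atoms: Iterable[ChargedAtom]):
        self.atoms: tuple[ChargedAtom, ...] = tuple(atoms)
        self._index: dict[AtomID, int] = {}
        for i, a in enumerate(self.atoms):
            if a.atom_id in self._index:
                raise ValidationError(f"duplicate atom identifier {a.atom_id}")
            self._index[a.atom_id] = i
        self.positions = (np.stack([a.position for a in self.atoms])
                          if self.atoms else np.empty((0, 3)))
        self.positions.setflags(write=False)

    def __len__(self) -> int:
        return len(self.atoms)

    def __contains__(self, atom_id: AtomID) -> bool:
        return atom_id in self._index

    def index_of(self, atom_id: AtomID) -> int:
        try:
            return self._index[atom_id]
        except KeyError:
            raise KeyError(f"atom {atom_id} not in structure")

    def find(self, chain: str, resnum: str, name: str) -> ChargedAtom:
        """Look an atom up by chain / residue number / atom name."""
        hits = [a for a in self.atoms
                if a.atom_id.chain == chain and a.atom_id.resnum == str(resnum)
                and a.atom_id.name == name]
        if not hits:
            raise KeyError(f"no atom {chain}/{resnum}/{name}")
        if len(hits) > 1:
            raise KeyError(f"ambiguous atom selection {chain}/{resnum}/{name}")
        return hits[0]


@dataclass(frozen=True)
class ChargeState:
    """Named per-atom partial charges (e) for one redox/protonation state."""

    name: str
    charges: Mapping[AtomID, float]

    def __post_init__(self):
        object.__setattr__(self, "charges", dict(self.charges))
        if not all(math.isfinite(q) for q in self.charges.values()):
            raise ValidationError(f"state {self.name!r}: charges must be finite")

    @property
    def total_charge(self) -> float:
        return float(sum(self.charges.values()))

    def charge_vector(self, structure: ChargedStructure) -> np.ndarray:
        """Charges aligned with ``structure.atoms``; unlisted atoms carry 0 e.

        Raises if the state references an atom absent from the structure.
        """
        q = np.zeros(len(structure))
        for atom_id, charge in self.charges.items():
            q[structure.index_of(atom_id)] = charge
        return q

    @classmethod
    def from_mapping(cls, name: str, structure: ChargedStructure,
                     mapping: Mapping[str, float],
                     base: "ChargeState | None" = None) -> "ChargeState":
        """Build a state from ``chain/resnum/atom → charge`` keys, optionally
        overriding a base state's charges."""
        charges = dict(base.charges) if base is not None else {}
        for key, q in mapping.items():
            parts = str(key).split("/")
            if len(parts) != 3:
                raise ValidationError(
                    f"state {name!r}: key {key!r} is not 'chain/resnum/atom'")
            atom = structure.find(*parts)
            charges[atom.atom_id] = float(q)
        return cls(name, charges)


@dataclass(frozen=True)
class ProbeGeometry:
    """The Fe–C–O probe frame: atom positions in Å, with the evaluation point
    at the C–O midpoint and the projection axis p from C to O."""

    fe_position: np.ndarray
    c_position: np.ndarray
    o_position: np.ndarray

    def __post_init__(self):
        for attr in ("fe_position", "c_position", "o_position"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (3,) or not np.isfinite(v).all():
                raise ValidationError(f"{attr} must be a finite 3-vector")
            object.__setattr__(self, attr, v)
        if np.linalg.norm(self.o_position - self.c_position) <= 0:
            raise ValidationError("C and O positions coincide")

    @property
    def midpoint(self) -> np.ndarray:
        """Center of the C–O bond, the field evaluation point."""
        return (self.c_position + self.o_position) / 2.0

    @property
    def p(self) -> np.ndarray:
        """Unit vector from C to O."""
        v = self.o_position - self.c_position
        return v / np.linalg.norm(v)

    @property
    def fe_c_o_angle(self) -> float:
        """The Fe–C–O angle in degrees, derived from the coordinates."""
        u = self.fe_position - self.c_position
        v = self.o_position - self.c_position
        cosang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


@dataclass(frozen=True)
class FieldResult:
    """A field (change) vector with its projection on the probe axis, MV/cm."""

    field_vector: np.ndarray
    projection: float
    eps_r: float
    state_names: tuple[str, ...]
    delta_total_charge: float | None = None

    def __post_init__(self):
        v = np.asarray(self.field_vector, dtype=float)
        object.__setattr__(self, "field_vector", v)
        if abs(self.projection) > np.linalg.norm(v) + 1e-12:
            raise ValidationError("|projection| exceeds |field vector|")


# ---------------------------------------------------------------------------
# Structure readers
# ---------------------------------------------------------------------------


def _read_pdb(path) -> tuple[ChargedStructure, None]:
    import gemmi

    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    n_before = sum(1 for model in st for chain in model for res in chain for _ in res)
    st.remove_alternative_conformations()
    n_after = sum(1 for model in st for chain in model for res in chain for _ in res)
    if n_after < n_before:
        logger.info("dropped %d alternate-location atoms (first altloc kept)",
                    n_before - n_after)
    atoms = []
    model = st[0]
    for chain in model:
        for res in chain:
            resnum = str(res.seqid.num) + (res.seqid.icode.strip() or "")
            for atom in res:
                atoms.append(ChargedAtom(
                    AtomID(chain.name, res.name, resnum, atom.name),
                    np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
    try:
        return ChargedStructure(atoms), None
    except ValidationError as e:
        raise FormatError(str(e), path) from e


def _read_pqr(path) -> tuple[ChargedStructure, ChargeState]:
    """Whitespace-token PQR: ATOM/HETATM serial name resname [chain] resnum
    x y z charge radius."""
    atoms = []
    charges: dict[AtomID, float] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.split()[0] not in ("ATOM", "HETATM"):
                continue
            toks = line.split()
            if len(toks) == 11:
                _, _, name, resname, chain, resnum = toks[:6]
                rest = toks[6:]
            elif len(toks) == 10:
                _, _, name, resname, resnum = toks[:5]
                chain = ""
                rest = toks[5:]
            else:
                raise FormatError(
                    f"expected 10 or 11 whitespace-separated fields, got {len(toks)}",
                    path, ln)
            try:
                x, y, z, q, _radius = (float(t) for t in rest)
            except ValueError:
                raise FormatError("non-numeric coordinate/charge/radius field", path, ln)
            atom_id = AtomID(chain, resname, resnum, name)
            if atom_id in charges:
                raise FormatError(f"duplicate atom identifier {atom_id}", path, ln)
            atoms.append(ChargedAtom(atom_id, np.array([x, y, z])))
            charges[atom_id] = q
    if not atoms:
        raise FormatError("no ATOM/HETATM records found", path)
    return ChargedStructure(atoms), ChargeState("pqr", charges)


def read_structure(path, format: str | None = None):
    """Read a PDB (atoms only) or PQR (atoms + base charge state) file.

    Returns ``(structure, charge_state_or_None)``.  Coordinates in Å; for PDB
    files only the first alternate location of each atom is kept (the dropped
    count is logged); duplicate atom identifiers raise.
    """
    if format is None:
        suffix = str(path).rsplit(".", 1)[-1].lower()
        format = {"pdb": "pdb", "ent": "pdb", "pqr": "pqr"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format of {path!r}; pass format='pdb'|'pqr'")
    if format == "pdb":
        return _read_pdb(path)
    if format == "pqr":
        return _read_pqr(path)
    raise ValueError(f"unknown structure format {format!r}")


# ---------------------------------------------------------------------------
# Field evaluation
# ---------------------------------------------------------------------------


def coulomb_field(structure: ChargedStructure, state: ChargeState, point,
                  eps_r: float = DEFAULT_EPS_R) -> np.ndarray:
    """Electric field vector (MV/cm) at ``point`` (Å) from the state's charges.

    The field of a positive charge points away from it.  Raises
    :class:`SingularityError` if ``point`` lies within 1e-6 Å of a charged atom.
    """
    if not eps_r > 0:
        raise ValidationError("eps_r must be > 0")
    point = np.asarray(point, dtype=float)
    q = state.charge_vector(structure)
    rvec = point[None, :] - structure.positions
    dist = np.linalg.norm(rvec, axis=1)
    near = dist <= 1e-6
    if near.any():
        i = int(np.argmax(near))
        raise SingularityError(
            f"evaluation point coincides with atom {structure.atoms[i].atom_id} "
            f"(distance {dist[i]:.2e} Å)")
    contrib = (q / dist**3)[:, None] * rvec
    return COULOMB_MV_CM / eps_r * contrib.sum(axis=0)


def project_field(field_vector, probe: ProbeGeometry) -> float:
    """Scalar projection p·E of a field vector on the probe axis (MV/cm)."""
    return float(probe.p @ np.asarray(field_vector, dtype=float))


def field_change(structure: ChargedStructure, state_ox: ChargeState,
                 state_red: ChargeState, probe: ProbeGeometry,
                 eps_r: float = DEFAULT_EPS_R) -> FieldResult:
    """Projected field change p·[E_ox − E_red] at the C–O bond midpoint.

    By linearity this equals the field of the charge-difference distribution.
    """
    point = probe.midpoint
    dE = (coulomb_field(structure, state_ox, point, eps_r)
          - coulomb_field(structure, state_red, point, eps_r))
    return FieldResult(field_vector=dE, projection=project_field(dE, probe),
                       eps_r=eps_r, state_names=(state_ox.name, state_red.name),
                       delta_total_charge=state_ox.total_charge - state_red.total_charge)


# ---------------------------------------------------------------------------
# Probe placement
# ---------------------------------------------------------------------------


def place_co_probe(fe_position, axis_unit_vector, geometry: str = "bent",
                   d_fe_c: float | None = None, d_co: float = DEFAULT_D_CO,
                   angle_deg: float | None = None,
                   bend_plane: Sequence[float] | None = None) -> ProbeGeometry:
    """Construct the CO ligand geometry on a heme axis.

    ``idealized_linear``: Fe–C–O collinear along ``axis_unit_vector`` with
    d(Fe–C) = 1.70 Å by default.  ``bent``: d(Fe–C) = 1.67 Å and an Fe–C–O
    angle of 169° by default, with the O bent inside the plane spanned by the
    axis and ``bend_plane``.  The returned geometry reproduces the requested
    angle within 0.01°.
    """
    fe = np.asarray(fe_position, dtype=float)
    u = np.asarray(axis_unit_vector, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise ValidationError("axis_unit_vector must have unit norm (within 1e-9)")
    if geometry == "idealized_linear":
        d_fe_c = 1.70 if d_fe_c is None else d_fe_c
        angle = 180.0 if angle_deg is None else angle_deg
        if abs(angle - 180.0) > 1e-9:
            raise ValidationError("idealized_linear geometry implies a 180° angle")
        c = fe + d_fe_c * u
        return ProbeGeometry(fe, c, c + d_co * u)
    if geometry != "bent":
        raise ValueError(f"unknown geometry {geometry!r}")
    d_fe_c = 1.67 if d_fe_c is None else d_fe_c
    angle = 169.0 if angle_deg is None else angle_deg
    if bend_plane is None:
        raise ValidationError("bent geometry requires a bend_plane vector")
    b = np.asarray(bend_plane, dtype=float)
    b = b / np.linalg.norm(b)
    w = b - (b @ u) * u  # in-plane direction perpendicular to the axis
    norm_w = np.linalg.norm(w)
    if norm_w < 1e-9:
        raise ValidationError("bend_plane vector is parallel to the axis")
    w = w / norm_w
    c = fe + d_fe_c * u
    alpha = math.radians(angle)
    # direction of C→O making the requested angle with C→Fe (= −u)
    v = math.cos(alpha) * (-u) + math.sin(alpha) * w
    probe = ProbeGeometry(fe, c, c + d_co * v)
    if abs(probe.fe_c_o_angle - angle) > 0.01:
        raise ValidationError(
            f"constructed angle {probe.fe_c_o_angle:.4f}° misses request {angle}°")
    return probe


# ---------------------------------------------------------------------------
# Transition table
# ---------------------------------------------------------------------------


class Transition(NamedTuple):
    """A named charge-state change, evaluated as final − initial."""

    name: str
    initial: ChargeState
    final: ChargeState


def report_transitions(structure: ChargedStructure,
                       transitions: Sequence[Transition | tuple],
                       probes: Mapping[str, ProbeGeometry],
                       eps_r: float = DEFAULT_EPS_R,
                       sums: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
    """Projected field changes (MV/cm) per transition and per probe geometry.

    Rows are transitions (plus one row per requested sum of transitions, for
    combined redox + protonation hypotheses); columns are probe names, plus
    the change in total charge.  Sums referencing unknown transition names
    raise ``KeyError``.
    """
    transitions = [t if isinstance(t, Transition) else Transition(*t) for t in transitions]
    names = [t.name for t in transitions]
    if len(set(names)) != len(names):
        raise ValidationError("transition names must be unique")
    rows = {}
    dq = {}
    for t in transitions:
        vals = {}
        for pname, probe in probes.items():
            res = field_change(structure, t.final, t.initial, probe, eps_r)
            vals[pname] = res.projection
        rows[t.name] = vals
        dq[t.name] = (t.final.total_charge - t.initial.total_charge)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["delta_charge_e"] = pd.Series(dq)
    if sums:
        for sum_name, members in sums.items():
            missing = [m for m in members if m not in table.index]
            if missing:
                raise KeyError(f"sum {sum_name!r} references unknown transitions {missing}")
            table.loc[sum_name] = table.loc[list(members)].sum(axis=0)
    table.attrs["eps_r"] = eps_r
    table.attrs["units"] = "MV/cm"
    table.attrs["convention"] = "p from C to O; field change = final − initial state"
    return table
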