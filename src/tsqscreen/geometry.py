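"""Ring geometries, torsion/planarity metrics and the HOMA index.

A candidate triplet-state quencher is judged partly on shape: whether its
8pi-electron ring is planar in the T1 state, how puckered it is in S0, and
how much the ring flattens on excitation.  This module reads per-state XYZ
geometries, computes the n signed ring torsions, the mean absolute dihedral
phi per state, the excitation change Delta(phi_T1 - phi_S0), and the
geometry-based HOMA aromaticity index.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    PairingError,
    RingIndexError,
    UnknownElementError,
    XYZParseError,
)

# Consecutive ring atoms must sit within this distance window (angstrom)
# for the declared cycle to be chemically sensible.
BOND_DISTANCE_MIN = 0.9
BOND_DISTANCE_MAX = 2.2

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn".split()
)


class StateLabel(str, Enum):
    """Electronic state of a stored geometry."""

    S0 = "S0"
    T1 = "T1"


@dataclass(frozen=True)
class StateGeometry:
    """One electronic state's molecular geometry plus its 8pi ring.

    ``ring_atoms`` is the ordered, 0-based cycle of the 6-, 7- or
    8-membered 8pi-electron ring on which every planarity and aromaticity
    metric is evaluated.
    """

    compound_id: str
    state_label: StateLabel
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), angstrom
    ring_atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "state_label", StateLabel(self.state_label))
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "ring_atoms", tuple(int(i) for i in self.ring_atoms))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise XYZParseError("coords must be an (n_atoms, 3) array")
        if len(self.elements) != coords.shape[0]:
            raise XYZParseError("element count does not match coordinate rows")
        for sym in self.elements:
            if sym not in _ELEMENTS:
                raise UnknownElementError(f"unknown element symbol {sym!r}")
        if not np.all(np.isfinite(coords)):
            raise XYZParseError("non-finite coordinates")
        n = len(self.ring_atoms)
        if n not in (6, 7, 8):
            raise RingIndexError(f"ring size must be 6, 7 or 8, got {n}")
        if len(set(self.ring_atoms)) != n:
            raise RingIndexError("ring_atoms contains duplicate indices")
        for i in self.ring_atoms:
            if not 0 <= i < coords.shape[0]:
                raise RingIndexError(f"ring atom index {i} out of range")
        ring = coords[list(self.ring_atoms)]
        d = np.linalg.norm(ring - np.roll(ring, -1, axis=0), axis=1)
        if np.any(d < BOND_DISTANCE_MIN) or np.any(d > BOND_DISTANCE_MAX):
            raise RingIndexError(
                "consecutive ring atoms outside the "
                f"{BOND_DISTANCE_MIN}-{BOND_DISTANCE_MAX} angstrom bond window"
            )

    @property
    def ring_size(self) -> int:
        return len(self.ring_atoms)


@dataclass(frozen=True)
class PlanaritySummary:
    """Mean absolute ring torsion per state and the excitation change.

    ``delta_phi`` = phi_T1 - phi_S0; negative values mean the ring
    planarizes on excitation to T1 (the behaviour of COT and of nearly all
    7/8-membered-ring candidates), positive values mean T1 puckering.
    """

    phi_s0: float
    phi_t1: float
    delta_phi: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.phi_s0 < 0 or self.phi_t1 < 0:
            raise ValueError("mean absolute dihedrals are non-negative")
        object.__setattr__(self, "delta_phi", self.phi_t1 - self.phi_s0)

    @property
    def planarizes_in_t1(self) -> bool:
        return self.delta_phi < 0


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def read_xyz(
    path: str | Path,
    ring_atoms: Sequence[int] | None = None,
    compound_id: str | None = None,
    state_label: str | StateLabel | None = None,
) -> StateGeometry:
    """Read a standard XYZ file into a :class:`StateGeometry`.

    Ring atoms (and optionally compound/state metadata) may be supplied
    directly or through a JSON sidecar ``<path>.ring.json`` with keys
    ``compound_id``, ``state``, ``ring_atoms`` (0-based).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n_atoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise XYZParseError(f"{path}: bad atom-count line {lines[0]!r}") from exc
    body = lines[2 : 2 + n_atoms]
    if len(body) < n_atoms:
        raise XYZParseError(
            f"{path}: count line declares {n_atoms} atoms, found {len(body)}"
        )
    elements: list[str] = []
    coords = np.empty((n_atoms, 3))
    for k, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: malformed atom line {line!r}")
        elements.append(parts[0])
        try:
            coords[k] = [float(x) for x in parts[1:4]]
        except ValueError as exc:
            raise XYZParseError(f"{path}: non-numeric coordinate in {line!r}") from exc

    sidecar = path.with_suffix(path.suffix + ".ring.json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if ring_atoms is None:
        ring_atoms = meta.get("ring_atoms")
    if ring_atoms is None:
        raise RingIndexError(
            f"{path}: no ring_atoms given and no sidecar {sidecar.name} found"
        )
    compound_id = compound_id or meta.get("compound_id") or path.stem
    state_label = state_label or meta.get("state") or StateLabel.S0
    return StateGeometry(
        compound_id=compound_id,
        state_label=StateLabel(state_label),
        elements=tuple(elements),
        coords=coords,
        ring_atoms=tuple(ring_atoms),
    )


def write_xyz(geom: StateGeometry, path: str | Path, sidecar: bool = True) -> None:
    """Write an XYZ file and (by default) the ring-atom JSON sidecar."""
    path = Path(path)
    lines = [str(len(geom.elements)), f"{geom.compound_id} {geom.state_label.value}"]
    for sym, (x, y, z) in zip(geom.elements, geom.coords):
        lines.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        meta = {
            "compound_id": geom.compound_id,
            "state": geom.state_label.value,
            "ring_atoms": list(geom.ring_atoms),
        }
        path.with_suffix(path.suffix + ".ring.json").write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# Torsions and planarity
# ---------------------------------------------------------------------------

def _torsion(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed IUPAC torsion angle in degrees, range (-180, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if (
        np.linalg.norm(n1) < 1e-10 * np.linalg.norm(b1) * norm_b2
        or np.linalg.norm(n2) < 1e-10 * np.linalg.norm(b3) * norm_b2
    ):
        raise DegenerateGeometryError("collinear atom triple; torsion undefined")
    ang = math.degrees(math.atan2(np.dot(np.cross(n1, n2), b2 / norm_b2), np.dot(n1, n2)))
    return 180.0 if ang <= -180.0 else ang


def ring_torsions(geom: StateGeometry) -> np.ndarray:
    """The n signed torsions over consecutive ring quadruples (i..i+3 mod n)."""
    ring = geom.coords[list(geom.ring_atoms)]
    n = len(ring)
    out = np.empty(n)
    for i in range(n):
        out[i] = _torsion(ring[i], ring[(i + 1) % n], ring[(i + 2) % n], ring[(i + 3) % n])
    return out


def mean_abs_dihedral(geom: StateGeometry) -> float:
    """phi: arithmetic mean of |torsion| over the ring, degrees (>= 0)."""
    return float(np.mean(np.abs(ring_torsions(geom))))


def delta_phi(geom_t1: StateGeometry, geom_s0: StateGeometry) -> PlanaritySummary:
    """Planarity change on S0 -> T1 excitation for one compound.

    Negative ``delta_phi`` means the ring is more planar in T1 than in S0.
    """
    if geom_t1.compound_id != geom_s0.compound_id:
        raise PairingError(
            f"compound mismatch: {geom_t1.compound_id!r} vs {geom_s0.compound_id!r}"
        )
    if geom_t1.ring_size != geom_s0.ring_size:
        raise PairingError(
            f"ring size mismatch: {geom_t1.ring_size} vs {geom_s0.ring_size}"
        )
    return PlanaritySummary(
        phi_s0=mean_abs_dihedral(geom_s0), phi_t1=mean_abs_dihedral(geom_t1)
    )


# ---------------------------------------------------------------------------
# HOMA
# ---------------------------------------------------------------------------

BondType = frozenset

#: Krygowski reference parameterization: bond type -> (alpha / A^-2, R_opt / A).
DEFAULT_HOMA_PARAMS: dict[frozenset, tuple[float, float]] = {
    frozenset({"C"}): (257.7, 1.388),
    frozenset({"C", "N"}): (93.52, 1.334),
    frozenset({"C", "O"}): (157.38, 1.265),
    frozenset({"C", "S"}): (94.09, 1.677),
    frozenset({"N"}): (130.33, 1.309),
    frozenset({"N", "O"}): (57.21, 1.248),
}


@dataclass(frozen=True)
class HomaParameters:
    """Per-bond-type (alpha, R_opt) table for the HOMA index.

    Bond types are unordered element pairs; no bond-order perception is
    attempted.  alpha is in A^-2, R_opt in angstrom.
    """

    table: Mapping[frozenset, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HOMA_PARAMS)
    )

    def __post_init__(self) -> None:
        for key, (alpha, r_opt) in self.table.items():
            if alpha <= 0:
                raise ConfigurationError(f"alpha must be positive for {set(key)}")
            if not 1.1 < r_opt < 2.0:
                raise ConfigurationError(
                    f"R_opt {r_opt} outside (1.1, 2.0) angstrom for {set(key)}"
                )

    def lookup(self, el_a: str, el_b: str) -> tuple[float, float]:
        key = frozenset({el_a, el_b})
        try:
            return self.table[key]
        except KeyError:
            raise ConfigurationError(
                f"no HOMA parameters for bond type {el_a}-{el_b}"
            ) from None

    @classmethod
    def from_json(cls, path: str | Path) -> "HomaParameters":
        """Load overrides from JSON: {"CC": [257.7, 1.388], "CN": ...}."""
        raw = json.loads(Path(path).read_text())
        table = dict(DEFAULT_HOMA_PARAMS)
        for name, (alpha, r_opt) in raw.items():
            pair = _split_bond_name(name)
            table[pair] = (float(alpha), float(r_opt))
        return cls(table=table)


def _split_bond_name(name: str) -> frozenset:
    """'CN' -> {C, N}; handles two-letter symbols like 'CSi' by case."""
    symbols = []
    cur = ""
    for ch in name:
        if ch.isupper():
            if cur:
                symbols.append(cur)
            cur = ch
        else:
            cur += ch
    if cur:
        symbols.append(cur)
    if len(symbols) == 1:
        symbols = symbols * 2
    if len(symbols) != 2:
        raise ConfigurationError(f"cannot parse bond type name {name!r}")
    return frozenset(symbols)


def homa(geom: StateGeometry, params: HomaParameters | None = None) -> float:
    """Harmonic-oscillator model of aromaticity over the declared ring.

    HOMA = 1 - (1/n) sum_i alpha_i (R_opt,i - R_i)^2 over the n ring bonds;
    1 for a perfectly bond-equalized aromatic ring, near 0 or negative for
    non- or antiaromatic rings.
    """
    params = params or HomaParameters()
    ring_idx = list(geom.ring_atoms)
    ring = geom.coords[ring_idx]
    n = len(ring_idx)
    total = 0.0
    for i in range(n):
        j = (i + 1) % n
        alpha, r_opt = params.lookup(
            geom.elements[ring_idx[i]], geom.elements[ring_idx[j]]
        )
        r = float(np.linalg.norm(ring[j] - ring[i]))
        total += alpha * (r_opt - r) ** 2
    return 1.0 - total / n
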