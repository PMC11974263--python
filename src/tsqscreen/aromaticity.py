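"""Multicenter index (MCI) aromaticity from atomic-overlap matrices.

The MCI quantifies multicenter electron delocalization around a ring from
the atomic-overlap matrices S(A) of an atoms-in-molecules partition,
expressed in the occupied-MO basis.  For a ring ordering (A1...An),

    Iring = occ^n * sum_{i1..in occ} S_{i1 i2}(A1) S_{i2 i3}(A2) ... S_{in i1}(An)
          = occ^n * Tr[ S(A1) S(A2) ... S(An) ]

and MCI sums Iring over all ring orderings distinct under rotation and
reversal, (n-1)!/2 of them — equivalently 1/(2n) times the sum over all n!
permutations.  Closed-shell wavefunctions use a single channel with MO
occupation 2 (factor 2^n); open-shell triplets use alpha and beta channels
with occupation 1 each, summed, which reduces to the closed-shell value
when the two channels coincide.

Normalized MCI^(1/n) makes rings of different size comparable; the
difference Delta MCI^(1/n) (T1 - S0) measures the aromaticity gained on
excitation — positive for Baird-aromatic T1 states such as planar COT.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AOMFormatError, DomainError
from .geometry import StateLabel

logger = logging.getLogger(__name__)

#: Largest ring size accepted by the (n-1)!/2 enumeration.
MAX_RING_SIZE = 10

#: Default tolerance on || sum_A S(A) - I || for a complete atomic partition.
CLOSURE_TOLERANCE = 1e-6

SYMMETRY_TOLERANCE = 1e-8


@dataclass(frozen=True)
class AtomicOverlapSet:
    """Per-atom, per-spin-channel overlap matrices in the occupied-MO basis.

    ``channels`` holds one array of shape (n_atoms, m, m) per spin channel:
    a single channel for a closed-shell state (occupation 2 per MO) or two
    (alpha, beta; occupation 1) for an open-shell triplet.
    """

    compound_id: str
    state_label: StateLabel
    channels: tuple[np.ndarray, ...]
    closure_tolerance: float = CLOSURE_TOLERANCE

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_label", StateLabel(self.state_label))
        chans = tuple(np.asarray(c, dtype=float) for c in self.channels)
        object.__setattr__(self, "channels", chans)
        if len(chans) not in (1, 2):
            raise AOMFormatError("expected 1 (closed-shell) or 2 (alpha/beta) channels")
        n_atoms = chans[0].shape[0]
        for c, mats in enumerate(chans):
            if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
                raise AOMFormatError(f"channel {c}: matrices must be square")
            if mats.shape[0] != n_atoms:
                raise AOMFormatError("channels disagree on atom count")
            if np.max(np.abs(mats - mats.transpose(0, 2, 1))) > SYMMETRY_TOLERANCE:
                raise AOMFormatError(f"channel {c}: S(A) not symmetric")
            resid = np.linalg.norm(mats.sum(axis=0) - np.eye(mats.shape[1]))
            if resid > self.closure_tolerance:
                # Numerically integrated partitions never close exactly;
                # warn with the residual instead of refusing the data.
                logger.warning(
                    "%s %s channel %d: sum_A S(A) deviates from identity "
                    "(||residual|| = %.3e)",
                    self.compound_id,
                    self.state_label.value,
                    c,
                    resid,
                )

    @property
    def n_atoms(self) -> int:
        return self.channels[0].shape[0]

    @property
    def spin_channels(self) -> int:
        return len(self.channels)

    @property
    def occupations(self) -> tuple[float, ...]:
        return (2.0,) if len(self.channels) == 1 else (1.0, 1.0)

    def closure_residual(self) -> float:
        return max(
            float(np.linalg.norm(c.sum(axis=0) - np.eye(c.shape[1])))
            for c in self.channels
        )


@dataclass(frozen=True)
class AromaticityRecord:
    """Raw and ring-size-normalized aromaticity indices for one compound.

    ``d_mci_norm`` = MCI_T1^(1/n) - MCI_S0^(1/n): the change in normalized
    multicenter delocalization on excitation.
    """

    n: int
    mci_s0: float
    mci_t1: float
    homa_s0: float
    homa_t1: float
    mci_norm_s0: float = field(default=None)  # type: ignore[assignment]
    mci_norm_t1: float = field(default=None)  # type: ignore[assignment]
    d_mci_norm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mci_norm_s0", normalized_mci(self.mci_s0, self.n))
        object.__setattr__(self, "mci_norm_t1", normalized_mci(self.mci_t1, self.n))
        object.__setattr__(self, "d_mci_norm", self.mci_norm_t1 - self.mci_norm_s0)


# ---------------------------------------------------------------------------
# AOM file I/O
# ---------------------------------------------------------------------------

def write_aom(aom: AtomicOverlapSet, directory: str | Path) -> Path:
    """Write one whitespace matrix file per atom/channel plus a manifest.

    Files follow ``<compound>_<state>_<spin>_atom<k>.aom``; the manifest
    JSON records the layout so :func:`read_aom` can reassemble the set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spin_names = ("a",) if aom.spin_channels == 1 else ("a", "b")
    files: list[dict] = []
    for spin, mats in zip(spin_names, aom.channels):
        for k in range(aom.n_atoms):
            name = f"{aom.compound_id}_{aom.state_label.value}_{spin}_atom{k}.aom"
            np.savetxt(directory / name, mats[k])
            files.append({"file": name, "spin": spin, "atom": k})
    manifest = {
        "compound_id": aom.compound_id,
        "state": aom.state_label.value,
        "spin_channels": aom.spin_channels,
        "occupations": list(aom.occupations),
        "files": files,
    }
    manifest_path = directory / f"{aom.compound_id}_{aom.state_label.value}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_aom(manifest_path: str | Path) -> AtomicOverlapSet:
    """Assemble an :class:`AtomicOverlapSet` from a manifest written by
    :func:`write_aom` (or hand-built in the same layout)."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    meta = json.loads(manifest_path.read_text())
    n_channels = int(meta["spin_channels"])
    spin_names = ("a",) if n_channels == 1 else ("a", "b")
    by_spin: dict[str, dict[int, np.ndarray]] = {s: {} for s in spin_names}
    for entry in meta["files"]:
        fpath = directory / entry["file"]
        if not fpath.exists():
            raise AOMFormatError(
                f"missing AOM file for atom {entry['atom']} spin {entry['spin']}: "
                f"{entry['file']}"
            )
        mat = np.atleast_2d(np.loadtxt(fpath))
        if mat.shape[0] != mat.shape[1]:
            raise AOMFormatError(f"{entry['file']}: matrix is not square {mat.shape}")
        by_spin[entry["spin"]][int(entry["atom"])] = mat
    channels = []
    for spin in spin_names:
        mats = by_spin[spin]
        if not mats:
            raise AOMFormatError(f"no matrices for spin channel {spin!r}")
        dims = {m.shape[0] for m in mats.values()}
        if len(dims) != 1:
            raise AOMFormatError(
                f"spin {spin!r}: matrix dimensions differ across atoms: {sorted(dims)}"
            )
        n_atoms = max(mats) + 1
        if set(mats) != set(range(n_atoms)):
            missing = sorted(set(range(n_atoms)) - set(mats))
            raise AOMFormatError(f"spin {spin!r}: missing atoms {missing}")
        channels.append(np.stack([mats[k] for k in range(n_atoms)]))
    return AtomicOverlapSet(
        compound_id=meta["compound_id"],
        state_label=StateLabel(meta["state"]),
        channels=tuple(channels),
    )


# ---------------------------------------------------------------------------
# Iring / MCI
# ---------------------------------------------------------------------------

def iring(aom: AtomicOverlapSet, ring_order: Sequence[int]) -> float:
    """Giambiagi ring index for one fixed ring ordering.

    Per channel this is occ^n * Tr[S(A1)...S(An)]; channels are summed.
    Invariant under cyclic rotation and reversal of ``ring_order``.
    """
    order = [int(i) for i in ring_order]
    n = len(order)
    if n < 3:
        raise DomainError("ring_order must contain at least 3 atoms")
    if len(set(order)) != n:
        raise DomainError("duplicate atom index in ring_order")
    for i in order:
        if not 0 <= i < aom.n_atoms:
            raise DomainError(f"atom index {i} out of range")
    total = 0.0
    for occ, mats in zip(aom.occupations, aom.channels):
        prod = mats[order[0]].copy()
        for a in order[1:]:
            prod = prod @ mats[a]
        total += occ**n * float(np.trace(prod))
    return total


def mci(aom: AtomicOverlapSet, ring_atoms: Sequence[int]) -> float:
    """Multicenter index: sum of Iring over the (n-1)!/2 ring orderings
    distinct under rotation and reversal.

    Equivalent to 1/(2n) times the full n!-permutation sum (see
    :func:`mci_permutation_oracle`, retained as an independent check).
    """
    atoms = [int(i) for i in ring_atoms]
    n = len(atoms)
    if n < 3:
        raise DomainError("MCI needs at least 3 ring atoms")
    if n > MAX_RING_SIZE:
        raise DomainError(
            f"ring size {n} exceeds the factorial-enumeration cap {MAX_RING_SIZE}"
        )
    if len(set(atoms)) != n:
        raise DomainError("duplicate atom index in ring_atoms")
    first, rest = atoms[0], atoms[1:]
    total = 0.0
    for perm in itertools.permutations(rest):
        # Fixing the first atom kills rotations; keeping only orderings with
        # perm[0] < perm[-1] picks one representative per reversal pair.
        if perm[0] < perm[-1]:
            total += iring(aom, (first, *perm))
    return total


def mci_permutation_oracle(aom: AtomicOverlapSet, ring_atoms: Sequence[int]) -> float:
    """Slow reference route: average Iring over all n! permutations, /(2n).

    Exists to cross-check :func:`mci`; do not use for production rings.
    """
    atoms = [int(i) for i in ring_atoms]
    n = len(atoms)
    total = 0.0
    for perm in itertools.permutations(atoms):
        total += iring(aom, perm)
    return total / (2 * n)


def normalized_mci(mci_value: float, n: int) -> float:
    """Ring-size-normalized MCI: sign-preserving n-th root sign(x)|x|^(1/n).

    The sign-preserving branch keeps the normalized axis continuous through
    zero, so antiaromatic (negative-MCI) states map to negative values.
    """
    if n < 3:
        raise DomainError("ring size must be >= 3")
    if mci_value == 0:
        return 0.0
    return math.copysign(abs(mci_value) ** (1.0 / n), mci_value)


def aromaticity_change(
    rec_s0: tuple[float, float], rec_t1: tuple[float, float], n: int
) -> AromaticityRecord:
    """Assemble the per-compound aromaticity record from (MCI, HOMA) pairs.

    ``rec_s0`` and ``rec_t1`` are (MCI, HOMA) for the two states of the
    same compound/ring; derived normalized fields are filled in.
    """
    mci_s0, homa_s0 = rec_s0
    mci_t1, homa_t1 = rec_t1
    return AromaticityRecord(
        n=n, mci_s0=mci_s0, mci_t1=mci_t1, homa_s0=homa_s0, homa_t1=homa_t1
    )
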