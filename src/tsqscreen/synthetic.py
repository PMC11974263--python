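"""Synthetic study-condition generators.

Every input the screening pipeline consumes can be generated here with the
statistical structure of the real candidate portfolio: a 214-compound-like
table of 6/7/8-membered-ring 8pi species with ring-size-specific property
distributions, planar/puckered ring geometries for the planarity metrics,
exact Hueckel-model atomic-overlap matrices for the MCI machinery, and
noisy sigmoid-truth radical-addition datasets for the photostability fit.

Ring-size property distributions (defaults):

==========  ====================  ==================  =================
property    6-MR                  7-MR                8-MR
==========  ====================  ==================  =================
E_T1        U(150, 370)           U(5, 250)           U(100, 140)
SOC         LogU(5, 126)          LogU(0.3, 14)       U(0.1, 1.0)
d_phi       N(+8, 5) deg          N(-15, 8) deg       N(-25, 8) deg
dG_inv      U(0, 10)              U(0, 40)            U(5, 40)
MCI_T1^1/n  U(0.0, 0.35)          U(0.2, 0.6)         U(0.4, 0.7)
==========  ====================  ==================  =================

lambda = E_T1 + N(10, 15) truncated to lambda > 5 kJ/mol, so most records
land in the Marcus normal region; E_S1 = E_T1 + U(80, 180) kJ/mol.  All
generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aromaticity import AromaticityRecord, AtomicOverlapSet
from .errors import DomainError
from .fits import RadicalAdditionPoint, SigmoidModel
from .geometry import PlanaritySummary, StateGeometry, StateLabel
from .photophysics import PhotophysicsRecord
from .screening import CompoundRecord, ScreeningCriteria, evaluate_compound

#: Per-ring-size sampling parameters; override via PortfolioSpec.overrides.
DEFAULT_DISTRIBUTIONS: dict[int, dict] = {
    6: {
        "e_t1": ("uniform", 150.0, 370.0),
        "soc": ("loguniform", 5.0, 126.0),
        "d_phi": ("normal", 8.0, 5.0),
        "dg_inv": ("uniform", 0.0, 10.0),
        "mci_norm_t1": ("uniform", 0.0, 0.35),
        "mci_norm_s0": ("uniform", -0.15, 0.15),
    },
    7: {
        "e_t1": ("uniform", 5.0, 250.0),
        "soc": ("loguniform", 0.3, 14.0),
        "d_phi": ("normal", -15.0, 8.0),
        "dg_inv": ("uniform", 0.0, 40.0),
        "mci_norm_t1": ("uniform", 0.2, 0.6),
        "mci_norm_s0": ("uniform", -0.1, 0.25),
    },
    8: {
        "e_t1": ("uniform", 100.0, 140.0),
        "soc": ("uniform", 0.1, 1.0),
        "d_phi": ("normal", -25.0, 8.0),
        "dg_inv": ("uniform", 5.0, 40.0),
        "mci_norm_t1": ("uniform", 0.4, 0.7),
        "mci_norm_s0": ("uniform", -0.2, 0.1),
    },
}

_HETERO_ELEMENTS = ("N", "O", "S")


@dataclass(frozen=True)
class PortfolioSpec:
    """Portfolio composition: compounds per ring size, seed, overrides.

    The default composition mirrors the screened candidate set: 117 6-MR,
    75 7-MR and 22 8-MR compounds (214 total).  ``overrides`` maps
    ring size -> {property: (family, a, b)} and is merged over
    :data:`DEFAULT_DISTRIBUTIONS`.
    """

    n6: int = 117
    n7: int = 75
    n8: int = 22
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n6, self.n7, self.n8) < 0:
            raise DomainError("compound counts must be non-negative")

    def distributions(self, ring_size: int) -> dict:
        dist = dict(DEFAULT_DISTRIBUTIONS[ring_size])
        dist.update(self.overrides.get(ring_size, {}))
        return dist


def _draw(rng: np.random.Generator, spec: tuple) -> float:
    family, a, b = spec
    if family == "uniform":
        return float(rng.uniform(a, b))
    if family == "loguniform":
        return float(np.exp(rng.uniform(np.log(a), np.log(b))))
    if family == "normal":
        return float(rng.normal(a, b))
    raise DomainError(f"unknown distribution family {family!r}")


def generate_portfolio(
    spec: PortfolioSpec, criteria: ScreeningCriteria | None = None
) -> tuple[list[CompoundRecord], dict]:
    """Generate a synthetic candidate portfolio plus planted truth labels.

    Truth labels are the per-criterion and overall verdicts of each
    generated record under ``criteria`` (defaults), recorded at generation
    time so downstream screening can be checked for exact recovery.
    """
    criteria = criteria or ScreeningCriteria()
    rng = np.random.default_rng(spec.seed)
    records: list[CompoundRecord] = []
    for ring_size, count in ((6, spec.n6), (7, spec.n7), (8, spec.n8)):
        dist = spec.distributions(ring_size)
        for k in range(count):
            e_t1 = _draw(rng, dist["e_t1"])
            soc = _draw(rng, dist["soc"])
            d_phi = _draw(rng, dist["d_phi"])
            dg_inv = _draw(rng, dist["dg_inv"])
            mci_norm_t1 = _draw(rng, dist["mci_norm_t1"])
            mci_norm_s0 = _draw(rng, dist["mci_norm_s0"])
            # lambda just above E_T1 on average: most compounds normal-region
            while True:
                lam = e_t1 + rng.normal(10.0, 15.0)
                if lam > 5.0:
                    break
            e_s1 = e_t1 + rng.uniform(80.0, 180.0)
            # per-state mean dihedrals consistent with the planted d_phi:
            # 7/8-MR planarize in T1, 6-MR pucker
            if ring_size == 6:
                phi_s0 = abs(rng.normal(0.0, 3.0))
                phi_t1 = max(phi_s0 + d_phi, 0.0)
            else:
                phi_t1 = abs(rng.normal(0.0, 2.0))
                phi_s0 = max(phi_t1 - d_phi, 0.0)
            n_het = int(rng.integers(1, 5))
            het = tuple(sorted(rng.choice(_HETERO_ELEMENTS, size=n_het)))
            mci_t1 = math.copysign(abs(mci_norm_t1) ** ring_size, mci_norm_t1)
            mci_s0 = math.copysign(abs(mci_norm_s0) ** ring_size, mci_norm_s0)
            homa_t1 = min(float(mci_norm_t1 + rng.normal(0.0, 0.05)), 1.0)
            homa_s0 = min(float(mci_norm_s0 + rng.normal(0.0, 0.05)), 1.0)
            rec = CompoundRecord(
                compound_id=f"mr{ring_size}-{k:03d}",
                ring_size=ring_size,
                class_id=int(rng.integers(1, 29)),
                heteroatoms=het,
                photophysics=PhotophysicsRecord(
                    e_t1=e_t1,
                    e_s1=e_s1,
                    soc=soc,
                    lambda_reorg=lam,
                    dg_inversion=dg_inv,
                ),
                aromaticity=AromaticityRecord(
                    n=ring_size,
                    mci_s0=mci_s0,
                    mci_t1=mci_t1,
                    homa_s0=homa_s0,
                    homa_t1=homa_t1,
                ),
                planarity=PlanaritySummary(phi_s0=phi_s0, phi_t1=phi_t1),
            )
            records.append(rec)

    truth = {}
    for rec in records:
        v = evaluate_compound(rec, criteria)
        truth[rec.compound_id] = {
            "ring_size": rec.ring_size,
            "overall": v.overall,
            "e_t1_window": v.e_t1_window,
            "soc_weak_nonzero": v.soc_weak_nonzero,
            "inversion_ok": v.inversion_ok,
            "planar_t1": v.planar_t1,
            "baird_aromatic_t1": v.baird_aromatic_t1,
            "o2_safe": v.o2_safe,
            "region": "normal"
            if rec.photophysics.e_t1 <= rec.photophysics.lambda_reorg
            else "inverted",
        }
    return records, truth


def generate_ring_geometry(
    n: int,
    pucker_amplitude: float = 0.0,
    mode: str = "planar",
    seed: int = 0,
    compound_id: str = "synthetic-ring",
    state_label: str | StateLabel = StateLabel.S0,
    jitter: float = 0.0,
) -> StateGeometry:
    """Build an n-membered carbon ring on a circle with optional pucker.

    The circle radius targets 1.40 angstrom bonds; out-of-plane
    displacement is the alternating pattern z_k = amplitude * (-1)^k
    (``tub``: the COT-like tub for even rings; ``chair-like``: the same
    alternation, restricted to even rings where it is the true chair).
    ``jitter`` adds seeded Gaussian noise to all coordinates, for
    irregular test geometries.  amplitude 0 gives an exactly planar ring.
    """
    if n not in (6, 7, 8):
        raise DomainError(f"ring size must be 6, 7 or 8, got {n}")
    if pucker_amplitude < 0:
        raise DomainError("pucker amplitude must be >= 0")
    if mode not in ("planar", "tub", "chair-like"):
        raise DomainError(f"unsupported pucker mode {mode!r}")
    if mode == "chair-like" and n % 2:
        raise DomainError("chair-like pucker requires an even-membered ring")
    radius = 1.40 / (2.0 * math.sin(math.pi / n))
    theta = 2.0 * math.pi * np.arange(n) / n
    z = np.zeros(n)
    if mode != "planar" and pucker_amplitude > 0:
        z = pucker_amplitude * (-1.0) ** np.arange(n)
    coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    if jitter > 0:
        coords = coords + np.random.default_rng(seed).normal(0.0, jitter, coords.shape)
    return StateGeometry(
        compound_id=compound_id,
        state_label=StateLabel(state_label),
        elements=("C",) * n,
        coords=coords,
        ring_atoms=tuple(range(n)),
    )


def hueckel_cycle_mos(n: int) -> np.ndarray:
    """Real orthonormal MOs of the n-site cycle, rows ordered by energy.

    Degenerate pairs are resolved to cosine/sine combinations with a fixed
    phase (cosine first), so the basis is deterministic.
    """
    mos = [np.full(n, 1.0 / math.sqrt(n))]
    a = np.arange(n)
    for k in range(1, (n - 1) // 2 + 1):
        mos.append(math.sqrt(2.0 / n) * np.cos(2.0 * math.pi * k * a / n))
        mos.append(math.sqrt(2.0 / n) * np.sin(2.0 * math.pi * k * a / n))
    if n % 2 == 0:
        mos.append((-1.0) ** a / math.sqrt(n))
    return np.array(mos)


def generate_hueckel_aom(
    n: int,
    electrons_per_spin: tuple[int, int],
    seed: int = 0,
    compound_id: str = "hueckel-cycle",
    state_label: str | StateLabel | None = None,
) -> AtomicOverlapSet:
    """Exact atomic-overlap matrices for a Hueckel n-site cycle.

    Filling the lowest ``(n_alpha, n_beta)`` cycle MOs per spin gives
    S(A)_ij = c_i(A) c_j(A), whose atomic sum is exactly the identity:
    an analytically closed partition for exercising the MCI machinery.
    Equal spin counts collapse to a single closed-shell channel.
    """
    n_alpha, n_beta = (int(e) for e in electrons_per_spin)
    if n_alpha < 0 or n_beta < 0 or n_alpha + n_beta > 2 * n:
        raise DomainError(f"infeasible electron counts {electrons_per_spin} for n={n}")
    if max(n_alpha, n_beta) > n or min(n_alpha, n_beta) < 1:
        raise DomainError("each spin channel needs between 1 and n electrons")
    mos = hueckel_cycle_mos(n)

    def channel(n_occ: int) -> np.ndarray:
        occ = mos[:n_occ]  # (n_occ, n) -- rows are occupied MOs
        return np.einsum("ia,ja->aij", occ, occ)

    if state_label is None:
        state_label = StateLabel.S0 if n_alpha == n_beta else StateLabel.T1
    if n_alpha == n_beta:
        channels: tuple[np.ndarray, ...] = (channel(n_alpha),)
    else:
        channels = (channel(n_alpha), channel(n_beta))
    return AtomicOverlapSet(
        compound_id=compound_id,
        state_label=StateLabel(state_label),
        channels=channels,
    )


def generate_sigmoid_dataset(
    model: SigmoidModel,
    n_points: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
    x_range: tuple[float, float] = (-0.1, 0.7),
    radical: str = "methyl",
) -> list[RadicalAdditionPoint]:
    """Sample a noisy radical-addition dataset from a known sigmoid truth.

    x (MCI_T1) is uniform over ``x_range``; y adds N(0, noise_sd) kJ/mol
    to the model curve.  The generating model is the stored truth.
    """
    if n_points < 5:
        raise DomainError("need at least 5 points")
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(*x_range, size=n_points))
    y = model(x) + (rng.normal(0.0, noise_sd, size=n_points) if noise_sd > 0 else 0.0)
    from .fits import Radical

    rad = Radical(radical)
    return [RadicalAdditionPoint(mci_t1=float(a), de_rxn=float(b), radical=rad) for a, b in zip(x, y)]
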