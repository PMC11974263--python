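"""The combined attribute funnel: per-compound verdicts, portfolio screening,
Marcus-region census and fluorophore matching.

A viable self-healing TSQ must simultaneously (i) have a triplet energy in
the 80-200 kJ/mol window spanned by visible-spectrum imaging fluorophores,
(iii) relax T1 -> S0 through a weak-but-nonzero spin-orbit coupling,
(iv) planarize cheaply — a low S0 inversion barrier and a planar T1 ring —
and (vi) be unable to sensitize singlet oxygen.  Baird-aromatic character
of the T1 ring (ii) is the photostability indicator and is reported as an
advisory criterion (no numeric cutoff is enforced by default), and the
heteroatom count (v) is reported but never filtered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aromaticity import AromaticityRecord
from .errors import IncompleteRecordError, SchemaError
from .geometry import PlanaritySummary
from .photophysics import (
    E_SINGLET_O2_KJMOL,
    EV_TO_KJMOL,
    MarcusRegion,
    PhotophysicsRecord,
    RateResult,
    WEAK_SOC_CUTOFF,
    classify_soc,
    marcus_k_isc,
    singlet_oxygen_gap,
)

REPORT_SCHEMA_VERSION = 1

#: Funnel order mirrors the narrative: energy window first, oxygen last.
FUNNEL_ORDER = ("e_t1_window", "soc_weak_nonzero", "inversion_ok", "planar_t1", "o2_safe")


@dataclass(frozen=True)
class CompoundRecord:
    """One screening row: identity, photophysics, aromaticity, planarity."""

    compound_id: str
    ring_size: int
    photophysics: PhotophysicsRecord
    class_id: int | None = None
    heteroatoms: tuple[str, ...] = ()
    aromaticity: AromaticityRecord | None = None
    planarity: PlanaritySummary | None = None
    rate: RateResult | None = None

    def __post_init__(self) -> None:
        if self.ring_size not in (6, 7, 8):
            raise SchemaError(
                f"{self.compound_id}: ring_size must be 6, 7 or 8, got {self.ring_size}"
            )
        if self.aromaticity is not None and self.aromaticity.n != self.ring_size:
            raise SchemaError(
                f"{self.compound_id}: aromaticity ring size {self.aromaticity.n} "
                f"inconsistent with ring_size {self.ring_size}"
            )

    def with_derived(self) -> "CompoundRecord":
        """Return a copy with the Marcus rate filled in (needs lambda)."""
        if self.photophysics.lambda_reorg is None:
            return self
        return replace(self, rate=marcus_k_isc(self.photophysics))


@dataclass(frozen=True)
class ScreeningCriteria:
    """Thresholds for the attribute funnel; every window is closed.

    ``mci_t1_norm_min`` is advisory by default (reported, not enforced):
    the screening narrative never fixes a numeric Baird-aromaticity cutoff.
    """

    e_t1_min: float = 80.0
    e_t1_max: float = 200.0
    soc_max_weak: float = WEAK_SOC_CUTOFF
    dg_inv_max: float = 35.0
    phi_t1_planar_max: float = 5.0
    mci_t1_norm_min: float = 0.35
    enforce_baird: bool = False
    e_singlet_o2: float = E_SINGLET_O2_KJMOL
    require_o2_endergonic: bool = True
    s1_margin: float = 0.0

    def __post_init__(self) -> None:
        if not self.e_t1_min < self.e_t1_max:
            raise SchemaError("e_t1_min must be below e_t1_max")
        for name in (
            "e_t1_min",
            "e_t1_max",
            "soc_max_weak",
            "dg_inv_max",
            "phi_t1_planar_max",
            "mci_t1_norm_min",
            "e_singlet_o2",
            "s1_margin",
        ):
            if not np.isfinite(getattr(self, name)):
                raise SchemaError(f"criterion {name} must be finite")

    def enforced(self) -> tuple[str, ...]:
        names = ["e_t1_window", "soc_weak_nonzero", "inversion_ok", "planar_t1"]
        if self.enforce_baird:
            names.append("baird_aromatic_t1")
        if self.require_o2_endergonic:
            names.append("o2_safe")
        return tuple(names)

    @classmethod
    def from_json(cls, path: str | Path) -> "ScreeningCriteria":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ScreeningVerdict:
    """Per-criterion booleans for one compound; ``overall`` conjoins the
    criteria enforced by the ScreeningCriteria used."""

    compound_id: str
    e_t1_window: bool
    soc_weak_nonzero: bool
    inversion_ok: bool
    planar_t1: bool
    baird_aromatic_t1: bool | None
    o2_safe: bool
    overall: bool
    notes: tuple[str, ...] = ()

    def criterion(self, name: str) -> bool:
        value = getattr(self, name)
        return bool(value)


def evaluate_compound(rec: CompoundRecord, crit: ScreeningCriteria) -> ScreeningVerdict:
    """Apply the attribute funnel's criteria to one compound.

    Raises :class:`IncompleteRecordError` when an enforced criterion needs
    a datum the record does not carry.
    """
    ph = rec.photophysics
    notes: list[str] = []

    e_t1_window = crit.e_t1_min <= ph.e_t1 <= crit.e_t1_max
    soc_weak_nonzero = 0.0 < ph.soc <= crit.soc_max_weak

    if ph.dg_inversion is None:
        raise IncompleteRecordError(
            f"{rec.compound_id}: dg_inversion required by the inversion criterion"
        )
    inversion_ok = ph.dg_inversion <= crit.dg_inv_max

    if rec.planarity is None:
        raise IncompleteRecordError(
            f"{rec.compound_id}: planarity (phi_T1) required by the planarity criterion"
        )
    planar_t1 = rec.planarity.phi_t1 <= crit.phi_t1_planar_max

    if rec.aromaticity is None:
        baird = None
        if crit.enforce_baird:
            raise IncompleteRecordError(
                f"{rec.compound_id}: aromaticity (MCI_T1^(1/n)) required because "
                "the Baird criterion is enforced"
            )
        notes.append("baird criterion skipped: no aromaticity record")
    else:
        baird = rec.aromaticity.mci_norm_t1 >= crit.mci_t1_norm_min

    _, o2_safe = singlet_oxygen_gap(ph.e_t1, crit.e_singlet_o2)

    flags = {
        "e_t1_window": e_t1_window,
        "soc_weak_nonzero": soc_weak_nonzero,
        "inversion_ok": inversion_ok,
        "planar_t1": planar_t1,
        "baird_aromatic_t1": baird,
        "o2_safe": o2_safe,
    }
    overall = all(flags[name] for name in crit.enforced())
    return ScreeningVerdict(
        compound_id=rec.compound_id, overall=overall, notes=tuple(notes), **flags
    )


@dataclass(frozen=True)
class ScreeningReport:
    """Verdicts plus ring-size totals and the sequential-criterion funnel."""

    verdicts: tuple[ScreeningVerdict, ...]
    counts_by_ring: dict  # ring size -> {"total": int, "passed": int}
    funnel: tuple[tuple[str, int], ...]  # survivors after each conjoined step
    criteria: ScreeningCriteria

    @property
    def n_total(self) -> int:
        return len(self.verdicts)

    @property
    def n_passed(self) -> int:
        return sum(v.overall for v in self.verdicts)

    def to_json_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_total": self.n_total,
            "n_passed": self.n_passed,
            "counts_by_ring": {
                str(k): dict(v) for k, v in sorted(self.counts_by_ring.items())
            },
            "funnel": [{"criterion": c, "survivors": s} for c, s in self.funnel],
            "verdicts": [
                {
                    "compound_id": v.compound_id,
                    "overall": v.overall,
                    **{
                        name: v.criterion(name) if getattr(v, name) is not None else None
                        for name in (
                            "e_t1_window",
                            "soc_weak_nonzero",
                            "inversion_ok",
                            "planar_t1",
                            "baird_aromatic_t1",
                            "o2_safe",
                        )
                    },
                }
                for v in self.verdicts
            ],
        }


def screen_portfolio(
    records: Iterable[CompoundRecord], crit: ScreeningCriteria | None = None
) -> ScreeningReport:
    """Screen a portfolio: verdicts, ring-size breakdown, criterion funnel.

    The funnel conjoins enforced criteria in :data:`FUNNEL_ORDER` (energy
    window first, singlet-oxygen criterion last) and reports the survivor
    count after each step.  Deterministic and pure.
    """
    crit = crit or ScreeningCriteria()
    records = list(records)
    verdicts = tuple(evaluate_compound(r, crit) for r in records)

    counts_by_ring: dict[int, dict[str, int]] = {}
    for rec, v in zip(records, verdicts):
        slot = counts_by_ring.setdefault(rec.ring_size, {"total": 0, "passed": 0})
        slot["total"] += 1
        slot["passed"] += int(v.overall)

    enforced = set(crit.enforced())
    funnel: list[tuple[str, int]] = []
    alive = [True] * len(verdicts)
    for name in FUNNEL_ORDER:
        if name not in enforced:
            continue
        alive = [a and v.criterion(name) for a, v in zip(alive, verdicts)]
        funnel.append((name, sum(alive)))
    return ScreeningReport(
        verdicts=verdicts,
        counts_by_ring=counts_by_ring,
        funnel=tuple(funnel),
        criteria=crit,
    )


@dataclass(frozen=True)
class MarcusCensus:
    """Normal/inverted-region counts per ring size."""

    by_ring: dict  # ring size -> {"normal": int, "inverted": int}
    skipped: int

    def inverted(self, ring_size: int) -> int:
        return self.by_ring.get(ring_size, {}).get("inverted", 0)

    def normal(self, ring_size: int) -> int:
        return self.by_ring.get(ring_size, {}).get("normal", 0)


def marcus_census(records: Iterable[CompoundRecord]) -> MarcusCensus:
    """Count compounds in the Marcus normal vs inverted region per ring size.

    A compound is normal when E_T1 <= lambda.  Records without a
    reorganization energy are skipped (counted, logged)."""
    import logging

    by_ring: dict[int, dict[str, int]] = {}
    skipped = 0
    for rec in records:
        lam = rec.photophysics.lambda_reorg
        if lam is None or lam <= 0:
            logging.getLogger(__name__).warning(
                "%s: no reorganization energy; skipped from Marcus census",
                rec.compound_id,
            )
            skipped += 1
            continue
        region = (
            MarcusRegion.NORMAL
            if rec.photophysics.e_t1 <= lam
            else MarcusRegion.INVERTED
        )
        slot = by_ring.setdefault(rec.ring_size, {"normal": 0, "inverted": 0})
        slot[region.value] += 1
    return MarcusCensus(by_ring=by_ring, skipped=skipped)


def rank_for_fluorophore(
    records: Iterable[CompoundRecord],
    fluor_e_t1: float,
    fluor_e_s1: float,
    s1_margin: float = 0.0,
) -> list[CompoundRecord]:
    """Rank TSQ candidates for one fluorophore by triplet-energy match.

    Candidates whose S1 lies at or below the fluorophore's S1 (+ margin)
    are excluded — a low TSQ S1 would quench the fluorophore's bright
    state.  Survivors sort by |E_T1(TSQ) - E_T1(fluor)| ascending, ties by
    larger k_ISC, then compound_id (stable total order).
    """
    if fluor_e_t1 <= 0 or fluor_e_s1 <= 0:
        raise SchemaError("fluorophore energies must be positive")
    pool = []
    for rec in records:
        e_s1 = rec.photophysics.e_s1
        if e_s1 is None or e_s1 <= fluor_e_s1 + s1_margin:
            continue
        rec = rec.with_derived() if rec.rate is None else rec
        pool.append(rec)
    return sorted(
        pool,
        key=lambda r: (
            abs(r.photophysics.e_t1 - fluor_e_t1),
            -(r.rate.k_isc if r.rate is not None else 0.0),
            r.compound_id,
        ),
    )


# ---------------------------------------------------------------------------
# Portfolio CSV I/O
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("compound_id", "ring_size", "e_t1_kjmol", "soc_cm1")

_OPTIONAL_NUMERIC = (
    "e_s1_kjmol",
    "lambda_kjmol",
    "dg_inv_kjmol",
    "phi_s0_deg",
    "phi_t1_deg",
    "mci_s0",
    "mci_t1",
    "homa_s0",
    "homa_t1",
)

#: Columns whose values are declared in eV by their header name and are
#: converted to the canonical kJ/mol columns on load.
_EV_ALIASES = {"e_t1_ev": "e_t1_kjmol", "e_s1_ev": "e_s1_kjmol", "lambda_ev": "lambda_kjmol"}


def load_portfolio(path: str | Path) -> list[CompoundRecord]:
    """Load a portfolio CSV into validated :class:`CompoundRecord` rows.

    Units are declared in the header: canonical columns carry a unit
    suffix (``e_t1_kjmol``, ``soc_cm1`` ...); ``*_ev`` energy columns are
    accepted and converted (x 96.485).  Missing optional columns yield
    partially populated records.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    for ev_col, kj_col in _EV_ALIASES.items():
        if ev_col in df.columns:
            if kj_col in df.columns:
                raise SchemaError(f"{path}: both {ev_col} and {kj_col} present")
            df[kj_col] = pd.to_numeric(df[ev_col], errors="coerce") * EV_TO_KJMOL
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records: list[CompoundRecord] = []
    for idx, row in df.iterrows():
        def num(col, required=False):
            if col not in df.columns or pd.isna(row[col]):
                if required:
                    raise SchemaError(f"{path}: row {idx}: missing value in {col!r}")
                return None
            try:
                return float(row[col])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path}: row {idx}: non-numeric value {row[col]!r} in {col!r}"
                ) from None

        ring_size = num("ring_size", required=True)
        if ring_size != int(ring_size):
            raise SchemaError(f"{path}: row {idx}: ring_size must be an integer")
        ph = PhotophysicsRecord(
            e_t1=num("e_t1_kjmol", required=True),
            e_s1=num("e_s1_kjmol"),
            soc=num("soc_cm1", required=True),
            lambda_reorg=num("lambda_kjmol"),
            dg_inversion=num("dg_inv_kjmol"),
        )
        arom = None
        if all(
            c in df.columns and not pd.isna(row[c])
            for c in ("mci_s0", "mci_t1", "homa_s0", "homa_t1")
        ):
            arom = AromaticityRecord(
                n=int(ring_size),
                mci_s0=num("mci_s0"),
                mci_t1=num("mci_t1"),
                homa_s0=num("homa_s0"),
                homa_t1=num("homa_t1"),
            )
        plan = None
        if all(
            c in df.columns and not pd.isna(row[c]) for c in ("phi_s0_deg", "phi_t1_deg")
        ):
            plan = PlanaritySummary(phi_s0=num("phi_s0_deg"), phi_t1=num("phi_t1_deg"))
        het: tuple[str, ...] = ()
        if "heteroatoms" in df.columns and not pd.isna(row["heteroatoms"]):
            het = tuple(s for s in str(row["heteroatoms"]).split(";") if s)
        class_id = None
        if "class_id" in df.columns and not pd.isna(row["class_id"]):
            class_id = int(row["class_id"])
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                ring_size=int(ring_size),
                class_id=class_id,
                heteroatoms=het,
                photophysics=ph,
                aromaticity=arom,
                planarity=plan,
            )
        )
    return records


def portfolio_frame(records: Sequence[CompoundRecord], derived: bool = True) -> pd.DataFrame:
    """Flatten records to the canonical portfolio table.

    With ``derived=True`` the Marcus rate, region, SOC class and
    singlet-oxygen flag columns are recomputed and appended.
    """
    rows = []
    for rec in records:
        ph = rec.photophysics
        row: dict = {
            "compound_id": rec.compound_id,
            "class_id": rec.class_id,
            "ring_size": rec.ring_size,
            "heteroatoms": ";".join(rec.heteroatoms),
            "n_heteroatoms": len(rec.heteroatoms),
            "e_t1_kjmol": ph.e_t1,
            "e_s1_kjmol": ph.e_s1,
            "soc_cm1": ph.soc,
            "lambda_kjmol": ph.lambda_reorg,
            "dg_inv_kjmol": ph.dg_inversion,
        }
        if rec.planarity is not None:
            row.update(
                phi_s0_deg=rec.planarity.phi_s0,
                phi_t1_deg=rec.planarity.phi_t1,
                d_phi_deg=rec.planarity.delta_phi,
            )
        if rec.aromaticity is not None:
            a = rec.aromaticity
            row.update(
                mci_s0=a.mci_s0,
                mci_t1=a.mci_t1,
                homa_s0=a.homa_s0,
                homa_t1=a.homa_t1,
                mci_norm_s0=a.mci_norm_s0,
                mci_norm_t1=a.mci_norm_t1,
                d_mci_norm=a.d_mci_norm,
            )
        if derived:
            row["soc_class"] = classify_soc(ph.soc).value
            gap, endergonic = singlet_oxygen_gap(ph.e_t1)
            row["o2_gap_kjmol"] = gap
            row["o2_endergonic"] = endergonic
            if ph.lambda_reorg is not None and ph.lambda_reorg > 0:
                rate = marcus_k_isc(ph)
                row["k_isc_per_s"] = rate.k_isc
                row["region"] = rate.region.value
        rows.append(row)
    return pd.DataFrame(rows)


def save_portfolio(
    records: Sequence[CompoundRecord], path: str | Path, derived: bool = False
) -> None:
    portfolio_frame(records, derived=derived).to_csv(path, index=False)
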