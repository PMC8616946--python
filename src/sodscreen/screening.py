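"""Three-stage high-throughput screening funnel for SOD-mimetic candidates.

Stage 1 keeps simple, stable chemistries: at most ``max_elements`` elements,
energy above the convex hull below ``hull_max`` (thermodynamic stability),
minimum phonon-frequency-squared proxy above ``omega2_min_threshold``
(kinetic stability) and a nonzero HSE band gap.  Stage 2 keeps materials
whose only iFMO is a single band edge (types I or II by default).  Stage 3
applies the adsorption-energy selectivity criterion.  Comparisons are
strict exactly as stated for each filter: hull "<", omega2 ">", gap ">",
element count "<=", adsorption energies ">".

Missing data is a per-stage machine-readable fail reason
(``missing_data:<field>``), never an exception, so one malformed record
cannot abort a run.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import __version__ as _pkg_version
from .energy_levels import (
    BandStructureSummary,
    BandType,
    PotentialWindow,
    DEFAULT_WINDOW,
    classify_band_structure,
)
from .exceptions import InvalidInputError, InvalidTableError
from .thermo import (
    AdsorptionEnergies,
    Conditions,
    DEFAULT_CONDITIONS,
    DEFAULT_FREE_ENERGY_MODEL,
    FreeEnergyModel,
    criterion_thresholds,
    evaluate_adsorption_criterion,
)

# coded fail reasons
TOO_MANY_ELEMENTS = "too_many_elements"
HULL_EXCEEDED = "hull_exceeded"
NOT_KINETICALLY_STABLE = "not_kinetically_stable"
ZERO_GAP = "zero_gap"
NO_IFMO = "no_ifmo"
DISALLOWED_TYPE = "disallowed_type"
HO_BELOW_THRESHOLD = "ho_below_threshold"
H_BELOW_THRESHOLD = "h_below_threshold"
X1_BELOW_HALF = "x1_below_half"


def missing(fieldname: str) -> str:
    return f"missing_data:{fieldname}"


@dataclass(frozen=True)
class MaterialRecord:
    """One screening candidate with stability, band and adsorption descriptors."""

    material_id: str
    formula: str = ""
    n_elements: int | None = None
    delta_h_hull: float | None = None  # eV/atom above the convex hull
    omega2_min: float | None = None  # eV/A^2, minimum phonon omega^2 proxy
    e_gap_hse: float | None = None  # eV
    band_summary: BandStructureSummary | None = None
    ads: AdsorptionEnergies | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not str(self.material_id):
            raise InvalidInputError("material_id must be non-empty")
        if self.n_elements is not None and self.n_elements < 1:
            raise InvalidInputError(f"{self.material_id}: n_elements must be >= 1")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and sub-model settings for one funnel run."""

    max_elements: int = 2
    hull_max: float = 0.2  # eV/atom, strict "<"
    omega2_min_threshold: float = 1e-5  # eV/A^2, strict ">"
    gap_min: float = 0.0  # eV, strict ">"
    window: PotentialWindow = field(default_factory=PotentialWindow)
    allowed_types: frozenset[BandType] = frozenset({BandType.I, BandType.II})
    adsorption_mode: str = "rectangle"
    conditions: Conditions = field(default_factory=Conditions)
    free_energy_model: FreeEnergyModel = field(default_factory=FreeEnergyModel)

    def __post_init__(self) -> None:
        for name in ("hull_max", "omega2_min_threshold", "gap_min"):
            v = getattr(self, name)
            if v is None or v != v:
                raise InvalidInputError(f"{name} must be a finite number")
        if not self.allowed_types:
            raise InvalidInputError("allowed_types must be non-empty")
        object.__setattr__(
            self, "allowed_types", frozenset(BandType(t) for t in self.allowed_types)
        )
        if self.adsorption_mode not in ("rectangle", "full_x1"):
            raise InvalidInputError(f"unknown adsorption_mode {self.adsorption_mode!r}")

    def snapshot(self) -> dict:
        """JSON-serialisable view of the configuration."""
        return {
            "max_elements": self.max_elements,
            "hull_max": self.hull_max,
            "omega2_min_threshold": self.omega2_min_threshold,
            "gap_min": self.gap_min,
            "window": {
                "phi1": self.window.phi1,
                "phi2": self.window.phi2,
                "tolerance": self.window.tolerance,
            },
            "allowed_types": sorted(t.value for t in self.allowed_types),
            "adsorption_mode": self.adsorption_mode,
            "conditions": {
                "temperature": self.conditions.temperature,
                "ph": self.conditions.ph,
                "nernst_slope": self.conditions.nernst_slope,
                "proton_coefficients": list(self.conditions.proton_coefficients),
            },
            "free_energy_constants": list(self.free_energy_model.constants),
        }


DEFAULT_CONFIG = ScreenConfig()


@dataclass(frozen=True)
class StageResult:
    """Outcome of one stage for one material; passed iff no fail reasons."""

    material_id: str
    stage: int
    passed: bool
    fail_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (not self.fail_reasons):
            raise InvalidInputError("passed must be equivalent to empty fail_reasons")


def _result(material_id: str, stage: int, reasons: Sequence[str]) -> StageResult:
    return StageResult(
        material_id=material_id,
        stage=stage,
        passed=not reasons,
        fail_reasons=tuple(reasons),
    )


def stage_stability(r: MaterialRecord, cfg: ScreenConfig = DEFAULT_CONFIG) -> StageResult:
    """Stage 1: composition simplicity, thermodynamic/kinetic stability, gap."""
    reasons: list[str] = []
    if r.n_elements is None:
        reasons.append(missing("n_elements"))
    elif r.n_elements > cfg.max_elements:
        reasons.append(TOO_MANY_ELEMENTS)
    if r.delta_h_hull is None:
        reasons.append(missing("delta_h_hull"))
    elif not r.delta_h_hull < cfg.hull_max:
        reasons.append(HULL_EXCEEDED)
    if r.omega2_min is None:
        reasons.append(missing("omega2_min"))
    elif not r.omega2_min > cfg.omega2_min_threshold:
        reasons.append(NOT_KINETICALLY_STABLE)
    if r.e_gap_hse is None:
        reasons.append(missing("e_gap_hse"))
    elif not r.e_gap_hse > cfg.gap_min:
        reasons.append(ZERO_GAP)
    return _result(r.material_id, 1, reasons)


def stage_energy_level(r: MaterialRecord, cfg: ScreenConfig = DEFAULT_CONFIG) -> StageResult:
    """Stage 2: the only iFMO must be a band edge of an allowed type."""
    if r.band_summary is None:
        return _result(r.material_id, 2, [missing("band_summary")])
    c = classify_band_structure(r.band_summary, cfg.window)
    if not c.passes_energy_criterion:
        return _result(r.material_id, 2, [NO_IFMO])
    if c.band_type not in cfg.allowed_types:
        return _result(r.material_id, 2, [DISALLOWED_TYPE])
    return _result(r.material_id, 2, [])


def stage_adsorption(r: MaterialRecord, cfg: ScreenConfig = DEFAULT_CONFIG) -> StageResult:
    """Stage 3: adsorption-energy selectivity criterion."""
    reasons: list[str] = []
    ads = r.ads
    if ads is None:
        return _result(r.material_id, 3, [missing("e_ads_ho"), missing("e_ads_h")])
    if ads.e_ads_ho is None:
        reasons.append(missing("e_ads_ho"))
    if ads.e_ads_h is None:
        reasons.append(missing("e_ads_h"))
    if reasons:
        return _result(r.material_id, 3, reasons)
    if cfg.adsorption_mode == "rectangle":
        ho_thr, h_thr = criterion_thresholds(cfg.conditions, cfg.free_energy_model)
        if not ads.e_ads_ho > ho_thr:
            reasons.append(HO_BELOW_THRESHOLD)
        if not ads.e_ads_h > h_thr:
            reasons.append(H_BELOW_THRESHOLD)
    else:
        passes, _x1 = evaluate_adsorption_criterion(
            ads, cfg.conditions, cfg.adsorption_mode, cfg.free_energy_model
        )
        if not passes:
            reasons.append(X1_BELOW_HALF)
    return _result(r.material_id, 3, reasons)


_STAGES = (stage_stability, stage_energy_level, stage_adsorption)


@dataclass(frozen=True)
class FunnelReport:
    """Per-stage counts and per-material results of one screening run."""

    input_count: int
    stage_counts: tuple[int, int, int]  # survivors after stages 1, 2, 3
    results: Mapping[str, tuple[StageResult, ...]]
    config: dict
    metadata: dict

    def __post_init__(self) -> None:
        counts = (self.input_count, *self.stage_counts)
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise InvalidInputError("funnel counts must be non-increasing")

    @property
    def survivors(self) -> list[str]:
        """Materials that passed all three stages, in input order."""
        return [
            mid
            for mid, res in self.results.items()
            if len(res) == 3 and all(r.passed for r in res)
        ]

    def missing_data_counts(self) -> dict[str, int]:
        """How often each missing_data:<field> reason occurred."""
        counts: dict[str, int] = {}
        for res in self.results.values():
            for stage in res:
                for reason in stage.fail_reasons:
                    if reason.startswith("missing_data:"):
                        counts[reason] = counts.get(reason, 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "stage_counts": list(self.stage_counts),
            "results": {
                mid: [
                    {
                        "stage": r.stage,
                        "passed": r.passed,
                        "fail_reasons": list(r.fail_reasons),
                    }
                    for r in res
                ]
                for mid, res in self.results.items()
            },
            "config": self.config,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FunnelReport":
        results = {
            mid: tuple(
                StageResult(
                    material_id=mid,
                    stage=r["stage"],
                    passed=r["passed"],
                    fail_reasons=tuple(r["fail_reasons"]),
                )
                for r in res
            )
            for mid, res in d["results"].items()
        }
        return cls(
            input_count=d["input_count"],
            stage_counts=tuple(d["stage_counts"]),
            results=results,
            config=d.get("config", {}),
            metadata=d.get("metadata", {}),
        )


def run_screen(
    records: Sequence[MaterialRecord],
    cfg: ScreenConfig = DEFAULT_CONFIG,
    seed: int | None = None,
) -> FunnelReport:
    """Run the three-stage funnel over a materials table.

    A material is evaluated at stage k only if it passed stage k-1, so its
    result list is as long as its survival.  The run is deterministic for a
    fixed input table and order-invariant in its counts and per-material
    results.
    """
    records = list(records)
    if not records:
        raise InvalidTableError("the materials table is empty")
    ids = [r.material_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidTableError(f"duplicate material ids: {dupes}")

    results: dict[str, tuple[StageResult, ...]] = {}
    counts = [0, 0, 0]
    for rec in records:
        trail: list[StageResult] = []
        for k, stage in enumerate(_STAGES):
            res = stage(rec, cfg)
            trail.append(res)
            if not res.passed:
                break
            counts[k] += 1
        results[rec.material_id] = tuple(trail)

    metadata = {
        "seed": seed,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        "version": _pkg_version,
    }
    return FunnelReport(
        input_count=len(records),
        stage_counts=tuple(counts),
        results=results,
        config=cfg.snapshot(),
        metadata=metadata,
    )


def supercell_plan(a_length: float, b_length: float) -> tuple[int, int]:
    """In-plane supercell multipliers for adsorption calculations.

    Single pass: first the aspect check — if one vector is strictly more
    than 1.5x the other, the shorter one is doubled; then, on the updated
    lengths, the minimum-length check — if either is no larger than 5 A
    (<=), both are doubled.  Multipliers are therefore in {1, 2, 4}.
    """
    if not (a_length > 0 and b_length > 0):
        raise InvalidInputError("cell vector lengths must be positive")
    mult_a = mult_b = 1
    if a_length > 1.5 * b_length:
        mult_b = 2
    elif b_length > 1.5 * a_length:
        mult_a = 2
    a_new, b_new = a_length * mult_a, b_length * mult_b
    if a_new <= 5.0 or b_new <= 5.0:
        mult_a *= 2
        mult_b *= 2
    return mult_a, mult_b
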