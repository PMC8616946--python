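"""Materials-table and report file formats, plus the run configuration schema.

Tables travel as UTF-8 CSV (header row, C-locale numbers, empty cell =
absent, semicolon-separated mid-gap lists) or as a JSON array of objects
with the same keys.  All potentials in files are V vs the hydrogen
electrode at pH 7; all energies eV; units are baked into the column names.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .energy_levels import BandStructureSummary, BandType, PotentialWindow
from .exceptions import FormatError, InvalidInputError, SodscreenError
from .screening import FunnelReport, MaterialRecord, ScreenConfig
from .thermo import AdsorptionEnergies, Conditions, FreeEnergyModel, ScalingRelation

logger = logging.getLogger("sodscreen")

COLUMNS = [
    "material_id",
    "formula",
    "n_elements",
    "is_metal",
    "fermi_potential_V",
    "vbm_potential_V",
    "cbm_potential_V",
    "occupied_midgap_V",
    "unoccupied_midgap_V",
    "delta_h_hull_eV_per_atom",
    "omega2_min_eV_per_A2",
    "e_gap_hse_eV",
    "e_ads_ho_eV",
    "e_ads_h_eV",
    "e_ads_o_eV",
]

#: significant digits preserved by the round trip
_SIGNIFICANT_DIGITS = 12


def _fmt(v: float | int | str | None) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return v
    if isinstance(v, int):
        return str(v)
    return f"{v:.{_SIGNIFICANT_DIGITS}g}"


def _parse_float(cell: str | None, column: str, line: int) -> float | None:
    if cell is None or str(cell).strip() == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise FormatError(f"line {line}: column {column!r}: unparsable number {cell!r}") from exc


def _parse_midgap(cell, column: str, line: int) -> tuple[float, ...]:
    if cell is None:
        return ()
    if isinstance(cell, (list, tuple)):
        return tuple(float(v) for v in cell)
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(
        _parse_float(part, column, line) for part in text.split(";") if part.strip() != ""
    )


@dataclass(frozen=True)
class RowDiagnostic:
    """A recoverable problem found while reading a table row."""

    line: int
    material_id: str
    message: str


class MaterialsTable(Sequence):
    """A validated list of records plus per-row read diagnostics."""

    def __init__(self, records: list[MaterialRecord], diagnostics: list[RowDiagnostic]):
        self.records = records
        self.diagnostics = diagnostics

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self):
        return iter(self.records)


def _record_from_cells(cells: dict, line: int) -> MaterialRecord:
    mid = str(cells.get("material_id") or "").strip()
    if not mid:
        raise FormatError(f"line {line}: material_id is required")
    metal_raw = cells.get("is_metal")
    metal_txt = "" if metal_raw is None else str(metal_raw).strip().lower()
    fermi = _parse_float(cells.get("fermi_potential_V"), "fermi_potential_V", line)
    vbm = _parse_float(cells.get("vbm_potential_V"), "vbm_potential_V", line)
    cbm = _parse_float(cells.get("cbm_potential_V"), "cbm_potential_V", line)
    omg = _parse_midgap(cells.get("occupied_midgap_V"), "occupied_midgap_V", line)
    umg = _parse_midgap(cells.get("unoccupied_midgap_V"), "unoccupied_midgap_V", line)
    if metal_txt in ("true", "1"):
        is_metal = True
    elif metal_txt in ("false", "0"):
        is_metal = False
    elif metal_txt == "":
        # infer from which frontier levels are present
        is_metal = fermi is not None and vbm is None and cbm is None
    else:
        raise FormatError(f"line {line}: is_metal must be true/false, got {metal_raw!r}")

    summary: BandStructureSummary | None = None
    try:
        if is_metal and fermi is not None:
            summary = BandStructureSummary(
                material_id=mid, is_metal=True, fermi_potential=fermi
            )
        elif not is_metal and vbm is not None and cbm is not None:
            summary = BandStructureSummary(
                material_id=mid,
                is_metal=False,
                vbm_potential=vbm,
                cbm_potential=cbm,
                occupied_midgap=omg,
                unoccupied_midgap=umg,
            )
    except InvalidInputError as exc:
        raise FormatError(f"line {line}: {exc}") from exc

    n_elements_f = _parse_float(cells.get("n_elements"), "n_elements", line)
    ads = AdsorptionEnergies(
        e_ads_ho=_parse_float(cells.get("e_ads_ho_eV"), "e_ads_ho_eV", line),
        e_ads_h=_parse_float(cells.get("e_ads_h_eV"), "e_ads_h_eV", line),
        e_ads_o=_parse_float(cells.get("e_ads_o_eV"), "e_ads_o_eV", line),
    )
    return MaterialRecord(
        material_id=mid,
        formula=str(cells.get("formula") or ""),
        n_elements=None if n_elements_f is None else int(n_elements_f),
        delta_h_hull=_parse_float(
            cells.get("delta_h_hull_eV_per_atom"), "delta_h_hull_eV_per_atom", line
        ),
        omega2_min=_parse_float(
            cells.get("omega2_min_eV_per_A2"), "omega2_min_eV_per_A2", line
        ),
        e_gap_hse=_parse_float(cells.get("e_gap_hse_eV"), "e_gap_hse_eV", line),
        band_summary=summary,
        ads=ads,
    )


def _infer_format(path: Path, format: str | None) -> str:
    if format:
        return format
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_materials_table(path: str | Path, format: str | None = None) -> MaterialsTable:
    """Read and validate a materials table.

    A malformed header is a hard :class:`FormatError` naming the missing
    column.  Row-level problems (unparsable numbers, violated band-edge
    conventions) become :class:`RowDiagnostic` entries with line numbers;
    the offending rows are excluded from the returned records.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[MaterialRecord] = []
    diagnostics: list[RowDiagnostic] = []

    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise FormatError(f"{path}: empty file") from None
            for col in COLUMNS:
                if col not in header:
                    raise FormatError(f"{path}: missing header column {col!r}")
            extra = [c for c in header if c not in COLUMNS]
            if extra:
                raise FormatError(f"{path}: unknown header columns {extra}")
            for line_no, row in enumerate(reader, start=2):
                if not any(cell.strip() for cell in row):
                    continue
                cells = dict(zip(header, row))
                try:
                    records.append(_record_from_cells(cells, line_no))
                except SodscreenError as exc:
                    diagnostics.append(
                        RowDiagnostic(
                            line=line_no,
                            material_id=str(cells.get("material_id", "")),
                            message=str(exc),
                        )
                    )
                    logger.warning("skipping row: %s", exc)
    elif fmt == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(data, list):
            raise FormatError(f"{path}: a JSON materials table must be an array of objects")
        for idx, obj in enumerate(data, start=1):
            unknown = [k for k in obj if k not in COLUMNS]
            if unknown:
                raise FormatError(f"{path}: record {idx}: unknown keys {unknown}")
            try:
                records.append(_record_from_cells(obj, idx))
            except SodscreenError as exc:
                diagnostics.append(
                    RowDiagnostic(
                        line=idx, material_id=str(obj.get("material_id", "")), message=str(exc)
                    )
                )
                logger.warning("skipping record: %s", exc)
    else:
        raise FormatError(f"unknown table format {fmt!r}")

    return MaterialsTable(records, diagnostics)


def _record_to_cells(r: MaterialRecord) -> dict:
    s = r.band_summary
    ads = r.ads
    return {
        "material_id": r.material_id,
        "formula": r.formula,
        "n_elements": r.n_elements,
        "is_metal": None if s is None else s.is_metal,
        "fermi_potential_V": None if s is None else s.fermi_potential,
        "vbm_potential_V": None if s is None else s.vbm_potential,
        "cbm_potential_V": None if s is None else s.cbm_potential,
        "occupied_midgap_V": None if s is None else list(s.occupied_midgap),
        "unoccupied_midgap_V": None if s is None else list(s.unoccupied_midgap),
        "delta_h_hull_eV_per_atom": r.delta_h_hull,
        "omega2_min_eV_per_A2": r.omega2_min,
        "e_gap_hse_eV": r.e_gap_hse,
        "e_ads_ho_eV": None if ads is None else ads.e_ads_ho,
        "e_ads_h_eV": None if ads is None else ads.e_ads_h,
        "e_ads_o_eV": None if ads is None else ads.e_ads_o,
    }


def write_materials_table(
    records: Sequence[MaterialRecord], path: str | Path, format: str | None = None
) -> Path:
    """Write records in the table format (values kept to 12 significant digits)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(COLUMNS)
            for r in records:
                cells = _record_to_cells(r)
                row = []
                for col in COLUMNS:
                    v = cells[col]
                    if isinstance(v, list):
                        row.append(";".join(_fmt(x) for x in v))
                    else:
                        row.append(_fmt(v))
                writer.writerow(row)
    elif fmt == "json":
        payload = []
        for r in records:
            cells = _record_to_cells(r)
            obj = {}
            for col in COLUMNS:
                v = cells[col]
                if v is None or v == []:
                    continue
                if isinstance(v, float):
                    v = float(f"{v:.{_SIGNIFICANT_DIGITS}g}")
                elif isinstance(v, list):
                    v = [float(f"{x:.{_SIGNIFICANT_DIGITS}g}") for x in v]
                obj[col] = v
            payload.append(obj)
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise FormatError(f"unknown table format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# funnel reports
# ---------------------------------------------------------------------------


def write_report(
    report: FunnelReport, path: str | Path, format: Literal["json", "csv", "markdown"] = "json"
) -> Path:
    """Serialise a funnel report as machine-readable JSON, per-material CSV
    or a markdown funnel summary."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=1), encoding="utf-8")
    elif format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["material_id", "last_stage", "passed_all", "fail_reasons"]
            )
            for mid, res in report.results.items():
                last = res[-1]
                passed_all = len(res) == 3 and last.passed
                writer.writerow(
                    [mid, last.stage, str(passed_all).lower(), ";".join(last.fail_reasons)]
                )
    elif format == "markdown":
        lines = [
            "| stage | description | surviving |",
            "| --- | --- | --- |",
            f"| input | materials read | {report.input_count} |",
            f"| 1 | stability and composition | {report.stage_counts[0]} |",
            f"| 2 | single band-edge iFMO in window | {report.stage_counts[1]} |",
            f"| 3 | adsorption-energy selectivity | {report.stage_counts[2]} |",
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise FormatError(f"unknown report format {format!r}")
    return path


def read_report(path: str | Path) -> FunnelReport:
    """Reload a JSON funnel report."""
    return FunnelReport.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConditionsConfig(_Forbid):
    temperature: float = 298.15
    ph: float = 7.0
    nernst_slope: float = 0.0592
    proton_coefficients: list[float] = Field(default_factory=lambda: [1, 1, 1, 1, 1])


class WindowConfig(_Forbid):
    phi1: float = -0.16
    phi2: float = 0.94
    tolerance: float = 0.0


class ScalingConfig(_Forbid):
    slope: float = 1.87
    intercept: float = 1.42


class FreeEnergyConfig(_Forbid):
    constants: list[float] = Field(default_factory=lambda: [-1.3, 1.4, 2.1, 8.54, 16.4])
    ho_coefficients: list[float] = Field(default_factory=lambda: [0, 1, 0, 2.87, 3.74])
    h_coefficients: list[float] = Field(default_factory=lambda: [0, 0, 1, 0, 1])


class ScreenSettings(_Forbid):
    max_elements: int = 2
    hull_max: float = 0.2
    omega2_min_threshold: float = 1e-5
    gap_min: float = 0.0
    allowed_types: list[str] = Field(default_factory=lambda: ["I", "II"])
    adsorption_mode: Literal["rectangle", "full_x1"] = "rectangle"


class RunConfig(_Forbid):
    """Schema of the run-configuration file (YAML or JSON); unknown keys rejected."""

    screen: ScreenSettings = Field(default_factory=ScreenSettings)
    conditions: ConditionsConfig = Field(default_factory=ConditionsConfig)
    window: WindowConfig = Field(default_factory=WindowConfig)
    scaling: ScalingConfig = Field(default_factory=ScalingConfig)
    free_energy: FreeEnergyConfig = Field(default_factory=FreeEnergyConfig)

    def to_screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            max_elements=self.screen.max_elements,
            hull_max=self.screen.hull_max,
            omega2_min_threshold=self.screen.omega2_min_threshold,
            gap_min=self.screen.gap_min,
            window=PotentialWindow(
                phi1=self.window.phi1, phi2=self.window.phi2, tolerance=self.window.tolerance
            ),
            allowed_types=frozenset(BandType(t) for t in self.screen.allowed_types),
            adsorption_mode=self.screen.adsorption_mode,
            conditions=Conditions(
                temperature=self.conditions.temperature,
                ph=self.conditions.ph,
                nernst_slope=self.conditions.nernst_slope,
                proton_coefficients=tuple(self.conditions.proton_coefficients),
            ),
            free_energy_model=FreeEnergyModel(
                constants=tuple(self.free_energy.constants),
                ho_coefficients=tuple(self.free_energy.ho_coefficients),
                h_coefficients=tuple(self.free_energy.h_coefficients),
            ),
        )

    def scaling_relation(self) -> ScalingRelation:
        return ScalingRelation(slope=self.scaling.slope, intercept=self.scaling.intercept)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML/JSON run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise FormatError(f"{path}: invalid run configuration:\n{exc}") from exc
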