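"""Synthetic materials tables and packaged worked-example records.

The generator emulates a 2D-materials-database-like property table: each
record carries the stability descriptors, band-edge placement relative to
the dismutation window, and adsorption energies correlated along the
O*-vs-HO* scaling line.  Every screening stage removes a tunable fraction
of records, so funnel behaviour can be exercised at any size without a
download.  Band-edge placement is parameterised by the probabilities of
the type outcomes (I, II, III, ...) rather than by absolute-potential
distributions, which makes stage-2 behaviour directly tunable.

Default stage-pass targets mirror the proportions of the published 2D
screen: roughly 10% of gapped candidates survive the stability stage, a
third of those expose a single band edge in the window, and ~96% of those
satisfy the adsorption criterion.

:func:`reference_fixture` packages the handful of experimentally or
computationally characterised reference materials (graphene, V2C MXene,
nanographene, the MIL-53(Fe)-X substituent series, pristine CeO2(111) and
a MIL-47(V)-like frame) as frozen, source-annotated records.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .energy_levels import BandStructureSummary, BandType, PotentialWindow
from .exceptions import InvalidInputError
from .screening import MaterialRecord
from .thermo import AdsorptionEnergies, ScalingRelation, DEFAULT_SCALING

_ELEMENTS = (
    "B", "C", "N", "O", "Si", "P", "S", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Zr", "Nb", "Mo", "Pd", "Sn", "Hf", "Ta", "W", "Pt",
)


def _check_fraction(name: str, v: float, upper_open: bool = False) -> float:
    ok = 0.0 <= v < 1.0 if upper_open else 0.0 <= v <= 1.0
    if not ok:
        raise InvalidInputError(f"{name} must lie in [0, 1{')' if upper_open else ']'}, got {v}")
    return float(v)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic materials table.

    ``stage1_pass_target`` applies within the gapped subpopulation (metals
    have no gap and always fail the stability stage's gap filter);
    ``stage2_pass_target`` is the probability that a gapped survivor is of
    type I or II; ``stage3_pass_target`` the probability that both
    adsorption energies clear their thresholds.  Targets are approximate —
    they set per-gate sampling probabilities, and realised fractions
    fluctuate binomially.
    """

    n_materials: int = 500
    seed: int = 0
    metal_fraction: float = 0.1
    stage1_pass_target: float = 370 / 3814
    stage2_pass_target: float = 126 / 370
    stage3_pass_target: float = 121 / 126
    hull_threshold: float = 0.2  # eV/atom boundary the hull draw straddles
    omega2_threshold: float = 1e-5  # eV/A^2
    window: PotentialWindow = field(default_factory=PotentialWindow)
    scaling: ScalingRelation = field(default_factory=ScalingRelation)
    scaling_noise_sd: float = 0.15  # eV, scatter around the O*-HO* line
    missing_rate: float = 0.0  # per optional adsorption field

    def __post_init__(self) -> None:
        if self.n_materials < 1:
            raise InvalidInputError("n_materials must be >= 1")
        _check_fraction("metal_fraction", self.metal_fraction)
        for name in ("stage1_pass_target", "stage2_pass_target", "stage3_pass_target"):
            _check_fraction(name, getattr(self, name))
        _check_fraction("missing_rate", self.missing_rate, upper_open=True)
        if self.scaling_noise_sd < 0:
            raise InvalidInputError("scaling_noise_sd must be >= 0")


def _formula(rng: np.random.Generator, n_elements: int) -> str:
    symbols = rng.choice(len(_ELEMENTS), size=n_elements, replace=False)
    parts = []
    for idx in symbols:
        count = int(rng.integers(1, 4))
        parts.append(_ELEMENTS[idx] + (str(count) if count > 1 else ""))
    return "".join(parts)


def _gapped_summary(
    rng: np.random.Generator, material_id: str, band_type: BandType, w: PotentialWindow
) -> BandStructureSummary:
    """Place band edges (and mid-gap levels) realising the requested type."""
    lo, hi = w.phi1, w.phi2
    inside = lambda: float(rng.uniform(lo + 0.05, hi - 0.05))
    below = lambda: float(rng.uniform(lo - 2.0, lo - 0.05))
    above = lambda: float(rng.uniform(hi + 0.05, hi + 2.0))
    omg: tuple[float, ...] = ()
    umg: tuple[float, ...] = ()
    if band_type is BandType.I:
        vbm, cbm = inside(), below()
    elif band_type is BandType.II:
        cbm, vbm = inside(), above()
    elif band_type is BandType.III:
        a, b = sorted(rng.uniform(lo + 0.05, hi - 0.05, size=2))
        cbm, vbm = float(a), float(b)
        if vbm - cbm < 1e-3:
            vbm = cbm + 1e-3
    elif band_type is BandType.IV:
        cbm, vbm = below(), above()
        omg = (inside(),)
    elif band_type is BandType.V:
        cbm, vbm = below(), above()
        umg = (inside(),)
    elif band_type is BandType.VI:
        cbm, vbm = below(), above()
    elif band_type is BandType.VII:
        vbm = below()
        cbm = float(rng.uniform(lo - 4.0, vbm - 0.05))
    elif band_type is BandType.VIII:
        cbm = above()
        vbm = float(rng.uniform(cbm + 0.05, hi + 4.0))
    else:  # pragma: no cover - metals handled separately
        raise InvalidInputError(f"not a gapped type: {band_type}")
    return BandStructureSummary(
        material_id=material_id,
        is_metal=False,
        vbm_potential=vbm,
        cbm_potential=cbm,
        occupied_midgap=omg,
        unoccupied_midgap=umg,
    )


#: relative weights of the non-passing gapped types drawn when stage 2 fails
_FAIL_TYPE_WEIGHTS = {
    BandType.III: 0.15,
    BandType.IV: 0.10,
    BandType.V: 0.10,
    BandType.VI: 0.25,
    BandType.VII: 0.20,
    BandType.VIII: 0.20,
}


def generate_materials_table(spec: FixtureSpec) -> list[MaterialRecord]:
    """Draw ``spec.n_materials`` records, reproducibly for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    # gap filter auto-passes for gapped records, so stage 1 has three live gates
    p_gate = spec.stage1_pass_target ** (1.0 / 3.0)
    p_ads_gate = math.sqrt(spec.stage3_pass_target)
    fail_types = list(_FAIL_TYPE_WEIGHTS)
    fail_weights = np.array([_FAIL_TYPE_WEIGHTS[t] for t in fail_types])
    fail_weights = fail_weights / fail_weights.sum()

    records: list[MaterialRecord] = []
    for i in range(spec.n_materials):
        mid = f"syn-{i:05d}"
        is_metal = bool(rng.random() < spec.metal_fraction)

        if rng.random() < p_gate:
            n_elements = int(rng.integers(1, 3))
        else:
            n_elements = int(rng.integers(3, 6))
        if rng.random() < p_gate:
            hull = float(rng.uniform(0.0, spec.hull_threshold))
        else:
            hull = float(rng.uniform(spec.hull_threshold, 3 * spec.hull_threshold))
        if rng.random() < p_gate:
            omega2 = float(10 ** rng.uniform(-4.0, -1.0))
        else:
            omega2 = float(rng.uniform(-0.05, 0.0))  # imaginary mode present

        if is_metal:
            gap = 0.0
            # metal Fermi level inside/below/above the window
            u = rng.random()
            if u < 0.4:
                fermi = float(rng.uniform(spec.window.phi1 + 0.05, spec.window.phi2 - 0.05))
            elif u < 0.7:
                fermi = float(rng.uniform(spec.window.phi1 - 2.0, spec.window.phi1 - 0.05))
            else:
                fermi = float(rng.uniform(spec.window.phi2 + 0.05, spec.window.phi2 + 2.0))
            summary = BandStructureSummary(
                material_id=mid, is_metal=True, fermi_potential=fermi
            )
        else:
            if rng.random() < spec.stage2_pass_target:
                btype = BandType.I if rng.random() < 0.5 else BandType.II
            else:
                btype = fail_types[int(rng.choice(len(fail_types), p=fail_weights))]
            summary = _gapped_summary(rng, mid, btype, spec.window)
            gap = summary.gap

        if rng.random() < p_ads_gate:
            e_ho = float(rng.uniform(-2.6, -0.5))
        else:
            e_ho = float(rng.uniform(-4.5, -2.8))
        if rng.random() < p_ads_gate:
            e_h = float(rng.uniform(-3.3, -0.5))
        else:
            e_h = float(rng.uniform(-6.0, -3.5))
        e_o = spec.scaling.predict(e_ho) + float(rng.normal(0.0, spec.scaling_noise_sd))

        ho_v: float | None = e_ho
        h_v: float | None = e_h
        o_v: float | None = e_o
        if spec.missing_rate > 0:
            if rng.random() < spec.missing_rate:
                ho_v = None
            if rng.random() < spec.missing_rate:
                h_v = None
            if rng.random() < spec.missing_rate:
                o_v = None

        records.append(
            MaterialRecord(
                material_id=mid,
                formula=_formula(rng, n_elements),
                n_elements=n_elements,
                delta_h_hull=hull,
                omega2_min=omega2,
                e_gap_hse=gap,
                band_summary=summary,
                ads=AdsorptionEnergies(e_ads_ho=ho_v, e_ads_h=h_v, e_ads_o=o_v),
                provenance=f"synthetic seed={spec.seed}",
            )
        )
    return records


def generate_scaling_points(
    n: int,
    slope: float = DEFAULT_SCALING.slope,
    intercept: float = DEFAULT_SCALING.intercept,
    noise_sd: float = 0.0,
    seed: int = 0,
    ho_range: tuple[float, float] = (-5.0, 0.0),
) -> list[tuple[float, float]]:
    """(E_ads,HO, E_ads,O) pairs on the scaling line plus Gaussian noise."""
    if n < 2:
        raise InvalidInputError("n must be >= 2")
    rng = np.random.default_rng(seed)
    x = rng.uniform(ho_range[0], ho_range[1], size=n)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n)
    return [(float(a), float(b)) for a, b in zip(x, y)]


# ---------------------------------------------------------------------------
# worked-example records
# ---------------------------------------------------------------------------

#: Hammett sigma_m substituent constants (standard handbook values).
HAMMETT_SIGMA_M = {
    "NH2": -0.16,
    "CH3": -0.07,
    "H": 0.00,
    "OH": 0.12,
    "F": 0.34,
    "Cl": 0.37,
    "Br": 0.39,
    "NO2": 0.71,
}


@dataclass(frozen=True)
class MOFRecord:
    """One MIL-53(Fe)-X substituent with its reduction potential (V vs HE, pH 7).

    Only the series endpoints (X = NH2 and NO2) have individually reported
    potentials; the intermediates are linear interpolations in sigma_m and
    carry ``synthetic_interpolated=True``.
    """

    substituent: str
    hammett_sigma_m: float
    reduction_potential: float
    synthetic_interpolated: bool
    source: str


def mil53_series() -> list[MOFRecord]:
    """The MIL-53(Fe)-X substituent series ordered by electron-withdrawing strength."""
    anchors = {"NH2": 0.28, "NO2": 0.31}
    s_lo, s_hi = HAMMETT_SIGMA_M["NH2"], HAMMETT_SIGMA_M["NO2"]
    v_lo, v_hi = anchors["NH2"], anchors["NO2"]
    out = []
    for x, sigma in sorted(HAMMETT_SIGMA_M.items(), key=lambda kv: kv[1]):
        if x in anchors:
            pot, interp = anchors[x], False
            src = "cyclic-voltammetry reduction potential vs HE at pH 7"
        else:
            pot = v_lo + (sigma - s_lo) / (s_hi - s_lo) * (v_hi - v_lo)
            interp = True
            src = "synthetic: linear interpolation in sigma_m between reported endpoints"
        out.append(
            MOFRecord(
                substituent=x,
                hammett_sigma_m=sigma,
                reduction_potential=round(pot, 4),
                synthetic_interpolated=interp,
                source=src,
            )
        )
    return out


@dataclass(frozen=True)
class ReferenceMaterial:
    """One packaged worked-example material with a provenance note."""

    name: str
    band_summary: BandStructureSummary | None = None
    reduction_potential: float | None = None
    ads: AdsorptionEnergies | None = None
    source: str = ""


def reference_fixture() -> dict[str, ReferenceMaterial]:
    """Frozen reference records used throughout examples and tests."""
    fx: dict[str, ReferenceMaterial] = {}
    fx["graphene"] = ReferenceMaterial(
        name="graphene",
        band_summary=BandStructureSummary(
            material_id="graphene", is_metal=True, fermi_potential=-0.19
        ),
        source="reported Fermi level of graphene, V vs HE at pH 7 (just below phi1)",
    )
    fx["V2C"] = ReferenceMaterial(
        name="V2C",
        band_summary=BandStructureSummary(
            material_id="V2C", is_metal=True, fermi_potential=-0.11
        ),
        source="measured reduction potential of the V2C MXene, V vs HE at pH 7",
    )
    fx["nanographene"] = ReferenceMaterial(
        name="nanographene",
        reduction_potential=0.40,
        source="measured reduction potential of nanographene, inside the window",
    )
    fx["CeO2_111_pristine"] = ReferenceMaterial(
        name="CeO2_111_pristine",
        ads=AdsorptionEnergies(e_ads_ho=None, e_ads_h=-3.68),
        source="DFT H* adsorption energy on the defect-free ceria (111) surface",
    )
    fx["MIL47_V"] = ReferenceMaterial(
        name="MIL47_V",
        ads=AdsorptionEnergies(e_ads_ho=-0.76, e_ads_h=-4.25),
        source="DFT adsorption energies typical of the MIL-47(V)-X frames "
        "(HO* about -0.76 eV, H* at or below -4.25 eV)",
    )
    for rec in mil53_series():
        fx[f"MIL53_{rec.substituent}"] = ReferenceMaterial(
            name=f"MIL53_{rec.substituent}",
            reduction_potential=rec.reduction_potential,
            source=rec.source,
        )
    return fx


def fixture_checksum() -> str:
    """SHA-256 over a canonical serialisation of the packaged fixture values.

    Guards against silent drift of the frozen reference numbers.
    """
    fx = reference_fixture()
    payload = {}
    for name, rec in sorted(fx.items()):
        payload[name] = {
            "fermi": rec.band_summary.fermi_potential if rec.band_summary else None,
            "reduction_potential": rec.reduction_potential,
            "e_ads_ho": rec.ads.e_ads_ho if rec.ads else None,
            "e_ads_h": rec.ads.e_ads_h if rec.ads else None,
        }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
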