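"""Energy-level (frontier-orbital) screening of superoxide-dismutase mimics.

Superoxide dismutation proceeds through two half-reactions whose reduction
potentials at pH 7 are phi1 = -0.16 V (O2/O2-) and phi2 = 0.94 V
(O2-,H+/H2O2) versus the hydrogen electrode.  A material can shuttle
electrons between the two half-reactions only if it owns a frontier level
whose potential lies strictly inside the window (phi1, phi2); such a level
is called an intermediate frontier molecular orbital (iFMO).  Candidate
frontier levels are the valence-band maximum (VBM), conduction-band minimum
(CBM), mid-gap impurity levels (occupied or unoccupied), or, for metals,
the Fermi level.

Band structures fall into eleven types: I-VIII for gapped materials (I VBM
inside, II CBM inside, III both edges inside, IV occupied mid-gap level
inside, V unoccupied mid-gap level inside, VI window spanned by the gap,
VII all levels below phi1, VIII all levels above phi2) and IX-XI for metals
(Fermi level inside / below / above).  Occupied iFMOs drive a
HOMO-mediated cycle (the material is first oxidised), unoccupied iFMOs a
LUMO-mediated one (first reduced); a metallic or mixed set supports both.
Activity is expected to peak for levels near the window midpoint
(phi1 + phi2)/2 = 0.39 V.

Convention: the canonical scale is V versus the hydrogen electrode at pH 7,
on which more positive = more oxidising, so a gapped material satisfies
vbm_potential > cbm_potential (the conduction edge is the more reducing
level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .exceptions import InvalidInputError

#: Default absolute potential of the standard hydrogen electrode vs vacuum (V).
ABSOLUTE_SHE_DEFAULT = 4.44


class BandType(str, Enum):
    """The eleven frontier-level dispositions relative to the window."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"
    IX = "IX"
    X = "X"
    XI = "XI"


#: Occupancy labels for iFMO levels.
OCCUPIED = "occupied"
UNOCCUPIED = "unoccupied"
METALLIC = "metallic"

#: Mechanism labels.
HOMO_MEDIATED = "HOMO-mediated"
LUMO_MEDIATED = "LUMO-mediated"
BOTH = "both"
NONE = "none"


def _finite(name: str, v: float) -> float:
    if v is None or not math.isfinite(v):
        raise InvalidInputError(f"{name} must be a finite number, got {v!r}")
    return float(v)


@dataclass(frozen=True)
class PotentialWindow:
    """The dismutation half-reaction window (phi1, phi2), V vs HE at pH 7.

    ``tolerance`` widens the open interval symmetrically; the default 0
    keeps membership strictly open, so a level exactly at phi1 or phi2 is
    outside.
    """

    phi1: float = -0.16
    phi2: float = 0.94
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        _finite("phi1", self.phi1)
        _finite("phi2", self.phi2)
        if not self.phi1 < self.phi2:
            raise InvalidInputError("phi1 must be < phi2")
        if self.tolerance < 0:
            raise InvalidInputError("tolerance must be >= 0")

    @property
    def lower(self) -> float:
        return self.phi1 - self.tolerance

    @property
    def upper(self) -> float:
        return self.phi2 + self.tolerance

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.phi1 + self.phi2)

    def contains(self, potential: float) -> bool:
        """Strictly-open membership test (phi1 - tol, phi2 + tol)."""
        return self.lower < potential < self.upper


DEFAULT_WINDOW = PotentialWindow()


@dataclass(frozen=True)
class BandStructureSummary:
    """Frontier-level summary of one material on the V-vs-HE(pH 7) scale.

    Metals carry ``fermi_potential`` and no band edges.  Gapped materials
    carry both edges with vbm_potential > cbm_potential, and every mid-gap
    level strictly between the edges.
    """

    material_id: str
    is_metal: bool
    fermi_potential: float | None = None
    vbm_potential: float | None = None
    cbm_potential: float | None = None
    occupied_midgap: tuple[float, ...] = ()
    unoccupied_midgap: tuple[float, ...] = ()
    work_function: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "occupied_midgap", tuple(self.occupied_midgap))
        object.__setattr__(self, "unoccupied_midgap", tuple(self.unoccupied_midgap))
        if self.is_metal:
            _finite("fermi_potential", self.fermi_potential)
            if self.vbm_potential is not None or self.cbm_potential is not None:
                raise InvalidInputError(
                    f"{self.material_id}: a metal carries a Fermi level and no band edges"
                )
            if self.occupied_midgap or self.unoccupied_midgap:
                raise InvalidInputError(f"{self.material_id}: a metal has no mid-gap levels")
        else:
            if self.fermi_potential is not None:
                raise InvalidInputError(
                    f"{self.material_id}: gapped materials are described by band edges, "
                    "not a Fermi potential"
                )
            vbm = _finite("vbm_potential", self.vbm_potential)
            cbm = _finite("cbm_potential", self.cbm_potential)
            if not vbm > cbm:
                raise InvalidInputError(
                    f"{self.material_id}: on the potential scale the VBM must lie above "
                    f"the CBM (vbm_potential > cbm_potential); got vbm={vbm}, cbm={cbm}"
                )
            for level in self.occupied_midgap + self.unoccupied_midgap:
                _finite("mid-gap level", level)
                if not (cbm < level < vbm):
                    raise InvalidInputError(
                        f"{self.material_id}: mid-gap level {level} V must lie strictly "
                        f"between the CBM ({cbm} V) and the VBM ({vbm} V)"
                    )
        if self.work_function is not None:
            _finite("work_function", self.work_function)

    @property
    def gap(self) -> float | None:
        """Band gap in eV (potential separation of the edges); None for metals."""
        if self.is_metal:
            return None
        return self.vbm_potential - self.cbm_potential


@dataclass(frozen=True)
class FMOClassification:
    """Outcome of the energy-level screen for one material."""

    material_id: str
    band_type: BandType
    ifmo_levels: tuple[tuple[float, str], ...]
    mechanism: str
    passes_energy_criterion: bool

    def __post_init__(self) -> None:
        if self.passes_energy_criterion != bool(self.ifmo_levels):
            raise InvalidInputError("passes_energy_criterion must mirror iFMO presence")
        if (self.mechanism == NONE) != (not self.ifmo_levels):
            raise InvalidInputError("mechanism is 'none' exactly when there is no iFMO")


def _mechanism_from_levels(levels: Iterable[tuple[float, str]]) -> str:
    occupancies = {occ for _, occ in levels}
    if not occupancies:
        return NONE
    if METALLIC in occupancies or occupancies == {OCCUPIED, UNOCCUPIED}:
        return BOTH
    return HOMO_MEDIATED if occupancies == {OCCUPIED} else LUMO_MEDIATED


def classify_band_structure(
    s: BandStructureSummary, w: PotentialWindow = DEFAULT_WINDOW
) -> FMOClassification:
    """Assign the band-structure type and collect every iFMO.

    Mixed cases (a band edge and a mid-gap level both inside) keep the
    edge-based type label and list all in-window levels.
    """
    ifmo: list[tuple[float, str]] = []
    if s.is_metal:
        ef = s.fermi_potential
        if w.contains(ef):
            ifmo.append((ef, METALLIC))
            band_type = BandType.IX
        elif ef <= w.lower:
            band_type = BandType.X
        else:
            band_type = BandType.XI
    else:
        vbm_in = w.contains(s.vbm_potential)
        cbm_in = w.contains(s.cbm_potential)
        if vbm_in:
            ifmo.append((s.vbm_potential, OCCUPIED))
        if cbm_in:
            ifmo.append((s.cbm_potential, UNOCCUPIED))
        omg_in = [lv for lv in s.occupied_midgap if w.contains(lv)]
        umg_in = [lv for lv in s.unoccupied_midgap if w.contains(lv)]
        ifmo.extend((lv, OCCUPIED) for lv in omg_in)
        ifmo.extend((lv, UNOCCUPIED) for lv in umg_in)
        if vbm_in and cbm_in:
            band_type = BandType.III
        elif vbm_in:
            band_type = BandType.I
        elif cbm_in:
            band_type = BandType.II
        elif omg_in:
            band_type = BandType.IV
        elif umg_in:
            band_type = BandType.V
        elif s.vbm_potential <= w.lower:
            band_type = BandType.VII  # everything below phi1
        elif s.cbm_potential >= w.upper:
            band_type = BandType.VIII  # everything above phi2
        else:
            band_type = BandType.VI  # the gap spans the window
    mechanism = _mechanism_from_levels(ifmo)
    return FMOClassification(
        material_id=s.material_id,
        band_type=band_type,
        ifmo_levels=tuple(ifmo),
        mechanism=mechanism,
        passes_energy_criterion=bool(ifmo),
    )


def predict_mechanism(c: FMOClassification) -> str:
    """Mechanism implied by the iFMO occupancies of a classification."""
    return _mechanism_from_levels(c.ifmo_levels)


def evaluate_energy_criterion(
    s: BandStructureSummary, w: PotentialWindow = DEFAULT_WINDOW
) -> bool:
    """True iff the material owns at least one iFMO (phi1 < E_FMO < phi2)."""
    return classify_band_structure(s, w).passes_energy_criterion


def midpoint_proximity_score(
    level: float, w: PotentialWindow = DEFAULT_WINDOW
) -> tuple[float, float]:
    """(window midpoint, |level - midpoint|); lower score = predicted more active."""
    _finite("level", level)
    mid = w.midpoint
    return mid, abs(level - mid)


def rank_by_midpoint_proximity(
    named_levels: Sequence[tuple[str, float]], w: PotentialWindow = DEFAULT_WINDOW
) -> list[tuple[str, float, float]]:
    """Sort (name, level) pairs by midpoint proximity, most active first.

    Returns (name, level, score) triples sorted by ascending score.
    """
    scored = [(name, lv, midpoint_proximity_score(lv, w)[1]) for name, lv in named_levels]
    return sorted(scored, key=lambda t: t[2])


# ---------------------------------------------------------------------------
# reference-scale conversions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeMeasurement:
    """One electrochemical potential with its reference electrode and pH."""

    value: float
    reference: str
    measured_ph: float
    sce_offset: float = 0.245
    nernst_slope: float = 0.0592

    def __post_init__(self) -> None:
        _finite("value", self.value)
        ref = str(self.reference).upper()
        if ref not in ("SCE", "HE"):
            raise InvalidInputError(f"unknown reference electrode {self.reference!r}")
        object.__setattr__(self, "reference", ref)
        if not 0.0 <= self.measured_ph <= 14.0:
            raise InvalidInputError(f"measured_ph must be in [0, 14], got {self.measured_ph}")


def delta_ph(m: ElectrodeMeasurement, target_ph: float) -> float:
    """Signed pH difference target - measured used by the conversion."""
    return target_ph - m.measured_ph


def convert_potential(m: ElectrodeMeasurement, target_ph: float) -> float:
    """Convert a measurement to V vs the hydrogen electrode at ``target_ph``.

    result = value - nernst_slope * (target_ph - measured_ph)
             + sce_offset (only for SCE-referenced values).
    """
    _finite("target_ph", target_ph)
    out = m.value - m.nernst_slope * delta_ph(m, target_ph)
    if m.reference == "SCE":
        out += m.sce_offset
    return out


def vacuum_to_he(
    level_vs_vacuum: float,
    target_ph: float = 0.0,
    absolute_she: float = ABSOLUTE_SHE_DEFAULT,
    nernst_slope: float = 0.0592,
) -> float:
    """Map an electron level referenced to vacuum onto the HE potential scale.

    ``level_vs_vacuum`` is the electron energy in eV (a work function W_f
    enters as -W_f).  The standard hydrogen electrode sits at
    -absolute_she eV vs vacuum (default 4.44 V, configurable), and the
    hydrogen-electrode scale shifts with pH by the Nernst slope using the
    same sign convention as :func:`convert_potential`.
    """
    _finite("level_vs_vacuum", level_vs_vacuum)
    return -(level_vs_vacuum + absolute_she) - nernst_slope * target_ph


def he_to_vacuum(
    potential: float,
    target_ph: float = 0.0,
    absolute_she: float = ABSOLUTE_SHE_DEFAULT,
    nernst_slope: float = 0.0592,
) -> float:
    """Inverse of :func:`vacuum_to_he`; round-trips to within 1e-12."""
    _finite("potential", potential)
    return -(potential + nernst_slope * target_ph) - absolute_she


def summary_from_reduction_potential(
    material_id: str,
    potential: float,
    gap_placeholder: float = 3.0,
) -> BandStructureSummary:
    """Ingest a measured reduction potential as a band-structure summary.

    A reduction potential is the potential at which the material accepts an
    electron, i.e. its lowest unoccupied frontier level; it is represented
    as the CBM of a gapped material.  The VBM is unknown from such a
    measurement, so a synthetic placeholder ``gap_placeholder`` volts above
    the CBM (well outside the default window) is used.
    """
    _finite("potential", potential)
    if gap_placeholder <= 0:
        raise InvalidInputError("gap_placeholder must be > 0")
    return BandStructureSummary(
        material_id=material_id,
        is_metal=False,
        cbm_potential=potential,
        vbm_potential=potential + gap_placeholder,
    )
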