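"""Mixed-field BNCT dosimetry: kerma-based absorbed dose and CBE/RBE weighting.

In boron neutron capture therapy the absorbed dose delivered during a
thermal-neutron irradiation is the sum of four components:

* ``D_B`` — the boron dose from the ¹⁰B(n,α)⁷Li capture reaction, linear in
  both the ¹⁰B tissue concentration (μg ¹⁰B/g) and the thermal-neutron
  fluence (n/cm²) through a kerma coefficient of 7.43×10⁻¹⁴ Gy·cm² per
  (μg ¹⁰B/g);
* ``D_N`` — the nitrogen dose from ¹⁴N(n,p)¹⁴C capture, linear in the tissue
  nitrogen content (weight %) and the thermal fluence with kerma
  coefficient 6.78×10⁻¹⁴ Gy·cm² per weight %;
* ``D_H`` — the hydrogen-recoil dose from elastic scattering of epithermal
  and fast neutrons on ¹H;
* ``D_γ`` — the photon dose from ¹H(n,γ)²H capture and beam contamination.

``D_H`` and ``D_γ`` depend on the epithermal/fast spectrum and the photon
field, which a fluence-based model cannot predict; they are accepted as
measured per-irradiation calibration inputs.

The photon-equivalent dose (Gy-Eq) weights each component by its biological
effectiveness relative to photons: the compound biological effectiveness
(CBE) for the boron component — tissue- and compound-specific, 3.8 for
spinal-cord tumour and 1.35 for normal spinal cord with BPA — and relative
biological effectiveness (RBE) factors of 3.0 for the nitrogen and
hydrogen-recoil components. The photon component carries weight 1.

Because only total absorbed doses are usually tabulated, the module also
supports the background-subtraction decomposition: the absorbed dose of a
boron-free ("neutron only") irradiation is subtracted from a boron-loaded
total to recover ``D_B``, which is then CBE-weighted and added to the
background photon-equivalent dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._rounding import round_half_up

__all__ = [
    "BORON_KERMA",
    "NITROGEN_KERMA",
    "CBE_TUMOR",
    "CBE_NORMAL_CORD",
    "RBE_NITROGEN",
    "RBE_HYDROGEN",
    "DEFAULT_NITROGEN_WT_PCT",
    "NeutronField",
    "TissueComposition",
    "RadiobiologicalWeights",
    "DoseComponents",
    "DoseReport",
    "fluence_from_flux",
    "boron_dose",
    "nitrogen_dose",
    "absorbed_dose",
    "photon_equivalent_dose",
    "decompose_boron_component",
    "equivalent_via_background",
    "build_dose_report",
]

#: Kerma coefficient of the ¹⁰B(n,α)⁷Li reaction, Gy·cm² per (μg ¹⁰B/g).
BORON_KERMA = 7.43e-14
#: Kerma coefficient of the ¹⁴N(n,p)¹⁴C reaction, Gy·cm² per weight-% N.
NITROGEN_KERMA = 6.78e-14

#: Compound biological effectiveness of BPA in spinal-cord tumour tissue.
CBE_TUMOR = 3.8
#: Compound biological effectiveness of BPA in normal spinal cord.
CBE_NORMAL_CORD = 1.35
#: RBE of the nitrogen-capture proton dose.
RBE_NITROGEN = 3.0
#: RBE of the hydrogen-recoil (fast neutron) dose.
RBE_HYDROGEN = 3.0

#: Soft-tissue nitrogen content (weight %) used when none is supplied.
DEFAULT_NITROGEN_WT_PCT = 3.5


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class NeutronField:
    """A thermal-neutron irradiation field.

    Either ``thermal_fluence`` is given directly, or it is derived from
    ``flux × duration``. If all three are supplied they must be
    consistent. ``measured_dh`` and ``measured_dgamma`` are the calibrated
    hydrogen-recoil and photon doses for this irradiation, in Gy.
    """

    thermal_fluence: float | None = None  # n/cm²
    flux: float | None = None  # n/cm²/s
    duration: float | None = None  # s
    measured_dh: float = 0.0  # Gy
    measured_dgamma: float = 0.0  # Gy

    def __post_init__(self) -> None:
        for name in ("thermal_fluence", "flux", "duration"):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(
                    self, name, _require_finite_nonneg(name, value)
                )
        _require_finite_nonneg("measured_dh", self.measured_dh)
        _require_finite_nonneg("measured_dgamma", self.measured_dgamma)
        if self.thermal_fluence is None:
            if self.flux is None or self.duration is None:
                raise ValueError(
                    "NeutronField needs thermal_fluence or both flux and duration"
                )
            object.__setattr__(
                self, "thermal_fluence", fluence_from_flux(self.flux, self.duration)
            )
        elif self.flux is not None and self.duration is not None:
            derived = self.flux * self.duration
            if not math.isclose(derived, self.thermal_fluence, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    "thermal_fluence inconsistent with flux × duration: "
                    f"{self.thermal_fluence!r} vs {derived!r}"
                )


@dataclass(frozen=True)
class TissueComposition:
    """Boron and nitrogen content of one tissue."""

    name: str
    boron_conc: float  # μg ¹⁰B/g
    nitrogen_wt_pct: float = DEFAULT_NITROGEN_WT_PCT  # weight %

    def __post_init__(self) -> None:
        _require_finite_nonneg("boron_conc", self.boron_conc)
        if not 0 <= self.nitrogen_wt_pct <= 100:
            raise ValueError(
                f"nitrogen_wt_pct must be in [0, 100], got {self.nitrogen_wt_pct!r}"
            )


@dataclass(frozen=True)
class RadiobiologicalWeights:
    """CBE/RBE weights applied to the dose components of one tissue."""

    cbe: float
    rbe_n: float = RBE_NITROGEN
    rbe_h: float = RBE_HYDROGEN

    def __post_init__(self) -> None:
        for name in ("cbe", "rbe_n", "rbe_h"):
            value = float(getattr(self, name))
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class DoseComponents:
    """The four absorbed-dose terms for one tissue, in Gy."""

    d_b: float
    d_n: float
    d_h: float
    d_gamma: float

    def __post_init__(self) -> None:
        for name in ("d_b", "d_n", "d_h", "d_gamma"):
            _require_finite_nonneg(name, getattr(self, name))

    def total(self) -> float:
        return self.d_b + self.d_n + self.d_h + self.d_gamma


@dataclass(frozen=True)
class DoseReport:
    """Absorbed and photon-equivalent dose for one tissue."""

    tissue: str
    components: DoseComponents
    weights: RadiobiologicalWeights
    absorbed: float = field(init=False)
    photon_equivalent: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "absorbed", absorbed_dose(self.components))
        object.__setattr__(
            self,
            "photon_equivalent",
            photon_equivalent_dose(self.components, self.weights),
        )

    def rounded(self, ndigits: int = 1) -> tuple[float, float]:
        """(absorbed, photon-equivalent) rounded half-up for table output."""
        return (
            round_half_up(self.absorbed, ndigits),
            round_half_up(self.photon_equivalent, ndigits),
        )


def fluence_from_flux(flux: float, duration: float) -> float:
    """Time-integrated fluence (n/cm²) of a constant flux over ``duration`` s."""
    return _require_finite_nonneg("flux", flux) * _require_finite_nonneg(
        "duration", duration
    )


def boron_dose(boron_conc: float, thermal_fluence: float) -> float:
    """Absorbed dose (Gy) from ¹⁰B(n,α)⁷Li capture.

    ``7.43e-14 Gy·cm²/(μg ¹⁰B/g) × boron_conc × thermal_fluence``.
    """
    return (
        BORON_KERMA
        * _require_finite_nonneg("boron_conc", boron_conc)
        * _require_finite_nonneg("thermal_fluence", thermal_fluence)
    )


def nitrogen_dose(nitrogen_wt_pct: float, thermal_fluence: float) -> float:
    """Absorbed dose (Gy) from ¹⁴N(n,p)¹⁴C capture.

    ``6.78e-14 Gy·cm²/weight% × nitrogen_wt_pct × thermal_fluence``.
    """
    if not 0 <= nitrogen_wt_pct <= 100:
        raise ValueError(
            f"nitrogen_wt_pct must be in [0, 100], got {nitrogen_wt_pct!r}"
        )
    return (
        NITROGEN_KERMA
        * nitrogen_wt_pct
        * _require_finite_nonneg("thermal_fluence", thermal_fluence)
    )


def absorbed_dose(components: DoseComponents) -> float:
    """Total absorbed dose in Gy: D_B + D_N + D_H + D_γ."""
    return components.total()


def photon_equivalent_dose(
    components: DoseComponents, weights: RadiobiologicalWeights
) -> float:
    """Photon-equivalent dose in Gy-Eq.

    ``D_B × CBE + D_N × RBE_N + D_H × RBE_H + D_γ`` — the photon term
    carries an implicit weight of 1.
    """
    return (
        components.d_b * weights.cbe
        + components.d_n * weights.rbe_n
        + components.d_h * weights.rbe_h
        + components.d_gamma
    )


def decompose_boron_component(
    total_absorbed_bnct: float, background_absorbed: float
) -> float:
    """Recover D_B by subtracting a boron-free background absorbed dose.

    The background is the absorbed dose of an identical irradiation without
    boron loading (its components are D_N + D_H + D_γ only), so the excess
    of the boron-loaded total over it is the boron dose.
    """
    total = _require_finite_nonneg("total_absorbed_bnct", total_absorbed_bnct)
    background = _require_finite_nonneg("background_absorbed", background_absorbed)
    if background > total:
        raise ValueError(
            f"background absorbed dose {background!r} exceeds total {total!r}"
        )
    return total - background


def equivalent_via_background(
    total_absorbed_bnct: float,
    background_absorbed: float,
    background_photon_eq: float,
    cbe: float,
) -> float:
    """Photon-equivalent dose reconstructed from tabulated absorbed doses.

    D_B is recovered by background subtraction, CBE-weighted, and added to
    the photon-equivalent dose of the boron-free background (whose own
    RBE weighting is already folded into ``background_photon_eq``).
    """
    if not math.isfinite(cbe) or cbe <= 0:
        raise ValueError(f"cbe must be finite and > 0, got {cbe!r}")
    d_b = decompose_boron_component(total_absorbed_bnct, background_absorbed)
    return d_b * cbe + _require_finite_nonneg(
        "background_photon_eq", background_photon_eq
    )


def build_dose_report(
    tissue: TissueComposition,
    weights: RadiobiologicalWeights,
    neutron_field: NeutronField,
) -> DoseReport:
    """Assemble the four dose components for one tissue in one field.

    D_B and D_N come from the kerma model at the field's thermal fluence;
    D_H and D_γ are the field's measured calibration values.
    """
    components = DoseComponents(
        d_b=boron_dose(tissue.boron_conc, neutron_field.thermal_fluence),
        d_n=nitrogen_dose(tissue.nitrogen_wt_pct, neutron_field.thermal_fluence),
        d_h=neutron_field.measured_dh,
        d_gamma=neutron_field.measured_dgamma,
    )
    return DoseReport(tissue=tissue.name, components=components, weights=weights)
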