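"""Linear vibrational Stark effect conversion between band shift and field.

A vibrational probe in a linear Stark regime shifts its frequency by
Δν = |Δμ|·ΔE, where |Δμ| is the Stark tuning rate and ΔE the change in the
local electric field projected onto the probe bond.  For CO bound to a heme
iron the externally calibrated tuning rate is 2.4 cm⁻¹/(MV/cm); relating it
to the field actually felt inside a protein matrix requires the local field
correction f (≈ 2), so the effective tuning rate is 2.4/f and

    ΔE [MV/cm] = Δν [cm⁻¹] · f / 2.4 .

A blueshift (positive Δν) maps to a positive field change along the probe
axis (C → O).  The conversion is linear and sign-preserving; a warning is
logged for |Δν| > 20 cm⁻¹, outside the linear-response regime the relation
assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ValidationError

#: Stark tuning rate of heme-bound CO before local-field correction, cm⁻¹/(MV/cm)
DEFAULT_TUNING_RATE = 2.4
#: local field correction factor
DEFAULT_LOCAL_FIELD_FACTOR = 2.0
#: |Δν| beyond which the linear Stark approximation is questionable, cm⁻¹
LINEAR_REGIME_LIMIT = 20.0


@dataclass(frozen=True)
class StarkProbe:
    """Tuning-rate and local-field parameters of a vibrational Stark probe."""

    tuning_rate_base: float = DEFAULT_TUNING_RATE
    local_field_factor: float = DEFAULT_LOCAL_FIELD_FACTOR

    def __post_init__(self):
        if not self.tuning_rate_base > 0:
            raise ValidationError("tuning_rate_base must be > 0")
        if not self.local_field_factor > 0:
            raise ValidationError("local_field_factor must be > 0")

    @property
    def effective_tuning_rate(self) -> float:
        """cm⁻¹ per (MV/cm) felt by the probe inside the matrix."""
        return self.tuning_rate_base / self.local_field_factor

    def provenance(self) -> dict:
        return {
            "tuning_rate_base_cm-1_per_MV/cm": self.tuning_rate_base,
            "local_field_factor": self.local_field_factor,
            "effective_tuning_rate_cm-1_per_MV/cm": self.effective_tuning_rate,
            "sign_convention": "blueshift (+Δν) → +ΔE along the C→O axis",
        }


@dataclass(frozen=True)
class FieldChangeResult:
    """A band shift Δν (cm⁻¹) with its projected field change ΔE (MV/cm)."""

    delta_nu: float
    delta_E_projected: float
    probe: StarkProbe

    def __post_init__(self):
        expected = self.delta_nu * self.probe.local_field_factor / self.probe.tuning_rate_base
        if abs(self.delta_E_projected - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValidationError(
                "delta_E_projected inconsistent with delta_nu × f / tuning_rate_base")


def _check_regime(delta_nu: float) -> None:
    if abs(delta_nu) > LINEAR_REGIME_LIMIT:
        warnings.warn(
            f"|Δν| = {abs(delta_nu):.1f} cm⁻¹ exceeds {LINEAR_REGIME_LIMIT} cm⁻¹; "
            "the linear Stark relation may not apply", stacklevel=3)


def field_from_shift(delta_nu: float, probe: StarkProbe = StarkProbe()) -> float:
    """Projected field change (MV/cm) producing the band shift ``delta_nu`` (cm⁻¹)."""
    _check_regime(delta_nu)
    return delta_nu / probe.effective_tuning_rate


def shift_from_field(delta_E: float, probe: StarkProbe = StarkProbe()) -> float:
    """Band shift (cm⁻¹) caused by a projected field change ``delta_E`` (MV/cm)."""
    delta_nu = delta_E * probe.effective_tuning_rate
    _check_regime(delta_nu)
    return delta_nu


def field_change_result(delta_nu: float, probe: StarkProbe = StarkProbe()) -> FieldChangeResult:
    """Bundle a shift with its converted field and the probe used."""
    return FieldChangeResult(delta_nu, field_from_shift(delta_nu, probe), probe)
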