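"""Body-composition arithmetic: four-component fat mass, BMI, CV.

The four-component (4C) model combines body volume (air-displacement
plethysmography), total body water (deuterium dilution), bone mineral
content (DXA) and body weight into a fat-mass estimate via a fixed linear
form.  The default coefficients are transcribed from the classic 4C
literature (Fuller and colleagues); they are configuration, not a constant —
laboratories publish slightly different weightings, so the coefficient
object is explicit and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FourCInputs",
    "FourCCoefficients",
    "fat_mass_4c",
    "bmi",
    "coefficient_of_variation",
]


@dataclass(frozen=True)
class FourCInputs:
    """BV: body volume (l); TBW: total body water (l); BMC: bone mineral
    content (kg); Wt: body weight (kg)."""

    BV: float
    TBW: float
    BMC: float
    Wt: float

    def validate(self) -> None:
        for name in ("BV", "TBW", "BMC", "Wt"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite field {name!r}")
        if self.Wt > 0:
            if not self.TBW < self.Wt:
                raise ValueError("total body water must be below body weight")
            if not self.BMC < self.Wt:
                raise ValueError("bone mineral content must be below body weight")


@dataclass(frozen=True)
class FourCCoefficients:
    """Signed weights on (BV, TBW, BMC, Wt); defaults from the 4C literature."""

    BV: float = 2.747
    TBW: float = -0.710
    BMC: float = 1.460
    Wt: float = -2.050

    def validate(self) -> None:
        for name in ("BV", "TBW", "BMC", "Wt"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite coefficient {name!r}")


def fat_mass_4c(
    inputs: FourCInputs, coefs: FourCCoefficients | None = None
) -> float:
    """Fat mass (kg) as the 4C linear combination of the named fields.

    Coefficients bind by field name, not position.  Negative outputs are
    returned as-is (they are physiologically implausible but arithmetically
    valid; callers should flag them).
    """
    coefs = coefs or FourCCoefficients()
    inputs.validate()
    coefs.validate()
    return float(
        sum(getattr(coefs, f) * getattr(inputs, f) for f in ("BV", "TBW", "BMC", "Wt"))
    )


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight / height^2 (kg/m^2)."""
    if not height_m > 0:
        raise ValueError("height must be positive")
    return weight_kg / height_m**2


def coefficient_of_variation(values) -> float:
    """100 * SD / mean in percent (SD with denominator n-1)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(100.0 * x.std(ddof=1) / m)
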