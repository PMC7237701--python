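"""Linear-quadratic dose conversion: BED and EQD2.

BED = n * d * (1 + d / (alpha/beta)) and EQD2 = BED / (1 + 2 / (alpha/beta)),
with n fractions of d Gy each.  HDR brachytherapy fractions are converted at
their own per-fraction dose and then summed — not one conversion of the
summed physical dose — because the quadratic cell-kill term acts within each
fraction.  Conventional alpha/beta: 10 Gy for tumour targets, 3 Gy for the
bladder / rectum / sigmoid organs at risk.

These operations take Gy; the dose engine's cGy values are divided by 100 at
the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_engine import DoseVolume
from .errors import ValidationError

#: default alpha/beta (Gy) by structure role
DEFAULT_ALPHA_BETA = {"hrctv": 10.0, "bladder": 3.0, "rectum": 3.0, "sigmoid": 3.0}


@dataclass(frozen=True)
class FractionScheme:
    """n fractions of d Gy for a tissue with the given alpha/beta (Gy)."""

    n: int
    d_gy: float
    alpha_beta: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValidationError(f"fraction count must be an integer >= 1, got {self.n}")
        if self.d_gy < 0:
            raise ValidationError(f"dose per fraction must be >= 0 Gy, got {self.d_gy}")
        if not self.alpha_beta > 0:
            raise ValidationError(f"alpha/beta must be > 0 Gy, got {self.alpha_beta}")


def bed(scheme: FractionScheme) -> float:
    """Biologically effective dose n*d*(1 + d/(alpha/beta)) in Gy."""
    return scheme.n * scheme.d_gy * (1.0 + scheme.d_gy / scheme.alpha_beta)


def eqd2(scheme: FractionScheme) -> float:
    """Equivalent dose in 2-Gy fractions: BED / (1 + 2/(alpha/beta)) in Gy."""
    return bed(scheme) / (1.0 + 2.0 / scheme.alpha_beta)


def eqd2_from_dose(d_gy, alpha_beta: float, n: int = 1):
    """Vectorized EQD2 of n fractions of d Gy (arrays allowed)."""
    d = np.asarray(d_gy, dtype=float)
    if np.any(d < 0):
        raise ValidationError("doses must be >= 0 Gy")
    out = n * d * (1.0 + d / alpha_beta) / (1.0 + 2.0 / alpha_beta)
    return float(out) if np.ndim(d_gy) == 0 else out


def eqd2_total(per_fraction_doses_gy, alpha_beta: float) -> tuple[float, list[float]]:
    """Total EQD2 across fractions delivered at their own per-fraction doses.

    Returns ``(total_gy, per_fraction_eqd2_gy)``.
    """
    breakdown = [eqd2_from_dose(float(d), alpha_beta, n=1) for d in per_fraction_doses_gy]
    return float(sum(breakdown)), breakdown


def eqd2_volume(dose: DoseVolume, alpha_beta: float, n: int = 1) -> DoseVolume:
    """Voxelwise EQD2 conversion of a per-fraction dose volume (cGy -> Gy)."""
    values_gy = eqd2_from_dose(dose.values / 100.0, alpha_beta, n=n)
    meta = dict(dose.metadata)
    meta["units"] = "Gy (EQD2)"
    meta["alpha_beta_gy"] = alpha_beta
    meta["n_fractions"] = n
    return DoseVolume(grid=dose.grid, values=values_gy, metadata=meta)
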