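"""Organ-level absorbed dose: D = (A-tilde/m) * Delta * Phi.

Blood dose comes from the area under a blood time-activity curve; bone
marrow is estimated from blood via a fixed marrow-to-blood dose ratio (0.58
for i.p. radioimmunoconjugates); the peritoneal surface receives half the
equilibrium dose of the injected fluid under the no-clearance assumption
(antibody concentration in the i.p. fluid stays at its injected value over
the short nuclide lifetime).
"""

from __future__ import annotations

from dataclasses import dataclass

from .decay import (
    MBQ_PER_ML_TO_BQ_PER_KG,
    InvalidParameterError,
    Radionuclide,
    TimeActivityCurve,
    time_integrated_activity_conc,
)

#: Marrow-to-blood absorbed dose ratio for i.p. injected alpha conjugates.
DEFAULT_MARROW_TO_BLOOD = 0.58


@dataclass(frozen=True)
class OrganDoseFactors:
    marrow_to_blood: float = DEFAULT_MARROW_TO_BLOOD
    absorbed_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("marrow_to_blood", "absorbed_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise InvalidParameterError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class DoseResult:
    """An organ dose together with the (A/m, Delta, Phi) inputs that produced it."""

    organ: str
    dose_gy: float
    a_per_m: float
    delta_j: float
    phi: float

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise InvalidParameterError("dose must be >= 0 Gy")

    def rounded(self, ndigits: int = 1) -> float:
        return round(self.dose_gy, ndigits)


def absorbed_dose(a_per_m: float, delta_j: float, phi: float = 1.0) -> float:
    """Absorbed dose in Gy from time-integrated activity per mass.

    ``a_per_m`` in Bq*s/kg, ``delta_j`` the mean alpha energy per decay in J,
    ``phi`` the absorbed fraction (<= 1).  Gy = J/kg.
    """
    if a_per_m < 0 or delta_j < 0 or phi < 0:
        raise InvalidParameterError("dose inputs must be >= 0")
    if phi > 1.0:
        raise InvalidParameterError(f"absorbed fraction must be <= 1, got {phi}")
    return a_per_m * delta_j * phi


def blood_dose(
    tac: TimeActivityCurve | float,
    nuclide: Radionuclide,
    phi: float = 1.0,
    tail: str | float = "physical",
) -> DoseResult:
    """Blood absorbed dose from a blood TAC (or scalar C0 for pure decay)."""
    a_per_m = time_integrated_activity_conc(tac, nuclide, tail=tail)
    return DoseResult(
        organ="blood",
        dose_gy=absorbed_dose(a_per_m, nuclide.delta_j, phi),
        a_per_m=a_per_m,
        delta_j=nuclide.delta_j,
        phi=phi,
    )


def bone_marrow_dose(blood_dose_gy: float, factors: OrganDoseFactors | None = None) -> float:
    """Bone-marrow dose estimated as marrow_to_blood * blood dose, in Gy."""
    if blood_dose_gy < 0:
        raise InvalidParameterError("blood dose must be >= 0 Gy")
    factors = factors or OrganDoseFactors()
    return blood_dose_gy * factors.marrow_to_blood


def equilibrium_dose(conc_bq_per_kg: float, nuclide: Radionuclide) -> float:
    """Dose in an infinite uniform medium of initial concentration C0: (C0/lambda)*Delta."""
    a_per_m = time_integrated_activity_conc(conc_bq_per_kg, nuclide)
    return absorbed_dose(a_per_m, nuclide.delta_j, 1.0)


def peritoneal_surface_dose(conc_bq_per_kg: float, nuclide: Radionuclide) -> DoseResult:
    """Peritoneal surface dose: half the equilibrium dose of the injected fluid.

    A plane surface bounding a half-space of uniformly radioactive fluid
    receives half the dose of an infinite medium (2pi vs 4pi geometry).
    """
    a_per_m = time_integrated_activity_conc(conc_bq_per_kg, nuclide)
    return DoseResult(
        organ="peritoneum",
        dose_gy=0.5 * absorbed_dose(a_per_m, nuclide.delta_j, 1.0),
        a_per_m=a_per_m,
        delta_j=nuclide.delta_j,
        phi=1.0,
    )


def peritoneal_surface_dose_mbq_per_ml(conc_mbq_per_ml: float, nuclide: Radionuclide) -> DoseResult:
    """Convenience wrapper taking the clinical unit MBq/mL (fluid density 1 kg/L)."""
    return peritoneal_surface_dose(conc_mbq_per_ml * MBQ_PER_ML_TO_BQ_PER_KG, nuclide)
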