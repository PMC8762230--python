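"""Reference adult oral-dosing parameter set used as package defaults.

Final joint-model estimates from a therapeutic-drug-monitoring cohort of 78
immunocompromised adults on oral voriconazole 200 mg twice daily: absorption
and the saturable-pathway constants (F, ka, Km, Imax, IC50) fixed from prior
literature, disposition parameters estimated, and CYP2C19 phenotype acting
multiplicatively on Vmax (IM -26.7%, PM -45.7% relative to NM).
"""

from .model_core import FixedEffects
from .popsim import OmegaSpec, SigmaSpec


def reference_fixed_effects(**overrides) -> FixedEffects:
    """Typical-value estimates (units: L, L/h, mg/h, mg/L; theta_* log-scale)."""
    params = dict(
        F=0.895, ka=1.1,
        V1=207.29, CL1=1.91, V2=10.01, Vmax=18.80, Km=1.15, CL2=4.65,
        Imax=0.75, IC50=14.6,
        theta_NM=0.0, theta_IM=-0.31, theta_PM=-0.61,
        kn=1.0,
    )
    params.update(overrides)
    return FixedEffects(**params)


def reference_omega(convention: str = "cv_percent") -> OmegaSpec:
    """Inter-individual variability, percent figures as printed in fit reports."""
    return OmegaSpec(omega_V1=240.77, omega_CL1=6.02, omega_CL2=25.57,
                     omega_Vmax=21.13, convention=convention)


def reference_sigma() -> dict[str, SigmaSpec]:
    """Proportional residual error per analyte."""
    return {"VCZ": SigmaSpec("proportional", proportional=0.4697),
            "VNO": SigmaSpec("proportional", proportional=0.2793)}
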