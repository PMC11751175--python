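"""Reduced-order cupula mechanics.

Each cupula is modeled as a thin clamped circular plate (radius R, thickness
h, Young modulus E, Poisson ratio nu) loaded by the effective transcupular
pressure.  For a uniform load q the center deflection is

    w0 = q R^4 / (64 D),      D = E h^3 / (12 (1 - nu^2)),

and the strain measure reported at the crista — the averaged shear strain in
the attachment annulus where the cupula meets the crista — is taken
proportional to the rim bending strain of the plate,

    eps = 4 w0 h / R^2,

signed positive for utriculopetal deflection (toward the utricle).  The sign
convention for hair-cell stimulation follows canal physiology: utriculopetal
deflection excites the horizontal crista but inhibits the superior and
posterior ones.

Temporally the strain relaxes to its steady state as a first-order system
with the canal long time constant tau; the plateau time is defined by the
convergence rule that the rim shear-stress increment over a trailing window
stays below a threshold (1 uPa over 2 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CupulaParams",
    "ConvergenceCriterion",
    "CristaStimulusSet",
    "plate_center_deflection",
    "steady_strain",
    "excitation_sign",
    "stimulus_from_strain",
    "temporal_response",
    "plateau_time",
    "assemble_stimuli",
]

#: geometric constant linking rim strain to w0 * h / R^2 for the clamped
#: uniformly loaded plate (second radial derivative of the deflection shape
#: at the rim, times h/2)
RIM_STRAIN_COEFF = 4.0


@dataclass(frozen=True)
class CupulaParams:
    """Cupula material and plate geometry (SI)."""

    E: float = 4.26              # Pa
    nu: float = 0.48
    rho_c: float = 1000.0        # kg/m^3
    mu_c: float = 8.15e-4        # Pa s
    radius_m: float = 0.6e-3     # plate radius (= ampulla radius)
    thickness_m: float = 0.3e-3
    tau_s: float = 4.2           # canal long time constant

    def validate(self):
        if not (0 < self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if min(self.E, self.radius_m, self.thickness_m, self.tau_s) <= 0:
            raise ValueError("E, R, h and tau must be positive")

    @property
    def bending_stiffness(self) -> float:
        return self.E * self.thickness_m**3 / (12 * (1 - self.nu**2))

    @property
    def shear_modulus(self) -> float:
        return self.E / (2 * (1 + self.nu))


@dataclass(frozen=True)
class ConvergenceCriterion:
    """Stress-increment plateau rule: increment < threshold over the window."""

    threshold_pa: float = 1e-6
    window_s: float = 2.0

    def validate(self):
        if self.threshold_pa <= 0 or self.window_s <= 0:
            raise ValueError("criterion threshold and window must be positive")


@dataclass(frozen=True)
class CristaStimulusSet:
    """Signed averaged crista shear strains; positive = excitation."""

    s_LH: float
    s_RH: float
    s_LS: float
    s_RS: float
    s_LP: float
    s_RP: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("s_LH", "s_RH", "s_LS", "s_RS", "s_LP", "s_RP")}

    def signs(self) -> dict:
        return {k: int(np.sign(v)) for k, v in self.as_dict().items()}


def plate_center_deflection(q: float, params: CupulaParams) -> float:
    """Center deflection (m) of the clamped plate under uniform load q (Pa)."""
    params.validate()
    return q * params.radius_m**4 / (64 * params.bending_stiffness)


def steady_strain(
    dp_transcupular: float,
    params: CupulaParams,
    direct_force_load: float = 0.0,
) -> float:
    """Signed averaged rim shear strain for a given transcupular pressure.

    ``dp_transcupular`` is ampullar-side minus utricular-side pressure (Pa):
    positive pushes the cupula toward the utricle (utriculopetal), which is
    the positive strain direction here.  ``direct_force_load`` adds the
    equivalent pressure of the Lorentz force acting on the cupula volume
    itself (mean utriculopetal force density times thickness).
    """
    params.validate()
    q = dp_transcupular + direct_force_load
    w0 = plate_center_deflection(q, params)
    return RIM_STRAIN_COEFF * w0 * params.thickness_m / params.radius_m**2


def excitation_sign(flow_direction: str, canal_type: str) -> str:
    """Map cupula deflection direction to hair-cell response per canal type.

    Horizontal cristae are excited by utriculopetal deflection; superior and
    posterior cristae by utriculofugal deflection.
    """
    if flow_direction not in ("utriculopetal", "utriculofugal"):
        raise ValueError(f"unknown flow direction {flow_direction!r}")
    if canal_type not in ("H", "S", "P"):
        raise ValueError(f"unknown canal type {canal_type!r}")
    toward = flow_direction == "utriculopetal"
    if canal_type == "H":
        return "excitation" if toward else "inhibition"
    return "inhibition" if toward else "excitation"


def stimulus_from_strain(strain_utriculopetal: float, canal_type: str) -> float:
    """Signed crista stimulus (positive = excitation) from signed plate strain."""
    if canal_type == "H":
        return strain_utriculopetal
    if canal_type in ("S", "P"):
        return -strain_utriculopetal
    raise ValueError(f"unknown canal type {canal_type!r}")


def temporal_response(
    steady_strain_value: float,
    params: CupulaParams,
    criterion: ConvergenceCriterion = ConvergenceCriterion(),
    t_max: float = 120.0,
    dt: float = 0.01,
):
    """First-order strain relaxation eps(t) = eps_ss (1 - exp(-t/tau)).

    Returns ``(t, eps, plateau_t)``; ``plateau_t`` is NaN when the criterion
    is not met within ``t_max`` (reported as not converged).
    """
    params.validate()
    criterion.validate()
    t = np.arange(0.0, t_max + dt / 2, dt)
    eps = steady_strain_value * (1.0 - np.exp(-t / params.tau_s))
    pt = plateau_time(steady_strain_value, params, criterion)
    if pt > t_max:
        pt = float("nan")
    return t, eps, pt


def plateau_time(
    steady_strain_value: float,
    params: CupulaParams,
    criterion: ConvergenceCriterion = ConvergenceCriterion(),
) -> float:
    """First time at which the rim shear-stress increment over the trailing
    window falls below the threshold (closed form).

    The increment over [t, t + w] is
    ``G |eps_ss| exp(-t/tau) (1 - exp(-w/tau))``; setting it equal to the
    threshold gives the plateau time.
    """
    params.validate()
    criterion.validate()
    g = params.shear_modulus
    amp = g * abs(steady_strain_value) * (1.0 - np.exp(-criterion.window_s / params.tau_s))
    if amp <= criterion.threshold_pa:
        return 0.0
    return float(params.tau_s * np.log(amp / criterion.threshold_pa))


def assemble_stimuli(left: dict, right: dict, meta_left=None, meta_right=None) -> CristaStimulusSet:
    """Combine per-canal signed strains of both labyrinths into one stimulus set.

    ``left`` / ``right`` map canal type ("H", "S", "P") to the signed
    utriculopetal strain of that labyrinth's cupula.  ``meta_left`` /
    ``meta_right`` may carry (orientation, B) tuples; if both are given they
    must match.
    """
    if meta_left is not None and meta_right is not None:
        ol, bl = meta_left
        orr, br = meta_right
        if ol != orr or not np.allclose(bl, br):
            raise ValueError("left and right runs were made under different conditions")
    vals = {}
    for side, strains in (("L", left), ("R", right)):
        for canal in ("H", "S", "P"):
            vals[f"s_{side}{canal}"] = stimulus_from_strain(strains[canal], canal)
    return CristaStimulusSet(**vals)
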