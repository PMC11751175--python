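"""Vestibulo-ocular reflex slow-phase velocity synthesis and sweeps.

The six signed crista stimuli map onto the three eye-movement components
through the known VOR pathways with unit gain and linear summation.  Writing
each stimulus as a signed number (positive = excitation), the excitatory /
inhibitory bookkeeping reduces to

    spv_hor = s_LH - s_RH
    spv_ver = s_LS + s_RS - s_LP - s_RP
    spv_tor = s_LS - s_RS + s_LP - s_RP

with positive SPV = rightward / upward / counterclockwise (top pole toward
the subject's right).

Head-orientation sweeps run either through the full physics pipeline or in a
fast surrogate mode where each crista responds sinusoidally in the sweep
angle with null angles taken from the model's characterization of the crista
responses (ear-to-shoulder: H +/-12 deg, P +/-19 deg, S +/-42 deg, mirrored
between ears; flexion-extension: H -27/153, P -71/109, S -42/138, identical
in both ears but with opposite sign).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cupula import CristaStimulusSet

__all__ = [
    "SPVRecord",
    "SinusoidFit",
    "NullPoints",
    "spv_from_cristae",
    "spv_from_cristae_bookkeeping",
    "SurrogateCristaModel",
    "surrogate_stimuli",
    "sweep_surrogate",
    "fit_sinusoid",
    "find_nulls",
    "normalize_spv",
    "fe_torsional_amplitude_ratio",
    "ETS_NULLS_DEG",
    "FE_NULLS_DEG",
]

#: first null angle (deg) of each crista's sinusoidal response in an
#: ear-to-shoulder sweep, left ear; the right ear is mirrored (sign flipped)
ETS_NULLS_DEG = {"H": 12.0, "P": 19.0, "S": 42.0}

#: first null angle (deg) of each crista pair in a flexion-extension sweep
#: (same for both ears)
FE_NULLS_DEG = {"H": -27.0, "P": -71.0, "S": -42.0}

#: sign of each canal's supine response template: s = sign * A * sin(...)
#: chosen so the supine (0 deg) pattern is LH-, RH+, LS+, RS-, LP+, RP-
_CANAL_SIGN = {"H": -1.0, "P": 1.0, "S": 1.0}


@dataclass
class SPVRecord:
    """One slow-phase velocity triple with its provenance."""

    spv_hor: float
    spv_ver: float
    spv_tor: float
    angle_deg: float | None = None
    axis: str | None = None              # "ETS" | "FE" | None
    B_magnitude: float | None = None
    B_axis_sign: str | None = None
    norm_hor: float | None = None
    norm_ver: float | None = None
    norm_tor: float | None = None

    def components(self) -> np.ndarray:
        return np.array([self.spv_hor, self.spv_ver, self.spv_tor])


def spv_from_cristae(s: CristaStimulusSet) -> SPVRecord:
    """Signed reduction of the VOR summation."""
    d = s.as_dict()
    if not all(np.isfinite(v) for v in d.values()):
        raise ValueError("crista stimuli must be finite")
    return SPVRecord(
        spv_hor=d["s_LH"] - d["s_RH"],
        spv_ver=d["s_LS"] + d["s_RS"] - d["s_LP"] - d["s_RP"],
        spv_tor=d["s_LS"] - d["s_RS"] + d["s_LP"] - d["s_RP"],
    )


def spv_from_cristae_bookkeeping(s: CristaStimulusSet) -> SPVRecord:
    """Literal excitatory/inhibitory bookkeeping of the VOR summation.

    Each crista contributes the magnitude of its response to either its
    excitatory or its inhibitory term depending on the sign of the stimulus;
    used as an independent cross-check of :func:`spv_from_cristae`.
    """
    ex = {}
    inh = {}
    for name, v in s.as_dict().items():
        key = name[2:]                     # LH, RH, ...
        ex[key] = abs(v) if v > 0 else 0.0
        inh[key] = abs(v) if v < 0 else 0.0
    hor = ex["LH"] + inh["RH"] - inh["LH"] - ex["RH"]
    ver = (
        ex["LS"] + ex["RS"] + inh["LP"] + inh["RP"]
        - inh["LS"] - inh["RS"] - ex["LP"] - ex["RP"]
    )
    tor = (
        ex["LS"] + inh["RS"] + ex["LP"] + inh["RP"]
        - inh["LS"] - ex["RS"] - inh["LP"] - ex["RP"]
    )
    return SPVRecord(spv_hor=hor, spv_ver=ver, spv_tor=tor)


# ---------------------------------------------------------------------------
# surrogate sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateCristaModel:
    """Sinusoidal per-crista responses parametrized by their null angles.

    Amplitudes are per canal type and mirrored between ears (the default);
    they rescale individual sinusoids but, in an ETS sweep, never move the
    horizontal/torsional nulls away from +/-90 deg.
    """

    amplitudes: dict = field(default_factory=lambda: {"H": 1.0, "P": 1.0, "S": 1.0})
    ets_nulls_deg: dict = field(default_factory=lambda: dict(ETS_NULLS_DEG))
    fe_nulls_deg: dict = field(default_factory=lambda: dict(FE_NULLS_DEG))


def surrogate_stimuli(
    theta_deg: float, axis: str, model: SurrogateCristaModel = SurrogateCristaModel()
) -> CristaStimulusSet:
    """Crista stimulus set at one sweep angle in surrogate mode."""
    th = math.radians(theta_deg)
    vals = {}
    if axis.upper() == "ETS":
        for canal, amp in model.amplitudes.items():
            d = math.radians(model.ets_nulls_deg[canal])
            # mirror rule between ears: s_R(theta) = -s_L(-theta)
            vals[f"s_L{canal}"] = _CANAL_SIGN[canal] * amp * math.sin(th + d)
            vals[f"s_R{canal}"] = _CANAL_SIGN[canal] * amp * math.sin(th - d)
    elif axis.upper() == "FE":
        for canal, amp in model.amplitudes.items():
            d = math.radians(model.fe_nulls_deg[canal])
            vals[f"s_L{canal}"] = _CANAL_SIGN[canal] * amp * math.sin(th - d)
            vals[f"s_R{canal}"] = -_CANAL_SIGN[canal] * amp * math.sin(th - d)
    else:
        raise ValueError(f"unknown sweep axis {axis!r}")
    return CristaStimulusSet(**vals)


def sweep_surrogate(
    axis: str,
    angles_deg=None,
    model: SurrogateCristaModel = SurrogateCristaModel(),
) -> list[SPVRecord]:
    """Surrogate orientation sweep; defaults to a 1-degree grid over (-180, 180]."""
    if angles_deg is None:
        angles_deg = np.arange(-179.0, 181.0, 1.0)
    out = []
    for th in np.asarray(angles_deg, float):
        rec = spv_from_cristae(surrogate_stimuli(th, axis, model))
        rec.angle_deg = float(th)
        rec.axis = axis.upper()
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# fits, nulls, normalization
# ---------------------------------------------------------------------------

@dataclass
class SinusoidFit:
    amplitude: float
    phase_deg: float            # y = amplitude * sin(theta - phase)
    period_deg: float
    offset: float
    adjusted_r2: float
    degenerate: bool = False    # all-zero input


def fit_sinusoid(angles_deg, values, period_deg: float = 360.0) -> SinusoidFit:
    """Least-squares fit of A sin(theta - phi) with fixed period and zero offset.

    Adjusted R^2 uses p = 2 fitted parameters.  An identically-zero component
    is reported as degenerate with amplitude 0 rather than NaN.
    """
    th = np.radians(np.asarray(angles_deg, float)) * (360.0 / period_deg)
    y = np.asarray(values, float)
    if len(th) < 4:
        raise ValueError("need at least 4 distinct angles to fit a sinusoid")
    if np.allclose(y, 0.0):
        return SinusoidFit(0.0, 0.0, period_deg, 0.0, float("nan"), degenerate=True)
    X = np.column_stack([np.sin(th), np.cos(th)])
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    amp = float(np.hypot(a, b))
    phase = float(np.degrees(np.arctan2(-b, a)))
    resid = y - X @ [a, b]
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, p = len(y), 2
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    if phase <= -180.0:
        phase += 360.0
    return SinusoidFit(amp, phase, period_deg, 0.0, float(adj))


def phase_lag_deg(fit_a: SinusoidFit, fit_b: SinusoidFit) -> float:
    """Phase of b relative to a, folded into [0, 180] (sign-free lag)."""
    d = (fit_b.phase_deg - fit_a.phase_deg) % 360.0
    return min(d, 360.0 - d)


@dataclass
class NullPoints:
    axis: str
    component: str
    angles_deg: list            # in (-180, 180]
    null_everywhere: bool = False


def _wrap(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def find_nulls(records: list[SPVRecord], component: str, method: str = "fit") -> NullPoints:
    """Zero crossings of one SPV component over a sweep.

    ``method="fit"`` locates them analytically from the fitted sinusoid
    (phase and phase+180); ``method="bisect"`` finds sign changes on the
    sweep grid and bisects linearly.  An identically-zero component is
    reported with ``null_everywhere``.
    """
    attr = {"hor": "spv_hor", "ver": "spv_ver", "tor": "spv_tor"}[component]
    angles = np.array([r.angle_deg for r in records])
    vals = np.array([getattr(r, attr) for r in records])
    axis = records[0].axis or ""
    if np.allclose(vals, 0.0):
        return NullPoints(axis, component, [], null_everywhere=True)
    if method == "fit":
        fit = fit_sinusoid(angles, vals)
        nulls = sorted({_wrap(fit.phase_deg), _wrap(fit.phase_deg + 180.0)})
        return NullPoints(axis, component, nulls)
    if method == "bisect":
        nulls = []
        order = np.argsort(angles)
        a, v = angles[order], vals[order]
        for i in range(len(a)):
            j = (i + 1) % len(a)
            v0, v1 = v[i], v[j]
            a0, a1 = a[i], a[j]
            if j == 0:
                a1 = a1 + 360.0
            if v0 == 0.0:
                nulls.append(_wrap(a0))
            elif v0 * v1 < 0:
                nulls.append(_wrap(a0 + (a1 - a0) * v0 / (v0 - v1)))
        return NullPoints(axis, component, sorted(set(round(x, 9) for x in nulls)))
    raise ValueError(f"unknown method {method!r}")


def normalize_spv(records: list[SPVRecord]) -> list[SPVRecord]:
    """Normalize a set of SPV records in place and return it.

    Horizontal and torsional components are scaled by their own peak absolute
    value over the set; the vertical component — near-null in the supine
    reference — is scaled by the horizontal peak.  Zero-peak components
    normalize to zeros.
    """
    if not records:
        raise ValueError("empty record set")
    hor = np.array([r.spv_hor for r in records])
    ver = np.array([r.spv_ver for r in records])
    tor = np.array([r.spv_tor for r in records])
    hpk = np.abs(hor).max()
    tpk = np.abs(tor).max()
    for r in records:
        r.norm_hor = r.spv_hor / hpk if hpk > 0 else 0.0
        r.norm_ver = r.spv_ver / hpk if hpk > 0 else 0.0
        r.norm_tor = r.spv_tor / tpk if tpk > 0 else 0.0
    del ver
    return records


def fe_torsional_amplitude_ratio(null_deg: float) -> float:
    """Superior:posterior amplitude ratio that places the FE torsional null.

    Solves A_S sin(th - nu_S) + A_P sin(th - nu_P) = 0 at the requested
    angle with the flexion-extension crista nulls; returns A_S / A_P.  A
    calibration helper: the default equal amplitudes put the torsional null
    where the symmetric idealization puts it, and this inverts the choice
    for a user-supplied null angle.
    """
    th = math.radians(null_deg)
    ns = math.radians(FE_NULLS_DEG["S"])
    np_ = math.radians(FE_NULLS_DEG["P"])
    denom = math.sin(th - ns)
    if abs(denom) < 1e-12:
        raise ValueError("requested null coincides with the superior crista null")
    return -math.sin(th - np_) / denom
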