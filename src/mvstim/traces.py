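"""Synthetic three-channel eye-position traces with nystagmus structure.

Emulates 100 Hz video-oculography recordings: per-component slow phases
drifting at a prescribed slow-phase velocity, quick phases (instantaneous
resetting jumps), blinks (masked gaps with held position), additive Gaussian
position noise, and an optional baseline drift standing in for inherent
nystagmus in darkness.  Ground truth (the injected SPV and the slow-phase
segment boundaries) rides along so detection pipelines can be validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["EyeTraceSpec", "EyeTrace", "generate_trace", "write_trace_csv", "read_trace_csv"]


@dataclass(frozen=True)
class EyeTraceSpec:
    duration_s: float = 60.0
    rate_hz: float = 100.0
    spv_deg_s: tuple = (-3.0, 0.0, 2.0)      # horizontal, vertical, torsional
    quick_phase_rate_hz: float = 2.0
    quick_phase_amplitude_deg: float = 1.5
    blink_rate_hz: float = 0.2
    blink_duration_s: float = 0.25
    noise_sd_deg: float = 0.05
    baseline_drift_deg_s: tuple = (0.0, 0.0, 0.0)
    oculomotor_range_deg: float = 20.0
    seed: int = 0

    def validate(self):
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")
        if self.quick_phase_rate_hz < 0 or self.blink_rate_hz < 0:
            raise ValueError("event rates must be non-negative")


@dataclass
class EyeTrace:
    t: np.ndarray                    # (n,) s
    positions: np.ndarray            # (n, 3) deg: horizontal, vertical, torsional
    valid: np.ndarray                # (n,) bool, False during blinks
    true_spv: np.ndarray             # (3,) deg/s (injected SPV + baseline drift)
    spec: EyeTraceSpec
    true_segments: list = field(default_factory=list)   # [(i0, i1)] slow phases

    def __len__(self):
        return len(self.t)


def generate_trace(spec: EyeTraceSpec) -> EyeTrace:
    """Generate one trace; identical spec (and seed) gives a bit-identical trace."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    dt = 1.0 / spec.rate_hz
    t = np.arange(n) * dt
    v = np.asarray(spec.spv_deg_s, float) + np.asarray(spec.baseline_drift_deg_s, float)

    # quick-phase and blink event times (Poisson)
    qp_idx = np.array([], dtype=int)
    if spec.quick_phase_rate_hz > 0:
        n_qp = rng.poisson(spec.quick_phase_rate_hz * spec.duration_s)
        qp_idx = np.unique(rng.integers(1, max(n - 1, 2), size=n_qp))
    blink_spans = []
    if spec.blink_rate_hz > 0:
        n_bl = rng.poisson(spec.blink_rate_hz * spec.duration_s)
        width = max(int(round(spec.blink_duration_s * spec.rate_hz)), 1)
        for start in np.sort(rng.integers(0, max(n - width, 1), size=n_bl)):
            blink_spans.append((int(start), int(start + width)))

    # quick phases reset the eye beyond the recentre point (anticipatory
    # overshoot, as in physiological nystagmus): the restart position leads
    # the drift by half the effective beat amplitude, which keeps the
    # position bounded for any injected SPV and makes every reset a
    # super-threshold velocity event for the detection pipeline
    vmax = np.abs(v).max()
    amp_eff = spec.quick_phase_amplitude_deg
    if spec.quick_phase_rate_hz > 0 and vmax > 0:
        amp_eff = max(amp_eff, 1.5 * vmax / spec.quick_phase_rate_hz)
    restart = -0.5 * amp_eff * v / vmax if vmax > 0 else np.zeros(3)

    pos = np.zeros((n, 3))
    cur = np.zeros(3)
    qp_set = set(qp_idx.tolist())
    for i in range(n):
        if i > 0:
            cur = cur + v * dt
            if i in qp_set and vmax > 0:
                cur = restart.copy()
            cur = np.clip(cur, -spec.oculomotor_range_deg, spec.oculomotor_range_deg)
        pos[i] = cur

    valid = np.ones(n, dtype=bool)
    for s0, s1 in blink_spans:
        valid[s0:s1] = False
        if s0 > 0:
            pos[s0:s1] = pos[s0 - 1]      # held position during the blink

    if spec.noise_sd_deg > 0:
        pos = pos + rng.normal(0.0, spec.noise_sd_deg, size=pos.shape)

    # ground-truth slow-phase segments: spans between quick phases/blinks
    cut = np.zeros(n, dtype=bool)
    for i in qp_set:
        cut[i] = True
    cut |= ~valid
    segments = []
    start = 0
    for i in range(n + 1):
        if i == n or cut[i]:
            if i - start >= 2:
                segments.append((start, i))
            start = i + 1
    return EyeTrace(t=t, positions=pos, valid=valid, true_spv=v, spec=spec, true_segments=segments)


def write_trace_csv(trace: EyeTrace, csv_path, sidecar_path=None) -> None:
    """Write the trace as CSV (t, h, v, torsion, valid) plus a JSON sidecar."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "t": trace.t,
            "h": trace.positions[:, 0],
            "v": trace.positions[:, 1],
            "torsion": trace.positions[:, 2],
            "valid": trace.valid.astype(int),
        }
    )
    df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        meta = {
            "schema_version": 1,
            "true_spv_deg_s": list(map(float, trace.true_spv)),
            "seed": trace.spec.seed,
            "spec": asdict(trace.spec),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_trace_csv(csv_path, sidecar_path=None) -> EyeTrace:
    import pandas as pd

    df = pd.read_csv(csv_path)
    spec = EyeTraceSpec()
    true_spv = np.zeros(3)
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        raw = dict(meta["spec"])
        for key in ("spv_deg_s", "baseline_drift_deg_s"):
            raw[key] = tuple(raw[key])
        spec = EyeTraceSpec(**raw)
        true_spv = np.asarray(meta["true_spv_deg_s"], float)
    return EyeTrace(
        t=df["t"].to_numpy(),
        positions=df[["h", "v", "torsion"]].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
        true_spv=true_spv,
        spec=spec,
    )
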