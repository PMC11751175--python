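"""Head-orientation sweeps of the synthesized slow-phase velocity.

Sweeps the head through 360 degrees of ear-to-shoulder roll and of
flexion-extension pitch in surrogate mode (per-crista sinusoids), fits
360-degree-period sinusoids and reports the null points: the head angles at
which each eye-movement component vanishes.
"""

import numpy as np

from mvstim.vor import find_nulls, fit_sinusoid, normalize_spv, sweep_surrogate

for axis in ("ETS", "FE"):
    recs = normalize_spv(sweep_surrogate(axis))
    angles = [r.angle_deg for r in recs]
    print(f"\n{axis} sweep (1-degree grid):")
    for comp in ("hor", "ver", "tor"):
        nulls = find_nulls(recs, comp)
        if nulls.null_everywhere:
            print(f"  {comp}: identically zero at every angle")
            continue
        fit = fit_sinusoid(angles, [getattr(r, f"spv_{comp}") for r in recs])
        print(
            f"  {comp}: nulls at {[round(a, 1) for a in nulls.angles_deg]} deg, "
            f"phase {fit.phase_deg:+.1f} deg, adjusted R^2 = {fit.adjusted_r2:.12f}"
        )

# the two nulls of each component are 180 degrees apart; in the ETS sweep the
# horizontal and torsional components vanish at +/-90 deg (ear on the field
# axis) while the vertical one vanishes in the supine and prone positions
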