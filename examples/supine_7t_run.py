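"""Full supine 7 T run: build both labyrinths, solve the physics, print the
crista stimulation pattern and the synthesized slow-phase velocity.

The signs tell the story: the left horizontal crista is inhibited and the
right excited (a leftward horizontal slow phase), the superior/posterior
pairs balance vertically, and the torsional component is counterclockwise.
The plateau time is when the cupula shear response settles under the
1 uPa / 2 s convergence rule.
"""

from mvstim.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig())

print(f"calibrated dark-cell drive: {res.drive_current_a * 1e6:.2f} uA")
print("crista stimuli (positive = excitation):")
for name, value in res.stimuli.as_dict().items():
    state = "excited" if value > 0 else "inhibited"
    print(f"  {name[2:]}: {value:+.3e}  ({state})")
print("slow-phase velocity (model units; + = rightward/upward/counterclockwise):")
print(f"  horizontal {res.spv.spv_hor:+.3e}")
print(f"  vertical   {res.spv.spv_ver:+.3e}")
print(f"  torsional  {res.spv.spv_tor:+.3e}")
print(f"cupula plateau time: {res.plateau_s:.1f} s")
print("peak endolymph speeds (um/s):",
      {k: round(v * 1e6, 2) for k, v in res.speed_summary.items()})
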