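"""Electric current paths through the labyrinth.

Solves the quasi-static conduction problem and integrates streamlines of the
current density from the secretory dark-cell patches.  In the continuum every
current path runs from a dark-cell region to a sensory hair-cell patch (the
cristae and the utricular macula); the printed table shows where each
seeded path terminates.
"""

from collections import Counter

from mvstim.electrodynamics import (
    current_and_force,
    magnetic_reynolds,
    solve_potential,
    trace_current_streamlines,
)
from mvstim.geometry import HeadOrientation, build_labyrinth, orient

value, order = magnetic_reynolds()
print(f"magnetic Reynolds number: {value:.2e} (order 1e{order}) -> one-way coupling")

geom, B = orient(build_labyrinth(), HeadOrientation(), 7.0, "head_to_feet")
sol = current_and_force(solve_potential(geom), B)
lines = trace_current_streamlines(sol, n_seeds=100, seed=1)

table = Counter((l.origin_patch, l.terminal_patch) for l in lines)
print("origin -> terminal (count):")
for (src, dst), n in sorted(table.items(), key=lambda kv: -kv[1]):
    print(f"  {src:18s} -> {dst:18s} {n}")
hair = sum(n for (s, d), n in table.items() if d.startswith("hair_"))
print(f"{hair}/{len(lines)} paths terminate on hair-cell patches")
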