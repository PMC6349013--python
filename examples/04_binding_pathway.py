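"""Binding pathway of a scripted well-to-well hop.

Generates a trajectory that dwells in one well, crosses the barrier ridge and
settles in a second well; extracts the dwell-based key positions and the
energy barrier climbed on each hop of the simplified pathway.
"""

import numpy as np

from bindscape import GeoPosition, build_grid
from bindscape.geometry import ReferenceFrame, to_geographic
from bindscape.pathway import annotate_barriers, build_pathway
from bindscape.synth import FIXTURE_CENTER, SyntheticPotential, scripted_walk
from bindscape.landscape import tps_smooth
from bindscape.wells import segment_wells

potential = SyntheticPotential(
    wells=(
        (GeoPosition(-13.5, -58.5), -9.5, 8.0),
        (GeoPosition(16.5, 61.5), -9.0, 8.0),
    )
)
frame = ReferenceFrame(
    origin=FIXTURE_CENTER,
    ex=np.array([1.0, 0.0, 0.0]),
    ey=np.array([0.0, 1.0, 0.0]),
    ez=np.array([0.0, 0.0, 1.0]),
)
records = scripted_walk(potential, [w[0] for w in potential.wells],
                        dwell_frames=40, seed=2, frame=frame)
positions = [to_geographic(frame, r.com) for r in records]
grid = build_grid(positions, [r.energy for r in records], B=20, seed=2)
wells = segment_wells(grid)
pathway = build_pathway(records, frame, grid=grid, wells=wells,
                        traj_id="scripted:Traj. 1", ligand_id="A",
                        dwell_min=10)
surface = tps_smooth(grid, lam=0.0)
annotate_barriers(pathway, surface)

print(pathway.to_frame().to_string(index=False))
print(f"\ndestination well: {pathway.destination_well_id} "
      f"({next(w.category for w in wells if w.id == pathway.destination_well_id)})")
print()
print("Each row is a key position (a cell the ligand occupied for >= 10")
print("frames); barrier_to_next is the energy climbed along the great-circle")
print("hop to the next key position on the smoothed landscape.")
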