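"""Behavioural statistics and place-cell rate maps for one exploration.

Prints the movement summary and, per pyramidal cell, the spatial coding
statistics used to select place cells (coherence > 0.5, sparsity < 0.3).
"""

import numpy as np

from placecode import placemaps as pm
from placecode.behavior import behavior_summary
from placecode.synth import CONTROL, simulate_session

plan = (("familiar_explore", 1200.0), ("sleep_familiar", 60.0))
bundle = simulate_session(CONTROL, seed=3, n_pyr=15, n_int=3, epoch_plan=plan)
ep = bundle.epoch_interval("familiar_explore")

beh = behavior_summary(bundle.tracking_in(*ep), bundle.arena)
print(f"mean speed      {beh.mean_speed_cm_s:6.1f} cm/s")
print(f"immobility      {beh.immobility_fraction:6.1%} of 1 s windows travelling < 2 cm")
print(f"arena uncovered {beh.uncovered_fraction:6.1%} of in-arena 5 cm bins\n")

print(f"{'unit':>4} {'info(bits/sp)':>13} {'field frac':>10} {'coherence':>9} "
      f"{'sparsity':>8} {'place cell':>10}")
for u in bundle.units_of_class("pyr"):
    m = pm.build_rate_map(bundle.tracking, u.spike_times, bundle.arena, epoch=ep)
    s = pm.place_cell_stats(m)
    print(f"{u.unit_id:>4} {s.spatial_info_bits_per_spike:>13.2f} "
          f"{s.field_size_fraction:>10.2f} {s.coherence:>9.2f} {s.sparsity:>8.2f} "
          f"{'yes' if s.is_place_cell else 'no':>10}")

# Narrow planted fields give high bits/spike and small field fractions;
# cells failing the coherence/sparsity gate are excluded from decoding.
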