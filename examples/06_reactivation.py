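"""Peri-SWR firing and exploration-to-sleep reactivation.

Detects SWRs in the post-exploration sleep, aligns pyramidal firing to
their centres, and correlates waking-theta cofiring with SWR cofiring
across cell pairs to measure reactivation strength.
"""

import numpy as np

from placecode import lfp_events as le
from placecode.reactivation import cofiring, peri_swr_rates, reactivation_strength
from placecode.synth import CONTROL, simulate_session

plan = (("novel_explore", 600.0), ("sleep_novel", 900.0))
bundle = simulate_session(CONTROL, seed=41, n_pyr=40, n_int=8, epoch_plan=plan)
explore = bundle.epoch_interval("novel_explore")
sleep = bundle.epoch_interval("sleep_novel")

swrs = le.detect_swrs(bundle.lfp, np.array([sleep]))
print(f"{swrs.n_events} SWRs detected in {sleep[1]-sleep[0]:.0f} s of sleep")

for cls in ("pyr", "int"):
    per = peri_swr_rates(bundle.units, swrs.centers, cell_class=cls)
    print(f"{cls}: peri-SWR peak {per.peak_rate():.2f} Hz vs baseline "
          f"{per.baseline_rate():.2f} Hz per cell ({per.n_cells} cells)")

theta = le.detect_theta_epochs(bundle.lfp, explore)
trains = [u.spike_times for u in bundle.units_of_class("pyr")]
wake = cofiring(trains, le.intervals_intersect(theta.intervals, np.array([explore])))
swr_cof = cofiring(trains, swrs.intervals)
react = reactivation_strength(wake, swr_cof)
print(f"reactivation: r = {react.reactivation_r:.3f} across {react.n_pairs} pairs "
      f"(p = {react.p:.2e})")

# Positive r means cell pairs that fired together during waking theta also
# fire together inside sleep SWRs - the signature of replay/reactivation.
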