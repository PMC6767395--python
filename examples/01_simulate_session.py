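"""Simulate a synthetic CA1 recording day and inspect its contents.

Generates a control-preset session (short epochs for speed), prints what
the bundle holds, and round-trips it through the on-disk format.
"""

import tempfile

import numpy as np

from placecode import SessionBundle
from placecode.synth import CONTROL, simulate_session

plan = (("familiar_explore", 300.0), ("sleep_familiar", 300.0))
bundle = simulate_session(CONTROL, seed=7, n_pyr=25, n_int=5, epoch_plan=plan)

print("epochs:")
print(bundle.epochs.to_string(index=False))
n_spikes = sum(len(u.spike_times) for u in bundle.units)
print(f"\nunits: {len(bundle.units)} ({len(bundle.units_of_class('pyr'))} pyramidal, "
      f"{len(bundle.units_of_class('int'))} interneurons), {n_spikes} spikes total")
print(f"LFP: {bundle.lfp.data.shape[0]} channels x {bundle.lfp.n_samples} samples "
      f"at {bundle.lfp.fs:.0f} Hz, roles {list(bundle.lfp.roles)}")
gt = bundle.ground_truth
print(f"ground truth: {len(gt.swr_times)} planted SWRs, field widths "
      f"{np.round(gt.pyr.sigma_cm[:5], 1)} cm ...")

with tempfile.TemporaryDirectory() as d:
    bundle.save(d)
    reloaded = SessionBundle.load(d)
    print(f"\nround-trip through {d!s}: {len(reloaded.units)} units, "
          f"{len(reloaded.tracking)} tracking samples")

# The epoch table defines the protocol; the planted parameters in
# ground_truth are what the analysis modules are expected to recover.
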