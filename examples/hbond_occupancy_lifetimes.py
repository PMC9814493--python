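"""Effective occupancy and dwell-time statistics of a breathing H-bond.

A two-state Markov chain with mean bound/unbound lifetimes of 7 ns / 1 ns
emulates an H-bond that breathes on the saving-interval timescale; the
event extractor recovers the stationary occupancy (0.875) and the lifetime
distribution.
"""

import numpy as np

import piezotraj as pt

cfg = pt.GeneratorConfig(seed=3, tau_on=7000.0, tau_off=1000.0)
indicator = pt.gen_two_state_series(cfg, n_frames=100_000)
series = pt.BondedSeries(indicator, frame_interval=100.0, label="toy-bond")
events, record = pt.extract_events(series)

lifetimes = np.array([e.lifetime for e in events])
print(f"effective occupancy = {record.effective_occupancy:.4f} "
      f"(stationary value 0.875)")
print(f"{record.n_events} events, mean lifetime {lifetimes.mean():.2f} ns "
      f"(generator tau_on = 7 ns)")
print("lifetime bins (0,6] / (6,100] / (100,inf) ns:",
      record.lifetime_bin_counts)
# occupancy is the fraction of frames bonded after degeneracy merging;
# the bin counts split breathing events from constantly-formed bonds.
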