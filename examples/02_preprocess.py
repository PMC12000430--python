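"""Preprocessing chain: filters, epochs, artifact rejection, PARRM, segments.

Runs the standard cleaning sequence on a simulated DBS-ON recording:
notch (50 Hz + harmonics), 3–150 Hz bandpass, stimulation-artifact
removal keyed to the 130 Hz period, 2 s epochs, amplitude-based epoch
rejection and bootstrap length standardisation.
"""

import numpy as np

from ctxstn import preprocess as pp
from ctxstn import synth

cfg = synth.SimConfig(sampling_rate=4000.0, duration=30.0, seed=1,
                      coupling_delay=25.0)
rec, _ = synth.couple_and_mix(synth.simulate_sources(cfg), cfg, condition="dbs")
rec = synth.add_dbs_artifact(rec, frequency=130.0, pulse_width=60.0,
                             amplitude=200.0, seed=2)
print(f"raw RMS with DBS artifact: {rec.data.std():.1f} µV")

rec = pp.notch_filter(rec, 50.0)
rec = pp.bandpass_filter(rec, 3.0, 150.0)
rec = pp.parrm_remove(rec, stim_freq=130.0)
print(f"estimated artifact period: {rec.meta['parrm_period_samples']:.4f} samples "
      f"(true {4000 / 130:.4f})")
print(f"cleaned RMS: {rec.data.std():.1f} µV")

epochs = pp.make_epochs(rec, duration=2.0)
epochs = pp.resample(epochs, 500.0)
epochs, log = pp.reject_artifact_epochs(epochs, z_thresh=4.0)
print(f"epochs: {epochs.n_epochs} of 2 s, {log['n_rejected']} rejected")

segments = pp.bootstrap_segments(epochs, n_segments=200, epochs_per_segment=30, seed=3)
print(f"bootstrap: {segments.n_segments} segments x "
      f"{segments.epochs_per_segment} epochs (60 s each); "
      f"coverage of kept epochs: {segments.coverage:.0%}")
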