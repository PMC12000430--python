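"""Undirected and directed cortex–STN coupling on synthetic data.

ImCoh (grand average), MIC (maximised, with spatial patterns) and
time-reversed Granger causality on a simulation with a known
cortex→STN beta-band interaction.  Expect: coupling concentrated in and
around the source band, MIC patterns matching the mixing weights, and
positive TRGC (cortex drives STN).
"""

import numpy as np

from ctxstn import coupling, preprocess as pp, spectral, synth

cfg = synth.SimConfig(sampling_rate=500.0, duration=60.0, source_band=(18.0, 24.0),
                      coupling_delay=20.0, coupling_gain=0.8, snr=10.0,
                      line_noise_amplitude=0.0, n_cortex_channels=5,
                      n_stn_channels=3, seed=5)
rec, truth = synth.couple_and_mix(synth.simulate_sources(cfg), cfg)
epochs = pp.make_epochs(rec)
segments = pp.bootstrap_segments(epochs, n_segments=50, seed=6)
csds = coupling.bootstrap_csds(epochs, segments)

cortex, stn = [0, 1, 2, 3, 4], [5, 6, 7]
imcoh = coupling.average_segments(
    [coupling.imcoh_grand_average(c, cortex, stn) for c in csds])
mic = coupling.average_segments(
    [coupling.mic(c, cortex, stn) for c in csds])
trgc = coupling.average_segments(
    [coupling.trgc(c, cortex, stn, order=40, band=(3.0, 50.0)) for c in csds])

band = (imcoh.freqs >= 18) & (imcoh.freqs <= 24)
# the skewed sources carry (coupled) harmonics up to ~53 Hz, so the
# uncoupled reference band sits well above them
out = (imcoh.freqs >= 70) & (imcoh.freqs <= 90)
print(f"ImCoh  in band {imcoh.values[band].mean():.3f}   "
      f"off band {imcoh.values[out].mean():.3f}")
print(f"MIC    in band {mic.values[band].mean():.3f}   "
      f"off band {mic.values[out].mean():.3f}")
gband = (trgc.freqs >= 18) & (trgc.freqs <= 24)
print(f"TRGC   in band {trgc.values[gband].mean():+.3f}  "
      f"(positive = cortex drives STN)")

pat = mic.seed_patterns_z[:, band].mean(axis=1)
true_abs = np.abs(truth.mixing_cortex[:, 0])
print(f"MIC cortex pattern vs mixing |r| = "
      f"{abs(np.corrcoef(pat, true_abs)[0, 1]):.3f}")
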