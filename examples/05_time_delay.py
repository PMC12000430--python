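"""Bispectral time-delay estimation with bootstrap confidence screening.

A skewed broadband source drives the STN channel 25 ms after the
cortex channel at 10 dB SNR.  The cross-bispectrum phase method
estimates the delay per bootstrap segment; the 80% CI over segment taus
screens out noise-dominated connections, and local strength peaks are
grouped into 10 ms bins (1–9 ms first bin).
"""

from ctxstn import bisdelay, preprocess as pp, synth

cfg = synth.SimConfig(sampling_rate=1000.0, duration=120.0, source_band=(10.0, 45.0),
                      coupling_delay=25.0, coupling_gain=0.8, snr=10.0,
                      line_noise_amplitude=0.0, n_cortex_channels=1,
                      n_stn_channels=1, seed=7)
rec, _ = synth.couple_and_mix(synth.simulate_sources(cfg), cfg)
epochs = pp.make_epochs(rec, duration=2.0)  # native 1000 Hz
segments = pp.bootstrap_segments(epochs, n_segments=400, seed=8)

coeffs, freqs = bisdelay.fourier_coefficients(epochs)
estimate = bisdelay.bootstrap_delay(coeffs[:, 0], coeffs[:, 1], freqs, segments,
                                    band=(3.0, 100.0))
estimate = bisdelay.peak_binning(estimate)

print(f"tau = {estimate.tau:.2f} ms (true 25 ms)")
print(f"80% CI over {segments.n_segments} segment taus: "
      f"[{estimate.ci80[0]:.1f}, {estimate.ci80[1]:.1f}] ms; "
      f"valid = {estimate.valid} (0 ms outside the CI)")
print(f"strength peaks at {estimate.peaks} ms")
print(f"peak bins: {estimate.bin_percentages}")
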