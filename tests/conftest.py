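import numpy as np
import pytest
from scipy import signal

from ctxstn import preprocess as pp
from ctxstn import synth


def make_recording(data: np.ndarray, fs: float, site_split: int | None = None,
                   condition: str = "off") -> pp.Recording:
    """Wrap an array as a Recording with generic channel metadata."""
    n_ch = data.shape[0]
    if site_split is None:
        site_split = n_ch
    info = []
    for i in range(n_ch):
        site = "cortex" if i < site_split else "stn"
        name = f"ECOG_{i + 1}" if site == "cortex" else f"LFP_{i - site_split + 1}"
        info.append(pp.ChannelInfo(name=name, site=site,
                                   region="motor" if site == "cortex" else "stn"))
    return pp.Recording(data=data, sampling_rate=fs, channel_info=info,
                        condition=condition)


def bandlimited_noise(rng: np.random.Generator, band, fs: float, n: int,
                      n_channels: int = 1) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, rng.standard_normal((n_channels, n)), axis=-1)


@pytest.fixture(scope="session")
def coupled_sim():
    """A beta-band cortex->STN simulation shared by several tests.

    20 ms delay, 5 cortex + 3 STN channels, 60 s at 500 Hz, SNR 10 dB.
    """
    cfg = synth.SimConfig(sampling_rate=500.0, duration=60.0, source_band=(18.0, 24.0),
                          coupling_delay=20.0, coupling_gain=0.8, snr=10.0,
                          line_noise_amplitude=0.0, n_cortex_channels=5,
                          n_stn_channels=3, seed=42)
    sources = synth.simulate_sources(cfg)
    rec, truth = synth.couple_and_mix(sources, cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def coupled_epochs(coupled_sim):
    _, rec, _ = coupled_sim
    return pp.make_epochs(rec)
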