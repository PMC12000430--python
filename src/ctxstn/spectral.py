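"""Multitaper power spectra, normalisation, band averages and SSD.

Power is estimated with Slepian (dpss) multitapers at a 5 Hz smoothing
bandwidth and expressed either raw (µV²/Hz) or as percentage of total
power over 5-60 Hz (with a 45-55 Hz line-noise exclusion window; a
broader 5-95 Hz range is supported as an alternative).  Spatio-spectral
decomposition (SSD) finds spatial filters maximising the ratio of
band-interior to flanking-band power via a generalised eigendecomposition,
returning the strongest oscillatory component per band together with a
Z-scored spatial pattern map of channel contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, signal
from scipy.signal.windows import dpss

from .preprocess import ChannelInfo, Epochs

#: fixed component counts used to equalise dimensionality across recordings
N_COMPONENTS = {
    ("cortex", "bipolar"): 4,
    ("stn", "bipolar"): 3,
    ("cortex", "unipolar"): 5,
    ("stn", "unipolar"): 3,
}


@dataclass
class BandDefinition:
    name: str
    lo: float
    hi: float


#: canonical frequency bands (Hz)
BANDS = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "mu_alpha": BandDefinition("mu_alpha", 8.0, 12.0),
    "low_beta": BandDefinition("low_beta", 12.0, 20.0),
    "high_beta": BandDefinition("high_beta", 20.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 90.0),
}


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    values: np.ndarray  # (channels, freqs)
    normalisation: str = "raw"
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.values.shape[1] != self.freqs.size:
            raise ValueError("values and freqs disagree in length")


@dataclass
class SSDModel:
    band: BandDefinition
    filters: np.ndarray  # channels x components
    patterns: np.ndarray  # channels x components, signed (covariance x filters)
    patterns_z: np.ndarray  # channels x components (|pattern|, Z-scored)
    snr_eigenvalues: np.ndarray  # descending
    component_spectrum: PowerSpectrum
    ridge_epsilon: float = 0.0


# ---------------------------------------------------------------------------
# multitaper layer


def multitaper_tapers(n_times: int, sampling_rate: float, bandwidth: float = 5.0) -> np.ndarray:
    """Slepian tapers for a given full smoothing bandwidth (Hz).

    ``bandwidth`` is the full spectral smoothing width; the half
    bandwidth W = bandwidth / 2 sets the time-bandwidth product
    NW = T x W and the taper count K = floor(2 NW) - 1.
    """
    half_bw = bandwidth / 2.0
    nw = n_times / sampling_rate * half_bw
    k = max(int(np.floor(2 * nw)) - 1, 1)
    if nw < 1:
        raise ValueError(
            f"bandwidth {bandwidth} Hz too narrow for {n_times / sampling_rate} s epochs"
        )
    return dpss(n_times, nw, Kmax=k)


def taper_fft(data: np.ndarray, sampling_rate: float, bandwidth: float = 5.0):
    """Tapered FFT coefficients of epoched data.

    ``data`` is (epochs, channels, times); returns (coeffs, freqs) where
    ``coeffs`` is (epochs, tapers, channels, freqs).  This is the shared
    front end of the PSD, CSD and segment-bootstrap estimators: the
    per-epoch coefficients are computed once and reused for every
    bootstrap segment.
    """
    data = np.asarray(data, dtype=float)
    data = data - data.mean(axis=-1, keepdims=True)
    n_times = data.shape[-1]
    tapers = multitaper_tapers(n_times, sampling_rate, bandwidth)
    freqs = np.fft.rfftfreq(n_times, 1.0 / sampling_rate)
    # (epochs, 1, channels, times) * (tapers, 1, times)
    tapered = data[:, None, :, :] * tapers[None, :, None, :]
    coeffs = np.fft.rfft(tapered, axis=-1)
    return coeffs, freqs


def psd_from_coeffs(coeffs: np.ndarray, freqs: np.ndarray, sampling_rate: float,
                    n_times: int) -> np.ndarray:
    """One-sided PSD (µV²/Hz) averaged over tapers and epochs."""
    power = (np.abs(coeffs) ** 2).mean(axis=(0, 1)) / sampling_rate
    power *= 2.0
    power[..., 0] /= 2.0
    if n_times % 2 == 0:
        power[..., -1] /= 2.0
    return power


def multitaper_psd(epochs: Epochs, bandwidth: float = 5.0) -> PowerSpectrum:
    """Multitaper power spectral density, one spectrum per channel.

    Slepian-taper estimates are averaged over tapers and kept epochs;
    the frequency resolution is 1/epoch_duration.
    """
    data = epochs.kept_data
    if data.shape[0] == 0:
        raise ValueError("no kept epochs")
    coeffs, freqs = taper_fft(data, epochs.sampling_rate, bandwidth)
    values = psd_from_coeffs(coeffs, freqs, epochs.sampling_rate, data.shape[-1])
    return PowerSpectrum(freqs=freqs, values=values, normalisation="raw",
                         channel_names=epochs.channel_names)


# ---------------------------------------------------------------------------
# normalisation and band summaries


def normalize_percent_total(
    spectrum: PowerSpectrum,
    range_hz: tuple[float, float] = (5.0, 60.0),
    exclusion: tuple[float, float] | None = (45.0, 55.0),
) -> PowerSpectrum:
    """Express power as a percentage of total power over ``range_hz``.

    The denominator sums raw power over ``range_hz`` (inclusive) minus
    the ``exclusion`` window (inclusive; pass ``None`` to disable), per
    channel; every bin is scaled so included bins sum to 100.
    """
    if spectrum.normalisation != "raw":
        raise ValueError("expected a raw spectrum")
    lo, hi = range_hz
    include = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if exclusion is not None:
        elo, ehi = exclusion
        include &= ~((spectrum.freqs >= elo) & (spectrum.freqs <= ehi))
    totals = spectrum.values[:, include].sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("zero total power in the normalisation range")
    tag = f"pct_{lo:g}_{hi:g}" + ("" if exclusion is None else f"_excl_{exclusion[0]:g}_{exclusion[1]:g}")
    return replace(spectrum, values=100.0 * spectrum.values / totals, normalisation=tag)


def band_average(spectrum: PowerSpectrum, band: BandDefinition) -> np.ndarray:
    """Arithmetic mean over bins with lo <= f <= hi (inclusive), per channel."""
    mask = (spectrum.freqs >= band.lo) & (spectrum.freqs <= band.hi)
    if not mask.any():
        raise ValueError(f"band {band.name} ({band.lo}-{band.hi} Hz) contains no bins")
    return spectrum.values[:, mask].mean(axis=1)


# ---------------------------------------------------------------------------
# rank normalisation


def reduce_rank(epochs: Epochs, site: str, montage: str,
                n_components: int | None = None) -> tuple[Epochs, np.ndarray]:
    """Project a site's channels onto its fixed number of principal components.

    Dimensionality is equalised across recordings by SVD of the
    (channel-demeaned) data and retention of the first n left singular
    vectors; n comes from the fixed table {bipolar cortex: 4, bipolar
    STN: 3, unipolar cortex: 5, unipolar STN: 3} unless overridden.
    Returns (component epochs, projection) with projection (channels x n)
    mapping component patterns back to channel space.
    """
    n = n_components if n_components is not None else N_COMPONENTS[(site, montage)]
    data = epochs.data  # (epochs, channels, times)
    n_ep, n_ch, n_t = data.shape
    if n_ch < n:
        raise ValueError(f"{n_ch} channels < {n} requested components for {site}/{montage}")
    flat = data.transpose(1, 0, 2).reshape(n_ch, n_ep * n_t)
    means = flat.mean(axis=1)
    flat = flat - means[:, None]
    u, s, _ = np.linalg.svd(flat, full_matrices=False)
    proj = u[:, :n]
    data = data - means[None, :, None]  # project the demeaned data
    # deterministic sign: largest-magnitude weight positive
    for j in range(n):
        k = int(np.argmax(np.abs(proj[:, j])))
        if proj[k, j] < 0:
            proj[:, j] = -proj[:, j]
    reduced = np.einsum("cn,ect->ent", proj, data)
    info = [ChannelInfo(name=f"{site}_pc{j + 1}", site=site,  # type: ignore[arg-type]
                        montage=montage, region="stn" if site == "stn" else "motor")
            for j in range(n)]
    red = Epochs(data=reduced, sampling_rate=epochs.sampling_rate,
                 epoch_duration=epochs.epoch_duration, channel_info=info,
                 kept_mask=epochs.kept_mask.copy(), condition=epochs.condition,
                 subject_id=epochs.subject_id)
    return red, proj


# ---------------------------------------------------------------------------
# spatio-spectral decomposition


def _filtfilt_power_bandwidth(sos_list, sampling_rate: float, n_points: int = 8192) -> float:
    """Equivalent noise bandwidth (Hz) of a forward-backward filter cascade."""
    w = np.linspace(0, sampling_rate / 2, n_points)
    h = np.ones_like(w)
    for sos in sos_list:
        _, resp = signal.sosfreqz(sos, worN=w, fs=sampling_rate)
        h = h * np.abs(resp) ** 2  # filtfilt squares the magnitude response
    return float(np.trapezoid(h**2, w))  # power response of the cascade is |H|^2 -> squared


def _epoch_filtfilt(sos, data: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def ssd_fit(epochs: Epochs, band: BandDefinition, flank_width: float = 1.0,
            bandwidth: float = 5.0) -> SSDModel:
    """Spatio-spectral decomposition for one frequency band.

    Spatial filters w maximise the generalised Rayleigh quotient
    (w' C_s w) / (w' C_n w), where C_s is the covariance of the data
    bandpass filtered to the band and C_n the covariance of the flanking
    strips (band ± ``flank_width`` with the band interior removed).
    Both covariances are scaled by their filters' equivalent noise
    bandwidths, so eigenvalues are per-Hz SNR ratios (~1 for white
    noise).  Patterns are computed as C_s W (W' C_s W)^{-1}, their
    absolute values Z-scored across channels within each component.
    The strongest component's spectrum is estimated by applying its
    filter to band-filtered data and running the multitaper PSD.
    """
    fs = epochs.sampling_rate
    lo, hi = band.lo, band.hi
    if hi + flank_width >= fs / 2:
        raise ValueError("band plus flanks must lie below Nyquist")
    sos_sig = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    sos_wide = signal.butter(4, [lo - flank_width, hi + flank_width],
                             btype="bandpass", fs=fs, output="sos")
    sos_stop = signal.butter(4, [lo, hi], btype="bandstop", fs=fs, output="sos")

    data = epochs.kept_data
    sig = _epoch_filtfilt(sos_sig, data)
    noise = _epoch_filtfilt(sos_stop, _epoch_filtfilt(sos_wide, data))

    def _cov(x: np.ndarray) -> np.ndarray:
        n_ep, n_ch, n_t = x.shape
        flat = x.transpose(1, 0, 2).reshape(n_ch, -1)
        flat = flat - flat.mean(axis=1, keepdims=True)
        return flat @ flat.T / flat.shape[1]

    bw_sig = _filtfilt_power_bandwidth([sos_sig], fs)
    bw_noise = _filtfilt_power_bandwidth([sos_wide, sos_stop], fs)
    cs = _cov(sig) / bw_sig
    cn = _cov(noise) / bw_noise

    eps = 0.0
    n_ch = cs.shape[0]
    if np.linalg.cond(cn) > 1e10:
        eps = 1e-8 * np.trace(cn) / n_ch
        cn = cn + eps * np.eye(n_ch)
    evals, evecs = linalg.eigh(cs, cn)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    filters = evecs[:, order]
    for j in range(filters.shape[1]):
        k = int(np.argmax(np.abs(filters[:, j])))
        if filters[k, j] < 0:
            filters[:, j] = -filters[:, j]
    wcw = filters.T @ cs @ filters
    patterns = cs @ filters @ np.linalg.inv(wcw)
    pat = np.abs(patterns)
    patterns_z = (pat - pat.mean(axis=0)) / pat.std(axis=0)

    comp = np.einsum("c,ect->et", filters[:, 0], sig)[:, None, :]
    comp_epochs = Epochs(
        data=comp, sampling_rate=fs, epoch_duration=epochs.epoch_duration,
        channel_info=[ChannelInfo(name=f"ssd_{band.name}", site="cortex")],
    )
    spectrum = multitaper_psd(comp_epochs, bandwidth=bandwidth)
    return SSDModel(band=band, filters=filters, patterns=patterns,
                    patterns_z=patterns_z, snr_eigenvalues=evals,
                    component_spectrum=spectrum, ridge_epsilon=eps)
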