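"""Frequency-resolved coupling between cortical and subthalamic channel sets.

Undirected coupling uses the imaginary part of coherency (ImCoh), which
by construction ignores zero-phase-lag (volume-conducted or common
reference) interactions, both as a grand average over seed-target
channel pairs and in its maximised multivariate form (MIC), which also
yields spatial filters and Z-scored channel-contribution patterns for
the seed (cortex) and target (STN) sets.

Directed coupling uses multivariate spectral Granger causality from a
vector autoregressive model fitted to the multitaper cross-spectral
density via the autocovariance sequence, with time-reversal correction:
net scores (seed->target minus target->seed) computed on the original
and on the time-reversed data (transposed autocovariances) are
subtracted, suppressing spurious directionality from weak data
asymmetries.  Positive values mean cortex drives STN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .preprocess import Epochs, SegmentSet
from .spectral import taper_fft


@dataclass
class CrossSpectralDensity:
    freqs: np.ndarray
    matrices: np.ndarray  # (freqs, channels, channels), Hermitian
    channel_names: list[str] | None = None
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.matrices = np.asarray(self.matrices)
        if self.matrices.shape[0] != self.freqs.size:
            raise ValueError("matrices and freqs disagree in length")

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]


@dataclass
class CouplingSpectrum:
    freqs: np.ndarray
    values: np.ndarray
    method: str  # imcoh | mic | gc_net | trgc
    seed_patterns_z: np.ndarray | None = None  # (seed channels, freqs)
    target_patterns_z: np.ndarray | None = None
    segment_count: int = 1
    meta: dict = field(default_factory=dict)


@dataclass
class VARModel:
    coefs: np.ndarray  # (order, m, m)
    sigma: np.ndarray  # (m, m)

    @property
    def order(self) -> int:
        return self.coefs.shape[0]


# ---------------------------------------------------------------------------
# cross-spectral density


def _csd_scale(n_times: int, sampling_rate: float, n_freqs: int) -> np.ndarray:
    scale = np.full(n_freqs, 2.0 / sampling_rate)
    scale[0] = 1.0 / sampling_rate
    if n_times % 2 == 0:
        scale[-1] = 1.0 / sampling_rate
    return scale


def epoch_cross_products(coeffs: np.ndarray, freqs: np.ndarray, sampling_rate: float,
                         n_times: int) -> np.ndarray:
    """Per-epoch taper-averaged cross-spectra (epochs, freqs, ch, ch).

    This cache makes bootstrap-segment CSDs a weighted average over
    epochs instead of a fresh FFT pass per segment.
    """
    p = np.einsum("etcf,etdf->efcd", coeffs, np.conj(coeffs)) / coeffs.shape[1]
    return p * _csd_scale(n_times, sampling_rate, freqs.size)[None, :, None, None]


def csd_multitaper(epochs: Epochs, bandwidth: float = 5.0) -> CrossSpectralDensity:
    """Multitaper cross-spectral density averaged over tapers and kept epochs."""
    data = epochs.kept_data
    if data.shape[1] < 2:
        raise ValueError("coupling is undefined for a single channel")
    coeffs, freqs = taper_fft(data, epochs.sampling_rate, bandwidth)
    p = epoch_cross_products(coeffs, freqs, epochs.sampling_rate, data.shape[-1])
    return CrossSpectralDensity(freqs=freqs, matrices=p.mean(axis=0),
                                channel_names=epochs.channel_names,
                                sampling_rate=epochs.sampling_rate)


def bootstrap_csds(epochs: Epochs, segments: SegmentSet,
                   bandwidth: float = 5.0) -> list[CrossSpectralDensity]:
    """One CSD per bootstrap segment, sharing a single tapered-FFT pass."""
    data = epochs.data
    coeffs, freqs = taper_fft(data, epochs.sampling_rate, bandwidth)
    p = epoch_cross_products(coeffs, freqs, epochs.sampling_rate, data.shape[-1])
    n_ep = data.shape[0]
    counts = np.zeros((segments.n_segments, n_ep))
    for i, seg in enumerate(segments.segments):
        counts[i] = np.bincount(seg, minlength=n_ep)
    counts /= segments.epochs_per_segment
    flat = p.reshape(n_ep, -1)
    seg_flat = counts @ flat
    mats = seg_flat.reshape(segments.n_segments, freqs.size, data.shape[1], data.shape[1])
    return [CrossSpectralDensity(freqs=freqs, matrices=mats[i],
                                 channel_names=epochs.channel_names,
                                 sampling_rate=epochs.sampling_rate)
            for i in range(segments.n_segments)]


# ---------------------------------------------------------------------------
# imaginary coherency


def imcoh_grand_average(csd: CrossSpectralDensity, seed_idx: Sequence[int],
                        target_idx: Sequence[int],
                        abs_before_average: bool = True) -> CouplingSpectrum:
    """Grand-average absolute imaginary coherency over seed-target pairs.

    Coherency C_ij = S_ij / sqrt(S_ii S_jj); |Im C_ij| is averaged over
    all seed-target channel pairs (absolute value per pair by default;
    set ``abs_before_average=False`` to average signed values first).
    """
    seed_idx = np.asarray(seed_idx, dtype=int)
    target_idx = np.asarray(target_idx, dtype=int)
    if seed_idx.size == 0 or target_idx.size == 0:
        raise ValueError("need at least one seed and one target channel")
    s = csd.matrices
    diag = np.real(np.einsum("fii->fi", s))
    if np.any(diag <= 0):
        raise ValueError("zero or negative diagonal power in CSD")
    cross = s[:, seed_idx[:, None], target_idx[None, :]]
    denom = np.sqrt(diag[:, seed_idx][:, :, None] * diag[:, target_idx][:, None, :])
    imc = np.imag(cross / denom)
    if abs_before_average:
        values = np.abs(imc).mean(axis=(1, 2))
    else:
        values = np.abs(imc.mean(axis=(1, 2)))
    return CouplingSpectrum(freqs=csd.freqs, values=values, method="imcoh")


def _inv_sqrt_psd(mats: np.ndarray, ridge: float) -> tuple[np.ndarray, float]:
    """Batch inverse square root of symmetric PSD matrices with optional ridge."""
    n = mats.shape[-1]
    eps_used = 0.0
    evals, evecs = np.linalg.eigh(mats)
    tiny = np.max(evals, axis=-1, keepdims=True) * 1e-12
    if np.any(evals <= tiny):
        eps_used = ridge * float(np.mean(np.trace(mats, axis1=-2, axis2=-1))) / n
        mats = mats + eps_used * np.eye(n)
        evals, evecs = np.linalg.eigh(mats)
    inv_sqrt = evecs @ (evecs / np.sqrt(evals)[..., None, :]).transpose(0, 2, 1)
    return inv_sqrt, eps_used


def mic(csd: CrossSpectralDensity, seed_idx: Sequence[int], target_idx: Sequence[int],
        ridge: float = 1e-8, seed_projection: np.ndarray | None = None,
        target_projection: np.ndarray | None = None) -> CouplingSpectrum:
    """Maximised imaginary coherency between two channel sets.

    Per frequency, the seed and target blocks are whitened by the
    inverse square roots of the real parts of their auto-spectral
    blocks; the largest singular value of the whitened imaginary
    cross-block is the MIC, and the singular vectors back-transform to
    spatial filters.  Patterns (real auto-block x filter) are taken in
    absolute value and Z-scored across channels; optional projection
    matrices map component-space patterns back to sensor space first.
    """
    seed_idx = np.asarray(seed_idx, dtype=int)
    target_idx = np.asarray(target_idx, dtype=int)
    s = csd.matrices
    saa = np.real(s[:, seed_idx[:, None], seed_idx[None, :]])
    sbb = np.real(s[:, target_idx[:, None], target_idx[None, :]])
    sab = s[:, seed_idx[:, None], target_idx[None, :]]
    pa, eps_a = _inv_sqrt_psd(saa, ridge)
    pb, eps_b = _inv_sqrt_psd(sbb, ridge)
    d = pa @ np.imag(sab) @ pb
    u, sv, vt = np.linalg.svd(d)
    values = sv[:, 0]
    alpha = np.einsum("fij,fj->fi", pa, u[:, :, 0])  # seed filters
    beta = np.einsum("fij,fj->fi", pb, vt[:, 0, :])  # target filters
    pat_a = np.abs(np.einsum("fij,fj->fi", saa, alpha))  # (F, ns)
    pat_b = np.abs(np.einsum("fij,fj->fi", sbb, beta))
    if seed_projection is not None:
        pat_a = np.abs(pat_a @ seed_projection.T)  # back to sensor space
    if target_projection is not None:
        pat_b = np.abs(pat_b @ target_projection.T)

    def _z(p: np.ndarray) -> np.ndarray:
        sd = p.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return ((p - p.mean(axis=1, keepdims=True)) / sd).T  # (channels, F)

    return CouplingSpectrum(
        freqs=csd.freqs, values=values, method="mic",
        seed_patterns_z=_z(pat_a), target_patterns_z=_z(pat_b),
        meta={"ridge_seed": eps_a, "ridge_target": eps_b},
    )


# ---------------------------------------------------------------------------
# VAR from CSD (Yule-Walker on the autocovariance sequence)


def autocov_from_csd(csd: CrossSpectralDensity, n_lags: int) -> np.ndarray:
    """Autocovariance sequence Gamma_0..Gamma_n by inverse Fourier transform.

    Requires the CSD on the full rfft grid (0..Nyquist, uniform step).
    """
    freqs = csd.freqs
    if freqs[0] != 0 or np.ptp(np.diff(freqs)) > 1e-9:
        raise ValueError("CSD must be on a full uniform frequency grid starting at 0")
    fs = csd.sampling_rate
    if fs is None:
        fs = 2 * freqs[-1]
    df = freqs[1] - freqs[0]
    n_fft = int(round(fs / df))
    n_f = freqs.size
    # undo the one-sided doubling to recover the two-sided density
    two = csd.matrices.copy().astype(complex)
    two[1:] /= 2.0
    if n_fft % 2 == 0:
        two[-1] *= 2.0
    full = np.zeros((n_fft,) + two.shape[1:], dtype=complex)
    full[:n_f] = two
    full[n_f:] = np.conj(two[1:n_fft - n_f + 1][::-1])
    gamma = np.fft.ifft(full, axis=0).real * fs
    if n_lags >= n_fft:
        raise ValueError(f"order {n_lags} too high for grid of {n_fft} lags")
    return gamma[: n_lags + 1]


def var_from_autocov(gamma: np.ndarray) -> VARModel:
    """Solve the block Yule-Walker equations for VAR coefficients.

    Gamma is (p+1, m, m) with Gamma_k = E[x_t x_{t-k}^T]; returns the
    order-p model (A_1..A_p, innovation covariance).
    """
    gamma = np.asarray(gamma, dtype=float)
    p = gamma.shape[0] - 1
    m = gamma.shape[1]

    def g(d: int) -> np.ndarray:
        return gamma[d] if d >= 0 else gamma[-d].T

    big = np.empty((m * p, m * p))
    for k in range(p):
        for j in range(p):
            big[k * m:(k + 1) * m, j * m:(j + 1) * m] = g(j - k)
    rhs = np.hstack([gamma[j] for j in range(1, p + 1)])  # (m, m*p)
    try:
        b = np.linalg.solve(big.T, rhs.T).T
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"ill-conditioned autocovariance system (cond={np.linalg.cond(big):.3g})"
        ) from exc
    coefs = b.reshape(m, p, m).transpose(1, 0, 2)
    sigma = gamma[0].copy()
    for k in range(1, p + 1):
        sigma -= coefs[k - 1] @ gamma[k].T
    sigma = (sigma + sigma.T) / 2.0
    evals = np.linalg.eigvalsh(sigma)
    if evals.min() <= 0:
        raise ValueError(
            f"non-positive-definite innovation covariance (min eig {evals.min():.3g}); "
            f"autocovariance system cond={np.linalg.cond(big):.3g}"
        )
    return VARModel(coefs=coefs, sigma=sigma)


def var_from_csd(csd: CrossSpectralDensity, order: int = 60) -> VARModel:
    """Fit a VAR model to a cross-spectral density via its autocovariances."""
    gamma = autocov_from_csd(csd, order)
    return var_from_autocov(gamma)


def var_transfer(var: VARModel, freqs: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Transfer function H(f) = (I - sum_k A_k e^{-2pi i f k / fs})^{-1}."""
    p, m, _ = var.coefs.shape
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / sampling_rate)
    a = np.tile(np.eye(m, dtype=complex), (len(freqs), 1, 1))
    a -= np.einsum("fk,kij->fij", z, var.coefs.astype(complex))
    return np.linalg.inv(a)


def spectral_gc(var: VARModel, freqs: np.ndarray, sampling_rate: float,
                seed_idx: Sequence[int], target_idx: Sequence[int]) -> np.ndarray:
    """Geweke's frequency-resolved Granger causality, seed -> target.

    GC(f) = ln det S_yy(f) - ln det( H_yy(f) Sigma_{y|x} H_yy(f)^H )
    with the partialised innovation covariance
    Sigma_{y|x} = Sigma_yy - Sigma_yx Sigma_xx^{-1} Sigma_xy.
    """
    x = np.asarray(seed_idx, dtype=int)
    y = np.asarray(target_idx, dtype=int)
    h = var_transfer(var, freqs, sampling_rate)
    s = h @ var.sigma @ h.conj().transpose(0, 2, 1)
    s_yy = s[:, y[:, None], y[None, :]]
    sig = var.sigma
    sig_cond = (sig[np.ix_(y, y)]
                - sig[np.ix_(y, x)] @ np.linalg.solve(sig[np.ix_(x, x)], sig[np.ix_(x, y)]))
    h_yy = h[:, y[:, None], y[None, :]]
    intrinsic = h_yy @ sig_cond @ h_yy.conj().transpose(0, 2, 1)
    num = np.linalg.det(s_yy).real
    den = np.linalg.det(intrinsic).real
    return np.log(np.maximum(num, 1e-300)) - np.log(np.maximum(den, 1e-300))


def trgc(csd: CrossSpectralDensity, seed_idx: Sequence[int], target_idx: Sequence[int],
         order: int = 60, band: tuple[float, float] | None = None,
         time_reversed: bool = True) -> CouplingSpectrum:
    """Net (and, by default, time-reversed) spectral Granger causality.

    net(f) = GC(seed->target) - GC(target->seed) from a VAR fit to the
    CSD's autocovariance sequence; with ``time_reversed`` the same net
    score computed on the transposed autocovariance sequence is
    subtracted.  Positive values mean the seed set (cortex) drives the
    target set (STN).
    """
    fs = csd.sampling_rate if csd.sampling_rate is not None else 2 * csd.freqs[-1]
    gamma = autocov_from_csd(csd, order)
    if band is None:
        fmask = np.ones(csd.freqs.size, dtype=bool)
    else:
        fmask = (csd.freqs >= band[0]) & (csd.freqs <= band[1])
    freqs = csd.freqs[fmask]

    def _net(g: np.ndarray) -> np.ndarray:
        model = var_from_autocov(g)
        fwd = spectral_gc(model, freqs, fs, seed_idx, target_idx)
        rev = spectral_gc(model, freqs, fs, target_idx, seed_idx)
        return fwd - rev

    values = _net(gamma)
    method = "gc_net"
    if time_reversed:
        values = values - _net(gamma.transpose(0, 2, 1))
        method = "trgc"
    return CouplingSpectrum(freqs=freqs, values=values, method=method,
                            meta={"order": order})


# ---------------------------------------------------------------------------
# segment averaging


def average_segments(spectra: Sequence[CouplingSpectrum]) -> CouplingSpectrum:
    """Element-wise mean of per-segment coupling spectra."""
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for sp in spectra[1:]:
        if sp.method != first.method or not np.allclose(sp.freqs, first.freqs):
            raise ValueError("mismatched frequency grids or methods")
    values = np.mean([sp.values for sp in spectra], axis=0)
    out = replace(first, values=values,
                  segment_count=sum(sp.segment_count for sp in spectra))
    for attr in ("seed_patterns_z", "target_patterns_z"):
        pats = [getattr(sp, attr) for sp in spectra]
        if all(p is not None for p in pats):
            setattr(out, attr, np.mean(pats, axis=0))
    return out
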