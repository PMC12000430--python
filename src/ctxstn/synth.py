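"""Synthetic recordings, connectome fixtures and cohort tables with ground truth.

Every generator is a pure function of its configuration and seed, and
returns (or stores alongside its output) a ground-truth record so that
downstream estimators can be validated by parameter recovery:

* band-limited, optionally skewed (non-Gaussian) oscillatory sources,
  linearly mixed into a "cortex" and an "STN" channel set with a
  unidirectional, delayed interaction between the two sets;
* 1/f background noise, 50 Hz line noise and (optionally) a periodic
  charge-balanced DBS pulse-train artifact;
* stable vector-autoregressive processes with known coefficients (the
  analytic test bed for spectral Granger causality);
* streamline atlases with exact per-contact-pair connection counts;
* 4D functional volumes with planted seed-correlated parcels;
* multi-subject observation tables with known mixed-model coefficients.

Non-Gaussianity matters because the bispectrum (the Fourier transform of
the third-order moment) vanishes for Gaussian signals; bispectral
time-delay estimation therefore needs skewed sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal, stats

from .preprocess import ChannelInfo, Condition, Recording


@dataclass
class DBSParams:
    """Stimulation settings: 130 Hz, 60 µs pulses is the clinical standard."""

    frequency: float = 130.0  # Hz
    pulse_width: float = 60.0  # µs
    amplitude: float = 200.0  # µV, scale of the artifact in the recording


@dataclass
class SimConfig:
    """Conditions of a simulated rest recording.

    Defaults mirror a clinical ECoG + STN-LFP acquisition: 4 kHz
    sampling, a 6-contact subdural strip and an 8-contact DBS lead,
    beta-band oscillatory sources, and a cortex->STN interaction delayed
    by 25 ms (the scale of cortico-subthalamic transmission).
    """

    sampling_rate: float = 4000.0  # Hz
    duration: float = 180.0  # s
    n_cortex_channels: int = 6
    n_stn_channels: int = 8
    source_band: tuple[float, float] = (12.0, 30.0)  # Hz
    coupling_delay: float = 25.0  # ms
    coupling_gain: float = 0.8  # dimensionless
    snr: float = 10.0  # dB, per-channel source power over background power
    line_noise_amplitude: float = 5.0  # µV
    dbs: DBSParams | None = None
    nongaussianity: float = 1.0  # skewing-transform strength; 0 -> Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.source_band
        if not (0 < lo < hi):
            raise ValueError("source_band must satisfy 0 < lo < hi")
        if self.sampling_rate <= 2 * hi:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz must exceed twice the "
                f"upper band edge ({hi} Hz)"
            )
        if self.coupling_delay < 0:
            raise ValueError("coupling_delay must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def delay_samples(self) -> float:
        return self.coupling_delay * self.sampling_rate / 1000.0


@dataclass
class GroundTruth:
    """What the generator actually planted; the recovery target for tests."""

    mixing_cortex: np.ndarray  # channels x sources
    mixing_stn: np.ndarray
    true_delay: float  # ms
    true_direction: str  # 'cortex->stn' | 'stn->cortex' | 'none'
    source_band: tuple[float, float]
    true_fiber_counts: dict | None = None
    true_betas: dict | None = None
    extras: dict = field(default_factory=dict)


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    return signal.butter(order, band, btype="bandpass", fs=fs, output="sos")


def _skew(x: np.ndarray, strength: float) -> np.ndarray:
    """Monotone exponential-type skewing transform, zero mean, unit variance."""
    z = (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, keepdims=True)
    y = np.expm1(strength * z) / strength  # -> z as strength -> 0
    y -= y.mean(axis=-1, keepdims=True)
    return y / y.std(axis=-1, keepdims=True)


def simulate_sources(
    config: SimConfig,
    n_sources: int = 2,
    skew_floor: float = 0.1,
) -> np.ndarray:
    """Generate independent band-limited oscillatory sources (sources x samples).

    White noise is bandpass filtered to ``config.source_band``; when
    ``config.nongaussianity > 0`` it is passed through a monotone
    exponential skewing transform and re-filtered, giving sources with
    non-vanishing third-order cumulants (required for bispectral
    time-delay estimation).  Each source has unit variance.

    Raises if the band falls outside Nyquist, or if the requested
    non-Gaussianity fails to produce skewness above ``skew_floor``.
    """
    lo, hi = config.source_band
    if hi >= config.sampling_rate / 2:
        raise ValueError(
            f"source band upper edge {hi} Hz is not below Nyquist "
            f"({config.sampling_rate / 2} Hz)"
        )
    rng = np.random.default_rng(config.seed)
    sos = _bandpass_sos(config.source_band, config.sampling_rate)
    x = rng.standard_normal((n_sources, config.n_samples))
    x = signal.sosfiltfilt(sos, x, axis=-1)
    if config.nongaussianity > 0:
        # The skewing transform puts third-moment content at sum frequencies
        # (f1 + f2, up to 2*hi); the re-filter must keep that harmonic band,
        # otherwise the signal reverts to a (symmetric) narrowband process
        # with a vanishing bispectrum.  The harmonic components are weak, so
        # variance stays concentrated in the fundamental band.
        x = _skew(x, config.nongaussianity)
        re_hi = min(2.2 * hi, 0.45 * config.sampling_rate)
        fundamental = signal.sosfiltfilt(sos, x, axis=-1)
        sos_harm = _bandpass_sos((hi, re_hi), config.sampling_rate)
        harmonic = signal.sosfiltfilt(sos_harm, x, axis=-1)
        # keep the sum-frequency (harmonic) components weak so variance stays
        # concentrated in the band, but present so the bispectrum is non-zero
        eta = 0.08
        gain = np.sqrt(eta * fundamental.var(axis=-1) / harmonic.var(axis=-1))
        x = fundamental + gain[:, None] * harmonic
        sk = stats.skew(x, axis=-1)
        if np.any(np.abs(sk) < skew_floor):
            raise RuntimeError(
                f"skewness {sk} below floor {skew_floor}; increase nongaussianity"
            )
    x /= x.std(axis=-1, keepdims=True)
    return x


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, int],
                      fs: float, exponent: float = 1.0) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f**exponent, unit variance."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal((shape[0], freqs.size))
            + 1j * rng.standard_normal((shape[0], freqs.size))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _default_channel_info(config: SimConfig) -> list[ChannelInfo]:
    regions = ["prefrontal", "motor", "motor", "sensory", "parietal", "parietal"]
    info: list[ChannelInfo] = []
    for i in range(config.n_cortex_channels):
        info.append(ChannelInfo(
            name=f"ECOG_{i + 1}",
            site="cortex",
            region=regions[i % len(regions)],  # type: ignore[arg-type]
            mni_xyz=(-40.0, -65.0 + 12.0 * i, 55.0),
        ))
    for j in range(config.n_stn_channels):
        info.append(ChannelInfo(
            name=f"LFP_{j + 1}",
            site="stn",
            region="stn",
            mni_xyz=(-12.0, -13.0, -7.0 + 1.5 * j),
        ))
    return info


def couple_and_mix(
    sources: np.ndarray,
    config: SimConfig,
    condition: Condition = "off",
    subject_id: str = "sub-01",
    mixing_cortex: np.ndarray | None = None,
    mixing_stn: np.ndarray | None = None,
) -> tuple[Recording, GroundTruth]:
    """Build a recording with a delayed cortex->STN interaction.

    ``sources[0]`` is the cortical seed source; the subthalamic source is
    ``coupling_gain`` times the seed delayed by ``coupling_delay`` plus an
    independent innovation (``sources[1]``).  Both are mixed into their
    channel sets by random full-rank mixing columns, then 1/f background
    noise (at the configured SNR) and common zero-lag 50 Hz line noise
    are added.
    """
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if sources.shape[0] < 2:
        raise ValueError("need >= 2 sources (seed + innovation)")
    d_float = config.delay_samples
    d = int(round(d_float))
    if abs(d_float - d) > 1e-9:
        finest = 1000.0 / config.sampling_rate
        raise ValueError(
            f"coupling_delay {config.coupling_delay} ms is not an integer number "
            f"of samples at {config.sampling_rate} Hz; finest representable "
            f"delay step is {finest:.6g} ms"
        )
    rng = np.random.default_rng(config.seed + 1)
    seed_src = sources[0]
    innov = sources[1]
    shifted = np.zeros_like(seed_src)
    if d > 0:
        shifted[d:] = seed_src[:-d]
    else:
        shifted[:] = seed_src
    target_src = config.coupling_gain * shifted + innov

    def _mix_column(n: int) -> np.ndarray:
        col = rng.uniform(0.5, 1.5, size=n) * rng.choice([-1.0, 1.0], size=n)
        return col

    m_c = (np.asarray(mixing_cortex, dtype=float).ravel()
           if mixing_cortex is not None else _mix_column(config.n_cortex_channels))
    m_s = (np.asarray(mixing_stn, dtype=float).ravel()
           if mixing_stn is not None else _mix_column(config.n_stn_channels))
    sig_c = np.outer(m_c, seed_src)
    sig_s = np.outer(m_s, target_src)
    sig = np.vstack([sig_c, sig_s])

    n_ch = config.n_cortex_channels + config.n_stn_channels
    if np.isinf(config.snr):
        data = sig.copy()
    else:
        noise = _one_over_f_noise(rng, (n_ch, config.n_samples), config.sampling_rate)
        sig_power = sig.var(axis=-1)
        noise_power = sig_power / (10.0 ** (config.snr / 10.0))
        # channels with (near) zero signal still get the median noise floor
        floor = np.median(noise_power[noise_power > 0]) if np.any(noise_power > 0) else 1.0
        noise_power = np.where(noise_power > 0, noise_power, floor)
        data = sig + noise * np.sqrt(noise_power)[:, None]

    if config.line_noise_amplitude > 0:
        t = np.arange(config.n_samples) / config.sampling_rate
        line = np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        gains = rng.uniform(0.5, 1.5, size=n_ch)
        data = data + config.line_noise_amplitude * gains[:, None] * line[None, :]

    rec = Recording(
        data=data,
        sampling_rate=config.sampling_rate,
        channel_info=_default_channel_info(config),
        condition=condition,
        subject_id=subject_id,
    )
    truth = GroundTruth(
        mixing_cortex=m_c[:, None],
        mixing_stn=m_s[:, None],
        true_delay=config.coupling_delay,
        true_direction="cortex->stn" if config.coupling_gain != 0 else "none",
        source_band=config.source_band,
        extras={"seed_source": seed_src, "target_source": target_src},
    )
    return rec, truth


def add_dbs_artifact(
    recording: Recording,
    frequency: float = 130.0,
    pulse_width: float = 60.0,
    amplitude: float = 200.0,
    seed: int = 0,
) -> Recording:
    """Superimpose a periodic charge-balanced biphasic pulse-train artifact.

    The train is synthesised band-limited: as the truncated Fourier
    series of the continuous biphasic rectangular pulse (width
    ``pulse_width`` µs per phase) at harmonics of ``frequency`` below
    Nyquist, so its sampled power sits exactly at the stimulation
    harmonics.  Channel gains are drawn log-uniform in [0.25, 1] x
    ``amplitude``.  The exact artifact period (samples) is recorded in
    ``recording.meta['dbs_period_samples']``.
    """
    fs = recording.sampling_rate
    if frequency >= fs / 2:
        raise ValueError(f"stimulation frequency {frequency} Hz >= Nyquist ({fs / 2} Hz)")
    pw = pulse_width * 1e-6  # s
    if 2 * pw > 1.0 / frequency:
        raise ValueError("biphasic pulse does not fit within one stimulation period")
    out = Recording(
        data=recording.data.copy(),
        sampling_rate=fs,
        channel_info=list(recording.channel_info),
        condition=recording.condition,
        subject_id=recording.subject_id,
        meta=dict(recording.meta),
    )
    out.meta["dbs_period_samples"] = fs / frequency
    out.meta["dbs_frequency"] = frequency
    if amplitude == 0:
        return out
    rng = np.random.default_rng(seed)
    gains = np.exp(rng.uniform(np.log(0.25), np.log(1.0), size=recording.n_channels))
    t = np.arange(recording.n_samples) / fs
    k_max = int(np.floor((fs / 2) / frequency))
    train = np.zeros(recording.n_samples)
    for k in range(1, k_max + 1):
        w = 2 * np.pi * k * frequency
        c_k = frequency * (1 - np.exp(-1j * w * pw)) ** 2 / (1j * w)
        train += 2 * np.real(c_k * np.exp(1j * w * t))
    train *= amplitude / np.max(np.abs(train))
    out.data += gains[:, None] * train[None, :]
    return out


# ---------------------------------------------------------------------------
# vector autoregressive test bed


def check_var_stable(coefs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (< 1 for stability)."""
    coefs = np.asarray(coefs, dtype=float)
    p, m, _ = coefs.shape
    companion = np.zeros((m * p, m * p))
    companion[:m, :] = coefs.transpose(1, 0, 2).reshape(m, m * p)
    if p > 1:
        companion[m:, : m * (p - 1)] = np.eye(m * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def simulate_var(
    coefficient_matrices: np.ndarray,
    innovation_covariance: np.ndarray,
    n_samples: int,
    seed: int = 0,
    burn: int = 1000,
) -> np.ndarray:
    """Simulate a stationary VAR(p) realisation (channels x samples)."""
    coefs = np.asarray(coefficient_matrices, dtype=float)
    if coefs.ndim != 3 or coefs.shape[1] != coefs.shape[2]:
        raise ValueError("coefficient_matrices must be (p, m, m)")
    radius = check_var_stable(coefs)
    if radius >= 1.0:
        raise ValueError(f"unstable VAR: companion spectral radius {radius:.4f} >= 1")
    p, m, _ = coefs.shape
    sigma = np.asarray(innovation_covariance, dtype=float)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(sigma)
    total = n_samples + burn
    e = rng.standard_normal((total, m)) @ chol.T
    x = np.zeros((total, m))
    for t in range(p, total):
        acc = e[t].copy()
        for k in range(p):
            acc += coefs[k] @ x[t - k - 1]
        x[t] = acc
    return x[burn:].T.copy()


def var_csd(coefs: np.ndarray, sigma: np.ndarray, freqs: np.ndarray,
            fs: float) -> np.ndarray:
    """Closed-form (two-sided density) cross-spectrum of a VAR process.

    S(f) = H(f) Sigma H(f)^H / fs with H = (I - sum_k A_k z^-k)^{-1};
    used as the analytic oracle for spectral estimators and for
    Granger-causality recovery tests.
    """
    coefs = np.asarray(coefs, dtype=float)
    p, m, _ = coefs.shape
    freqs = np.asarray(freqs, dtype=float)
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)  # (F, p)
    a = np.tile(np.eye(m, dtype=complex), (freqs.size, 1, 1))
    a -= np.einsum("fk,kij->fij", z, coefs.astype(complex))
    h = np.linalg.inv(a)
    return h @ sigma @ h.conj().transpose(0, 2, 1) / fs


# ---------------------------------------------------------------------------
# connectome fixtures


def simulate_fiber_atlas(
    contact_geometry: Mapping[str, np.ndarray],
    pair_counts: Mapping[tuple[int, int], int],
    seed: int = 0,
    n_decoys: int = 20,
    r_ecog: float = 5.0,
    r_stn: float = 3.0,
):
    """Build a streamline atlas with exact per-contact-pair connection counts.

    ``contact_geometry`` maps ``'cortex'`` and ``'stn'`` to (n, 3) MNI-mm
    coordinate arrays.  For each requested (cortex index, stn index) pair
    the atlas contains exactly that many streamlines passing within
    ``r_ecog`` of the cortex contact and ``r_stn`` of the STN contact
    (and qualifying for no other pair); decoy streamlines violate at
    least one radius for every pair.  Returns (FiberAtlas, ground-truth
    count dict).
    """
    from .connectome import ContactPair, FiberAtlas, count_connecting_fibers

    cortex = np.asarray(contact_geometry["cortex"], dtype=float)
    stn = np.asarray(contact_geometry["stn"], dtype=float)
    for (ci, sj), cnt in pair_counts.items():
        if cnt < 0:
            raise ValueError("pair counts must be >= 0")
        if ci >= len(cortex) or sj >= len(stn):
            raise ValueError(f"pair index {(ci, sj)} outside contact geometry")
    dists = np.linalg.norm(cortex[:, None, :] - stn[None, :, :], axis=-1)
    if np.any(dists < r_ecog + r_stn):
        raise ValueError(
            "cortex and STN contacts closer than the combined radii; decoy "
            "streamlines violating both radius tests cannot be constructed"
        )
    rng = np.random.default_rng(seed)
    streamlines: list[np.ndarray] = []

    def _qualifies(line: np.ndarray) -> set[tuple[int, int]]:
        hits = set()
        dc = np.linalg.norm(line[:, None, :] - cortex[None, :, :], axis=-1).min(axis=0)
        ds = np.linalg.norm(line[:, None, :] - stn[None, :, :], axis=-1).min(axis=0)
        for i in np.flatnonzero(dc <= r_ecog):
            for j in np.flatnonzero(ds <= r_stn):
                hits.add((int(i), int(j)))
        return hits

    for (ci, sj), cnt in sorted(pair_counts.items()):
        made = 0
        attempts = 0
        while made < cnt:
            attempts += 1
            if attempts > 500 * max(cnt, 1):
                raise RuntimeError(f"could not satisfy pair {(ci, sj)} geometrically")
            a = cortex[ci] + _random_in_ball(rng, 0.8 * r_ecog)
            b = stn[sj] + _random_in_ball(rng, 0.8 * r_stn)
            n_pts = int(rng.integers(3, 8))
            ts = np.linspace(0, 1, n_pts)[:, None]
            line = a[None, :] * (1 - ts) + b[None, :] * ts
            line[1:-1] += rng.normal(0, 0.5, size=line[1:-1].shape)
            if _qualifies(line) == {(ci, sj)}:
                streamlines.append(line)
                made += 1
    made_decoys = 0
    attempts = 0
    while made_decoys < n_decoys:
        attempts += 1
        if attempts > 200 * max(n_decoys, 1):
            break
        center = stn.mean(axis=0) + rng.uniform(-60, 60, size=3)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        ts = np.linspace(-20, 20, int(rng.integers(3, 9)))[:, None]
        line = center[None, :] + ts * direction[None, :]
        if not _qualifies(line):
            streamlines.append(line)
            made_decoys += 1
    # one boundary decoy: nearest vertex exactly 0.1 mm outside the cortex radius
    direction = np.array([0.0, 0.0, 1.0])
    base = cortex[0] + np.array([r_ecog + 0.1, 0.0, 0.0])
    line = base[None, :] + np.linspace(-5, 5, 5)[:, None] * direction[None, :]
    # push the line's closest approach to exactly r_ecog + 0.1 in x only
    if not _qualifies(line):
        streamlines.append(line)
    order = rng.permutation(len(streamlines))
    atlas = FiberAtlas(streamlines=[streamlines[i] for i in order])
    truth = {}
    for ci in range(len(cortex)):
        for sj in range(len(stn)):
            pair = ContactPair(ecog_xyz=tuple(cortex[ci]), stn_xyz=tuple(stn[sj]),
                               r_ecog=r_ecog, r_stn=r_stn)
            truth[(ci, sj)] = count_connecting_fibers(atlas, pair)
    for key, cnt in pair_counts.items():
        if truth[key] != cnt:  # pragma: no cover - construction is self-checked
            raise RuntimeError(f"fixture self-check failed for pair {key}")
    return atlas, truth


def _random_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    return v * radius * rng.uniform(0, 1) ** (1 / 3)


def simulate_functional_volume(
    seed_xyz: tuple[float, float, float],
    parcel_center_xyz: tuple[float, float, float],
    shape: tuple[int, int, int] = (16, 16, 16),
    n_timepoints: int = 200,
    voxel_size: float = 4.0,
    parcel_radius: float = 8.0,
    coupling: float = 0.8,
    seed: int = 0,
):
    """Synthesise a 4D functional volume with a planted seed-parcel correlation.

    Voxels within 5 mm of ``seed_xyz`` share a common time course; voxels
    of a spherical "parcel" around ``parcel_center_xyz`` carry that time
    course scaled by ``coupling`` plus independent noise.  Returns
    (nibabel image, parcel boolean mask, ground truth dict).
    """
    import nibabel as nib

    rng = np.random.default_rng(seed)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    # centre the field of view midway between seed and parcel
    center = (np.asarray(seed_xyz, dtype=float) + np.asarray(parcel_center_xyz)) / 2.0
    affine[:3, 3] = center - voxel_size * (np.asarray(shape) - 1) / 2.0
    half_extent = voxel_size * (np.asarray(shape) - 1) / 2.0
    if np.any(np.abs(np.asarray(seed_xyz) - center) > half_extent) or np.any(
            np.abs(np.asarray(parcel_center_xyz) - center) > half_extent):
        raise ValueError("seed and parcel centres do not fit in the volume; "
                         "increase shape or voxel_size")
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    mm = nib.affines.apply_affine(affine, vox)
    data = rng.standard_normal((vox.shape[0], n_timepoints))
    ts = rng.standard_normal(n_timepoints)
    d_seed = np.linalg.norm(mm - np.asarray(seed_xyz), axis=1)
    d_parcel = np.linalg.norm(mm - np.asarray(parcel_center_xyz), axis=1)
    in_seed = d_seed <= 5.0
    in_parcel = d_parcel <= parcel_radius
    data[in_seed] = ts[None, :] + 0.05 * data[in_seed]
    data[in_parcel] = coupling * ts[None, :] + np.sqrt(1 - coupling**2) * data[in_parcel]
    vol = data.reshape(*shape, n_timepoints)
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    parcel_mask = in_parcel.reshape(shape)
    truth = {"coupling": coupling, "n_seed_voxels": int(in_seed.sum()),
             "n_parcel_voxels": int(in_parcel.sum())}
    return img, parcel_mask, truth


# ---------------------------------------------------------------------------
# cohort tables for mixed-effects recovery


def simulate_lme_cohort(
    n_subjects: int = 18,
    n_obs_per_subject: int = 10,
    true_betas: Sequence[float] = (1.0, 4.0, 0.5),
    random_intercept_sd: float = 1.0,
    residual_sd: float = 1.0,
    seed: int = 0,
):
    """Observation table for ``response ~ pattern + medication + (1 | subject)``.

    ``true_betas`` are (intercept, beta_pattern, beta_medication).
    Medication alternates 0/1 within subject (paired off/on
    observations); the pattern predictor is standard normal.
    Returns (pandas DataFrame, GroundTruth-style dict).
    """
    import pandas as pd

    if n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    if random_intercept_sd < 0 or residual_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    b0, b_pat, b_med = true_betas
    rng = np.random.default_rng(seed)
    rows = []
    intercepts = rng.normal(0, random_intercept_sd, size=n_subjects)
    for s in range(n_subjects):
        pattern = rng.standard_normal(n_obs_per_subject)
        medication = np.arange(n_obs_per_subject) % 2
        eps = rng.normal(0, residual_sd, size=n_obs_per_subject)
        response = b0 + b_pat * pattern + b_med * medication + intercepts[s] + eps
        for o in range(n_obs_per_subject):
            rows.append((f"sub-{s + 1:02d}", pattern[o], int(medication[o]), response[o]))
    table = pd.DataFrame(rows, columns=["subject", "pattern", "medication", "response"])
    truth = {"betas": {"Intercept": b0, "pattern": b_pat, "medication": b_med},
             "random_intercept_sd": random_intercept_sd, "residual_sd": residual_sd}
    return table, truth
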