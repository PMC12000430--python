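"""End-to-end orchestration of the synthetic-cohort analysis.

``run_pipeline`` drives simulate -> preprocess -> power/SSD -> coupling
-> time delay -> statistics -> connectomics over a multi-subject,
multi-condition synthetic cohort, writing each stage's artifacts (TSV /
JSON / raw-binary recordings) under its own subdirectory plus a
manifest with SHA-256 hashes of every output, the resolved
configuration and the root seed, so any run is regenerable and
verifiable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import bids_io, bisdelay, connectome, coupling, permstats, preprocess, spectral, synth


class SimStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = 6
    conditions: list[str] = ["off", "levodopa"]
    sampling_rate: float = 4000.0
    duration: float = 180.0
    n_cortex_channels: int = 6
    n_stn_channels: int = 8
    source_band: tuple[float, float] = (12.0, 30.0)
    coupling_delay: float = 25.0
    coupling_gain: float = 0.8
    snr: float = 10.0
    line_noise_amplitude: float = 5.0
    nongaussianity: float = 1.0
    levodopa_gain_factor: float = 0.5
    dbs_gain_factor: float = 0.5
    dbs_frequency: float = 130.0
    dbs_pulse_width: float = 60.0
    dbs_amplitude: float = 200.0


class PreprocessStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    line_freq: float = 50.0
    bandpass: tuple[float, float] = (3.0, 150.0)
    epoch_duration: float = 2.0
    resample_rate: float = 500.0
    tde_rate: float = 1000.0
    z_thresh: float = 4.0


class PowerStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bandwidth: float = 5.0
    norm_range: tuple[float, float] = (5.0, 60.0)
    norm_exclusion: tuple[float, float] = (45.0, 55.0)
    ssd_bands: list[str] = ["low_beta", "high_beta"]
    flank_width: float = 1.0


class CouplingStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_segments: int = 200
    epochs_per_segment: int = 30
    bandwidth: float = 5.0
    gc_order: int = 60
    gc_band: tuple[float, float] = (3.0, 50.0)
    pattern_bands: list[str] = ["low_beta", "high_beta"]


class TdeStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_segments: int = 400
    epochs_per_segment: int = 30
    band: tuple[float, float] = (3.0, 100.0)
    ci_level: float = 80.0


class StatsStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = 100_000
    alpha: float = 0.05
    cluster_band: tuple[float, float] = (3.0, 50.0)


class ConnectomeStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r_ecog: float = 5.0
    r_stn: float = 3.0
    true_betas: tuple[float, float, float] = (1.0, 4.0, 0.5)
    random_intercept_sd: float = 1.0
    residual_sd: float = 1.0
    pattern_band: str = "low_beta"


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    stages: list[str] = ["simulate", "preprocess", "power", "coupling",
                         "tde", "stats", "connectome"]
    sim: SimStage = SimStage()
    preprocess: PreprocessStage = PreprocessStage()
    power: PowerStage = PowerStage()
    coupling: CouplingStage = CouplingStage()
    tde: TdeStage = TdeStage()
    stats: StatsStage = StatsStage()
    connectome: ConnectomeStage = ConnectomeStage()


def _derive_seed(*parts) -> int:
    h = hashlib.sha256(json.dumps(parts, sort_keys=True).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _subjects(cfg: PipelineConfig) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(cfg.sim.n_subjects)]


def _recording_bases(cfg: PipelineConfig, stage_dir: Path) -> dict:
    out = {}
    for sub in _subjects(cfg):
        for cond in cfg.sim.conditions:
            out[(sub, cond)] = stage_dir / f"{sub}_task-rest_acq-{cond}"
    return out


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    stage = out / "simulate"
    stage.mkdir(parents=True, exist_ok=True)
    s = cfg.sim
    truth_all = {}
    for si, sub in enumerate(_subjects(cfg)):
        for ci, cond in enumerate(s.conditions):
            gain = s.coupling_gain
            if cond == "levodopa":
                gain *= s.levodopa_gain_factor
            elif cond == "dbs":
                gain *= s.dbs_gain_factor
            sim_cfg = synth.SimConfig(
                sampling_rate=s.sampling_rate, duration=s.duration,
                n_cortex_channels=s.n_cortex_channels, n_stn_channels=s.n_stn_channels,
                source_band=tuple(s.source_band), coupling_delay=s.coupling_delay,
                coupling_gain=gain, snr=s.snr,
                line_noise_amplitude=s.line_noise_amplitude,
                nongaussianity=s.nongaussianity,
                seed=_derive_seed(cfg.seed, "simulate", si, ci),
            )
            sources = synth.simulate_sources(sim_cfg)
            rec, truth = synth.couple_and_mix(sources, sim_cfg, condition=cond,  # type: ignore[arg-type]
                                              subject_id=sub)
            if cond == "dbs":
                rec = synth.add_dbs_artifact(rec, s.dbs_frequency, s.dbs_pulse_width,
                                             s.dbs_amplitude,
                                             seed=_derive_seed(cfg.seed, "dbs", si, ci))
            bids_io.write_recording(rec, stage)
            truth_all[f"{sub}_{cond}"] = {
                "true_delay_ms": truth.true_delay,
                "true_direction": truth.true_direction,
                "coupling_gain": gain,
                "source_band": list(truth.source_band),
                "mixing_cortex": truth.mixing_cortex.ravel().tolist(),
                "mixing_stn": truth.mixing_stn.ravel().tolist(),
            }
    with open(stage / "ground_truth.json", "w") as fh:
        json.dump(truth_all, fh, indent=2, sort_keys=True)


def stage_preprocess(cfg: PipelineConfig, out: Path) -> None:
    stage = out / "preprocess"
    stage.mkdir(parents=True, exist_ok=True)
    report = {}
    for (sub, cond), base in _recording_bases(cfg, out / "simulate").items():
        rec = bids_io.read_recording(base)
        rec = preprocess.notch_filter(rec, cfg.preprocess.line_freq)
        rec = preprocess.bandpass_filter(rec, *cfg.preprocess.bandpass)
        entry = {}
        if rec.condition == "dbs":
            rec = preprocess.parrm_remove(rec, cfg.sim.dbs_frequency)
            entry["parrm_period_samples"] = rec.meta.get("parrm_period_samples")
        bids_io.write_recording(rec, stage)
        report[f"{sub}_{cond}"] = entry
    with open(stage / "preprocess_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def _clean_epochs(cfg: PipelineConfig, out: Path, sub: str, cond: str,
                  rate: float, bipolar: bool) -> preprocess.Epochs:
    base = (out / "preprocess") / f"{sub}_task-rest_acq-{cond}"
    rec = bids_io.read_recording(base)
    if bipolar:
        rec = preprocess.bipolar_reference(rec)
    ep = preprocess.make_epochs(rec, cfg.preprocess.epoch_duration)
    ep = preprocess.resample(ep, rate)
    ep, _ = preprocess.reject_artifact_epochs(ep, cfg.preprocess.z_thresh)
    return ep


def stage_power(cfg: PipelineConfig, out: Path) -> None:
    stage = out / "power"
    stage.mkdir(parents=True, exist_ok=True)
    spec_rows, band_rows, ssd_rows = [], [], []
    for sub in _subjects(cfg):
        for cond in cfg.sim.conditions:
            ep = _clean_epochs(cfg, out, sub, cond, cfg.preprocess.resample_rate, bipolar=True)
            psd = spectral.multitaper_psd(ep, cfg.power.bandwidth)
            norm = spectral.normalize_percent_total(psd, tuple(cfg.power.norm_range),
                                                    tuple(cfg.power.norm_exclusion))
            for c, name in enumerate(ep.channel_names):
                for f, v in zip(norm.freqs, norm.values[c]):
                    if f <= 100.0:
                        spec_rows.append((sub, cond, name, f, v))
            for bname, band in spectral.BANDS.items():
                if band.hi <= norm.freqs[-1]:
                    vals = spectral.band_average(norm, band)
                    for c, name in enumerate(ep.channel_names):
                        band_rows.append((sub, cond, name, bname, vals[c]))
            for site in ("cortex", "stn"):
                idx = [i for i, c in enumerate(ep.channel_info) if c.site == site]
                site_ep = preprocess.Epochs(
                    data=ep.data[:, idx], sampling_rate=ep.sampling_rate,
                    epoch_duration=ep.epoch_duration,
                    channel_info=[ep.channel_info[i] for i in idx],
                    kept_mask=ep.kept_mask.copy())
                n_comp = min(spectral.N_COMPONENTS[(site, "bipolar")], len(idx))
                red, proj = spectral.reduce_rank(site_ep, site, "bipolar",
                                                 n_components=n_comp)
                for bname in cfg.power.ssd_bands:
                    model = spectral.ssd_fit(red, spectral.BANDS[bname],
                                             cfg.power.flank_width, cfg.power.bandwidth)
                    sensor = np.abs(proj @ model.patterns[:, 0])
                    z = (sensor - sensor.mean()) / sensor.std()
                    for i, ci in enumerate(idx):
                        info = ep.channel_info[ci]
                        ssd_rows.append((sub, cond, site, bname, info.name,
                                         *info.mni_xyz, z[i],
                                         model.snr_eigenvalues[0]))
    pd.DataFrame(spec_rows, columns=["subject", "condition", "channel", "frequency",
                                     "pct_power"]).to_csv(
        stage / "spectra.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(band_rows, columns=["subject", "condition", "channel", "band",
                                     "pct_power"]).to_csv(
        stage / "band_averages.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(ssd_rows, columns=["subject", "condition", "site", "band", "channel",
                                    "x", "y", "z", "pattern_z", "snr_eigenvalue"]).to_csv(
        stage / "ssd_patterns.tsv", sep="\t", index=False, float_format="%.10g")


def stage_coupling(cfg: PipelineConfig, out: Path) -> None:
    stage = out / "coupling"
    stage.mkdir(parents=True, exist_ok=True)
    cc = cfg.coupling
    spec_rows, pat_rows = [], []
    for si, sub in enumerate(_subjects(cfg)):
        for ci, cond in enumerate(cfg.sim.conditions):
            ep = _clean_epochs(cfg, out, sub, cond, cfg.preprocess.resample_rate,
                               bipolar=False)
            segs = preprocess.bootstrap_segments(
                ep, cc.n_segments, cc.epochs_per_segment,
                seed=_derive_seed(cfg.seed, "coupling", si, ci))
            cortex = [i for i, c in enumerate(ep.channel_info) if c.site == "cortex"]
            stn = [i for i, c in enumerate(ep.channel_info) if c.site == "stn"]
            # bivariate ImCoh on the unipolar channels
            csds = coupling.bootstrap_csds(ep, segs, cc.bandwidth)
            imcoh = coupling.average_segments(
                [coupling.imcoh_grand_average(c, cortex, stn) for c in csds])
            # multivariate measures on rank-normalised components
            sub_eps, projs = {}, {}
            for site, idx in (("cortex", cortex), ("stn", stn)):
                site_ep = preprocess.Epochs(
                    data=ep.data[:, idx], sampling_rate=ep.sampling_rate,
                    epoch_duration=ep.epoch_duration,
                    channel_info=[ep.channel_info[i] for i in idx],
                    kept_mask=ep.kept_mask.copy())
                n_comp = min(spectral.N_COMPONENTS[(site, "unipolar")], len(idx))
                sub_eps[site], projs[site] = spectral.reduce_rank(
                    site_ep, site, "unipolar", n_components=n_comp)
            joint = preprocess.Epochs(
                data=np.concatenate([sub_eps["cortex"].data, sub_eps["stn"].data], axis=1),
                sampling_rate=ep.sampling_rate, epoch_duration=ep.epoch_duration,
                channel_info=sub_eps["cortex"].channel_info + sub_eps["stn"].channel_info,
                kept_mask=ep.kept_mask.copy())
            n_seed = sub_eps["cortex"].data.shape[1]
            n_targ = sub_eps["stn"].data.shape[1]
            seed_idx = list(range(n_seed))
            targ_idx = list(range(n_seed, n_seed + n_targ))
            jcsds = coupling.bootstrap_csds(joint, segs, cc.bandwidth)
            mic_avg = coupling.average_segments(
                [coupling.mic(c, seed_idx, targ_idx,
                              seed_projection=projs["cortex"],
                              target_projection=projs["stn"]) for c in jcsds])
            trgc_avg = coupling.average_segments(
                [coupling.trgc(c, seed_idx, targ_idx, cc.gc_order, tuple(cc.gc_band))
                 for c in jcsds])
            for spec in (imcoh, mic_avg, trgc_avg):
                for f, v in zip(spec.freqs, spec.values):
                    if f <= 100.0:
                        spec_rows.append((sub, cond, spec.method, f, v))
            for bname in cc.pattern_bands:
                band = spectral.BANDS[bname]
                fmask = (mic_avg.freqs >= band.lo) & (mic_avg.freqs <= band.hi)
                for site, idx, pats in (("cortex", cortex, mic_avg.seed_patterns_z),
                                        ("stn", stn, mic_avg.target_patterns_z)):
                    band_pat = pats[:, fmask].mean(axis=1)
                    for k, chi in enumerate(idx):
                        info = ep.channel_info[chi]
                        pat_rows.append((sub, cond, site, bname, info.name,
                                         *info.mni_xyz, band_pat[k]))
    pd.DataFrame(spec_rows, columns=["subject", "condition", "method", "frequency",
                                     "value"]).to_csv(
        stage / "coupling_spectra.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(pat_rows, columns=["subject", "condition", "site", "band", "channel",
                                    "x", "y", "z", "pattern_z"]).to_csv(
        stage / "mic_patterns.tsv", sep="\t", index=False, float_format="%.10g")


def stage_tde(cfg: PipelineConfig, out: Path) -> None:
    stage = out / "tde"
    stage.mkdir(parents=True, exist_ok=True)
    delay_rows, peak_rows, strength_rows = [], [], []
    for si, sub in enumerate(_subjects(cfg)):
        for ci, cond in enumerate(cfg.sim.conditions):
            ep = _clean_epochs(cfg, out, sub, cond, cfg.preprocess.tde_rate, bipolar=True)
            segs = preprocess.bootstrap_segments(
                ep, cfg.tde.n_segments, cfg.tde.epochs_per_segment,
                seed=_derive_seed(cfg.seed, "tde", si, ci))
            seed_name = next(c.name for c in ep.channel_info if c.site == "cortex")
            targ_name = next(c.name for c in ep.channel_info if c.site == "stn")
            coeffs, freqs = bisdelay.fourier_coefficients(
                ep, picks=[seed_name, targ_name],
                expected_rate=cfg.preprocess.tde_rate)
            est = bisdelay.bootstrap_delay(coeffs[:, 0], coeffs[:, 1], freqs, segs,
                                           tuple(cfg.tde.band), cfg.tde.ci_level,
                                           sampling_rate=cfg.preprocess.tde_rate)
            est = bisdelay.peak_binning(est)
            delay_rows.append((sub, cond, seed_name, targ_name, est.tau,
                               est.meta["strength_peak_ms"], est.ci80[0], est.ci80[1],
                               int(bool(est.valid))))
            if est.bin_percentages:
                for label, pct in est.bin_percentages.items():
                    peak_rows.append((sub, cond, label, pct))
            for lag, s in zip(est.lags, est.strength):
                if abs(lag) <= 100:
                    strength_rows.append((sub, cond, lag, s))
    pd.DataFrame(delay_rows, columns=["subject", "condition", "seed_channel",
                                      "target_channel", "tau_ms", "strength_peak_ms",
                                      "ci_lo_ms", "ci_hi_ms", "valid"]).to_csv(
        stage / "delays.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(peak_rows, columns=["subject", "condition", "bin_ms",
                                     "percentage"]).to_csv(
        stage / "peak_bins.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(strength_rows, columns=["subject", "condition", "lag_ms",
                                         "strength"]).to_csv(
        stage / "strength_functions.tsv", sep="\t", index=False, float_format="%.10g")


def stage_stats(cfg: PipelineConfig, out: Path) -> None:
    stage = out / "stats"
    stage.mkdir(parents=True, exist_ok=True)
    conds = cfg.sim.conditions
    if len(conds) < 2:
        return
    cond_a, cond_b = conds[0], conds[1]
    rows = []
    band_df = pd.read_csv(out / "power" / "band_averages.tsv", sep="\t")
    stn_beta = band_df[band_df["channel"].str.startswith("LFP")]
    for bname in ("low_beta", "high_beta"):
        sub_means = (stn_beta[stn_beta["band"] == bname]
                     .groupby(["subject", "condition"])["pct_power"].mean().unstack())
        res = permstats.paired_permutation(
            sub_means[cond_a].to_numpy(), sub_means[cond_b].to_numpy(),
            n_perm=cfg.stats.n_perm, alpha=cfg.stats.alpha,
            seed=_derive_seed(cfg.seed, "stats", bname))
        rows.append(("stn_pct_power", bname, res.observed_stat, res.p_value,
                     res.n_permutations, "none"))
    cpl = pd.read_csv(out / "coupling" / "coupling_spectra.tsv", sep="\t")
    lo, hi = cfg.stats.cluster_band
    for method in ("imcoh", "mic", "trgc"):
        dfm = cpl[(cpl["method"] == method) & (cpl["frequency"] >= lo)
                  & (cpl["frequency"] <= hi)]
        wide = dfm.pivot_table(index=["subject", "condition"], columns="frequency",
                               values="value")
        a = wide.xs(cond_a, level="condition").to_numpy()
        b = wide.xs(cond_b, level="condition").to_numpy()
        res = permstats.cluster_permutation(
            a, b, n_perm=cfg.stats.n_perm, alpha=cfg.stats.alpha,
            seed=_derive_seed(cfg.seed, "stats", method))
        freqs = wide.columns.to_numpy()
        if res.clusters:
            for cl in res.clusters:
                rows.append((f"{method}_spectrum",
                             f"{freqs[cl.start]:g}-{freqs[cl.stop]:g}Hz",
                             cl.mass, cl.p_value, res.n_permutations, "cluster"))
        else:
            rows.append((f"{method}_spectrum", f"{lo:g}-{hi:g}Hz", 0.0, 1.0,
                         res.n_permutations, "cluster"))
    pd.DataFrame(rows, columns=["measure", "band_or_range", "observed", "p_value",
                                "n_permutations", "correction"]).to_csv(
        stage / "contrasts.tsv", sep="\t", index=False, float_format="%.10g")


def stage_connectome(cfg: PipelineConfig, out: Path) -> None:
    stage = out / "connectome"
    stage.mkdir(parents=True, exist_ok=True)
    cn = cfg.connectome
    pats = pd.read_csv(out / "coupling" / "mic_patterns.tsv", sep="\t")
    pats = pats[(pats["band"] == cn.pattern_band) & (pats["site"] == "cortex")]
    conds = [c for c in cfg.sim.conditions if c in ("off", "levodopa")]
    # structural fixture: exact streamline counts around the first subject's contacts
    cortex_xyz = (pats[["channel", "x", "y", "z"]].drop_duplicates("channel")
                  .sort_values("channel")[["x", "y", "z"]].to_numpy())
    stn_xyz = np.array([[-12.0, -13.0, -7.0 + 1.5 * j]
                        for j in range(cfg.sim.n_stn_channels)])
    rng = np.random.default_rng(_derive_seed(cfg.seed, "connectome", "fibers"))
    pair_counts = {(int(i), 0): int(rng.integers(0, 9)) for i in range(len(cortex_xyz))}
    atlas, fiber_truth = synth.simulate_fiber_atlas(
        {"cortex": cortex_xyz, "stn": stn_xyz[:1]}, pair_counts,
        seed=_derive_seed(cfg.seed, "connectome", "atlas"),
        r_ecog=cn.r_ecog, r_stn=cn.r_stn)
    bids_io.write_streamlines_tsv(atlas, stage / "streamlines.tsv")
    fiber_rows = [(i, j, pair_counts.get((i, j), 0), cnt)
                  for (i, j), cnt in sorted(fiber_truth.items())]
    pd.DataFrame(fiber_rows, columns=["cortex_contact", "stn_contact",
                                      "requested", "counted"]).to_csv(
        stage / "fiber_counts.tsv", sep="\t", index=False)
    # functional fixture: seed map + indirect-pathway parcel mean
    seed_xyz = tuple(cortex_xyz[0])
    parcel_center = tuple(np.asarray(seed_xyz) + np.array([18.0, 12.0, -15.0]))
    img, parcel_mask, f_truth = synth.simulate_functional_volume(
        seed_xyz, parcel_center_xyz=parcel_center,
        seed=_derive_seed(cfg.seed, "connectome", "fmri"))
    cmap = connectome.seed_correlation_map(img, seed_xyz, r=cn.r_ecog)
    pm = connectome.parcel_mean(cmap, parcel_mask)
    with open(stage / "fmri_summary.json", "w") as fh:
        json.dump({"seed_xyz": list(seed_xyz), "parcel_mean_r": pm,
                   "planted_coupling": f_truth["coupling"]}, fh, indent=2, sort_keys=True)
    # mixed-effects linkage: known-coefficient response against measured patterns
    b0, b_pat, b_med = cn.true_betas
    rng = np.random.default_rng(_derive_seed(cfg.seed, "connectome", "lme"))
    rows = []
    for si, sub in enumerate(_subjects(cfg)):
        u = rng.normal(0, cn.random_intercept_sd)
        for cond in conds:
            med = 1 if cond == "levodopa" else 0
            sel = pats[(pats["subject"] == sub) & (pats["condition"] == cond)]
            for _, r in sel.iterrows():
                resp = (b0 + b_pat * r["pattern_z"] + b_med * med + u
                        + rng.normal(0, cn.residual_sd))
                rows.append((sub, cond, r["channel"], r["pattern_z"], med, resp))
    table = pd.DataFrame(rows, columns=["subject", "condition", "channel",
                                        "pattern", "medication", "response"])
    table.to_csv(stage / "lme_table.tsv", sep="\t", index=False, float_format="%.10g")
    result = connectome.lme_fit(table)
    reduced = connectome.lme_fit(table, fixed_effects=("medication",))
    summary = {
        "full_model": {
            "fixed_effects": result.fixed_effects,
            "conditional_r2": result.conditional_r2,
            "bic": result.bic,
            "fit_quality_r": result.fit_quality_r,
        },
        "no_pattern_model_bic": reduced.bic,
        "true_betas": {"Intercept": b0, "pattern": b_pat, "medication": b_med},
        "bic_prefers_full": bool(result.bic < reduced.bic),
    }
    with open(stage / "lme_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "power": stage_power,
    "coupling": stage_coupling,
    "tde": stage_tde,
    "stats": stage_stats,
    "connectome": stage_connectome,
}


def run_pipeline(config: PipelineConfig | dict, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Run the configured stages and write a hash manifest; returns out_dir."""
    if isinstance(config, dict):
        config = PipelineConfig(**config)
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in config.stages:
        if name not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {name!r}")
        try:
            _STAGE_FUNCS[name](config, out)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    with open(out / "config_resolved.json", "w") as fh:
        json.dump(config.model_dump(), fh, indent=2, sort_keys=True, default=str)
    manifest = {"seed": config.seed, "stages": config.stages, "files": {}}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest["files"][str(path.relative_to(out))] = digest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
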