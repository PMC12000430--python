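"""Recording I/O in a BIDS-iEEG-style layout.

A recording is stored as a raw binary data file plus a JSON sidecar
(sampling rate, dtype, shape) together with ``*_channels.tsv`` (name,
site, montage, region, status) and ``*_electrodes.tsv`` (name, x, y, z
in MNI mm).  File naming follows BIDS roles (``*_ieeg.bin``,
``*_channels.tsv``, ``*_electrodes.tsv``); full BIDS validation is out
of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ChannelInfo, Recording


def _base_name(recording: Recording) -> str:
    return f"{recording.subject_id}_task-rest_acq-{recording.condition}"


def write_recording(recording: Recording, out_dir: str | Path,
                    dtype: str = "float64") -> Path:
    """Write data, sidecar, channels and electrodes files; returns the base path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = out_dir / _base_name(recording)
    data = np.ascontiguousarray(recording.data.astype(dtype))
    data.tofile(f"{base}_ieeg.bin")
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "dtype": dtype,
        "byte_order": "little",
        "order": "C",
        "condition": recording.condition,
        "subject_id": recording.subject_id,
        "meta": {k: v for k, v in recording.meta.items()
                 if isinstance(v, (int, float, str, bool))},
    }
    with open(f"{base}_ieeg.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    rows = []
    for c in recording.channel_info:
        rows.append({
            "name": c.name, "site": c.site, "montage": c.montage,
            "region": c.region, "is_stim_contact": int(c.is_stim_contact),
            "constituents": "|".join(c.constituents) if c.constituents else "n/a",
        })
    pd.DataFrame(rows).to_csv(f"{base}_channels.tsv", sep="\t", index=False)
    el = [{"name": c.name, "x": c.mni_xyz[0], "y": c.mni_xyz[1], "z": c.mni_xyz[2]}
          for c in recording.channel_info]
    pd.DataFrame(el).to_csv(f"{base}_electrodes.tsv", sep="\t", index=False,
                            float_format="%.6g")
    return base


def read_recording(base: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``base`` is the path prefix (without the ``_ieeg.*`` suffix) or a
    directory containing exactly one recording.  Channel metadata is
    joined to data rows by order, electrode coordinates by channel name;
    mismatches are fatal.
    """
    base = Path(base)
    if base.is_dir():
        sidecars = sorted(base.glob("*_ieeg.json"))
        if len(sidecars) != 1:
            raise ValueError(f"{base} contains {len(sidecars)} recordings; pass a base path")
        base = Path(str(sidecars[0])[: -len("_ieeg.json")])
    with open(f"{base}_ieeg.json") as fh:
        sidecar = json.load(fh)
    data = np.fromfile(f"{base}_ieeg.bin", dtype=sidecar["dtype"])
    n_ch, n_s = sidecar["n_channels"], sidecar["n_samples"]
    if data.size != n_ch * n_s:
        raise ValueError(f"data file holds {data.size} values, sidecar says {n_ch}x{n_s}")
    data = data.reshape(n_ch, n_s)
    channels = pd.read_csv(f"{base}_channels.tsv", sep="\t")
    if len(channels) != n_ch:
        raise ValueError(f"channels.tsv has {len(channels)} rows but data has {n_ch} rows")
    electrodes = pd.read_csv(f"{base}_electrodes.tsv", sep="\t").set_index("name")
    info = []
    for _, row in channels.iterrows():
        name = str(row["name"])
        if name not in electrodes.index:
            raise ValueError(f"channel {name!r} missing from electrodes table")
        xyz = tuple(float(electrodes.loc[name, ax]) for ax in ("x", "y", "z"))
        constituents = None
        if isinstance(row.get("constituents"), str) and row["constituents"] != "n/a":
            parts = row["constituents"].split("|")
            constituents = (parts[0], parts[1])
        info.append(ChannelInfo(
            name=name, site=row["site"], montage=row["montage"],
            region=row["region"], mni_xyz=xyz,
            is_stim_contact=bool(row["is_stim_contact"]),
            constituents=constituents,
        ))
    return Recording(data=data, sampling_rate=float(sidecar["sampling_rate"]),
                     channel_info=info, condition=sidecar["condition"],
                     subject_id=sidecar["subject_id"],
                     meta=dict(sidecar.get("meta", {})))


def write_streamlines_tsv(atlas, path: str | Path) -> None:
    """Write streamlines in the TSV polyline dialect.

    Columns: streamline_id, point_index, x, y, z (MNI mm).
    """
    rows = []
    for sid, line in enumerate(atlas.streamlines):
        for pi, (x, y, z) in enumerate(line):
            rows.append((sid, pi, x, y, z))
    pd.DataFrame(rows, columns=["streamline_id", "point_index", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_streamlines_tsv(path: str | Path):
    """Read a TSV polyline file back into a FiberAtlas."""
    from .connectome import FiberAtlas

    df = pd.read_csv(path, sep="\t")
    lines = []
    for _, grp in df.groupby("streamline_id", sort=True):
        grp = grp.sort_values("point_index")
        lines.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
    return FiberAtlas(streamlines=lines)
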