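"""Readers/writers: the portable trial container, GDF ingestion, text tables
and topographic export.

The internal container is a NumPy ``.npz`` archive per subject holding the
trial tensor, labels, sample rate and montage (schema documented in
:data:`CONTAINER_SCHEMA`); it round-trips ``EEGTrialSet`` losslessly.
Figures are decorative; the per-channel numbers behind every topomap are
always written as delimited text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import EEGTrialSet, TFDynamics
from .montage import Montage, get_montage

__all__ = [
    "save_trialset", "load_trialset", "save_truth", "load_truth",
    "save_dynamics", "load_dynamics", "topomap_export", "read_gdf",
]

CONTAINER_SCHEMA = {
    "data": "(n_trials, n_channels, n_samples) float64, microvolts",
    "labels": "(n_trials,) unicode class labels",
    "sample_rate": "scalar float, Hz",
    "channels": "(n_channels,) unicode channel names",
    "positions": "(n_channels, 2) float schematic scalp coordinates",
    "montage_name": "scalar unicode",
    "subject_id": "scalar unicode",
}


def save_trialset(trials: EEGTrialSet, path: str | Path) -> Path:
    """Write an EEGTrialSet to the internal .npz container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path, data=trials.data, labels=trials.labels.astype(str),
        sample_rate=np.float64(trials.sample_rate),
        channels=np.asarray(trials.montage.channels),
        positions=trials.montage.positions,
        montage_name=trials.montage.name,
        subject_id=trials.subject_id,
    )
    return path


def load_trialset(path: str | Path) -> EEGTrialSet:
    with np.load(path, allow_pickle=False) as z:
        mont = Montage(str(z["montage_name"]), tuple(z["channels"].tolist()),
                       z["positions"])
        return EEGTrialSet(data=z["data"], labels=z["labels"],
                           sample_rate=float(z["sample_rate"]),
                           montage=mont, subject_id=str(z["subject_id"]))


def save_truth(truth, path: str | Path) -> Path:
    """Flat key-value JSON sidecar for planted ground truth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "erd_map": truth.erd_map,
        "wpli_map": truth.wpli_map,
        "discriminative_channels": sorted(truth.discriminative_channels),
        "subject_gains": truth.subject_gains,
    }
    path.write_text(json.dumps(payload, indent=1, default=list))
    return path


def load_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_dynamics(theta: TFDynamics, out_dir: str | Path, stem: str) -> list[Path]:
    """Write theta grids as delimited text, one (band x position) matrix per
    (label, channel) would be huge; instead one file per label with long-format
    columns (band_lo, band_hi, position, channel, value), 9 significant digits."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for lab in theta.labels:
        name = f"{stem}_{lab if lab is not None else 'merged'}.tsv"
        p = out_dir / name
        arr = theta.values[lab]
        with p.open("w") as fh:
            fh.write("band_lo\tband_hi\tposition\tchannel\tvalue\n")
            for fi, (lo, hi) in enumerate(theta.bands):
                for wi, pos in enumerate(theta.positions):
                    for ci, ch in enumerate(theta.channels):
                        fh.write(f"{lo:g}\t{hi:g}\t{pos:.9g}\t{ch}\t"
                                 f"{arr[fi, wi, ci]:.9g}\n")
        written.append(p)
    return written


def load_dynamics(paths: list[str | Path]) -> TFDynamics:
    """Rebuild a TFDynamics from save_dynamics output (one file per label)."""
    import pandas as pd
    values = {}
    bands = positions = channels = None
    for p in paths:
        p = Path(p)
        lab = p.stem.rsplit("_", 1)[-1]
        lab = None if lab == "merged" else lab
        df = pd.read_csv(p, sep="\t")
        bands = [tuple(b) for b in
                 df[["band_lo", "band_hi"]].drop_duplicates().to_numpy()]
        positions = np.sort(df["position"].unique())
        channels = tuple(dict.fromkeys(df["channel"]))
        arr = df["value"].to_numpy().reshape(len(bands), len(positions),
                                             len(channels))
        values[lab] = arr
    return TFDynamics(values=values, bands=bands, positions=positions,
                      channels=channels)


def topomap_export(theta_cell: np.ndarray, montage: Montage,
                   out_path: str | Path, title: str = "") -> tuple[Path, Path]:
    """Interpolated scalp map (PNG) plus the exact per-channel values (TSV).

    ``theta_cell`` is one per-channel vector; unknown lengths are rejected.
    """
    theta_cell = np.asarray(theta_cell, float).ravel()
    if len(theta_cell) != montage.n_channels:
        raise ValueError(f"theta has {len(theta_cell)} values but montage "
                         f"{montage.name!r} has {montage.n_channels} channels")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    tsv = out_path.with_suffix(".tsv")
    with tsv.open("w") as fh:
        fh.write("channel\tx\ty\tvalue\n")
        for ch, (x, y), v in zip(montage.channels, montage.positions, theta_cell):
            fh.write(f"{ch}\t{x:g}\t{y:g}\t{v:.9g}\n")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata
    pos = montage.positions
    pad = 0.5
    xi = np.linspace(pos[:, 0].min() - pad, pos[:, 0].max() + pad, 100)
    yi = np.linspace(pos[:, 1].min() - pad, pos[:, 1].max() + pad, 100)
    XI, YI = np.meshgrid(xi, yi)
    ZI = griddata(pos, theta_cell, (XI, YI), method="cubic")
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.contourf(XI, YI, ZI, levels=20, cmap="RdBu_r")
    ax.scatter(pos[:, 0], pos[:, 1], c="k", s=8)
    for ch, (x, y) in zip(montage.channels, pos):
        ax.annotate(ch, (x, y), fontsize=6, ha="center", va="bottom")
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path, tsv


# Cue event codes of the left/right-hand motor-imagery paradigm (GDF event
# table): 769 = left-hand cue, 770 = right-hand cue; 1023 marks a rejected
# (artifact) trial.
GDF_EVENT_LABELS = {"769": "left", "770": "right"}
GDF_ARTIFACT_CODE = "1023"


def read_gdf(path: str | Path, trial_span: float = 7.0,
             montage_name: str | None = None) -> EEGTrialSet:
    """Epoch a GDF (or EDF/EDF+) recording into [0, trial_span] s labeled trials.

    Uses the left/right cue annotations; trials flagged with the artifact
    code are dropped. EOG channels are excluded. Requires a recording whose
    annotations contain the cue codes; otherwise raises with the missing
    codes listed.
    """
    import mne
    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    picks = [ch for ch in raw.ch_names if "EOG" not in ch.upper()]
    raw.pick(picks)
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    present = set(event_id)
    wanted = {c for c in GDF_EVENT_LABELS if c in present}
    if not wanted:
        raise ValueError(f"no cue events found; missing codes "
                         f"{sorted(set(GDF_EVENT_LABELS) - present)}")
    fs = raw.info["sfreq"]
    n_samp = int(round(trial_span * fs)) + 1
    bad_onsets = {events[i, 0] for i in range(len(events))
                  if events[i, 2] == event_id.get(GDF_ARTIFACT_CODE, -1)}
    data_rows, labels = [], []
    sig = raw.get_data() * 1e6  # volts -> microvolts
    for onset, _, code in events:
        lab = next((GDF_EVENT_LABELS[c] for c in wanted
                    if event_id[c] == code), None)
        if lab is None or onset in bad_onsets:
            continue
        # epoch from 2 s before the cue (trial start) per the paradigm timing
        start = onset - int(round(2.0 * fs))
        if start < 0 or start + n_samp > sig.shape[1]:
            continue
        data_rows.append(sig[:, start:start + n_samp])
        labels.append(lab)
    if not data_rows:
        raise ValueError("recording contains zero usable labeled trials")
    data = np.stack(data_rows)
    if montage_name is None:
        montage_name = "mi22" if data.shape[1] == 22 else "grid"
    mont = get_montage(montage_name, data.shape[1])
    return EEGTrialSet(data=data, labels=np.asarray(labels), sample_rate=fs,
                       montage=mont, subject_id=path.stem)
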