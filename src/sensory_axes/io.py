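"""Readers and writers for the plain-text interchange formats.

* responses CSV: one row per participant, `participant_id`, `item_001`..`item_060`;
* item map CSV: `item_id`, `quadrant`;
* personality responses CSV: `participant_id`, `epq_01`..`epq_24`;
* personality map CSV: `item_id`, `scale`, `reverse`;
* normative table: YAML mapping quadrant -> {mean, sd};
* EEG: BDF/EDF through mne when available, or a CSV fallback (wide, one
  column per channel, `# sample_rate=<Hz>` header line) plus an event
  table CSV (`sample`, `kind`, `pair_id`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .epq import EPQItemMap
from .profile import ItemMap, NormativeTable, ResponseSet
from .serp import EventMarker, Recording

PathLike = Union[str, Path]


# -- questionnaire formats -------------------------------------------------

def read_item_map(path: PathLike) -> ItemMap:
    df = pd.read_csv(path, dtype=str)
    return ItemMap(dict(zip(df["item_id"], df["quadrant"])))


def write_item_map(item_map: ItemMap, path: PathLike) -> None:
    pd.DataFrame(
        {"item_id": list(item_map.entries), "quadrant": list(item_map.entries.values())}
    ).to_csv(path, index=False)


def read_responses(path: PathLike) -> List[ResponseSet]:
    df = pd.read_csv(path)
    items = [c for c in df.columns if c != "participant_id"]
    out = []
    for _, row in df.iterrows():
        out.append(
            ResponseSet(
                participant_id=str(row["participant_id"]),
                ratings={i: int(row[i]) for i in items},
            )
        )
    return out


def write_responses(responses: List[ResponseSet], path: PathLike) -> None:
    items = list(responses[0].ratings)
    rows = [{"participant_id": r.participant_id, **{i: r.ratings[i] for i in items}}
            for r in responses]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_epq_map(path: PathLike) -> EPQItemMap:
    df = pd.read_csv(path)
    entries = dict(zip(df["item_id"].astype(str), df["scale"].astype(str)))
    reverse = frozenset(df.loc[df["reverse"].astype(bool), "item_id"].astype(str))
    return EPQItemMap(entries=entries, reverse_items=reverse)


def write_epq_map(epq_map: EPQItemMap, path: PathLike) -> None:
    pd.DataFrame(
        {
            "item_id": list(epq_map.entries),
            "scale": list(epq_map.entries.values()),
            "reverse": [i in epq_map.reverse_items for i in epq_map.entries],
        }
    ).to_csv(path, index=False)


def read_epq_responses(path: PathLike) -> Dict[str, Dict[str, int]]:
    df = pd.read_csv(path)
    items = [c for c in df.columns if c != "participant_id"]
    return {
        str(row["participant_id"]): {i: int(row[i]) for i in items}
        for _, row in df.iterrows()
    }


def write_epq_responses(ratings: Dict[str, Dict[str, int]], path: PathLike) -> None:
    rows = [{"participant_id": pid, **r} for pid, r in ratings.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_norms(path: PathLike) -> NormativeTable:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return NormativeTable({q: (float(v["mean"]), float(v["sd"])) for q, v in raw.items()})


def write_norms(norms: NormativeTable, path: PathLike) -> None:
    data = {q: {"mean": float(m), "sd": float(s)} for q, (m, s) in norms.values.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def write_erp_csv(erp, path: PathLike, channels: Optional[List[str]] = None,
                  decimals: int = 4) -> None:
    """Write an averaged ERP waveform: `time_ms` plus one column per channel."""
    channels = channels or list(erp.channels)
    idx = [list(erp.channels).index(c) for c in channels]
    df = pd.DataFrame({"time_ms": np.round(erp.times_ms, 3)})
    for c, i in zip(channels, idx):
        df[c] = np.round(erp.data[i], decimals)
    df.to_csv(path, index=False)


# -- EEG formats -----------------------------------------------------------

def write_recording_csv(rec: Recording, data_path: PathLike, events_path: PathLike) -> None:
    with open(data_path, "w") as fh:
        fh.write(f"# sample_rate={rec.fs}\n")
        pd.DataFrame(rec.data.T, columns=list(rec.channels)).to_csv(fh, index=False)
    pd.DataFrame(
        {
            "sample": [m.sample for m in rec.markers],
            "kind": [m.kind for m in rec.markers],
            "pair_id": [m.pair_id if m.pair_id is not None else "" for m in rec.markers],
        }
    ).to_csv(events_path, index=False)


def read_events(path: PathLike) -> List[EventMarker]:
    df = pd.read_csv(path)
    markers = []
    for _, row in df.iterrows():
        pid = row.get("pair_id")
        pid = None if pd.isna(pid) or pid == "" else int(pid)
        markers.append(EventMarker(sample=int(row["sample"]), kind=str(row["kind"]), pair_id=pid))
    return markers


def read_recording_csv(data_path: PathLike, events_path: Optional[PathLike] = None) -> Recording:
    with open(data_path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# sample_rate="):
            raise ValueError(f"{data_path}: expected a '# sample_rate=' header line")
        fs = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    markers = read_events(events_path) if events_path else []
    return Recording(fs=fs, channels=list(df.columns), data=df.to_numpy().T, markers=markers)


def read_recording_edf(path: PathLike, events_path: Optional[PathLike] = None) -> Recording:
    """Read a BDF/EDF file through mne (signal scaled to microvolts)."""
    import mne  # deferred: only needed for binary EEG formats

    path = Path(path)
    if path.suffix.lower() == ".bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    markers = read_events(events_path) if events_path else []
    return Recording(fs=float(raw.info["sfreq"]), channels=list(raw.ch_names),
                     data=data, markers=markers)


def read_recording(data_path: PathLike, events_path: Optional[PathLike] = None) -> Recording:
    suffix = Path(data_path).suffix.lower()
    if suffix in (".bdf", ".edf"):
        return read_recording_edf(data_path, events_path)
    return read_recording_csv(data_path, events_path)
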