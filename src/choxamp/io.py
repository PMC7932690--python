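"""Plain-text persistence: CSV traces/recordings with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cleaning import MultiChannelRecording, TransferFunction
from .events import EventSet
from .sensor import SimTrace


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))


def save_trace(trace: SimTrace, csv_path, with_snapshots: bool = False) -> None:
    """Trace as CSV plus a JSON parameter sidecar; profile snapshots
    optionally as a long-format CSV keyed by (t, r)."""
    csv_path = Path(csv_path)
    pd.DataFrame({
        "t": trace.t, "current_pA": trace.current,
        "bulk_ch_uM": trace.bulk_ch, "bulk_o2_uM": trace.bulk_o2,
        "surface_ch_uM": trace.surface_ch, "surface_o2_uM": trace.surface_o2,
    }).to_csv(csv_path, index=False)
    dump_json({"step_times": trace.step_times, "params": trace.params},
              csv_path.with_suffix(".json"))
    if with_snapshots and trace.snapshots:
        rows = []
        for snap in trace.snapshots:
            df = pd.DataFrame({"t": snap.t, "r": snap.r, "ch": snap.ch,
                               "o2": snap.o2, "h2o2": snap.h2o2})
            for i, name in enumerate(("E", "ECh", "EredBA", "EoxBA",
                                      "EredGB", "EoxGB")):
                df[name] = snap.enzymes[i]
            rows.append(df)
        pd.concat(rows).to_csv(csv_path.with_name(csv_path.stem + "_profiles.csv"),
                               index=False)


def load_trace(csv_path) -> SimTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    return SimTrace(df["t"].to_numpy(), df["current_pA"].to_numpy(),
                    df["bulk_ch_uM"].to_numpy(), df["bulk_o2_uM"].to_numpy(),
                    df["surface_ch_uM"].to_numpy(), df["surface_o2_uM"].to_numpy(),
                    np.asarray(side["step_times"], float), [], side["params"])


def save_recording(rec: MultiChannelRecording, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = rec.n_samples
    df = pd.DataFrame({"t": np.arange(n) / rec.fs})
    for site, x in rec.channels.items():
        df[site] = x
    df.to_csv(out / "channels.csv", index=False)
    dump_json({"fs": rec.fs, "potentials": rec.potentials, "meta": rec.meta},
              out / "meta.json")
    for name, (fs_aux, x) in rec.aux.items():
        pd.DataFrame({"t": np.arange(len(x)) / fs_aux, name: x}).to_csv(
            out / f"aux_{name}.csv", index=False)
        dump_json({"fs": fs_aux}, out / f"aux_{name}.json")


def load_recording(in_dir) -> MultiChannelRecording:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    df = pd.read_csv(src / "channels.csv")
    channels = {c: df[c].to_numpy() for c in df.columns if c != "t"}
    aux = {}
    for p in src.glob("aux_*.csv"):
        name = p.stem[4:]
        fs_aux = json.loads(p.with_suffix(".json").read_text())["fs"]
        aux[name] = (fs_aux, pd.read_csv(p)[name].to_numpy())
    return MultiChannelRecording(meta["fs"], channels, meta.get("potentials", {}),
                                 aux, meta.get("meta", {}))


def save_events(events: EventSet, path) -> None:
    df = pd.DataFrame({"kind": events.kind, "onset_s": events.onsets,
                       "peak_s": events.times, "amplitude": events.amplitudes,
                       "duration_ms": 1e3 * events.durations})
    df.to_csv(path, index=False)


def transfer_to_json(tf: TransferFunction, path) -> None:
    dump_json({"freqs": tf.freqs, "gain": tf.gain, "phase": tf.phase,
               "plv": tf.plv, "extrapolated_mask": tf.extrapolated_mask,
               "nperseg": tf.nperseg, "fs": tf.fs, "meta": tf.meta}, path)


def transfer_from_json(path) -> TransferFunction:
    d = json.loads(Path(path).read_text())
    return TransferFunction(np.asarray(d["freqs"]), np.asarray(d["gain"]),
                            np.asarray(d["phase"]), np.asarray(d["plv"]),
                            np.asarray(d["extrapolated_mask"], bool),
                            d["nperseg"], d["fs"], d.get("meta", {}))
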