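"""CSV / JSON / YAML serialization of timelines, stimulus sets and configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import PairTimeline, PlayerParams, SimConfig
from .stats import WDCCProfile
from .stimuli import StimulusSet


def timeline_to_frame(timeline: PairTimeline) -> pd.DataFrame:
    """Tidy frame with columns player (1|2), tap_index (1-based), time_ms."""
    rows = []
    for player in (1, 2):
        taps = timeline.taps(player)
        rows.append(
            pd.DataFrame(
                {
                    "player": player,
                    "tap_index": np.arange(1, len(taps) + 1),
                    "time_ms": taps * 1e3,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_timeline_csv(timeline: PairTimeline, path) -> None:
    timeline_to_frame(timeline).to_csv(path, index=False)


def read_timeline_csv(path, seed: int = -1) -> PairTimeline:
    df = pd.read_csv(path)
    taps = []
    for player in (1, 2):
        sub = df[df["player"] == player].sort_values("tap_index")
        taps.append(sub["time_ms"].to_numpy() / 1e3)
    return PairTimeline(taps[0], taps[1], seed=seed)


def write_wdcc_csv(profile: WDCCProfile, path) -> None:
    profile.to_frame().to_csv(path, index=False)


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["tap_order"] = list(config.tap_order)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for key in ("params_p1", "params_p2"):
        if isinstance(d.get(key), dict):
            d[key] = PlayerParams(**d[key])
    if "tap_order" in d:
        d["tap_order"] = tuple(d["tap_order"])
    return SimConfig(**d)


def write_config_yaml(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config)))


def read_config_yaml(path) -> SimConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def write_stimulus_set(stimulus_set: StimulusSet, outdir) -> Path:
    """Write per-stimulus timeline CSVs, WDCC CSVs and a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for stim in sorted(stimulus_set.stimuli, key=lambda s: s.rank):
        tl_path = outdir / f"{stim.stimulus_id}_timeline.csv"
        write_timeline_csv(stim.timeline, tl_path)
        wd_path = outdir / f"{stim.stimulus_id}_wdcc.csv"
        write_wdcc_csv(stim.profile, wd_path)
        entries.append(
            {
                "stimulus_id": stim.stimulus_id,
                "rank": stim.rank,
                "distance": stim.distance,
                "seed": stim.timeline.seed,
                "timeline_csv": tl_path.name,
                "wdcc_csv": wd_path.name,
            }
        )
    manifest = {
        "label": stimulus_set.label,
        "b_level": stimulus_set.b_level,
        "base_seed": stimulus_set.base_seed,
        "n_stimuli": len(stimulus_set.stimuli),
        "config": config_to_dict(stimulus_set.config) if stimulus_set.config else None,
        "stimuli": entries,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
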