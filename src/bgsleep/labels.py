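"""Hypnogram handling: consensus filtering, stage schemes, sleep parameters.

Stages follow the AASM vocabulary W / N1 / N2 / N3 / REM on a 30-s epoch
grid; '?' marks unscored epochs. Two label streams (human scorer and an
automatic stager) are reconciled by keeping only epochs where both agree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "SLEEP_STAGES",
    "Hypnogram",
    "SleepParameters",
    "consensus_filter",
    "map_stages",
    "sleep_parameters",
    "inclusion_filter",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
]

STAGES = ("W", "N1", "N2", "N3", "REM", "?")
SLEEP_STAGES = ("N1", "N2", "N3", "REM")
#: three-class scheme collapses the NREM substages
_THREE_CLASS = {"N1": "NREM", "N2": "NREM", "N3": "NREM"}
#: epochs per minute on the 30-s grid
_EPM = 2


@dataclass
class Hypnogram:
    """Per-epoch stage labels with lights-out / lights-on markers."""

    stages: np.ndarray
    epoch_length: float = 30.0
    lights_out_index: int = 0
    lights_on_index: int | None = None
    scorer: str = ""

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        if self.lights_on_index is None:
            self.lights_on_index = len(self.stages)
        bad = sorted(set(self.stages) - set(STAGES) - {"NREM"})
        if bad:
            raise ValueError(f"unknown stage labels: {bad}")
        if not (0 <= self.lights_out_index <= self.lights_on_index <= len(self.stages)):
            raise ValueError("need 0 <= lights_out <= lights_on <= n_epochs")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_length

    def is_sleep(self) -> np.ndarray:
        return np.isin(self.stages, SLEEP_STAGES + ("NREM",))


@dataclass
class SleepParameters:
    """The four whole-night summary parameters.

    structure_pct maps each sleep stage to its share (percent) of sleep
    epochs; latency is lights-out to first sleep epoch in minutes;
    efficiency is sleep time over time in bed in percent; fragmentation
    counts awakenings longer than 2 min between sleep onset and the last
    sleep epoch. ``valid`` is False when the night contains no sleep, in
    which case latency/structure are undefined (NaN).
    """

    structure_pct: dict[str, float]
    latency_min: float
    efficiency_pct: float
    fragmentation_count: int
    valid: bool = True


def consensus_filter(manual: Hypnogram, algorithmic: Hypnogram) -> np.ndarray:
    """Indices of epochs where the two scorers agree.

    Agreement is judged in the five-class scheme, so an N2-vs-N3
    disagreement removes the epoch even for downstream three-class
    decoding. Epochs unscored ('?') by either stream never agree.
    """
    if len(manual) != len(algorithmic) or manual.epoch_length != algorithmic.epoch_length:
        raise ValueError(
            f"hypnograms differ in shape: {len(manual)}x{manual.epoch_length}s "
            f"vs {len(algorithmic)}x{algorithmic.epoch_length}s"
        )
    a = map_stages(manual, "five_class").stages
    b = map_stages(algorithmic, "five_class").stages
    agree = (a == b) & (a != "?")
    return np.flatnonzero(agree)


def map_stages(
    h: Hypnogram, scheme: Literal["three_class", "five_class"]
) -> Hypnogram:
    """Map to the three-class (W/NREM/REM) or five-class scheme.

    Five-class is the identity; '?' passes through unchanged.
    """
    if scheme == "five_class":
        stages = h.stages.copy()
    elif scheme == "three_class":
        stages = np.asarray(
            [_THREE_CLASS.get(s, s) for s in h.stages], dtype=object
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return Hypnogram(
        stages=stages, epoch_length=h.epoch_length,
        lights_out_index=h.lights_out_index, lights_on_index=h.lights_on_index,
        scorer=h.scorer,
    )


def sleep_parameters(h: Hypnogram) -> SleepParameters:
    """Compute latency, efficiency, fragmentation and stage structure.

    Definitions: latency = lights-out to the first epoch of any sleep
    stage; efficiency = total sleep time / time in bed; fragmentation =
    number of wake interruptions strictly longer than 2 min (>= 5
    epochs) after sleep onset and before the final sleep epoch;
    structure = percentage of sleep epochs in each stage.
    """
    in_bed = slice(h.lights_out_index, h.lights_on_index)
    stages = h.stages[in_bed]
    sleep_mask = np.isin(stages, SLEEP_STAGES + ("NREM",))
    n_bed = len(stages)
    n_sleep = int(sleep_mask.sum())

    if n_sleep == 0:
        return SleepParameters(
            structure_pct={s: float("nan") for s in SLEEP_STAGES},
            latency_min=float("nan"),
            efficiency_pct=0.0,
            fragmentation_count=0,
            valid=False,
        )

    onset = int(np.flatnonzero(sleep_mask)[0])
    last = int(np.flatnonzero(sleep_mask)[-1])
    latency_min = onset * h.epoch_length / 60.0
    efficiency_pct = 100.0 * n_sleep / n_bed

    # maximal wake runs strictly inside the sleep period
    frag = 0
    run = 0
    for i in range(onset, last + 1):
        if not sleep_mask[i]:
            run += 1
        else:
            if run * h.epoch_length > 120.0:
                frag += 1
            run = 0

    structure = {
        s: 100.0 * float(np.sum(stages == s)) / n_sleep for s in SLEEP_STAGES
    }
    if "NREM" in stages:
        structure["NREM"] = 100.0 * float(np.sum(stages == "NREM")) / n_sleep
    return SleepParameters(
        structure_pct=structure,
        latency_min=latency_min,
        efficiency_pct=efficiency_pct,
        fragmentation_count=frag,
    )


def inclusion_filter(
    h: Hypnogram,
    scheme: Literal["three_class", "five_class"] = "three_class",
    min_minutes_per_stage: float = 5.0,
) -> tuple[bool, dict[str, float]]:
    """Whether every stage of the chosen scheme has enough data.

    Returns the include flag and per-stage minutes. A recording is
    usable only when every scheme stage reaches ``min_minutes_per_stage``
    (>= 10 epochs at the default 5 min).
    """
    mapped = map_stages(h, scheme)
    used = ("W", "NREM", "REM") if scheme == "three_class" else ("W",) + SLEEP_STAGES
    minutes = {
        s: float(np.sum(mapped.stages == s)) * h.epoch_length / 60.0 for s in used
    }
    include = all(m >= min_minutes_per_stage for m in minutes.values())
    return include, minutes


def write_hypnogram_csv(h: Hypnogram, path: str | Path) -> None:
    """Write epoch_index,stage rows with lights markers in header comments."""
    with open(path, "w") as fh:
        fh.write(f"# epoch_length={h.epoch_length}\n")
        fh.write(f"# lights_out_index={h.lights_out_index}\n")
        fh.write(f"# lights_on_index={h.lights_on_index}\n")
        fh.write(f"# scorer={h.scorer}\n")
        fh.write("epoch_index,stage\n")
        for i, s in enumerate(h.stages):
            fh.write(f"{i},{s}\n")


def read_hypnogram_csv(path: str | Path) -> Hypnogram:
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    table = pd.read_csv(body)
    return Hypnogram(
        stages=table["stage"].to_numpy(dtype=object),
        epoch_length=float(meta.get("epoch_length", 30.0)),
        lights_out_index=int(meta.get("lights_out_index", 0)),
        lights_on_index=int(meta["lights_on_index"]) if "lights_on_index" in meta else None,
        scorer=meta.get("scorer", ""),
    )
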