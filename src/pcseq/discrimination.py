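"""Spike detection and IN/OUT response classification.

A sequence pair is classified by whether the soma spiked for the IN and/or
OUT presentation: BOTH, IN_ONLY, OUT_ONLY, or NEITHER.  The discriminated
fraction of a sweep is (IN_ONLY + OUT_ONLY) / total - the sequences for
which the cell's spiking output encodes stimulus direction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import CType
from .solver import RecordedTrace


@dataclass(frozen=True)
class SpikeDetectorConfig:
    """Upward threshold-crossing detector.  The underlying experiments only
    report spiking vs not spiking; 0 mV with 2 ms separation is unambiguous
    for Hodgkin-Huxley-type somatic spikes."""

    threshold: float = 0.0       # mV
    min_separation: float = 2.0  # ms
    grace: float = 500.0         # ms after last pulse offset counted as response

    def __post_init__(self):
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")


class ResponseClass(enum.Enum):
    BOTH = "BOTH"
    IN_ONLY = "IN_ONLY"
    OUT_ONLY = "OUT_ONLY"
    NEITHER = "NEITHER"


def detect_spikes(tr: RecordedTrace | np.ndarray, cfg: SpikeDetectorConfig | None = None,
                  times: np.ndarray | None = None, compartment: int | None = None) -> np.ndarray:
    """Spike times (ms): upward crossings of the threshold, successive
    detections at least min_separation apart."""
    cfg = cfg or SpikeDetectorConfig()
    if isinstance(tr, RecordedTrace):
        v = tr.v[:, 0] if compartment is None else tr[compartment]
        times = tr.times
    else:
        v = np.asarray(tr, dtype=float)
        if times is None:
            raise ValueError("times required for a bare voltage array")
    if v.size == 0:
        raise ValueError("empty trace")
    above = v >= cfg.threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    out = []
    last = -np.inf
    for idx in crossings:
        t = times[idx]
        if t - last >= cfg.min_separation:
            out.append(t)
            last = t
    return np.array(out)


def spiked_in_window(tr: RecordedTrace, window: tuple[float, float],
                     cfg: SpikeDetectorConfig | None = None) -> bool:
    """Whether >=1 somatic spike falls in [t0, t1]."""
    st = detect_spikes(tr, cfg)
    return bool(np.any((st >= window[0]) & (st <= window[1])))


def classify(spiked_in: bool, spiked_out: bool) -> ResponseClass:
    if spiked_in and spiked_out:
        return ResponseClass.BOTH
    if spiked_in:
        return ResponseClass.IN_ONLY
    if spiked_out:
        return ResponseClass.OUT_ONLY
    return ResponseClass.NEITHER


SWEEP_COLUMNS = ("n_pulses", "interval_ms", "weight_nA", "spiked_in", "spiked_out", "class")


@dataclass
class SweepResult:
    """Row-level outcome of one sweep cube plus metadata."""

    rows: pd.DataFrame
    start_id: int | None = None
    ctype: CType | None = None
    config_hash: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(SWEEP_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"sweep rows missing columns {sorted(missing)}")
        for _, r in self.rows.iterrows():
            expected = classify(bool(r["spiked_in"]), bool(r["spiked_out"])).value
            if r["class"] != expected:
                raise ValueError(
                    f"inconsistent row: flags ({r['spiked_in']}, {r['spiked_out']}) "
                    f"vs class {r['class']!r}")

    def class_counts(self) -> dict[str, int]:
        counts = {rc.value: 0 for rc in ResponseClass}
        counts.update(self.rows["class"].value_counts().to_dict())
        return counts

    def __len__(self) -> int:
        return len(self.rows)


def discriminated_ratio(r: SweepResult | pd.DataFrame) -> float:
    """Fraction of sequences whose spiking output depends on direction."""
    rows = r.rows if isinstance(r, SweepResult) else r
    if len(rows) == 0:
        raise ValueError("empty sweep result")
    n_sel = int((rows["class"].isin([ResponseClass.IN_ONLY.value,
                                     ResponseClass.OUT_ONLY.value])).sum())
    return n_sel / len(rows)


def summarize_cubes(results: list[SweepResult]) -> pd.DataFrame:
    """Per-compartment-type mean of per-cube discriminated ratios
    (unweighted across cubes, whose sizes may differ), plus cube values."""
    if not results:
        raise ValueError("no sweep results")
    rows = []
    for r in results:
        rows.append({
            "ctype": r.ctype.value if r.ctype else "unknown",
            "start_id": r.start_id,
            "n_sequences": len(r),
            "ratio": discriminated_ratio(r),
        })
    per_cube = pd.DataFrame(rows)
    means = (per_cube.groupby("ctype")["ratio"].mean()
             .rename("mean_ratio").reset_index())
    return per_cube.merge(means, on="ctype")
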