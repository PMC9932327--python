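"""Experiment runners: discrimination sweep, tau-scan, learning/reversal.

Each runner takes explicit objects (morphology, channel set, grids, solver
and detector configs) and returns tabular results; `ExperimentConfig` loads
the same inputs from a single TOML file for the command-line interface.
Every output file embeds the configuration hash and package version so that
two runs with equal hashes are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .channels import ChannelSet, load_channel_set, scale_tau
from .discrimination import (ResponseClass, SpikeDetectorConfig, SweepResult,
                             classify, discriminated_ratio, spiked_in_window)
from .morphology import (CType, Morphology, ReducedSpec, generate_reduced,
                         read_genesis_p, read_swc)
from .plasticity import (LearningProtocol, PlasticityParams, reversal_search)
from .solver import CompiledModel, SolverConfig, init_state, run, settle
from .stimulation import (Direction, PulseMode, SweepGrid, grid_sequences,
                          make_protocol)

log = logging.getLogger("pcseq")


def config_hash(payload: dict) -> str:
    """Stable short hash of a configuration dictionary."""
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, chash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# pcseq {__version__} config_hash={chash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _write_json(payload: dict, path: Path, chash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"pcseq_version": __version__, "config_hash": chash, **payload}
    path.write_text(json.dumps(payload, indent=1, default=str) + "\n")


# ---------------------------------------------------------------------------
# Core evaluation
# ---------------------------------------------------------------------------

def evaluate_pairs(model: CompiledModel, pairs, solver_cfg: SolverConfig,
                   det: SpikeDetectorConfig, state=None,
                   max_cells: int | None = None) -> pd.DataFrame:
    """Simulate both directions of each (IN, OUT) spec pair from a shared
    settled state and classify the responses."""
    if state is None:
        state = settle(model, init_state(model, solver_cfg.v_init), solver_cfg)
    rows = []
    for i, (seq_in, seq_out) in enumerate(pairs):
        if max_cells is not None and i >= max_cells:
            break
        flags = {}
        for seq in (seq_in, seq_out):
            proto = make_protocol(seq, grace=det.grace)
            tr = run(model, proto, solver_cfg, state=state)
            window = (seq.onset, seq.onset + seq.duration_physical + det.grace)
            flags[seq.direction] = spiked_in_window(tr, window, det)
        cls = classify(flags[Direction.IN], flags[Direction.OUT])
        rows.append({"n_pulses": seq_in.n_pulses, "interval_ms": seq_in.interval,
                     "weight_nA": seq_in.weight,
                     "spiked_in": flags[Direction.IN],
                     "spiked_out": flags[Direction.OUT], "class": cls.value})
        log.info("pair %d/%d n=%d interval=%g w=%g -> %s", i + 1, len(pairs),
                 seq_in.n_pulses, seq_in.interval, seq_in.weight, cls.value)
    return pd.DataFrame(rows)


def run_sweep(m: Morphology, cs: ChannelSet, grid: SweepGrid,
              solver_cfg: SolverConfig | None = None,
              det: SpikeDetectorConfig | None = None,
              max_cells: int | None = None,
              out_dir: Path | None = None,
              chash: str = "") -> SweepResult:
    """One sweep cube: enumerate the grid, simulate both directions per
    triplet, classify, and (optionally) write CSV + summary JSON."""
    solver_cfg = solver_cfg or SolverConfig()
    det = det or SpikeDetectorConfig()
    pairs = grid_sequences(m, grid)
    model = CompiledModel(m, cs)
    rows = evaluate_pairs(model, pairs, solver_cfg, det, max_cells=max_cells)
    result = SweepResult(rows=rows, start_id=grid.start_id,
                         ctype=m[grid.start_id].ctype, config_hash=chash or None)
    if out_dir is not None:
        out_dir = Path(out_dir)
        _write_csv(rows, out_dir / f"sweep_start{grid.start_id}.csv", chash)
        _write_json({"start_id": grid.start_id,
                     "ctype": result.ctype.value,
                     "class_counts": result.class_counts(),
                     "n_sequences": len(result),
                     "discriminated_ratio": discriminated_ratio(result)},
                    out_dir / f"sweep_start{grid.start_id}_summary.json", chash)
    return result


def run_tau_scan(m: Morphology, cs: ChannelSet, channel: str,
                 f_values, grid: SweepGrid,
                 solver_cfg: SolverConfig | None = None,
                 det: SpikeDetectorConfig | None = None,
                 out_dir: Path | None = None, chash: str = "") -> pd.DataFrame:
    """Scan the inactivation-tau factor f of CaP or CaT against the stimulus
    interval; each (f, interval) cell is classified like a sweep cell.

    The grid fixes n_pulses and weight (classically n=6, w=6.633 nA) and
    varies the interval; f multiplies the h-gate time constant."""
    if channel not in ("CaP", "CaT"):
        raise ValueError("tau scan applies to CaP or CaT")
    solver_cfg = solver_cfg or SolverConfig()
    det = det or SpikeDetectorConfig()
    frames = []
    for f in f_values:
        if f <= 0:
            raise ValueError("f must be positive")
        cs_f = scale_tau(cs, channel, float(f))
        model = CompiledModel(m, cs_f)
        pairs = grid_sequences(m, grid)
        rows = evaluate_pairs(model, pairs, solver_cfg, det)
        rows.insert(0, "f", float(f))
        frames.append(rows)
    table = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        _write_csv(table, Path(out_dir) / f"tau_scan_{channel}.csv", chash)
    return table


def run_learning_experiment(m: Morphology, cs: ChannelSet, grid: SweepGrid,
                            params: PlasticityParams,
                            lp_template: LearningProtocol,
                            solver_cfg: SolverConfig | None = None,
                            det: SpikeDetectorConfig | None = None,
                            max_cells: int | None = None,
                            out_dir: Path | None = None,
                            chash: str = ""):
    """identify -> learn -> retest -> diff.

    Returns (before: SweepResult, after: DataFrame, flipped: DataFrame).
    When learning is disabled the retest is skipped (weights are unchanged
    and the solver is deterministic) and `after` equals `before` exactly.
    """
    solver_cfg = solver_cfg or SolverConfig()
    det = det or SpikeDetectorConfig()
    pairs = grid_sequences(m, grid)
    if max_cells is not None:
        pairs = pairs[:max_cells]
    model = CompiledModel(m, cs)
    state = settle(model, init_state(model, solver_cfg.v_init), solver_cfg)
    before_rows = evaluate_pairs(model, pairs, solver_cfg, det, state=state)
    before = SweepResult(rows=before_rows, start_id=grid.start_id,
                         ctype=m[grid.start_id].ctype, config_hash=chash or None)
    after = before_rows.copy()
    if lp_template.learning_enabled:
        diff = reversal_search(model, before_rows, pairs, params, lp_template,
                               solver_cfg, det, state=state)
        for _, d in diff.iterrows():
            mask = ((after["n_pulses"] == d["n_pulses"])
                    & (after["interval_ms"] == d["interval_ms"])
                    & (after["weight_nA"] == d["weight_nA"]))
            cls = ResponseClass(d["class_after"])
            after.loc[mask, "class"] = cls.value
            after.loc[mask, "spiked_in"] = cls in (ResponseClass.BOTH, ResponseClass.IN_ONLY)
            after.loc[mask, "spiked_out"] = cls in (ResponseClass.BOTH, ResponseClass.OUT_ONLY)
        flipped = diff[diff["flipped"]].reset_index(drop=True)
    else:
        diff = pd.DataFrame(columns=["n_pulses", "interval_ms", "weight_nA",
                                     "class_before", "class_after", "flipped",
                                     "w_learned_mean"])
        flipped = diff
    if out_dir is not None:
        out_dir = Path(out_dir)
        _write_csv(before_rows, out_dir / "learning_before.csv", chash)
        _write_csv(after, out_dir / "learning_after.csv", chash)
        _write_csv(flipped.drop(columns=["flipped"], errors="ignore"),
                   out_dir / "learning_flipped.csv", chash)
    return before, after, diff


# ---------------------------------------------------------------------------
# Configuration file support
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Structured experiment description loaded from one TOML file."""

    raw: dict
    path: Path | None = None

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls(raw=raw, path=path)
        morph = raw.get("morphology", {})
        src = morph.get("file")
        if src is not None and not (path.parent / src).exists() and not Path(src).exists():
            raise FileNotFoundError(f"morphology file {src!r} not found")
        chan = raw.get("channels", {}).get("file")
        if chan is not None and not (path.parent / chan).exists() and not Path(chan).exists():
            raise FileNotFoundError(f"channel file {chan!r} not found")
        return cfg

    @property
    def hash(self) -> str:
        return config_hash(self.raw)

    def _resolve(self, rel: str) -> Path:
        p = Path(rel)
        if p.exists() or self.path is None:
            return p
        return self.path.parent / rel

    def morphology(self) -> Morphology:
        m = self.raw.get("morphology", {})
        src = m.get("file")
        if src is None:
            keys = {f.name for f in ReducedSpec.__dataclass_fields__.values()}
            spec = ReducedSpec(**{k: v for k, v in m.items() if k in keys})
            return generate_reduced(spec)
        fmt = m.get("format", Path(src).suffix.lstrip(".").lower())
        path = self._resolve(src)
        if fmt == "swc":
            return read_swc(path)
        if fmt == "p":
            return read_genesis_p(path)
        if fmt == "json":
            return Morphology.from_json(path.read_text())
        raise ValueError(f"unknown morphology format {fmt!r}")

    def channel_set(self) -> ChannelSet:
        src = self.raw.get("channels", {}).get("file")
        return load_channel_set(self._resolve(src) if src else None)

    def solver(self) -> SolverConfig:
        return SolverConfig(**self.raw.get("solver", {}))

    def detector(self) -> SpikeDetectorConfig:
        return SpikeDetectorConfig(**self.raw.get("detector", {}))

    def grid(self, m: Morphology) -> SweepGrid:
        s = dict(self.raw.get("stimulus", {}))
        kwargs = {}
        if "start_id" in s:
            kwargs["start_id"] = int(s["start_id"])
        else:
            kwargs["start_id"] = max(c.id for c in m.compartments)  # distal tip
        for src_key, dst in (("n_pulses", "n_pulses_values"),
                             ("intervals", "interval_values"),
                             ("weights", "weight_values")):
            if src_key in s:
                kwargs[dst] = tuple(s[src_key])
        if "mode" in s:
            kwargs["mode"] = PulseMode(s["mode"])
        if "tau_i" in s:
            kwargs["tau_i"] = float(s["tau_i"])
        if "toward_soma" in s:
            kwargs["toward_soma"] = bool(s["toward_soma"])
        return SweepGrid(**kwargs)

    def plasticity(self) -> PlasticityParams:
        keys = {f.name for f in PlasticityParams.__dataclass_fields__.values()}
        p = self.raw.get("plasticity", {})
        return PlasticityParams(**{k: v for k, v in p.items() if k in keys})

    def learning_protocol(self, sequence) -> LearningProtocol:
        p = self.raw.get("plasticity", {})
        return LearningProtocol(
            sequence=sequence,
            cf_delay=float(p.get("cf_delay", 2.0)),
            trial_duration=float(p.get("trial_duration", 5000.0)),
            presentations=int(p.get("presentations", 1)),
            learning_enabled=bool(p.get("learning_enabled", True)))

    def out_dir(self) -> Path:
        return Path(self.raw.get("output", {}).get("dir", "pcseq_out"))
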