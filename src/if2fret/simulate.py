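"""Synthetic two-channel smFRET trajectory generator.

Emulates TIRF-microscope donor/acceptor intensity trajectories of surface
tethered 30S initiation complexes that reversibly bind fluorophore-labeled
IF2 from solution:

* a continuous-time two-state (free/bound) Markov path with exponential
  dwells — free→bound at the pseudo-first-order rate ``k_a·[IF2]``,
  bound→free at ``k_d``;
* one bound-state FRET substate drawn per binding event (Gaussian around the
  configured subpopulation means), held for the whole dwell unless an
  intra-dwell switching rate is enabled;
* single-step Cy3 (donor) and Cy5 (acceptor) photobleaching.  The donor sits
  on the P-site tRNA and bleaches on a single per-trace clock; the acceptor
  rides the exchanging IF2, so by default every binding event carries a
  fresh acceptor whose bleach clock starts at dwell entry;
* exact dwell-time-weighted frame averaging (transition frames are blurred),
  donor→acceptor bleed-through, and additive Gaussian channel noise.

Every trajectory is paired with its ground truth (dwell list, substate
indices, bleach times) so downstream estimators can be validated against
the generating parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "DwellEvent",
    "GroundTruth",
    "RawTrajectory",
    "simulate_state_path",
    "render_trajectory",
    "generate_dataset",
    "write_dataset",
    "read_traces",
    "read_ground_truth",
]


@dataclasses.dataclass
class DwellEvent:
    """One macro-state dwell of the continuous-time path."""

    t_start: float
    t_end: float
    macro: str  # "free" or "bound"
    substate: int  # -1 for free dwells
    efret: float  # ideal FRET efficiency held over the dwell
    cy5_bleach: float = np.inf  # absolute acceptor bleach time for this dwell


@dataclasses.dataclass
class GroundTruth:
    """Ground-truth annotation for one simulated trajectory."""

    trace_id: str
    events: list[DwellEvent]
    cy3_bleach_time: float | None
    cy5_bleach_time: float | None
    duration: float

    def macro_frame_labels(self, frame_time: float, n_frames: int) -> np.ndarray:
        """True macro label per frame (majority occupancy within the frame)."""
        edges = np.arange(n_frames + 1) * frame_time
        bound_time = np.zeros(n_frames)
        for ev in self.events:
            if ev.macro != "bound":
                continue
            lo = np.clip(edges[:-1], ev.t_start, ev.t_end)
            hi = np.clip(edges[1:], ev.t_start, ev.t_end)
            bound_time += np.maximum(hi - lo, 0.0)
        return np.where(bound_time > frame_time / 2, 1, 0)


@dataclasses.dataclass
class RawTrajectory:
    """Per-frame donor/acceptor intensities for one immobilized complex."""

    trace_id: str
    frame_time: float
    donor: np.ndarray
    acceptor: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor must have equal length")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ValueError("intensities must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_time


def _draw_efret(rng: np.random.Generator, mean: float, width: float) -> float:
    """Dwell-level ideal efficiency: Gaussian around the substate mean,
    clipped to the physical [0, 1] range."""
    return float(np.clip(rng.normal(mean, width) if width > 0 else mean, 0.0, 1.0))


def simulate_state_path(
    config: SimulationConfig, rng: np.random.Generator, trace_id: str = "trace"
) -> GroundTruth:
    """Draw one continuous-time free/bound path with photobleach times.

    The initial state is drawn from the equilibrium occupancy
    ``k_a[IF2] / (k_a[IF2] + k_d)``; dwells alternate thereafter with
    exponential waiting times. Each binding event draws one substate from
    the configured weights and holds it for the whole dwell (unless
    ``substate_switch_rate`` is on, in which case the substate is redrawn at
    exponential switch times within the dwell — recorded as successive
    bound events).
    """
    kon = config.pseudo_first_order_rate
    koff = config.k_d
    for rate in (kon, koff):
        if not np.isfinite(rate) or rate < 0:
            raise ValueError("rates must be finite and non-negative")
    T = config.duration
    weights = np.array([s.weight for s in config.substates]) if config.substates else None

    if kon + koff > 0:
        state = int(rng.random() < kon / (kon + koff))
    else:
        state = 0

    cy3 = rng.exponential(1.0 / config.kb_cy3) if config.kb_cy3 > 0 else np.inf
    cy5_trace = (
        rng.exponential(1.0 / config.kb_cy5)
        if (config.cy5_bleach_mode == "per_trace" and config.kb_cy5 > 0)
        else np.inf
    )

    events: list[DwellEvent] = []
    t = 0.0
    cy5_first: float = np.inf
    while t < T:
        if state == 0:
            dwell = rng.exponential(1.0 / kon) if kon > 0 else np.inf
            t_end = min(t + dwell, T)
            events.append(DwellEvent(t, t_end, "free", -1,
                                     _draw_efret(rng, config.free_efret_mean,
                                                 config.free_efret_width)))
            t = t + dwell
        else:
            dwell = rng.exponential(1.0 / koff) if koff > 0 else np.inf
            t_dwell_end = min(t + dwell, T)
            if config.cy5_bleach_mode == "per_event":
                bleach = (t + rng.exponential(1.0 / config.kb_cy5)
                          if config.kb_cy5 > 0 else np.inf)
            else:
                bleach = cy5_trace
            # sub-segments on intra-dwell substate switches
            seg_start = t
            while seg_start < t_dwell_end:
                if config.substate_switch_rate > 0:
                    seg_len = rng.exponential(1.0 / config.substate_switch_rate)
                else:
                    seg_len = np.inf
                seg_end = min(seg_start + seg_len, t_dwell_end)
                sub = int(rng.choice(len(weights), p=weights))
                s = config.substates[sub]
                events.append(DwellEvent(seg_start, seg_end, "bound", sub,
                                         _draw_efret(rng, s.mean, s.width), bleach))
                seg_start = seg_end
            if bleach < t_dwell_end:
                cy5_first = min(cy5_first, bleach)
            t = t + dwell
        state = 1 - state

    cy3_time = float(cy3) if cy3 < T else None
    if config.cy5_bleach_mode == "per_trace":
        cy5_time = float(cy5_trace) if cy5_trace < T else None
    else:
        cy5_time = float(cy5_first) if cy5_first < T else None
    return GroundTruth(trace_id, events, cy3_time, cy5_time, T)


def _ideal_efret_segments(truth: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant ideal E(t): breakpoints and per-segment values,
    with acceptor bleaching folded in (E drops to 0 at the dwell's Cy5
    bleach time)."""
    starts, vals = [], []
    for ev in truth.events:
        starts.append(ev.t_start)
        vals.append(ev.efret)
        if ev.macro == "bound" and ev.t_start <= ev.cy5_bleach < ev.t_end:
            starts.append(ev.cy5_bleach)
            vals.append(0.0)
    return np.array(starts), np.array(vals)


def render_trajectory(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> RawTrajectory:
    """Render ground truth into noisy two-channel frame intensities.

    Per frame the ideal efficiency is the exact dwell-time-weighted average
    of the piecewise-constant E(t) over the frame, so transition-straddling
    frames land at intermediate values. Pre-noise, pre-bleach channel sums
    equal ``total_intensity`` exactly; Cy3 bleaching zeroes both channels
    (time-weighted within the bleach frame); bleed-through adds
    ``bleedthrough·donor`` to the acceptor; channel noise is additive
    zero-mean Gaussian.
    """
    n, dt = config.n_frames, config.frame_time
    starts, vals = _ideal_efret_segments(truth)
    # cumulative integral of E(t)·alive(t) and of alive(t), alive = pre-Cy3
    cy3 = truth.cy3_bleach_time if truth.cy3_bleach_time is not None else np.inf
    edges = np.arange(n + 1) * dt
    bounds = np.append(starts, truth.duration)
    seg_lo = np.minimum(bounds[:-1], cy3)
    seg_hi = np.minimum(bounds[1:], cy3)
    seg_int = vals * np.maximum(seg_hi - seg_lo, 0.0)
    cum = np.concatenate([[0.0], np.cumsum(seg_int)])

    def cum_at(t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(bounds, t, side="right") - 1
        idx = np.clip(idx, 0, len(vals) - 1)
        lo = np.minimum(bounds[idx], cy3)
        hi = np.minimum(t, cy3)
        return cum[idx] + vals[idx] * np.maximum(hi - lo, 0.0)

    e_int = np.diff(cum_at(edges)) / dt                      # ∫E·alive / dt
    alive = np.diff(np.minimum(edges, cy3)) / dt             # ∫alive / dt
    acceptor = config.total_intensity * e_int
    donor = config.total_intensity * (alive - e_int)
    acceptor = acceptor + config.bleedthrough * donor
    if config.noise_sd > 0:
        donor = donor + rng.normal(0.0, config.noise_sd, n)
        acceptor = acceptor + rng.normal(0.0, config.noise_sd, n)
    return RawTrajectory(truth.trace_id, dt, donor, acceptor)


def generate_dataset(
    config: SimulationConfig,
) -> list[list[tuple[RawTrajectory, GroundTruth]]]:
    """Generate ``n_replicates`` independent sets of ``n_traces`` trajectories.

    Per-trace random streams are spawned deterministically from
    ``config.seed`` so the output is bit-reproducible for a given config.
    """
    root = np.random.SeedSequence(config.seed)
    replicate_seeds = root.spawn(config.n_replicates)
    replicates = []
    for r, rep_seed in enumerate(replicate_seeds):
        traces = []
        for i, trace_seed in enumerate(rep_seed.spawn(config.n_traces)):
            rng = np.random.default_rng(trace_seed)
            trace_id = f"rep{r}_trace{i:04d}"
            truth = simulate_state_path(config, rng, trace_id)
            raw = render_trajectory(truth, config, rng)
            traces.append((raw, truth))
        replicates.append(traces)
    return replicates


def _traces_frame(traces: list[RawTrajectory]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "trace_id": tr.trace_id,
            "frame": np.arange(tr.n_frames),
            "time_s": tr.times,
            "donor": tr.donor,
            "acceptor": tr.acceptor,
        }))
    if not rows:
        return pd.DataFrame(columns=["trace_id", "frame", "time_s", "donor", "acceptor"])
    return pd.concat(rows, ignore_index=True)


def _truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    rows = []
    for gt in truths:
        for ev in gt.events:
            rows.append((gt.trace_id, ev.t_start, ev.t_end, ev.macro, ev.substate))
    return pd.DataFrame(rows, columns=["trace_id", "t_start_s", "t_end_s",
                                       "macro_state", "substate"])


def write_dataset(config: SimulationConfig, out_dir, force: bool = False) -> Path:
    """Generate and write the dataset as per-replicate CSVs plus a manifest.

    Refuses to overwrite an existing output directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty; pass force=True")
    out.mkdir(parents=True, exist_ok=True)
    replicates = generate_dataset(config)
    manifest = {"config": config.model_dump(), "replicates": []}
    for r, traces in enumerate(replicates):
        rep_dir = out / f"replicate_{r}"
        rep_dir.mkdir(exist_ok=True)
        _traces_frame([t for t, _ in traces]).to_csv(rep_dir / "traces.csv", index=False)
        _truth_frame([g for _, g in traces]).to_csv(rep_dir / "ground_truth.csv",
                                                    index=False)
        bleach = {
            g.trace_id: {"cy3_bleach_s": g.cy3_bleach_time,
                         "cy5_bleach_s": g.cy5_bleach_time}
            for _, g in traces
        }
        (rep_dir / "bleach_times.json").write_text(json.dumps(bleach, indent=1))
        manifest["replicates"].append({
            "dir": rep_dir.name, "n_traces": len(traces),
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_traces(path) -> list[RawTrajectory]:
    """Read a traces CSV (columns trace_id, frame, time_s, donor, acceptor)."""
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("frame")
        t = grp["time_s"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 0.1
        out.append(RawTrajectory(str(tid), dt, grp["donor"].to_numpy(),
                                 grp["acceptor"].to_numpy()))
    return out


def read_ground_truth(path) -> dict[str, pd.DataFrame]:
    """Read a ground-truth CSV, keyed by trace id."""
    df = pd.read_csv(path)
    return {str(tid): grp.reset_index(drop=True)
            for tid, grp in df.groupby("trace_id", sort=False)}
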