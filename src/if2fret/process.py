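"""Raw-trajectory processing: corrections, selection, FRET efficiency.

The chain mirrors standard smFRET curation of two-channel TIRF data:

1. subtract donor→acceptor bleed-through (``acceptor' = acceptor − β·donor``);
2. locate single-step photobleaches of either dye by a windowed change-point
   scan;
3. baseline-correct each channel using the post-bleach segment;
4. keep trajectories showing donor/acceptor anti-correlation and either a
   single-step photobleach or single-fluorophore intensities;
5. compute ``E = I_acceptor / (I_acceptor + I_donor)`` per frame and truncate
   at the donor (Cy3) photobleach.

Frames whose total intensity falls below a configurable floor are masked as
invalid rather than divided; nothing is clamped or interpolated silently.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .simulate import RawTrajectory

__all__ = [
    "EfretTrajectory",
    "SelectionReport",
    "correct_bleedthrough",
    "detect_photobleach",
    "correct_baseline",
    "select_trajectory",
    "compute_efret",
    "process_trajectory",
    "process_dataset",
]


@dataclasses.dataclass
class EfretTrajectory:
    """Corrected FRET-efficiency trajectory, truncated at donor bleach.

    ``efret`` has length ``truncation_frame``; entries where ``valid`` is
    False are noise-dominated frames (denominator below the floor) and are
    NaN.  Values may transiently leave [0, 1] through noise; they are never
    clamped.
    """

    trace_id: str
    frame_time: float
    efret: np.ndarray
    valid: np.ndarray
    truncation_frame: int
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.efret)


@dataclasses.dataclass
class SelectionReport:
    """Per-criterion curation outcome for one trajectory."""

    trace_id: str
    accepted: bool
    anticorrelation: float
    anticorrelation_pass: bool
    single_step_bleach: bool
    intensity_plausible: bool


def correct_bleedthrough(raw: RawTrajectory, beta: float = 0.07) -> RawTrajectory:
    """Remove the fraction ``beta`` of donor signal from the acceptor channel."""
    if not (0.0 <= beta < 1.0):
        raise ValueError(f"bleed-through coefficient must be in [0, 1), got {beta}")
    meta = dict(raw.meta)
    meta["bleedthrough"] = beta
    return RawTrajectory(raw.trace_id, raw.frame_time, raw.donor.copy(),
                         raw.acceptor - beta * raw.donor, meta)


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise sd from the MAD of first differences (step-insensitive)."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _windowed_drops(x: np.ndarray, w: int) -> np.ndarray:
    """Drop in windowed mean at each interior frame k: mean of the w frames
    before k minus mean of the w frames from k on."""
    n = len(x)
    drops = np.full(n, -np.inf)
    if n < 2 * w:
        return drops
    c = np.concatenate([[0.0], np.cumsum(x)])
    pre = (c[w:n - w + 1] - c[:n - 2 * w + 1]) / w
    post = (c[2 * w:] - c[w:n - w + 1]) / w
    drops[w:n - w + 1] = pre - post
    return drops


def _dark_level(x: np.ndarray, w: int = 10) -> float:
    """Level of the darkest stretch of a channel: the minimum rolling mean.

    Unlike a low percentile this is a genuine dark level even when the
    channel is bright for most of the trace (a percentile would land inside
    the bright cluster and make real signal look like baseline).
    """
    n = len(x)
    if n < w:
        return float(np.min(x)) if n else 0.0
    c = np.concatenate([[0.0], np.cumsum(x)])
    rolling = (c[w:] - c[:-w]) / w
    return float(rolling.min())


def _find_steps(x: np.ndarray, w: int, min_drop: float) -> list[int]:
    """All change-point candidates with windowed-mean drop above
    ``min_drop``, greedily extracted largest-first with ±2w exclusion."""
    drops = _windowed_drops(x, w)
    steps: list[int] = []
    work = drops.copy()
    while True:
        k = int(np.argmax(work))
        if work[k] <= min_drop:
            break
        steps.append(k)
        lo, hi = max(0, k - 2 * w), min(len(x), k + 2 * w)
        work[lo:hi] = -np.inf
    return sorted(steps)


def detect_photobleach(
    raw: RawTrajectory, window: int = 5
) -> tuple[int | None, int | None]:
    """Locate single-step Cy5 (acceptor) and Cy3 (donor) photobleach frames.

    Returns ``(cy5_frame, cy3_frame)``; absent events are ``None``.  The Cy3
    bleach is sought on the summed channel (the sum is FRET-independent while
    the donor is alive) and requires both channels at baseline afterwards.
    The Cy5 candidate is the largest acceptor drop, before any Cy3 bleach,
    whose post-step acceptor stays at baseline.  A step counts only if its
    drop exceeds 5× the robust noise sd of its channel.  Note that a terminal
    acceptor drop is indistinguishable from a final dissociation; the Cy5
    frame is used for curation and baselines, never for kinetics.
    """
    if raw.n_frames < 10:
        return None, None
    total = raw.donor + raw.acceptor
    rsd_tot = _robust_noise_sd(total)

    cy3_frame: int | None = None
    base_d = _dark_level(raw.donor)
    base_a = _dark_level(raw.acceptor)
    tol_d = 3 * max(_robust_noise_sd(raw.donor), 1e-9)
    tol_a = 3 * max(_robust_noise_sd(raw.acceptor), 1e-9)
    for k in _find_steps(total, window, max(5 * rsd_tot, 1e-9)):
        if (abs(raw.donor[k:].mean() - base_d) < tol_d
                and abs(raw.acceptor[k:].mean() - base_a) < tol_a):
            cy3_frame = k
            break

    end = cy3_frame if cy3_frame is not None else raw.n_frames
    cy5_frame: int | None = None
    acc = raw.acceptor[:end]
    if len(acc) >= 10:
        rsd_a = _robust_noise_sd(acc)
        tol_a = 3 * max(rsd_a, 1e-9)
        base_a = _dark_level(acc)
        for k in _find_steps(acc, window, max(5 * rsd_a, 1e-9)):
            if abs(acc[k:].mean() - base_a) < tol_a:
                cy5_frame = k
                break
    return cy5_frame, cy3_frame


def correct_baseline(
    raw: RawTrajectory, bleach_frames: tuple[int | None, int | None] | None = None,
    min_segment: int = 5, fallback: str = "none",
) -> RawTrajectory:
    """Subtract per-channel baselines.

    Each channel's baseline is the median of the segment in which that
    channel is dark — the donor after the Cy3 bleach, the acceptor after
    the later of the Cy5 and Cy3 bleaches.  When no such segment of at
    least ``min_segment`` frames exists the channel is left unshifted
    (``fallback="none"``, the default: without a dark segment any offset
    estimate would subtract real signal and bias E); ``fallback="p5"``
    subtracts the channel's 5th percentile instead.  Offsets are recorded
    in ``meta['baseline']``.
    """
    if bleach_frames is None:
        bleach_frames = detect_photobleach(raw)
    cy5_frame, cy3_frame = bleach_frames
    acc_dark = max((f for f in bleach_frames if f is not None), default=None)
    offsets = {}
    for name, chan, dark in (("donor", raw.donor, cy3_frame),
                             ("acceptor", raw.acceptor, acc_dark)):
        if dark is not None and raw.n_frames - dark >= min_segment:
            offsets[name] = float(np.median(chan[dark:]))
        elif fallback == "p5":
            offsets[name] = float(np.percentile(chan, 5))
        else:
            offsets[name] = 0.0
    meta = dict(raw.meta)
    meta["baseline"] = offsets
    return RawTrajectory(raw.trace_id, raw.frame_time,
                         raw.donor - offsets["donor"],
                         raw.acceptor - offsets["acceptor"], meta)


def select_trajectory(
    raw: RawTrajectory,
    anticorrelation_threshold: float = -0.3,
    expected_total: float = 1000.0,
    plausibility_band: tuple[float, float] = (0.5, 1.5),
    window: int = 5,
) -> SelectionReport:
    """Apply the curation criteria to a corrected trajectory.

    Accepted iff (a) the Pearson correlation of frame-to-frame donor vs.
    acceptor changes over FRET-active frames is at or below the threshold,
    and (b) a single-step photobleach is detected in at least one channel OR
    the pre-bleach total intensity sits in the single-fluorophore band.
    FRET-active frame pairs are those where both channels move by more than
    3× their difference noise sd (a genuine state change moves donor and
    acceptor together; requiring both keeps noise-only pairs out of the
    statistic); with fewer than 3 active pairs the correlation is taken
    over all differences, which rejects traces without observable
    transitions.
    """
    cy5_frame, cy3_frame = detect_photobleach(raw, window)
    end = cy3_frame if cy3_frame is not None else raw.n_frames
    dd = np.diff(raw.donor[:end])
    da = np.diff(raw.acceptor[:end])
    if len(dd) >= 2:
        rsd_d = max(_robust_noise_sd(raw.donor[:end]), 1e-9)
        rsd_a = max(_robust_noise_sd(raw.acceptor[:end]), 1e-9)
        sd_diff_d, sd_diff_a = np.sqrt(2) * rsd_d, np.sqrt(2) * rsd_a
        active = (np.abs(dd) > 3 * sd_diff_d) & (np.abs(da) > 3 * sd_diff_a)
        n_active = int(active.sum())
        if n_active >= 2:
            sel_dd, sel_da = dd[active], da[active]
        elif n_active == 1:
            # one clean joint excursion: score it by its sign alone
            sel_dd = sel_da = None
            r = -1.0 if float(dd[active][0] * da[active][0]) < 0 else 1.0
        else:
            sel_dd, sel_da = dd, da
        if sel_dd is not None:
            with np.errstate(invalid="ignore"):
                if sel_dd.std() > 0 and sel_da.std() > 0:
                    r = float(np.corrcoef(sel_dd, sel_da)[0, 1])
                else:
                    r = 0.0
    else:
        r = 0.0
    anticorr_pass = r <= anticorrelation_threshold

    # single-step criterion: a detected bleach with no second comparable step
    single_step = False
    if cy3_frame is not None or cy5_frame is not None:
        chan = raw.donor + raw.acceptor if cy3_frame is not None else raw.acceptor
        rsd = max(_robust_noise_sd(chan), 1e-9)
        steps = _find_steps(chan, window, 5 * rsd)
        drops = _windowed_drops(chan, window)
        if steps:
            largest = max(drops[k] for k in steps)
            comparable = [k for k in steps if drops[k] > 0.5 * largest]
            single_step = len(comparable) == 1
    pre_end = min((f for f in (cy5_frame, cy3_frame) if f is not None),
                  default=raw.n_frames)
    mean_total = float((raw.donor[:pre_end] + raw.acceptor[:pre_end]).mean()) \
        if pre_end > 0 else 0.0
    lo, hi = plausibility_band
    plausible = lo * expected_total <= mean_total <= hi * expected_total
    accepted = anticorr_pass and (single_step or plausible)
    return SelectionReport(raw.trace_id, accepted, r, anticorr_pass,
                           single_step, plausible)


def compute_efret(
    raw: RawTrajectory,
    cy3_bleach_frame: int | None = None,
    denominator_floor: float = 100.0,
) -> EfretTrajectory:
    """Per-frame ``E = acceptor / (acceptor + donor)`` up to the Cy3 bleach.

    Frames whose summed intensity is below ``denominator_floor`` (default
    10% of the nominal single-fluorophore total) are flagged invalid and set
    to NaN rather than divided.
    """
    end = cy3_bleach_frame if cy3_bleach_frame is not None else raw.n_frames
    donor = raw.donor[:end]
    acceptor = raw.acceptor[:end]
    denom = donor + acceptor
    valid = denom >= denominator_floor
    efret = np.full(end, np.nan)
    np.divide(acceptor, denom, out=efret, where=valid)
    meta = dict(raw.meta)
    meta["denominator_floor"] = denominator_floor
    return EfretTrajectory(raw.trace_id, raw.frame_time, efret, valid, end, meta)


def process_trajectory(
    raw: RawTrajectory,
    bleedthrough: float = 0.07,
    expected_total: float = 1000.0,
    select: bool = True,
) -> tuple[EfretTrajectory | None, SelectionReport]:
    """Full chain for one trace; returns ``(efret, report)``.

    ``efret`` is ``None`` when selection is enabled and the trace fails it.
    """
    corrected = correct_bleedthrough(raw, bleedthrough)
    bleach = detect_photobleach(corrected)
    corrected = correct_baseline(corrected, bleach)
    report = select_trajectory(corrected, expected_total=expected_total)
    if select and not report.accepted:
        return None, report
    eff = compute_efret(corrected, bleach[1],
                        denominator_floor=0.1 * expected_total)
    return eff, report


def process_dataset(
    traces: list[RawTrajectory],
    bleedthrough: float = 0.07,
    expected_total: float = 1000.0,
    select: bool = True,
) -> tuple[list[EfretTrajectory], list[SelectionReport]]:
    """Process a list of raw traces; returns accepted efret trajectories and
    all selection reports."""
    kept, reports = [], []
    for raw in traces:
        eff, rep = process_trajectory(raw, bleedthrough, expected_total, select)
        reports.append(rep)
        if eff is not None and eff.n_frames > 0:
            kept.append(eff)
    return kept, reports


def efret_frame(trajs: list[EfretTrajectory]) -> pd.DataFrame:
    """Long-format efficiency table (trace_id, frame, time_s, efret, valid)."""
    rows = []
    for tr in trajs:
        rows.append(pd.DataFrame({
            "trace_id": tr.trace_id,
            "frame": np.arange(tr.n_frames),
            "time_s": np.arange(tr.n_frames) * tr.frame_time,
            "efret": tr.efret,
            "valid": tr.valid,
        }))
    if not rows:
        return pd.DataFrame(columns=["trace_id", "frame", "time_s", "efret", "valid"])
    return pd.concat(rows, ignore_index=True)
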