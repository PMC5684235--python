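"""Transition-probability-matrix kinetics with photobleach corrections.

Frame-to-frame free/bound transitions of the idealized trajectories are
pooled into a 2×2 counting matrix per replicate data set, row-normalized to
a transition probability matrix, and converted to rate constants:

    k_a = −ln(p_free→free) / ([IF2]·t)        (µM⁻¹ s⁻¹, [IF2] in µM)
    k_d = −ln(p_bound→bound) / t              (s⁻¹)

with ``t`` the frame time.  Two corrections address photobleaching biases:

* **Acceptor (Cy5) bleaching** mimics dissociation, so for long-lived
  binders the trailing zero-FRET stretch of a trajectory inflates the free
  counts and contributes a spurious bound→free exit.  The correction drops
  each trajectory's final free dwell from the counting.  By default the
  bound→free transition entering that dwell is dropped with it (the entire
  dwell is removed from the analysis), which is what removes the spurious
  exit; ``keep_entry_transition=True`` retains it.
* **Donor (Cy3) bleaching** truncates trajectories before rare binders ever
  bind, which removes free-state exposure and inflates k_a.  The correction
  pads the data set with simulated all-zero-FRET trajectories, sized by the
  correction factor Cf = (%capable − %observed)/%observed, where %capable
  is the fraction of trajectories with at least one binding event in a
  reference condition that binds readily, and %observed the same fraction
  in the condition under analysis.

Counts are pooled across traces within a replicate before normalization;
replicate-level rates are aggregated as mean ± SE.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .idealize import IdealizedPath

__all__ = [
    "CountingMatrix",
    "TransitionMatrix",
    "PaddingPlan",
    "KineticEstimate",
    "count_transitions",
    "transition_probabilities",
    "rates_from_probabilities",
    "plan_cy3_padding",
    "make_padding_paths",
    "estimate_replicate",
    "estimate_condition",
    "paths_from_truth",
]

FREE, BOUND = 0, 1


@dataclasses.dataclass
class CountingMatrix:
    """Pooled 2×2 frame-to-frame macro transition counts (free=0, bound=1)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("counting matrix must be 2x2 with counts >= 0")

    def __add__(self, other: "CountingMatrix") -> "CountingMatrix":
        return CountingMatrix(self.counts + other.counts)


@dataclasses.dataclass
class TransitionMatrix:
    """Row-normalized transition probabilities at the frame interval."""

    probs: np.ndarray
    frame_time: float
    row_defined: np.ndarray  # bool per row; False where the row had no counts


@dataclasses.dataclass
class PaddingPlan:
    """Sizing of the zero-FRET padding set for the Cy3 correction."""

    percent_capable: float
    percent_observed: float
    correction_factor: float
    n_observed_with_event: int
    n_simulated: int
    length_frames: int


@dataclasses.dataclass
class KineticEstimate:
    """Replicate-aggregated rate constants for one condition."""

    condition: str
    k_a_replicates: list[float]
    k_d_replicates: list[float]
    kd_nM_replicates: list[float]
    k_a: float
    k_a_se: float | None
    k_d: float
    k_d_se: float | None
    kd_nM: float
    kd_nM_se: float | None
    corrections: dict
    counting: list[CountingMatrix]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["counting"] = [c.counts.tolist() for c in self.counting]
        return d


def _macro_int(path: IdealizedPath) -> np.ndarray:
    return np.asarray(path.macro, bool).astype(np.int64)


def count_transitions(
    paths: list[IdealizedPath],
    exclude_final_free_dwell: bool = False,
    keep_entry_transition: bool = False,
) -> CountingMatrix:
    """Accumulate frame-pair counts n_ij over a set of idealized paths.

    With ``exclude_final_free_dwell``, a path ending in the free macro-state
    has its final free dwell removed from the counting: the internal
    free→free pairs are always dropped, and the bound→free transition
    entering the dwell is dropped too unless ``keep_entry_transition``.
    Paths shorter than two frames contribute nothing.
    """
    n = np.zeros((2, 2), dtype=np.int64)
    for path in paths:
        m = _macro_int(path)
        L = len(m)
        if L < 2:
            continue
        end = L  # count pairs (j, j+1) for j in range(end - 1)
        if exclude_final_free_dwell and m[-1] == FREE:
            i = L - 1
            while i > 0 and m[i - 1] == FREE:
                i -= 1
            # pairs fully inside the final dwell start at index i
            end = i
            if keep_entry_transition and i > 0:
                n[m[i - 1], m[i]] += 1
        for j in range(end - 1):
            n[m[j], m[j + 1]] += 1
    return CountingMatrix(n)


def transition_probabilities(
    counting: CountingMatrix, frame_time: float
) -> TransitionMatrix:
    """Row-normalize the counting matrix; zero rows are flagged undefined."""
    counts = counting.counts.astype(float)
    row_sums = counts.sum(axis=1)
    probs = np.full((2, 2), np.nan)
    defined = row_sums > 0
    probs[defined] = counts[defined] / row_sums[defined, None]
    return TransitionMatrix(probs, frame_time, defined)


def rates_from_probabilities(
    tm: TransitionMatrix, if2_conc: float
) -> tuple[float, float]:
    """Convert staying probabilities to (k_a, k_d).

    ``if2_conc`` is in µM so k_a emerges in µM⁻¹ s⁻¹.  Undefined or zero
    staying probabilities yield NaN (rate unavailable).
    """
    if if2_conc <= 0 or tm.frame_time <= 0:
        raise ValueError("if2_conc and frame_time must be positive")
    p_ff = tm.probs[FREE, FREE]
    p_bb = tm.probs[BOUND, BOUND]
    k_a = np.nan
    k_d = np.nan
    if tm.row_defined[FREE] and p_ff > 0:
        k_a = -np.log(p_ff) / (if2_conc * tm.frame_time)
    if tm.row_defined[BOUND] and p_bb > 0:
        k_d = -np.log(p_bb) / tm.frame_time
    return float(k_a), float(k_d)


def _has_binding_event(path: IdealizedPath) -> bool:
    return bool(np.asarray(path.macro, bool).any())


def plan_cy3_padding(
    observed: list[IdealizedPath], reference: list[IdealizedPath]
) -> PaddingPlan:
    """Size the zero-FRET padding set from observed and reference data.

    ``%capable`` is the fraction of reference trajectories showing at least
    one binding event; ``%observed`` the same fraction among the observed
    trajectories.  The number of simulated trajectories is
    ``round(n_observed_with_event × Cf)`` and their length is the average
    observed trajectory length (already truncated at the Cy3 bleach).
    """
    if not observed or not reference:
        raise ValueError("observed and reference sets must be nonempty")
    cap = float(np.mean([_has_binding_event(p) for p in reference]))
    obs = float(np.mean([_has_binding_event(p) for p in observed]))
    if obs == 0:
        raise ValueError(
            "no observed trajectory shows a binding event; the Cy3 correction "
            "factor is undefined — collect more traces or skip padding")
    cf = max((cap - obs) / obs, 0.0)
    n_with_event = int(sum(_has_binding_event(p) for p in observed))
    n_sim = int(round(n_with_event * cf))
    length = int(round(float(np.mean([p.n_frames for p in observed]))))
    return PaddingPlan(100 * cap, 100 * obs, cf, n_with_event, n_sim, length)


def make_padding_paths(plan: PaddingPlan, frame_time: float) -> list[IdealizedPath]:
    """Deterministic all-free padding trajectories (only their free→free
    dwell mass matters, so they carry no noise)."""
    out = []
    for i in range(plan.n_simulated):
        L = plan.length_frames
        out.append(IdealizedPath(
            trace_id=f"cy3pad_{i:04d}", frame_time=frame_time,
            states=np.zeros(L, dtype=np.int64),
            macro=np.zeros(L, dtype=bool),
            state_means=np.array([0.0]),
            valid=np.ones(L, dtype=bool)))
    return out


def estimate_replicate(
    paths: list[IdealizedPath],
    if2_conc: float,
    frame_time: float,
    exclude_final_free_dwell: bool = False,
    keep_entry_transition: bool = False,
    padding: PaddingPlan | None = None,
) -> tuple[float, float, CountingMatrix]:
    """k_a, k_d for one replicate data set (pooled counting matrix)."""
    pooled = list(paths)
    if padding is not None:
        pooled += make_padding_paths(padding, frame_time)
    counting = count_transitions(pooled, exclude_final_free_dwell,
                                 keep_entry_transition)
    tm = transition_probabilities(counting, frame_time)
    k_a, k_d = rates_from_probabilities(tm, if2_conc)
    return k_a, k_d, counting


def _mean_se(values: list[float]) -> tuple[float, float | None]:
    arr = np.asarray([v for v in values if np.isfinite(v)], float)
    if len(arr) == 0:
        return float("nan"), None
    mean = float(arr.mean())
    if len(arr) < 2:
        return mean, None
    return mean, float(arr.std(ddof=1) / np.sqrt(len(arr)))


def estimate_condition(
    replicates: list[list[IdealizedPath]],
    if2_conc: float,
    frame_time: float,
    condition: str = "",
    exclude_final_free_dwell: bool = False,
    keep_entry_transition: bool = False,
    reference_replicates: list[list[IdealizedPath]] | None = None,
    padding_plans: list[PaddingPlan] | None = None,
) -> KineticEstimate:
    """Replicate-level rates with mean ± SE and exact K_d = k_d/k_a.

    When ``reference_replicates`` is given, each replicate is padded with
    zero-FRET trajectories sized against the matching reference replicate
    (Cy3 correction); precomputed ``padding_plans`` (one per replicate,
    e.g. sized on the full pre-selection populations) take precedence.
    K_d is reported in nM (k_d/k_a gives µM).
    """
    k_as, k_ds, kds, countings = [], [], [], []
    pads = []
    for i, paths in enumerate(replicates):
        padding = None
        if padding_plans is not None:
            padding = padding_plans[i % len(padding_plans)]
        elif reference_replicates is not None:
            ref = reference_replicates[i % len(reference_replicates)]
            padding = plan_cy3_padding(paths, ref)
        pads.append(padding)
        k_a, k_d, counting = estimate_replicate(
            paths, if2_conc, frame_time, exclude_final_free_dwell,
            keep_entry_transition, padding)
        k_as.append(k_a)
        k_ds.append(k_d)
        kds.append(1000.0 * k_d / k_a if (np.isfinite(k_a) and k_a > 0
                                          and np.isfinite(k_d)) else float("nan"))
        countings.append(counting)
    k_a_mean, k_a_se = _mean_se(k_as)
    k_d_mean, k_d_se = _mean_se(k_ds)
    kd_mean, kd_se = _mean_se(kds)
    corrections = {
        "exclude_final_free_dwell": exclude_final_free_dwell,
        "keep_entry_transition": keep_entry_transition,
        "cy3_padding": [dataclasses.asdict(p) if p else None for p in pads],
    }
    return KineticEstimate(condition, k_as, k_ds, kds, k_a_mean, k_a_se,
                           k_d_mean, k_d_se, kd_mean, kd_se, corrections,
                           countings)


def paths_from_truth(
    truths, frame_time: float, n_frames: int,
    observed: bool = False, threshold: float = 0.2,
) -> list[IdealizedPath]:
    """Idealized paths built from ground-truth labels (bypassing the HMM),
    for estimator-consistency and correction-property checks.

    With ``observed=False`` the labels are the true macro states over the
    full window.  With ``observed=True`` they are what an ideal detector
    would report: the dwell-time-weighted noiseless efficiency per frame
    (acceptor bleaching folded in) thresholded at ``threshold``, truncated
    at the Cy3 bleach — i.e. ground-truth idealization of the *apparent*
    trajectory.
    """
    from .simulate import _ideal_efret_segments

    out = []
    for gt in truths:
        if not observed:
            macro = gt.macro_frame_labels(frame_time, n_frames).astype(bool)
        else:
            starts, vals = _ideal_efret_segments(gt)
            cy3 = gt.cy3_bleach_time if gt.cy3_bleach_time is not None else np.inf
            bounds = np.append(starts, gt.duration)
            edges = np.arange(n_frames + 1) * frame_time
            seg_int = vals * np.maximum(
                np.minimum(bounds[1:], cy3) - np.minimum(bounds[:-1], cy3), 0.0)
            cum = np.concatenate([[0.0], np.cumsum(seg_int)])
            idx = np.clip(np.searchsorted(bounds, edges, side="right") - 1,
                          0, len(vals) - 1)
            cum_at = cum[idx] + vals[idx] * np.maximum(
                np.minimum(edges, cy3) - np.minimum(bounds[idx], cy3), 0.0)
            efret = np.diff(cum_at) / frame_time
            n_keep = int(np.searchsorted(
                (np.arange(n_frames) + 0.5) * frame_time, cy3))
            macro = efret[:n_keep] > threshold
        out.append(IdealizedPath(
            trace_id=gt.trace_id, frame_time=frame_time,
            states=macro.astype(np.int64), macro=macro,
            state_means=np.array([0.0, 0.87]),
            valid=np.ones(len(macro), dtype=bool)))
    return out
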