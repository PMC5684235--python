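"""Bound-state FRET-efficiency distributions and their decomposition.

Pools the efficiency values of all frames idealized as IF2-bound, fits one-
versus two-component Gaussian mixtures (BIC-selected, deterministic
initialization), aggregates replicate-level component means and weights as
mean ± SE, and builds post-synchronized population surfaces in which every
binding event is re-indexed to start at lag zero.

The histogram unit is the frame: a subpopulation weight is the fraction of
bound-state Gaussian area, not of binding events.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .idealize import IdealizedPath
from .process import EfretTrajectory

__all__ = [
    "MixtureFit",
    "PopulationSurface",
    "bound_frame_samples",
    "fit_mixture",
    "fit_mixture_replicates",
    "compare_means",
    "postsync_surface",
]


@dataclasses.dataclass
class MixtureFit:
    """Gaussian mixture over bound-state E values.

    Components are ordered by descending mean.  For replicate-aggregated
    fits, ``means``/``weights`` are replicate averages and the ``*_se``
    fields their standard errors; ``replicates`` holds the per-replicate
    fits.
    """

    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bic: float
    means_se: np.ndarray | None = None
    weights_se: np.ndarray | None = None
    replicates: list["MixtureFit"] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "bic": self.bic,
            "means_se": None if self.means_se is None else self.means_se.tolist(),
            "weights_se": None if self.weights_se is None else self.weights_se.tolist(),
            "replicates": [r.to_dict() for r in self.replicates],
        }


@dataclasses.dataclass
class PopulationSurface:
    """(lag since binding-event start) × (E bin) occupancy counts."""

    counts: np.ndarray      # shape (n_lags, n_bins)
    lag_times: np.ndarray   # seconds
    bin_edges: np.ndarray
    n_events: int


def bound_frame_samples(
    paths: list[IdealizedPath], trajs: list[EfretTrajectory],
    trim_edges: int = 1,
) -> np.ndarray:
    """Valid E values of frames whose macro label is bound, pooled.

    ``trim_edges`` drops that many frames from each end of every bound
    dwell (default 1): transition-straddling frames carry time-averaged
    intermediate efficiencies that belong to neither state.  Pass 0 to pool
    every bound frame.
    """
    by_id = {t.trace_id: t for t in trajs}
    chunks = []
    for path in paths:
        traj = by_id.get(path.trace_id)
        if traj is None:
            continue
        n = min(path.n_frames, traj.n_frames)
        m = np.asarray(path.macro[:n], bool)
        sel = m & np.asarray(traj.valid[:n], bool) & np.isfinite(traj.efret[:n])
        if trim_edges > 0 and m.any():
            interior = m.copy()
            for _ in range(trim_edges):
                interior &= np.r_[False, interior[:-1]] & np.r_[interior[1:], False]
            sel &= interior
        chunks.append(traj.efret[:n][sel])
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def _order_desc(means, sds, weights):
    order = np.argsort(means)[::-1]
    return means[order], sds[order], weights[order]


def fit_mixture(
    samples: np.ndarray, max_components: int = 2, random_state: int = 0,
    n_components: int | None = None,
) -> MixtureFit:
    """Fit Gaussian mixtures with 1..``max_components`` components on the
    raw samples and select by BIC, or fit a fixed ``n_components``.

    Initialization is k-means++ with a fixed seed, so the fit is
    deterministic for a given sample set.  With fewer than 100 samples a
    single-component fit is returned with a warning.
    """
    x = np.asarray(samples, float).reshape(-1, 1)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to fit a mixture")
    kmax = max_components
    if len(x) < 100:
        warnings.warn("fewer than 100 samples; falling back to a single "
                      "Gaussian component", stacklevel=2)
        kmax = 1
        n_components = None
    ks = range(1, kmax + 1) if n_components is None else [n_components]
    best: MixtureFit | None = None
    for k in ks:
        gm = _fit_k(x, k, random_state)
        bic = float(gm.bic(x))
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.copy()
        weights = weights / weights.sum()
        means, sds, weights = _order_desc(means, sds, weights)
        if best is None or bic < best.bic:
            best = MixtureFit(k, means, sds, weights, bic)
    return best


def _fit_k(x: np.ndarray, k: int, random_state: int) -> GaussianMixture:
    """Best-of-several EM fits at fixed component count.

    Overlapping components make the likelihood surface multimodal and
    k-means++ alone often lands on a ridge that trades weight against
    width, so quantile-spread initializations are tried as well and the
    highest final likelihood wins.  All starts are deterministic.
    """
    common = dict(n_components=k, covariance_type="diag", reg_covar=1e-8,
                  tol=1e-6, max_iter=2000, random_state=random_state)
    fits = [GaussianMixture(init_params="k-means++", n_init=5, **common).fit(x)]
    sd0 = max(float(x.std()) / max(k, 2), 1e-3)
    for lo, hi in ((0.1, 0.9), (0.25, 0.75), (0.02, 0.98)):
        q = np.quantile(x, np.linspace(lo, hi, k)).reshape(-1, 1)
        gm = GaussianMixture(means_init=q,
                             weights_init=np.full(k, 1.0 / k),
                             precisions_init=np.full((k, 1), 1.0 / sd0 ** 2),
                             **common)
        fits.append(gm.fit(x))
    return max(fits, key=lambda g: g.score(x))


def fit_mixture_replicates(
    sample_sets: list[np.ndarray], max_components: int = 2, random_state: int = 0,
    n_components: int | None = None,
) -> MixtureFit:
    """Per-replicate mixture fits aggregated to mean ± SE.

    Unless ``n_components`` is forced, the component count is chosen per
    replicate by BIC and reconciled by majority (ties favor more
    components); replicates whose selected count differs are refit at the
    consensus count so components can be matched by rank order of their
    means.
    """
    fits = [fit_mixture(s, max_components, random_state, n_components)
            for s in sample_sets]
    counts = [f.n_components for f in fits]
    consensus = max(sorted(set(counts)), key=lambda k: (counts.count(k), k))
    refit = []
    for s, f in zip(sample_sets, fits):
        if f.n_components != consensus:
            gm = GaussianMixture(n_components=consensus, covariance_type="diag",
                                 init_params="k-means++", n_init=3,
                                 random_state=random_state, reg_covar=1e-8)
            x = np.asarray(s, float).reshape(-1, 1)
            gm.fit(x)
            m, sd, w = _order_desc(gm.means_.ravel(),
                                   np.sqrt(gm.covariances_.ravel()),
                                   gm.weights_ / gm.weights_.sum())
            f = MixtureFit(consensus, m, sd, w, float(gm.bic(x)))
        refit.append(f)
    means = np.vstack([f.means for f in refit])
    sds = np.vstack([f.sds for f in refit])
    weights = np.vstack([f.weights for f in refit])
    n = len(refit)
    means_se = means.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else None
    weights_se = weights.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else None
    return MixtureFit(consensus, means.mean(axis=0), sds.mean(axis=0),
                      weights.mean(axis=0), float(np.mean([f.bic for f in refit])),
                      means_se, weights_se, refit)


def compare_means(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided two-sample t-test on replicate-level mean E values.

    Returns the p value; NaN (undefined) when both groups have zero
    variance and differ, 1.0 when the groups are numerically identical.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicate means per condition")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else float("nan")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def postsync_surface(
    paths: list[IdealizedPath],
    trajs: list[EfretTrajectory],
    max_lag: int = 50,
    bin_width: float = 0.02,
    e_range: tuple[float, float] = (-0.2, 1.2),
) -> PopulationSurface:
    """Superimpose binding events re-indexed from their start frame.

    Every contiguous bound run contributes its E values at lags
    0..min(len, max_lag)-1; counts accumulate on a (lag, E-bin) grid.
    """
    edges = np.arange(e_range[0], e_range[1] + bin_width / 2, bin_width)
    counts = np.zeros((max_lag, len(edges) - 1), dtype=np.int64)
    by_id = {t.trace_id: t for t in trajs}
    n_events = 0
    frame_time = paths[0].frame_time if paths else 0.1
    for path in paths:
        traj = by_id.get(path.trace_id)
        if traj is None:
            continue
        m = np.asarray(path.macro, bool)
        n = min(len(m), traj.n_frames)
        starts = np.flatnonzero(m[:n] & ~np.r_[False, m[:n - 1]])
        for s in starts:
            e = s
            while e < n and m[e]:
                e += 1
            n_events += 1
            seg = traj.efret[s:min(e, s + max_lag)]
            ok = np.isfinite(seg)
            lags = np.arange(len(seg))[ok]
            idx = np.digitize(seg[ok], edges) - 1
            keep = (idx >= 0) & (idx < counts.shape[1])
            np.add.at(counts, (lags[keep], idx[keep]), 1)
    return PopulationSurface(counts, np.arange(max_lag) * frame_time,
                             edges, n_events)
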