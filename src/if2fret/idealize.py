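"""Per-trace HMM idealization of FRET-efficiency trajectories.

Each trajectory is fit independently with Gaussian-emission HMMs of 1 to
``max_states`` states by expectation-maximization; the state count is chosen
by the Bayesian information criterion.  EM starts from five deterministic
quantile-based seedings per state count and the best likelihood is kept, so
fits are reproducible without a random stream.  Decoding is Viterbi; each
state is mapped to the free/bound dichotomy by its mean efficiency, with
free defined inclusively as mean E ≤ 0.2.

Frames masked invalid are treated as missing observations (the emission term
is omitted and the chain bridges them), not imputed.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._hmm import _em_fit, _viterbi, path_log_likelihood
from .config import FREE_EFRET_THRESHOLD
from .process import EfretTrajectory

__all__ = ["HmmModel", "IdealizedPath", "fit_hmm", "decode", "idealize_dataset"]

N_RESTARTS = 5


@dataclasses.dataclass
class HmmModel:
    """Fitted Gaussian-emission HMM for one trajectory."""

    n_states: int
    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    bic: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_obs": self.n_obs,
        }


@dataclasses.dataclass
class IdealizedPath:
    """Viterbi path with free/bound macro labels for one trajectory."""

    trace_id: str
    frame_time: float
    states: np.ndarray       # per-frame state index
    macro: np.ndarray        # per-frame bool, True = bound
    state_means: np.ndarray  # mean E per state
    valid: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.states)


def _seed_means(obs: np.ndarray, k: int, restart: int) -> np.ndarray:
    """Deterministic quantile-based initial means for one EM restart."""
    if restart < 3:
        offset = (0.5, 0.25, 0.75)[restart]
        q = (np.arange(k) + offset) / k
        return np.quantile(obs, np.clip(q, 0.01, 0.99))
    if restart == 3:
        return np.quantile(obs, np.linspace(0.05, 0.95, k))
    return np.linspace(obs.min(), obs.max(), k + 2)[1:-1]


def _n_params(k: int) -> int:
    # start (k-1) + transitions k(k-1) + emission means and sds (2k)
    return (k - 1) + k * (k - 1) + 2 * k


def fit_hmm(
    traj: EfretTrajectory, max_states: int = 3,
    max_iter: int = 200, tol: float = 1e-5,
) -> HmmModel:
    """Fit HMMs with 1..``max_states`` states and select by BIC.

    Requires at least 20 valid frames.  A degenerate (near-constant) signal
    returns the single-state model directly.
    """
    valid = np.asarray(traj.valid, bool) & np.isfinite(traj.efret)
    obs = np.where(valid, traj.efret, 0.0).astype(float)
    n_valid = int(valid.sum())
    if n_valid < 20:
        raise ValueError(f"trace {traj.trace_id}: need >= 20 valid frames, "
                         f"have {n_valid}")
    x = obs[valid]
    if x.std() < 1e-6:
        means = np.array([x.mean()])
        sds = np.array([1e-3])
        A = np.ones((1, 1))
        pi = np.ones(1)
        ll = float(np.sum(np.log(
            np.exp(-0.5 * ((x - means[0]) / sds[0]) ** 2)
            / (sds[0] * np.sqrt(2 * np.pi)) + 1e-300)))
        return HmmModel(1, means, sds, A, pi, ll,
                        -2 * ll + _n_params(1) * np.log(n_valid), n_valid)

    best_model: HmmModel | None = None
    for k in range(1, max_states + 1):
        best_ll = -np.inf
        best = None
        sd0 = max(float(x.std()) / k, 0.02)
        tried: set[bytes] = set()
        for r in range(N_RESTARTS):
            m0 = np.sort(np.asarray(_seed_means(x, k, r), float))
            key = np.round(m0, 6).tobytes()
            if key in tried:
                continue
            tried.add(key)
            A0 = np.full((k, k), 0.05 / max(k - 1, 1))
            np.fill_diagonal(A0, 0.95)
            pi0 = np.full(k, 1.0 / k)
            means, sds, A, pi, ll, _ = _em_fit(
                obs, valid, m0, np.full(k, sd0), A0, pi0, max_iter, tol)
            if ll > best_ll:
                best_ll = ll
                best = (means, sds, A, pi)
        means, sds, A, pi = best
        bic = -2 * best_ll + _n_params(k) * np.log(n_valid)
        if best_model is None or bic < best_model.bic:
            best_model = HmmModel(k, means, sds, A, pi, best_ll, bic, n_valid)
    return best_model


def decode(model: HmmModel, traj: EfretTrajectory) -> IdealizedPath:
    """Viterbi decoding plus macro labeling.

    A state is macro-free iff its mean efficiency is at or below the 0.2
    threshold (the tie at exactly 0.2 is free, matching the inclusive
    definition of the free state).
    """
    valid = np.asarray(traj.valid, bool) & np.isfinite(traj.efret)
    obs = np.where(valid, traj.efret, 0.0).astype(float)
    path, _ = _viterbi(obs, valid, model.means, model.sds,
                       model.transmat, model.startprob)
    bound_state = model.means > FREE_EFRET_THRESHOLD
    macro = bound_state[path]
    return IdealizedPath(traj.trace_id, traj.frame_time, path, macro,
                         model.means.copy(), valid)


def idealize_dataset(
    trajs: list[EfretTrajectory], max_states: int = 3, min_valid: int = 20,
) -> tuple[list[IdealizedPath], list[HmmModel]]:
    """Fit and decode every trajectory with enough valid frames."""
    paths, models = [], []
    for traj in trajs:
        n_valid = int((np.asarray(traj.valid, bool)
                       & np.isfinite(traj.efret)).sum())
        if n_valid < min_valid:
            continue
        model = fit_hmm(traj, max_states)
        paths.append(decode(model, traj))
        models.append(model)
    return paths, models


def models_to_json(models: list[HmmModel], trace_ids: list[str]) -> str:
    return json.dumps({tid: m.to_dict() for tid, m in zip(trace_ids, models)},
                      indent=1)


__all__.append("path_log_likelihood")
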