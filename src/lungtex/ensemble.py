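"""Weighted-average fusion of the seven networks and the weight search.

The ensemble output for a sample x is the weighted sum of the member
probability vectors,

    Y(x) = sum_i  w_i * P_i(x),        w_i in [0, 1],

*not* renormalized (the argmax decision is invariant to positive scaling).
The weights are found by minimizing a validation objective — by default
1 - macro balanced accuracy — with one of:

* TPE (Tree-structured Parzen Estimator): models p(w | score) with two
  Parzen density estimators split at the gamma quantile of the observed
  scores, and proposes the candidate maximizing the good/bad density
  ratio;
* RS: uniform random search over [0, 1]^n;
* BO: Gaussian-process expected improvement over the same space.

A majority-voting rule over the member argmax decisions is provided as
the non-weighting baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .tissue import N_CLASSES, TissueClass

SEARCH_METHODS = ("TPE", "RS", "BO")


class SearchConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EnsembleWeights:
    """Non-negative fusion weights, one per member, in canonical order."""

    w: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        if self.w.ndim != 1:
            raise ValueError("weights must be a 1D vector")
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")

    def __len__(self):
        return len(self.w)

    def to_json(self, model_names: Sequence[str], **metadata) -> str:
        payload = {"weights": {n: float(v) for n, v in zip(model_names, self.w)},
                   "metadata": metadata}
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str, model_names: Sequence[str]) -> "EnsembleWeights":
        payload = json.loads(text)
        return cls(np.asarray([payload["weights"][n] for n in model_names]))


@dataclass
class SearchConfig:
    """Weight-search settings. ``objective`` maps (fused scores (N, C),
    labels (N,)) to a scalar to minimize; None means 1 - macro balanced
    accuracy over the classes present in the labels."""

    method: str = "TPE"
    n_trials: int = 200
    gamma: float = 0.25
    n_candidates: int = 24
    n_startup: int = 20
    rng_seed: int = 0
    objective: Optional[Callable[[np.ndarray, np.ndarray], float]] = None

    def __post_init__(self):
        if self.method not in SEARCH_METHODS:
            raise SearchConfigError(
                f"method must be one of {SEARCH_METHODS}, got {self.method!r}")
        if self.n_trials < 1:
            raise SearchConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if not 0.0 < self.gamma < 1.0:
            raise SearchConfigError(f"gamma must be in (0, 1), got {self.gamma}")


# ----------------------------------------------------------------- fusion

def fuse(probs: np.ndarray, weights) -> np.ndarray:
    """Weighted sum of member probability vectors.

    ``probs`` has shape (n_models, n_classes) for one sample or
    (n_models, N, n_classes) for a batch; the result drops the model axis.
    """
    w = weights.w if isinstance(weights, EnsembleWeights) else np.asarray(weights, float)
    probs = np.asarray(probs)
    if probs.shape[0] != len(w):
        raise ValueError(
            f"got {probs.shape[0]} member outputs for {len(w)} weights")
    return np.tensordot(w, probs, axes=(0, 0))


def decide(fused: np.ndarray) -> np.ndarray:
    """Argmax decision over fused scores; ties go to the lowest class
    index (np.argmax's convention). Works on (C,) or (N, C)."""
    fused = np.asarray(fused)
    return fused.argmax(axis=-1)


def majority_vote(votes: np.ndarray, probs: Optional[np.ndarray] = None) -> np.ndarray:
    """Modal class of the member argmax decisions.

    ``votes``: (n_models,) or (n_models, N) integer classes. Ties are
    broken by the highest summed probability among the tied classes (when
    ``probs`` with shape (n_models, [N,] n_classes) is given), then by the
    lowest class index.
    """
    votes = np.asarray(votes)
    if votes.ndim == 1:                            # one sample
        votes = votes[:, None]
    # (M, N)
    M, N = votes.shape
    counts = np.zeros((N, N_CLASSES))
    for m in range(M):
        counts[np.arange(N), votes[m]] += 1
    top = counts.max(axis=1, keepdims=True)
    tied = counts == top
    if probs is not None:
        p = np.asarray(probs)
        if p.ndim == 2:
            p = p[:, None, :]
        summed = p.sum(axis=0)                     # (N, C)
        # rank tied classes by summed probability, then lowest index
        score = np.where(tied, summed, -np.inf)
        return score.argmax(axis=1)
    return tied.argmax(axis=1)


# -------------------------------------------------------------- objective

def balanced_accuracy_objective(fused: np.ndarray, labels: np.ndarray) -> float:
    """1 - macro balanced accuracy over the classes present in ``labels``."""
    pred = decide(fused)
    labels = np.asarray(labels)
    bas = []
    for c in np.unique(labels):
        pos = labels == c
        tp = np.count_nonzero(pred[pos] == c)
        fn = np.count_nonzero(pos) - tp
        fp = np.count_nonzero(pred[~pos] == c)
        tn = np.count_nonzero(~pos) - fp
        sn = tp / (tp + fn)
        sp = tn / (tn + fp) if (tn + fp) else 1.0
        bas.append(0.5 * (sn + sp))
    return 1.0 - float(np.mean(bas))


def geometric_mean_objective(fused: np.ndarray, labels: np.ndarray) -> float:
    pred = decide(fused)
    labels = np.asarray(labels)
    gms = []
    for c in np.unique(labels):
        pos = labels == c
        tp = np.count_nonzero(pred[pos] == c)
        fn = np.count_nonzero(pos) - tp
        fp = np.count_nonzero(pred[~pos] == c)
        tn = np.count_nonzero(~pos) - fp
        sn = tp / (tp + fn)
        sp = tn / (tn + fp) if (tn + fp) else 1.0
        gms.append(np.sqrt(sn * sp))
    return 1.0 - float(np.mean(gms))


# ---------------------------------------------------------- weight search

@dataclass
class Trial:
    w: np.ndarray
    score: float


def _parzen_logpdf(x: np.ndarray, obs: np.ndarray, bw: float) -> np.ndarray:
    """Log density of a 1D Parzen (Gaussian-kernel) mixture at points x."""
    d = (x[:, None] - obs[None, :]) / bw
    log_k = -0.5 * d * d - np.log(bw * np.sqrt(2 * np.pi))
    m = log_k.max(axis=1, keepdims=True)
    return (m[:, 0] + np.log(np.exp(log_k - m).mean(axis=1)))


def _bandwidth(obs: np.ndarray) -> float:
    n = len(obs)
    spread = max(obs.max() - obs.min(), 1e-3)
    return max(spread * n ** (-1.0 / 5.0), 0.02)


def _tpe_propose(history: List[Trial], dim: int, gamma: float,
                 n_candidates: int, rng: np.random.Generator) -> np.ndarray:
    scores = np.asarray([t.score for t in history])
    order = np.argsort(scores, kind="stable")
    n_good = max(1, int(np.ceil(gamma * len(history))))
    good = np.asarray([history[i].w for i in order[:n_good]])
    bad = np.asarray([history[i].w for i in order[n_good:]])
    if len(bad) == 0:
        bad = good
    cands = np.empty((n_candidates, dim))
    for d in range(dim):
        g_obs, b_obs = good[:, d], bad[:, d]
        bw_g, bw_b = _bandwidth(g_obs), _bandwidth(b_obs)
        # draw from the good-density mixture, clipped to the unit box
        comp = rng.integers(0, len(g_obs), size=n_candidates)
        draws = np.clip(g_obs[comp] + bw_g * rng.standard_normal(n_candidates),
                        0.0, 1.0)
        cands[:, d] = draws
    # score candidates by the good/bad log-density ratio, summed over dims
    ratio = np.zeros(n_candidates)
    for d in range(dim):
        g_obs, b_obs = good[:, d], bad[:, d]
        ratio += (_parzen_logpdf(cands[:, d], g_obs, _bandwidth(g_obs))
                  - _parzen_logpdf(cands[:, d], b_obs, _bandwidth(b_obs)))
    return cands[int(np.argmax(ratio))]


def _bo_propose(history: List[Trial], dim: int, rng: np.random.Generator,
                n_candidates: int = 256) -> np.ndarray:
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, WhiteKernel
    from scipy.stats import norm

    X = np.asarray([t.w for t in history])
    y = np.asarray([t.score for t in history])
    y_mu, y_sd = y.mean(), max(y.std(), 1e-9)
    gp = GaussianProcessRegressor(
        kernel=1.0 * RBF(length_scale=0.3) + WhiteKernel(1e-4),
        normalize_y=False, random_state=int(rng.integers(2 ** 31)))
    gp.fit(X, (y - y_mu) / y_sd)
    cands = rng.uniform(0, 1, size=(n_candidates, dim))
    mu, sd = gp.predict(cands, return_std=True)
    best = ((y - y_mu) / y_sd).min()
    imp = best - mu
    z = imp / np.maximum(sd, 1e-12)
    ei = imp * norm.cdf(z) + sd * norm.pdf(z)
    return cands[int(np.argmax(ei))]


def optimize_weights(probs: np.ndarray, labels: np.ndarray,
                     cfg: Optional[SearchConfig] = None,
                     ) -> Tuple[EnsembleWeights, List[Trial]]:
    """Search fusion weights minimizing the validation objective.

    Parameters
    ----------
    probs : ndarray, shape (n_models, N, n_classes)
        Precomputed member validation probabilities (the members are never
        retrained inside the search).
    labels : ndarray, shape (N,)
        True classes of the validation samples.
    cfg : SearchConfig

    Returns
    -------
    (EnsembleWeights, list of Trial)
        The best weight vector over all trials and the full history.
    """
    cfg = cfg or SearchConfig()
    probs = np.asarray(probs)
    if probs.ndim != 3:
        raise ValueError("probs must have shape (n_models, N, n_classes)")
    labels = np.asarray(labels)
    if probs.shape[1] != len(labels):
        raise ValueError("probs and labels disagree on the number of samples")
    objective = cfg.objective or balanced_accuracy_objective
    dim = probs.shape[0]
    rng = np.random.default_rng(cfg.rng_seed)
    history: List[Trial] = []
    # deterministic warm start: each member alone (one-hot weights) and the
    # unweighted average; guarantees the returned ensemble never scores
    # worse than its best single member
    warm = [np.ones(dim)] + [np.eye(dim)[i] for i in range(dim)]
    warm = warm[:cfg.n_trials]
    n_startup = min(cfg.n_startup, cfg.n_trials)
    for t in range(cfg.n_trials):
        if t < len(warm):
            w = warm[t]
        elif cfg.method == "RS" or t < len(warm) + n_startup:
            w = rng.uniform(0.0, 1.0, size=dim)
        elif cfg.method == "TPE":
            w = _tpe_propose(history, dim, cfg.gamma, cfg.n_candidates, rng)
        else:  # BO
            w = _bo_propose(history, dim, rng)
        score = float(objective(fuse(probs, w), labels))
        history.append(Trial(w=w, score=score))
    best = min(history, key=lambda t: t.score)
    return EnsembleWeights(best.w.copy()), history


@dataclass
class WeightedEnsemble:
    """The fused classifier: zoo members plus their optimized weights.

    ``predict_proba`` returns the weighted average renormalized to sum to
    one, so the maximum entry doubles as the certainty of the decision;
    the argmax is identical to that of the raw weighted sum.
    """

    models: Sequence[object]            # PatchClassifier-like members
    weights: EnsembleWeights
    norm_stats: Optional[object] = None

    def __post_init__(self):
        if len(self.models) != len(self.weights):
            raise ValueError(
                f"{len(self.models)} members but {len(self.weights)} weights")
        if np.sum(self.weights.w) <= 0:
            raise ValueError("at least one weight must be positive")

    def member_probs(self, vol, points, batch_size: int = 128) -> np.ndarray:
        kwargs = {} if self.norm_stats is None else {"norm_stats": self.norm_stats}
        return np.stack([
            m.classify_points(vol, points, batch_size=batch_size, **kwargs)
            for m in self.models])

    def classify_points(self, vol, points, batch_size: int = 128) -> np.ndarray:
        fused = fuse(self.member_probs(vol, points, batch_size), self.weights)
        return fused / fused.sum(axis=-1, keepdims=True)

    def fuse_member_probs(self, probs: np.ndarray) -> np.ndarray:
        fused = fuse(probs, self.weights)
        return fused / fused.sum(axis=-1, keepdims=True)


def single_model_objectives(probs: np.ndarray, labels: np.ndarray,
                            objective=None) -> np.ndarray:
    """Objective of each member alone (one-hot weights)."""
    objective = objective or balanced_accuracy_objective
    return np.asarray([float(objective(probs[i], labels))
                       for i in range(probs.shape[0])])
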