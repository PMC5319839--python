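"""Two-state HMM click classifier with a PCA front end.

Discrete ("click") selections are decoded by a hidden Markov model over two
intent states, move and click.  Binned features are first reduced to the top
four eigenvalue-ranked principal components; each state's emission is a
multivariate Gaussian with its own mean and covariance in that 4-D space.
Per bin, the filtered state posterior follows the recursion

    p(s_k, t)  propto  p(z_t | s_k) * sum_i p(s_k | s_i) p(s_i, t-1),

renormalized across the two states.  The click threshold is calibrated
without supervision at the 93rd quantile of the click-state posterior over
the retraining block, and at run time a click is generated after two
consecutive 15-ms bins above threshold (the consecutive counter re-arms
after each click, so a sustained excursion cannot machine-gun selections
faster than once per two bins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .synthetic import ConfigurationError

MOVE, CLICK = 0, 1
N_COMPONENTS = 4


@dataclass
class PCAProjection:
    """Affine map to the top-4 principal-component space."""

    mean: np.ndarray        # (d,)
    components: np.ndarray  # (4, d), rows orthonormal, eigenvalue-ranked
    explained_variance: np.ndarray  # (4,)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.components.T


def fit_pca(X: np.ndarray, n_components: int = N_COMPONENTS) -> PCAProjection:
    """Top-``n_components`` eigenvalue-ranked PCs of the calibration features.

    Deterministic sign convention: each component's largest-magnitude
    loading is made positive, so duplicated datasets yield identical
    projections.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 50:
        raise ConfigurationError("need at least 50 calibration bins for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    if np.sum(evals > max(evals.max(), 0) * 1e-12) < n_components:
        raise ConfigurationError(f"feature rank < {n_components}; PCA front end undefined")
    comps = evecs[:, order].T  # (k, d)
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAProjection(mean=mean, components=comps,
                         explained_variance=evals[order])


@dataclass
class HMMParams:
    """Fitted click-decoder parameters (PCA + Gaussian emissions + transitions)."""

    projection: PCAProjection
    means: np.ndarray        # (2, 4) per-state emission means
    covariances: np.ndarray  # (2, 4, 4) per-state SPD covariances
    transition: np.ndarray   # (2, 2), rows sum to 1
    click_threshold: float = 0.5
    consecutive_bins_required: int = 2
    _chol: np.ndarray | None = field(default=None, repr=False)
    _logdet: np.ndarray | None = field(default=None, repr=False)
    _precision: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigurationError("transition rows must sum to 1")
        self._chol = np.array([np.linalg.cholesky(c) for c in self.covariances])
        self._logdet = np.array([2.0 * np.sum(np.log(np.diag(L))) for L in self._chol])
        self._precision = np.array([np.linalg.inv(c) for c in self.covariances])

    def log_likelihoods(self, y: np.ndarray) -> np.ndarray:
        """log p(y | state) for both states at one projected bin."""
        out = np.empty(2)
        k = self.means.shape[1]
        const = -0.5 * k * np.log(2.0 * np.pi)
        for s in range(2):
            d = y - self.means[s]
            out[s] = const - 0.5 * self._logdet[s] - 0.5 * float(d @ self._precision[s] @ d)
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite emission log-likelihood")
        return out

    def to_json(self) -> str:
        return json.dumps({
            "schema": "bcisim.hmm.v1",
            "pca_mean": self.projection.mean.tolist(),
            "pca_components": self.projection.components.tolist(),
            "pca_explained": self.projection.explained_variance.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "transition": self.transition.tolist(),
            "click_threshold": self.click_threshold,
            "consecutive_bins_required": self.consecutive_bins_required,
        })

    @classmethod
    def from_json(cls, text: str) -> "HMMParams":
        d = json.loads(text)
        if d.get("schema") != "bcisim.hmm.v1":
            raise ValueError("unrecognised decoder file schema")
        proj = PCAProjection(
            mean=np.array(d["pca_mean"]),
            components=np.array(d["pca_components"]),
            explained_variance=np.array(d["pca_explained"]),
        )
        return cls(
            projection=proj, means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            transition=np.array(d["transition"]),
            click_threshold=float(d["click_threshold"]),
            consecutive_bins_required=int(d["consecutive_bins_required"]),
        )


@dataclass(frozen=True)
class StateProbs:
    """Filtered posterior over (move, click) for one bin; sums to 1."""

    p_move: float
    p_click: float
    time: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.p_move, self.p_click])


def fit_hmm(
    Y: np.ndarray,
    labels: np.ndarray,
    pseudocount: float = 1.0,
    cov_ridge: float = 1e-9,
) -> HMMParams:
    """Supervised fit from projected calibration bins and move/click labels.

    Emissions are the per-label Gaussian mean and covariance; the transition
    matrix comes from label bigram frequencies with a configurable
    pseudocount (so neither cross-transition is ever exactly zero).

    The PCA projection is attached by :func:`fit_click_decoder`; this
    function operates purely in the projected space.
    """
    Y = np.asarray(Y, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if Y.shape[0] != lab.shape[0]:
        raise ValueError("one label per projected bin required")
    k = Y.shape[1]
    means = np.zeros((2, k))
    covs = np.zeros((2, k, k))
    for s in (MOVE, CLICK):
        sel = Y[lab == s]
        if sel.shape[0] < 10:
            raise ConfigurationError(
                f"state {s} has {sel.shape[0]} labelled bins; need >= 10"
            )
        means[s] = sel.mean(axis=0)
        c = np.cov(sel.T)
        covs[s] = c + cov_ridge * np.trace(c) / k * np.eye(k) + 1e-12 * np.eye(k)
    counts = np.full((2, 2), pseudocount, dtype=float)
    np.add.at(counts, (lab[:-1], lab[1:]), 1.0)
    transition = counts / counts.sum(axis=1, keepdims=True)
    proj = PCAProjection(mean=np.zeros(1), components=np.zeros((1, 1)),
                         explained_variance=np.zeros(1))
    return HMMParams(projection=proj, means=means, covariances=covs,
                     transition=transition)


def fit_click_decoder(
    X: np.ndarray,
    labels: np.ndarray,
    pseudocount: float = 1.0,
) -> HMMParams:
    """PCA front end + supervised HMM fit from raw calibration features."""
    proj = fit_pca(X)
    params = fit_hmm(proj.transform(X), labels, pseudocount=pseudocount)
    params.projection = proj
    return params


def hmm_step(params: HMMParams, y: np.ndarray, prev: StateProbs) -> StateProbs:
    """One step of the filtered recursion, renormalized across the two states.

    Implemented with a max-shift in the log domain so emission likelihoods
    down to 1e-300 (and far below) remain numerically stable.
    """
    loglik = params.log_likelihoods(np.asarray(y, dtype=float))
    prior = params.transition.T @ prev.as_array()  # sum_i p(s_k|s_i) p(s_i)
    logpost = loglik + np.log(np.maximum(prior, 1e-300))
    logpost -= logpost.max()
    post = np.exp(logpost)
    post /= post.sum()
    return StateProbs(p_move=float(post[MOVE]), p_click=float(post[CLICK]),
                      time=prev.time + 0.015)


def forward_filter(
    params: HMMParams,
    Y: np.ndarray,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Batch filtered posteriors for a whole projected stream; (T, 2)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    probs = np.empty((Y.shape[0], 2))
    state = StateProbs(0.5, 0.5) if initial is None else StateProbs(*initial)
    for t in range(Y.shape[0]):
        state = hmm_step(params, Y[t], state)
        probs[t] = state.as_array()
    return probs


def calibrate_click_threshold(p_click: np.ndarray, quantile: float = 0.93) -> float:
    """Unsupervised threshold at the 93rd quantile of click-state posteriors.

    Computed over the retraining block's per-bin click probabilities with
    linear interpolation between order statistics, so by construction 7% of
    the calibration bins lie above it.
    """
    p = np.asarray(p_click, dtype=float)
    if p.size < 100:
        raise ConfigurationError("need >= 100 calibration bins for the threshold")
    if np.ptp(p) == 0.0:
        raise ConfigurationError("degenerate (constant) click-probability stream")
    return float(np.quantile(p, quantile))


class ClickDetector:
    """Consecutive-bin counter automaton for streaming click generation.

    Emits a click on the ``consecutive``-th consecutive above-threshold bin
    and then re-arms (the counter resets), so a sustained excursion yields
    at most one click per ``consecutive`` bins.
    """

    def __init__(self, threshold: float, consecutive: int = 2):
        self.threshold = threshold
        self.consecutive = consecutive
        self._run = 0

    def reset(self) -> None:
        self._run = 0

    def step(self, p_click: float) -> bool:
        if p_click > self.threshold:
            self._run += 1
            if self._run >= self.consecutive:
                self._run = 0
                return True
        else:
            self._run = 0
        return False


def detect_click(
    p_click: np.ndarray,
    params: HMMParams | None = None,
    threshold: float | None = None,
    consecutive: int | None = None,
) -> np.ndarray:
    """Click event bin indices for a time-ordered probability stream."""
    thr = threshold if threshold is not None else params.click_threshold
    need = consecutive if consecutive is not None else (
        params.consecutive_bins_required if params is not None else 2
    )
    det = ClickDetector(thr, need)
    return np.array(
        [t for t, p in enumerate(np.asarray(p_click, dtype=float)) if det.step(p)],
        dtype=int,
    )
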