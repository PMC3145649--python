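"""Latent-class mixture model for multi-source interaction scores.

A score matrix ``Y`` (n protein pairs x p data sources) is modelled with a
binary latent interaction status ``z_i`` per pair and, within each source
``j``, a pair of score densities

    f_0j  — scores of non-interacting pairs,
    f_1j  — scores of interacting pairs,

each an H-component Gaussian mixture sharing weights ``pi_h`` and precisions
``tau_h`` across sources and statuses, with component locations

    mu_{h,0,j}               (non-interacting)
    mu_{h,1,j} = mu_{h,0,j} + delta_{h,j},   delta_{h,j} >= 0,

so that f_0j is stochastically smaller than f_1j: high scores are evidence
of interaction.  The posterior probability of interaction for a pair with
score row y is

    P(z=1 | y) = nu * prod_j f_1j(y_j) /
                 [nu * prod_j f_1j(y_j) + (1 - nu) * prod_j f_0j(y_j)],

with nu the prior interaction probability.  This module holds the data
containers and this likelihood arithmetic; the sampler that fits the
mixture lives in :mod:`nbel.gibbs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ScoreMatrix",
    "Hyperparams",
    "MixtureState",
    "PosteriorSummary",
    "normalize_columns",
    "mixture_density",
    "posterior_interaction_prob",
    "classify",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ScoreMatrix:
    """An n x p table of real-valued interaction scores with pair identifiers.

    ``scores[i, j]`` is the score of pair ``pair_ids[i]`` in data source j.
    Missing entries are not representable: any non-finite value raises at
    construction.  ``column_stats`` holds the (mean, sd) used by
    :func:`normalize_columns` so the transform is invertible.
    """

    pair_ids: list
    scores: np.ndarray
    normalized: bool = False
    column_stats: np.ndarray | None = None  # shape (2, p): row 0 means, row 1 sds

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D array (pairs x sources)")
        n, p = self.scores.shape
        if n < 1 or p < 1:
            raise ValueError(f"need at least one pair and one source, got {n}x{p}")
        if len(self.pair_ids) != n:
            raise ValueError(
                f"{len(self.pair_ids)} pair identifiers for {n} score rows"
            )
        if not np.all(np.isfinite(self.scores)):
            bad = np.argwhere(~np.isfinite(self.scores))[0]
            raise ValueError(
                "non-finite score at row "
                f"{bad[0]} (pair {self.pair_ids[bad[0]]!r}), column {bad[1]}; "
                "missing values must be resolved before analysis"
            )

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def p(self) -> int:
        return self.scores.shape[1]


@dataclass
class Hyperparams:
    """Prior constants and MCMC settings for the truncated mixture model.

    Defaults are weakly informative on column-standardised scores:
    stick-breaking concentration ``alpha``; Normal(mu0, 1/kappa) prior on
    baseline locations; Gamma(a_tau, b_tau) (shape/rate) on component
    precisions; half-Normal(0, a_delta_var) on the nonnegative ordering
    offsets; Beta(a_nu, b_nu) on the interaction proportion nu, unless
    ``nu_fixed`` pins it.
    """

    H: int = 20
    alpha: float = 1.0
    mu0: float = 0.0
    kappa: float = 1.0
    a_tau: float = 1.0
    b_tau: float = 1.0
    # offsets on standardised scores are group separations, O(1-3), so the
    # half-normal prior uses sd 2; a unit-variance prior over-shrinks them
    a_delta_var: float = 4.0
    a_nu: float = 1.0
    b_nu: float = 1.0
    nu_fixed: float | None = None
    n_iter: int = 5000
    n_burn: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.H < 2:
            raise ValueError("truncation level H must be >= 2")
        for name in ("alpha", "kappa", "a_tau", "b_tau", "a_delta_var", "a_nu", "b_nu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nu_fixed is not None and not (0.0 < self.nu_fixed < 1.0):
            raise ValueError("nu_fixed must lie strictly in (0, 1)")
        if not (self.n_iter > self.n_burn >= 0):
            raise ValueError("need n_iter > n_burn >= 0")


@dataclass
class MixtureState:
    """One iterate of the mixture model's unknowns.

    ``pi``: (H,) stick-breaking weights; ``tau``: (H,) precisions;
    ``mu0loc``: (H, p) non-interacting locations; ``delta``: (H, p)
    nonnegative offsets (interacting locations are ``mu0loc + delta``);
    ``z``: (n,) latent 0/1 statuses; ``nu``: interaction proportion;
    ``comp``: (n,) component allocations in 0..H-1 (sampler bookkeeping).
    """

    pi: np.ndarray
    tau: np.ndarray
    mu0loc: np.ndarray
    delta: np.ndarray
    z: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    nu: float = 0.5
    comp: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.mu0loc = np.atleast_2d(np.asarray(self.mu0loc, dtype=float))
        self.delta = np.atleast_2d(np.asarray(self.delta, dtype=float))

    @property
    def H(self) -> int:
        return self.pi.shape[0]

    @property
    def p(self) -> int:
        return self.mu0loc.shape[1]

    def validate(self) -> None:
        H, p = self.H, self.p
        if self.tau.shape != (H,) or self.mu0loc.shape != (H, p) or self.delta.shape != (H, p):
            raise ValueError("inconsistent shapes in MixtureState")
        if abs(self.pi.sum() - 1.0) > 1e-10 or np.any(self.pi < 0):
            raise ValueError("pi must be a simplex (sum 1 within 1e-10)")
        if np.any(self.tau <= 0):
            raise ValueError("all precisions tau must be positive")
        if np.any(self.delta < 0):
            raise ValueError("ordering offsets delta must be nonnegative")
        if not (0.0 < self.nu < 1.0):
            raise ValueError("nu must lie in (0, 1)")
        if self.z.size and not np.isin(self.z, (0, 1)).all():
            raise ValueError("z must be binary")
        if self.comp.size and (self.comp.min() < 0 or self.comp.max() >= H):
            raise ValueError("component allocations out of range")

    def locations(self, status: int) -> np.ndarray:
        """(H, p) component locations for the given interaction status."""
        if status not in (0, 1):
            raise ValueError(f"interaction status must be 0 or 1, got {status!r}")
        return self.mu0loc + status * self.delta


@dataclass
class PosteriorSummary:
    """Rao-Blackwellised posterior interaction probabilities and calls."""

    prob: np.ndarray
    zhat: np.ndarray
    threshold: float = 0.5
    n_iter_used: int = 0

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValueError("posterior probabilities must lie in [0, 1]")


def normalize_columns(sm: ScoreMatrix, log_transform: bool = False) -> ScoreMatrix:
    """Standardise each source column to mean 0 and unit sample variance.

    With ``log_transform=True`` the (strictly positive) raw likelihood-ratio
    scores are log-transformed first; simulated scores are already on the
    real line and skip the log.  Uses the n-1 sample-variance convention.
    The per-column (mean, sd) pairs are stored for inverse transformation.
    """
    if sm.normalized:
        raise ValueError("score matrix is already normalized")
    x = sm.scores
    if log_transform:
        if np.any(x <= 0):
            bad = np.argwhere(x <= 0)[0]
            raise ValueError(
                f"log transform requires positive scores; row {bad[0]}, column {bad[1]}"
            )
        x = np.log(x)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if sm.n > 1 else np.zeros(sm.p)
    zero = np.flatnonzero(sd < 1e-12)
    if zero.size:
        raise ValueError(f"column {zero[0]} has zero variance; cannot standardise")
    out = (x - mu) / sd
    return ScoreMatrix(
        pair_ids=list(sm.pair_ids),
        scores=out,
        normalized=True,
        column_stats=np.vstack([mu, sd]),
    )


def _component_logpdfs(y: float | np.ndarray, j: int, status: int, state: MixtureState) -> np.ndarray:
    """Log N(y; mu_{h,status,j}, 1/tau_h) for every component h."""
    if not 0 <= j < state.p:
        raise ValueError(f"source index {j} out of range for p={state.p}")
    loc = state.locations(status)[:, j]
    y = np.asarray(y, dtype=float)
    return 0.5 * (np.log(state.tau) - _LOG_2PI) - 0.5 * state.tau * (y[..., None] - loc) ** 2


def mixture_density(y: float, j: int, status: int, state: MixtureState) -> float:
    """Mixture density f_{status,j}(y) = sum_h pi_h N(y; mu_{h,status,j}, 1/tau_h)."""
    lp = _component_logpdfs(y, j, status, state)
    return float(np.exp(logsumexp(lp, b=state.pi, axis=-1)))


def _log_joint(row: np.ndarray, status: int, state: MixtureState) -> float:
    """log prod_j f_{status,j}(y_j), accumulated in log space."""
    total = 0.0
    for j in range(state.p):
        total += logsumexp(_component_logpdfs(row[j], j, status, state), b=state.pi)
    return float(total)


def posterior_interaction_prob(row: np.ndarray, state: MixtureState, nu_i: float) -> float:
    """Posterior interaction probability for one score row.

    Evaluates nu * prod_j f_1j / (nu * prod_j f_1j + (1-nu) * prod_j f_0j)
    in log space, so products over many sources cannot underflow.
    """
    if not (0.0 < nu_i < 1.0):
        raise ValueError("prior interaction probability nu_i must lie in (0, 1)")
    row = np.asarray(row, dtype=float)
    if row.shape != (state.p,):
        raise ValueError(f"score row has shape {row.shape}, expected ({state.p},)")
    a1 = np.log(nu_i) + _log_joint(row, 1, state)
    a0 = np.log1p(-nu_i) + _log_joint(row, 0, state)
    # logistic of the log posterior odds
    return float(1.0 / (1.0 + np.exp(a0 - a1)))


def classify(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """0-1-loss Bayes rule: call interaction iff prob strictly exceeds threshold.

    Ties at the threshold are classified non-interacting (conservative for
    false-positive control).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("classification threshold must lie in (0, 1)")
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs > threshold).astype(np.int64)
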