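"""The Mk model: equal-rates CTMC machinery for a k-state discrete trait.

The character (here, cutting preference with states dicot / grass /
dicot-grass) evolves along the tree as a continuous-time Markov chain with
rate matrix Q.  Under the equal-rates (ER) parameterization every
off-diagonal entry shares a single rate q per unit time:

    Q_ij = q (i != j),   Q_ii = -(k-1) q

whose transition probabilities have the closed form

    P_ii(t) = 1/k + (1 - 1/k) exp(-k q t)
    P_ij(t) = 1/k - (1/k)     exp(-k q t)

ER with a uniform root prior is time-reversible with uniform stationary
distribution, which is what licenses the re-rooting method for marginal
ancestral states.

Tip data enter as per-tip likelihood vectors (indicator for a known state,
all-ones for an ambiguous observation); :func:`pruning_log_likelihood`
evaluates the Felsenstein pruning recursion with per-node scaling, and
:func:`fit_er_rate` maximizes it over q by bounded 1-D optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .tree_io import Chronogram


def build_er_q(k: int, q: float) -> np.ndarray:
    """Equal-rates rate matrix: off-diagonals q, diagonal -(k-1)q."""
    if k < 2:
        raise ValueError(f"Mk model needs k >= 2 states, got k={k}")
    if q <= 0:
        raise ValueError(f"rate q must be positive, got {q}")
    Q = np.full((k, k), float(q))
    np.fill_diagonal(Q, -(k - 1) * float(q))
    return Q


def er_transition_matrix(k: int, q: float, t: float) -> np.ndarray:
    """Closed-form ER transition probabilities P(t)."""
    if t < 0:
        raise ValueError(f"time t must be nonnegative, got {t}")
    e = np.exp(-k * q * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, 1.0 / k + (1.0 - 1.0 / k) * e)
    return P


def _is_er(Q: np.ndarray) -> bool:
    off = Q[~np.eye(Q.shape[0], dtype=bool)]
    return off.size > 0 and np.allclose(off, off[0], rtol=1e-12, atol=0.0)


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Qt); closed form when Q has the ER structure."""
    if t < 0:
        raise ValueError(f"time t must be nonnegative, got {t}")
    k = Q.shape[0]
    if t == 0:
        return np.eye(k)
    if _is_er(Q):
        q = Q[0, 1]
        return er_transition_matrix(k, q, t)
    return expm(Q * t)


@dataclass(frozen=True)
class MkModel:
    """k-state equal-rates Mk model with a root prior.

    Parameters
    ----------
    state_labels
        Ordered state names; k = len(state_labels).
    q
        Instantaneous rate of each off-diagonal transition, per time unit.
    root_prior
        Length-k simplex vector; defaults to uniform, which equals the ER
        stationary distribution and keeps the model time-reversible.
    """

    state_labels: tuple[str, ...]
    q: float
    root_prior: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("MkModel needs at least 2 states")
        if self.q <= 0:
            raise ValueError(f"rate q must be positive, got {self.q}")
        if self.root_prior is not None:
            pi = np.asarray(self.root_prior, dtype=float)
            if pi.shape != (self.k,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
                raise ValueError("root_prior must be a length-k simplex vector")

    @property
    def k(self) -> int:
        return len(self.state_labels)

    @property
    def Q(self) -> np.ndarray:
        return build_er_q(self.k, self.q)

    @property
    def pi(self) -> np.ndarray:
        if self.root_prior is None:
            return np.full(self.k, 1.0 / self.k)
        return np.asarray(self.root_prior, dtype=float)

    def transition_matrix(self, t: float) -> np.ndarray:
        return er_transition_matrix(self.k, self.q, t)

    def is_reversible(self, tol: float = 1e-9) -> bool:
        """Detailed balance pi_i Q_ij == pi_j Q_ji with pi stationary."""
        pi, Q = self.pi, self.Q
        if not np.allclose(pi @ Q, 0.0, atol=tol):
            return False
        M = pi[:, None] * Q
        return bool(np.allclose(M, M.T, atol=tol))

    def with_rate(self, q: float) -> "MkModel":
        return MkModel(self.state_labels, q, self.root_prior)


@dataclass
class LikelihoodResult:
    """Pruning output: log L, scaled per-node partials, optional fitted rate."""

    log_likelihood: float
    q_hat: float | None = None
    partials: dict[int, np.ndarray] = field(default_factory=dict)
    n_tips_used: int = 0


def _prepare_tip_vectors(tree: Chronogram, tip_vectors, k: int) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    missing = []
    for tip in tree.tips():
        if tip.label not in tip_vectors:
            missing.append(tip.label)
            continue
        v = np.asarray(tip_vectors[tip.label], dtype=float)
        if v.shape != (k,):
            raise ValidationError(
                f"tip vector for {tip.label} has shape {v.shape}, expected ({k},)"
            )
        if np.all(v == 0):
            raise ValidationError(
                f"tip {tip.label} has an all-zero vector (impossible observation)"
            )
        out[tip.id] = v
    if missing:
        raise ValidationError("tips without state vectors: " + ", ".join(sorted(missing)))
    return out


def pruning_log_likelihood(
    tree: Chronogram, tip_vectors, model: MkModel
) -> LikelihoodResult:
    """Felsenstein pruning pass; retains scaled per-node partials.

    Each node's conditional-likelihood vector is rescaled by its maximum, with
    the log-scalers accumulated into the final log-likelihood, so deep trees
    (<= ~10^4 tips) do not underflow.  The stored ``partials`` are the scaled
    vectors; downstream uses (ancestral states, joint node sampling) only need
    them up to a per-node positive constant.
    """
    k = model.k
    vecs = _prepare_tip_vectors(tree, tip_vectors, k)
    partials: dict[int, np.ndarray] = {}
    log_scale = 0.0
    # transition matrices cached per distinct branch length
    P_cache: dict[float, np.ndarray] = {}

    def P(t: float) -> np.ndarray:
        got = P_cache.get(t)
        if got is None:
            got = model.transition_matrix(t)
            P_cache[t] = got
        return got

    for node in tree.postorder():
        if node.is_tip:
            partials[node.id] = vecs[node.id]
            continue
        d = np.ones(k)
        for child in node.children:
            d = d * (P(child.length or 0.0) @ partials[child.id])
        m = d.max()
        if m <= 0:
            raise ValidationError("zero likelihood: contradictory tip observations")
        partials[node.id] = d / m
        log_scale += np.log(m)
    lik = float(model.pi @ partials[tree.root.id])
    return LikelihoodResult(
        log_likelihood=float(np.log(lik) + log_scale),
        partials=partials,
        n_tips_used=tree.n_tips,
    )


#: Scale-free optimization bracket for q, relative to 1/T (T = root age).
Q_LO_FACTOR = 1e-8
Q_HI_FACTOR = 1e3


def fit_er_rate(
    tree: Chronogram,
    tip_vectors,
    state_labels: tuple[str, ...],
    *,
    root_prior=None,
    bounds: tuple[float, float] | None = None,
) -> LikelihoodResult:
    """Maximum-likelihood estimate of the ER rate q.

    Optimizes the pruning log-likelihood over log q on a bounded bracket
    ``[1e-8/T, 1e3/T]`` (T = root age), covering effectively-frozen through
    saturated regimes regardless of the tree's time units.  Deterministic for
    fixed inputs.

    If every tip carries the same certain state the likelihood is monotone
    decreasing in q; a warning is issued and the lower bound returned.
    """
    k = len(state_labels)
    vecs = _prepare_tip_vectors(tree, tip_vectors, k)
    informative = [v for v in vecs.values() if np.unique(v).size > 1]
    if len(informative) < 2:
        raise ValidationError(
            "rate fitting needs at least 2 tips with non-uniform state vectors"
        )
    if tree.total_branch_length <= 0:
        raise ValidationError("tree has no positive branch length")
    T = max(tree.root_age, np.finfo(float).tiny)
    q_lo, q_hi = bounds if bounds is not None else (Q_LO_FACTOR / T, Q_HI_FACTOR / T)

    def result_at(q: float) -> LikelihoodResult:
        model = MkModel(tuple(state_labels), q, root_prior)
        res = pruning_log_likelihood(tree, tip_vectors, model)
        res.q_hat = q
        return res

    rows = [vecs[t.id] for t in tree.tips()]
    certain = [np.argmax(r) for r in rows if np.count_nonzero(r) == 1]
    if len(certain) == len(rows) and len(set(certain)) == 1:
        warnings.warn(
            "all tips share one certain state; no transitions observed, "
            "returning the lower rate bound",
            stacklevel=2,
        )
        return result_at(q_lo)

    def neg_ll(x: float) -> float:
        model = MkModel(tuple(state_labels), float(np.exp(x)), root_prior)
        return -pruning_log_likelihood(tree, tip_vectors, model).log_likelihood

    opt = minimize_scalar(
        neg_ll,
        bounds=(np.log(q_lo), np.log(q_hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return result_at(float(np.exp(opt.x)))
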