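"""Jump-process parameterization of synchronous synaptic input.

Synaptic drive is modeled as a compound Poisson process: synaptic *events*
occur at Poisson times with rate ``b`` and, at each event, a random subset of
the inputs coactivates.  The total dimensionless conductance jump delivered to
neuron ``a`` at an event is ``(We_a, Wi_a)``, the weighted sum of the active
excitatory and inhibitory inputs.  Input synchrony is entirely encoded in the
joint distribution of these jumps; the spiking correlation between two inputs
is the ``dt -> 0`` limit of the Pearson correlation of their binned spike
counts, which reduces to

    rho_{k,l} = E[X_k X_l] / sqrt(E[X_k] E[X_l])

over the per-event activation indicators ``X_k``, and more generally for
``n`` inputs to ``E[X_k1 ... X_kn] / (E[X_k1] ... E[X_kn])**(1/n)``.  These
coefficients are nonnegative by construction: the framework represents
positive spiking correlations only.

Three jump-model backends are provided: exact enumeration over discrete
atoms, exact summation over the event-count distribution of the exchangeable
beta-binomial model, and seeded Monte Carlo for models that are only
available through a sampler.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import betaln, gammaln, psi

__all__ = [
    "InputPool",
    "CorrelationSpec",
    "BetaBinomialModel",
    "JumpModel",
    "DiscreteJumpModel",
    "SampledJumpModel",
    "DegenerateInputError",
    "pairwise_correlation",
    "higher_order_correlation",
    "coactivation_moment",
    "collective_event_rate",
    "pair_event_rate",
    "subsample_rate",
    "faulty_transmission_transform",
    "jump_expectation",
]


class DegenerateInputError(ValueError):
    """Raised when a spiking correlation is requested for an input that never
    activates, so that the correlation coefficient is undefined."""


# ---------------------------------------------------------------------------
# input pools and correlation structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputPool:
    """A homogeneous-by-type pool of synaptic inputs.

    ``kind`` is ``"e"`` or ``"i"``; ``weights`` and ``rates`` may be scalars
    (uniform pool) or per-input arrays of length ``K``.  Weights are the
    dimensionless efficacies ``w = g * tau_s / C``; rates are in Hz.
    """

    kind: str
    K: int
    weights: float | Sequence[float] = 0.0
    rates: float | Sequence[float] = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("e", "i"):
            raise ValueError(f"pool kind must be 'e' or 'i', got {self.kind!r}")
        if self.K < 0:
            raise ValueError("pool size K must be nonnegative")
        if np.any(self.weight_array < 0):
            raise ValueError("synaptic weights must be nonnegative")
        if np.any(self.rate_array < 0):
            raise ValueError("input rates must be nonnegative")

    @property
    def weight_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.weights, dtype=float), (self.K,))

    @property
    def rate_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.rates, dtype=float), (self.K,))


@dataclass(frozen=True)
class CorrelationSpec:
    """Block-structured pairwise spiking correlations across ``L`` homogeneous
    input subpopulations.

    ``block_rho[i, j]`` is the spiking correlation between any input of
    subpopulation ``i`` and any input of subpopulation ``j`` (within-block
    values on the diagonal).  ``assignment`` maps ``(neuron, pool)`` keys to
    subpopulation indices for bookkeeping in multi-neuron models.
    """

    block_rho: np.ndarray
    assignment: dict | None = None

    def __post_init__(self) -> None:
        rho = np.atleast_2d(np.asarray(self.block_rho, dtype=float))
        object.__setattr__(self, "block_rho", rho)
        if rho.shape[0] != rho.shape[1]:
            raise ValueError("block_rho must be square")
        if not np.allclose(rho, rho.T):
            raise ValueError("block_rho must be symmetric")
        if np.any(rho < 0):
            raise ValueError("spiking correlations must be nonnegative")
        d = np.diag(rho)
        if np.any(d <= 0) or np.any(d > 1):
            raise ValueError("diagonal correlations must lie in (0, 1]")
        # cross-block coefficients are bounded by the geometric mean of the
        # within-block ones (admissibility of the joint activation law)
        bound = np.sqrt(np.outer(d, d))
        if np.any(rho > bound + 1e-12):
            raise ValueError("cross-block correlation exceeds sqrt(rho_i * rho_j)")

    @property
    def L(self) -> int:
        return self.block_rho.shape[0]


# ---------------------------------------------------------------------------
# beta-binomial exchangeable synchrony
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaBinomialModel:
    """Exchangeable synchronous pool with beta-distributed event sizes.

    ``K`` inputs fire at individual rate ``r`` with uniform pairwise spiking
    correlation ``rho = 1/(1 + beta)``.  Conditional on a synaptic event, the
    number ``k >= 1`` of coactivating inputs follows

        p(k)  proportional to  C(K, k) * B(k, K - k + beta),

    the ``alpha -> 0`` limit of beta-binomial bin counts, and the event rate
    is ``b = r * beta * (psi(K + beta) - psi(beta))`` (digamma function
    ``psi``), which grows like ``beta * r * ln K`` for large pools.
    """

    K: int
    rho: float
    r: float

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")
        if not self.r > 0:
            raise ValueError("rate must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / self.rho - 1.0

    @property
    def event_rate(self) -> float:
        return collective_event_rate(self, self.K)

    def count_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Distribution of the number of coactive inputs per synaptic event.

        Returns ``(k, p)`` with ``k = 1..K``; exact up to floating point.
        """
        ks = np.arange(1, self.K + 1)
        if self.rho == 1.0:
            p = np.zeros(self.K)
            p[-1] = 1.0
            return ks, p
        b = self.beta
        logp = (
            gammaln(self.K + 1)
            - gammaln(ks + 1)
            - gammaln(self.K - ks + 1)
            + betaln(ks, self.K - ks + b)
        )
        p = np.exp(logp - logp.max())
        return ks, p / p.sum()

    # -- event-level activation moments (exchangeable inputs) ----------------

    def activation_probability(self, _input=None) -> float:
        ks, p = self.count_pmf()
        return float(np.sum(p * ks) / self.K)

    def activation_moment(self, inputs: Sequence) -> float:
        """``E[X_k1 ... X_kn]`` per event, for ``n`` *distinct* inputs."""
        n = len(inputs)
        if len(set(inputs)) != n:
            raise ValueError("inputs must be distinct")
        if n > self.K:
            return 0.0
        ks, p = self.count_pmf()
        num = np.ones_like(ks, dtype=float)
        den = 1.0
        for j in range(n):
            num = num * (ks - j)
            den *= self.K - j
        return float(np.sum(p * np.clip(num, 0.0, None)) / den)


def collective_event_rate(bb: BetaBinomialModel, K_subset: int) -> float:
    """Rate of synaptic events experienced collectively by ``K_subset`` of the
    pool's inputs: ``r * beta * (psi(K + beta) - psi(beta))``.

    Equals ``r`` for a single input and grows like ``beta * r * ln K``;
    sublinear growth is the signature of synchrony (coactivations are counted
    once).  For ``rho -> 0`` (``beta -> inf``) it tends to the additive rate
    ``K * r``.
    """
    if K_subset < 1:
        raise ValueError("K_subset must be >= 1")
    if K_subset > bb.K:
        raise ValueError("K_subset exceeds pool size")
    if bb.rho == 1.0:
        return bb.r
    b = bb.beta
    return float(bb.r * b * (psi(K_subset + b) - psi(b)))


# ---------------------------------------------------------------------------
# jump models
# ---------------------------------------------------------------------------


class JumpModel:
    """Joint distribution of per-event conductance jumps for a neuron set.

    Concrete backends implement :meth:`expect`, the expectation of a
    functional of the jump vectors ``(We_a, Wi_a)`` for the labeled neurons,
    returning ``(value, standard_error)``; exact backends report a standard
    error of zero.
    """

    labels: tuple
    rate: float

    @property
    def n_neurons(self) -> int:
        return len(self.labels)

    def expect(self, f: Callable[[np.ndarray, np.ndarray], np.ndarray]):
        raise NotImplementedError

    def index_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"neuron label {label!r} not in model") from None


@dataclass(frozen=True)
class DiscreteJumpModel(JumpModel):
    """Jump model supported on finitely many atoms; all expectations exact.

    ``We`` and ``Wi`` have shape ``(n_atoms, n_neurons)``; ``probs`` sums to
    one.  Optionally carries the per-event activation indicators of the
    individual inputs (``activations``, shape ``(n_atoms, n_inputs)``) so
    spiking correlations of any order can be evaluated.
    """

    labels: tuple
    rate: float
    We: np.ndarray
    Wi: np.ndarray
    probs: np.ndarray
    input_labels: tuple | None = None
    activations: np.ndarray | None = None

    def __post_init__(self) -> None:
        We = np.atleast_2d(np.asarray(self.We, dtype=float))
        Wi = np.atleast_2d(np.asarray(self.Wi, dtype=float))
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "We", We)
        object.__setattr__(self, "Wi", Wi)
        object.__setattr__(self, "probs", probs)
        if We.shape != Wi.shape or We.shape[0] != probs.size:
            raise ValueError("inconsistent atom array shapes")
        if We.shape[1] != len(self.labels):
            raise ValueError("jump arrays must have one column per neuron")
        if not self.rate > 0:
            raise ValueError("event rate must be positive")
        if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("atom probabilities must be nonnegative and sum to 1")
        if np.any(We < 0) or np.any(Wi < 0):
            raise ValueError("jump components must be nonnegative")
        total = We.sum(axis=1) + Wi.sum(axis=1)
        if np.any(total <= 0):
            raise ValueError("every atom must deliver input to at least one neuron")

    # -- expectations --------------------------------------------------------

    def expect(self, f):
        vals = np.asarray(f(self.We, self.Wi), dtype=float)
        return float(np.sum(self.probs * vals)), 0.0

    # -- activation-level quantities ----------------------------------------

    def _input_index(self, label) -> int:
        if self.input_labels is None or self.activations is None:
            raise ValueError("model does not carry per-input activations")
        try:
            return self.input_labels.index(label)
        except ValueError:
            raise KeyError(f"input label {label!r} not in model") from None

    def activation_probability(self, input_label) -> float:
        j = self._input_index(input_label)
        return float(np.sum(self.probs * self.activations[:, j]))

    def activation_moment(self, inputs: Sequence) -> float:
        idx = [self._input_index(lab) for lab in inputs]
        prod = np.prod(self.activations[:, idx], axis=1)
        return float(np.sum(self.probs * prod))

    # -- structure -----------------------------------------------------------

    def subsample(self, subset: Sequence) -> "DiscreteJumpModel":
        """Restrict to a subset of neurons, dropping events that deliver no
        input to the subset and rescaling the event rate accordingly."""
        if len(subset) == 0:
            raise ValueError("subset must be nonempty")
        cols = [self.index_of(a) for a in subset]
        We, Wi = self.We[:, cols], self.Wi[:, cols]
        hit = (We.sum(axis=1) + Wi.sum(axis=1)) > 0
        mass = float(np.sum(self.probs[hit]))
        if mass == 0:
            raise ValueError("subset receives no input")
        return DiscreteJumpModel(
            labels=tuple(subset),
            rate=self.rate * mass,
            We=We[hit],
            Wi=Wi[hit],
            probs=self.probs[hit] / mass,
            input_labels=self.input_labels,
            activations=None if self.activations is None else self.activations[hit],
        )

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        idx = rng.choice(self.probs.size, size=n, p=self.probs)
        return self.We[idx], self.Wi[idx]

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": list(self.labels),
                "rate": self.rate,
                "atoms": [
                    {"We": we.tolist(), "Wi": wi.tolist(), "p": float(p)}
                    for we, wi, p in zip(self.We, self.Wi, self.probs)
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscreteJumpModel":
        d = json.loads(text)
        return cls(
            labels=tuple(d["labels"]),
            rate=d["rate"],
            We=np.array([a["We"] for a in d["atoms"]]),
            Wi=np.array([a["Wi"] for a in d["atoms"]]),
            probs=np.array([a["p"] for a in d["atoms"]]),
        )

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_asynchronous_pools(cls, pools: Sequence[InputPool], label=0) -> "DiscreteJumpModel":
        """Independent inputs: every event is a single spike of one input, the
        event rate is the additive rate and input ``k`` is the active one with
        probability ``r_k / b``."""
        ws, rs, kinds, in_labels = [], [], [], []
        for ip, pool in enumerate(pools):
            for k in range(pool.K):
                ws.append(pool.weight_array[k])
                rs.append(pool.rate_array[k])
                kinds.append(pool.kind)
                in_labels.append((pool.kind, ip, k))
        rs = np.asarray(rs, float)
        ws = np.asarray(ws, float)
        keep = (rs > 0) & (ws > 0)
        rs, ws = rs[keep], ws[keep]
        kinds = [k for k, m in zip(kinds, keep) if m]
        in_labels = [l for l, m in zip(in_labels, keep) if m]
        b = float(rs.sum())
        if b <= 0:
            raise ValueError("total input rate must be positive")
        n = rs.size
        We = np.zeros((n, 1))
        Wi = np.zeros((n, 1))
        for j, (w, kind) in enumerate(zip(ws, kinds)):
            (We if kind == "e" else Wi)[j, 0] = w
        # the one-hot activation matrix is only worth materializing for
        # moderately sized pools (correlation queries); skip it for huge ones
        small = n <= 4000
        return cls(
            labels=(label,),
            rate=b,
            We=We,
            Wi=Wi,
            probs=rs / b,
            input_labels=tuple(in_labels) if small else None,
            activations=np.eye(n) if small else None,
        )

    @classmethod
    def from_beta_binomial(
        cls, bb: BetaBinomialModel, w: float, kind: str = "e", label=0
    ) -> "DiscreteJumpModel":
        """Single-neuron jump model of a uniform beta-binomial pool: the event
        jump is ``w * k`` with ``k`` drawn from the event-count pmf."""
        ks, p = bb.count_pmf()
        W = (ks * w).reshape(-1, 1)
        zero = np.zeros_like(W)
        return cls(
            labels=(label,),
            rate=bb.event_rate,
            We=W if kind == "e" else zero,
            Wi=zero if kind == "e" else W,
            probs=p,
        )


@dataclass(frozen=True)
class SampledJumpModel(JumpModel):
    """Jump model available only through a sampler; expectations are seeded
    Monte Carlo averages with a reported standard error."""

    labels: tuple
    rate: float
    #: draws ``n`` jump vectors: ``sampler(n, rng) -> (We, Wi)`` of shape
    #: ``(n, n_neurons)``
    sampler: Callable[[int, np.random.Generator], tuple[np.ndarray, np.ndarray]]
    n_draws: int = 1_000_000
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.seed is None:
            raise ValueError("SampledJumpModel requires an explicit seed policy")

    def expect(self, f):
        rng = np.random.default_rng(self.seed)
        We, Wi = self.sampler(self.n_draws, rng)
        vals = np.asarray(f(np.atleast_2d(We), np.atleast_2d(Wi)), dtype=float)
        se = float(vals.std(ddof=1) / math.sqrt(vals.size))
        return float(vals.mean()), se

    def sample(self, n: int, rng: np.random.Generator):
        return self.sampler(n, rng)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def jump_expectation(jm: JumpModel, f) -> tuple[float, float]:
    """Expectation of a functional of the jump vector under ``jm``.

    ``f(We, Wi)`` receives arrays of shape ``(n_draws_or_atoms, n_neurons)``
    and must return one value per row.  Returns ``(value, standard_error)``;
    the standard error is zero on exact (atom or count-pmf) backends.
    """
    return jm.expect(f)


def _activation_model(jm):
    if isinstance(jm, (BetaBinomialModel, DiscreteJumpModel)):
        return jm
    raise TypeError("model does not expose per-input activations")


def coactivation_moment(jm, inputs: Sequence) -> float:
    """Raw per-event coactivation moment ``E[X_k1 ... X_kn]``."""
    return _activation_model(jm).activation_moment(list(inputs))


def higher_order_correlation(jm, inputs: Sequence) -> float:
    """Spiking correlation coefficient of order ``n = len(inputs)``:

        rho = E[X_k1 ... X_kn] / (E[X_k1] ... E[X_kn])**(1/n)

    with expectations over the per-event activation law.  Lies in [0, 1];
    equals the pairwise coefficient for ``n = 2`` and 1 under full synchrony.
    """
    m = _activation_model(jm)
    inputs = list(inputs)
    if len(inputs) < 2:
        raise ValueError("need at least two inputs")
    if isinstance(m, BetaBinomialModel):
        ps = [m.activation_probability() for _ in inputs]
    else:
        ps = [m.activation_probability(lab) for lab in inputs]
    if any(p <= 0 for p in ps):
        raise DegenerateInputError("input never activates; correlation undefined")
    num = m.activation_moment(inputs) if not isinstance(m, BetaBinomialModel) else m.activation_moment(list(range(len(inputs))))
    den = math.prod(ps) ** (1.0 / len(inputs))
    return float(num / den)


def pairwise_correlation(jm, input_a, input_b) -> float:
    """Pairwise spiking correlation between two inputs of the model; the
    ``dt -> 0`` limit of the Pearson correlation of their binned counts."""
    if isinstance(jm, BetaBinomialModel):
        return higher_order_correlation(jm, [0, 1])
    return higher_order_correlation(jm, [input_a, input_b])


def pair_event_rate(b1: float, b2: float, q12: float) -> float:
    """Event rate seen collectively by a neuron pair:
    ``b12 = (b1 + b2) / (1 + q12)``.

    ``q12`` is the probability that both neurons receive input given that at
    least one does; ``q12 = 0`` gives the additive rate, the optimally
    synchronous value ``min/max`` gives ``max(b1, b2)``.
    """
    if b1 <= 0 or b2 <= 0:
        raise ValueError("individual rates must be positive")
    qmax = min(b1, b2) / max(b1, b2)
    if not 0 <= q12 <= qmax + 1e-12:
        raise ValueError(f"q12 must lie in [0, {qmax}], got {q12}")
    return (b1 + b2) / (1.0 + q12)


def subsample_rate(jm: JumpModel, subset: Sequence) -> float:
    """Event rate experienced by a subset of the model's neurons:
    ``b_A = b_B * P[sum_{a in A}(We_a + Wi_a) > 0]``."""
    if len(subset) == 0:
        raise ValueError("subset must be nonempty")
    cols = [jm.index_of(a) for a in subset]

    def hit(We, Wi):
        return (We[:, cols].sum(axis=1) + Wi[:, cols].sum(axis=1) > 0).astype(float)

    p, _ = jm.expect(hit)
    return jm.rate * p


def faulty_transmission_transform(
    pools: Sequence[InputPool],
    corr: CorrelationSpec,
    p,
    compensate: bool = False,
) -> tuple[list[InputPool], CorrelationSpec]:
    """Effective input statistics under all-or-none synaptic failure.

    Each spike of input ``k`` is transmitted with probability ``p_k``
    (independent Bernoulli thinning), which scales the effective rates as
    ``r' = p * r`` and the spiking correlations as
    ``rho'_{kl} = rho_{kl} * sqrt(p_k * p_l)``.  ``p`` is a scalar or one
    value per pool (uniform within a pool, as required for the block
    correlation structure to survive thinning).

    With ``compensate=True`` the pool sizes are enlarged to ``K' = K / p``
    at unchanged weights, which restores the first moment of the drive
    exactly and the small-weight variance and third moment to leading order
    in ``1/K``.
    """
    p_arr = np.broadcast_to(np.asarray(p, dtype=float), (len(pools),)).copy()
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("release probabilities must lie in (0, 1]")
    new_pools = []
    for pool, pk in zip(pools, p_arr):
        rates = np.asarray(pool.rates, dtype=float) * pk
        weights = pool.weights
        K = pool.K
        if compensate:
            if np.unique(pool.rate_array).size > 1 or np.unique(pool.weight_array).size > 1:
                raise ValueError("compensation assumes homogeneous pools")
            K = int(round(pool.K / pk))
            rates = float(pool.rate_array[0]) * pk
            weights = float(pool.weight_array[0])
        new_pools.append(InputPool(kind=pool.kind, K=K, weights=weights, rates=rates))
    if corr.L != len(pools):
        raise ValueError("correlation spec must have one block per pool")
    scale = np.sqrt(np.outer(p_arr, p_arr))
    rho = corr.block_rho * scale
    # within-block diagonal stays at the pairwise value; CorrelationSpec keeps
    # block (off-diagonal pair) coefficients, so plain scaling applies
    return new_pools, CorrelationSpec(block_rho=rho, assignment=corr.assignment)
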