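"""Exact stationary voltage moments of jump-driven conductance-based neurons.

In the instantaneous-synapse limit the membrane voltage of an AONCB neuron is
a Markov process that relaxes exponentially toward its resting level between
Poisson synaptic events and jumps at events according to the Marcus rule

    V  ->  V * Y + Rtilde * (1 - Y),      Y = exp(-(We + Wi)),
    Rtilde = (We * Ve + Wi * Vi) / (We + Wi),

so the post-event voltage is a ``Y``-weighted average of the pre-event
voltage and the mixed reversal potential ``Rtilde``.  Because Poisson
arrivals see time averages (PASTA), the stationary law sampled just before an
event equals the stationary law at a typical time, which turns stationarity
into a fixed-point (conservation) equation for the shifted mixed moments

    mu_An = E[ prod_{a in An} (V_a - I_a/G_a) ],

``An`` a multiset of neuron labels.  Expanding one Marcus update and one
exponential waiting time yields the triangular linear system

    mu_An * ( sum_a m_a/tau_a + b * E[1 - prod_a Y_a^m_a] )
        = b * sum_{j < m} prod_a C(m_a, j_a)
              * mu_j * E[ prod_a Y_a^{j_a} (R'_a (1 - Y_a))^{m_a - j_a} ],

with ``R'_a = Rtilde_a - I_a/G_a`` and ``mu_empty = 1``, which this module
solves bottom-up over sub-multisets for any order.  All closed-form special
cases (mean, covariance, asynchronous variance, third moment) and the
small-weight approximations are provided alongside and are consistency
checked against the general engine in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .params import NeuronParams
from .synchrony import (
    BetaBinomialModel,
    CorrelationSpec,
    DiscreteJumpModel,
    InputPool,
    JumpModel,
)

__all__ = [
    "MomentTable",
    "general_mixed_moment",
    "moment_table",
    "rate_coefficients",
    "stationary_mean",
    "stationary_covariance",
    "variance_asynchronous",
    "variance_small_weight",
    "covariance_small_weight",
    "excitatory_variability_share",
    "correlation_shared_inputs",
    "kappa_synchrony",
    "correlation_synchrony",
    "third_moment",
    "skewness_excitation_approx",
    "skewness_sign_change_rate",
    "gap_junction_means",
    "heterogeneity_equivalent_variance",
    "small_weight_mean",
]


# ---------------------------------------------------------------------------
# jump-term preparation
# ---------------------------------------------------------------------------


def _params_map(jm: JumpModel, params) -> dict:
    if isinstance(params, NeuronParams):
        return {lab: params for lab in jm.labels}
    out = dict(params)
    missing = [lab for lab in jm.labels if lab not in out]
    if missing:
        raise KeyError(f"missing NeuronParams for labels {missing}")
    return out


def _draws(jm: JumpModel, n_draws: int | None = None, seed: int | None = None):
    """Jump draws and weights: exact atoms for discrete models, seeded Monte
    Carlo otherwise.  Returns (We, Wi, weights, exact_flag)."""
    if isinstance(jm, DiscreteJumpModel):
        return jm.We, jm.Wi, jm.probs, True
    rng = np.random.default_rng(jm.seed if seed is None else seed)
    n = n_draws or getattr(jm, "n_draws", 1_000_000)
    We, Wi = jm.sample(n, rng)
    We, Wi = np.atleast_2d(We), np.atleast_2d(Wi)
    w = np.full(We.shape[0], 1.0 / We.shape[0])
    return We, Wi, w, False


def _jump_terms(jm: JumpModel, pmap: dict, n_draws=None, seed=None):
    """Per-draw Y_a and R'_a arrays for every neuron label."""
    We, Wi, w, exact = _draws(jm, n_draws, seed)
    Y = np.empty_like(We)
    Rp = np.empty_like(We)
    for j, lab in enumerate(jm.labels):
        p = pmap[lab]
        W = We[:, j] + Wi[:, j]
        Y[:, j] = np.exp(-W)
        safe = np.where(W > 0, W, 1.0)
        # R' is irrelevant on the W = 0 atoms (factor 1 - Y vanishes); set 0
        Rp[:, j] = np.where(
            W > 0, (We[:, j] * p.Ve + Wi[:, j] * p.Vi) / safe - p.Iratio, 0.0
        )
    return Y, Rp, w, exact


# ---------------------------------------------------------------------------
# the general engine
# ---------------------------------------------------------------------------


@dataclass
class MomentTable:
    """Stationary shifted and centered mixed moments keyed by multisets of
    neuron labels (stored as sorted tuples)."""

    labels: tuple
    means: dict = field(default_factory=dict)
    shifted: dict = field(default_factory=dict)
    centered: dict = field(default_factory=dict)
    provenance: str = "exact"
    mc_standard_error: float = 0.0

    def variance(self, label) -> float:
        return self.centered[(label, label)]

    def covariance(self, a, b) -> float:
        return self.centered[tuple(sorted((a, b), key=repr))]

    def correlation(self, a, b) -> float:
        return self.covariance(a, b) / math.sqrt(self.variance(a) * self.variance(b))

    def skewness(self, label) -> float:
        v = self.variance(label)
        if v <= 0:
            raise ZeroDivisionError("skewness undefined for zero variance")
        return self.centered[(label, label, label)] / v**1.5

    def to_dict(self) -> dict:
        key = lambda d: {" ,".join(map(str, k)): v for k, v in d.items()}
        return {
            "labels": list(self.labels),
            "means": {str(k): v for k, v in self.means.items()},
            "shifted": key(self.shifted),
            "centered": key(self.centered),
            "provenance": self.provenance,
        }


def _multiset_key(labels: Sequence) -> tuple:
    return tuple(sorted(labels, key=repr))


def _solve_shifted(jm, pmap, counts_max, n_draws=None, seed=None) -> dict:
    """Solve the triangular PASTA system for all shifted moments with
    multiplicities ``<= counts_max`` (one entry per distinct label)."""
    labs = jm.labels
    Y, Rp, w, _ = _jump_terms(jm, pmap, n_draws, seed)
    b = jm.rate
    oneY = 1.0 - Y

    def ev(powers_Y, powers_R):
        """E[prod_a Y_a^{jy_a} * (R'_a (1 - Y_a))^{jr_a}]"""
        vals = np.ones(Y.shape[0])
        for j in range(len(labs)):
            if powers_Y[j]:
                vals = vals * Y[:, j] ** powers_Y[j]
            if powers_R[j]:
                vals = vals * (Rp[:, j] * oneY[:, j]) ** powers_R[j]
        return float(np.sum(w * vals))

    mu: dict[tuple, float] = {(0,) * len(labs): 1.0}
    # iterate multisets in order of total multiplicity
    all_counts = sorted(
        itertools.product(*(range(c + 1) for c in counts_max)), key=sum
    )
    for m in all_counts:
        order = sum(m)
        if order == 0:
            continue
        leak = sum(m[j] / pmap[labs[j]].tau for j in range(len(labs)))
        denom = leak + b * (1.0 - ev(m, (0,) * len(labs)))
        rhs = 0.0
        for jvec in itertools.product(*(range(c + 1) for c in m)):
            if jvec == m:
                continue
            comb = math.prod(math.comb(m[j], jvec[j]) for j in range(len(labs)))
            rvec = tuple(m[j] - jvec[j] for j in range(len(labs)))
            rhs += comb * mu[jvec] * ev(jvec, rvec)
        mu[m] = b * rhs / denom
    return mu


def general_mixed_moment(jm: JumpModel, params, multiset: Sequence) -> float:
    """Shifted stationary mixed moment ``mu_An`` for a multiset of labels.

    Reduces to the stationary mean (minus ``I/G``) at order one and to the
    covariance plus mean products at order two.
    """
    if len(multiset) < 1:
        raise ValueError("multiset must be nonempty")
    pmap = _params_map(jm, params)
    counts = [0] * len(jm.labels)
    for lab in multiset:
        counts[jm.index_of(lab)] += 1
    mu = _solve_shifted(jm, pmap, tuple(counts))
    return mu[tuple(counts)]


def moment_table(
    jm: JumpModel, params, order: int = 3, n_draws=None, seed=None
) -> MomentTable:
    """All stationary moments of the model's neurons up to ``order``.

    Shifted moments come from the triangular PASTA system; centered moments
    follow by binomial expansion around the means.  The sub-multiset lattice
    grows combinatorially, so orders above ~6 get expensive.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    pmap = _params_map(jm, params)
    labs = jm.labels
    n = len(labs)
    counts_max = (order,) * n
    mu_all = _solve_shifted(jm, pmap, counts_max, n_draws, seed)

    tab = MomentTable(labels=labs)
    mu1 = {labs[j]: mu_all[tuple(1 if k == j else 0 for k in range(n))] for j in range(n)}
    for lab in labs:
        tab.means[lab] = mu1[lab] + pmap[lab].Iratio

    for counts, val in mu_all.items():
        if not 1 <= sum(counts) <= order:
            continue
        ms = []
        for j, c in enumerate(counts):
            ms.extend([labs[j]] * c)
        tab.shifted[_multiset_key(ms)] = val
        # centered: E[prod (U_a - mu_a)^{m_a}] expanded over sub-multisets
        cent = 0.0
        for jvec in itertools.product(*(range(c + 1) for c in counts)):
            comb = math.prod(math.comb(counts[k], jvec[k]) for k in range(n))
            shift = math.prod(
                (-mu1[labs[k]]) ** (counts[k] - jvec[k]) for k in range(n)
            )
            cent += comb * shift * mu_all[jvec]
        tab.centered[_multiset_key(ms)] = cent

    if not isinstance(jm, DiscreteJumpModel):
        tab.provenance = "monte_carlo"
    return tab


# ---------------------------------------------------------------------------
# closed-form special cases
# ---------------------------------------------------------------------------


def rate_coefficients(jm: JumpModel, params, label=None) -> tuple[float, float]:
    """Synaptic rate coefficients ``(c_e, c_i)`` of one neuron:
    ``c_alpha = b * E[ W_alpha/(We+Wi) * (1 - exp(-(We+Wi))) ]``."""
    pmap = _params_map(jm, params)
    lab = jm.labels[0] if label is None else label
    j = jm.index_of(lab)

    def make(alpha):
        def f(We, Wi):
            W = We[:, j] + Wi[:, j]
            num = We[:, j] if alpha == "e" else Wi[:, j]
            safe = np.where(W > 0, W, 1.0)
            return np.where(W > 0, num / safe * (1.0 - np.exp(-W)), 0.0)

        return f

    ce, _ = jm.expect(make("e"))
    ci, _ = jm.expect(make("i"))
    return jm.rate * ce, jm.rate * ci


def stationary_mean(jm: JumpModel, params, label=None) -> float:
    """Exact stationary mean voltage (mV):

    ``m = (c_e Ve + c_i Vi + I/(b tau G)) / (1/tau + c_e + c_i)`` with the
    rate coefficients of :func:`rate_coefficients`.  Bounded by the reversal
    potentials for zero injected current.
    """
    pmap = _params_map(jm, params)
    lab = jm.labels[0] if label is None else label
    p = pmap[lab]
    ce, ci = rate_coefficients(jm, params, lab)
    return (ce * p.Ve + ci * p.Vi + p.Iratio / p.tau) / (1.0 / p.tau + ce + ci)


def stationary_covariance(jm: JumpModel, params, labels=None) -> float:
    """Exact stationary voltage covariance of a neuron pair (mV^2).

    Evaluates the PASTA fixed point for the pair: with ``Y_a`` and the
    centered mixed reversal ``R_a = Rtilde_a - m_a``,

        M12 = b12 * E[R_1 (1-Y_1) R_2 (1-Y_2)]
              / (1/tau_1 + 1/tau_2 + b12 * E[1 - Y_1 Y_2]).

    The variance is recovered when both labels coincide.
    """
    pmap = _params_map(jm, params)
    if labels is None:
        labels = jm.labels[:2] if jm.n_neurons >= 2 else (jm.labels[0], jm.labels[0])
    la, lb = labels
    ja, jb = jm.index_of(la), jm.index_of(lb)
    ma = stationary_mean(jm, params, la)
    mb = ma if lb == la else stationary_mean(jm, params, lb)
    pa, pb = pmap[la], pmap[lb]

    def f_num(We, Wi):
        out = np.ones(We.shape[0])
        for j, p, m in ((ja, pa, ma), (jb, pb, mb)):
            W = We[:, j] + Wi[:, j]
            safe = np.where(W > 0, W, 1.0)
            R = np.where(W > 0, (We[:, j] * p.Ve + Wi[:, j] * p.Vi) / safe - m, 0.0)
            out = out * R * (1.0 - np.exp(-W))
        return out

    def f_den(We, Wi):
        return 1.0 - np.exp(-(We[:, ja] + Wi[:, ja] + We[:, jb] + Wi[:, jb]))

    num, _ = jm.expect(f_num)
    den, _ = jm.expect(f_den)
    return jm.rate * num / (1.0 / pa.tau + 1.0 / pb.tau + jm.rate * den)


def third_moment(jm: JumpModel, params, label=None) -> tuple[float, float]:
    """Exact third centered stationary moment and skewness of one neuron.

    Solves the PASTA fixed point at orders 1-3 (the compact published-style
    expression in terms of ``Y = exp(-(We+Wi))``, the centered mixed reversal
    ``R = Rtilde - m`` and the variance is an algebraic rearrangement of the
    same triangular system).  Returns ``(M3, skewness)`` with
    ``skewness = M3 / M2**1.5``.
    """
    pmap = _params_map(jm, params)
    lab = jm.labels[0] if label is None else label
    sub = jm
    if isinstance(jm, DiscreteJumpModel) and jm.n_neurons > 1:
        sub = jm.subsample([lab])
    tab = moment_table(sub, pmap[lab], order=3)
    M3 = tab.centered[(lab, lab, lab)]
    M2 = tab.centered[(lab, lab)]
    if M2 <= 0:
        raise ZeroDivisionError("skewness undefined: zero stationary variance")
    return M3, M3 / M2**1.5


def variance_asynchronous(pools: Sequence[InputPool], params: NeuronParams) -> float:
    """Exact stationary variance for independent (asynchronous) inputs:

        M = [ sum_k r_k (1 - e^{-w_k})^2 (V_alpha - m)^2 ]
            / [ 2/tau + sum_k r_k (1 - e^{-2 w_k}) ],

    summing over all excitatory and inhibitory inputs.  Coincides with the
    effective-time-constant form, with shot-noise (exponential) efficacies.
    """
    if all(np.all(p.weight_array * p.rate_array == 0) for p in pools):
        return 0.0
    jm = DiscreteJumpModel.from_asynchronous_pools(pools)
    m = stationary_mean(jm, params)
    num = 0.0
    den = 2.0 / params.tau
    for pool in pools:
        V = params.Ve if pool.kind == "e" else params.Vi
        w = pool.weight_array
        r = pool.rate_array
        num += float(np.sum(r * (1.0 - np.exp(-w)) ** 2)) * (V - m) ** 2
        den += float(np.sum(r * (1.0 - np.exp(-2.0 * w))))
    return num / den


def small_weight_mean(pools: Sequence[InputPool], params: NeuronParams) -> float:
    """Small-weight stationary mean: rate coefficients ``c_alpha = sum r w``."""
    ce = sum(float(np.sum(p.rate_array * p.weight_array)) for p in pools if p.kind == "e")
    ci = sum(float(np.sum(p.rate_array * p.weight_array)) for p in pools if p.kind == "i")
    return (ce * params.Ve + ci * params.Vi + params.Iratio / params.tau) / (
        1.0 / params.tau + ce + ci
    )


def variance_small_weight(
    pools: Sequence[InputPool],
    corr: CorrelationSpec | None,
    params: NeuronParams,
    mean: float | None = None,
) -> float:
    """Small-weight stationary variance with synchrony:

        M = sum_{pools i,j} (V_i - m)(V_j - m)
              * sum_{k,l} rho_{ij,kl} sqrt(r_k r_l) w_k w_l
            / ( 2 (1/tau + sum_k r_k w_k) ).

    ``corr.block_rho[i, j]`` is the uniform pairwise spiking correlation
    between (distinct) inputs of pools ``i`` and ``j``; diagonal pairs
    ``k = l`` always carry coefficient one, which reproduces the
    asynchronous variance at ``rho = 0``.  Cross e-i coefficients contribute
    with the (negative) product of driving forces and reduce the variance.
    """
    m = small_weight_mean(pools, params) if mean is None else mean
    L = len(pools)
    rho = np.zeros((L, L)) if corr is None else corr.block_rho
    if rho.shape != (L, L):
        raise ValueError("correlation spec must have one block per pool")
    V = np.array([params.Ve if p.kind == "e" else params.Vi for p in pools])
    den = 2.0 * (
        1.0 / params.tau
        + sum(float(np.sum(p.rate_array * p.weight_array)) for p in pools)
    )
    num = 0.0
    for i, pi in enumerate(pools):
        si = float(np.sum(np.sqrt(pi.rate_array) * pi.weight_array))
        qi = float(np.sum(pi.rate_array * pi.weight_array**2))
        for j, pj in enumerate(pools):
            sj = float(np.sum(np.sqrt(pj.rate_array) * pj.weight_array))
            pair_sum = rho[i, j] * si * sj
            if i == j:
                # replace the k = l diagonal by its exact unit coefficient
                diag = float(np.sum(pi.rate_array * pi.weight_array**2))
                pair_sum += (1.0 - rho[i, j]) * diag
            num += (V[i] - m) * (V[j] - m) * pair_sum
    return num / den


def covariance_small_weight(
    pools1: Sequence[InputPool],
    pools2: Sequence[InputPool],
    cross: Sequence[tuple],
    params1: NeuronParams,
    params2: NeuronParams | None = None,
    means: tuple[float, float] | None = None,
) -> float:
    """Small-weight voltage covariance of a neuron pair.

    ``cross`` lists the correlated pool pairs as tuples
    ``(i, j, rho, n_pairs)``: pool ``i`` of neuron 1 versus pool ``j`` of
    neuron 2 with uniform pairwise spiking correlation ``rho`` over
    ``n_pairs`` input pairs (default ``K_i * K_j``; pass the shared count
    with ``rho = 1`` to encode physically shared inputs).  Uniform pools are
    assumed within each cross term.

        M12 = sum (V_i - m1)(V_j - m2) rho n_pairs sqrt(r_i r_j) w_i w_j
              / ( 1/tau1 + 1/tau2 + sum_pools r (w_1 + w_2) ).

    Linear in every spiking correlation coefficient; negative if only
    opposite-type (e-i) cross correlations are present.
    """
    p2 = params1 if params2 is None else params2
    m1 = small_weight_mean(pools1, params1) if means is None else means[0]
    m2 = small_weight_mean(pools2, p2) if means is None else means[1]
    den = 1.0 / params1.tau + 1.0 / p2.tau
    for pools in (pools1, pools2):
        den += sum(float(np.sum(p.rate_array * p.weight_array)) for p in pools)
    num = 0.0
    for term in cross:
        i, j, rho, *rest = term
        pi, pj = pools1[i], pools2[j]
        n_pairs = rest[0] if rest else pi.K * pj.K
        Vi_ = params1.Ve if pi.kind == "e" else params1.Vi
        Vj_ = p2.Ve if pj.kind == "e" else p2.Vi
        ri = float(pi.rate_array.mean())
        rj = float(pj.rate_array.mean())
        wi = float(pi.weight_array.mean())
        wj = float(pj.weight_array.mean())
        num += (Vi_ - m1) * (Vj_ - m2) * rho * n_pairs * math.sqrt(ri * rj) * wi * wj
    return num / den


# ---------------------------------------------------------------------------
# interpretable worked formulas
# ---------------------------------------------------------------------------


def excitatory_variability_share(
    Ke: float, re: float, we: float, Ki: float, ri: float, wi: float,
    m: float, params: NeuronParams | None = None,
) -> float:
    """Share of the small-weight voltage variance due to excitation:

        q = Ke re we^2 (Ve - m)^2 / sum_alpha K_alpha r_alpha w_alpha^2 (V_alpha - m)^2.

    Decreasing in the mean depolarization ``m`` since the excitatory driving
    force shrinks while the inhibitory one grows.
    """
    p = params or NeuronParams()
    num = Ke * re * we**2 * (p.Ve - m) ** 2
    den = num + Ki * ri * wi**2 * (p.Vi - m) ** 2
    if den == 0:
        raise ZeroDivisionError("no variability")
    return num / den


def correlation_shared_inputs(fe: float, fi: float, q: float) -> float:
    """Voltage correlation of two neurons sharing input fractions ``fe``
    (excitatory) and ``fi`` (inhibitory): ``rho_V = fe q + fi (1 - q)``."""
    for name, val in (("fe", fe), ("fi", fi), ("q", q)):
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    return fe * q + fi * (1.0 - q)


def kappa_synchrony(Ke: float, Ki: float, q: float, case: str = "ii") -> float:
    """Ratio of the fully synchronous to the asynchronous voltage variance.

    Case ``"i"`` (excitation and inhibition synchronous separately but
    mutually independent): ``kappa = Ke q + Ki (1 - q)``.  Case ``"ii"``
    (uniformly cross-correlated excitation and inhibition): the fully
    synchronous event is a single joint e+i activation whose driving forces
    partially cancel, giving

        kappa = ( sqrt(Ke q) - sqrt(Ki (1 - q)) )^2,

    the ratio of the small-weight quadratic forms at ``rho = 1`` and
    ``rho = 0``.
    """
    if case == "i":
        return Ke * q + Ki * (1.0 - q)
    if case == "ii":
        return (math.sqrt(Ke * q) - math.sqrt(Ki * (1.0 - q))) ** 2
    raise ValueError("case must be 'i' or 'ii'")


def correlation_synchrony(rho_within: float, rho_cross: float, kappa: float) -> float:
    """Voltage correlation of two synchronously driven neurons:

        rho_V = rho' / ( (1 - rho)/kappa + rho ),

    with within-neuron input correlation ``rho``, cross-neuron input
    correlation ``rho' <= rho`` and variance ratio ``kappa``.  Always below
    the saturation value ``rho'/rho``.
    """
    if not 0 < rho_within <= 1:
        raise ValueError("rho_within must lie in (0, 1]")
    if rho_cross < 0 or rho_cross > rho_within:
        raise ValueError("need 0 <= rho_cross <= rho_within")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return rho_cross / ((1.0 - rho_within) / kappa + rho_within)


def skewness_excitation_approx(
    Ke: float, we: float, re: float, rho_e: float, params: NeuronParams | None = None
) -> dict:
    """Approximate skewness of an excitation-only neuron (``Ke we ~ 1``,
    beta-binomial synchrony):

        S[V] ~ s[V] * (1 - 2 c_e tau)/(1 + c_e tau) * sqrt(1 + rho_e Ke),
        s[V] = 2 sqrt(2) / (3 sqrt(Ke re tau)),

    where ``s[V]`` is the skewness of the matched asynchronous current-based
    model (constant driving force) and ``c_e = Ke re we`` is the total
    excitatory rate coefficient (equal to ``re`` at the biophysical
    operating point ``Ke we = 1``, where the drive factor is the familiar
    ``(1 - 2 re tau)/(1 + re tau)``).  The drive-dependent factor changes
    sign at ``c_e = 1/(2 tau)``; synchrony amplifies the right skew through
    the variance-style factor ``1 + rho_e Ke``.  Valid for weak synchrony
    (``rho_e Ke`` not too large); the exact route is :func:`third_moment`.

    Returns a dict with the total ``skewness`` and its three factors.
    """
    p = params or NeuronParams()
    if rho_e < 0:
        raise ValueError("rho_e must be nonnegative")
    ce = Ke * re * we
    baseline = 2.0 * math.sqrt(2.0) / (3.0 * math.sqrt(Ke * re * p.tau))
    drive = (1.0 - 2.0 * ce * p.tau) / (1.0 + ce * p.tau)
    sync = math.sqrt(1.0 + rho_e * Ke)
    return {
        "skewness": baseline * drive * sync,
        "current_based_baseline": baseline,
        "drive_factor": drive,
        "synchrony_factor": sync,
    }


def skewness_sign_change_rate(tau: float, Ke_we: float = 1.0) -> float:
    """Drive rate (Hz) at which the approximate skewness changes sign: the
    root in ``re`` of the drive factor ``(1 - 2 Ke we re tau)/(1 + ...)``,
    i.e. ``1/(2 tau)`` at the operating point ``Ke we = 1``; located
    numerically for robustness."""
    f = lambda r: (1.0 - 2.0 * Ke_we * r * tau) / (1.0 + Ke_we * r * tau)
    return brentq(f, 1e-9, 10.0 / tau, xtol=1e-12)


def gap_junction_means(
    jm: JumpModel, params, g: float, labels=None
) -> tuple[float, float]:
    """Stationary means of an electrically coupled pair (coupling
    ``g = G12/G``, identical membrane time constants).

    Solving the first-order PASTA balance of the coupled linear relaxation
    gives weighted averages of the uncoupled means ``m_a|0``:

        m1 = [A1 A2 m1|0 + (g/tau)(A1 m1|0 + A2 m2|0)]
             / [A1 A2 + (g/tau)(A1 + A2)],

    with ``A_a = 1/tau + c_a`` and ``c_a = b E[1 - Y_a]`` the total rate
    coefficient.  ``g = 0`` recovers the uncoupled means; ``g -> inf`` makes
    both means equal to the ``A``-weighted average.
    """
    if g < 0:
        raise ValueError("coupling must be nonnegative")
    pmap = _params_map(jm, params)
    if labels is None:
        labels = jm.labels[:2]
    la, lb = labels
    taus = {pmap[la].tau, pmap[lb].tau}
    if len(taus) != 1:
        raise ValueError("closed form assumes identical membrane time constants")
    tau = taus.pop()
    out = []
    A = {}
    m0 = {}
    for lab in (la, lb):
        j = jm.index_of(lab)

        def f(We, Wi, j=j):
            return 1.0 - np.exp(-(We[:, j] + Wi[:, j]))

        c, _ = jm.expect(f)
        A[lab] = 1.0 / tau + jm.rate * c
        m0[lab] = stationary_mean(jm, params, lab)
    gp = g / tau
    den = A[la] * A[lb] + gp * (A[la] + A[lb])
    m1 = (A[la] * A[lb] * m0[la] + gp * (A[la] * m0[la] + A[lb] * m0[lb])) / den
    m2 = (A[la] * A[lb] * m0[lb] + gp * (A[lb] * m0[lb] + A[la] * m0[la])) / den
    return m1, m2


def heterogeneity_equivalent_variance(
    weights: Sequence[float], r: float, params: NeuronParams
) -> dict:
    """Small-weight variance of an asynchronous heterogeneous excitatory pool
    factored through the squared coefficient of variation of the weights:

        numerator = r K <w>^2 (1 + CV^2[w]) (Ve - m)^2,

    so heterogeneity amplifies variability exactly like an effective
    synchrony factor ``1 + rho (K - 1) = 1 + CV^2[w]``.
    """
    w = np.asarray(weights, dtype=float)
    K = w.size
    mean_w = float(w.mean())
    cv2 = float(w.var() / mean_w**2) if mean_w > 0 else 0.0
    pool = InputPool(kind="e", K=K, weights=w, rates=r)
    var = variance_small_weight([pool], None, params)
    return {
        "variance": var,
        "cv2": cv2,
        "amplification": 1.0 + cv2,
        "K_mean_w2": K * mean_w**2,
    }
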