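"""Empirical stationary moments of event-driven voltage traces.

Because the trace is piecewise exponential, time integrals of voltage
products are available in closed form: on an inter-event interval
``[T_n, T_{n+1})`` the product ``prod_a (V_a(t) - I_a/G_a)`` decays at rate
``s = sum_a 1/tau_a``, so the ``m``-th order empirical shifted moment over a
window of length ``T`` is the exact sum

    mu_{Am,T} = (1/T) * sum_n (1 - exp(-s (T_{n+1} - T_n))) / s
                        * prod_a (V_{a,n} - I_a/G_a),

with the final partial interval included (``T_{N+1} = T``).  There is no
quadrature error beyond floating point.  Standard errors come from a block
bootstrap over contiguous trace segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simulate import VoltageTrace

__all__ = ["EmpiricalMoments", "empirical_shifted_moment", "empirical_summary"]

#: default burn-in, in units of the (largest) membrane time constant
BURN_IN_TAUS = 20.0
#: default bootstrap block length, in units of the membrane time constant
BLOCK_TAUS = 100.0


def _segments(trace: VoltageTrace, burn_in: float):
    """Post-event shifted voltages and segment durations after burn-in.

    Returns ``(u, durations)`` where ``u[k, a] = V_a - I_a/G_a`` at the start
    of segment ``k`` and the first segment starts exactly at ``burn_in``.
    """
    T = trace.T
    if T <= burn_in:
        raise ValueError(f"trace (T={T}) shorter than burn-in ({burn_in})")
    t = trace.times
    keep = t > burn_in
    starts = np.concatenate(([burn_in], t[keep]))
    v_start = np.vstack([trace.sample(np.array([burn_in]))[0], trace.V[keep]])
    rest = np.array([p.Iratio for p in trace.params])
    durations = np.diff(np.concatenate((starts, [T])))
    return v_start - rest, durations, starts


def _segment_integral(trace: VoltageTrace, u: np.ndarray, dur: np.ndarray, cols):
    """Exact integral of the shifted voltage product over each inter-event
    segment, given the start values ``u`` and durations ``dur``.

    Uncoupled neurons decay independently, so the product decays at rate
    ``sum_a 1/tau_a``.  For a gap-junction pair the product is expanded in
    the sum/difference eigenmodes, each power combination decaying at its
    own rate ``(m + n (1 + 2g))/tau``.
    """
    g = getattr(trace, "gap_coupling", 0.0)
    if not g:
        s = sum(1.0 / trace.params[j].tau for j in cols)
        return np.prod(u[:, cols], axis=1) * (1.0 - np.exp(-s * dur)) / s
    tau = trace.params[0].tau
    j = list(cols).count(0)
    k = list(cols).count(1)
    s0 = 0.5 * (u[:, 0] + u[:, 1])
    d0 = 0.5 * (u[:, 0] - u[:, 1])
    total = np.zeros(u.shape[0])
    for p_ in range(j + 1):
        for q in range(k + 1):
            coef = math.comb(j, p_) * math.comb(k, q) * (-1) ** (k - q)
            ms = p_ + q
            nd = (j - p_) + (k - q)
            rate = (ms + nd * (1.0 + 2.0 * g)) / tau
            total += coef * s0**ms * d0**nd * (1.0 - np.exp(-rate * dur)) / rate
    return total


def empirical_shifted_moment(
    trace: VoltageTrace, multiset: Sequence, burn_in: float | None = None
) -> float:
    """Exact time-average of ``prod_a (V_a(t) - I_a/G_a)`` over the multiset
    ``Am`` of neuron labels, after discarding the burn-in."""
    cols = [trace.labels.index(lab) for lab in multiset]
    if burn_in is None:
        burn_in = BURN_IN_TAUS * max(p.tau for p in trace.params)
    u, dur, _ = _segments(trace, burn_in)
    return float(np.sum(_segment_integral(trace, u, dur, cols)) / dur.sum())


@dataclass
class EmpiricalMoments:
    """Empirical stationary moments with bootstrap standard errors.

    ``shifted[key] = (estimate, se)`` for multiset keys; derived statistics
    (means, variances, covariances, correlations, skewness) likewise.
    """

    labels: tuple
    T_effective: float
    n_events: int
    burn_in: float
    shifted: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    variances: dict = field(default_factory=dict)
    covariances: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    skewness: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(d):
            return {str(k): {"value": v[0], "se": v[1]} for k, v in d.items()}

        return {
            "labels": list(map(str, self.labels)),
            "T_effective": self.T_effective,
            "n_events": self.n_events,
            "burn_in": self.burn_in,
            "shifted": conv(self.shifted),
            "means": conv(self.means),
            "variances": conv(self.variances),
            "covariances": conv(self.covariances),
            "correlations": conv(self.correlations),
            "skewness": conv(self.skewness),
        }


def _multisets(labels, orders):
    out = []
    n = len(labels)
    for order in orders:
        def rec(start, current):
            if len(current) == order:
                out.append(tuple(current))
                return
            for j in range(start, n):
                rec(j, current + [labels[j]])
        rec(0, [])
    return out


def empirical_summary(
    trace: VoltageTrace,
    orders: Sequence[int] = (1, 2, 3),
    burn_in: float | None = None,
    block: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> EmpiricalMoments:
    """Empirical means, (co)variances, correlations and skewness with block
    bootstrap standard errors.

    The trace is cut into contiguous blocks of length ``block`` (default
    ``100 tau``); each bootstrap replicate resamples blocks with replacement
    and recomputes every derived statistic, so the standard errors propagate
    through the centering nonlinearities.
    """
    taus = [p.tau for p in trace.params]
    if burn_in is None:
        burn_in = BURN_IN_TAUS * max(taus)
    if block is None:
        block = BLOCK_TAUS * max(taus)
    u, dur, starts = _segments(trace, burn_in)
    labels = trace.labels
    msets = _multisets(labels, orders)

    # per-segment closed-form integrals for every multiset
    seg_int = {}
    for ms in msets:
        cols = [labels.index(lab) for lab in ms]
        seg_int[ms] = _segment_integral(trace, u, dur, cols)

    # block assignment by segment start
    block_idx = ((starts - burn_in) / block).astype(int)
    n_blocks = block_idx.max() + 1 if block_idx.size else 1
    blk_T = np.bincount(block_idx, weights=dur, minlength=n_blocks)
    blk = {ms: np.bincount(block_idx, weights=seg_int[ms], minlength=n_blocks)
           for ms in msets}

    def derive(total_T, sums):
        mu = {ms: sums[ms] / total_T for ms in msets}
        rest = {lab: p.Iratio for lab, p in zip(labels, trace.params)}
        out = {"shifted": mu, "means": {}, "variances": {}, "covariances": {},
               "correlations": {}, "skewness": {}}
        for lab in labels:
            out["means"][lab] = mu[(lab,)] + rest[lab]
        if 2 in orders:
            for lab in labels:
                out["variances"][lab] = mu[(lab, lab)] - mu[(lab,)] ** 2
            for i, la in enumerate(labels):
                for lb in labels[i + 1:]:
                    key = tuple(sorted((la, lb), key=repr))
                    cov = mu[key] - mu[(la,)] * mu[(lb,)]
                    out["covariances"][key] = cov
                    va, vb = out["variances"][la], out["variances"][lb]
                    out["correlations"][key] = (
                        cov / math.sqrt(va * vb) if va > 0 and vb > 0 else np.nan
                    )
        if 3 in orders and 2 in orders:
            for lab in labels:
                m1, m2, m3 = mu[(lab,)], mu[(lab, lab)], mu[(lab, lab, lab)]
                M3 = m3 - 3 * m2 * m1 + 2 * m1**3
                v = out["variances"][lab]
                out["skewness"][lab] = M3 / v**1.5 if v > 0 else np.nan
        return out

    point = derive(dur.sum(), {ms: blk[ms].sum() for ms in msets})

    rng = np.random.default_rng(seed)
    reps: list[dict] = []
    for _ in range(n_boot):
        pick = rng.integers(0, n_blocks, n_blocks)
        reps.append(
            derive(blk_T[pick].sum(), {ms: blk[ms][pick].sum() for ms in msets})
        )

    res = EmpiricalMoments(
        labels=labels,
        T_effective=float(dur.sum()),
        n_events=int(dur.size - 1),
        burn_in=burn_in,
    )
    for field_name in ("shifted", "means", "variances", "covariances",
                       "correlations", "skewness"):
        target = getattr(res, field_name)
        for key, val in point[field_name].items():
            draws = np.array([r[field_name][key] for r in reps])
            target[key] = (float(val), float(np.nanstd(draws, ddof=1)))
    return res
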