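"""Correlated spike-train generation via beta marginals and a Gaussian copula.

Spiking synchrony is generated with a doubly stochastic construction: time is
discretized in bins of width ``dt`` (default 0.1 ms) and, in each bin, every
homogeneous input subpopulation ``i`` of size ``K_i`` draws a mixing variable
``theta_i`` and then a binomial spike count ``k_i ~ Bin(K_i, theta_i)``.
Marginally ``theta_i`` follows a beta distribution with

    alpha_i = r_i dt (1/rho_ii - 1),   beta_i = (1 - r_i dt)(1/rho_ii - 1),

so the mean count is exactly ``r_i dt`` and the within-population pairwise
spike-count correlation is ``rho_ii + o(dt)``.  Across subpopulations the
mixing vector is coupled through a Gaussian copula whose correlation matrix
``Sigma`` is calibrated, pair by pair, so that the mixed second moments
satisfy ``E[theta_i theta_j] = r_i r_j rho_ij dt``.

Rasters can be jittered (independent Gaussian shifts of every spike, wrapped
periodically) to turn perfect, instantaneous synchrony into temporally
spread synchrony with correlations that decay at fine timescales, and can be
converted into the synaptic event trains that drive the Marcus simulator:
all spikes falling in one bin form a single synaptic event.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .synchrony import CorrelationSpec, InputPool

__all__ = [
    "SpikeRaster",
    "EventTrain",
    "beta_marginal_params",
    "calibrate_copula_sigma",
    "sample_raster",
    "jitter_spikes",
    "empirical_count_correlation",
    "raster_to_events",
    "spike_times_from_counts",
    "counts_from_spike_times",
]

#: threshold below which within-block correlation is treated as zero
#: (independent binomial thinning; the beta parameters diverge)
_RHO_TINY = 1e-12


@dataclass
class SpikeRaster:
    """Binned spike counts of ``L`` input subpopulations.

    ``counts`` has shape ``(L, n_bins)``; ``subpop_meta`` carries one dict
    per subpopulation with at least ``K`` (pool size) and ``r`` (rate, Hz),
    and optionally a ``weights`` map ``{neuron_label: signed weight}``
    (positive = excitatory, negative = inhibitory).
    """

    dt: float
    counts: np.ndarray
    subpop_meta: list = field(default_factory=list)
    per_input: list | None = None  # optional per-input binary arrays

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.counts.ndim != 2:
            raise ValueError("counts must be L x n_bins")
        for i, meta in enumerate(self.subpop_meta):
            if np.any(self.counts[i] > meta["K"]):
                raise ValueError(f"counts exceed pool size in subpopulation {i}")

    @property
    def L(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV (subpop, bin, count; zero rows omitted) plus a JSON
        sidecar holding ``dt`` and the subpopulation metadata."""
        path = Path(path)
        sub, bins = np.nonzero(self.counts)
        pd.DataFrame(
            {"subpop": sub, "bin": bins, "count": self.counts[sub, bins]}
        ).to_csv(path, index=False)
        meta = {
            "dt": self.dt,
            "n_bins": int(self.n_bins),
            "subpop_meta": [
                {k: v for k, v in m.items() if k != "weights"}
                | {"weights": {str(k): v for k, v in m.get("weights", {}).items()}}
                for m in self.subpop_meta
            ],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpikeRaster":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path)
        L = len(meta["subpop_meta"])
        counts = np.zeros((L, meta["n_bins"]), dtype=int)
        counts[df["subpop"].to_numpy(), df["bin"].to_numpy()] = df["count"].to_numpy()
        return cls(dt=meta["dt"], counts=counts, subpop_meta=meta["subpop_meta"])


@dataclass
class EventTrain:
    """Ordered synaptic-event times with per-event, per-neuron jumps.

    ``We`` and ``Wi`` have shape ``(n_events, n_neurons)``; times are strictly
    increasing and every event delivers a positive total jump to at least one
    neuron.
    """

    times: np.ndarray
    We: np.ndarray
    Wi: np.ndarray
    labels: tuple = (0,)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.We = np.atleast_2d(np.asarray(self.We, dtype=float))
        self.Wi = np.atleast_2d(np.asarray(self.Wi, dtype=float))
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if self.We.shape != self.Wi.shape or self.We.shape[0] != self.times.size:
            raise ValueError("jump arrays must be (n_events, n_neurons)")
        if self.times.size and np.any(self.We.sum(axis=1) + self.Wi.sum(axis=1) <= 0):
            raise ValueError("every event must carry a positive total jump")

    @property
    def n_events(self) -> int:
        return self.times.size

    @property
    def n_neurons(self) -> int:
        return self.We.shape[1]

    def to_csv(self, path: str | Path) -> None:
        cols = {"time": self.times}
        for j, lab in enumerate(self.labels):
            cols[f"We_{lab}"] = self.We[:, j]
            cols[f"Wi_{lab}"] = self.Wi[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTrain":
        df = pd.read_csv(path)
        labels = tuple(c[3:] for c in df.columns if c.startswith("We_"))
        We = np.column_stack([df[f"We_{lab}"] for lab in labels])
        Wi = np.column_stack([df[f"Wi_{lab}"] for lab in labels])
        return cls(times=df["time"].to_numpy(), We=We, Wi=Wi, labels=labels)


# ---------------------------------------------------------------------------
# beta marginals and copula calibration
# ---------------------------------------------------------------------------


def beta_marginal_params(r: float, rho: float, dt: float) -> tuple[float, float]:
    """Beta parameters of the per-bin mixing variable:
    ``alpha = r dt (1/rho - 1)``, ``beta = (1 - r dt)(1/rho - 1)``.

    The beta mean is exactly ``r dt``.  The boundary cases ``rho = 0``
    (independent thinning) and ``rho = 1`` (single shared Bernoulli mixing)
    are handled separately by the samplers, not through beta parameters.
    """
    if not 0 < rho < 1:
        raise ValueError("beta marginals require 0 < rho < 1")
    if not 0 < r * dt < 1:
        raise ValueError("need 0 < r*dt < 1")
    c = 1.0 / rho - 1.0
    return r * dt * c, (1.0 - r * dt) * c


def _pair_moment(sigma: float, dist_i, dist_j, nodes: int = 48) -> float:
    """``E[theta_i theta_j]`` under a bivariate Gaussian copula with
    correlation ``sigma``, by Gauss-Hermite quadrature."""
    x, wq = np.polynomial.hermite_e.hermegauss(nodes)
    w = wq / math.sqrt(2.0 * math.pi)
    ti = dist_i.ppf(np.clip(stats.norm.cdf(x), 1e-300, 1 - 1e-16))
    z2 = sigma * x[:, None] + math.sqrt(max(1.0 - sigma**2, 0.0)) * x[None, :]
    tj = dist_j.ppf(np.clip(stats.norm.cdf(z2), 1e-300, 1 - 1e-16))
    inner = tj @ w  # E[theta_j | z1]
    return float(np.sum(w * ti * inner))


def calibrate_copula_sigma(
    corr: CorrelationSpec,
    rates: Sequence[float],
    dt: float,
    *,
    tol: float = 1e-10,
    _cache: dict = {},
) -> np.ndarray:
    """Copula correlation matrix ``Sigma`` hitting the target cross moments

        E[theta_i theta_j] = r_i r_j dt^2 + rho_ij sqrt(r_i r_j) dt,

    which makes the per-bin Pearson correlation between an input of block
    ``i`` and one of block ``j`` equal to ``rho_ij + O(dt)`` (the
    ``r_i r_j dt^2`` part is the independent-moment baseline).

    Each off-diagonal entry is found by one-dimensional root finding on the
    bivariate-copula moment (monotone in ``sigma``); entries are cached per
    ``(rho_ij, r_i, r_j, dt)``.  Raises if a target is infeasible (would
    need ``sigma > 1``) or if the assembled matrix is not positive
    semidefinite.
    """
    rho = corr.block_rho
    L = corr.L
    rates = np.asarray(rates, dtype=float)
    if rates.size != L:
        raise ValueError("need one rate per subpopulation")
    dists = []
    for i in range(L):
        a, b = beta_marginal_params(rates[i], np.diag(rho)[i], dt)
        dists.append(stats.beta(a, b))
    Sigma = np.eye(L)
    for i in range(L):
        for j in range(i + 1, L):
            if rho[i, j] <= _RHO_TINY:
                continue
            key = (round(rho[i, j], 12), rates[i], rates[j], dt, rho[i, i], rho[j, j])
            if key not in _cache:
                base = rates[i] * dt * rates[j] * dt  # independent moment
                target = base + rho[i, j] * math.sqrt(rates[i] * rates[j]) * dt
                top = _pair_moment(1.0 - 1e-9, dists[i], dists[j])
                if target > top * (1 + 1e-9):
                    raise ValueError(
                        f"infeasible correlation target for pair ({i}, {j}): "
                        f"needs E[theta_i theta_j]={target:.3e} > comonotone "
                        f"maximum {top:.3e}"
                    )
                f = lambda s: _pair_moment(s, dists[i], dists[j]) - target
                _cache[key] = brentq(f, 0.0, 1.0 - 1e-9, xtol=tol, rtol=8.9e-16)
            Sigma[i, j] = Sigma[j, i] = _cache[key]
    evals = np.linalg.eigvalsh(Sigma)
    if evals.min() < -1e-10:
        raise ValueError(
            "calibrated copula matrix is not positive semidefinite "
            f"(min eigenvalue {evals.min():.3e}); consider projecting to the "
            "nearest PSD matrix or reducing cross-block correlations"
        )
    return Sigma


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_raster(
    corr: CorrelationSpec,
    pools: Sequence[InputPool] | Sequence[dict],
    dt: float,
    T: float,
    seed: int,
    *,
    Sigma: np.ndarray | None = None,
    per_input: bool = False,
    weights_maps: Sequence[dict] | None = None,
) -> SpikeRaster:
    """Sample a correlated spike raster.

    Bins are i.i.d.: per bin a Gaussian vector with correlation ``Sigma`` is
    mapped through the normal CDF and the inverse beta CDFs to the mixing
    probabilities ``theta_i``, from which binomial counts are drawn.  With
    ``per_input=True`` each subpopulation additionally records per-input
    Bernoulli outcomes (whose sum is the binomial count).  A single integer
    seed spawns independent streams for the copula draws and the binomial
    draws.
    """
    if T <= 0:
        raise ValueError("duration must be positive")
    pools = [
        p if isinstance(p, InputPool) else InputPool(**p) for p in pools
    ]
    L = len(pools)
    if corr.L != L:
        raise ValueError("one correlation block per pool required")
    rates = np.array([float(p.rate_array.mean()) for p in pools])
    rho_d = np.diag(corr.block_rho)
    need_copula = np.any(corr.block_rho - np.diag(rho_d) > _RHO_TINY)
    if Sigma is None:
        Sigma = (
            calibrate_copula_sigma(corr, rates, dt) if need_copula else np.eye(L)
        )
    n_bins = int(round(T / dt))
    ss = np.random.SeedSequence(seed)
    rng_copula, rng_binom = (np.random.default_rng(s) for s in ss.spawn(2))

    # mixing probabilities per bin
    theta = np.empty((L, n_bins))
    chol = np.linalg.cholesky(Sigma + 1e-14 * np.eye(L))
    Z = chol @ rng_copula.standard_normal((L, n_bins))
    U = stats.norm.cdf(Z)
    for i in range(L):
        p_bin = rates[i] * dt
        if rho_d[i] <= _RHO_TINY:
            theta[i] = p_bin  # independent thinning limit
        elif rho_d[i] >= 1.0 - _RHO_TINY:
            theta[i] = (U[i] < p_bin).astype(float)  # all-or-none mixing
        else:
            a, b = beta_marginal_params(rates[i], rho_d[i], dt)
            theta[i] = stats.beta(a, b).ppf(U[i])

    counts = np.empty((L, n_bins), dtype=np.int64)
    per_input_arrays: list | None = [] if per_input else None
    for i, pool in enumerate(pools):
        if per_input:
            X = rng_binom.random((pool.K, n_bins)) < theta[i]
            per_input_arrays.append(X)
            counts[i] = X.sum(axis=0)
        else:
            counts[i] = rng_binom.binomial(pool.K, theta[i])

    meta = []
    for i, pool in enumerate(pools):
        m = {"K": pool.K, "r": rates[i], "kind": pool.kind,
             "w": float(pool.weight_array.mean())}
        if weights_maps is not None:
            m["weights"] = weights_maps[i]
        meta.append(m)
    return SpikeRaster(dt=dt, counts=counts, subpop_meta=meta, per_input=per_input_arrays)


# ---------------------------------------------------------------------------
# jitter and empirical correlations
# ---------------------------------------------------------------------------


def spike_times_from_counts(counts: np.ndarray, dt: float) -> np.ndarray:
    """Expand a binned count vector into spike times at the bin right edges
    (one time per spike; multiplicities repeated)."""
    idx = np.nonzero(counts)[0]
    return np.repeat((idx + 1) * dt, counts[idx].astype(int))


def counts_from_spike_times(times: np.ndarray, window: float, T: float) -> np.ndarray:
    n = int(round(T / window))
    t = np.asarray(times, dtype=float)
    binned = np.minimum((t / window).astype(int), n - 1)
    return np.bincount(binned, minlength=n)[:n]


def jitter_spikes(
    spike_times: np.ndarray, sigmaJ: float, T: float, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Shift every spike by an independent centered Gaussian of SD ``sigmaJ``
    seconds; spikes leaving ``[0, T)`` are wrapped periodically, which
    preserves marginal rates exactly and stationarity of the train."""
    if sigmaJ < 0:
        raise ValueError("jitter SD must be nonnegative")
    t = np.asarray(spike_times, dtype=float)
    if sigmaJ == 0:
        return t.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    return np.sort(np.mod(t + rng.normal(0.0, sigmaJ, t.size), T))


def empirical_count_correlation(
    spikes_i: np.ndarray, spikes_j: np.ndarray, window: float, T: float
) -> float:
    """Pearson correlation of the two trains' spike counts in disjoint
    windows of the given width over ``[0, T)``."""
    if window <= 0:
        raise ValueError("window must be positive")
    if T < 100 * window:
        raise ValueError("recording must cover at least 100 windows")
    ci = counts_from_spike_times(spikes_i, window, T)
    cj = counts_from_spike_times(spikes_j, window, T)
    if ci.std() == 0 or cj.std() == 0:
        raise ZeroDivisionError("zero-variance counts: correlation undefined")
    return float(np.corrcoef(ci, cj)[0, 1])


# ---------------------------------------------------------------------------
# raster -> synaptic events
# ---------------------------------------------------------------------------


def raster_to_events(
    raster: SpikeRaster, weight_maps: Sequence[dict] | None = None,
    labels: Sequence | None = None,
) -> EventTrain:
    """Convert a raster into the synaptic event train driving a neuron set.

    All spikes within one bin form a single synaptic event at the bin's
    right edge ``j dt``; the event jump for neuron ``a`` sums
    ``k_i * |w_{i,a}|`` over the subpopulations assigned to it, excitatory
    and inhibitory components separately (sign of the weight encodes the
    type).  Subpopulations must map to a single signed weight per neuron.
    """
    if weight_maps is None:
        weight_maps = [m.get("weights", {}) for m in raster.subpop_meta]
    if labels is None:
        labels = sorted({lab for wm in weight_maps for lab in wm}, key=repr)
    labels = tuple(labels)
    if not labels:
        raise ValueError("no neuron assignments in weight maps")
    we_mat = np.zeros((raster.L, len(labels)))
    wi_mat = np.zeros((raster.L, len(labels)))
    for i, wm in enumerate(weight_maps):
        for j, lab in enumerate(labels):
            w = wm.get(lab, 0.0)
            if w > 0:
                we_mat[i, j] = w
            elif w < 0:
                wi_mat[i, j] = -w
    active = np.nonzero(raster.counts.sum(axis=0) > 0)[0]
    k = raster.counts[:, active].T.astype(float)  # (n_events, L)
    We = k @ we_mat
    Wi = k @ wi_mat
    hit = (We.sum(axis=1) + Wi.sum(axis=1)) > 0
    return EventTrain(
        times=(active[hit] + 1) * raster.dt, We=We[hit], Wi=Wi[hit], labels=labels
    )
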