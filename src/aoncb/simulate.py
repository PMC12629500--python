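"""Exact event-driven simulation of feedforward AONCB neurons.

In the instantaneous-synapse limit the voltage dynamics are piecewise
deterministic: between synaptic events each neuron relaxes exponentially
toward its resting level ``I/G`` with time constant ``tau``, and at an event
carrying dimensionless jumps ``(We, Wi)`` the voltage updates discontinuously
by the Marcus rule

    J = ( (We Ve + Wi Vi)/(We + Wi) - V ) * (1 - exp(-(We + Wi))),

the vanishing-regularization limit of the state-dependent conductance drive.
Given the event train, the scheme is exact (no discretization error) and
keeps the voltage inside ``(Vi, Ve)`` for zero injected current.

A finite synaptic-time-constant reference integrator (standard Euler with
box-car conductances of duration ``tau_s``) is provided to validate the
``tau_s/tau -> 0`` limit, and an exact propagator variant covers a pair of
neurons coupled by a gap junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .generator import EventTrain
from .params import NeuronParams
from .synchrony import JumpModel

__all__ = [
    "VoltageTrace",
    "marcus_jump",
    "simulate_population",
    "simulate_finite_synapse",
    "simulate_gap_junction_pair",
    "events_from_jump_model",
]


@dataclass
class VoltageTrace:
    """Piecewise-exponential voltage trace of a neuron set.

    Stores the post-event voltages ``V[n, a] = V_a(T_n)``; between events
    each neuron relaxes toward its resting level, so the trace is fully
    determined by ``(times, V, params, V0, T)``.
    """

    times: np.ndarray
    V: np.ndarray
    params: tuple
    labels: tuple
    V0: np.ndarray
    T: float
    #: gap-junction coupling g = G12/G for a coupled pair; 0 = uncoupled.
    #: with coupling, inter-event decay has a sum mode (rate 1/tau) and a
    #: difference mode (rate (1+2g)/tau)
    gap_coupling: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        self.V0 = np.atleast_1d(np.asarray(self.V0, dtype=float))
        if self.gap_coupling and self.n_neurons != 2:
            raise ValueError("gap coupling only supported for neuron pairs")

    @property
    def n_neurons(self) -> int:
        return self.V.shape[1]

    def resting(self, j: int) -> float:
        return self.params[j].Iratio

    def sample(self, tgrid: np.ndarray) -> np.ndarray:
        """Voltage at arbitrary times (exact interpolation)."""
        tgrid = np.asarray(tgrid, dtype=float)
        if self.times.size == 0:
            idx = np.full(tgrid.shape, -1, dtype=int)
            i0 = np.zeros(tgrid.shape, dtype=int)
            t_at = np.zeros_like(tgrid)
            V_tab = np.zeros((1, self.n_neurons))
        else:
            idx = np.searchsorted(self.times, tgrid, side="right") - 1
            i0 = np.maximum(idx, 0)
            t_at = np.where(idx >= 0, self.times[i0], 0.0)
            V_tab = self.V
        if self.gap_coupling:
            p = self.params[0]
            v1 = np.where(idx >= 0, V_tab[i0, 0], self.V0[0]) - p.Iratio
            v2 = np.where(idx >= 0, V_tab[i0, 1], self.V0[1]) - p.Iratio
            es = np.exp(-(tgrid - t_at) / p.tau)
            ed = np.exp(-(1.0 + 2.0 * self.gap_coupling) * (tgrid - t_at) / p.tau)
            s = 0.5 * (v1 + v2) * es
            d = 0.5 * (v1 - v2) * ed
            return np.column_stack((p.Iratio + s + d, p.Iratio + s - d))
        out = np.empty((tgrid.size, self.n_neurons))
        for j in range(self.n_neurons):
            p = self.params[j]
            v_at = np.where(idx >= 0, V_tab[i0, j], self.V0[j])
            out[:, j] = p.Iratio + (v_at - p.Iratio) * np.exp(-(tgrid - t_at) / p.tau)
        return out

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"time": self.times}
        for j, lab in enumerate(self.labels):
            cols[f"V_{lab}"] = self.V[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)


def marcus_jump(V_pre: float, We: float, Wi: float, params: NeuronParams) -> float:
    """Voltage jump of the Marcus rule (mV).

    The post-jump voltage is a convex combination of ``V_pre`` and the mixed
    reversal potential, so it stays inside ``(Vi, Ve)``.
    """
    if We < 0 or Wi < 0:
        raise ValueError("jump components must be nonnegative")
    W = We + Wi
    if W <= 0:
        raise ValueError("empty synaptic event: We = Wi = 0")
    mixed = (We * params.Ve + Wi * params.Vi) / W
    return (mixed - V_pre) * (1.0 - math.exp(-W))


def _affine_scan(logA: np.ndarray, B: np.ndarray, v0: float, max_decay: float = 250.0):
    """Solve ``v_n = exp(logA_n) v_{n-1} + B_n`` for all ``n`` by blocked
    cumulative products; blocks are capped at ``max_decay`` total log-decay
    to avoid under/overflow."""
    out = np.empty_like(B)
    n = B.size
    cum = np.cumsum(-logA)
    start = 0
    v = v0
    while start < n:
        stop = int(np.searchsorted(cum, cum[start] + max_decay)) + 1
        stop = min(max(stop, start + 1), n)
        P = np.exp(np.cumsum(logA[start:stop]))
        vn = P * (v + np.cumsum(B[start:stop] / P))
        out[start:stop] = vn
        v = vn[-1]
        start = stop
    return out


def simulate_population(
    events: EventTrain,
    params: Sequence[NeuronParams] | NeuronParams,
    V0=0.0,
    T: float | None = None,
) -> VoltageTrace:
    """Exact event-driven simulation of a feedforward neuron set.

    Each neuron relaxes independently toward ``I/G`` between events and
    applies its own Marcus update at each event; events with ``We = Wi = 0``
    for a neuron leave that neuron untouched.  The returned trace is exact
    for the given event train.
    """
    n = events.n_neurons
    if isinstance(params, NeuronParams):
        params = (params,) * n
    params = tuple(params)
    if len(params) != n:
        raise ValueError("one NeuronParams per neuron required")
    times = events.times
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("event times must be strictly increasing")
    T = float(times[-1]) if T is None else float(T)
    V0 = np.broadcast_to(np.asarray(V0, dtype=float), (n,)).copy()
    V = np.empty((times.size, n))
    dts = np.diff(np.concatenate(([0.0], times)))
    for j in range(n):
        p = params[j]
        if not (p.Vi < V0[j] < p.Ve):
            raise ValueError("initial voltage outside (Vi, Ve)")
        W = events.We[:, j] + events.Wi[:, j]
        Y = np.exp(-W)
        safe = np.where(W > 0, W, 1.0)
        mixed = np.where(
            W > 0, (events.We[:, j] * p.Ve + events.Wi[:, j] * p.Vi) / safe, 0.0
        )
        # u = V - I/G follows u_n = exp(-dt/tau - W) u_{n-1} + (mixed - I/G)(1-Y)
        logA = -dts / p.tau - W
        B = (mixed - p.Iratio) * (1.0 - Y)
        u = _affine_scan(logA, B, V0[j] - p.Iratio)
        V[:, j] = u + p.Iratio
    return VoltageTrace(times=times, V=V, params=params, labels=events.labels, V0=V0, T=T)


def simulate_finite_synapse(
    events: EventTrain,
    params: NeuronParams,
    tau_s: float,
    dt_euler: float,
    T: float | None = None,
    V0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler reference integrator at finite synaptic time constant ``tau_s``.

    Each synaptic event opens a box-car conductance of duration ``tau_s``
    and dimensionless amplitude ``W tau / tau_s`` (so the transferred charge
    matches the instantaneous-limit jump ``W``).  Integrates the full
    conductance-based dynamics with a forward Euler step and returns
    ``(tgrid, V)`` for a single neuron.  As ``epsilon = tau_s/tau -> 0`` the
    stationary statistics converge to the Marcus simulator's.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if dt_euler >= tau_s:
        raise ValueError("dt_euler must resolve tau_s (dt_euler < tau_s)")
    if events.n_neurons != 1:
        raise ValueError("finite-synapse reference integrator is single-neuron")
    T = float(events.times[-1] + 5 * tau_s) if T is None else float(T)
    n = int(round(T / dt_euler))
    ge = np.zeros(n + 1)
    gi = np.zeros(n + 1)
    amp = params.tau / tau_s
    starts = np.minimum((events.times / dt_euler).astype(int), n)
    stops = np.minimum(((events.times + tau_s) / dt_euler).astype(int), n)
    np.add.at(ge, starts, events.We[:, 0] * amp)
    np.add.at(ge, stops, -events.We[:, 0] * amp)
    np.add.at(gi, starts, events.Wi[:, 0] * amp)
    np.add.at(gi, stops, -events.Wi[:, 0] * amp)
    ge = np.cumsum(ge)[:n]
    gi = np.cumsum(gi)[:n]
    # V_{k+1} = V_k + dt/tau * (-(V_k - I/G) + ge (Ve - V_k) + gi (Vi - V_k))
    a = 1.0 - dt_euler / params.tau * (1.0 + ge + gi)
    if np.any(a <= 0):
        raise ValueError("Euler step unstable: reduce dt_euler")
    B = dt_euler / params.tau * (ge * params.Ve + gi * params.Vi + params.Iratio)
    V = _affine_scan(np.log(a), B, V0)
    tgrid = (np.arange(n) + 1) * dt_euler
    return tgrid, V


def simulate_gap_junction_pair(
    events: EventTrain,
    params: NeuronParams,
    g: float,
    V0=(0.0, 0.0),
    T: float | None = None,
) -> VoltageTrace:
    """Exact simulation of two identical neurons coupled by a gap junction.

    Between events the pair relaxes under the coupled linear system; in the
    symmetric/antisymmetric eigenbasis the sum mode decays at rate ``1/tau``
    and the difference mode at ``(1 + 2g)/tau``, which gives an exact
    inter-event propagator.  Marcus updates apply per neuron unchanged at
    events.  ``g = G12/G >= 0`` is the dimensionless coupling.
    """
    if g < 0:
        raise ValueError("coupling must be nonnegative")
    if events.n_neurons != 2:
        raise ValueError("gap-junction simulator expects a neuron pair")
    times = events.times
    T = float(times[-1]) if T is None else float(T)
    p = params
    V0 = np.asarray(V0, dtype=float)
    dts = np.diff(np.concatenate(([0.0], times)))
    ds = np.exp(-dts / p.tau)
    dd = np.exp(-(1.0 + 2.0 * g) * dts / p.tau)
    W = events.We + events.Wi
    Y = np.exp(-W)
    safe = np.where(W > 0, W, 1.0)
    mixed = np.where(W > 0, (events.We * p.Ve + events.Wi * p.Vi) / safe, 0.0)
    jump_add = (mixed - 0.0) * (1.0 - Y)  # post = Y*V + mixed*(1-Y)
    # equilibrium of the coupled relaxation (common for identical neurons)
    veq = p.Iratio  # symmetric resting level; difference mode decays to 0
    s = 0.5 * (V0[0] + V0[1]) - veq
    d = 0.5 * (V0[0] - V0[1])
    V = np.empty((times.size, 2))
    for i in range(times.size):
        s *= ds[i]
        d *= dd[i]
        v1 = veq + s + d
        v2 = veq + s - d
        v1 = Y[i, 0] * v1 + jump_add[i, 0]
        v2 = Y[i, 1] * v2 + jump_add[i, 1]
        V[i, 0], V[i, 1] = v1, v2
        s = 0.5 * (v1 + v2) - veq
        d = 0.5 * (v1 - v2)
    return VoltageTrace(
        times=times, V=V, params=(p, p), labels=events.labels, V0=V0, T=T,
        gap_coupling=g,
    )


def events_from_jump_model(
    jm: JumpModel, T: float, seed: int
) -> EventTrain:
    """Draw a Poisson event train from a jump model: event count
    ``Poisson(b T)``, uniform ordered times, i.i.d. jump draws."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(jm.rate * T)
    times = np.sort(rng.uniform(0.0, T, n))
    # guard against (measure-zero) float collisions
    keep = np.concatenate(([True], np.diff(times) > 0))
    times = times[keep]
    We, Wi = jm.sample(times.size, rng)
    return EventTrain(times=times, We=We, Wi=Wi, labels=jm.labels)
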