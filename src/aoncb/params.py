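"""Passive membrane parameters for all-or-none-conductance-based (AONCB) neurons.

The voltage of an AONCB neuron relaxes toward its resting level with membrane
time constant ``tau = C/G`` and is pushed around by excitatory and inhibitory
conductance transients bounded by the reversal potentials ``Ve`` and ``Vi``.
Potentials are measured relative to the leak reversal, which is fixed at 0 mV,
so that admissible voltages live in the open interval ``(Vi, Ve)`` whenever no
constant current is injected.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["NeuronParams"]


@dataclass(frozen=True)
class NeuronParams:
    """Passive membrane and reversal-potential constants of one neuron.

    Parameters
    ----------
    tau
        Passive membrane time constant ``C/G`` in seconds.
    Ve
        Excitatory reversal potential in mV (relative to leak).
    Vi
        Inhibitory reversal potential in mV (relative to leak).
    Iratio
        Constant-current resting level ``I/G`` in mV.  The neuron relaxes
        toward this value between synaptic events; 0 by default.

    Notes
    -----
    Defaults are the common cortical values ``tau = 15 ms``, ``Ve = 60 mV``
    and ``Vi = -10 mV``.
    """

    tau: float = 0.015
    Ve: float = 60.0
    Vi: float = -10.0
    Iratio: float = 0.0

    #: Leak reversal potential; the voltage origin.
    VL: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"membrane time constant must be positive, got {self.tau}")
        if not (self.Vi < self.VL < self.Ve):
            raise ValueError(
                f"reversal potentials must satisfy Vi < VL=0 < Ve, got Vi={self.Vi}, Ve={self.Ve}"
            )
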