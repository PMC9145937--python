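"""Receptor-register kinetics and the memantine/Mg2+ NMDA block model.

Each synapse carries receptor "registers" -- phenomenological
activation variables in [0, 1] that jump on a presynaptic spike and
decay exponentially between spikes (AMPA ~5 ms, NMDA ~100 ms, GABA
~10 ms by default).

The NMDA channel is voltage dependent: it stays closed (Mg2+ block)
below the calcium opening threshold of -68 mV, and above it conducts
with a memantine-dependent reduction.  Memantine is an uncompetitive,
voltage-dependent open-channel blocker: its potency follows a simple
Langmuir isotherm block = c / (c + IC50(V)), with IC50 interpolated
between 0.5 uM at -70 mV and 30 uM at -30 mV (hyperpolarized
potentials favour block), and the block is fully relieved by strong
depolarization above a relief threshold.  A virtual dose additionally
shifts the NMDA opening threshold upward, which is the mechanism by
which treatment limits tonic (excitotoxic) NMDA activity while
sparing strong phasic activation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

DEFAULT_TAU = {"AMPA": 0.005, "NMDA": 0.100, "GABA": 0.010}  # seconds
DEFAULT_INCREMENT = 0.7
DEFAULT_INCREMENTS = {"AMPA": 0.7, "NMDA": 0.15, "GABA": 0.7}


@dataclass(frozen=True)
class SynapticRegister:
    """Per-synapse receptor state with conductance-like activation."""

    receptor: str                  # AMPA | NMDA | GABA
    activation: float = 0.0        # unitless in [0, 1]
    weight: float = 1.0            # conductance-like scalar >= 0
    tau_decay: float = 0.0         # seconds; 0 -> receptor default

    def __post_init__(self):
        if self.receptor not in DEFAULT_TAU:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if not (0.0 <= self.activation <= 1.0):
            raise ValueError("activation must lie in [0, 1]")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.tau_decay == 0.0:
            object.__setattr__(self, "tau_decay", DEFAULT_TAU[self.receptor])
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be > 0")


def step_register(register: SynapticRegister, presyn_spike: bool,
                  dt: float, increment: float = DEFAULT_INCREMENT
                  ) -> SynapticRegister:
    """Advance a register by ``dt`` seconds.

    Without a presynaptic spike the activation decays as
    exp(-dt/tau); a spike adds ``increment`` and the result is
    clipped to 1.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a = register.activation * math.exp(-dt / register.tau_decay)
    if presyn_spike:
        a = min(1.0, a + increment)
    return replace(register, activation=a)


@dataclass(frozen=True)
class NMDAGatingParams:
    """Voltage gating and memantine-block parameters of the NMDA channel."""

    v_open_threshold: float = -68.0    # mV, Ca2+ opening threshold
    mg_block_enabled: bool = True
    memantine_conc: float = 0.0        # uM (bath concentration)
    ic50_hyperpol: float = 0.5         # uM at the hyperpolarized end
    ic50_depol: float = 30.0           # uM at the depolarized end
    v_hyperpol_range: tuple = (-70.0, -30.0)   # mV window of the IC50 data
    relief_threshold: float = -20.0    # mV; strong depolarization removes block
    shift_gain_mV: float = 9.3        # k: dose -> threshold shift scale
    shift_K_uM: float = 15.0           # half-saturating dose of the shift
    ca_shift_gain_mV: float = 80.0     # dose shift of the Ca opening threshold
    ca_shift_K_uM: float = 10.0       # half-saturating dose of the Ca shift
    ca_shift_hill: float = 1.5         # cooperativity of the Ca-shift dose law

    def __post_init__(self):
        if not (-90.0 < self.v_open_threshold < 0.0):
            raise ValueError("v_open_threshold must lie in (-90, 0) mV")
        if self.memantine_conc < 0:
            raise ValueError("memantine concentration must be >= 0")
        lo, hi = self.v_hyperpol_range
        if not lo < hi:
            raise ValueError("invalid hyperpolarized voltage range")
        if not (0 < self.ic50_hyperpol <= self.ic50_depol):
            raise ValueError("IC50 endpoints must satisfy 0 < low <= high")


def ic50_at_voltage(V: float, params: NMDAGatingParams) -> float:
    """Voltage-dependent IC50 (uM): linear between the window endpoints,
    clamped outside (0.5 uM at -70 mV up to 30 uM at -30 mV)."""
    lo, hi = params.v_hyperpol_range
    if V <= lo:
        return params.ic50_hyperpol
    if V >= hi:
        return params.ic50_depol
    f = (V - lo) / (hi - lo)
    return params.ic50_hyperpol + f * (params.ic50_depol - params.ic50_hyperpol)


def memantine_block_fraction(conc: float, V: float,
                             params: NMDAGatingParams | None = None) -> float:
    """Fraction of NMDA conductance blocked by memantine at potential V.

    Langmuir block c/(c + IC50(V)) below the relief threshold; zero at
    or above it (strong depolarization expels the blocker).
    """
    params = params or NMDAGatingParams()
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if conc == 0.0 or V >= params.relief_threshold:
        return 0.0
    return conc / (conc + ic50_at_voltage(V, params))


def nmda_open_fraction(V: float, nmda_activation: float,
                       params: NMDAGatingParams | None = None) -> float:
    """Open (conducting) fraction of the NMDA register at potential V.

    Zero below the (dose-shifted) opening threshold -- the Mg2+ block;
    above it, the activation reduced by the memantine block.  Never
    exceeds the activation itself.
    """
    params = params or NMDAGatingParams()
    if not (0.0 <= nmda_activation <= 1.0):
        raise ValueError("nmda_activation must lie in [0, 1]")
    thr = (effective_open_threshold(params.memantine_conc, params)
           if params.mg_block_enabled else -math.inf)
    if V < thr:
        return 0.0
    block = memantine_block_fraction(params.memantine_conc, V, params)
    return nmda_activation * (1.0 - block)


def threshold_shift(conc: float, params: NMDAGatingParams | None = None) -> float:
    """Dose-dependent upward shift (mV) of the NMDA opening threshold.

    Saturating in dose: k * c / (c + K); zero at zero dose, strictly
    increasing, bounded by k.
    """
    params = params or NMDAGatingParams()
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return params.shift_gain_mV * conc / (conc + params.shift_K_uM)


def effective_open_threshold(conc: float,
                             params: NMDAGatingParams | None = None) -> float:
    """Dose-shifted NMDA opening threshold (mV).

    At zero dose this is the printed -68 mV calcium opening threshold;
    virtual treatment raises it, so tonic near-rest NMDA activation is
    suppressed first while strongly depolarized (phasic) activation
    still opens the channel.
    """
    params = params or NMDAGatingParams()
    return params.v_open_threshold + threshold_shift(conc, params)


def effective_ca_threshold(conc: float,
                           params: NMDAGatingParams | None = None) -> float:
    """Dose-shifted calcium opening threshold (mV).

    Memantine raises the potential the channel must reach before
    calcium flows: the neuroprotective arm of the drug.  The shift is
    steeper in dose than the electrical threshold shift, so therapeutic
    doses abolish tonic (excitotoxic) calcium entry while synaptic
    charge transfer degrades only gradually.
    """
    params = params or NMDAGatingParams()
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    ch = conc ** params.ca_shift_hill
    Kh = params.ca_shift_K_uM ** params.ca_shift_hill
    return params.v_open_threshold + params.ca_shift_gain_mV * ch / (ch + Kh)


def dose_response_table(concs, voltages, params: NMDAGatingParams | None = None):
    """Block fraction over a conc x voltage grid, as row dicts
    (conc_uM, V_mV, block_fraction) -- the `dose-response` CLI payload."""
    params = params or NMDAGatingParams()
    return [
        {"conc_uM": c, "V_mV": v,
         "block_fraction": memantine_block_fraction(c, v, params)}
        for c in concs for v in voltages
    ]
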