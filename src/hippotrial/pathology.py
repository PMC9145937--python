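"""Alzheimer's disease pathology: synaptic decay and excitotoxicity.

Severity is imposed in two ways.

1. *Synaptic decay*: entorhinal-cortex layer-2 (EC2) synapses -- onto
   DG granule cells, DG interneurons and CA3 pyramidal cells -- are
   disabled one by one, in a seeded random order, until a target loss
   fraction is reached: 0% (control), 9% (moderate) or 18% (severe).

2. *Excitotoxicity*: raised extracellular glutamate over-stimulates
   NMDA receptors.  The phenomenological drive law

       power = powerA * (M - ReP),        powerA = 9

   uses the synaptic-function target M on a log scale: ln(9) = 2.197
   (control), ln(63) = 4.143 (moderate), ln(135) = 4.905 (severe).
   The engine consumes the severity as a multiplicative NMDA drive
   gain exp(M)/exp(M_control), i.e. 63/9 = 7x for moderate and
   135/9 = 15x for severe disease.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .network import Network

POWER_A = 9.0
SEVERITIES = ("control", "moderate", "severe")

_LOSS = {"control": 0.0, "moderate": 0.09, "severe": 0.18}
_SF_TARGET = {"control": math.log(9), "moderate": math.log(63),
              "severe": math.log(135)}


@dataclass
class PathologyState:
    """Severity level plus the record of what was done to the network."""

    severity: str
    target_loss_fraction: float
    sf_target: float
    disabled_synapses: list = field(default_factory=list)  # ordered ids
    powerA: float = POWER_A
    ReP: float = -70.0    # reference (resting) potential, mV

    @property
    def power(self) -> float:
        return excitotoxicity_power(self.sf_target, self.ReP, self.powerA)

    @property
    def drive_multiplier(self) -> float:
        return glutamate_drive_multiplier(self.severity)


def severity_params(severity: str) -> tuple[float, float]:
    """(target EC2 loss fraction, synaptic-function target M)."""
    if severity not in SEVERITIES:
        raise ValueError(f"unknown severity {severity!r}")
    return _LOSS[severity], _SF_TARGET[severity]


def excitotoxicity_power(M: float, ReP: float, powerA: float = POWER_A) -> float:
    """The excitotoxic drive law power = powerA * (M - ReP)."""
    if powerA <= 0:
        raise ValueError("powerA must be > 0")
    return powerA * (M - ReP)


def glutamate_drive_multiplier(severity: str) -> float:
    """NMDA drive gain relative to control: exp(M)/exp(M_control).

    control -> 1, moderate -> 63/9 = 7, severe -> 135/9 = 15.
    """
    _, sf = severity_params(severity)
    return math.exp(sf) / math.exp(_SF_TARGET["control"])


def eligible_synapses(network: Network) -> list[int]:
    """Indices of synapses eligible for AD pruning: every synapse whose
    presynaptic source is an EC2 fibre."""
    return [i for i, s in enumerate(network.synapses)
            if s.pre.startswith("EC2:")]


def apply_synaptic_decay(network: Network, target_loss_fraction: float,
                         rng_seed: int, severity: str = "control"
                         ) -> tuple[Network, PathologyState]:
    """Disable EC2 synapses one by one to the target loss fraction.

    Returns a deep-copied network (the input is untouched) and the
    pathology state with the ordered disabled-synapse ledger.  The
    number disabled is round-half-up(fraction * n_eligible).  With one
    seed, the severe disabled set extends the moderate one (the same
    one-by-one progression continued).
    """
    if not (0.0 <= target_loss_fraction < 1.0):
        raise ValueError("loss fraction must lie in [0, 1)")
    eligible = eligible_synapses(network)
    if not eligible:
        raise ValueError("network has no eligible EC2 synapses")

    n_disable = math.floor(target_loss_fraction * len(eligible) + 0.5)
    net = copy.deepcopy(network)
    order = np.random.default_rng(rng_seed).permutation(len(eligible))
    disabled = []
    for k in order[:n_disable]:
        idx = eligible[k]
        net.synapses[idx].enabled = False
        disabled.append(idx)

    _, sf = severity_params(severity)
    state = PathologyState(severity=severity,
                           target_loss_fraction=target_loss_fraction,
                           sf_target=sf, disabled_synapses=disabled)
    return net, state


def apply_severity(network: Network, severity: str, rng_seed: int
                   ) -> tuple[Network, PathologyState]:
    """Convenience wrapper: look up the severity's loss fraction and prune."""
    loss, _ = severity_params(severity)
    return apply_synaptic_decay(network, loss, rng_seed, severity=severity)


def decay_ledger(state: PathologyState):
    """Disabled-synapse ledger as row dicts (synapse_id, order_disabled)."""
    return [{"synapse_id": sid, "order_disabled": i + 1}
            for i, sid in enumerate(state.disabled_synapses)]
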