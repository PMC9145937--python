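"""Time-stepped simulation of the microcircuit under drive, pathology
and virtual memantine dose.

Neuron model: sixteen leaky-integrator compartments per cell with
passive nearest-neighbour coupling, conductance-based AMPA/NMDA/GABA
synaptic currents from the receptor registers, somatic threshold-reset
spiking with an absolute refractory period.  The NMDA conductance is
voltage gated (Mg2+ block below the dose-shifted opening threshold,
memantine Langmuir block above it) and is subject to per-cell
excitotoxic calcium-overload inactivation; see the receptors and
pathology modules for the science and docs/methods.md for the
calibration constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import stimulus
from ._kernel import run_kernel
from .network import Network
from .pathology import PathologyState, glutamate_drive_multiplier
from .receptors import (DEFAULT_INCREMENTS, DEFAULT_TAU, NMDAGatingParams,
                        effective_ca_threshold, effective_open_threshold)
from .stimulus import DriveConfig

TRIAL_DOSES = (0.0, 3.0, 10.0, 30.0)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    duration: float = 10.0         # seconds of recorded biological time
    burn_in: float = 2.0           # settling time before recording starts
    dt: float = 1e-4               # 0.1 ms integration step
    seed: int = 0
    severity: str = "control"
    dose_uM: float = 0.0
    allow_custom_dose: bool = False

    spike_threshold: float = -50.0  # mV
    v_reset: float = -70.0
    refractory: float = 5e-3        # seconds
    E_L: float = -70.0
    E_e: float = 0.0
    E_i: float = -75.0
    tau_m_principal: float = 0.020  # seconds
    tau_m_interneuron: float = 0.010
    g_coupling: float = 20.0        # inter-compartment, units of somatic g_leak
    g_leak_dend: float = 0.02       # dendritic leak relative to somatic

    # excitotoxic calcium-overload closure (see docs/methods.md)
    ca_chi: float = 0.0575          # load accumulation per unit NMDA current
    ca_tau: float = 0.6             # seconds, clearance time constant
    ca_high: float = 6.0            # shutdown threshold (load units)
    ca_low: float = 0.15            # recovery threshold
    ca_isat_ca1: float = 350      # CA1 influx saturation (current units)
    ca_vuln_ca1: float = 2.6        # CA1 excitotoxic vulnerability vs CA3

    het_sigma_drive: float = 0.03   # lognormal sigma of per-subject afferent drive
    het_sigma_chi: float = 0.15     # lognormal sigma of per-subject susceptibility

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.dose_uM not in TRIAL_DOSES and not self.allow_custom_dose:
            raise ValueError(
                f"dose_uM must be one of {TRIAL_DOSES} "
                "(set allow_custom_dose for exploratory doses)")
        if self.dose_uM < 0:
            raise ValueError("dose_uM must be >= 0")


@dataclass
class SpikeRecord:
    """Per-cell spike times (seconds, strictly increasing) for one run."""

    spike_times: dict              # cell_id -> np.ndarray of seconds
    regions: dict                  # cell_id -> region label
    kinds: dict                    # cell_id -> cell kind
    duration: float
    config: SimulationConfig

    def cells(self, region: str | None = None, principal_only: bool = True):
        """Cell ids of a region; by default the principal (projection)
        neurons only -- granule in DG, pyramidal in CA3/CA1."""
        principal = {"granule", "pyramidal"}
        return [cid for cid, reg in self.regions.items()
                if (region is None or reg == region)
                and (not principal_only or self.kinds[cid] in principal)]

    def to_rows(self):
        rows = []
        for cid, times in self.spike_times.items():
            for t in times:
                rows.append({"cell_id": cid, "region": self.regions[cid],
                             "spike_time_s": round(float(t), 6)})
        rows.sort(key=lambda r: (r["spike_time_s"], r["cell_id"]))
        return rows


def _external_index(network: Network):
    """Map external fibre ids to indices after the cells."""
    cfg = network.config
    idx, n = {}, len(network.cells)
    for k in range(cfg.n_ec2_fibres):
        idx[f"EC2:{k}"] = n + k
    base = n + cfg.n_ec2_fibres
    for k in range(cfg.n_ec3_fibres):
        idx[f"EC3:{k}"] = base + k
    base += cfg.n_ec3_fibres
    for k in range(cfg.n_septal_cells):
        idx[f"SEPTUM:{k}"] = base + k
    return idx


def compile_network(network: Network, nmda_gain: float = 1.0):
    """Flatten the synapse list into the kernel's arrays.

    Disabled synapses keep their slot with zero weight, so pathology
    changes nothing but the conductances.  ``nmda_gain`` is the
    severity's glutamate drive multiplier applied to every NMDA
    register weight.
    """
    ext = _external_index(network)

    def src(pre):
        return network.cell_index(pre) if ":" not in pre else ext[pre]

    e = [s for s in network.synapses if s.sign == "excitatory"]
    i = [s for s in network.synapses if s.sign == "inhibitory"]
    arr = {
        "pre_e": np.array([src(s.pre) for s in e], np.int64),
        "post_cell_e": np.array([network.cell_index(s.post_cell) for s in e],
                                np.int64),
        "post_comp_e": np.array([s.post_compartment for s in e], np.int64),
        "w_a": np.array([s.weights["AMPA"] * s.enabled for s in e]),
        "w_n": np.array([s.weights["NMDA"] * s.enabled * nmda_gain
                         for s in e]),
        "pre_i": np.array([src(s.pre) for s in i], np.int64),
        "post_cell_i": np.array([network.cell_index(s.post_cell) for s in i],
                                np.int64),
        "post_comp_i": np.array([s.post_compartment for s in i], np.int64),
        "w_g": np.array([s.weights["GABA"] * s.enabled for s in i]),
    }
    return arr


def run_simulation(network: Network, pathology: PathologyState | None,
                   drive: DriveConfig, sim_config: SimulationConfig,
                   rate_scale: float = 1.0, susceptibility: float = 1.0,
                   gating: NMDAGatingParams | None = None) -> SpikeRecord:
    """Integrate the network and return its spike record.

    ``pathology`` supplies the severity (NMDA drive gain); the network
    should already carry the pruned (disabled) synapses.  ``rate_scale``
    scales the afferent rate envelopes and ``susceptibility`` the
    excitotoxic load accumulation -- the two axes along which virtual
    subjects differ.  Bitwise reproducible for a given (network,
    configs, seed).
    """
    cfg = sim_config
    gain = (glutamate_drive_multiplier(pathology.severity)
            if pathology is not None else 1.0)
    gating = gating or NMDAGatingParams(memantine_conc=cfg.dose_uM)
    arrays = compile_network(network, nmda_gain=gain)

    n_cells = len(network.cells)
    n_steps = int(round((cfg.duration + cfg.burn_in) / cfg.dt))
    rec_from = int(round(cfg.burn_in / cfg.dt))
    netcfg = network.config

    # external drive rasters; one sub-seed per layer
    ss = np.random.SeedSequence(cfg.seed)
    s_ec2, s_ec3, s_sep = (int(c.generate_state(1)[0] % (2 ** 31))
                           for c in ss.spawn(3))
    ext = np.vstack([
        stimulus.binned_spike_matrix(cfg.duration + cfg.burn_in, "EC2", drive,
                                     netcfg.n_ec2_fibres, s_ec2,
                                     rate_scale, cfg.dt),
        stimulus.binned_spike_matrix(cfg.duration + cfg.burn_in, "EC3", drive,
                                     netcfg.n_ec3_fibres, s_ec3,
                                     rate_scale, cfg.dt),
        stimulus.binned_spike_matrix(cfg.duration + cfg.burn_in, "SEPTUM",
                                     drive,
                                     netcfg.n_septal_cells, s_sep,
                                     1.0, cfg.dt),
    ])

    V = np.full((n_cells, 16), cfg.E_L)
    # excitotoxic vulnerability is a property of pyramidal cells -- CA1
    # most of all (the classic pattern of delayed excitotoxic neuronal
    # death); granule cells (dense calcium buffering) and interneurons
    # resist overload
    ca_vuln = np.array(
        [(cfg.ca_vuln_ca1 if c.region == "CA1" else 1.0)
         if c.kind == "pyramidal" else 0.0 for c in network.cells])
    ca_isat = np.array([cfg.ca_isat_ca1 if c.region == "CA1" else 1e12
                        for c in network.cells])
    tau_m = np.array([cfg.tau_m_principal
                      if c.kind in ("granule", "pyramidal", "mossy")
                      else cfg.tau_m_interneuron for c in network.cells])

    max_spikes = int(n_cells * cfg.duration / cfg.refractory) + n_cells
    spike_cell = np.zeros(max_spikes, np.int32)
    spike_step = np.zeros(max_spikes, np.int32)

    theta_eff = effective_open_threshold(cfg.dose_uM, gating)
    theta_ca = effective_ca_threshold(cfg.dose_uM, gating)
    v_lo, v_hi = gating.v_hyperpol_range

    n_spikes, err_cell, err_step = run_kernel(
        n_steps, rec_from, cfg.dt, V, tau_m,
        arrays["pre_e"], arrays["post_cell_e"], arrays["post_comp_e"],
        arrays["w_a"], arrays["w_n"],
        arrays["pre_i"], arrays["post_cell_i"], arrays["post_comp_i"],
        arrays["w_g"],
        ext,
        np.exp(-cfg.dt / DEFAULT_TAU["AMPA"]),
        np.exp(-cfg.dt / DEFAULT_TAU["NMDA"]),
        np.exp(-cfg.dt / DEFAULT_TAU["GABA"]),
        DEFAULT_INCREMENTS["AMPA"], DEFAULT_INCREMENTS["NMDA"],
        DEFAULT_INCREMENTS["GABA"],
        cfg.E_L, cfg.E_e, cfg.E_i, cfg.spike_threshold, cfg.v_reset,
        int(round(cfg.refractory / cfg.dt)), cfg.g_coupling, cfg.g_leak_dend,
        theta_eff, theta_ca, gating.relief_threshold, cfg.dose_uM,
        gating.ic50_hyperpol, gating.ic50_depol, v_lo, v_hi,
        cfg.ca_chi * susceptibility, cfg.ca_tau, cfg.ca_high, cfg.ca_low,
        ca_isat, ca_vuln,
        spike_cell, spike_step,
    )
    if n_spikes < 0:
        raise SimulationError(
            f"non-finite potential in cell {network.cells[err_cell].id} "
            f"at t={(err_step - rec_from) * cfg.dt:.4f} s")
    n_spikes = min(n_spikes, max_spikes)

    times = {c.id: [] for c in network.cells}
    for k in range(n_spikes):
        times[network.cells[spike_cell[k]].id].append(spike_step[k] * cfg.dt)
    return SpikeRecord(
        spike_times={cid: np.array(ts) for cid, ts in times.items()},
        regions={c.id: c.region for c in network.cells},
        kinds={c.id: c.kind for c in network.cells},
        duration=cfg.duration,
        config=cfg,
    )


def detect_spikes(trace, spike_threshold: float, refractory: float,
                  dt: float) -> np.ndarray:
    """Spike times from a uniformly sampled potential trace.

    Upward threshold crossings; crossings within the refractory period
    of the previous spike are suppressed.
    """
    trace = np.asarray(trace, float)
    if trace.size == 0:
        return np.array([])
    above = trace >= spike_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    out, last = [], -np.inf
    for i in crossings:
        t = i * dt
        if t - last >= refractory:
            out.append(t)
            last = t
    return np.array(out)
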