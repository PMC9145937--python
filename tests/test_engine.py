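import numpy as np
import pytest

from hippotrial import DriveConfig, SimulationConfig, run_simulation
from hippotrial._kernel import run_kernel
from hippotrial.engine import compile_network, detect_spikes
from hippotrial.pathology import glutamate_drive_multiplier
from hippotrial.receptors import (DEFAULT_INCREMENTS, DEFAULT_TAU,
                                  NMDAGatingParams, effective_ca_threshold,
                                  effective_open_threshold)
from hippotrial.stats import count_spikes
from reference_kernel import reference_run


class TestDetectSpikes:
    def test_flat_subthreshold_trace(self):
        assert detect_spikes([-70] * 100, -50, 5e-3, 1e-4).size == 0

    def test_empty_trace(self):
        assert detect_spikes([], -50, 5e-3, 1e-4).size == 0

    def test_single_clean_crossing(self):
        trace = [-70] * 10 + [-45] * 5 + [-70] * 10
        times = detect_spikes(trace, -50, 5e-3, 1e-3)
        assert times.tolist() == [0.010]

    def test_refractory_suppresses_second_crossing(self):
        # two upward crossings 1 ms apart; 5 ms refractory keeps one
        trace = [-70, -45, -70, -45] + [-70] * 20
        assert detect_spikes(trace, -50, 5e-3, 1e-3).size == 1
        # with zero refractory both crossings count
        assert detect_spikes(trace, -50, 0.0, 1e-3).size == 2


class TestRunSimulation:
    def test_quiescence_without_drive(self, moderate_network, short_sim):
        net, path = moderate_network
        silent = DriveConfig(ec_rate_max=0.0, septal_rate_max=0.0)
        rec = run_simulation(net, path, silent, short_sim)
        assert sum(len(v) for v in rec.spike_times.values()) == 0

    def test_bitwise_determinism(self, moderate_network, short_sim, drive):
        net, path = moderate_network
        a = run_simulation(net, path, drive, short_sim)
        b = run_simulation(net, path, drive, short_sim)
        for cid in a.spike_times:
            assert np.array_equal(a.spike_times[cid], b.spike_times[cid])

    def test_zero_dose_reproduces_placebo_model(self, moderate_network,
                                                short_sim, drive):
        net, path = moderate_network
        a = run_simulation(net, path, drive, short_sim)
        b = run_simulation(net, path, drive, short_sim,
                           gating=NMDAGatingParams(memantine_conc=0.0))
        for cid in a.spike_times:
            assert np.array_equal(a.spike_times[cid], b.spike_times[cid])

    def test_spike_times_respect_contract(self, moderate_network, drive):
        net, path = moderate_network
        cfg = SimulationConfig(duration=1.0, burn_in=0.5, seed=2,
                               severity="moderate")
        rec = run_simulation(net, path, drive, cfg)
        total = 0
        for cid, times in rec.spike_times.items():
            total += len(times)
            if len(times):
                assert times.min() >= 0.0
                assert times.max() <= cfg.duration
            if len(times) > 1:
                assert np.diff(times).min() >= cfg.refractory - 1e-9
        assert total > 0

    def test_information_flow_dg_to_ca3(self, moderate_network, drive,
                                        short_sim):
        """Silencing every DG output does not increase CA3 spiking."""
        net, path = moderate_network
        base = run_simulation(net, path, drive, short_sim)
        import copy
        cut = copy.deepcopy(net)
        dg_cells = {c.id for c in cut.cells if c.region == "DG"}
        for s in cut.synapses:
            if s.pre in dg_cells:
                s.enabled = False
        silenced = run_simulation(cut, path, drive, short_sim)
        assert (count_spikes(silenced, "CA3")
                <= count_spikes(base, "CA3"))

    def test_invalid_dose_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dose_uM=7.0)
        SimulationConfig(dose_uM=7.0, allow_custom_dose=True)


def test_kernel_matches_pure_python_oracle(moderate_network, drive):
    """The compiled kernel reproduces, spike for spike, an independent
    step-by-step implementation of the same update rule."""
    from hippotrial import stimulus
    net, path = moderate_network
    cfg = SimulationConfig(duration=0.25, burn_in=0.05, seed=13,
                           severity="moderate", dose_uM=10.0)
    gain = glutamate_drive_multiplier("moderate")
    arrays = compile_network(net, nmda_gain=gain)
    gating = NMDAGatingParams(memantine_conc=cfg.dose_uM)

    n_cells = len(net.cells)
    n_steps = int(round((cfg.duration + cfg.burn_in) / cfg.dt))
    rec_from = int(round(cfg.burn_in / cfg.dt))
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(3)]
    ncfg = net.config
    ext = np.vstack([
        stimulus.binned_spike_matrix(cfg.duration + cfg.burn_in, "EC2",
                                     drive, ncfg.n_ec2_fibres, seeds[0],
                                     1.0, cfg.dt),
        stimulus.binned_spike_matrix(cfg.duration + cfg.burn_in, "EC3",
                                     drive, ncfg.n_ec3_fibres, seeds[1],
                                     1.0, cfg.dt),
        stimulus.binned_spike_matrix(cfg.duration + cfg.burn_in, "SEPTUM",
                                     drive, ncfg.n_septal_cells, seeds[2],
                                     1.0, cfg.dt),
    ])
    tau_m = np.array([cfg.tau_m_principal
                      if c.kind in ("granule", "pyramidal", "mossy")
                      else cfg.tau_m_interneuron for c in net.cells])
    ca_vuln = np.array([(cfg.ca_vuln_ca1 if c.region == "CA1" else 1.0)
                        if c.kind == "pyramidal" else 0.0
                        for c in net.cells])
    ca_isat = np.array([cfg.ca_isat_ca1 if c.region == "CA1" else 1e12
                        for c in net.cells])
    def args(V):
        return (n_steps, rec_from, cfg.dt, V, tau_m,
            arrays["pre_e"], arrays["post_cell_e"], arrays["post_comp_e"],
            arrays["w_a"], arrays["w_n"],
            arrays["pre_i"], arrays["post_cell_i"], arrays["post_comp_i"],
            arrays["w_g"], ext,
            np.exp(-cfg.dt / DEFAULT_TAU["AMPA"]),
            np.exp(-cfg.dt / DEFAULT_TAU["NMDA"]),
            np.exp(-cfg.dt / DEFAULT_TAU["GABA"]),
            DEFAULT_INCREMENTS["AMPA"], DEFAULT_INCREMENTS["NMDA"],
            DEFAULT_INCREMENTS["GABA"],
            cfg.E_L, cfg.E_e, cfg.E_i, cfg.spike_threshold, cfg.v_reset,
            int(round(cfg.refractory / cfg.dt)), cfg.g_coupling,
            cfg.g_leak_dend,
            effective_open_threshold(cfg.dose_uM, gating),
            effective_ca_threshold(cfg.dose_uM, gating),
            gating.relief_threshold, cfg.dose_uM,
            gating.ic50_hyperpol, gating.ic50_depol,
            *gating.v_hyperpol_range,
            cfg.ca_chi, cfg.ca_tau, cfg.ca_high, cfg.ca_low)

    spike_cell = np.zeros(100000, np.int32)
    spike_step = np.zeros(100000, np.int32)
    n, _, _ = run_kernel(*args(np.full((n_cells, 16), cfg.E_L)),
                         ca_isat, ca_vuln, spike_cell, spike_step)
    kernel_spikes = list(zip(spike_cell[:n].tolist(),
                             spike_step[:n].tolist()))
    oracle_spikes = reference_run(*args(np.full((n_cells, 16), cfg.E_L)),
                                  ca_isat, ca_vuln)
    assert n > 0
    assert kernel_spikes == oracle_spikes
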