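"""The in silico randomized trial.

Eighty virtual AD hippocampi are split by pathology into a moderate
group (9% EC2 synapse loss, 7x NMDA drive) and a severe group (18%
loss, 15x drive), forty each.  Each group is randomized into four
equal arms: placebo, 3 uM, 10 uM and 30 uM memantine.  Every
hippocampus is simulated once untreated (its baseline, 80 runs) and
every non-placebo hippocampus once more at its assigned dose (60
runs): 140 simulations in total for the default design.

Arm endpoint vectors use the placebo arm's baselines and each treated
arm's treated runs; the remaining baselines are retained as each
treated subject's own untreated reference.  Every virtual subject
carries its own synaptic-function factor (lognormal afferent-drive
scale), its own pruning pattern and its own afferent noise, all
derived from one master seed, so a full rerun is bit-for-bit
reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as st
from .engine import SimulationConfig, SpikeRecord, run_simulation
from .network import Network, NetworkConfig, build_network
from .pathology import apply_severity
from .stimulus import DriveConfig

ARM_LABELS = {0.0: "placebo", 3.0: "3uM", 10.0: "10uM", 30.0: "30uM"}


@dataclass(frozen=True)
class TrialDesign:
    arm_size: int = 10
    severities: tuple = ("moderate", "severe")
    doses: tuple = (0.0, 3.0, 10.0, 30.0)
    seed: int = 0

    @property
    def group_size(self) -> int:
        return self.arm_size * len(self.doses)

    @property
    def n_hippocampi(self) -> int:
        return self.group_size * len(self.severities)

    @property
    def n_simulations(self) -> int:
        n_treated_arms = sum(1 for d in self.doses if d > 0)
        return self.n_hippocampi + (len(self.severities) * n_treated_arms
                                    * self.arm_size)

    def __post_init__(self):
        if self.arm_size < 1:
            raise ValueError("arm_size must be >= 1")
        if 0.0 not in self.doses:
            raise ValueError("the dose set must include the placebo (0)")


@dataclass
class TrialResult:
    design: TrialDesign
    assignment: pd.DataFrame       # hippocampus_id, severity, arm
    endpoints: pd.DataFrame        # analysis set, one row per sim x region
    baselines: pd.DataFrame        # all 80 baseline runs (reference set)
    comparisons: dict              # (severity, region, endpoint) -> table
    correlations: pd.DataFrame     # severity, arm, pair, r, p, n


def randomize(design: TrialDesign, seed: int | None = None) -> pd.DataFrame:
    """Partition each severity group uniformly at random into equal arms.

    Returns a frame with hippocampus_id (e.g. ``moderate-07``),
    severity and arm; reproducible under the seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    arms = [ARM_LABELS[d] for d in sorted(design.doses)]
    for severity in design.severities:
        ids = [f"{severity}-{i:02d}" for i in range(design.group_size)]
        perm = rng.permutation(design.group_size)
        for slot, idx in enumerate(perm):
            rows.append({"hippocampus_id": ids[idx], "severity": severity,
                         "arm": arms[slot // design.arm_size]})
    return (pd.DataFrame(rows)
            .sort_values("hippocampus_id").reset_index(drop=True))


def _dose_of(arm: str) -> float:
    return {v: k for k, v in ARM_LABELS.items()}[arm]


def run_trial(design: TrialDesign,
              network_config: NetworkConfig | None = None,
              drive: DriveConfig | None = None,
              sim_config: SimulationConfig | None = None,
              keep_records: bool = False) -> TrialResult:
    """Run the full trial and its statistical analysis.

    One baseline simulation per hippocampus plus one treated
    simulation per non-placebo hippocampus.  The master seed in
    ``design.seed`` determines randomization, every subject's
    synaptic-function factor, pruning pattern and afferent noise.
    """
    drive = drive or DriveConfig()
    base_sim = sim_config or SimulationConfig()
    assignment = randomize(design)

    healthy = build_network(network_config)
    master = np.random.SeedSequence([design.seed, 2022])
    subject_seeds = master.spawn(design.n_hippocampi)

    analysis_records, baseline_records = {}, {}
    for (_, row), sseq in zip(assignment.iterrows(), subject_seeds):
        hid, severity, arm = (row.hippocampus_id, row.severity, row.arm)
        s_prune, s_sim, s_het = (int(c.generate_state(1)[0] % (2 ** 31))
                                 for c in sseq.spawn(3))
        het_rng = np.random.default_rng(s_het)
        rate_scale = float(np.exp(het_rng.normal(0.0,
                                                 base_sim.het_sigma_drive)))
        susceptibility = float(np.exp(het_rng.normal(
            0.0, base_sim.het_sigma_chi)))
        net, path = apply_severity(healthy, severity, s_prune)

        def simulate(dose):
            cfg = _with(base_sim, seed=s_sim, severity=severity,
                        dose_uM=dose)
            return run_simulation(net, path, drive, cfg,
                                  rate_scale=rate_scale,
                                  susceptibility=susceptibility)

        baseline = simulate(0.0)
        baseline_records[(hid, severity, "baseline")] = baseline
        if arm == "placebo":
            analysis_records[(hid, severity, arm)] = baseline
        else:
            analysis_records[(hid, severity, arm)] = simulate(_dose_of(arm))

    endpoints = st.endpoint_frame(analysis_records)
    baselines = st.endpoint_frame(baseline_records)
    comparisons = _compare_arms(endpoints, design)
    correlations = _correlate_regions(endpoints, design)
    result = TrialResult(design=design, assignment=assignment,
                         endpoints=endpoints, baselines=baselines,
                         comparisons=comparisons, correlations=correlations)
    if keep_records:
        result.records = analysis_records
        result.baseline_records = baseline_records
    return result


def _with(cfg: SimulationConfig, **kw) -> SimulationConfig:
    from dataclasses import replace
    return replace(cfg, **kw)


def _compare_arms(endpoints: pd.DataFrame, design: TrialDesign) -> dict:
    comparisons = {}
    specs = [(r, "n_spikes", "n_spikes") for r in ("DG", "CA3", "CA1")]
    specs += [("CA1", "mean_isi", "mean_isi_s"), ("CA1", "frequency",
                                                  "freq_hz")]
    for severity in design.severities:
        for region, endpoint, col in specs:
            groups = []
            sub = endpoints[(endpoints.severity == severity)
                            & (endpoints.region == region)]
            for dose in sorted(design.doses):
                arm = ARM_LABELS[dose]
                vals = sub[sub.arm == arm][col].dropna().to_numpy()
                if vals.size >= 2:
                    groups.append(st.EndpointVector(vals, endpoint, region,
                                                    arm))
            if len(groups) >= 2:
                comparisons[(severity, region, endpoint)] = \
                    st.anova_tukey(groups)
    return comparisons


def _correlate_regions(endpoints: pd.DataFrame, design: TrialDesign
                       ) -> pd.DataFrame:
    rows = []
    for severity in design.severities:
        for dose in sorted(design.doses):
            arm = ARM_LABELS[dose]
            sub = endpoints[(endpoints.severity == severity)
                            & (endpoints.arm == arm)]
            wide = sub.pivot(index="hippocampus_id", columns="region",
                             values="n_spikes")
            for a, b in (("CA1", "CA3"), ("DG", "CA3")):
                try:
                    r, p = st.pearson(wide[a], wide[b])
                except ValueError:
                    r, p = float("nan"), float("nan")
                rows.append({"severity": severity, "arm": arm,
                             "pair": f"{a}-{b}", "r": r, "p": p,
                             "n": len(wide)})
    return pd.DataFrame(rows)


def comparisons_to_json(result: TrialResult) -> dict:
    """Serializable stats.json payload."""
    out = {}
    for (severity, region, endpoint), tab in result.comparisons.items():
        out[f"{severity}/{region}/{endpoint}"] = {
            "anova_F": tab.anova_F,
            "anova_p": tab.anova_p,
            "brown_forsythe_p": tab.brown_forsythe_p,
            "shapiro_p": tab.shapiro_p,
            "group_means": tab.group_means.to_dict(orient="records"),
            "tukey": tab.tukey.to_dict(orient="records"),
        }
    out["correlations"] = result.correlations.to_dict(orient="records")
    return out
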