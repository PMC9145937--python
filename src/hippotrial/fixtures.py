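"""Deterministic synthetic fixtures for tests and examples.

`make_fixture` writes small spike CSVs or mini-networks used by the
stats and engine test surfaces; everything is generated from the
parameters and seed, never shipped as data files.
"""

from __future__ import annotations

import csv

import numpy as np

from .engine import SimulationConfig, SpikeRecord
from .network import Network, NetworkConfig, build_network

FIXTURE_KINDS = ("regular_trains", "poisson_trains", "toy_network")


def regular_record(rate_hz: float = 20.0, duration: float = 1.0,
                   n_cells: int = 8, region: str = "CA1") -> SpikeRecord:
    """A SpikeRecord of perfectly regular trains (rate_hz each)."""
    if rate_hz <= 0 or duration <= 0 or n_cells < 1:
        raise ValueError("rate, duration and n_cells must be positive")
    times = np.arange(0.0, duration - 1e-12, 1.0 / rate_hz)
    kind = {"DG": "granule"}.get(region, "pyramidal")
    ids = [f"{region}c{i}" for i in range(n_cells)]
    return SpikeRecord(
        spike_times={i: times.copy() for i in ids},
        regions={i: region for i in ids},
        kinds={i: kind for i in ids},
        duration=duration,
        config=SimulationConfig(duration=duration),
    )


def poisson_record(rate_hz: float = 20.0, duration: float = 1.0,
                   n_cells: int = 8, region: str = "CA1",
                   seed: int = 0) -> SpikeRecord:
    """A SpikeRecord of homogeneous Poisson trains."""
    if rate_hz < 0 or duration <= 0 or n_cells < 1:
        raise ValueError("invalid parameters")
    rng = np.random.default_rng(seed)
    kind = {"DG": "granule"}.get(region, "pyramidal")
    ids = [f"{region}c{i}" for i in range(n_cells)]
    trains = {}
    for i in ids:
        n = rng.poisson(rate_hz * duration)
        trains[i] = np.sort(rng.uniform(0, duration, n))
    return SpikeRecord(
        spike_times=trains,
        regions={i: region for i in ids},
        kinds={i: kind for i in ids},
        duration=duration,
        config=SimulationConfig(duration=duration),
    )


def toy_network() -> Network:
    """The full (but smallest shipped) network build -- used where a
    valid Network satisfying all invariants is needed cheaply."""
    return build_network(NetworkConfig(ec_multiplicity=1))


def make_fixture(kind: str, params: dict | None = None, seed: int = 0,
                 out_path=None):
    """Build a named fixture; optionally write it as CSV.

    regular_trains / poisson_trains -> SpikeRecord (CSV: cell_id,
    region, spike_time_s); toy_network -> Network (CSV: cell census).
    """
    params = dict(params or {})
    if kind == "regular_trains":
        obj = regular_record(**params)
    elif kind == "poisson_trains":
        obj = poisson_record(seed=seed, **params)
    elif kind == "toy_network":
        obj = toy_network()
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    if out_path is not None:
        with open(out_path, "w", newline="") as fh:
            if isinstance(obj, SpikeRecord):
                w = csv.DictWriter(fh, ["cell_id", "region", "spike_time_s"])
                w.writeheader()
                w.writerows(obj.to_rows())
            else:
                w = csv.DictWriter(fh, ["id", "region", "kind",
                                        "n_compartments"])
                w.writeheader()
                from .network import census
                w.writerows(census(obj)[0])
    return obj
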