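"""DG-CA3-CA1 hippocampal microcircuit construction.

The simulated circuit contains 33 cells: the dentate gyrus (8 granule
cells G1-G8, 2 basket cells, 1 mossy cell), CA3 (8 pyramidal cells,
2 basket cells, 1 O-LM cell) and CA1 (8 pyramidal cells, 2 basket
cells, 1 O-LM cell).  Every cell has 16 compartments (index 0 is the
soma, 1-15 are dendritic, proximal to distal).  External afferents --
entorhinal cortex layers 2 and 3 (EC2, EC3) and the GABAergic
medial-septum/diagonal-band pacemaker cells (T1-T9) -- are modelled as
spike sources, not integrated neurons.

Excitatory synapses carry two receptor registers (AMPA + NMDA);
inhibitory synapses carry one (GABA).  Topology is fully deterministic
for a given configuration; fan-in patterns are fixed round-robin
assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

N_COMPARTMENTS = 16
SOMA = 0

REGIONS = ("DG", "CA3", "CA1")
KINDS = ("granule", "pyramidal", "basket", "OLM", "mossy")

# external source labels -> number of fibres (resolved from config)
EXTERNAL_LAYERS = ("EC2", "EC3", "SEPTUM")


class ConfigurationError(ValueError):
    """Raised when a network configuration violates its contract."""


@dataclass(frozen=True)
class CellSpec:
    """One simulated cell: identity, region and type."""

    id: str
    region: str
    kind: str
    n_compartments: int = N_COMPARTMENTS

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ConfigurationError(f"unknown region {self.region!r}")
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown cell kind {self.kind!r}")
        if self.n_compartments != N_COMPARTMENTS:
            raise ConfigurationError("all cells are sixteen-compartmented")
        if self.kind == "granule" and self.region != "DG":
            raise ConfigurationError("granule cells live in DG only")
        if self.kind == "pyramidal" and self.region not in ("CA3", "CA1"):
            raise ConfigurationError("pyramidal cells live in CA3/CA1 only")


@dataclass
class Synapse:
    """A synapse with its receptor registers.

    ``pre`` is either a cell id (e.g. ``"P3"``) or an external fibre id
    (e.g. ``"EC2:4"``).  ``registers`` lists the receptor names only;
    register *state* lives in the engine.
    """

    pre: str
    post_cell: str
    post_compartment: int
    sign: str                      # "excitatory" | "inhibitory"
    weights: dict = field(default_factory=dict)   # receptor -> weight
    enabled: bool = True
    projection: str = ""

    def __post_init__(self):
        if self.sign == "excitatory":
            expected = {"AMPA", "NMDA"}
        elif self.sign == "inhibitory":
            expected = {"GABA"}
        else:
            raise ConfigurationError(f"unknown synapse sign {self.sign!r}")
        if set(self.weights) != expected:
            raise ConfigurationError(
                f"{self.sign} synapse must carry registers {sorted(expected)}"
            )
        for r, w in self.weights.items():
            if w < 0:
                raise ConfigurationError(f"negative weight for {r}")
        if not (0 <= self.post_compartment < N_COMPARTMENTS):
            raise ConfigurationError("compartment index out of range")

    @property
    def registers(self) -> list[str]:
        return sorted(self.weights)


@dataclass
class NetworkConfig:
    """Synaptic weights, fibre counts and placement defaults.

    Weights are conductances relative to the leak conductance.  The EC
    multiplicity (synapses per stated EC projection per target cell)
    defaults to 10 so that 9% / 18% pruning has integer resolution on
    the eligible EC2 census.
    """

    ec_multiplicity: int = 10
    n_ec2_fibres: int = 10
    n_ec3_fibres: int = 10
    n_septal_cells: int = 9

    # excitatory weights (AMPA, NMDA) per projection
    w_ec2_granule: tuple = (0.35, 0.40)
    w_ec2_dg_basket: tuple = (0.25, 0.005)
    w_ec2_ca3_pyr: tuple = (0.03, 0.006)
    w_ec2_ca3_basket: tuple = (0.15, 0.005)
    w_ec3_ca1_pyr: tuple = (0.06, 0.09)
    w_mossy_fibre: tuple = (0.06, 0.16)     # granule -> CA3 pyramidal
    w_granule_mossy: tuple = (0.15, 0.01)
    w_mossy_granule: tuple = (0.05, 0.01)
    w_granule_basket: tuple = (0.15, 0.005)
    w_ca3_recurrent: tuple = (0.01, 0.06)
    w_schaffer: tuple = (0.13, 0.02)        # CA3 -> CA1 pyramidal
    w_pyr_basket: tuple = (0.20, 0.005)
    w_pyr_olm: tuple = (0.10, 0.005)

    # inhibitory weights (GABA)
    w_basket_granule: float = 1.0
    w_basket_ca3: float = 1.0
    w_basket_ca1: float = 1.0
    w_olm_principal: float = 0.30
    w_septum_interneuron: float = 1.50

    # fan-in counts for internal projections
    fanin_mossy_fibre: int = 4
    fanin_schaffer: int = 4
    fanin_recurrent: int = 4
    fanin_granule_basket: int = 4
    fanin_pyr_basket: int = 4
    fanin_septum: int = 2

    def validate(self):
        for name in ("ec_multiplicity", "n_ec2_fibres", "n_ec3_fibres",
                     "n_septal_cells"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name, val in vars(self).items():
            if name.startswith("w_"):
                ws = val if isinstance(val, tuple) else (val,)
                if any(w < 0 for w in ws):
                    raise ConfigurationError(f"negative weight in {name}")
            if name.startswith("fanin_") and val < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        return self


@dataclass
class Network:
    cells: list            # list[CellSpec]
    synapses: list         # list[Synapse]
    config: NetworkConfig

    def cell_index(self, cell_id: str) -> int:
        return self._index[cell_id]

    def __post_init__(self):
        self._index = {c.id: i for i, c in enumerate(self.cells)}

    def cells_of(self, region: str | None = None, kind: str | None = None):
        if region is not None and region not in REGIONS:
            raise ConfigurationError(f"unknown region {region!r}")
        if kind is not None and kind not in KINDS:
            raise ConfigurationError(f"unknown cell kind {kind!r}")
        return [c for c in self.cells
                if (region is None or c.region == region)
                and (kind is None or c.kind == kind)]

    def synapses_from(self, pre_prefix: str):
        return [s for s in self.synapses if s.pre.startswith(pre_prefix)]


def _input_compartment(i: int) -> int:
    """Apical input zone (compartments 2..7).

    Excitatory afferents attach where the somatic reset still clamps
    the local potential into the memantine-sensitive voltage range;
    the outer cable (8..15) is a passive load."""
    return 2 + (i % 6)


def build_network(config: NetworkConfig | None = None) -> Network:
    """Construct the 33-cell microcircuit.

    Deterministic for a given config: fibre and fan-in assignments are
    round-robin, all synapses start enabled.
    """
    cfg = (config or NetworkConfig()).validate()

    cells = []
    cells += [CellSpec(f"G{i+1}", "DG", "granule") for i in range(8)]
    cells += [CellSpec("B1", "DG", "basket"), CellSpec("B2", "DG", "basket")]
    cells += [CellSpec("MC", "DG", "mossy")]
    cells += [CellSpec(f"P{i+1}", "CA3", "pyramidal") for i in range(8)]
    cells += [CellSpec("B3", "CA3", "basket"), CellSpec("B4", "CA3", "basket")]
    cells += [CellSpec("OLM1", "CA3", "OLM")]
    cells += [CellSpec(f"P{i+9}", "CA1", "pyramidal") for i in range(8)]
    cells += [CellSpec("B5", "CA1", "basket"), CellSpec("B6", "CA1", "basket")]
    cells += [CellSpec("OLM2", "CA1", "OLM")]

    granule = [f"G{i+1}" for i in range(8)]
    ca3_pyr = [f"P{i+1}" for i in range(8)]
    ca1_pyr = [f"P{i+9}" for i in range(8)]
    dg_baskets, ca3_baskets, ca1_baskets = ["B1", "B2"], ["B3", "B4"], ["B5", "B6"]

    syns: list[Synapse] = []

    def exc(pre, post, comp, w, projection):
        syns.append(Synapse(pre, post, comp, "excitatory",
                            {"AMPA": w[0], "NMDA": w[1]}, projection=projection))

    def inh(pre, post, comp, w, projection):
        syns.append(Synapse(pre, post, comp, "inhibitory",
                            {"GABA": w}, projection=projection))

    m = cfg.ec_multiplicity

    # EC2 -> DG granule cells and DG basket cells (perforant path, distal)
    for ci, post in enumerate(granule):
        for j in range(m):
            fibre = f"EC2:{(ci + j) % cfg.n_ec2_fibres}"
            exc(fibre, post, _input_compartment(ci + j), cfg.w_ec2_granule,
                "ec2_granule")
    for ci, post in enumerate(dg_baskets):
        for j in range(m):
            fibre = f"EC2:{(ci + j) % cfg.n_ec2_fibres}"
            exc(fibre, post, _input_compartment(ci + j), cfg.w_ec2_dg_basket,
                "ec2_dg_basket")
    # EC2 -> CA3 pyramidal cells and CA3 basket cells
    for ci, post in enumerate(ca3_pyr):
        for j in range(m):
            fibre = f"EC2:{(ci + j) % cfg.n_ec2_fibres}"
            exc(fibre, post, _input_compartment(ci + j), cfg.w_ec2_ca3_pyr,
                "ec2_ca3_pyr")
    for ci, post in enumerate(ca3_baskets):
        for j in range(m):
            fibre = f"EC2:{(ci + j) % cfg.n_ec2_fibres}"
            exc(fibre, post, _input_compartment(ci + j), cfg.w_ec2_ca3_basket,
                "ec2_ca3_basket")
    # EC3 -> CA1 pyramidal cells (temporoammonic path, distal)
    for ci, post in enumerate(ca1_pyr):
        for j in range(m):
            fibre = f"EC3:{(ci + j) % cfg.n_ec3_fibres}"
            exc(fibre, post, _input_compartment(ci + j), cfg.w_ec3_ca1_pyr,
                "ec3_ca1_pyr")

    # DG internal: granule <-> mossy cell, granule -> baskets
    for ci, pre in enumerate(granule):
        exc(pre, "MC", _input_compartment(ci), cfg.w_granule_mossy, "granule_mossy")
        exc("MC", pre, 2, cfg.w_mossy_granule, "mossy_granule")
    for ci, post in enumerate(dg_baskets):
        for j in range(cfg.fanin_granule_basket):
            exc(granule[(2 * ci + j) % 8], post, _input_compartment(j),
                cfg.w_granule_basket, "granule_dg_basket")

    # mossy fibres: granule -> CA3 pyramidal (proximal, detonator)
    for ci, post in enumerate(ca3_pyr):
        for j in range(cfg.fanin_mossy_fibre):
            exc(granule[(ci + j) % 8], post, 1 + (j % 3), cfg.w_mossy_fibre,
                "mossy_fibre")
    # CA3 recurrent collaterals
    for ci, post in enumerate(ca3_pyr):
        for j in range(cfg.fanin_recurrent):
            pre = ca3_pyr[(ci + 1 + j) % 8]
            exc(pre, post, _input_compartment(ci + j), cfg.w_ca3_recurrent,
                "ca3_recurrent")
    # CA3 pyramidal -> CA3 baskets, O-LM1
    for ci, post in enumerate(ca3_baskets):
        for j in range(cfg.fanin_pyr_basket):
            exc(ca3_pyr[(2 * ci + j) % 8], post, _input_compartment(j),
                cfg.w_pyr_basket, "ca3_pyr_basket")
    for pre in ca3_pyr:
        exc(pre, "OLM1", _input_compartment(0), cfg.w_pyr_olm, "ca3_pyr_olm")

    # Schaffer collaterals: CA3 -> CA1 pyramidal (mid-dendritic)
    for ci, post in enumerate(ca1_pyr):
        for j in range(cfg.fanin_schaffer):
            exc(ca3_pyr[(ci + j) % 8], post, _input_compartment(ci + j),
                cfg.w_schaffer, "schaffer")
    # CA1 pyramidal -> CA1 baskets, O-LM2
    for ci, post in enumerate(ca1_baskets):
        for j in range(cfg.fanin_pyr_basket):
            exc(ca1_pyr[(2 * ci + j) % 8], post, _input_compartment(j),
                cfg.w_pyr_basket, "ca1_pyr_basket")
    for pre in ca1_pyr:
        exc(pre, "OLM2", _input_compartment(0), cfg.w_pyr_olm, "ca1_pyr_olm")

    # perisomatic inhibition: baskets -> principal cells of their region
    for baskets, principals, w in ((dg_baskets, granule, cfg.w_basket_granule),
                                   (ca3_baskets, ca3_pyr, cfg.w_basket_ca3),
                                   (ca1_baskets, ca1_pyr, cfg.w_basket_ca1)):
        for pre in baskets:
            for post in principals:
                inh(pre, post, SOMA, w, "basket_principal")
    # distal-dendritic inhibition: O-LM -> principal cells
    for pre, principals in (("OLM1", ca3_pyr), ("OLM2", ca1_pyr)):
        for ci, post in enumerate(principals):
            inh(pre, post, _input_compartment(ci), cfg.w_olm_principal,
                "olm_principal")

    # septal (MS-DB, T1-T9) rhythmic inhibition of interneurons: the
    # theta-patterned disinhibitory pathway.
    interneurons = dg_baskets + ca3_baskets + ca1_baskets + ["OLM1", "OLM2"]
    for ci, post in enumerate(interneurons):
        for j in range(cfg.fanin_septum):
            pre = f"SEPTUM:{(ci + j) % cfg.n_septal_cells}"
            inh(pre, post, SOMA, cfg.w_septum_interneuron, "septum_interneuron")

    net = Network(cells=cells, synapses=syns, config=cfg)
    assert len(net.cells) == 33
    return net


def count_cells(network: Network, region: str | None = None,
                kind: str | None = None) -> int:
    """Number of cells matching ``region`` and/or ``kind``."""
    return len(network.cells_of(region, kind))


def census(network: Network):
    """Cell and synapse census as two row-dict lists (CSV-ready)."""
    cell_rows = [
        {"id": c.id, "region": c.region, "kind": c.kind,
         "n_compartments": c.n_compartments}
        for c in network.cells
    ]
    syn_rows = [
        {"pre": s.pre, "post_cell": s.post_cell,
         "post_compartment": s.post_compartment, "sign": s.sign,
         "enabled": s.enabled}
        for s in network.synapses
    ]
    return cell_rows, syn_rows
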