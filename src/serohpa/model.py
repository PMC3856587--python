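"""The 41-node serotonin / HPA-axis / BDNF depression model.

This module ships the biological network (see ``data/mdd_network.bnet``) and
the four simulation scenarios.  The model couples three pathways:

* **Serotonin handling in the dorsal raphe nucleus (DRN)** — synthesis
  (TRP → 5-HTP → 5-HT*), degradation (MAOA → 5-HIAA), vesicular packaging
  and release into the synaptic cleft, reuptake by the transporter 5-HTT,
  and the inhibitory autoreceptor 5-HT1A* with its K⁺-channel
  hyperpolarization branch.
* **The HPA stress axis** — stress → CRH/VPA → ACTH → cortisol, with
  glucocorticoid/mineralocorticoid (GR/MR) receptor negative feedback at the
  paraventricular nucleus and the pituitary, plus GR/MR control of the DRN
  (blocking TPH2) and of the hippocampal serotonin-sensitive cell (blocking
  NF-κB and hence 5-HT1A expression).
* **The BDNF/TRkB neurotrophin loop** — CREB-driven BDNF sustains TRkB
  signalling, which maintains the serotonergic phenotype genes and
  suppresses the autoreceptor; autoreceptor-driven hyperpolarization blocks
  the loop.

Three environmental inputs (stress, TRP, SSRI) are clamped: no rule
regulates them, so they keep their initial value for a whole run.  Nine
ubiquitously expressed signalling intermediates (Gi subunits, the cAMP/PKA
cascade, postsynaptic effectors) are carried as pass-through taps with no
outgoing functional edges; they are excluded from result plots, which show
the remaining 32 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

from .core import AttractorResult, BooleanNetwork, find_attractor, parse_bnet, simulate

__all__ = [
    "ScenarioSpec",
    "ModelCatalog",
    "SCENARIO_NAMES",
    "NODE_LABELS",
    "RELAY_NODES",
    "GRMR_GROUP",
    "KNOCKOUT_UNITS",
    "build_mdd_network",
    "scenario_initial_state",
    "run_scenario",
]

#: Display labels for plots and tables, keyed by internal node identifier.
NODE_LABELS: dict[str, str] = {
    "stress": "stress",
    "TRP": "TRP",
    "SSRI": "SSRI",
    "TPH2": "TPH2",
    "HTP5": "5-HTP",
    "AADC": "AADC",
    "HT5_DRN": "5-HT*",
    "MAOA": "MAOA",
    "HIAA5": "5-HIAA",
    "SLC18A2": "SL18A2",
    "VESICLE": "5-HT vesicle",
    "SNARE": "SNARE",
    "HT5_SYN": "5-HT",
    "HTT": "5-HTT",
    "HT1A_PRE": "5-HT1A*",
    "KCH_PRE": "K-Channel*",
    "K_PRE": "K+*",
    "HT1A_POST": "5-HT1A",
    "KCH_POST": "K-Channel",
    "K_POST": "K+",
    "NFKB": "NFkB",
    "CREB": "CREB",
    "BDNF": "BDNF",
    "TRKB": "TRkB",
    "CRH": "CRH",
    "VPA": "VPA",
    "ACTH": "ACTH",
    "CORT": "cortisol",
    "GRMR_PG": "GR/MR(PG)",
    "GRMR_PVN": "GR/MR(PVN)",
    "GRMR_DRN": "GR/MR(DRN)",
    "GRMR_SSC": "GR/MR(SSC)",
    "GI_PRE": "Gi*",
    "GBG_PRE": "Gbg*",
    "AC": "AC",
    "CAMP": "cAMP",
    "PKA": "PKA",
    "GI_POST": "Gi",
    "GBG_POST": "Gbg",
    "AC_POST": "AC(post)",
    "CAMP_POST": "cAMP(post)",
}

#: Ubiquitous signalling intermediates excluded from result plots.
RELAY_NODES: tuple[str, ...] = (
    "GI_PRE",
    "GBG_PRE",
    "AC",
    "CAMP",
    "PKA",
    "GI_POST",
    "GBG_POST",
    "AC_POST",
    "CAMP_POST",
)

#: The four GR/MR receptor nodes, treated as one unit in knockout analysis.
GRMR_GROUP: tuple[str, ...] = ("GRMR_PG", "GRMR_PVN", "GRMR_DRN", "GRMR_SSC")

#: Clamped environmental inputs.
INPUT_NODES: tuple[str, ...] = ("stress", "TRP", "SSRI")

#: Knockout roster: 22 single nodes plus the GR/MR group = 23 units.  The
#: clamped environmental inputs (stress, TRP, SSRI) are not knockout
#: candidates.
KNOCKOUT_UNITS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("TPH2", ("TPH2",)),
    ("5-HTP", ("HTP5",)),
    ("AADC", ("AADC",)),
    ("5-HT*", ("HT5_DRN",)),
    ("MAOA", ("MAOA",)),
    ("SL18A2", ("SLC18A2",)),
    ("5-HT", ("HT5_SYN",)),
    ("5-HT1A", ("HT1A_POST",)),
    ("K-Channel", ("KCH_POST",)),
    ("K+", ("K_POST",)),
    ("5-HT1A*", ("HT1A_PRE",)),
    ("K-Channel*", ("KCH_PRE",)),
    ("K+*", ("K_PRE",)),
    ("5-HTT", ("HTT",)),
    ("CREB", ("CREB",)),
    ("BDNF", ("BDNF",)),
    ("TRkB", ("TRKB",)),
    ("CRH", ("CRH",)),
    ("VPA", ("VPA",)),
    ("ACTH", ("ACTH",)),
    ("cortisol", ("CORT",)),
    ("GR/MR", GRMR_GROUP),
    ("NFkB", ("NFKB",)),
)

SCENARIO_NAMES = ("basal", "antidepressant", "chronic_stress", "complete")


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the four simulation scenarios (which clamped inputs are on)."""

    name: str
    stress_on: int
    ssri_on: int

    def __post_init__(self) -> None:
        if self.stress_on not in (0, 1) or self.ssri_on not in (0, 1):
            raise ValueError("stress_on/ssri_on must be 0 or 1")


def _load_scenarios() -> dict[str, ScenarioSpec]:
    text = (resources.files("serohpa") / "data" / "scenarios.yaml").read_text()
    raw = yaml.safe_load(text)["scenarios"]
    return {
        name: ScenarioSpec(name=name, stress_on=int(v["stress"]), ssri_on=int(v["ssri"]))
        for name, v in raw.items()
    }


@dataclass
class ModelCatalog:
    """The shipped model: network plus display and analysis metadata."""

    network: BooleanNetwork
    labels: dict[str, str]
    display_nodes: list[str]
    relay_nodes: tuple[str, ...]
    grmr_group: tuple[str, ...]
    knockout_units: tuple[tuple[str, tuple[str, ...]], ...]
    scenarios: dict[str, ScenarioSpec] = field(default_factory=dict)

    def display_indices(self) -> list[int]:
        return [self.network.index(n) for n in self.display_nodes]

    def scenario(self, name: str) -> ScenarioSpec:
        try:
            return self.scenarios[name]
        except KeyError:
            raise KeyError(
                f"unknown scenario {name!r}; choose from {sorted(self.scenarios)}"
            ) from None


def build_mdd_network() -> ModelCatalog:
    """Load and validate the shipped 41-node model."""
    text = (resources.files("serohpa") / "data" / "mdd_network.bnet").read_text()
    net = parse_bnet(text)
    display = [n for n in net.nodes if n not in RELAY_NODES]
    catalog = ModelCatalog(
        network=net,
        labels=dict(NODE_LABELS),
        display_nodes=display,
        relay_nodes=RELAY_NODES,
        grmr_group=GRMR_GROUP,
        knockout_units=KNOCKOUT_UNITS,
        scenarios=_load_scenarios(),
    )
    _validate_catalog(catalog)
    return catalog


def _validate_catalog(catalog: ModelCatalog) -> None:
    net = catalog.network
    if net.n_nodes != 41:
        raise ValueError(f"model must have 41 nodes, found {net.n_nodes}")
    if net.k_max > 4:
        raise ValueError(f"in-degree above 4: k_max={net.k_max}")
    clamped_names = {net.nodes[i] for i in net.clamped}
    if clamped_names != set(INPUT_NODES):
        raise ValueError(f"clamped set {clamped_names} != {set(INPUT_NODES)}")
    if len(catalog.display_nodes) != 32:
        raise ValueError(f"expected 32 display nodes, found {len(catalog.display_nodes)}")
    if len(catalog.knockout_units) != 23:
        raise ValueError("knockout roster must have 23 units")
    for name, members in catalog.knockout_units:
        for m in members:
            net.index(m)  # raises on unknown node


def scenario_initial_state(catalog: ModelCatalog, spec: ScenarioSpec | str) -> np.ndarray:
    """All-ones initial state with the stress and SSRI bits set from the
    scenario (TRP starts active in every scenario)."""
    if isinstance(spec, str):
        spec = catalog.scenario(spec)
    s = np.ones(catalog.network.n_nodes, dtype=np.uint8)
    s[catalog.network.index("stress")] = spec.stress_on
    s[catalog.network.index("SSRI")] = spec.ssri_on
    return s


def run_scenario(
    catalog: ModelCatalog,
    spec: ScenarioSpec | str,
    T: int = 100,
    max_steps: int = 10_000,
) -> tuple[np.ndarray, AttractorResult | None]:
    """Simulate a scenario for ``T`` steps and detect its attractor.

    Returns the ``(T + 1, 41)`` trajectory together with the attractor found
    within ``max_steps`` updates (``None`` if not found — with a finite state
    space this only happens when ``max_steps`` is set very low).
    """
    if isinstance(spec, str):
        spec = catalog.scenario(spec)
    s0 = scenario_initial_state(catalog, spec)
    trajectory = simulate(catalog.network, s0, T)
    attractor = find_attractor(catalog.network, s0, max_steps=max_steps)
    return trajectory, attractor
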