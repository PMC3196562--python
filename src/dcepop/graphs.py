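"""Compartment topologies for multi-tissue tracer kinetics.

A :class:`CompartmentGraph` is a directed graph of effective kinetic spaces.
Three compartments are observed (the second muscle, first tumor and second
liver compartments, which correspond to the imaged tissue ROIs); the rest are
latent.  The full nine-compartment topology chains three muscle compartments
off the central compartment, three liver compartments off the central
compartment, and attaches the two tumor compartments to the first liver
compartment — the tumor is perfused through the liver, not directly from the
central space.  Elimination is a single first-order loss from the central
compartment with a fixed plasma clearance.

Topologies are data, not code: every preset here can equally be loaded from a
YAML file, and reduced model variants (shortened muscle chain, removed distal
tumor/liver compartments, tumor attached centrally) are expressed as configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

from .errors import ConfigurationError

__all__ = [
    "CompartmentGraph",
    "mtl3_graph",
    "minimal_graph",
    "reduced_graph",
    "load_graph",
    "save_graph",
    "get_preset",
    "PRESET_NAMES",
    "REFERENCE_RATES",
    "DEFAULT_CLEARANCE",
    "TISSUE_TO_COMPARTMENT",
]

#: Observed-compartment labels for the three imaged tissues.
TISSUE_TO_COMPARTMENT = {"muscle": "M2", "tumor": "T2", "liver": "L2"}

#: Fixed plasma clearance of Gd-DTPA in rat [ml/s], taken from the literature
#: and never estimated.
DEFAULT_CLEARANCE = 0.04

#: Published population estimates of the transfer constants [1/s] for the full
#: nine-compartment model in rat.  Used as the default truth of the synthetic
#: study generator and as default initial estimates when refitting.
REFERENCE_RATES = {
    "k_C0": 0.013,
    "k_CM1": 0.3,
    "k_M1C": 0.012,
    "k_M1M2": 3.6,
    "k_M2M1": 300.0,
    "k_M2M3": 0.24,
    "k_M3M2": 0.0024,
    "k_CL1": 2.9,
    "k_L1C": 0.59,
    "k_L1T2": 0.03,
    "k_T2L1": 0.38,
    "k_T2T3": 3.7,
    "k_T3T2": 0.33,
    "k_L1L2": 0.0045,
    "k_L2L1": 0.021,
    "k_L2L3": 0.027,
    "k_L3L2": 2.3e-5,
}


@dataclass(frozen=True)
class CompartmentGraph:
    """Directed compartment topology.

    Parameters
    ----------
    compartments:
        Ordered compartment labels.  The order fixes row/column order of the
        rate matrix.
    observed:
        Labels of measured compartments (subset of ``compartments``).
    edges:
        Mapping ``(from, to) -> rate name`` for every transfer.
    dose_compartment:
        Label receiving the bolus.
    elimination:
        ``(compartment, rate name)`` of the single first-order elimination,
        or ``None`` for a closed system.
    """

    compartments: tuple[str, ...]
    observed: tuple[str, ...]
    edges: dict[tuple[str, str], str] = field(default_factory=dict)
    dose_compartment: str = "C"
    elimination: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        comps = self.compartments
        if len(set(comps)) != len(comps):
            raise ConfigurationError("duplicate compartment labels")
        missing = set(self.observed) - set(comps)
        if missing:
            raise ConfigurationError(f"observed compartments not in graph: {sorted(missing)}")
        if self.dose_compartment not in comps:
            raise ConfigurationError(f"dose compartment {self.dose_compartment!r} not in graph")
        names = list(self.edges.values())
        if len(set(names)) != len(names):
            raise ConfigurationError("transfer-rate names must be unique")
        for (frm, to) in self.edges:
            if frm not in comps or to not in comps:
                raise ConfigurationError(f"edge ({frm!r}, {to!r}) references unknown compartment")
            if frm == to:
                raise ConfigurationError(f"self-loop on {frm!r}")
        if self.elimination is not None:
            comp, name = self.elimination
            if comp not in comps:
                raise ConfigurationError(f"elimination compartment {comp!r} not in graph")
            if name in names:
                raise ConfigurationError(f"elimination rate {name!r} collides with an edge name")
        self._check_connected()

    def _check_connected(self) -> None:
        if len(self.compartments) <= 1:
            return
        adj: dict[str, set[str]] = {c: set() for c in self.compartments}
        for (frm, to) in self.edges:
            adj[frm].add(to)
            adj[to].add(frm)
        seen = {self.dose_compartment}
        stack = [self.dose_compartment]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != set(self.compartments):
            raise ConfigurationError(
                f"graph is not connected; unreachable: {sorted(set(self.compartments) - seen)}"
            )

    # -- indexing helpers -------------------------------------------------
    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def index(self, label: str) -> int:
        return self.compartments.index(label)

    def rate_names(self) -> list[str]:
        """Canonical rate order: elimination rate first, then edges in
        insertion order."""
        names = []
        if self.elimination is not None:
            names.append(self.elimination[1])
        names.extend(self.edges.values())
        return names

    def bidirectional_pairs(self) -> list[tuple[str, str, str, str]]:
        """Return ``(from, to, forward rate, backward rate)`` for every pair
        of compartments connected in both directions, each pair once."""
        pairs = []
        seen = set()
        for (frm, to), fwd in self.edges.items():
            if (to, frm) in seen or (frm, to) in seen:
                continue
            back = self.edges.get((to, frm))
            if back is not None:
                pairs.append((frm, to, fwd, back))
                seen.add((frm, to))
        return pairs

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "compartments": list(self.compartments),
            "observed": list(self.observed),
            "edges": [
                {"from": frm, "to": to, "rate": rate}
                for (frm, to), rate in self.edges.items()
            ],
            "dose_compartment": self.dose_compartment,
        }
        if self.elimination is not None:
            d["elimination"] = {"compartment": self.elimination[0], "rate": self.elimination[1]}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompartmentGraph":
        try:
            edges = {(e["from"], e["to"]): e["rate"] for e in d.get("edges", [])}
            elim = d.get("elimination")
            return cls(
                compartments=tuple(d["compartments"]),
                observed=tuple(d.get("observed", ())),
                edges=edges,
                dose_compartment=d.get("dose_compartment", "C"),
                elimination=(elim["compartment"], elim["rate"]) if elim else None,
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise ConfigurationError(f"missing key in topology config: {exc}") from exc


def _graph(compartments: Iterable[str], observed: Iterable[str],
           edge_list: Iterable[tuple[str, str, str]]) -> CompartmentGraph:
    return CompartmentGraph(
        compartments=tuple(compartments),
        observed=tuple(observed),
        edges={(frm, to): rate for frm, to, rate in edge_list},
        dose_compartment="C",
        elimination=("C", "k_C0"),
    )


def mtl3_graph() -> CompartmentGraph:
    """The full nine-compartment muscle/tumor/liver topology.

    Muscle: C <-> M1 <-> M2 <-> M3 with M2 observed.
    Liver:  C <-> L1 <-> L2 <-> L3 with L2 observed.
    Tumor:  L1 <-> T2 <-> T3 with T2 observed (the tumor chain attaches to
    the first liver compartment, reflecting hepatic perfusion of the tumor).
    """
    return _graph(
        ["C", "M1", "M2", "M3", "L1", "L2", "L3", "T2", "T3"],
        ["M2", "T2", "L2"],
        [
            ("C", "M1", "k_CM1"),
            ("M1", "M2", "k_M1M2"),
            ("M2", "M3", "k_M2M3"),
            ("M3", "M2", "k_M3M2"),
            ("M2", "M1", "k_M2M1"),
            ("M1", "C", "k_M1C"),
            ("C", "L1", "k_CL1"),
            ("L1", "T2", "k_L1T2"),
            ("T2", "T3", "k_T2T3"),
            ("T3", "T2", "k_T3T2"),
            ("T2", "L1", "k_T2L1"),
            ("L1", "L2", "k_L1L2"),
            ("L2", "L3", "k_L2L3"),
            ("L3", "L2", "k_L3L2"),
            ("L2", "L1", "k_L2L1"),
            ("L1", "C", "k_L1C"),
        ],
    )


def minimal_graph() -> CompartmentGraph:
    """Four-compartment minimal model: the three observed tissue compartments
    branch directly off the latent central compartment."""
    return _graph(
        ["C", "M2", "T2", "L2"],
        ["M2", "T2", "L2"],
        [
            ("C", "M2", "k_CM2"),
            ("M2", "C", "k_M2C"),
            ("C", "T2", "k_CT2"),
            ("T2", "C", "k_T2C"),
            ("C", "L2", "k_CL2"),
            ("L2", "C", "k_L2C"),
        ],
    )


def _drop_compartment(g: CompartmentGraph, label: str) -> CompartmentGraph:
    """Remove a leaf latent compartment and its edges."""
    if label in g.observed:
        raise ConfigurationError(f"cannot drop observed compartment {label!r}")
    comps = tuple(c for c in g.compartments if c != label)
    edges = {e: r for e, r in g.edges.items() if label not in e}
    return CompartmentGraph(comps, g.observed, edges, g.dose_compartment, g.elimination)


def reduced_graph(variant: str) -> CompartmentGraph:
    """Reduced-model family used for structural model evaluation.

    Variants: ``no_m3`` (shortened muscle chain), ``no_t3`` (distal tumor
    compartment removed), ``no_l3`` (distal liver compartment removed), and
    ``tumor_on_central`` (tumor chain attached to C instead of L1).
    """
    full = mtl3_graph()
    if variant == "no_m3":
        return _drop_compartment(full, "M3")
    if variant == "no_t3":
        return _drop_compartment(full, "T3")
    if variant == "no_l3":
        return _drop_compartment(full, "L3")
    if variant == "tumor_on_central":
        edges = dict(full.edges)
        edges.pop(("L1", "T2"))
        edges.pop(("T2", "L1"))
        edges[("C", "T2")] = "k_CT2"
        edges[("T2", "C")] = "k_T2C"
        return CompartmentGraph(full.compartments, full.observed, edges,
                                full.dose_compartment, full.elimination)
    raise ConfigurationError(f"unknown reduced-model variant {variant!r}")


PRESET_NAMES = ("mtl3", "minimal", "no_m3", "no_t3", "no_l3", "tumor_on_central")


def get_preset(name: str) -> CompartmentGraph:
    """Return a shipped topology preset by name."""
    if name == "mtl3":
        return mtl3_graph()
    if name == "minimal":
        return minimal_graph()
    if name in PRESET_NAMES:
        return reduced_graph(name)
    raise ConfigurationError(f"unknown topology preset {name!r}; choose from {PRESET_NAMES}")


def load_graph(path) -> CompartmentGraph:
    """Load a topology from a YAML config file."""
    with open(path) as fh:
        return CompartmentGraph.from_dict(yaml.safe_load(fh))


def save_graph(graph: CompartmentGraph, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(graph.to_dict(), fh, sort_keys=False)
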