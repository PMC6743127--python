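"""Evidence network implied by which respondents tested which devices.

Nodes are devices; an undirected edge between two devices carries, per
stratum, the number of respondents who tested both (the direct head-to-head
sample size).  The indirect-comparison model is identifiable for a stratum
only when this network is connected, so connectivity is checked per stratum
before any fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .devices import STRATA, sort_devices
from .errors import DisconnectedNetworkError, DuplicateObservationError
from .scoring import GUSRecord

logger = logging.getLogger(__name__)


@dataclass
class EvidenceNetwork:
    nodes: set[str]
    #: (device_a, device_b) in canonical order -> {stratum: respondent count}
    edges: dict[tuple[str, str], dict[str, int]]
    #: group id -> (device set, {stratum: n respondents})
    groups: dict[int, tuple[frozenset[str], dict[str, int]]]
    #: respondents appearing per stratum (incl. single-device ones)
    stratum_n: dict[str, int] = field(default_factory=dict)

    def edge_count(self, a: str, b: str, stratum: str | None = None) -> int:
        key = tuple(sort_devices([a, b]))
        counts = self.edges.get(key, {})
        if stratum is None:
            return sum(counts.values())
        return counts.get(stratum, 0)

    def graph(self, stratum: str) -> nx.Graph:
        """Subgraph of edges with a positive count in the stratum."""
        g = nx.Graph()
        for devs, ns in self.groups.values():
            if ns.get(stratum, 0) > 0:
                g.add_nodes_from(devs)
        for (a, b), counts in self.edges.items():
            if counts.get(stratum, 0) > 0:
                g.add_edge(a, b, n=counts[stratum])
        return g

    def to_frame(self) -> pd.DataFrame:
        """Edge list mirroring the published network figure's labelling."""
        rows = [
            {"device_a": a, "device_b": b, "stratum": s, "count": c}
            for (a, b), counts in sorted(self.edges.items())
            for s, c in sorted(counts.items())
            if c > 0
        ]
        return pd.DataFrame(rows, columns=["device_a", "device_b", "stratum", "count"])


def build_network(records: list[GUSRecord]) -> EvidenceNetwork:
    """Aggregate per-respondent device sets into the evidence network.

    Each respondent contributes +1 to every pairwise edge within their tested
    set; a single-device respondent contributes a node but no edge.
    """
    tested: dict[str, set[str]] = {}
    meta: dict[str, tuple[str, int]] = {}
    for r in records:
        devs = tested.setdefault(r.respondent_id, set())
        if r.device in devs:
            raise DuplicateObservationError(
                f"duplicate record for respondent {r.respondent_id}, device {r.device}"
            )
        devs.add(r.device)
        meta[r.respondent_id] = (r.stratum, r.group)

    nodes: set[str] = set()
    edges: dict[tuple[str, str], dict[str, int]] = {}
    groups: dict[int, tuple[set[str], dict[str, int]]] = {}
    stratum_n: dict[str, int] = {}
    for rid, devs in tested.items():
        stratum, gid = meta[rid]
        nodes.update(devs)
        stratum_n[stratum] = stratum_n.get(stratum, 0) + 1
        gdevs, gns = groups.setdefault(gid, (set(), {}))
        gdevs.update(devs)
        gns[stratum] = gns.get(stratum, 0) + 1
        ordered = sort_devices(devs)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                counts = edges.setdefault((a, b), {})
                counts[stratum] = counts.get(stratum, 0) + 1
    singletons = sum(1 for devs in tested.values() if len(devs) == 1)
    if singletons:
        logger.warning(
            "build_network: %d single-device respondent(s) contribute no edges",
            singletons,
        )
    return EvidenceNetwork(
        nodes=nodes,
        edges=edges,
        groups={g: (frozenset(d), n) for g, (d, n) in groups.items()},
        stratum_n=stratum_n,
    )


def assert_connected(network: EvidenceNetwork, stratum: str) -> bool:
    """True iff every device observed in the stratum is reachable from every
    other via edges with a positive count.

    Raises :class:`DisconnectedNetworkError` listing the components otherwise.
    """
    g = network.graph(stratum)
    if g.number_of_nodes() == 0:
        raise DisconnectedNetworkError(f"no records in stratum {stratum!r}")
    if nx.is_connected(g):
        return True
    components = [sorted(c) for c in nx.connected_components(g)]
    raise DisconnectedNetworkError(
        f"evidence network disconnected in stratum {stratum!r}: "
        f"components {components}"
    )


def design_summary(network: EvidenceNetwork) -> pd.DataFrame:
    """Per-group, per-stratum respondent counts with margins."""
    if not network.groups:
        return pd.DataFrame(
            columns=["group", "devices", *(f"n_{s}" for s in STRATA), "n_total"]
        )
    rows = []
    for gid in sorted(network.groups):
        devs, ns = network.groups[gid]
        row = {"group": str(gid), "devices": "+".join(sort_devices(devs))}
        for s in STRATA:
            row[f"n_{s}"] = ns.get(s, 0)
        row["n_total"] = sum(ns.values())
        rows.append(row)
    total = {
        "group": "total",
        "devices": "",
        **{f"n_{s}": sum(r[f"n_{s}"] for r in rows) for s in STRATA},
        "n_total": sum(r["n_total"] for r in rows),
    }
    return pd.DataFrame(rows + [total])
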