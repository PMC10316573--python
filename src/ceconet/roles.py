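"""Node roles in the Zi–Pi plane.

Zi (within-module connectivity) is the z-score of a node's link count into
its own module relative to its module peers; Pi (among-module connectivity,
the participation coefficient) is 1 - sum_s (k_is / k_i)^2 over modules s.
Nodes are classified as peripherals, connectors, module hubs, or network
hubs; hubs and connectors are the usual keystone-taxon candidates.

Default cut-offs follow the Guimera–Amaral convention widely used for
ecological networks: zi_cut = 2.5, pi_cut = 0.62, with boundary ties going
to the hub/connector side (>=).  Zi uses only within-module links; Pi uses
the total degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import Partition, as_graph

ZI_CUT_DEFAULT = 2.5
PI_CUT_DEFAULT = 0.62

ROLE_CATEGORIES = ("peripheral", "connector", "module_hub", "network_hub")


def _module_link_counts(g, assignment):
    """k_is: for each node, links into each module; dict node -> {module: count}."""
    counts: dict = {node: {} for node in g.nodes}
    for u, v in g.edges:
        counts[u][assignment[v]] = counts[u].get(assignment[v], 0) + 1
        counts[v][assignment[u]] = counts[v].get(assignment[u], 0) + 1
    return counts


def within_module_degree_z(network, partition) -> pd.Series:
    """Zi per node: (k_is - mean_s) / sd_s over nodes of the node's own
    module s (population sd; sd_s = 0 -> Zi = 0 by convention)."""
    g = as_graph(network)
    assignment = partition.assignment if isinstance(partition, Partition) else dict(partition)
    for node in g.nodes:
        if node not in assignment:
            raise ValueError(f"node {node!r} missing from partition")
    counts = _module_link_counts(g, assignment)
    k_in = {node: counts[node].get(assignment[node], 0) for node in g.nodes}
    by_module: dict = {}
    for node in g.nodes:
        by_module.setdefault(assignment[node], []).append(k_in[node])
    stats = {
        mod: (float(np.mean(v)), float(np.std(v))) for mod, v in by_module.items()
    }
    zi = {}
    for node in g.nodes:
        mean, sd = stats[assignment[node]]
        zi[node] = 0.0 if sd == 0 else (k_in[node] - mean) / sd
    return pd.Series(zi, name="zi")


def participation_coefficient(network, partition) -> pd.Series:
    """Pi per node: 1 - sum_s (k_is / k_i)^2; isolated nodes get Pi = 0."""
    g = as_graph(network)
    assignment = partition.assignment if isinstance(partition, Partition) else dict(partition)
    for node in g.nodes:
        if node not in assignment:
            raise ValueError(f"node {node!r} missing from partition")
    counts = _module_link_counts(g, assignment)
    pi = {}
    for node in g.nodes:
        k = sum(counts[node].values())
        if k == 0:
            pi[node] = 0.0
        else:
            pi[node] = 1.0 - sum((c / k) ** 2 for c in counts[node].values())
    return pd.Series(pi, name="pi")


@dataclass
class RoleTable:
    """Per-node Zi, Pi and role category, plus the thresholds used."""

    table: pd.DataFrame  # columns: zi, pi, role (+ optional module, degree)
    zi_cut: float = ZI_CUT_DEFAULT
    pi_cut: float = PI_CUT_DEFAULT

    def counts(self) -> dict:
        c = self.table["role"].value_counts().to_dict()
        return {cat: int(c.get(cat, 0)) for cat in ROLE_CATEGORIES}


def classify_roles(
    zi: pd.Series,
    pi: pd.Series,
    zi_cut: float = ZI_CUT_DEFAULT,
    pi_cut: float = PI_CUT_DEFAULT,
) -> RoleTable:
    """Four-way Zi–Pi classification.

    network_hub: Zi >= zi_cut and Pi >= pi_cut; module_hub: Zi >= zi_cut and
    Pi < pi_cut; connector: Zi < zi_cut and Pi >= pi_cut; else peripheral.
    """
    if not np.isfinite([zi_cut, pi_cut]).all():
        raise ValueError("thresholds must be finite")
    if len(zi) != len(pi) or not zi.index.equals(pi.index):
        raise ValueError("zi and pi must be aligned on the same nodes")
    roles = []
    for z, p in zip(zi, pi):
        if z >= zi_cut and p >= pi_cut:
            roles.append("network_hub")
        elif z >= zi_cut:
            roles.append("module_hub")
        elif p >= pi_cut:
            roles.append("connector")
        else:
            roles.append("peripheral")
    table = pd.DataFrame({"zi": zi, "pi": pi, "role": roles}, index=zi.index)
    return RoleTable(table=table, zi_cut=zi_cut, pi_cut=pi_cut)


def node_roles(
    network,
    partition,
    zi_cut: float = ZI_CUT_DEFAULT,
    pi_cut: float = PI_CUT_DEFAULT,
) -> RoleTable:
    """Zi, Pi and role per node of a partitioned network (one-stop wrapper)."""
    g = as_graph(network)
    zi = within_module_degree_z(g, partition)
    pi = participation_coefficient(g, partition)
    result = classify_roles(zi, pi, zi_cut=zi_cut, pi_cut=pi_cut)
    assignment = partition.assignment if isinstance(partition, Partition) else dict(partition)
    result.table["module"] = [assignment[n] for n in result.table.index]
    result.table["degree"] = [g.degree(n) for n in result.table.index]
    return result
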