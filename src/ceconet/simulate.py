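"""Synthetic compositional communities with planted correlation structure.

The generator emulates the data shape of a two-arm broiler-chicken feeding
trial: two groups x 16 cecal samples, a few hundred MAG-level taxa,
relative abundances closed to 1, a handful of planted correlated taxon
blocks (latent modules), a few "keystone" taxa loading on several blocks,
and continuous traits (SCFA concentrations, hormone levels, body weight)
linearly coupled to designated taxa.

The abundance model is a latent-Gaussian copula with log-normal marginals:
each planted block has one standard-normal factor per sample, and a block
member's latent score is sqrt(latent_corr) * factor +
sqrt(1 - latent_corr) * idiosyncratic noise, so the within-block latent
correlation is exactly ``latent_corr``.  Latent scores are shifted by a
per-taxon log-normal baseline, perturbed by per-sample multiplicative
noise, exponentiated, and closed to relative abundances.  Closure induces
the usual mild negative-correlation artifact of compositional data, which
is accepted deliberately — real relative-abundance tables have it too.

Everything is driven by a single integer seed; identical spec + seed give
bitwise-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd

from .corrnet import CoNetwork
from .tables import AbundanceTable, Lineage, TraitTable
from .topology import Partition, modularity

log = logging.getLogger(__name__)


def _default_module_sizes() -> tuple:
    return (12, 10, 10, 8, 8)


def _default_keystones() -> tuple:
    # taxon index -> blocks it bridges; indices sit just past the planted blocks
    return ((48, (0, 1)), (49, (1, 2)), (50, (2, 3, 4)))


def _default_traits() -> tuple:
    # (trait name, linked taxon index or None, slope, noise sd relative to signal sd)
    return (
        ("acetate", 0, 1.0, 0.5),
        ("ghrelin", 0, 0.8, 0.5),
        ("valerate", 1, 1.0, 0.5),
        ("isobutyrate", 2, 1.0, 0.5),
        ("body_weight", 12, 1.0, 0.5),
        ("igf1", 12, 0.6, 0.5),
        ("propionate", None, 0.0, 1.0),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults mirror the emulated trial at desk scale: 2 groups x 16 samples
    and 200 taxa (a parameter — the real study had 986 MAGs), five planted
    blocks totalling 48 taxa, three keystone bridges, and SCFA/hormone/body
    weight traits coupled to block members.  ``noise_sigma`` is per-sample
    multiplicative (log-scale) noise; trait noise sds are expressed relative
    to the sd of the trait's signal component so they are scale-free.
    """

    n_groups: int = 2
    n_samples_per_group: int = 16
    n_taxa: int = 200
    module_sizes: tuple = field(default_factory=_default_module_sizes)
    latent_corr: float = 0.85
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    noise_sigma: float = 0.1
    keystone_spec: tuple = field(default_factory=_default_keystones)
    trait_spec: tuple = field(default_factory=_default_traits)
    group_labels: tuple = ("CON", "AOS")
    seed: int = 0

    def __post_init__(self):
        if sum(self.module_sizes) > self.n_taxa:
            raise ValueError("module_sizes exceed n_taxa")
        if not (0 <= self.latent_corr < 1):
            raise ValueError("latent_corr must be in [0, 1)")
        planted = sum(self.module_sizes)
        for idx, blocks in self.keystone_spec:
            if idx >= self.n_taxa:
                raise ValueError(f"keystone index {idx} out of range")
            if idx < planted:
                raise ValueError(f"keystone index {idx} falls inside a planted block")
            for b in blocks:
                if b >= len(self.module_sizes):
                    raise ValueError(f"keystone block {b} does not exist")
        for name, idx, _, _ in self.trait_spec:
            if idx is not None and not (0 <= idx < self.n_taxa):
                raise ValueError(f"trait {name!r} links to unknown taxon index {idx}")

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.n_samples_per_group

    def taxon_name(self, i: int) -> str:
        return f"t{i:04d}"


@dataclass
class GroundTruth:
    """What the generator planted: block memberships, keystones, trait links."""

    block_membership: dict  # taxon -> block id, or None for independents
    keystone_nodes: set
    trait_links: dict  # trait name -> taxon (only linked traits)

    def planted_taxa(self) -> list:
        return [t for t, b in self.block_membership.items() if b is not None]

    def as_dict(self) -> dict:
        return {
            "block_membership": {
                t: (int(b) if b is not None else None)
                for t, b in self.block_membership.items()
            },
            "keystone_nodes": sorted(self.keystone_nodes),
            "trait_links": dict(self.trait_links),
        }


def _lineage_for(taxon_index: int, block: int | None) -> Lineage:
    family = f"Block{block}" if block is not None else f"Indep{taxon_index % 10}"
    return Lineage(
        (
            "Bacteria",
            "Firmicutes_A",
            "Clostridia",
            "Oscillospirales",
            family,
            f"g{taxon_index:04d}",
            f"s{taxon_index:04d}",
        )
    )


def generate_community(spec: SyntheticSpec):
    """Draw one synthetic abundance table and its ground truth.

    Sample ids are ``{group}_{i:02d}``; taxa are ``t0000``..; the first
    sum(module_sizes) taxa fill the planted blocks in order, keystone taxa
    sit at the indices named in ``keystone_spec``, and the remainder are
    independent.
    """
    rng = np.random.default_rng(spec.seed)
    n, t = spec.n_samples, spec.n_taxa
    n_blocks = len(spec.module_sizes)
    rc = spec.latent_corr

    # fixed draw order => bitwise reproducibility
    factors = rng.standard_normal((n, n_blocks)) if n_blocks else np.zeros((n, 0))
    idiosyncratic = rng.standard_normal((n, t))
    baselines = rng.normal(spec.lognormal_mu, spec.lognormal_sigma, size=t)
    sample_noise = rng.standard_normal((n, t)) * spec.noise_sigma

    block_of: list = [None] * t
    pos = 0
    for b, size in enumerate(spec.module_sizes):
        for _ in range(size):
            block_of[pos] = b
            pos += 1
    keystones = {idx: tuple(blocks) for idx, blocks in spec.keystone_spec}

    z = np.empty((n, t))
    sqrt_rc, sqrt_ic = np.sqrt(rc), np.sqrt(1.0 - rc)
    for j in range(t):
        if block_of[j] is not None:
            common = factors[:, block_of[j]]
        elif j in keystones:
            blocks = keystones[j]
            common = factors[:, list(blocks)].sum(axis=1) / np.sqrt(len(blocks))
        else:
            z[:, j] = idiosyncratic[:, j]
            continue
        z[:, j] = sqrt_rc * common + sqrt_ic * idiosyncratic[:, j]

    log_abund = baselines[None, :] + z + sample_noise
    raw = np.exp(log_abund)
    rel = raw / raw.sum(axis=1, keepdims=True)

    labels = list(spec.group_labels)[: spec.n_groups]
    sample_ids = [
        f"{labels[g]}_{i:02d}"
        for g in range(spec.n_groups)
        for i in range(spec.n_samples_per_group)
    ]
    groups = pd.Series(
        [labels[g] for g in range(spec.n_groups) for _ in range(spec.n_samples_per_group)],
        index=sample_ids,
        name="group",
    )
    taxon_ids = [spec.taxon_name(i) for i in range(t)]
    lineages = {
        taxon_ids[j]: _lineage_for(j, block_of[j]) for j in range(t)
    }
    table = AbundanceTable(
        pd.DataFrame(rel, index=sample_ids, columns=taxon_ids),
        lineages=lineages,
        groups=groups,
    )
    truth = GroundTruth(
        block_membership={taxon_ids[j]: block_of[j] for j in range(t)},
        keystone_nodes={spec.taxon_name(i) for i in keystones},
        trait_links={
            name: spec.taxon_name(idx)
            for name, idx, slope, _ in spec.trait_spec
            if idx is not None and slope != 0
        },
    )
    return table, truth


def generate_traits(table: AbundanceTable, truth: GroundTruth, spec: SyntheticSpec) -> TraitTable:
    """Traits as linear responses to their linked taxon's relative abundance.

    trait = slope * abundance + N(0, sd), with sd expressed as a multiple
    of the signal's own sd (scale-free); a ``None`` taxon gives a pure-noise
    trait.  Deterministic under the spec seed (independent stream from the
    community draw).
    """
    rng = np.random.default_rng([spec.seed, 1])
    n = table.n_samples
    columns = {}
    for name, idx, slope, noise_rel in spec.trait_spec:
        if idx is None:
            columns[name] = rng.standard_normal(n) * noise_rel
            continue
        taxon = spec.taxon_name(idx)
        if taxon not in table.data.columns:
            raise KeyError(f"linked taxon {taxon!r} not present in the abundance table")
        signal = slope * table.data[taxon].to_numpy(dtype=float)
        sd = float(np.std(signal))
        noise_sd = noise_rel * (sd if sd > 0 else 1.0)
        columns[name] = signal + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else signal
    return TraitTable(pd.DataFrame(columns, index=table.data.index))


# ---------------------------------------------------------------------------
# benchmark graphs with analytically known partitions and roles
# ---------------------------------------------------------------------------


def generate_benchmark_graph(kind: str, params: dict | None = None, seed: int = 0):
    """Small graphs whose partition and node roles are known by construction.

    kinds:
      ``two-cliques``      — two disjoint K_k; clique partition, Q = 0.5.
      ``ring-of-cliques``  — k cliques joined by dedicated bridge nodes, each
                             adjacent to one member of three consecutive
                             cliques.  Spanning three modules is what pushes
                             a bridge's participation coefficient (2/3) past
                             the 0.62 connector cut — a node touching only
                             two modules can never exceed Pi = 0.5.
      ``planted-partition``— stochastic block model with l groups of k nodes.

    Returns (CoNetwork, truth Partition, truth roles: node -> category, or
    None where roles are not analytic).
    """
    params = dict(params or {})
    if kind == "two-cliques":
        size = int(params.get("clique_size", 4))
        if size < 2:
            raise ValueError("clique_size must be >= 2")
        g = nx.Graph()
        assignment = {}
        for c in range(2):
            nodes = [f"c{c}_{i}" for i in range(size)]
            g.add_edges_from((a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:])
            assignment.update({v: c for v in nodes})
        part = Partition(assignment, q=0.0, n_modules=2)
        part.q = modularity(g, part)
        roles = {v: "peripheral" for v in g.nodes}
        return CoNetwork(g), part, roles

    if kind == "ring-of-cliques":
        k = int(params.get("n_cliques", 4))
        size = int(params.get("clique_size", 5))
        bridge = params.get("bridge", "node")
        if k < 2:
            raise ValueError("need at least 2 cliques")
        g = nx.Graph()
        cliques = []
        assignment = {}
        for c in range(k):
            nodes = [f"c{c}_{i}" for i in range(size)]
            g.add_edges_from((a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:])
            assignment.update({v: c for v in nodes})
            cliques.append(nodes)
        roles = {v: "peripheral" for v in g.nodes}
        if bridge == "edge":
            for c in range(k):
                g.add_edge(cliques[c][0], cliques[(c + 1) % k][1])
        elif bridge == "node":
            if k < 3:
                raise ValueError("node bridges need at least 3 cliques")
            for c in range(k):
                b = f"bridge_{c}"
                g.add_edge(b, cliques[c][0])
                g.add_edge(b, cliques[(c + 1) % k][1])
                g.add_edge(b, cliques[(c + 2) % k][2])
                assignment[b] = c  # truth: filed with its first clique
                roles[b] = "connector"
        else:
            raise ValueError("bridge must be 'node' or 'edge'")
        part = Partition(assignment, q=0.0, n_modules=k)
        part.q = modularity(g, part)
        return CoNetwork(g), part, roles

    if kind == "planted-partition":
        l = int(params.get("n_groups", 4))
        k = int(params.get("group_size", 20))
        p_in = float(params.get("p_in", 0.9))
        p_out = float(params.get("p_out", 0.01))
        if l < 2:
            raise ValueError("need at least 2 planted groups")
        g = nx.planted_partition_graph(l, k, p_in, p_out, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
        assignment = {f"n{i:03d}": i // k for i in range(l * k)}
        part = Partition(assignment, q=0.0, n_modules=l)
        part.q = modularity(g, part)
        return CoNetwork(nx.Graph(g)), part, None

    raise ValueError(f"unknown benchmark kind {kind!r}")
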