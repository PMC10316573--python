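"""Abundance and trait tables: reading, validation, normalization, aggregation.

The root input of the pipeline is a taxon-by-sample (or sample-by-taxon)
relative-abundance table in TSV form.  Taxa may carry GTDB-style lineage
strings (``d__...;p__...;c__...;o__...;f__...;g__...;s__...``), which make
rank-level aggregation (e.g. family-level indicator ratios) possible.
Orientation of the input file is always explicit — silent transposition is
the classic microbiome-pipeline bug — and defaults to rows-are-samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import networkx as nx

log = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = dict(zip(RANKS, ("d__", "p__", "c__", "o__", "f__", "g__", "s__")))

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class Lineage:
    """A seven-rank GTDB-style taxonomic lineage; empty strings mark missing ranks."""

    ranks: tuple[str, ...]

    def __post_init__(self):
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"lineage must have {len(RANKS)} ranks, got {len(self.ranks)}")

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        values = {r: "" for r in RANKS}
        for part in str(text).split(";"):
            part = part.strip()
            for rank, prefix in RANK_PREFIXES.items():
                if part.startswith(prefix):
                    values[rank] = part[len(prefix):]
                    break
        return cls(tuple(values[r] for r in RANKS))

    def __str__(self) -> str:
        return ";".join(RANK_PREFIXES[r] + v for r, v in zip(RANKS, self.ranks))

    def at(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; must be one of {RANKS}")
        return self.ranks[RANKS.index(rank)]

    def truncated(self, rank: str) -> "Lineage":
        """Lineage with every level below ``rank`` blanked out."""
        idx = RANKS.index(rank)
        return Lineage(self.ranks[: idx + 1] + ("",) * (len(RANKS) - idx - 1))


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(map(str, dups)))}")


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of non-negative abundances.

    ``data`` rows are samples and columns are taxa.  ``lineages`` maps taxon
    id to a :class:`Lineage`; ``groups`` is a per-sample categorical label
    aligned with the sample index.
    """

    data: pd.DataFrame
    lineages: dict[str, Lineage] | None = None
    groups: pd.Series | None = None

    def __post_init__(self):
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "taxon")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self.data.map(lambda v: not isinstance(v, (int, float, np.number)))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric abundance at sample {self.data.index[r]!r}, "
                f"taxon {self.data.columns[c]!r}"
            )
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing abundance at sample {self.data.index[r]!r}, "
                f"taxon {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"taxon {self.data.columns[c]!r}"
            )
        if self.groups is not None:
            g = self.groups.reindex(self.data.index)
            if g.isna().any():
                missing = list(g.index[g.isna()])
                raise ValueError(f"samples missing a group label: {missing}")
            self.groups = g

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def is_normalized(self, tol: float = _NORM_TOL) -> bool:
        return bool(np.allclose(self.values.sum(axis=1), 1.0, atol=tol))

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        sample_ids = list(sample_ids)
        groups = self.groups.loc[sample_ids] if self.groups is not None else None
        return AbundanceTable(self.data.loc[sample_ids].copy(), self.lineages, groups)

    def group_labels(self) -> list:
        if self.groups is None:
            return []
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class TraitTable:
    """Samples x traits matrix of continuous phenotypes; NaN marks missing values."""

    data: pd.DataFrame

    def __post_init__(self):
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "trait")
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            r, c = np.argwhere(np.isinf(values))[0]
            raise ValueError(
                f"non-finite trait value at sample {self.data.index[r]!r}, "
                f"trait {self.data.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def trait_names(self) -> list:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_LINEAGE_COLUMNS = ("lineage", "taxonomy", "classification")


def _read_header_ids(path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    return header.split("\t")[1:]


def read_abundance_table(
    path,
    orientation: str = "samples",
    groups: pd.Series | None = None,
) -> AbundanceTable:
    """Read a TSV abundance table.

    ``orientation`` is ``"samples"`` (rows are samples, default) or ``"taxa"``
    (rows are taxa).  A non-numeric column named ``lineage``/``taxonomy`` in a
    rows-are-taxa file is interpreted as per-taxon lineage strings.  Counts
    (rows not summing to 1) are accepted; call :func:`normalize_relative` to
    convert to relative abundances.
    """
    if orientation not in ("samples", "taxa"):
        raise ValueError("orientation must be 'samples' or 'taxa'")
    header_ids = _read_header_ids(path)
    _check_unique(header_ids, "column")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    lineages = None
    if orientation == "taxa":
        for col in df.columns:
            if col.lower() in _LINEAGE_COLUMNS:
                lineages = {t: Lineage.parse(s) for t, s in df[col].items()}
                df = df.drop(columns=[col])
                break
        df = df.T

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    numeric = numeric.astype(float)
    numeric.index.name = None
    numeric.columns.name = None
    table = AbundanceTable(numeric, lineages, groups)
    if not table.is_normalized():
        log.info("table %s does not contain relative abundances; normalization pending", path)
    return table


def read_groups(path, column: str = "group") -> pd.Series:
    """Read a per-sample group-label TSV (first column sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if column not in df.columns:
        raise ValueError(f"group column {column!r} not found in {path} (has {list(df.columns)})")
    return df[column].astype(str)


def read_trait_table(path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return TraitTable(df.astype(float))


def write_abundance_table(table: AbundanceTable, path, orientation: str = "samples") -> None:
    if orientation == "samples":
        table.data.to_csv(path, sep="\t", index_label="sample")
    elif orientation == "taxa":
        out = table.data.T
        if table.lineages is not None:
            out = out.copy()
            out["lineage"] = [str(table.lineages.get(t, Lineage(("",) * 7))) for t in out.index]
        out.to_csv(path, sep="\t", index_label="taxon")
    else:
        raise ValueError("orientation must be 'samples' or 'taxa'")


def write_trait_table(traits: TraitTable, path) -> None:
    traits.data.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each sample to relative abundances summing to 1 (idempotent)."""
    totals = table.values.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        raise ValueError(f"sample {table.data.index[np.argmax(zero)]!r} has zero total abundance")
    data = table.data.div(totals, axis=0)
    return AbundanceTable(data, table.lineages, table.groups)


def prevalence_filter(
    table: AbundanceTable, min_rel_abund: float, min_sample_frac: float
) -> AbundanceTable:
    """Keep taxa exceeding ``min_rel_abund`` in strictly more than
    ``min_sample_frac`` of samples; the sample set is unchanged."""
    for name, v in (("min_rel_abund", min_rel_abund), ("min_sample_frac", min_sample_frac)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    frac_present = (table.values > min_rel_abund).mean(axis=0)
    keep = frac_present > min_sample_frac
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    log.info("prevalence filter kept %d / %d taxa", len(kept), table.n_taxa)
    lineages = (
        {t: table.lineages[t] for t in kept if t in table.lineages}
        if table.lineages is not None
        else None
    )
    return AbundanceTable(table.data[kept].copy(), lineages, table.groups)


def aggregate_at_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum taxa sharing the same label at ``rank``; empty labels pool as
    ``Unassigned``.  Per-sample totals are conserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; must be one of {RANKS}")
    if table.lineages is None:
        raise ValueError("aggregation requires per-taxon lineages")
    labels = {}
    for t in table.taxon_ids:
        lin = table.lineages.get(t)
        label = lin.at(rank) if lin is not None else ""
        labels[t] = label if label else "Unassigned"
    grouped = table.data.T.groupby(pd.Series(labels), sort=True).sum().T
    new_lineages: dict[str, Lineage] = {}
    for t in table.taxon_ids:
        label = labels[t]
        if label not in new_lineages and label != "Unassigned":
            new_lineages[label] = table.lineages[t].truncated(rank)
    return AbundanceTable(grouped, new_lineages or None, table.groups)


# ---------------------------------------------------------------------------
# graph export / import (Gephi- and Cytoscape-compatible)
# ---------------------------------------------------------------------------


def write_graph(network, path, format: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML or a 4-column TSV edge list.

    GraphML carries node attributes (degree plus any genus/module/role
    annotation present) and edge attributes (rho, sign).  The edge list has
    columns source/target/rho/sign, sorted for determinism.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        log.warning("writing a network with 0 edges to %s", path)
    if format == "graphml":
        out = g.copy()
        degrees = dict(out.degree())
        for node, d in out.nodes(data=True):
            d["degree"] = degrees[node]
        if network.group_label is not None:
            out.graph["group_label"] = str(network.group_label)
        nx.write_graphml(out, path)
    elif format == "edgelist":
        rows = sorted(
            (str(u), str(v), d.get("rho", np.nan), d.get("sign", ""))
            for u, v, d in g.edges(data=True)
        )
        df = pd.DataFrame(rows, columns=["source", "target", "rho", "sign"])
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError("format must be 'graphml' or 'edgelist'")


def read_graph(path, format: str = "graphml"):
    """Read a network written by :func:`write_graph` back into a CoNetwork."""
    from .corrnet import CoNetwork  # local import to avoid a cycle

    if format == "graphml":
        g = nx.read_graphml(path)
        label = g.graph.pop("group_label", None)
        return CoNetwork(nx.Graph(g), group_label=label)
    if format == "edgelist":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(str(row.source), str(row.target), rho=float(row.rho), sign=str(row.sign))
        return CoNetwork(g)
    raise ValueError("format must be 'graphml' or 'edgelist'")
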