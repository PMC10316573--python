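"""End-to-end orchestration: per-group network inference, topology and null
models, module detection, node roles, and the community/association arms,
consolidated into one machine-readable JSON report.

All stochastic stages draw sub-seeds deterministically from the single
config seed, so two runs with identical config produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import correlation_panel_export, trait_correlations
from .community import alpha_diversity, bray_curtis, differential_abundance, family_ratio
from .corrnet import NetworkConfig, build_network, spearman_matrix
from .roles import node_roles
from .tables import (
    AbundanceTable,
    normalize_relative,
    prevalence_filter,
    read_abundance_table,
    read_groups,
    read_trait_table,
    write_graph,
)
from .topology import detect_modules, null_ensemble_summary, summarize_topology

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


@dataclass
class RunConfig:
    """Flat, file-round-trippable configuration of a full pipeline run."""

    abundance: str = ""
    groups: str | None = None
    traits: str | None = None
    orientation: str = "samples"
    normalize: bool = True
    prevalence_min_abund: float | None = None
    prevalence_min_frac: float | None = None
    rho_threshold: float = 0.7
    alpha: float = 0.05
    p_kind: str = "adjusted"
    drop_isolated_nodes: bool = True
    null_model: str = "rewire"
    null_replicates: int = 100
    n_swaps_factor: int = 10
    module_method: str = "louvain"
    zi_cut: float = 2.5
    pi_cut: float = 0.62
    r_cut: float = 0.35
    assoc_alpha: float = 0.05
    diffabund_alpha: float = 0.05
    ratio_numerator: str | None = None
    ratio_denominator: str | None = None
    ratio_pseudocount: float | None = None
    seed: int = 0
    outdir: str = "ceconet_out"

    def validate(self) -> None:
        if not self.abundance:
            raise ValueError("config must name an abundance table")
        if self.orientation not in ("samples", "taxa"):
            raise ValueError("orientation must be 'samples' or 'taxa'")
        if not (0 < self.rho_threshold <= 1):
            raise ValueError(f"rho_threshold must be in (0, 1], got {self.rho_threshold}")
        for name in ("alpha", "assoc_alpha", "diffabund_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (0 <= self.r_cut < 1):
            raise ValueError(f"r_cut must be in [0, 1), got {self.r_cut}")
        if self.p_kind not in ("adjusted", "raw"):
            raise ValueError("p_kind must be 'adjusted' or 'raw'")
        if self.null_model not in ("rewire", "gnm"):
            raise ValueError("null_model must be 'rewire' or 'gnm'")
        if self.null_replicates < 10:
            raise ValueError("null_replicates must be >= 10")
        if (self.prevalence_min_abund is None) != (self.prevalence_min_frac is None):
            raise ValueError("set both or neither prevalence thresholds")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage_seeds(seed: int) -> dict:
    """Deterministic per-stage sub-seeds (all below 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(8) & 0x7FFFFFFF
    names = ("corr", "modules", "null", "roles", "assoc", "diffabund", "spare1", "spare2")
    return {name: int(s) for name, s in zip(names, state)}


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def analyze_group(
    table: AbundanceTable,
    group_label: str,
    config: RunConfig,
    seeds: dict,
    outdir: Path | None = None,
):
    """Correlations -> network -> topology + nulls -> partition -> roles for
    one group's samples.  Returns (summary dict, network, partition, roles)."""
    corr = spearman_matrix(table)
    net = build_network(
        corr,
        NetworkConfig(
            rho_threshold=config.rho_threshold,
            alpha=config.alpha,
            use_adjusted_p=config.p_kind == "adjusted",
            drop_isolated_nodes=config.drop_isolated_nodes,
        ),
        group_label=group_label,
    )
    summary: dict = {"n_taxa_tested": table.n_taxa, "n_samples": table.n_samples}
    if net.n_edges == 0:
        log.warning("group %s: no edges survive thresholds", group_label)
        summary.update(summarize_topology(net))
        summary["null_stats"] = None
        summary["role_counts"] = None
        return summary, net, None, None
    partition = detect_modules(net, seed=seeds["modules"], method=config.module_method)
    summary.update(summarize_topology(net, partition))
    nulls = null_ensemble_summary(
        net,
        model=config.null_model,
        n_replicates=config.null_replicates,
        seed=seeds["null"],
        n_swaps_factor=config.n_swaps_factor,
    )
    summary["null_stats"] = nulls.as_dict()
    roles = node_roles(net, partition, zi_cut=config.zi_cut, pi_cut=config.pi_cut)
    summary["role_counts"] = roles.counts()

    if outdir is not None:
        prefix = outdir / f"network_{group_label}"
        write_graph(net, f"{prefix}.graphml", format="graphml")
        write_graph(net, f"{prefix}_edges.tsv", format="edgelist")
        corr.rho.to_csv(outdir / f"rho_{group_label}.tsv", sep="\t", float_format="%.10g")
        corr.p_adj.to_csv(outdir / f"padj_{group_label}.tsv", sep="\t", float_format="%.10g")
        part_df = pd.DataFrame(
            sorted(partition.assignment.items()), columns=["node", "module"]
        )
        part_df.to_csv(outdir / f"partition_{group_label}.tsv", sep="\t", index=False)
        roles.table.sort_index().to_csv(
            outdir / f"roles_{group_label}.tsv", sep="\t", index_label="node",
            float_format="%.10g",
        )
    return summary, net, partition, roles


def run_pipeline(config: RunConfig, table: AbundanceTable | None = None,
                 traits=None) -> dict:
    """Execute the full pipeline and write artifacts + report.json.

    ``table``/``traits`` may be passed in-memory (e.g. straight from the
    generator); otherwise they are read from the paths in the config.
    """
    config.validate()
    seeds = _stage_seeds(config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    if table is None:
        groups = read_groups(config.groups) if config.groups else None
        table = stage("read_abundance", read_abundance_table, config.abundance,
                      orientation=config.orientation, groups=groups)
    if traits is None and config.traits:
        traits = stage("read_traits", read_trait_table, config.traits)

    if config.normalize and not table.is_normalized():
        table = stage("normalize", normalize_relative, table)
    if config.prevalence_min_abund is not None:
        table = stage(
            "prevalence_filter", prevalence_filter, table,
            config.prevalence_min_abund, config.prevalence_min_frac,
        )
    log.info("input: %d samples x %d taxa", table.n_samples, table.n_taxa)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": asdict(config),
        "seeds": seeds,
        "input": {"n_samples": table.n_samples, "n_taxa": table.n_taxa},
        "groups": {},
        "global": {},
    }

    labels = table.group_labels() or ["ALL"]
    for label in labels:
        sub = (
            table.subset_samples(table.groups.index[table.groups == label])
            if table.groups is not None
            else table
        )
        summary, *_ = stage(f"network_{label}", analyze_group, sub, label, config, seeds, outdir)
        report["groups"][str(label)] = summary

    diversity = stage("alpha_diversity", alpha_diversity, table)
    diversity.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index_label="sample",
                     float_format="%.10g")
    report["global"]["alpha_diversity_mean"] = {
        c: float(diversity[c].mean()) for c in diversity.columns
    }

    bc = stage("bray_curtis", bray_curtis, table)
    bc.to_csv(outdir / "bray_curtis.tsv", sep="\t", index_label="sample",
              float_format="%.10g")
    report["global"]["bray_curtis_mean"] = float(
        bc.to_numpy()[np.triu_indices(len(bc), k=1)].mean()
    )

    if table.groups is not None and len(labels) == 2:
        da = stage("differential_abundance", differential_abundance, table,
                   config.diffabund_alpha)
        da.to_csv(outdir / "differential_abundance.tsv", sep="\t",
                  float_format="%.10g")
        report["global"]["differential_abundance"] = {
            "n_tested": int(len(da)),
            "n_significant": int(da["significant"].sum()),
            "alpha": config.diffabund_alpha,
        }

    if config.ratio_numerator and config.ratio_denominator:
        ratio = stage(
            "family_ratio", family_ratio, table,
            config.ratio_numerator, config.ratio_denominator, config.ratio_pseudocount,
        )
        ratio.ratios.to_csv(outdir / "family_ratio.tsv", sep="\t",
                            index_label="sample", float_format="%.10g")
        finite = ratio.ratios.replace(np.inf, np.nan)
        report["global"]["family_ratio"] = {
            "numerator": ratio.numerator,
            "denominator": ratio.denominator,
            "mean": float(finite.mean()),
            "n_flagged": len(ratio.flagged_samples),
        }

    if traits is not None:
        assoc = stage(
            "associations", trait_correlations, table, traits,
            r_cut=config.r_cut, alpha=config.assoc_alpha,
            use_adjusted_p=config.p_kind == "adjusted",
        )
        correlation_panel_export(assoc, outdir / "associations.tsv")
        report["global"]["associations"] = {
            "n_pairs": int(len(assoc.table)),
            "n_passing": int(assoc.table["passes"].sum()),
            "r_cut": assoc.r_cut,
            "alpha": assoc.alpha,
            "p_kind": assoc.p_kind,
        }

    report = _json_safe(report)
    validate_report(report)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return report


def compare_groups(report: dict) -> pd.DataFrame:
    """Side-by-side per-group contrast table of the headline network metrics."""
    groups = report.get("groups", {})
    if len(groups) < 2:
        raise ValueError("group comparison needs a report with at least 2 groups")
    metrics = [
        "n_nodes", "n_edges", "edges_per_node_E_over_N", "mean_degree_2E_over_N",
        "acc", "apl", "diameter", "modularity", "n_modules", "positive_edge_fraction",
    ]
    data = {}
    for label, summary in groups.items():
        col = {m: summary.get(m) for m in metrics}
        for role, count in (summary.get("role_counts") or {}).items():
            col[f"n_{role}"] = count
        data[label] = col
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# report schema validation (subset of JSON Schema shipped with the package)
# ---------------------------------------------------------------------------


def _load_schema() -> dict:
    ref = resources.files("ceconet") / "schema" / f"report-v{REPORT_SCHEMA_VERSION}.json"
    return json.loads(ref.read_text(encoding="utf-8"))


def _check(instance, schema, path="$") -> None:
    stype = schema.get("type")
    if stype:
        py = {
            "object": dict, "array": list, "string": str,
            "number": (int, float), "integer": int, "boolean": bool,
        }[stype]
        if stype == "number" and isinstance(instance, bool):
            raise ValueError(f"{path}: expected number, got bool")
        if not isinstance(instance, py) or (stype == "integer" and isinstance(instance, bool)):
            if not (instance is None and schema.get("nullable")):
                raise ValueError(f"{path}: expected {stype}, got {type(instance).__name__}")
    for key in schema.get("required", []):
        if not isinstance(instance, dict) or key not in instance:
            raise ValueError(f"{path}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if isinstance(instance, dict) and key in instance and instance[key] is not None:
            _check(instance[key], sub, f"{path}.{key}")
    if "additionalProperties" in schema and isinstance(schema["additionalProperties"], dict):
        known = set(schema.get("properties", {}))
        for key, value in (instance or {}).items():
            if key not in known and value is not None:
                _check(value, schema["additionalProperties"], f"{path}.{key}")


def validate_report(report: dict) -> None:
    """Raise if the report does not conform to the shipped schema."""
    _check(report, _load_schema())
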