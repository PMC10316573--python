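"""Microbe–trait and trait–trait association screening.

Pairs are screened with tie-aware Spearman correlation under a double
criterion: |rho| strictly greater than the magnitude cut (default 0.35)
AND the selected P-value (BH-adjusted by default) strictly below alpha
(default 0.05).  The taxon x trait rectangle and the trait x trait
triangle are corrected as separate BH families, mirroring the two panels
of a typical correlation figure.

Missing trait values are handled pairwise-complete, with the per-pair n
reported; pairs with fewer than 4 complete observations are flagged
untestable rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corrnet import bh_adjust
from .tables import AbundanceTable, TraitTable

log = logging.getLogger(__name__)

R_CUT_DEFAULT = 0.35
MIN_PAIR_N = 4


@dataclass
class AssociationResult:
    """Long-format screened correlations plus the screen parameters used."""

    table: pd.DataFrame  # entity1, entity2, kind, n, rho, p, p_adj, testable, passes
    r_cut: float
    alpha: float
    p_kind: str  # "adjusted" or "raw"

    def passing(self) -> pd.DataFrame:
        return self.table[self.table["passes"]]


def _pair_spearman(x: np.ndarray, y: np.ndarray):
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < MIN_PAIR_N:
        return n, np.nan, np.nan
    xm, ym = x[mask], y[mask]
    if np.all(xm == xm[0]) or np.all(ym == ym[0]):
        return n, 0.0, 1.0
    rho, p = stats.spearmanr(xm, ym)
    return n, float(rho), float(p)


def trait_correlations(
    table: AbundanceTable,
    traits: TraitTable,
    r_cut: float = R_CUT_DEFAULT,
    alpha: float = 0.05,
    use_adjusted_p: bool = True,
    taxa=None,
) -> AssociationResult:
    """Screen every taxon–trait pair and every trait–trait pair.

    ``taxa`` restricts the taxon side (e.g. to differentially abundant taxa
    only).  Samples are aligned on the abundance table's order; trait rows
    must be a superset of it.
    """
    if not (0 <= r_cut < 1):
        raise ValueError(f"r_cut must be in [0, 1), got {r_cut}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    missing = [s for s in table.sample_ids if s not in traits.data.index]
    if missing:
        raise ValueError(f"trait table lacks samples: {missing}")
    tdata = traits.data.reindex(table.data.index)
    taxa = list(taxa) if taxa is not None else table.taxon_ids
    unknown = [t for t in taxa if t not in table.data.columns]
    if unknown:
        raise ValueError(f"unknown taxa in subset: {unknown}")

    rows = []
    for taxon in taxa:
        x = table.data[taxon].to_numpy(dtype=float)
        for trait in tdata.columns:
            n, rho, p = _pair_spearman(x, tdata[trait].to_numpy(dtype=float))
            rows.append(("taxon_trait", taxon, trait, n, rho, p))
    trait_names = list(tdata.columns)
    for i, a in enumerate(trait_names):
        for b in trait_names[i + 1:]:
            n, rho, p = _pair_spearman(
                tdata[a].to_numpy(dtype=float), tdata[b].to_numpy(dtype=float)
            )
            rows.append(("trait_trait", a, b, n, rho, p))

    result = pd.DataFrame(
        rows, columns=["kind", "entity1", "entity2", "n", "rho", "p"]
    )
    result["testable"] = result["p"].notna()
    if (~result["testable"]).any():
        log.warning(
            "%d pairs have fewer than %d complete observations and are untestable",
            int((~result["testable"]).sum()), MIN_PAIR_N,
        )
    result["p_adj"] = np.nan
    for kind in ("taxon_trait", "trait_trait"):  # separate BH families
        sel = (result["kind"] == kind) & result["testable"]
        if sel.any():
            result.loc[sel, "p_adj"] = bh_adjust(result.loc[sel, "p"].to_numpy())
    p_sel = result["p_adj"] if use_adjusted_p else result["p"]
    result["passes"] = (
        result["testable"]
        & (result["rho"].abs() > r_cut)
        & (p_sel < alpha)
    )
    return AssociationResult(
        table=result,
        r_cut=r_cut,
        alpha=alpha,
        p_kind="adjusted" if use_adjusted_p else "raw",
    )


def correlation_panel_export(result: AssociationResult, path) -> None:
    """Write the full screened panel (all tested pairs, passing or not) as a
    deterministic long-format TSV ready for heatmap rendering."""
    if result.table.empty:
        raise ValueError("association result is empty; nothing to export")
    out = result.table.copy()
    out = out.sort_values(["kind", "entity1", "entity2"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
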