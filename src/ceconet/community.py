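"""Community-level statistics: alpha diversity, Bray–Curtis dissimilarity,
family-level indicator ratios, and Wilcoxon rank-sum differential abundance
with Benjamini–Hochberg correction.

Shannon entropy is reported in nats (natural log), the convention of the
vegan-style ecology stack.  The differential-abundance arm is the
non-parametric two-sided Wilcoxon rank-sum screen; effect-size scoring in
the LEfSe style is a separate external tool and is not reimplemented here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .corrnet import bh_adjust
from .tables import AbundanceTable, aggregate_at_rank, normalize_relative

log = logging.getLogger(__name__)


def _ensure_normalized(table: AbundanceTable) -> AbundanceTable:
    if table.is_normalized():
        return table
    log.info("rows do not sum to 1; normalizing to relative abundances")
    return normalize_relative(table)


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon (nats), Simpson (1 - sum p^2), inverse Simpson
    (1 / sum p^2) and richness (taxa with p > 0)."""
    table = _ensure_normalized(table)
    p = table.values
    shannon = np.array([-(row[row > 0] * np.log(row[row > 0])).sum() for row in p])
    sum_sq = (p**2).sum(axis=1)
    return pd.DataFrame(
        {
            "shannon": shannon,
            "simpson": 1.0 - sum_sq,
            "invsimpson": 1.0 / sum_sq,
            "richness": (p > 0).sum(axis=1),
        },
        index=table.data.index,
    )


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Sample x sample Bray–Curtis dissimilarity
    BC(a, b) = 1 - 2 sum_t min(a_t, b_t) / sum_t (a_t + b_t)."""
    values = table.values
    zero_rows = values.sum(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(values, metric="braycurtis"))
    if zero_rows.sum() >= 2:
        log.warning(
            "Bray–Curtis undefined between all-zero samples: %s",
            list(table.data.index[zero_rows]),
        )
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.data.index, columns=table.data.index)


@dataclass
class FamilyRatioResult:
    ratios: pd.Series                     # per-sample ratio
    group_summary: pd.DataFrame | None    # per-group mean/median, if groups known
    numerator: str
    denominator: str
    flagged_samples: list                 # samples with a zero denominator


def _strip_rank_prefix(name: str) -> str:
    return name.split("__", 1)[1] if "__" in name else name


def family_ratio(
    table: AbundanceTable,
    numerator_family: str,
    denominator_family: str,
    pseudocount: float | None = None,
) -> FamilyRatioResult:
    """Per-sample abundance ratio of two families (e.g. Lactobacillaceae /
    Enterobacteriaceae, a common intestinal-health indicator).

    A zero denominator yields +inf and flags the sample, unless a
    ``pseudocount`` is given, which is added to both terms.
    """
    fam = aggregate_at_rank(table, "family")
    num_name = _strip_rank_prefix(numerator_family)
    den_name = _strip_rank_prefix(denominator_family)
    for name in (num_name, den_name):
        if name not in fam.data.columns or float(fam.data[name].sum()) == 0.0:
            raise ValueError(f"family {name!r} is absent from every sample")
    num = fam.data[num_name].astype(float)
    den = fam.data[den_name].astype(float)
    flagged = list(num.index[den == 0])
    if pseudocount is not None:
        num = num + pseudocount
        den = den + pseudocount
    elif flagged:
        log.warning("zero denominator family in samples %s; ratio reported as inf", flagged)
    with np.errstate(divide="ignore"):
        ratios = num / den
    ratios.name = f"{num_name}/{den_name}"
    summary = None
    if table.groups is not None:
        finite = ratios.replace(np.inf, np.nan)
        summary = finite.groupby(table.groups).agg(["mean", "median", "count"])
    return FamilyRatioResult(ratios, summary, num_name, den_name, flagged)


def wilcoxon_rank_sum(x, y, mode: str = "auto"):
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    ``exact`` enumerates the permutation distribution (combined n <= 20, no
    ties); ``approx`` uses the tie-corrected normal approximation with
    continuity correction; ``auto`` picks exact when eligible.
    Returns (U statistic of x, two-sided P).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size < 3 or y.size < 3:
        raise ValueError("both groups must have at least 3 observations")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return x.size * y.size / 2.0, 1.0  # no information: never significant
    has_ties = np.unique(combined).size < combined.size
    eligible = combined.size <= 20 and not has_ties
    if mode == "auto":
        mode = "exact" if eligible else "approx"
    if mode == "exact":
        if not eligible:
            raise ValueError("exact mode requires combined n <= 20 and no ties")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "approx":
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError("mode must be 'exact', 'approx' or 'auto'")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def differential_abundance(
    table: AbundanceTable, alpha: float = 0.05, mode: str = "auto"
) -> pd.DataFrame:
    """Per-taxon two-group Wilcoxon screen with BH correction over all taxa.

    Requires a two-group table; returns a taxon-indexed frame with group
    medians, the U statistic, raw and adjusted P, and a significance flag
    on the adjusted P at ``alpha``.
    """
    if table.groups is None:
        raise ValueError("differential abundance requires per-sample group labels")
    labels = table.group_labels()
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1, g2 = labels
    idx1 = table.groups == g1
    idx2 = table.groups == g2
    if idx1.sum() == 0 or idx2.sum() == 0:
        raise ValueError("one of the groups is empty")
    rows = []
    for taxon in table.taxon_ids:
        col = table.data[taxon].to_numpy(dtype=float)
        x, y = col[idx1.to_numpy()], col[idx2.to_numpy()]
        stat, p = wilcoxon_rank_sum(x, y, mode=mode)
        rows.append(
            {
                "taxon": taxon,
                f"median_{g1}": float(np.median(x)),
                f"median_{g2}": float(np.median(y)),
                "statistic": stat,
                "p": p,
            }
        )
    result = pd.DataFrame(rows).set_index("taxon")
    result["p_adj"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["p_adj"] < alpha
    return result
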