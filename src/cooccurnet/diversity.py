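"""Relative abundance, abundance/prevalence filters, transforms and
alpha-diversity indices.

Conventions follow mothur: Shannon in nats, bias-corrected Chao1, and
Simpson evenness as (1/D)/S_obs with D the unbiased Simpson concentration
sum n_i(n_i-1) / (N(N-1)).  On very small samples the evenness can exceed
1 (a property of the estimator, documented rather than clamped); the
degenerate D = 0 case (all singletons) is defined as E = 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .correlation import bh_fdr, spearman_matrix
from .tables import OtuTable

logger = logging.getLogger("cooccurnet")


# ---------------------------------------------------------------------------
# relative abundance and filters
# ---------------------------------------------------------------------------

def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-wise closure to proportions; empty samples stay all-zero."""
    totals = counts.sum(axis=0)
    safe = totals.replace(0, 1)
    return counts.div(safe, axis=1)


def filter_otus(
    table: OtuTable,
    meta: pd.DataFrame,
    max_relabund_min: float = 0.001,
    prevalence_min: float = 0.7,
) -> dict[str, pd.Index]:
    """Per-fraction OTU screen used before network construction.

    Within each size fraction's samples, an OTU is kept iff its maximum
    per-sample relative abundance is strictly greater than
    ``max_relabund_min`` (0.1%) AND it is observed (count > 0) in strictly
    more than ``prevalence_min`` (70%) of that fraction's samples.
    Relative abundance is computed within the fraction's sample columns.

    Returns a mapping fraction -> kept OTU ids.
    """
    kept: dict[str, pd.Index] = {}
    for fraction in meta["fraction"].unique():
        samples = meta.index[meta["fraction"] == fraction]
        if len(samples) == 0:
            raise ValueError(f"fraction {fraction!r} has no samples")
        sub = table.counts[samples]
        rel = relative_abundance(sub)
        max_rel = rel.max(axis=1)
        prevalence = (sub > 0).mean(axis=1)
        mask = (max_rel > max_relabund_min) & (prevalence > prevalence_min)
        kept[fraction] = table.otu_ids[mask]
    return kept


def filter_phyto(
    phyto: pd.DataFrame, prevalence_min: float = 0.7
) -> pd.Index:
    """Keep phytoplankton genera observed in strictly more than 70% of
    samples; an empty table yields an empty subset."""
    if phyto.shape[0] == 0 or phyto.shape[1] == 0:
        return pd.Index([], dtype=object)
    prevalence = (phyto > 0).mean(axis=1)
    return phyto.index[prevalence > prevalence_min]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def arcsine_transform(p):
    """Variance-stabilizing arcsin(sqrt(p)) for proportions, in radians."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return out if arr.ndim else float(out)


def log10_phyto(x):
    """log10(x + 1) pseudocount transform for genus-level counts."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be >= 0")
    out = np.log10(arr + 1.0)
    return out if arr.ndim else float(out)


def top_families(
    relabund: pd.DataFrame,
    taxonomy: pd.DataFrame,
    meta: pd.DataFrame,
    k: int = 10,
    grouping: tuple[str, ...] = ("fraction", "depth"),
    transform: bool = True,
) -> pd.DataFrame:
    """Family-level mean relative abundance per fraction × depth group.

    OTU relative abundances are summed to family, averaged within each
    grouping cell, and the k families with the highest overall mean are
    returned (all families if k exceeds the family count), arcsine
    transformed by default.
    """
    fam = relabund.join(taxonomy["family"]).groupby("family").sum()
    groups = meta.loc[fam.columns, list(grouping)]
    means = fam.T.groupby([groups[g] for g in grouping]).mean().T
    order = fam.mean(axis=1).sort_values(ascending=False).index
    top = means.loc[order[: min(k, len(order))]]
    return top.apply(arcsine_transform) if transform else top


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts, base: float = np.e) -> float:
    """Shannon index H = -sum p_i log p_i over observed taxa (nats)."""
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    if n.size == 0:
        return 0.0
    p = n / n.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + n1(n1-1)/(2(n2+1)) (bias-corrected form)."""
    n = np.asarray(counts, dtype=float)
    s_obs = int((n > 0).sum())
    n1 = int((n == 1).sum())
    n2 = int((n == 2).sum())
    if bias_corrected:
        return s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    if n1 == 0:
        return float(s_obs)
    return s_obs + n1 * n1 / (2.0 * max(n2, 1))


def simpson_evenness(counts) -> float:
    """Simpson evenness E = (1/D) / S_obs with D = sum n_i(n_i-1)/(N(N-1)).

    D = 0 (all observed taxa singletons) is defined as E = 1.  The
    estimator can exceed 1 on small samples; values are reported as-is.
    """
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    s_obs = n.size
    if s_obs == 0:
        return 1.0
    total = n.sum()
    if total < 2:
        return 1.0
    d = (n * (n - 1)).sum() / (total * (total - 1))
    if d == 0:
        return 1.0
    return float(1.0 / d / s_obs)


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample diversity summary: H, Chao1, Simpson evenness plus the
    raw ingredients (S_obs, singletons, doubletons, library size)."""
    rows = {}
    for sample in table.sample_ids:
        n = table.counts[sample].to_numpy()
        rows[sample] = {
            "shannon": shannon(n),
            "chao1": chao1(n),
            "simpson_evenness": simpson_evenness(n),
            "S_obs": int((n > 0).sum()),
            "n1": int((n == 1).sum()),
            "n2": int((n == 2).sum()),
            "N": int(n.sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def diversity_env_correlation(
    diversity: pd.DataFrame, env: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlations between diversity indices and environmental
    parameters, with BH-adjusted Q-values.

    Returns a long table: index, env_var, rho, p, q.
    """
    idx_cols = [c for c in ("shannon", "chao1", "simpson_evenness")
                if c in diversity.columns]
    common = diversity.index.intersection(env.index)
    block = pd.concat(
        [diversity.loc[common, idx_cols], env.loc[common]], axis=1
    ).T
    rho, p = spearman_matrix(block)
    rows = []
    for ic in idx_cols:
        for ev in env.columns:
            rows.append({"index": ic, "env_var": ev,
                         "rho": rho.loc[ic, ev], "p": p.loc[ic, ev]})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
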