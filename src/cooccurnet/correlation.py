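"""Spearman correlation matrices, Benjamini–Hochberg FDR control and
thresholded co-occurrence network construction.

Variables are OTUs (per size fraction), environmental parameters and
optionally phytoplankton genera, observed over the water-mass grid
(month × station × depth).  A pair becomes an edge when its Q-value is
strictly below ``q_max`` and |rho| is at or above ``rho_min`` (0.7); for
October the Q cut-off is relaxed to 0.05, mirroring the sparser signal of
the post-typhoon mixing month.  Edges store rho, Q and the correlation
sign; by default both signs are admitted (the magnitude is thresholded)
and ``positive_only=True`` restricts to rho >= rho_min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import AnalysisBundle, MONTHS

logger = logging.getLogger("cooccurnet")


# ---------------------------------------------------------------------------
# correlation and FDR primitives
# ---------------------------------------------------------------------------

def spearman_matrix(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided P over the rows of ``X``
    (variables × samples).

    Ties receive average ranks; P-values come from the t statistic
    t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom, so
    |rho| = 1 gives P = 0.  Constant variables yield NaN rho (flagged and
    excluded downstream).  Fewer than 4 samples is an error.
    """
    n = X.shape[1]
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    values = X.to_numpy(dtype=float)
    if X.shape[0] == 1:
        rho = np.ones((1, 1))
        p = np.zeros((1, 1))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.spearmanr(values, axis=1)
            rho = np.atleast_2d(res.statistic)
            p = np.atleast_2d(res.pvalue)
        if rho.shape == (1, 1):  # scipy collapses the 2-variable case
            r = float(res.statistic)
            rho = np.array([[1.0, r], [r, 1.0]])
            pv = float(res.pvalue)
            p = np.array([[0.0, pv], [pv, 0.0]])
    constant = values.std(axis=1) == 0
    if constant.any():
        logger.warning("%d constant variables: correlations undefined",
                       int(constant.sum()))
        rho[constant, :] = np.nan
        rho[:, constant] = np.nan
        p[constant, :] = np.nan
        p[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    labels = X.index
    return (pd.DataFrame(rho, index=labels, columns=labels),
            pd.DataFrame(p, index=labels, columns=labels))


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up Q-values.

    Q_(i) = min_{j >= i} m * P_(j) / j, capped at 1, returned in the
    original order.  NaN or out-of-range P-values are an error.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# threshold policy
# ---------------------------------------------------------------------------

@dataclass
class ThresholdPolicy:
    """Edge-retention thresholds, with per-month overrides.

    The default month override relaxes October to Q < 0.05: with the
    standard cut-off that month yields roughly a fifth of the edges of the
    other months.
    """

    q_max: float = 0.01
    rho_min: float = 0.7
    month_q_max: dict[str, float] = field(
        default_factory=lambda: {"Oct": 0.05})
    positive_only: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max must lie in (0, 1]")
        if not (0 <= self.rho_min <= 1):
            raise ValueError("rho_min must lie in [0, 1]")

    def for_month(self, month: str | None) -> tuple[float, float]:
        """(q_max, rho_min) effective for a given month tag."""
        q = self.month_q_max.get(month, self.q_max) if month else self.q_max
        return q, self.rho_min


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(
    rho: pd.DataFrame,
    q: pd.DataFrame,
    policy: ThresholdPolicy,
    node_meta: pd.DataFrame | None = None,
    month: str | None = None,
    n_samples: int | None = None,
) -> nx.Graph:
    """Thresholded undirected network from aligned rho and Q matrices.

    Keeps the unordered pair (i, j) iff Q_ij < q_max and |rho_ij| >=
    rho_min (rho_ij >= rho_min when the policy is positive-only).
    Variables without any retained edge do not enter the node set, so the
    node count reflects connected variables.  An empty edge set yields a
    valid empty network with a warning.
    """
    q_max, rho_min = policy.for_month(month)
    g = nx.Graph(month=month, q_max=q_max, rho_min=rho_min)
    if n_samples is not None:
        g.graph["n_samples"] = n_samples
    labels = rho.index
    r = rho.to_numpy()
    qv = q.to_numpy()
    iu, ju = np.triu_indices(len(labels), k=1)
    mag = r[iu, ju] if policy.positive_only else np.abs(r[iu, ju])
    with np.errstate(invalid="ignore"):
        keep = (qv[iu, ju] < q_max) & (mag >= rho_min)
    keep &= ~np.isnan(r[iu, ju])
    for i, j in zip(iu[keep], ju[keep]):
        rij = float(r[i, j])
        g.add_edge(
            labels[i], labels[j],
            rho=rij, q=float(qv[i, j]),
            sign="positive" if rij >= 0 else "negative",
        )
    if node_meta is not None:
        for node in g.nodes:
            for key, val in node_meta.loc[node].items():
                if pd.notna(val):
                    g.nodes[node][key] = val
    if g.number_of_edges() == 0:
        logger.warning("network%s has no edges under Q<%g, |rho|>=%g",
                       f" for {month}" if month else "", q_max, rho_min)
    return g


def variable_matrix(
    bundle: AnalysisBundle,
    month: str | None = None,
    max_relabund_min: float = 0.001,
    prevalence_min: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the variables × water-mass matrix for one month (or pooled
    over all months when ``month`` is None).

    Per size fraction, OTUs pass the abundance/prevalence screen within
    that fraction's samples in scope; kept OTUs contribute one variable per
    fraction (relative abundance over the site grid).  Environmental
    parameters contribute one variable each; phytoplankton genera passing
    the prevalence screen contribute log10(x+1)-transformed variables.

    Returns ``(matrix, node_meta)`` where node_meta carries kind, fraction
    and taxonomy for every variable.
    """
    from .diversity import (filter_otus, filter_phyto, log10_phyto,
                            relative_abundance)
    from .tables import OtuTable

    meta = bundle.meta if month is None else bundle.meta[
        bundle.meta["month"] == month]
    if meta.empty:
        raise ValueError(f"no samples for month {month!r}")
    site_cols = ["month", "station", "depth"]
    sites = pd.MultiIndex.from_frame(meta[site_cols].drop_duplicates())
    fractions = list(dict.fromkeys(meta["fraction"]))

    # one sample per (site, fraction); drop sites not covered by all fractions
    by_site: dict[str, pd.Series] = {}
    complete = None
    for frac in fractions:
        sub = meta[meta["fraction"] == frac]
        lut = pd.Series(sub.index,
                        index=pd.MultiIndex.from_frame(sub[site_cols]))
        lut = lut[~lut.index.duplicated()]
        by_site[frac] = lut
        cov = sites.isin(lut.index)
        complete = cov if complete is None else (complete & cov)
    if not complete.all():
        logger.warning("dropping %d sites not sampled in every fraction",
                       int((~complete).sum()))
    sites = sites[complete]
    if len(sites) < 4:
        raise ValueError("fewer than 4 complete sites in scope")

    sub_table = OtuTable(bundle.otu.counts[meta.index])
    kept = filter_otus(sub_table, meta, max_relabund_min, prevalence_min)

    rows, meta_rows = [], []
    for frac in fractions:
        samples = by_site[frac].loc[sites].to_numpy()
        rel = relative_abundance(bundle.otu.counts[samples])
        for otu in kept[frac]:
            var = f"{otu}|{frac}"
            rows.append(pd.Series(rel.loc[otu].to_numpy(), name=var))
            info = {"kind": "otu", "fraction": frac, "otu_id": otu}
            if bundle.taxonomy is not None and otu in bundle.taxonomy.index:
                lineage = bundle.taxonomy.loc[otu]
                info.update({r: lineage[r]
                             for r in ("phylum", "order", "family")
                             if r in lineage})
            meta_rows.append(pd.Series(info, name=var))

    if bundle.env is not None:
        anchor = by_site[fractions[0]].loc[sites].to_numpy()
        for var in bundle.env.columns:
            rows.append(pd.Series(
                bundle.env.loc[anchor, var].to_numpy(), name=var))
            meta_rows.append(pd.Series({"kind": "env"}, name=var))

    if bundle.phyto is not None:
        anchor = by_site[fractions[0]].loc[sites].to_numpy()
        phyto = bundle.phyto[anchor]
        for genus in filter_phyto(phyto, prevalence_min):
            var = f"phyto:{genus}"
            rows.append(pd.Series(
                log10_phyto(phyto.loc[genus].to_numpy()), name=var))
            meta_rows.append(pd.Series({"kind": "phyto"}, name=var))

    matrix = pd.DataFrame(rows)
    matrix.columns = range(len(sites))
    node_meta = pd.DataFrame(meta_rows)
    return matrix, node_meta


def network_for_month(
    bundle: AnalysisBundle,
    policy: ThresholdPolicy,
    month: str | None = None,
    max_relabund_min: float = 0.001,
    prevalence_min: float = 0.7,
) -> nx.Graph:
    """Filter → Spearman → BH → threshold for one month (or pooled)."""
    matrix, node_meta = variable_matrix(
        bundle, month, max_relabund_min, prevalence_min)
    rho, p = spearman_matrix(matrix)
    iu, ju = np.triu_indices(len(matrix), k=1)
    pvec = p.to_numpy()[iu, ju]
    valid = ~np.isnan(pvec)
    qmat = np.full_like(p.to_numpy(), np.nan)
    qvec = np.full(pvec.shape, np.nan)
    qvec[valid] = bh_fdr(pvec[valid])
    qmat[iu, ju] = qvec
    qmat[ju, iu] = qvec
    q = pd.DataFrame(qmat, index=p.index, columns=p.columns)
    return build_network(rho, q, policy, node_meta, month=month,
                         n_samples=matrix.shape[1])


def monthly_networks(
    bundle: AnalysisBundle,
    policy: ThresholdPolicy | None = None,
    max_relabund_min: float = 0.001,
    prevalence_min: float = 0.7,
) -> list[tuple[str, nx.Graph]]:
    """One thresholded co-occurrence network per sampled month."""
    policy = policy or ThresholdPolicy()
    out = []
    for month in bundle.months():
        g = network_for_month(bundle, policy, month,
                              max_relabund_min, prevalence_min)
        out.append((month, g))
    return out
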