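"""Correlation inference and network construction.

All-pairs Spearman rank correlation with Benjamini–Hochberg FDR control,
diffusion-based enhancement of |ρ|, and dual-threshold edge retention: an
association becomes an edge only when it is statistically significant
(P < 0.01, Q < 0.05) and robust (|ρ| > 0.6 both before and after
enhancement).  Taxa–environment association networks use the looser
published thresholds (P < 0.05, Q < 0.05, |r| ≥ 0.6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enhance import network_enhance
from .tables import RelAbundanceTable, SampleMetadata, TaxonomyMap

__all__ = [
    "CorrelationSet",
    "spearman_all_pairs",
    "adjust_fdr",
    "build_network",
    "build_env_network",
    "enhanced_weights",
]


@dataclass
class CorrelationSet:
    """Symmetric Spearman ρ / raw P / BH Q matrices over all taxon pairs."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    #: taxa whose abundance vector had zero variance (ρ recorded as 0, p as 1)
    flagged: list[str] = field(default_factory=list)

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.rho.index]


def adjust_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values for a flat vector of p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def spearman_all_pairs(rel: RelAbundanceTable) -> CorrelationSet:
    """All-pairs Spearman correlation across samples.

    Requires at least 4 samples (p-values are meaningless below).  Ties are
    handled by midranks and two-sided p-values follow the t-approximation on
    n − 2 degrees of freedom.  Zero-variance taxa yield ρ = 0, p = 1 for all
    their pairs and are flagged.
    """
    if rel.n_samples < 4:
        raise ValueError("need at least 4 samples for correlation inference")
    vals = rel.values  # taxa × samples
    taxa = rel.taxon_ids
    n = rel.n_samples
    flagged = [t for t, v in zip(taxa, vals) if np.ptp(v) == 0]
    ranks = stats.rankdata(vals, axis=1)  # midranks
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks)
        rho = np.clip(np.asarray(rho, dtype=float), -1.0, 1.0)
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p[np.isinf(tstat)] = 0.0  # |rho| = 1
    bad = ~np.isfinite(rho)
    rho[bad] = 0.0
    p[bad] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(len(taxa), k=1)
    q = np.zeros_like(p)
    q[iu] = adjust_fdr(p[iu])
    q = q + q.T
    idx = pd.Index(taxa, name="taxon")
    return CorrelationSet(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        q=pd.DataFrame(q, index=idx, columns=idx),
        flagged=flagged,
    )


def enhanced_weights(cset: CorrelationSet, K: int | None = None,
                     alpha: float = 0.9, order: int = 2,
                     rescale: str = "node_max") -> pd.DataFrame:
    """Run network enhancement on |ρ| (diffusion needs non-negative weights)."""
    W = np.abs(cset.rho.to_numpy(dtype=float))
    np.fill_diagonal(W, 0.0)
    out = network_enhance(W, K=K, alpha=alpha, order=order, rescale=rescale)
    return pd.DataFrame(out, index=cset.rho.index, columns=cset.rho.columns)


def build_network(rel: RelAbundanceTable, cset: CorrelationSet,
                  enh: pd.DataFrame | np.ndarray | None,
                  rho_min: float = 0.6, p_max: float = 0.01,
                  q_max: float = 0.05,
                  tax: TaxonomyMap | None = None) -> nx.Graph:
    """Build the signed co-occurrence network from thresholded correlations.

    An edge (i, j) is retained iff ``p < p_max``, ``q < q_max``,
    ``|ρ| > rho_min`` and (when ``enh`` is given) the enhanced weight also
    exceeds ``rho_min``.  Edge weight is the signed ρ; isolated taxa are
    dropped.  Node attributes: mean relative abundance over the group's
    samples, plus family/lineage when a taxonomy is supplied.
    """
    taxa = cset.taxon_ids
    rho = cset.rho.to_numpy(dtype=float)
    p = cset.p.to_numpy(dtype=float)
    q = cset.q.to_numpy(dtype=float)
    keep = (p < p_max) & (q < q_max) & (np.abs(rho) > rho_min)
    if enh is not None:
        E = enh.to_numpy(dtype=float) if isinstance(enh, pd.DataFrame) else np.asarray(enh, float)
        keep &= E > rho_min
    means = dict(zip(rel.taxon_ids, rel.values.mean(axis=1)))
    g = nx.Graph()
    iu, ju = np.triu_indices(len(taxa), k=1)
    for i, j in zip(iu[keep[iu, ju]], ju[keep[iu, ju]]):
        r = float(rho[i, j])
        g.add_edge(taxa[i], taxa[j], weight=r,
                   sign="negative" if r < 0 else "positive")
    if g.number_of_edges() == 0:
        warnings.warn("no correlations survive the thresholds; empty network",
                      stacklevel=2)
    for n in g.nodes:
        g.nodes[n]["abundance"] = float(means.get(n, 0.0))
        if tax is not None and n in tax:
            g.nodes[n]["family"] = tax.family_label(n)
            g.nodes[n]["lineage"] = tax.lineage_string(n)
        g.nodes[n]["kind"] = "taxon"
    return g


def env_edge_mask(p: np.ndarray, q: np.ndarray, rho: np.ndarray,
                  p_max: float = 0.05, q_max: float = 0.05,
                  r_min: float = 0.6) -> np.ndarray:
    """Retention rule for taxon–environment edges (note ≥ on |r|)."""
    return (p < p_max) & (q < q_max) & (np.abs(rho) >= r_min)


def build_env_network(rel: RelAbundanceTable, meta: SampleMetadata,
                      base: nx.Graph, p_max: float = 0.05,
                      q_max: float = 0.05, r_min: float = 0.6) -> nx.Graph:
    """Taxa–environment association network.

    Each base-network taxon is tested (Spearman) against each numeric
    environmental variable; BH adjustment runs over the taxon × variable
    test family; an edge requires P < ``p_max``, Q < ``q_max`` and
    |r| ≥ ``r_min``.  Taxa–taxa edges are carried over from ``base``.
    Variables with missing values are computed pairwise-complete and flagged
    when fewer than 4 complete pairs remain.
    """
    meta.covers(rel.sample_ids)
    env = meta.env_frame().loc[rel.sample_ids]
    taxa = [n for n in base.nodes if base.nodes[n].get("kind", "taxon") == "taxon"]
    variables = list(env.columns)
    rho = np.zeros((len(taxa), len(variables)))
    p = np.ones_like(rho)
    low_n: list[tuple[str, str]] = []
    tvals = rel.frame.loc[taxa].to_numpy(dtype=float)
    for j, var in enumerate(variables):
        y = env[var].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 4:
            low_n.extend((t, var) for t in taxa)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(len(taxa)):
                r_, p_ = stats.spearmanr(tvals[i, ok], y[ok])
                if np.isfinite(r_):
                    rho[i, j], p[i, j] = r_, p_
    q = adjust_fdr(p.ravel()).reshape(p.shape)
    keep = env_edge_mask(p, q, rho, p_max=p_max, q_max=q_max, r_min=r_min)
    g = base.copy()
    for var in variables:
        g.add_node(var, kind="environment")
    for i, t in enumerate(taxa):
        for j, var in enumerate(variables):
            if keep[i, j]:
                r_ = float(rho[i, j])
                g.add_edge(t, var, weight=r_,
                           sign="negative" if r_ < 0 else "positive")
    if low_n:
        warnings.warn("environmental variable(s) with <4 complete pairs",
                      stacklevel=2)
    # drop environment variables that attracted no associations
    for var in variables:
        if g.degree(var) == 0:
            g.remove_node(var)
    return g
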