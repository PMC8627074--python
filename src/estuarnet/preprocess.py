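"""Count-table preprocessing: rarefaction, normalisation, filtering, grouping.

The operations here turn a raw ASV count table into the filtered relative
abundance tables that feed correlation inference, and partition samples into
the groups (all / season / region) that each network is built from.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable, RelAbundanceTable, SampleMetadata, TaxonomyMap

__all__ = [
    "rarefy",
    "to_relative",
    "filter_taxa",
    "aggregate_to_family",
    "subsample_uniform",
    "partition_samples",
    "SampleGrouping",
    "UPPER_BAY_STATIONS",
    "LOWER_BAY_STATIONS",
]

#: Stations assigned to the upper (freshwater side) and lower (ocean side) Bay.
UPPER_BAY_STATIONS = frozenset({"908", "845", "818"})
LOWER_BAY_STATIONS = frozenset({"707", "724", "744"})


def rarefy(table: CountTable, depth: int = 85_000, seed: int = 0) -> CountTable:
    """Rarefy each sample to ``depth`` reads without replacement.

    Each retained sample column is a multivariate-hypergeometric draw of
    exactly ``depth`` reads from the sample's reads.  Samples with fewer
    than ``depth`` total reads are dropped with a warning.  Deterministic
    per ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for s in table.sample_ids:
        col = table.frame[s].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(s)
            continue
        if total == depth:
            cols[s] = col.copy()
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    if not cols:
        raise ValueError(f"all samples have fewer than {depth} reads")
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} sample(s) below rarefaction depth "
            f"{depth}: {dropped}", stacklevel=2)
    df = pd.DataFrame(cols, index=table.frame.index, dtype=np.int64)
    return CountTable(df)


def to_relative(table: CountTable) -> RelAbundanceTable:
    """Per-sample relative abundances: count / sample total."""
    sums = table.frame.sum(axis=0)
    zero = [str(s) for s, t in sums.items() if t == 0]
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    return RelAbundanceTable(table.frame / sums)


def filter_taxa(rel: RelAbundanceTable, prevalence_min: float = 0.20,
                summed_abundance_min: float = 0.005) -> RelAbundanceTable:
    """Drop sparse and low-abundance taxa.

    A taxon is retained iff it is non-zero in at least
    ``ceil(prevalence_min * n_samples)`` samples (a tie at exactly the
    threshold is kept) and its relative abundance summed over samples is at
    least ``summed_abundance_min``.
    """
    for thr in (prevalence_min, summed_abundance_min):
        if not 0 < thr <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
    vals = rel.values
    need = math.ceil(prevalence_min * rel.n_samples)
    prevalent = (vals > 0).sum(axis=1) >= need
    abundant = vals.sum(axis=1) >= summed_abundance_min
    keep = prevalent & abundant
    if not keep.any():
        raise ValueError(
            "no taxa survive filtering; review prevalence/abundance thresholds")
    return RelAbundanceTable(rel.frame.loc[keep].copy())


def aggregate_to_family(table: CountTable | RelAbundanceTable,
                        tax: TaxonomyMap) -> CountTable | RelAbundanceTable:
    """Sum rows that share a family label.

    Taxa without a resolved family are grouped under a label derived from
    their most resolved rank, so unclassified taxa from different parents
    never merge.  Row order follows first appearance of each label; the
    table total is conserved.
    """
    missing = [t for t in table.taxon_ids if t not in tax]
    if missing:
        raise ValueError(f"taxa without taxonomy: {missing[:5]}")
    labels = [tax.family_label(t) for t in table.taxon_ids]
    grouped = table.frame.groupby(pd.Index(labels, name="family"), sort=False).sum()
    return type(table)(grouped)


def subsample_uniform(table: CountTable | RelAbundanceTable, n_samples: int,
                      n_taxa: int, seed: int = 0):
    """Uniform random subset of both axes, without replacement.

    Used to equalise network sizes across groups before inference.  The
    original ordering of retained rows and columns is preserved; one
    generator (from ``seed``) drives both draws.
    """
    if n_samples > table.n_samples:
        raise ValueError(
            f"requested {n_samples} samples but only {table.n_samples} available")
    if n_taxa > table.n_taxa:
        raise ValueError(
            f"requested {n_taxa} taxa but only {table.n_taxa} available")
    rng = np.random.default_rng(seed)
    si = np.sort(rng.choice(table.n_samples, size=n_samples, replace=False))
    ti = np.sort(rng.choice(table.n_taxa, size=n_taxa, replace=False))
    return type(table)(table.frame.iloc[ti, si].copy())


@dataclass
class SampleGrouping:
    """Disjoint sample groups under one scheme (all, season or region)."""

    scheme: str
    groups: dict[str, list[str]]


def partition_samples(meta: SampleMetadata, scheme: str = "all") -> SampleGrouping:
    """Partition samples by scheme.

    ``all`` puts every sample in one group; ``season`` groups by the season
    column; ``region`` maps stations 908/845/818 to the upper Bay and
    707/724/744 to the lower Bay, leaving other stations unassigned.
    """
    df = meta.frame
    if scheme == "all":
        return SampleGrouping("all", {"all": [str(s) for s in df.index]})
    if scheme == "season":
        groups = {str(season): [str(s) for s in sub.index]
                  for season, sub in df.groupby("season", sort=False)}
        return SampleGrouping("season", groups)
    if scheme == "region":
        stations = df["station"].astype(str)
        upper = [str(s) for s in df.index[stations.isin(UPPER_BAY_STATIONS)]]
        lower = [str(s) for s in df.index[stations.isin(LOWER_BAY_STATIONS)]]
        if not upper and not lower:
            raise ValueError("no samples from recognised upper/lower Bay stations")
        groups = {}
        if upper:
            groups["upper"] = upper
        if lower:
            groups["lower"] = lower
        return SampleGrouping("region", groups)
    raise ValueError(f"unknown grouping scheme {scheme!r}")
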