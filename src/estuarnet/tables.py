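"""Core tabular containers: count tables, relative abundances, sample metadata, taxonomy.

All containers are thin wrappers around :class:`pandas.DataFrame` that enforce
the invariants the downstream correlation machinery relies on (unique
identifiers, non-negative integer counts, per-sample normalisation).  Tables
are always oriented taxa × samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "RelAbundanceTable",
    "SampleMetadata",
    "TaxonomyMap",
    "RANKS",
    "ENV_VARIABLES",
    "SEASON_OF_MONTH",
]

#: Positional lineage ranks, coarsest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Numeric metadata columns eligible for taxa–environment association tests.
ENV_VARIABLES = (
    "temperature",
    "salinity",
    "TSS",
    "secchi_depth",
    "nitrate",
    "ammonium",
    "TON",
    "DOP",
    "OP",
    "chl_a",
    "PC",
)

#: Sampling-design months and the season each belongs to.
SEASON_OF_MONTH = {2: "winter", 3: "winter", 5: "spring", 6: "spring",
                   8: "summer", 10: "autumn"}

SEASONS = ("winter", "spring", "summer", "autumn")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """Integer abundance matrix, taxa × samples.

    Parameters
    ----------
    frame
        DataFrame with taxa as the index and samples as the columns; cells
        are non-negative integers.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        _check_unique(list(df.index), "taxon")
        _check_unique(list(df.columns), "sample")
        arr = df.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                # accept float frames holding exact integers (e.g. parsed TSV)
                if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                    bad = np.argwhere((arr != np.floor(arr)) | ~np.isfinite(arr))
                    r, c = bad[0]
                    raise ValueError(
                        f"non-integer count at taxon {df.index[r]!r}, "
                        f"sample {df.columns[c]!r}: {arr[r, c]!r}"
                    )
                df = df.astype(np.int64)
                self.frame = df
                arr = df.to_numpy()
            if (arr < 0).any():
                r, c = np.argwhere(arr < 0)[0]
                raise ValueError(
                    f"negative count at taxon {df.index[r]!r}, "
                    f"sample {df.columns[c]!r}: {arr[r, c]}"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.frame.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.columns]

    @property
    def counts(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_taxa(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def select(self, taxa: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "CountTable":
        df = self.frame
        if taxa is not None:
            df = df.loc[list(taxa)]
        if samples is not None:
            df = df[list(samples)]
        return CountTable(df.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class RelAbundanceTable:
    """Relative abundances in [0, 1], taxa × samples.

    Before taxon filtering every sample column sums to 1; after filtering
    column sums may fall below 1 but never exceed it.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        _check_unique(list(df.index), "taxon")
        _check_unique(list(df.columns), "sample")
        arr = df.to_numpy(dtype=float)
        if arr.size:
            if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
                raise ValueError("relative abundances must lie in [0, 1]")
            sums = arr.sum(axis=0)
            if (sums > 1 + 1e-9).any():
                s = df.columns[int(np.argmax(sums))]
                raise ValueError(f"sample {s!r} column sums above 1")

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.frame.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def select(self, taxa: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "RelAbundanceTable":
        df = self.frame
        if taxa is not None:
            df = df.loc[list(taxa)]
        if samples is not None:
            df = df[list(samples)]
        return RelAbundanceTable(df.copy())


@dataclass
class SampleMetadata:
    """Per-sample metadata: station, date, season and environmental variables.

    The frame is indexed by sample id.  ``season`` is derived from ``month``
    when absent, following the cruise design (Feb/Mar winter, May/Jun spring,
    Aug summer, Oct autumn); a month outside that design without an explicit
    season column is an error.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        _check_unique(list(df.index), "sample")
        if "station" not in df.columns:
            raise ValueError("metadata requires a 'station' column")
        df["station"] = df["station"].astype(str)
        if "season" not in df.columns:
            if "month" not in df.columns:
                raise ValueError("metadata requires 'season' or 'month'")
            months = df["month"].astype(int)
            unknown = sorted(set(months) - set(SEASON_OF_MONTH))
            if unknown:
                raise ValueError(
                    f"month(s) {unknown} outside the sampling design and no "
                    "season column given"
                )
            df["season"] = months.map(SEASON_OF_MONTH)
        else:
            bad = sorted(set(df["season"]) - set(SEASONS))
            if bad:
                raise ValueError(f"unknown season label(s): {bad}")
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def env_frame(self) -> pd.DataFrame:
        """Numeric environmental variables present in the table (samples × vars)."""
        cols = [c for c in ENV_VARIABLES if c in self.frame.columns]
        return self.frame[cols].astype(float)

    def covers(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.frame.index]
        if missing:
            raise ValueError(f"samples without metadata rows: {missing[:5]}")

    def subset(self, samples: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(samples)].copy())


PLACEHOLDER = "unclassified"


def _pad_lineage(ranks: Sequence[str]) -> tuple[str, ...]:
    ranks = [r.strip() for r in ranks]
    if len(ranks) > len(RANKS):
        ranks = ranks[: len(RANKS)]
    ranks = [r if r else PLACEHOLDER for r in ranks]
    ranks += [PLACEHOLDER] * (len(RANKS) - len(ranks))
    return tuple(ranks)


@dataclass
class TaxonomyMap:
    """taxon id → positional six-rank lineage (domain … genus).

    Missing trailing ranks are padded with the explicit ``unclassified``
    placeholder; they are never dropped.
    """

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_strings(cls, strings: Mapping[str, str], sep: str = ";") -> "TaxonomyMap":
        out: dict[str, tuple[str, ...]] = {}
        for taxon, s in strings.items():
            parts = [_strip_rank_prefix(p) for p in str(s).split(sep)]
            out[str(taxon)] = _pad_lineage(parts)
        return cls(out)

    def lineage(self, taxon: str) -> tuple[str, ...]:
        return self.lineages[taxon]

    def lineage_string(self, taxon: str, sep: str = ";") -> str:
        return sep.join(self.lineages.get(taxon, (PLACEHOLDER,) * len(RANKS)))

    def rank(self, taxon: str, rank: str) -> str:
        return self.lineages[taxon][RANKS.index(rank)]

    def family_label(self, taxon: str) -> str:
        """Family label for aggregation.

        Taxa without a resolved family are labelled by their most resolved
        rank (prefixed), so unclassified taxa under different parents are
        never merged with one another.
        """
        lin = self.lineages[taxon]
        fam = lin[RANKS.index("family")]
        if fam != PLACEHOLDER:
            return fam
        for rank, name in zip(reversed(RANKS[:4]), reversed(lin[:4])):
            if name != PLACEHOLDER:
                return f"{PLACEHOLDER}_{rank[0]}__{name}"
        return PLACEHOLDER

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


def _strip_rank_prefix(part: str) -> str:
    """Strip classifier-style rank prefixes like ``d__`` / ``p__``."""
    part = part.strip()
    if len(part) >= 3 and part[1:3] == "__" and part[0].isalpha():
        return part[3:]
    return part
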