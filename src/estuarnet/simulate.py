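"""Synthetic estuarine community generator with known ground truth.

Emulates the statistical structure the pipeline assumes downstream of read
processing: 7 stations × 4 seasons × 3 years of surface samples along a
temperature/salinity gradient, a few hundred taxa organised into ecological
guilds with strong within-guild rank correlation, antagonist guild pairs
(negative coupling), and rare "gatekeeper" taxa that bridge two guilds at
low abundance — producing, after inference, the low-abundance /
high-betweenness nodes whose removal fragments the network.

Latent model, per taxon t in guild g and sample s:

    x_t(s) = mu_t + sqrt(rho) * Z_g(s) + sqrt(1 - rho) * eps_t(s) + sd * nu_t(s)

where Z_g is a standardised guild factor (a mix of a Gaussian niche response
along temperature or salinity and a biotic component), rho is the target
within-guild correlation, and sd is extra log-scale dispersion.  Antagonist
guild pairs share a factor with opposite signs.  Counts per sample are a
single multinomial draw of ``depth`` reads over softmax(x), matching the
compositional, fixed-total character of a rarefied 16S table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import (CountTable, RelAbundanceTable, SampleMetadata,
                     TaxonomyMap, RANKS)

__all__ = [
    "GuildConfig",
    "GroundTruth",
    "generate_environment",
    "generate_community",
    "evaluate_recovery",
    "RecoveryReport",
    "DEFAULT_STATIONS",
]

#: Station ids ordered from the upper (freshwater) to the lower (ocean) Bay.
DEFAULT_STATIONS = ("908", "845", "818", "804", "707", "724", "744")

_SEASON_MONTHS = {"winter": (2, 3), "spring": (5, 6), "summer": (8,), "autumn": (10,)}
_SEASON_TEMP = {"winter": 4.0, "spring": 16.0, "summer": 27.0, "autumn": 19.0}

_PHYLA = ("Proteobacteria", "Bacteroidetes", "Actinobacteria",
          "Cyanobacteria", "Planctomycetes", "Verrucomicrobia")


def generate_environment(stations: int = 7, seasons: int = 4, years: int = 3,
                         seed: int = 0) -> SampleMetadata:
    """One sample per station × season × year with realistic gradients.

    Temperature follows the seasonal cycle (winter < spring < autumn <
    summer); salinity rises monotonically downstream from ~0 to ~30 PSU;
    TSS and nutrient load fall downstream; Chl a and particulate carbon
    covary with temperature and the freshwater end.  Deterministic per seed.
    """
    if stations < 1 or seasons < 1 or years < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    names = list(DEFAULT_STATIONS[:stations]) if stations <= len(DEFAULT_STATIONS) \
        else [f"S{i:03d}" for i in range(stations)]
    season_names = list(_SEASON_MONTHS)[:seasons]
    rows = []
    for yi, year in enumerate(range(2003, 2003 + years)):
        for season in season_names:
            months = _SEASON_MONTHS[season]
            month = months[yi % len(months)]
            for si, st in enumerate(names):
                frac = si / max(stations - 1, 1)  # 0 at head, 1 at mouth
                temp = _SEASON_TEMP[season] + 1.5 * frac + rng.normal(0, 1.0)
                sal = 30.0 * frac + rng.normal(0, 0.4)
                sal = max(sal, 0.05)
                tss = max(25.0 - 18.0 * frac + rng.normal(0, 2.0), 1.0)
                secchi = max(0.4 + 2.2 * frac + rng.normal(0, 0.15), 0.1)
                nitrate = max(1.4 - 1.1 * frac - 0.015 * (temp - 15)
                              + rng.normal(0, 0.08), 0.01)
                ammonium = max(0.06 + 0.10 * (1 - frac) + rng.normal(0, 0.02), 0.005)
                ton = max(0.6 - 0.35 * frac + rng.normal(0, 0.05), 0.05)
                dop = max(0.010 + 0.008 * (1 - frac) + rng.normal(0, 0.002), 0.001)
                op = max(0.008 + 0.010 * (1 - frac) + rng.normal(0, 0.002), 0.001)
                chl = max(4.0 + 0.55 * (temp - 15) + 7.0 * (1 - frac)
                          + rng.normal(0, 1.2), 0.2)
                pc = max(0.4 + 0.030 * tss + 0.045 * chl + rng.normal(0, 0.1), 0.05)
                rows.append({
                    "sample": f"{st}_{year}_{month:02d}",
                    "station": st, "year": year, "month": month, "season": season,
                    "temperature": temp, "salinity": sal, "TSS": tss,
                    "secchi_depth": secchi, "nitrate": nitrate,
                    "ammonium": ammonium, "TON": ton, "DOP": dop, "OP": op,
                    "chl_a": chl, "PC": pc,
                })
    df = pd.DataFrame(rows).set_index("sample")
    return SampleMetadata(df)


@dataclass
class GuildConfig:
    """Planted community structure for the generator."""

    n_guilds: int = 14
    taxa_per_guild: int = 10
    within_guild_correlation: float = 0.95
    #: guild index pairs whose shared factor has opposite signs
    antagonist_pairs: tuple[tuple[int, int], ...] = ((2, 3),)
    gatekeeper_count: int = 12
    #: shared seasonal forcing between guild factors: corr(Z_a, Z_b) for
    #: non-antagonist guilds; keeps cross-guild member pairs sub-threshold
    #: while letting bridging taxa correlate strongly with both guilds
    guild_factor_overlap: float = 0.4
    #: loading of a gatekeeper on the (standardised) sum of its two bridged
    #: guild factors; its correlation with each guild is
    #: loading * sqrt((1 + overlap) / 2) * sqrt(rho)
    gatekeeper_loading: float = 1.0
    #: taxa with no planted structure (pure noise rows; emulates the filtered
    #: ASVs that stay unconnected in the real networks)
    n_background: int = 248
    noise_sd: float = 0.2
    depth: int = 85_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.within_guild_correlation < 1:
            raise ValueError("within_guild_correlation must lie in (0, 1)")
        if not 0 < self.gatekeeper_loading <= 1:
            raise ValueError("gatekeeper_loading must lie in (0, 1]")
        for a, b in self.antagonist_pairs:
            if not (0 <= a < self.n_guilds and 0 <= b < self.n_guilds) or a == b:
                raise ValueError(f"invalid antagonist pair ({a}, {b})")

    @property
    def n_taxa(self) -> int:
        return (self.n_guilds * self.taxa_per_guild + self.gatekeeper_count
                + self.n_background)


@dataclass
class GroundTruth:
    """What the generator planted: guild labels, gatekeepers, signed pairs."""

    guild_of: dict[str, int]
    gatekeepers: set[str] = field(default_factory=set)
    #: list of (taxon_a, taxon_b, sign) with sign in {+1, -1}
    pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def pair_set(self) -> dict[frozenset, int]:
        return {frozenset((a, b)): s for a, b, s in self.pairs}


def _gaussian_niche(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((x - mu) ** 2) / (2 * sigma ** 2))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_community(meta: SampleMetadata, cfg: GuildConfig
                       ) -> tuple[CountTable, TaxonomyMap, GroundTruth]:
    """Draw a guild-structured count table over the given samples."""
    rng = np.random.default_rng(cfg.seed)
    n_s = len(meta.sample_ids)
    env = meta.frame
    temp = _standardize(env["temperature"].to_numpy(dtype=float))
    sal = _standardize(env["salinity"].to_numpy(dtype=float))
    rho = cfg.within_guild_correlation

    # guild factors: a shared seasonal forcing component (overlap w between
    # guilds) plus a guild-specific part mixing a Gaussian niche response
    # along the temperature or salinity gradient with a biotic component.
    # The guild-specific parts are orthogonalised against the forcing and
    # against one another, so corr(Z_a, Z_b) = w exactly for every
    # non-antagonist guild pair regardless of how niche optima fall.
    w = cfg.guild_factor_overlap
    forcing = _standardize(np.sqrt(0.45) * temp + np.sqrt(0.30) * sal
                           + np.sqrt(0.25) * rng.normal(size=n_s))
    drivers = [temp if g % 2 == 0 else sal for g in range(cfg.n_guilds)]
    z = np.empty((cfg.n_guilds, n_s))
    opposite_of: dict[int, int] = {}
    for a, b in cfg.antagonist_pairs:
        opposite_of[max(a, b)] = min(a, b)
    basis = [forcing / np.linalg.norm(forcing)]
    for g in range(cfg.n_guilds):
        if g in opposite_of:
            z[g] = -z[opposite_of[g]]
            continue
        niche = _standardize(_gaussian_niche(
            drivers[g], mu=float(rng.uniform(-1.0, 1.0)), sigma=1.5))
        own = np.sqrt(0.7) * niche + np.sqrt(0.3) * rng.normal(size=n_s)
        for b_vec in basis:
            own = own - (own @ b_vec) * b_vec
        own = _standardize(own)
        basis.append(own / np.linalg.norm(own))
        z[g] = _standardize(np.sqrt(w) * forcing + np.sqrt(1 - w) * own)

    taxa: list[str] = []
    latent = np.empty((cfg.n_taxa, n_s))
    guild_of: dict[str, int] = {}
    gatekeepers: set[str] = set()
    bridge_of: dict[str, tuple[int, int]] = {}
    t = 0
    for g in range(cfg.n_guilds):
        for _ in range(cfg.taxa_per_guild):
            tid = f"ASV{t:04d}"
            mu = rng.normal(0.0, 1.2)
            latent[t] = (mu + np.sqrt(rho) * z[g]
                         + np.sqrt(1 - rho) * rng.normal(size=n_s)
                         + cfg.noise_sd * rng.normal(size=n_s))
            taxa.append(tid)
            guild_of[tid] = g
            t += 1
    # gatekeepers: low-abundance taxa loading on two non-antagonist guilds;
    # bridged pairs are disjoint so every bridge is essential, leaving the
    # antagonist guilds (already joined by their negative edges) unbridged
    anti_members = {g for p in cfg.antagonist_pairs for g in p}
    free = [g for g in range(cfg.n_guilds) if g not in anti_members]
    guild_pairs = [(free[i], free[i + 1]) for i in range(0, len(free) - 1, 2)]
    if not guild_pairs:
        anti = {frozenset(p) for p in cfg.antagonist_pairs}
        guild_pairs = [(a, b) for a in range(cfg.n_guilds)
                       for b in range(a + 1, cfg.n_guilds)
                       if frozenset((a, b)) not in anti]
    for i in range(cfg.gatekeeper_count):
        tid = f"GK{i:02d}"
        a, b = guild_pairs[i % len(guild_pairs)] if guild_pairs else (0, 0)
        mu = rng.normal(-1.5, 0.2)  # bottom-decile log abundance (~15 reads/sample)
        c = cfg.gatekeeper_loading
        shared = _standardize(z[a] + z[b])
        latent[t] = (mu + c * shared
                     + np.sqrt(max(1 - c ** 2, 0.0)) * rng.normal(size=n_s)
                     + cfg.noise_sd * rng.normal(size=n_s))
        taxa.append(tid)
        gatekeepers.add(tid)
        bridge_of[tid] = (a, b)
        t += 1
    for i in range(cfg.n_background):
        tid = f"BG{i:02d}"
        mu = rng.normal(-0.5, 1.0)
        latent[t] = mu + rng.normal(size=n_s) + cfg.noise_sd * rng.normal(size=n_s)
        taxa.append(tid)
        t += 1

    if cfg.depth < cfg.n_taxa:
        warnings.warn("depth below taxon count; table will be very sparse",
                      stacklevel=2)
    probs = np.exp(latent - latent.max(axis=0, keepdims=True))
    probs /= probs.sum(axis=0, keepdims=True)
    counts = np.empty((cfg.n_taxa, n_s), dtype=np.int64)
    for s in range(n_s):
        counts[:, s] = rng.multinomial(cfg.depth, probs[:, s])
    table = CountTable(pd.DataFrame(counts, index=pd.Index(taxa, name="taxon"),
                                    columns=meta.sample_ids))

    # taxonomy: families cut across guilds so family-level aggregation mixes them
    fam_pool = [f"Family{i:02d}" for i in range(4 * len(_PHYLA))]
    lineages = {}
    for i, tid in enumerate(taxa):
        phylum = _PHYLA[i % len(_PHYLA)]
        fam = fam_pool[i % len(fam_pool)]
        lineages[tid] = ("Bacteria", phylum, f"{phylum}_c", f"{phylum}_o",
                         fam, f"Genus{i % 60:02d}")
    tax = TaxonomyMap({tid: lin[:len(RANKS)] for tid, lin in lineages.items()})

    pairs: list[tuple[str, str, int]] = []
    by_guild: dict[int, list[str]] = {}
    for tid, g in guild_of.items():
        by_guild.setdefault(g, []).append(tid)
    for g, members in by_guild.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j], 1))
    for a, b in cfg.antagonist_pairs:
        for ta in by_guild.get(a, []):
            for tb in by_guild.get(b, []):
                pairs.append((ta, tb, -1))
    for tid, (a, b) in bridge_of.items():
        for g in (a, b):
            for member in by_guild.get(g, []):
                pairs.append((tid, member, 1))
    # gatekeepers sharing both bridged guilds are themselves correlated
    gks = sorted(bridge_of)
    for i in range(len(gks)):
        for j in range(i + 1, len(gks)):
            if bridge_of[gks[i]] == bridge_of[gks[j]]:
                pairs.append((gks[i], gks[j], 1))
    truth = GroundTruth(guild_of=guild_of, gatekeepers=gatekeepers, pairs=pairs)
    return table, tax, truth


@dataclass
class RecoveryReport:
    precision: float
    recall: float
    n_edges: int
    n_planted: int
    gatekeeper_betweenness_percentile: float
    gatekeeper_abundance_percentile: float


def evaluate_recovery(net: nx.Graph, truth: GroundTruth,
                      signed: bool = True) -> RecoveryReport:
    """Precision/recall of planted pairs and gatekeeper centrality percentiles.

    Precision is the fraction of network edges that were planted (with the
    planted sign when ``signed``); recall is the fraction of planted pairs
    recovered.  Gatekeeper percentiles are means over gatekeepers present in
    the network, against the distribution over all network nodes.
    """
    planted = truth.pair_set()
    taxa_edges = [(u, v, d) for u, v, d in net.edges(data=True)
                  if net.nodes[u].get("kind", "taxon") == "taxon"
                  and net.nodes[v].get("kind", "taxon") == "taxon"]
    if not taxa_edges:
        warnings.warn("empty network; recovery is zero", stacklevel=2)
        return RecoveryReport(0.0, 0.0, 0, len(planted), 0.0, 0.0)
    hit = 0
    recovered: set[frozenset] = set()
    for u, v, d in taxa_edges:
        key = frozenset((u, v))
        want = planted.get(key)
        if want is None:
            continue
        sign = -1 if (d.get("sign") == "negative"
                      or float(d.get("weight", 0.0)) < 0) else 1
        if not signed or sign == want:
            hit += 1
            recovered.add(key)
    precision = hit / len(taxa_edges)
    recall = len(recovered) / len(planted) if planted else 0.0

    from . import topology  # local import to avoid cycle at module load
    bc = {n: c.betweenness for n, c in topology.centralities(net).items()} \
        if net.number_of_nodes() >= 2 else {}
    ab = {n: float(net.nodes[n].get("abundance", 0.0)) for n in net.nodes}
    gks = [g for g in truth.gatekeepers if g in net.nodes]
    if gks and bc:
        all_bc = np.array(list(bc.values()))
        all_ab = np.array(list(ab.values()))
        bpct = float(np.mean([stats.percentileofscore(all_bc, bc[g], kind="mean")
                              for g in gks]))
        apct = float(np.mean([stats.percentileofscore(all_ab, ab[g], kind="mean")
                              for g in gks]))
    else:
        bpct = apct = 0.0
    return RecoveryReport(precision=precision, recall=recall,
                          n_edges=len(taxa_edges), n_planted=len(planted),
                          gatekeeper_betweenness_percentile=bpct,
                          gatekeeper_abundance_percentile=apct)
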