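"""End-to-end pipeline: counts + metadata (+ taxonomy) → one network per
sample group (all, four seasons, two regions), each with a topology report
and attack trajectories, plus a taxa–environment association network and a
consolidated comparison table.

Every threshold and size is a named config key defaulting to the study
conditions; all randomness flows from named seeds derived from one root
seed.  The run manifest records the config snapshot, seeds, input digests
and output paths, so identical configs reproduce byte-identical outputs for
every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as eio
from . import preprocess, inference, topology, stability
from .tables import CountTable, SampleMetadata, TaxonomyMap

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("estuarnet")


@dataclass
class PipelineConfig:
    counts: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    out_dir: str = "estuarnet_run"
    seed: int = 0

    rarefaction_depth: int = 85_000
    prevalence_min: float = 0.20
    summed_abundance_min: float = 0.005
    #: per-scheme (n_samples, n_taxa) normalisation before inference
    subsample_season: tuple[int, int] | None = (18, 340)
    subsample_region: tuple[int, int] | None = (31, 384)

    rho_min: float = 0.6
    p_max: float = 0.01
    q_max: float = 0.05
    enhance: bool = True
    enhance_K: int | None = None
    enhance_alpha: float = 0.9
    enhance_order: int = 2

    env_p_max: float = 0.05
    env_q_max: float = 0.05
    env_r_min: float = 0.6

    attack_rounds: int = 10
    attack_k: int = 10
    attack_criteria: tuple[str, ...] = ("abundance", "degree", "betweenness")
    adaptive_attack: bool = True

    null_reps: int = 0  # random-graph reference replicates (0 = skip)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("subsample_season", "subsample_region"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        if "attack_criteria" in raw:
            raw["attack_criteria"] = tuple(raw["attack_criteria"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subsample_season"] = list(self.subsample_season) if self.subsample_season else None
        d["subsample_region"] = list(self.subsample_region) if self.subsample_region else None
        d["attack_criteria"] = list(self.attack_criteria)
        return d


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(root: int, tag: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{root}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _group_specs(cfg: PipelineConfig, meta: SampleMetadata):
    """(group label, sample ids, subsample sizes) for all / season / region."""
    specs = []
    for scheme in ("all", "season", "region"):
        try:
            grouping = preprocess.partition_samples(meta, scheme)
        except ValueError as exc:
            log.warning("skipping scheme %s: %s", scheme, exc)
            continue
        sizes = {"all": None, "season": cfg.subsample_season,
                 "region": cfg.subsample_region}[scheme]
        for label, samples in grouping.groups.items():
            specs.append((label, samples, sizes))
    return specs


def _infer_group(table: CountTable, samples: list[str], sizes, cfg: PipelineConfig,
                 tax: TaxonomyMap | None, seed_tag: str, root_seed: int):
    """Filter within the group, optionally subsample, infer one network."""
    sub = table.select(samples=samples)
    rel = preprocess.to_relative(sub)
    rel = preprocess.filter_taxa(rel, cfg.prevalence_min, cfg.summed_abundance_min)
    if sizes is not None:
        n_samples, n_taxa = sizes
        n_samples = min(n_samples, rel.n_samples)
        n_taxa = min(n_taxa, rel.n_taxa)
        rel = preprocess.subsample_uniform(
            rel, n_samples, n_taxa, seed=_stage_seed(root_seed, f"sub:{seed_tag}"))
    cset = inference.spearman_all_pairs(rel)
    enh = None
    if cfg.enhance:
        enh = inference.enhanced_weights(cset, K=cfg.enhance_K,
                                         alpha=cfg.enhance_alpha,
                                         order=cfg.enhance_order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = inference.build_network(rel, cset, enh, rho_min=cfg.rho_min,
                                      p_max=cfg.p_max, q_max=cfg.q_max, tax=tax)
    return rel, net


def run_pipeline(cfg: PipelineConfig,
                 table: CountTable | None = None,
                 meta: SampleMetadata | None = None,
                 tax: TaxonomyMap | None = None) -> dict:
    """Run the full analysis; returns the manifest (also written to disk).

    Inputs may be passed in memory or read from the paths in ``cfg``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests = {}
    if table is None:
        if cfg.counts is None:
            raise ValueError("no count table given (config 'counts' or in-memory)")
        table = eio.read_count_table(cfg.counts)
        digests["counts"] = _digest(cfg.counts)
    if meta is None:
        if cfg.metadata is None:
            raise ValueError("no metadata given")
        meta = eio.read_metadata(cfg.metadata)
        digests["metadata"] = _digest(cfg.metadata)
    if tax is None and cfg.taxonomy:
        tax = eio.read_taxonomy(cfg.taxonomy)
        digests["taxonomy"] = _digest(cfg.taxonomy)
    meta.covers(table.sample_ids)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = preprocess.rarefy(table, depth=cfg.rarefaction_depth,
                                  seed=_stage_seed(cfg.seed, "rarefy"))
    meta = meta.subset(table.sample_ids)

    from . import __version__  # deferred: avoids circular import at load
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "input_digests": digests,
        "seeds": {"root": cfg.seed},
        "groups": {},
        "outputs": {},
    }
    reports: dict[str, topology.TopologyReport] = {}
    couplings: dict[str, float] = {}
    base_rel = None
    base_net = None

    for label, samples, sizes in _group_specs(cfg, meta):
        if len(samples) < 4:
            log.warning("group %s has %d samples (<4); skipped", label, len(samples))
            continue
        gdir = out / label
        gdir.mkdir(exist_ok=True)
        mod_seed = _stage_seed(cfg.seed, f"mod:{label}")
        rel, net = _infer_group(table, samples, sizes, cfg, tax, label, cfg.seed)
        if net.number_of_nodes() < 2:
            log.warning("group %s yielded an empty network; skipped", label)
            continue
        topology.annotate(net, seed=mod_seed)
        eio.write_network(net, gdir / "network.graphml", "graphml")
        eio.write_network(net, gdir / "network", "edge_csv")
        report = topology.summarize(net, modularity_seed=mod_seed)
        reports[label] = report
        with open(gdir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        cp = stability.coupling(net)
        couplings[label] = cp.rho
        max_rounds = max((net.number_of_nodes() - 1) // cfg.attack_k - 1, 1)
        rounds = min(cfg.attack_rounds, max_rounds)
        for crit in cfg.attack_criteria:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = stability.attack_trajectory(
                    net, criterion=crit, rounds=rounds, k=cfg.attack_k,
                    adaptive=cfg.adaptive_attack,
                    seed=_stage_seed(cfg.seed, f"attack:{label}:{crit}"), rel=rel)
            rows = [{"round": i + 1, "removed_ids": ";".join(r.removed),
                     "N": r.n_after, "CL": r.cl_after, "f": r.f_after,
                     "E": r.e_after, "modularity": r.modularity_after}
                    for i, r in enumerate(traj.rounds)]
            pd.DataFrame(rows).to_csv(gdir / f"attack_{crit}.csv", index=False)
        manifest["groups"][label] = {
            "n_samples": rel.n_samples, "n_taxa": rel.n_taxa,
            "n_nodes": report.n_nodes, "n_edges": report.n_edges,
            "coupling_rho": cp.rho,
        }
        manifest["outputs"][label] = str(gdir)
        if label == "all":
            base_rel, base_net = rel, net

    if base_net is not None and base_rel is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            envnet = inference.build_env_network(
                base_rel, meta.subset(base_rel.sample_ids), base_net,
                p_max=cfg.env_p_max, q_max=cfg.env_q_max, r_min=cfg.env_r_min)
        eio.write_network(envnet, out / "env_network.graphml", "graphml")
        manifest["outputs"]["env_network"] = str(out / "env_network.graphml")

    if reports:
        cmp_rows = {label: r.to_dict() for label, r in reports.items()}
        cmp_df = pd.DataFrame(cmp_rows).T
        cmp_df.insert(len(cmp_df.columns), "coupling_rho",
                      [couplings.get(l, float("nan")) for l in cmp_df.index])
        cmp_df.to_csv(out / "comparison_table.csv", index_label="group")
        manifest["outputs"]["comparison_table"] = str(out / "comparison_table.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
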