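# estuarnet

Co-occurrence network inference, topology and stability analysis for
estuarine microbiome count tables.

## The problem

Planktonic microbial communities in estuaries such as the Chesapeake Bay
sit on strong temperature and salinity gradients. Which taxa rise and fall
together across stations and seasons — and how fragile that web of
associations is — says a great deal about community stability. This
package implements the full analysis path from an ASV (amplicon sequence
variant) count table plus sample metadata to:

- **signed co-occurrence networks**: all-pairs Spearman rank correlation
  with Benjamini–Hochberg FDR control, diffusion-based network enhancement
  to suppress spurious links, and dual-threshold edge retention
  (P < 0.01, Q < 0.05, |ρ| > 0.6 before *and* after enhancement);
- **topology reports**: nodes, edges, fragmentation, average degree,
  diameter, density, modularity (seeded Louvain), components, clustering
  coefficient, path length, clusters and negative-edge share;
- **stability under attack**: iterative removal of the top-k nodes by
  abundance, degree or betweenness, tracking the fragmentation statistic
  **f = log(CL)/log(N)** (CL = connected components, N = nodes; 0 =
  connected, 1 = fully fragmented), plus degree–betweenness coupling with
  a bootstrap Monte-Carlo comparison across networks;
- **taxa–environment association networks** (P < 0.05, Q < 0.05,
  |r| ≥ 0.6) against temperature, salinity, TSS, nutrients, Chl a and
  particulate carbon;
- a **synthetic community generator** with known ground truth — ecological
  guilds with controlled within-guild correlation, antagonist (negatively
  coupled) guild pairs, and rare low-abundance "gatekeeper" taxa bridging
  guilds — used as the test bed for every inference step.

It is aimed at microbial ecologists who have a rarefied 16S count table
and want reproducible, seeded network construction and stability analysis
without stitching together R scripts and a GUI graph tool.

## Worked example

```python
import estuarnet as en

# synthetic Chesapeake-like data: 7 stations x 4 seasons x 3 years
meta = en.generate_environment(seed=7)
table, tax, truth = en.generate_community(meta, en.GuildConfig(seed=7))

rel = en.filter_taxa(en.to_relative(table))          # 20% prevalence, 0.5% abundance
cset = en.spearman_all_pairs(rel)
net = en.build_network(rel, cset, en.enhanced_weights(cset), tax=tax)

report = en.summarize(net, modularity_seed=0)
print(f"nodes={report.n_nodes} edges={report.n_edges} "
      f"f={report.fragmentation:.2f} density={report.density:.3f}")
print(f"modularity={report.modularity:.3f} clusters={report.n_clusters} "
      f"negative={report.pct_negative_edges:.1f}%")

traj = en.attack_trajectory(net, criterion="betweenness", rounds=3, k=10, seed=0)
for i, r in enumerate(traj.rounds, 1):
    print(f"round {i}: N={r.n_after} CL={r.cl_after} f={r.f_after:.2f}")

rec = en.evaluate_recovery(net, truth)
print(f"precision={rec.precision:.2f} recall={rec.recall:.2f} "
      f"gatekeeper betweenness pct={rec.gatekeeper_betweenness_percentile:.0f}")
```

prints

```
nodes=152 edges=964 f=0.39 density=0.084
modularity=0.854 clusters=7 negative=10.4%
round 1: N=142 CL=11 f=0.48
round 2: N=132 CL=13 f=0.53
round 3: N=122 CL=12 f=0.52
precision=1.00 recall=0.99 gatekeeper betweenness pct=96
```

Reading this: of 400 simulated taxa, 152 carry significant robust
associations (964 edges, 10.4% negative — the antagonist guild pair).
Removing the ten highest-betweenness nodes per round fragments the network
(components climb from 7 to 11, then 13, and f from 0.39 toward 0.53) because the removals hit the planted gatekeepers: rare taxa
(bottom-decile abundance) that nevertheless sit on 96% of the betweenness
distribution and hold guilds together. Every network edge is a planted
association (precision 1.00) and 99% of planted associations are
recovered (recall 0.99).

The same pipeline runs end-to-end from the command line:

```bash
estuarnet simulate --seed 7 --out sim/
estuarnet run --config config.yaml        # all + 4 seasonal + 2 regional networks
estuarnet topology --net run/all/network.graphml --null-reps 200 --seed 0 --out report.json
estuarnet attack --net run/all/network.graphml --criterion betweenness --rounds 10 --out traj.csv
```

Seasonal networks are size-normalised (18 samples × 340 taxa) before
inference, regional networks to 31 × 384, with the 20%-prevalence /
0.5%-summed-abundance filters re-applied within each sample group; all
thresholds and sizes are config keys.

## Layout

```
src/estuarnet/
  tables.py      count/abundance/metadata/taxonomy containers
  io.py          TSV, GraphML, GEXF, edge/node CSV readers and writers
  preprocess.py  rarefaction, filtering, family aggregation, grouping
  inference.py   Spearman + FDR + thresholds, env association networks
  enhance.py     diffusion-based network enhancement
  topology.py    topology reports, centralities, communities, ER nulls
  stability.py   attack trajectories, coupling, Monte-Carlo comparison
  simulate.py    synthetic community generator with ground truth
  pipeline.py    end-to-end runner with manifest
  cli.py         `estuarnet` command group
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
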