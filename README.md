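# woodwebs

Weighted bipartite network analysis of insect–host rearing experiments.

Saproxylic (dead-wood-dependent) beetles oviposit in dying branches; rearing
the wood in isolation and counting the adults that emerge attributes every
individual to one host-tree species. Repeating this under several
spatio-temporal treatments (e.g. rain/dry season × canopy/ground) yields one
weighted host × beetle interaction matrix per treatment. `woodwebs`
implements the full comparative analysis of such an experiment:

- **α diversity** — Hill numbers ⁰D (richness), ¹D (exp Shannon),
  ²D (inverse Simpson), with multinomial-bootstrap 95% CIs, CI-overlap
  significance letters, and sample-coverage estimation;
- **β diversity** — the pairwise Sørensen partition
  β_sor = β_sim + β_sne (turnover + nestedness-resultant) on species pools,
  and whole-network interaction dissimilarity β_WN = β_OS + β_ST
  (rewiring among shared species + species turnover) on link sets;
- **network structure** — weighted nestedness WNODF (0–100), Barber's
  bipartite modularity Q maximized by weighted label propagation with
  agglomerative refinement and restarts, network specialization
  H₂′ = (H₂max − H₂)/(H₂max − H₂min), and mean pairwise Horn niche overlap
  per trophic level;
- **species-level indices** — degree, Blüthgen's d′ (standardized KL
  divergence of partner use from availability), effective partners
  (exp Shannon), and species strength (summed partner dependence);
- **significance** — fixed-marginal Patefield null models (random tables
  with the observed marginals, multiple-hypergeometric distributed),
  add-one p-values for WNODF/H₂′/overlap and a z ≥ 2 rule for modularity;
- **traits and ordination** — wood density, percent daily decomposition
  (PDD), beetle body-size index (BSI), and correlation-matrix PCAs joining
  traits with species-level indices (|r| ≥ 0.6 loading rule), plus
  Kruskal–Wallis treatment comparisons;
- **synthetic data** — a seeded generator of rearing experiments with
  latent modules, a specialization concentration κ, a nestedness gradient,
  and a cross-treatment species-retention knob ρ, so the whole pipeline
  runs and is testable without field data.

## Worked example

```python
import woodwebs as ww

cfg = ww.reference_preset(seed=1)          # four-treatment experiment
records, traits, truth = ww.generate_dataset(cfg)
nets = ww.build_networks(records)

rc = nets["Rc"]                            # rain-canopy network
print(f"Rc: {len(rc.hosts)} hosts x {len(rc.beetles)} beetles, "
      f"{rc.m} emergences")
print(f"WNODF = {ww.wnodf(rc):.2f}")
print(f"H2' = {ww.h2_prime(rc):.3f}")
part, q = ww.modularity_lp(rc, seed=1)
print(f"Q = {q:.3f}")
ens = ww.null_test(rc, "h2", n_rand=1000, seed=1)
print(f"H2' vs null: {ens.observed:.3f} vs {ens.null_mean:.3f}, "
      f"p = {ens.p_value:.4f}")
```

prints

```
Rc: 20 hosts x 21 beetles, 234 emergences
WNODF = 9.15
H2' = 0.586
Q = 0.530
H2' vs null: 0.586 vs 0.142, p = 0.0010
```

i.e. a weakly nested (WNODF ≈ 9 on a 0–100 scale), modular (Q ≈ 0.53)
network whose specialization (H₂′ ≈ 0.59) far exceeds the fixed-marginal
null expectation (≈ 0.14); with 1,000 randomizations the add-one p-value
bottoms out at 1/1001 ≈ 0.001.

The same stages run end-to-end from a shell:

```sh
woodwebs simulate --seed 1 --out data/
woodwebs analyze --records data/records.csv --traits data/traits.csv --out out/
woodwebs metrics --matrix adjacency.csv --metric wnodf   # one number on stdout
```

`analyze` writes plain-CSV reports (diversity table with significance
letters, β-diversity tables, a per-treatment structure table with
cross-treatment mean ± SD summary, null-model report, species-level
indices, PCA loadings) plus a JSON manifest; all output is byte-stable
under a fixed `--seed`.

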