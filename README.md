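# depthdiv

Depth-layer diversity, clustering and functional profiling of
shotgun-metagenome taxonomic classifications.

Ocean microbial communities change with depth: surveys of tropical and
subtropical stations sampled at the surface (SRF, 3–7 m), the deep
chlorophyll maximum (DCM, 7–200 m) and the mesopelagic zone (MES,
200–1000 m) report higher taxonomic diversity and a higher archaeal share in
the mesopelagic, with viruses most prominent near the surface. `depthdiv`
packages the downstream analysis of such surveys for anyone who already has
per-read taxonomic classifications (Kaiju-style tables) and, optionally,
per-read GO annotations:

- **Per-sample indices.** The abundance index of sample *j* is its total
  number of taxonomically attributed reads. Diversity is the Shannon–Wiener
  index over the sample's taxon proportions *p<sub>ij</sub>*,
  *H<sub>j</sub>* = −Σ<sub>i</sub> *p<sub>ij</sub>* ln *p<sub>ij</sub>*
  (nats), normalised to *H′<sub>j</sub>* = *H<sub>j</sub>* / ln *M* ∈ [0, 1],
  where *M* is the number of distinct taxa observed across **all** samples.
- **Unsupervised grouping.** Samples are clustered by UPGMA (size-weighted
  average linkage) on Euclidean distances between their normalised SWI
  values; the number of groups is set by the Mojena stopping rule
  θ<sub>k</sub> = ᾱ + k·σ̂<sub>α</sub> over the fusion heights α<sub>j</sub>,
  with k = 1.25, cutting immediately before the first merge whose height
  exceeds θ<sub>k</sub>. An sklearn-compatible `MojenaUPGMA` estimator wraps
  this stage.
- **Layer comparisons.** Two-sided Wilcoxon rank-sum tests between depth
  layers (exact enumeration for small tie-free groups, tie-corrected normal
  approximation otherwise), Bonferroni-adjusted within each response
  variable; domain proportions over {Archaea, Bacteria, Viruses} and top-N
  species tables.
- **Functional profiles.** Per-layer GO term occurrence counts, a
  log10-scaled top-term matrix, and the sets of terms exclusive to a single
  layer.
- **A synthetic community generator** with known ground truth (planted
  richness gradient, domain-mix gradient, layer-exclusive GO terms), so the
  whole pipeline is testable end to end without any downloads.

## Worked example

```python
import depthdiv as dd

# default study conditions (8 stations x 3 layers x 3 replicates) at a
# reduced fixed read depth of 10,000 reads/sample
cfg = dd.scaled_config(dd.default_config(seed=1), 10_000)
profiles, metadata, truth = dd.simulate_profiles(cfg)

table = dd.diversity_table(profiles)
print(f"M (taxa across all samples) = {table.m_total}")

values = dict(zip(table.samples["sample_id"], table.samples["normalized_swi"]))
dendro = dd.upgma(dd.euclidean_distances({s: [v] for s, v in values.items()}))
mojena, groups = dd.mojena_cut(dendro, k=1.25)
print(f"Mojena cut: theta = {mojena.theta:.4f}, {mojena.n_groups} groups")

for r in dd.compare_layers(values, metadata):
    print(f"{r.group_a}-{r.group_b}: adjusted p = {r.p_adjusted:.3g} ({r.stars})")

ann = dd.simulate_annotations(cfg, truth)
report = dd.exclusive_terms(dd.term_frequencies(ann, metadata))
print("exclusive terms:", report.counts())
```

prints

```
M (taxa across all samples) = 530
Mojena cut: theta = 0.0434, 5 groups
SRF-DCM: adjusted p = 1 (ns)
SRF-MES: adjusted p = 1.18e-08 (****)
DCM-MES: adjusted p = 1.34e-08 (****)
exclusive terms: {'SRF': 24, 'DCM': 53, 'MES': 10}
```

The mesopelagic layer is planted 2.5× richer than the photic layers, and the
pipeline recovers it: MES diversity differs from both SRF and DCM at
Bonferroni-adjusted p ≪ 0.001 while SRF–DCM is non-significant; mean
normalised SWI is 0.512 (SRF), 0.515 (DCM) and 0.650 (MES). The planted
layer-exclusive GO term sets (24, 53 and 10 terms) are recovered exactly.

## Command line

```sh
depthdiv simulate --out data/ --seed 7           # synthetic dataset + ground truth
depthdiv diversity --profiles data/classifications --metadata data/metadata.tsv --out diversity.tsv
depthdiv cluster  --diversity diversity.tsv --k 1.25 --out groups.tsv --newick tree.nwk
depthdiv compare  --values diversity.tsv --column normalized_swi --metadata data/metadata.tsv --out tests.tsv
depthdiv functional --annotations data/annotations --metadata data/metadata.tsv --top 50 --out terms.tsv --exclusive exclusive.tsv
depthdiv run --config pipeline.yaml              # everything, from one YAML
```

`depthdiv run` writes `diversity.tsv`, `groups.tsv`, `tree.nwk`,
`domain_proportions.tsv`, `tests.tsv`, `terms.tsv`, `exclusive.tsv` and a
`manifest.json`; identical config and inputs give byte-identical products.

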