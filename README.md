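# seasonet

Seasonal functional dynamics of marine microeukaryote plankton from
metatranscriptomic count data.

`seasonet` is for ecologists and bioinformaticians who have a
post-assembly, post-annotation metatranscriptome — a transcript × sample
count matrix with taxonomic (lineage + percent identity), functional
(KEGG KO) and protein-family (PFAM) annotations, ERCC-style spike-ins and
sample processing metadata — and want the downstream seasonal analysis:

- **Quantification** — TPM (length-normalized, per-sample sum 10⁶),
  taxonomic relative-abundance fractions with pooling of groups below 2%
  into "rare", KO-level aggregation, and spike-in-calibrated absolute
  abundance in **transcripts per liter (TPL)** of filtered seawater.
- **Co-expression modules** — weighted-network modules of KO identifiers:
  unsigned adjacency `a_ij = |cor(x_i, x_j)|^β` with the soft threshold β
  chosen for approximate scale-free topology, topological-overlap
  dissimilarity, average-linkage clustering with a dynamic-style tree cut
  (minimum module size 70, deepSplit 4), eigengene merging at r > 0.6,
  module membership, and module–trait correlations with
  Benjamini–Hochberg q-values.
- **Pathway association** — one-sided Mann–Whitney U tests asking whether
  a pathway's KOs sit nearer the top of the module-membership ranking than
  expected by chance, BH-corrected; plus pathway expression totals split
  into annotated (>90% identity) and taxon-attributed parts.
- **Richness statistics** — functional richness (unique expressed KOs per
  sample) and active species richness (species bins at >90% identity with
  >100 supported transcripts in at least one sample), with one-way ANOVA,
  Kruskal–Wallis and Pearson correlation tests whose p-values come from
  the package's own incomplete-gamma/beta tail routines.
- **Trophic modes** — the species-bin phototroph/heterotroph protocol:
  PFAM expression profiles for species bins (>90% identity), eligibility
  gate at >800 non-zero PFAMs, zero imputation and MinMax scaling with a
  scaler fitted on labelled training profiles, a pluggable classifier
  (gradient-boosted trees by default), and monthly majority-vote
  consensus.
- **Synthetic communities** — a generator producing the whole
  post-annotation data bundle with *known* truth: circular-Gaussian bloom
  phenology per taxon, gamma-Poisson counts, ~1% spike-in share, planted
  KO modules driven by orthogonal latent seasonal signals, and planted
  trophic PFAM blocks — so every stage above can be tested for recovery.

## Worked example

```python
from seasonet.simulate import SimConfig, simulate_community
from seasonet.quantify import (compute_tpm, split_spikes, aggregate_ko,
                               tpl_table, relative_fractions)
from seasonet.network import fit_modules, NetConfig
from seasonet.richness import functional_richness, one_way_anova

ds = simulate_community(SimConfig(seed=1))           # 6 stations x 12 months
tpm = compute_tpm(ds.counts, ds.lengths)
bio, spikes = split_spikes(tpm, list(ds.spikes["spike_id"]))
ko = aggregate_ko(bio, ds.annotations)
print("KO matrix:", ko.shape)

frac = relative_fractions(bio, ds.annotations, rank="group",
                          by="month", metadata=ds.metadata)
print(frac.round(3).iloc[:, :3])

fr = functional_richness(ko)
months = [s.rsplit("_", 1)[1] for s in fr.index]
res = one_way_anova([g.tolist() for _, g in fr.groupby(months)])
print(f"ANOVA F({res.df[0]},{res.df[1]}) = {res.statistic:.3f}, P = {res.p:.3f}")

fit = fit_modules(ko, NetConfig(candidate_powers=(6,)))  # power from fit table
print("modules:", fit.labels[fit.labels > 0].nunique())
```

prints

```
KO matrix: (800, 72)
                2020-07  2020-08  2020-09
copepod           0.107    0.091    0.165
ctenophore        0.063    0.067    0.108
diatom            0.225    0.189    0.128
dinoflagellate    0.259    0.320    0.249
green_alga        0.229    0.137    0.117
haptophyte        0.117    0.196    0.233
ANOVA F(11,60) = 1.000, P = 0.457
modules: 6
```

The fraction table is the monthly community composition (columns sum
to 1 over annotated groups); functional richness does not differ between
months on this draw (P = 0.457), while module detection finds the five
planted seasonal modules plus the bloom-driven background cluster.
`tpl_table(ds.counts, ds.lengths, ds.spikes, ds.metadata)` converts the
same counts into transcripts per liter (mean positive TPL ≈ 2.5 × 10⁶
here) via the per-sample spike recovery factor
`k = Σ counts / Σ (molecules·length)` and the processing chain
library→extract→residue→liter.

A command-line interface mirrors the library:

```sh
seasonet simulate --config config.yaml --out data --seed 1
seasonet quantify --data data --out results
seasonet modules  --data data --out results
seasonet run-all  --out results --seed 1
```

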