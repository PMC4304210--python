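# enhdyn

Enhancer definition, combinatorial TF-binding classification and
post-stimulation class dynamics in myeloid antigen-presenting cells
(macrophages and dendritic cells), driven by a seeded synthetic-data
generator with recorded ground truth.

## The problem

Distal regulatory regions (enhancers) in myeloid cells can be defined
operationally from chromatin: high H3K4me1 without the promoter signature of
H3K4me3 plus transcription initiation, and distinct from Polycomb-repressed
regions carrying H3K27me3. Once defined, enhancers differ in which of six
*principal* transcription factors bind them before stimulation — PU.1,
C/EBPβ, ATF3, IRF4, JunB and CTCF — and these combinatorial binding classes
behave differently after LPS stimulation: classes exchange members over
time, binding by signal-dependent factors (NF-κB, STATs) concentrates on
highly bound classes, and enhancers switching into a class tend to lie near
pre-existing members of that class.

`enhdyn` implements this analysis pipeline end to end:

1. **Region discovery** — tags counted in 200-bp bins (ChIP reads shifted
   75 bp 3′-ward, TSS-seq per strand); bins with Poisson upper-tail
   p ≤ 10⁻⁶ over the genome-wide background rate λ = total tags / total
   bins; significant bins merged across features when separated by
   < 500 bp; each region centered on the ppm-weighted mean bin and given an
   oriented 21-bin × feature profile (4.2 kb).
2. **Chromatin states** — k-means (k = 4) over the profiles; centroids
   named *active promoter*, *enhancer*, *repressed 1/2* from their feature
   content; the enhancer state is carried forward.
3. **TF-binding classes** — per enhancer and TF, the highest peak score in
   the central 11 bins (±1.1 kb), capped at the binding threshold 26.9 and
   scaled to [0, 1]; k-means at 0 h with k chosen by the Gap statistic;
   classes named `H_i`/`M_i`/`L_i`/`C_i` by the number of TFs their centroid
   binds; later time points assigned to the nearest 0 h centroid
   (Euclidean), giving class transition tables.
4. **Expression** — RPKM, quantile normalization, ≥ 3-fold differential
   genes clustered into early/late/gradual induction and repression sets,
   plus a fixed-size no-change control set.
5. **Enrichment** — each enhancer assigned to its most proximal gene TSS;
   per (gene set, class), Z = (observed − mean) / sd over permutations of
   the class labels.
6. **Dynamics** — binding-fraction time courses conditioned on class
   transitions, and Welch t-tests on log₁₀ distances asking whether
   class-switching enhancers lie nearer pre-existing members of the target
   class than non-switching ones.

The synthetic generator (`enhdyn.simulate`) emulates the statistical
structure these steps assume — Poisson tag tracks with planted enriched
regions, TF peak tables with planted class structure, transitions and
spatial clustering, and expression matrices whose induced genes link to
planted highly bound enhancers — and records the ground truth needed to
score recovery.

## Worked example

```python
import pandas as pd
from enhdyn.simulate import SimulationConfig, simulate
from enhdyn.regions import discover_regions
from enhdyn.chromatin import cluster_chromatin_states, select_enhancers
from enhdyn.tfclasses import TFBindingClassifier, build_binding_vectors
from enhdyn.enrichment import assign_enhancer_to_gene, permutation_enrichment

cfg = SimulationConfig(seed=1, expression_link=1.0)
res = simulate(cfg)

table, profiles = discover_regions(res.tracks, cfg.chrom_lengths)
model, _ = cluster_chromatin_states(profiles)
enh = table.iloc[select_enhancers(table, model.state_labels_)].reset_index(drop=True)

v0, _ = build_binding_vectors(enh, res.peaks, 0.0)
clf = TFBindingClassifier(n_clusters=13, random_state=17).fit(v0)

labels = pd.Series(clf.predict_names(v0), index=enh["region_id"].to_numpy())
assignment = assign_enhancer_to_gene(enh, res.genome.genes)
gt = res.truth.gene_sets
induced = gt[gt["set_label"].str.endswith("induction")]["gene_id"]
print(permutation_enrichment(assignment, induced, labels, n_perm=100, seed=1))
```

On the default 2 × 5 Mb genome this detects all 440 planted regions,
labels 260 of them enhancers (plus 60 active promoters and 120 repressed
regions), and recovers the 13 planted binding classes. With full
enhancer–gene linkage the highly bound classes are enriched around induced
genes while the unbound class is depleted:

```
class  observed  expected_mean  expected_sd     z
  H_1        20          10.48         2.12  4.48
  H_2        20          10.81         2.13  4.31
  H_3        20          10.17         2.33  4.22
  L_4         2          10.61         2.07 -4.16
```

i.e. class `H_1` enhancers sit next to induced genes about twice as often
as label-shuffled expectation (Z ≈ 4.5), and enhancers bound by none of the
principal TFs (`L_4`) avoid them (Z ≈ −4.2).

The same steps are available as a CLI for file-based runs:

```sh
enhdyn simulate --out sim/ --seed 1
enhdyn call-regions --tracks sim/manifest.yaml --out regions/
enhdyn classify-chromatin --regions regions/regions.bed --profiles regions/profiles.tsv --out chrom/
enhdyn classify-tf --enhancers chrom/enhancers.bed --peaks sim/peaks.tsv --out tf/
enhdyn expression --counts sim/counts.tsv --lengths sim/gene_lengths.tsv --out expr/
enhdyn enrich --enhancers chrom/enhancers.bed --assignments tf/assignments.tsv \
  --genes-gtf sim/genes.gtf --gene-sets expr/gene_sets.tsv --out enrichment.tsv
enhdyn dynamics --enhancers chrom/enhancers.bed --assignments tf/assignments.tsv \
  --scores tf/scores.tsv --out dyn/
```

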