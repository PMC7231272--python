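# promotif

Promoter motif enrichment, co-expression clustering and cross-species motif
conservation — a self-contained regulatory-genomics pipeline with a
synthetic-data module that plants known ground truth for every stage.

The pipeline answers the kind of question raised by stress-inducible genes
such as the retrotransposon-derived *gag* homologues of *Drosophila*: which
transcription factors plausibly drive a gene's stress-induced expression?
It proceeds by (1) calling differentially expressed genes and partitioning a
co-expression network into clusters, (2) testing each cluster's promoters
for transcription-factor binding-site (TFBS) enrichment against a random
reference set, and (3) asking whether the implicated motifs sit at conserved
positions in the promoters of the gene's orthologs.

## The statistics at the core

Promoter windows (−1000..+100 bp around the TSS) are scanned on both strands
with TRANSFAC-format position weight matrices, scored as log2 odds with a
background-distributed pseudocount.  Score thresholds are calibrated to a
maximum site frequency of one site per 2000 bp on the reference set.  For a
matrix *M* and gene set *G*, with a = |{promoters of G with ≥1 site}| (b the
rest) and c, d likewise for the reference set:

* one-sided Fisher exact test on (a, b, c, d);
* one-sided binomial test of the collapsed target site count s_t over B_t bp
  against the reference rate λ = s_r / B_r:  p = P(X ≥ s_t), X ~ Bin(B_t, λ);
* **adjusted fold enrichment** — the lower 99% confidence bound of the odds
  ratio, AFE = exp(ln OR⁺ − z₀.₉₉₅ · SE), OR⁺ and SE = √(Σ 1/(cell+½))
  Haldane–Anscombe corrected, maximised over the admissible score-threshold
  grid;
* Benjamini–Hochberg FDR over the binomial p-values within each cluster,
  with the decision rule **AFE > 1 and FDR < 0.05**.

Co-expression graphs (|Spearman ρ| ≥ 0.7) are partitioned with a
from-scratch MCODE (k-core-based node weights, seeded BFS at node score
cutoff 0.2, haircut and fluff).  Conservation reports lift per-species motif
hits into alignment columns and merge windows across species.  qPCR tables
are analysed by 2^ΔCt against three reference genes with exact Mann–Whitney
contrasts.  Details, conventions and caveats: [docs/methods.md](docs/methods.md).

## Worked example

```python
import promotif as pm

# a planted enrichment study: 200 target promoters carry a 10-bp motif with
# probability 0.5; 5000 reference promoters with probability 0.02
panel = pm.studies.default_matrix_panel(n_matrices=5)
cfg = pm.SimConfig(seed=7, n_target_promoters=200, n_reference_promoters=5000,
                   promoter_length=1100, plant_probability=0.5)
targets, refs, log, _ = pm.simulate_enrichment_study(cfg, panel[0],
                                                     reference_plant_probability=0.02)
report = pm.enrich_report({"cluster2": targets.ids}, panel, targets, refs)
print(report[["matrix_id", "a", "c", "afe", "binom_p", "fdr", "significant"]]
      .round(3).to_string(index=False))
```

```
   matrix_id  a    c   afe  binom_p   fdr  significant
  planted_01 30   93 5.292    0.000 0.000         True
unplanted_00 99 2013 1.004    0.059 0.073        False
unplanted_01  2    9 1.051    0.051 0.073        False
unplanted_02 63 1371 0.820    0.075 0.075        False
unplanted_03 48  840 1.018    0.006 0.015         True
```

The planted matrix is recovered decisively: at its AFE-maximising threshold,
30 of 200 target promoters carry a site versus 93 of 5000 references, the
confidence-adjusted fold enrichment is 5.3 (>1) and the binomial FDR is
essentially 0.  The unplanted matrices hover at AFE ≈ 1 — and this seed also
shows the method's one caveat honestly: `unplanted_03` sneaks over both
gates (AFE 1.018, FDR 0.015).  Maximising the confidence-adjusted odds ratio
over the threshold grid is a selection step that makes such borderline false
calls somewhat more common than the nominal 5% (about 7% per unplanted
matrix at these study sizes); see the calibration caveat in
[docs/methods.md](docs/methods.md).

The same stages are exposed as a CLI for file-based use:

```bash
promotif simulate promoters --config sim.yaml --out study/
promotif extract --genome genome.fa --tss tss.tsv --out promoters.fa
promotif scan --matrices m.transfac --promoters promoters.fa --cap 2000 --out hits.tsv
promotif enrich --matrices m.transfac --promoters promoters.fa \
    --references refs.fa --clusters clusters.tsv --report enrichment.tsv
promotif cluster --expr expr.tsv --contrast stress:control --anchor Gagr --out complexes.tsv
promotif conserve --alignment orthologs.aln --matrices m.transfac --out report/
promotif qpcr --ct ct.tsv --refs alphaTub84D,RpL40,EloB --contrast stress:control --out mw.tsv
```

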