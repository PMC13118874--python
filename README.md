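# woundsig

Surgical wounding triggers a healing program — inflammation, coagulation,
angiogenesis, then adhesion, survival signalling and metabolic rewiring — that
can transiently favor the outgrowth of residual tumor after cytoreductive
surgery. `woundsig` implements a complete, testable pipeline for studying this
at the transcriptome level in a three-arm, multi-timepoint design (no
treatment **N**, anesthesia only **A**, anesthesia plus wounding **AW**,
sampled at baseline and at three post-intervention timepoints T1–T3):

1. **Normalization** — raw gene counts → TPM → per-sample upper-quartile
   scaling (TPM-UQ) → log2(x + 1).
2. **Differential expression** — per-timepoint Welch *t* contrasts of each arm
   against baseline; DEGs at |log2FC| ≥ 0.58 and raw *p* ≤ 0.05, a
   high-magnitude "Top-DEG" tier at |log2FC| ≥ 4 and *p* ≤ 0.01, Storey
   *q*-values reported alongside.
3. **Wound-signature extraction** — Venn exclusion
   WsDEG = DEG(AW) \ (DEG(N) ∪ DEG(A)), split into up/down query tag sets.
4. **Connectivity scoring** — the classic unweighted Kolmogorov–Smirnov
   enrichment statistic of each tag set within every perturbagen signature of
   an L1000-style z-score reference (GCT 1.3),

       a  = max_j ( j/t − V(j)/n ),   b = max_j ( V(j)/n − (j−1)/t ),
       ES = a  if a > b  else −b,
       score = (ES_up − ES_down)/2  if the two signs differ, else 0,

   so a negative score flags a compound predicted to *reverse* the wound
   state.
5. **Candidate prioritization** — per-perturbagen frequency in the top-K
   most-negative signatures, one-sided Fisher exact enrichment, the filters
   freq > 3 and *p* < 0.05, and MoA/clinical-phase annotation.
6. **Enrichment** — hypergeometric over-representation of WsDEG sets against
   GMT collections (count > 3, *p* < 0.01), BH *q*-values, and Cohen's-kappa
   single-linkage clustering (κ > 0.3) of redundant terms.

Because the real tumor RNA-seq data and the LINCS database are external, a
first-class synthetic-data module (`woundsig.synthetic_data`) generates the
whole study — negative-binomial counts for the 10-subgroup design with
planted progression / anesthesia / wound programs, an L1000-like reference
with planted reverser compounds, gene-set collections and tumor weights —
with ground-truth labels, so every stage's recovery is measurable.

## Worked example

```python
from woundsig import synthetic_data as syn, normalization
from woundsig import differential_expression as de
from woundsig.signatures import extract_wsdegs
from woundsig.connectivity import score_all
from woundsig.prioritization import rank_candidates

design = syn.SimDesign(n_genes=5000, seed=20260921)
experiment, truth = syn.simulate_counts(design)
expr = normalization.normalize(experiment)

degs = {iv: de.test_contrast(expr, de.ContrastSpec("T1", iv)) for iv in ("N", "A", "AW")}
ws = extract_wsdegs(degs["AW"], degs["N"], degs["A"])
print(ws.provenance)
```

prints (seed 20260921):

```
{'n_deg_aw': 563, 'n_excluded_overlap': 259, 'n_wsdeg': 304, 'n_up': 137,
 'n_down': 167, 'n_excluded_discordant_direction': 12, 'direction_aware': False}
```

i.e. 563 genes respond in the wounded arm at T1, 259 of them also move in the
no-treatment or anesthesia-only arm (tumor progression or anesthesia effects)
and are excluded, leaving a 304-gene wound-only signature (137 up, 167 down).
Scoring that signature against a synthetic 978-gene × 2000-signature
reference with five planted reverser compounds:

```python
query = ws.capped(150)
reference, ref_truth = syn.simulate_reference(
    978, 200, 10, 5, query, seed=3, loading=2.0)
table = rank_candidates(score_all(query, reference), reference.pert_meta, k=100)
print(table[table.passed_filters][["freq_topk", "fisher_p", "rank"]])
```

recovers all five planted compounds at ranks 1–5, each with all 10 of its
signatures inside the top-100 negative set (Fisher *p* ≈ 6 × 10⁻¹⁴).

## The analysis

`analysis/01_simulate_data.py` … `06_connectivity_repurposing.py` run the full
study end to end (simulation → tumor burden → DEGs → wound signatures →
enrichment → repurposing), printing what each stage found and writing summary
tables under `results/`; bulky intermediates go to `scratch/`. Run them in
order from the repository root.

A YAML-configured one-shot run of the same chain is available as
`woundsig run --config <yaml>`, and each stage separately as `woundsig
simulate|normalize|deg|signature|connect|prioritize|enrich`.

## Scaling to real data

The pipeline reads a counts TSV (gene id, `gene_length`, one column per
sample) with a sample-metadata TSV, a GCT 1.3 reference with signature and
perturbagen annotation TSVs, and GMT gene-set collections. For a LINCS-scale
reference raise `top_k` back to its default of 1000 (the analysis scripts use
K = 100, scaled to their 2000-signature reference) and supply an ortholog map
(`connectivity.score_all(..., ortholog_map=...)`) if query gene symbols are
murine; by default symbols are matched case-insensitively.
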