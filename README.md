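# bdcnv

Multi-caller germline CNV consensus and cohort analysis for pediatric
birth-defect/cancer studies.

## The problem

Children with serious birth defects (BD) carry an elevated risk of
developing malignant tumors, and germline copy number variants (CNVs) from
blood-derived whole-genome sequencing are a candidate mechanism. Individual
CNV callers are noisy, so a standard design is to call each genome with
several independent tools (MANTA, CNVnator, DELLY, LUMPY), keep only events
the callers agree on, and then ask which impacted genes occur exclusively
in the affected cohort (BD children with cancer) and never in BD-only
children or healthy family controls.

`bdcnv` implements that analysis as a tested, reusable pipeline:

1. **Consensus merging** — per sample, calls of the same type whose
   breakpoints agree within *d*<sub>max</sub> = 1 kb are clustered
   (connected components of the pairwise-compatibility graph) and collapsed
   to their median coordinates. Events are kept when supported by ≥ 3 of
   the 4 callers, ≥ 10 kb long, every MANTA member has QUAL ≥ 100 and every
   DELLY member QUAL ≥ 1000, and the cohort-wide carrier frequency of the
   locus is < 5%.
2. **Gene impact** — each retained CNV × gene overlap is classified as
   full or partial deletion/duplication (full ⇔ the gene interval is
   contained in the CNV interval), for protein-coding genes and ncRNAs.
3. **Case-exclusive genes** — genes with deletion (or duplication) impacts
   in ≥ 1 case and in no BD-only or control sample, with per-gene
   recurrence counts, and base-pair comparison of the sub-loci of genes
   partially hit in both case cohorts.
4. **lncRNA targets** — impacted lncRNAs looked up in a curated
   regulator→target table (LncTarD-style schema; small fixtures ship with
   the package, a full database download drops in).
5. **Enrichment** — over-representation analysis: one-sided
   hypergeometric tail *P*(X ≥ k) for the overlap k between the selected
   genes (n of N in the universe) and each gene set (K members), with
   Benjamini–Hochberg FDR within each collection.
6. **Phenotype clustering** — patient × enriched-term incidence matrices
   per CNV class, aggregated over seven ICD-derived pediatric cancer
   subtype groups (brain/nervous, bone and connective/soft tissue,
   respiratory/digestive, endocrine/gland, kidney, eye, other).

Because real cohorts of this kind are access-controlled, the package
includes a first-class synthetic-data generator (`bdcnv.simulate`) that
emits four-caller VCF call sets over the three cohorts with breakpoint
jitter, caller-specific quality scales, false positives, a polymorphic
common CNV, and planted case-exclusive gene deletions drawn from a planted
pathway — together with the ground truth needed to score recovery.

## Worked example

```python
from bdcnv import pipeline
from bdcnv.simulate import SimConfig, simulate_cohort, score_recovery

sim = simulate_cohort(SimConfig(seed=1))     # 60 case / 80 BD-only / 40 control
res = pipeline.analyze(sim.samples, sim.gene_models,
                       sim.calls_by_sample, sim.collections)
score = score_recovery(res.consensus, sim.truth,
                       exclusive_reported=[r.gene_id for r in res.exclusive_del],
                       enrichment_results=res.enrichment_del)
print(score.to_dict())
```

prints

```
{'recall': 0.9538, 'precision': 1.0, 'n_truth': 1581, 'n_consensus': 1508,
 'exclusive_recovery': 1.0, 'n_exclusive_reported': 90,
 'planted_term_rank': 1, 'common_cnv_retained': 0}
```

Reading: 95.4% of the 1581 true rare CNVs survive four noisy callers and
the full filter chain (the closed-form expectation from per-caller
sensitivity 0.92 and the quality floors is 95.4%), every retained event is
real, all 12 planted case-exclusive genes are recovered, the planted
pathway ranks first by FDR among 30 tested terms, and the 10%-carrier
common CNV was removed from every sample by the frequency filter.

The same pipeline runs from files via the `bdcnv` CLI
(`simulate`, `merge`, `impact`, `exclusive`, `targets`, `enrich`,
`run-all`, `score` subcommands), writing TSV/JSON stage outputs and a
manifest with row counts and a config hash.

```bash
bdcnv simulate --outdir sim --seed 1
bdcnv run-all --vcf-dir sim/vcfs --genes sim/genes.bed --cohort sim/cohort.tsv \
              --gmt-dir sim/gmt --outdir sim/out
```

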