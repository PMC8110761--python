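# hybridexpr

Analysis toolkit for parent / reciprocal-hybrid RNA-seq count experiments:

* **Differential expression** — negative-binomial Wald test with
  median-of-ratios size factors, trend-shrunk method-of-moments
  dispersion, Benjamini–Hochberg FDR and a twofold / padj < 0.01 call
  rule.
* **Inheritance-mode classification** — each gene's three pairwise calls
  (hybrid vs each parent, parent vs parent) map onto conserved /
  additive / P1-dominant / P2-dominant / overdominant / underdominant
  (residual patterns are reported as *ambiguous*), with a chi-square
  comparison of reciprocal-cross category profiles.
* **Transgressive sets & bias** — genes over/underexpressed versus both
  parents, a Yates-corrected proportion test for over/under bias, and
  Venn-region counts for shared genes across crosses.
* **Enrichment** — ortholog-mediated hypergeometric term
  over-representation with BH correction.
* **Synthetic data** — a seeded generator producing counts, sample
  design and a ground-truth table for all six inheritance modes, so the
  whole stack is testable offline at desk scale.

## CLI

All tables are TSV; configs are YAML. Subcommands:

```sh
hybridexpr simulate --n-genes 2000 --n-replicates 3 --seed 1 --outdir sim/
hybridexpr filter   --counts sim/counts.tsv --design sim/design.tsv --out filtered.tsv
hybridexpr de       --counts filtered.tsv --design sim/design.tsv \
                    --num H_fwd:testis --den P1:testis --out de_hp1.tsv
hybridexpr inherit  --de-hp1 de_hp1.tsv --de-hp2 de_hp2.tsv --de-p1p2 de_pp.tsv \
                    --out-table inheritance.tsv --out-profile profile.tsv
hybridexpr sets     --de-hp1 de_hp1.tsv --de-hp2 de_hp2.tsv \
                    --out-over over.tsv --out-under under.tsv
hybridexpr enrich   --study over.tsv --background expressed.tsv \
                    --orthologs orth.tsv --terms terms.tsv --out enrich.tsv
hybridexpr run      --config run.yaml [--plot]
```

`run` executes the whole pipeline (filter → normalize → three DE
contrasts per hybrid trio → inheritance classification → transgressive
sets + bias test → reciprocal-profile chi-square → shared sets →
optional enrichment) per tissue and writes a `run_log.json` manifest
with gene counts at every step. A minimal `run.yaml`:

```yaml
counts: sim/counts.tsv
design: sim/design.tsv
outdir: results/run
alpha: 0.01
lfc_threshold: 1.0
min_reads: 10
```

The design TSV has columns `sample_id`, `line` (one of `P1`, `P2`,
`H_fwd`, `H_rev`), `tissue`, `replicate`.

## Library use

```python
import hybridexpr as hx

cfg = hx.SimConfig(n_genes=2000, n_replicates=3, seed=1)
matrix, design, truth = hx.simulate_experiment(cfg)
filtered, removed = hx.filter_low_counts(matrix, design)
sf = hx.estimate_size_factors(filtered)
disp = hx.estimate_dispersion(filtered, sf, design)
de = hx.call_deg(hx.nb_wald_test(filtered, sf, disp, design,
                 hx.Contrast(("H_fwd", "testis"), ("P1", "testis"))))
```
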