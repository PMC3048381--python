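# gssa

Gene-Set Selection Analysis: a segmentation test that detects functional
modules (GO/KEGG-style gene sets) whose genes are significantly skewed toward
high or low values in genome-wide rankings of evolutionary rates (dS, dN,
ω = dN/dS, and Δω = ω − ω_ancestral).

For one ranked gene list the test:

1. ranks all genes of a genome by one evolutionary variable (highest first);
2. assigns functional terms to the ranked genes (with optional DAG
   propagation to ancestor terms, level windows, and a 15-gene minimum);
3. places 30 evenly spaced partitions along the list;
4. runs a two-tailed Fisher's exact test per (term, partition), comparing the
   upper side A against the lower side B;
5. corrects the joint terms × partitions family with Benjamini–Hochberg and
   calls each term SH (significantly high), SL (significantly low) or NS,
   at 5% and 0.1% FDR tiers.

The package also ships the randomization-based false-positive calibration
(permute the gene↔annotation assignment, rerun the full test, report
false-positive proportions by term size) and a synthetic-data generator with
planted rank-shifted modules for power testing.

## CLI

```bash
# generate a synthetic genome with planted modules
gssa simulate --n-genes 5000 --plant SH:100:2.0 --plant SL:50:1.5 --seed 7 \
     --out-rates rates.tsv --out-sets sets.gmt --out-truth truth.tsv

# run the full pipeline (defaults: 30 partitions, 15-gene minimum, 5%/0.1% FDR)
gssa run --rates rates.tsv --sets sets.gmt --variable omega --out results.tsv
# with DAG propagation and a GO-level window:
gssa run --rates rates.tsv --sets sets.gmt --edges dag.tsv --level-window 2:8 \
     --variable delta_omega --out results.tsv

# false-positive calibration under randomized annotation
gssa calibrate --rates rates.tsv --sets sets.gmt --variable omega \
     --replicates 200 --seed 42 --out calib.tsv

# combine several runs into a terms × runs verdict matrix (SH**, SH*, SL**, SL*, NS)
gssa summarize results_omega.tsv results_dN.tsv --out matrix.tsv
```

Input formats: rate tables are TSV with columns `gene_id, branch_id, dS, dN`
(optional `omega`, `omega_ancestral`, `aln_length_bp`; ω and Δω are derived
when absent; `NA`/empty are missing). Gene sets are GMT or a two-column
gene/term TSV; term DAGs are two-column child/parent TSVs.

## Layout

- `src/gssa/rates.py` — rate-table I/O, Δω, saturation/length filters, ranking
- `src/gssa/annotation.py` — GMT/table I/O, DAG propagation, levels, term filters
- `src/gssa/core.py` — partitions, two-tailed Fisher, BH, SH/SL/NS calls, PSG t-test
- `src/gssa/calibration.py` — randomized-assignment false-positive scan
- `src/gssa/synthetic.py` — synthetic rate tables and planted modules
- `src/gssa/cli.py` — `gssa run | calibrate | simulate | summarize`
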