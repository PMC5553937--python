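# tcrnet

Similarity-network analysis of T-cell receptor (TCRβ) repertoires.

`tcrnet` builds **Levenshtein-distance-1 networks** over CDR3 amino-acid
sequences and provides the surrounding analysis toolkit:

- **repertoires** — read/write clonotype tables (plain TSV or AIRR
  Rearrangement TSV), aggregate rows to AA-level clonotypes, select
  deterministic top-N and seeded random subsets.
- **network** — distance-1 similarity graphs (deletion-variant neighbor
  index, exact post-check), connected-component clusters (≥ 2 nodes),
  degree, betweenness, per-cluster dominant V/J genes, GraphML/SIF export
  with a node-attribute CSV.
- **sharing** — sharing levels against reference cohorts, public/private/
  relatively-private classification, cross-species sharing curves,
  cross-species (CS-) public sets, cumulative frequencies,
  degree-vs-sharing correlations.
- **stats** — Gini inequality coefficient, convergent recombination
  (distinct nucleotide variants per AA clonotype by sharing level),
  subsampling connectivity curves, Fisher exact and Wilcoxon
  signed-rank tests.
- **annotations** — link externally annotated CDR3 sequences to a network
  (identical node or one edit step away) and test self-related category
  enrichment among clustered sequences.
- **simulate** — a V(D)J rearrangement simulator (weighted segment choice,
  truncated-geometric trimming/insertion, productive rejection sampling,
  power-law clone sizes) that generates single repertoires, cohorts, and
  two-species cohorts with homologous J segments; includes exhaustive
  enumeration of toy configurations and an oligoclonal-expansion
  perturbation model.
- **pipeline / cli** — figure-level runners producing tidy CSV tables.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including the
synthetic-cohort emergent-structure battery (several minutes of runtime).
The reference-cohort reproduction tests need the external sequencing
datasets; set `TCRNET_DATA_DIR` to a directory containing `mouse_cd4/`
(12 TSVs), `mouse_ref/` (28 TSVs) and `human_young/` (11 TSVs) to enable
them — they are skipped otherwise.

## Command line

```bash
# distance-1 network from the 1000 most frequent clonotypes
tcrnet build-net --input mouse_00.tsv --select top:1000 \
    --reference ref_dir/ --export graphml --out net

# sharing table against one or two reference cohorts
tcrnet sharing --query mouse_00.tsv --reference mouse_ref/ \
    --reference2 human_young/ --out sharing.tsv

# statistics
tcrnet stats gini --input mouse_00.tsv --top 1000
tcrnet stats convergence --input mouse_00.tsv --reference mouse_ref/ --out conv.csv
tcrnet stats subsample --input mouse_00.tsv --sizes 100,500,1000 --out curve.csv
tcrnet stats fisher 51 12 34 27

# annotation linkage + enrichment
tcrnet annotate --input mouse_00.tsv --select top:1000 \
    --annotations annotations.tsv --out linkage.tsv

# synthetic cohorts
tcrnet simulate --species mouse --individuals 28 --size 30000 --seed 1 --out sim/

# figure-level tables
tcrnet fig1 --cohort cd4_dir/ --reference ref_dir/ --out out1/
tcrnet fig2 --mouse mouse_ref/ --human human_young/ --out out2/
tcrnet fig5 --cohort baseline base_dir/ --cohort immunized imm_dir/ \
    --reference ref_dir/ --out out5/
```

Input TSV columns: `cdr3_aa`, `count`, `v_gene`, `j_gene`, optional
`cdr3_nt`; or AIRR fields `junction_aa`, `duplicate_count`, `v_call`,
`j_call`, optional `junction`.

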