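# drsn

Construction and analysis of bipartite **dr**ug–metabolic **s**ubpathway
**n**etworks from drug perturbation expression profiles and metabolic
pathway graphs.

The pipeline:

1. **Subpathway mining** — local pathway regions are mined as maximal node
   sets whose pairwise graph distance is at most *k* (the maximal cliques of
   the distance-*k* power graph), default *k* = 3.
2. **DEG calling** — per paired treatment/control instance, genes with
   |log2 fold change| > 1 are called differentially expressed; per-drug
   affected-gene sets are unions over instances.
3. **Enrichment network** — each drug's gene set is tested against each
   subpathway with an upper-tail hypergeometric test against the
   pathway-annotated gene background; pairs with p < 0.01 become edges of a
   bipartite drug–subpathway network. Descriptive statistics, log-log
   power-law degree fits, and degree-preserving drug–gene shuffle nulls are
   provided.
4. **Drug-pair pharmacology** — connected drug pairs (sharing ≥ 1
   subpathway) are tested for shared indications (permutation test with
   strict exceedance counting), shared side-effect counts vs the all-pairs
   background (one-sided rank-sum), and the shared-subpathways vs
   shared-side-effects trend (OLS on binned means).
5. **Drug–disease association** — fold enrichment ratios (FER = observed /
   expected shared subpathways) are aggregated into drug-class ×
   disease-class association scores; pair overlaps are tested
   hypergeometrically against the mined-subpathway population.
6. **Tissue specificity** — network subpathways are split into therapeutic
   vs non-therapeutic (linked drug's own targets among its affected genes in
   the subpathway), with TEG/HKG composition ratios and tissue-homogeneity
   (TH) coefficients per subpathway.
7. **Synthetic data** — a fully seeded generator produces every input with
   controllable planted structure (perturbed subpathways, side-effect
   sharing on co-linked drugs, class-aligned disease subpathway blocks,
   tissue labels), so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic input directory and run the full pipeline
drsn all --in simdir --simulate --seed 1 --k 3 --alpha 0.01 --out rundir

# or stage by stage
drsn simulate --seed 1 --out simdir
drsn mine    --in simdir --k 3 --min-size 2 --out rundir/catalog.tsv
drsn degs    --in simdir --log2-threshold 1 --out rundir/drug_genes.tsv
drsn network --in simdir --degs rundir/drug_genes.tsv --catalog rundir/catalog.tsv \
             --alpha 0.01 --n-random 1000 --seed 1 --out rundir/network.tsv
drsn pairs   --network rundir/network.tsv --associations simdir/associations \
             --n-perm 1000 --seed 1 --out rundir/pairs.tsv
drsn disease --network rundir/network.tsv --associations simdir/associations \
             --out rundir/association_scores.tsv
drsn tissue  --network rundir/network.tsv --degs rundir/drug_genes.tsv \
             --catalog rundir/catalog.tsv --associations simdir/associations \
             --out rundir/tissue_profiles.tsv

# descriptive statistics of any drug/subpathway edge TSV
drsn validate-s2 --edges data/dataset_s2.tsv
```

All stages are deterministic under `--seed`; `drsn all` writes a
`provenance.json` with the exact configuration used.

## Input formats

All plain text; see `src/drsn/pathway_io.py` docstrings for the full
dialects:

- pathway edgelist TSV (`#id<TAB>name` header, `NODE`/`EDGE` rows) or a
  KGML-subset XML (`entry` of type enzyme/gene + `relation`/`reaction`
  connectivity, collapsed to undirected edges);
- expression matrix TSV (genes × samples) plus an instance annotation TSV
  pairing treatment and control columns per drug;
- two-column association TSVs (drug class/indication/side
  effects/targets, disease class/subpathways) and a three-column tissue
  label file (gene, HKG|TEG, semicolon tissue list).

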