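# indolepath

Genome-to-metabolite inference for the microbial tryptophan indole-derivative
pathway, aimed at comparative-genomics studies of lactic acid bacteria (LAB)
and similar strain cohorts.

Gut microbes convert tryptophan (Trp) into indole derivatives — indole-3-pyruvic
acid (IPYA), indole-3-lactic acid (ILA), 3-indoleacrylic acid (IA),
indole-3-propionic acid (IPA), tryptamine (TA), indole-3-acetamide (IAM),
indole-3-acetaldehyde (IAAld), indole-3-acetic acid (IAA) and 3-indolealdehyde
(IAld) — several of which are immunomodulatory AhR ligands.  Whether a given
strain can produce a given derivative is largely determined by which pathway
enzymes its genome encodes.  `indolepath` turns that observation into a tested
pipeline:

1. **Homology search** — every protein of a strain proteome is aligned
   (affine-gap Smith–Waterman, BLOSUM62 11/1, Karlin–Altschul E-values)
   against a reference database of the 14 pathway enzyme families
   (ArAT, TDC, TMO, amiE, fldH, LDH, HdhD, fldA, fldBC, fldI, acdA, ALD,
   IPD, PPD).  A hit counts iff identity ≥ 30 %, E ≤ 10⁻³ and both query and
   subject coverage ≥ 70 %.  Externally produced 12-column tabular searches
   (BLAST/DIAMOND `outfmt 6`) can be imported and re-filtered identically.
2. **Pathway-completeness prediction** — a strain is predicted to produce a
   metabolite iff some directed path from Trp to it has every reaction
   requirement satisfied, where a requirement is a disjunction of enzyme
   conjunctions (e.g. IPYA→ILA needs fldH *or* LDH; ILA→IA needs fldA *and*
   fldBC *and* fldI).  The IAA→IAld enzyme is unknown, so IAld is never
   predicted.
3. **Species summary** — per species, the percentage of strains predicted to
   produce each metabolite (one-decimal, half-away-from-zero rounding).
4. **Genotype–phenotype concordance** — concentrations (ng/mL) become
   presence/absence phenotypes via a detection threshold; IPYA presence is
   inferred from ILA (its only downstream product); each strain × metabolite
   cell is classed GE/GA × PE/PA and accuracy = %(GE_PE + GA_PA).
5. **Association statistics** — tie-corrected Spearman ρ between gene counts
   and concentrations with Benjamini–Hochberg FDR across all enzyme ×
   metabolite pairs (reported iff |ρ| > 0.3 and q < α), plus exact/asymptotic
   Mann–Whitney U comparisons between isolation sources.
6. **Homolog phylogenetics** — pairwise global-identity distances,
   neighbor-joining trees, and detection of species-exclusive clades
   (divergent same-species homolog types).

A seeded synthetic-data generator produces proteomes with planted, diverged
enzyme homologs among random decoys, and concentration tables with
species-level lognormal structure, false negatives and genotype-discordant
injections — so the whole pipeline runs and is tested without any downloads.

## Worked example

Simulate a tiny two-species cohort and run the pipeline:

```python
from indolepath import RunConfig, run_pipeline
from indolepath.synthetic import (CohortSpec, SpeciesSpec, generate_cohort,
                                  synthetic_reference_db)

refdb = synthetic_reference_db()
spec = CohortSpec(species=(
    SpeciesSpec("L. curvatus", 4, ("amiE", "ALD")),
    SpeciesSpec("L. acidophilus", 8, ("ArAT", "LDH", "amiE", "ALD"), {"TMO": 1}),
), seed=1, decoys_per_proteome=5)
cohort = generate_cohort(spec, refdb)
res = run_pipeline(cohort.proteomes, refdb, cohort.species_map, config=RunConfig())
print(res.summary.formatted())
```

prints

```
                n_strains IPYA  ILA IA IPA   IAM TA IAAld   IAA
species
L. acidophilus          8  100  100  0   0  12.5  0     0  12.5
L. curvatus             4    0    0  0   0     0  0     0     0
```

Reading the rows: *L. curvatus* strains carry only amidase and aldehyde
dehydrogenase — no first-step enzyme (ArAT/TDC/TMO) — so nothing downstream of
Trp is predicted.  All *L. acidophilus* strains carry ArAT and LDH, hence
IPYA and ILA at 100 %; exactly one of the eight also carries TMO, so IAM and
(via amidase) IAA read 12.5 %.  Columns IA/IPA stay 0 because no strain has
the fldA/fldBC/fldI cluster, and TA stays 0 because none encodes TDC.

The same stages are available from the shell:

```sh
indolepath simulate --config default --seed 1 --out sim/
indolepath run --proteomes sim/proteomes --metadata sim/metadata.tsv \
    --concentrations sim/concentrations.tsv \
    --reference sim/reference.fasta --reference-map sim/reference_map.tsv \
    --out run/
```

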