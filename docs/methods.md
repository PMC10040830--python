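# Methods

## The metabolic model

The package models the microbial branch of tryptophan catabolism as a fixed
directed acyclic network of ten metabolites and ten reactions:

| reaction | requirement |
|---|---|
| Trp → IPYA | ArAT |
| Trp → TA | TDC |
| Trp → IAM | TMO |
| IPYA → ILA | fldH **or** LDH |
| ILA → IA | fldA **and** fldBC **and** fldI |
| IA → IPA | acdA |
| IPYA → IAAld | IPD **or** PPD |
| IAAld → IAA | ALD |
| IAM → IAA | amiE |
| IAA → IAld | unknown (never satisfiable) |

A reaction requirement is a disjunction of conjunctions of enzyme families.
The prediction rule — a strain produces a metabolite iff some Trp-path has
every requirement satisfied by the strain's detected enzyme set — is
implemented as fixed-point reachability and verified exhaustively against an
independent path-enumeration oracle over all 2¹⁴ subsets of the registry.
Satisfaction is monotone in the enzyme set, which gives the chain invariants
(IPA ⇒ IA ⇒ ILA ⇒ IPYA) tested as properties.  Because the IAA→IAld enzyme
is unidentified, IAld is excluded from the predictable set and never scored.

Two modelling conventions are worth making explicit.  The α and β subunits
of the phenyllactoyl-CoA dehydratase are treated as a single family (fldBC)
with its own references, since the pathway needs both together and curated
sets list them as a unit.  D-2-hydroxyacid dehydrogenase (HdhD) has its own
registry entry and references but its hits are folded into fldH by default
(`hdhd_as_fldh=True`): it shares fldH's EC class and acts as an indolelactate
dehydrogenase; the flag exists because the identification is inferential.

## Homology search

Every proteome × reference pair is aligned with affine-gap Smith–Waterman
(Gotoh) via Bio.Align's C kernel; a gap of length k costs open + k·extend.
Defaults: BLOSUM62, open 11, extend 1.  E-values come from the
Karlin–Altschul formula E = K·m·n·exp(−λS) with the standard published gapped
parameters for this scheme (λ = 0.267, K = 0.041); bit score
S′ = (λS − ln K)/ln 2.  These are configuration values, not constants baked
into the algorithm.

Filter semantics (all inclusive): identity ≥ 30 %, E ≤ 10⁻³, query cover
≥ 70 %, subject cover ≥ 70 %.  Identity is counted over alignment columns
including gap columns (the common BLAST `pident` convention); coverage is
(aligned span)/(sequence length) on each side, spans taken from the optimal
local alignment.  A score-only pass screens each pair first and the full
traceback is computed only when the score alone could clear the E-value
threshold; this is an exact optimization, not a heuristic.  Per enzyme
family, the count is the number of *distinct* strain proteins with ≥ 1
passing hit, and the best hit is chosen by bit score, then identity, then
lexicographic subject id (the best-hit criterion had to be fixed somewhere;
bitscore-first matches common search-tool practice).  One strain protein may
count toward several families unless `unique_best_family` is set.

Seed heuristics and composition-based score adjustment of production search
tools are deliberately not reproduced: proteomes at the scale this package
targets are searched exhaustively, and the tests compare the aligner against
a brute-force dynamic-programming oracle rather than against any external
tool.  External searches in the 12-column tabular dialect can be imported;
rows are re-filtered under the same thresholds with coverage recomputed from
the 1-based inclusive coordinates, and a round-trip test guarantees the
import path agrees with the built-in aligner on its own exports.

## Concordance scoring

Phenotype presence is concentration > threshold, with threshold defaulting to
0 ng/mL — any positive quantified amount counts, since quantification limits
vary by instrument and no single limit is canonical.  NaN cells and
unmeasured metabolites are excluded from all denominators rather than
imputed (IAAld is typically unmeasured; IAld is outside the predictable
set).  IPYA is never observed directly — it is consumed as fast as it forms —
so its phenotype is set equal to ILA's (measured-by-inference); the
`include_ipya_in_accuracy` flag (default on) controls whether those inferred
cells enter the accuracy figures, because either convention is defensible.

Accuracy is reported two ways: the unweighted mean of per-metabolite
accuracies (headline) and the pooled accuracy over all evaluated cells.  The
pooled figure equals the evaluated-cell-count-weighted mean of per-metabolite
accuracies, which is tested as an invariant.

## Statistics

Spearman ρ uses mid-ranks for ties and the t approximation
t = ρ√((n−2)/(1−ρ²)) for p; for n ≤ 9 an exact permutation p is computed by
full enumeration instead.  BH-FDR is the literal step-up
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j applied across the full enzyme × metabolite family
in one run.  An association is *reported* iff |ρ| > 0.3 (strict) and
q < α (default α = 0.05, configurable — the screening convention treats the
correlation magnitude and the FDR as separate gates, and the magnitude gate
applies to both signs).  All-zero gene-count columns are routine, so constant
columns yield ρ = NaN / never-reported rather than an error in the family
scan, while the scalar `spearman` raises on constant input.

Mann–Whitney U reports U = min(U_A, U_B), exact by enumeration of all
C(n, n_A) assignments when n ≤ 12 and tie-free (two-sided p is the
probability of a min-U at least as extreme), otherwise the normal
approximation with tie correction and 0.5 continuity correction.  Exact
results are tested against full enumeration for every split with pooled
n ≤ 8; scipy's implementations serve as independent cross-checks only.

## Phylogenetics of enzyme homologs

Distances are d = 1 − identity/100 from pairwise global (Needleman–Wunsch)
alignments — a deliberate simplification that trades multiple alignment and
maximum-likelihood inference for a fully deterministic, dependency-free
construction whose conclusions (cluster membership) are what downstream
analysis consumes.  Neighbor joining follows Saitou–Nei with the Q-criterion;
ties break toward the lowest index pair; a negative branch length is clamped
to zero with the deficit moved to its sibling so the joined pair's total
length is preserved.  On additive matrices the generating topology is
recovered with Robinson–Foulds distance 0 and path-length error < 10⁻⁹
(tested on random 5–8 leaf trees; scikit-bio's NJ is the independent
topology oracle).  No bootstrap support is computed; reports say "no
support".

"Independently clustered" homolog types are operationalized as
species-exclusive clades: both sides of every internal edge are enumerated,
and maximal sides (≥ 2 leaves) whose leaves all carry one species label are
reported.  Note one structural consequence, visible in the test fixtures: if
all other-species leaves form a single clade, the complementary side (all
same-species leaves) is itself exclusive and maximality merges the types; the
pattern of separate divergent types is only detectable when other-species
lineages interleave them, which is also what real trees show.  Externally
built newick trees can be fed to the detector directly.

## Synthetic data

The generator emulates the cohort structure the analysis assumes.  Proteomes:
planted homologs are produced by randomly substituting residues of a
reference (optionally with indels) until global identity lands within ±2
points of the target — targets of 30–90 % span the divergence regime of real
pathway homologs (~35–45 % for distant indolelactate dehydrogenases) — mixed
with i.i.d. decoy proteins drawn from Robinson–Robinson background
frequencies (default 20 decoys of length 150–450 per strain).  Random decoys
fail the joint identity+coverage filter (their high-scoring local alignments
are short), which the suite verifies.

The default cohort configuration has 13 species with sizes
(8, 14, 4, 11, 8, 9, 15, 10, 10, 30, 9, 12, 8) — 148 strains — and per-species
enzyme profiles chosen to reproduce the reference species-level prediction
table the pipeline is validated against (e.g. a 4-strain species with no
first-step enzyme predicting nothing; a 30-strain species with 2/30 TMO
carriage giving 6.7 % IAM).  Planted identity defaults to 60 %, safely inside
the detection band at the default thresholds.

Concentrations: genotype-positive cells draw lognormal values with
species-level means (CV 0.8) and are zeroed with probability
`false_negative_rate` (default 0); genotype-negative cells are 0 except for
injected (species, metabolite) anomalies, which emulate observed
phenotype-without-genotype cases — `paper_like_metabolomics_spec()` injects
tryptamine into every *L. helveticus* strain and indoleacrylate into every
*L. mucosae* strain and gives *L. salivarius* a ~20-fold elevated ILA mean.
Values below the detection limit (default 0) are floored to 0.  All
randomness flows from integer seeds through `numpy.random.Generator`
streams keyed by species and strain index, so outputs are order-independent
and reproducible across platforms.

The bundled reference enzyme database is itself synthetic — random proteins
of family-typical lengths generated from a fixed internal seed, one per
family plus diverged second references for ArAT and LDH.  No real sequences
ship with the package; `load_reference_db` accepts any curated FASTA +
mapping table for real analyses.

What passing tests therefore show: the pipeline's logic — thresholding,
completeness prediction, summarization arithmetic, concordance accounting,
statistical calibration — is correct on data with the assumed structure.
What they do not show: recovery rates on real proteomes, where homologs have
domain structure, compositional bias and paralogs that i.i.d. decoys and
uniform substitution do not imitate, and where the reference set's curation
dominates sensitivity.

## Numerical choices and problem sizes

Percentages are rounded half away from zero to one decimal, formatted with a
trailing ".0" dropped ("100", "6.7").  Threshold comparisons are inclusive.
Alignment traceback ties follow Bio.Align's deterministic ordering; scores
are tie-free by construction of the DP, and all score-level tests are exact.
The suites run at deliberately desk-scale sizes chosen as realistic for the
cohort being emulated: the recovery suite uses the full 148-strain default
cohort; the worked-example suite uses the five documented species
configurations (66 strains); null calibration uses 1000 replicates at
n = 148; alignment oracle checks use lengths ≤ 8 over a reduced alphabet
where exhaustive DP is feasible.

## Known limitations

* E-values use fixed gapped Karlin–Altschul parameters rather than
  per-composition estimation, so they differ from production BLAST/DIAMOND
  values; the filter semantics, not the exact E-values, are the contract.
* Identity-based NJ is not a substitute for ML phylogenetics when branch
  support or substitution-model effects matter.
* The concordance module scores presence/absence only; concentrations are
  never predicted.
* Kynurenine and serotonin branches of tryptophan catabolism (host pathways)
  are out of scope, as are genome assembly, gene calling and reference
  retrieval.
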