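# Methods

This note records the models, decision rules and numerical choices behind
agpkit, and what its synthetic-data tests do and do not demonstrate.

## Composition screen and classification

AGP backbones are low-complexity and mutually divergent, so identification
uses composition bias rather than homology. For each protein the PAST
fraction (Pro+Ala+Ser+Thr over all residues, signal peptide included — the
screen precedes signal prediction in the workflow) places it in one of two
pools:

* classical pool: PAST ≥ 0.50 and length > 90 residues;
* AG-peptide pool: PAST ≥ 0.35 and length in [50, 90] residues.

Both thresholds are inclusive and applied to the unrounded fraction. The
packaged attribute table fixes the boundary semantics: a gene printed at
exactly 50 % PAST is high-confidence, and a 90-residue peptide is inside the
peptide window, so 50 % and 90 aa must pass. `ScreenConfig` exposes every
threshold.

Subfamily and confidence rules, in order:

1. any annotated non-P/HRGP domain (fasciclin, early nodulin, nsLTP, …) →
   **chimeric**, excluded. Domain evidence is an input table; no HMM
   scanning is attempted (AGP detection by profile methods is exactly what
   the composition screen replaces).
2. classical-pool member with a Lys-rich domain → **lys-rich AGP**;
   otherwise pool membership gives **classical** or **AG peptide**.
3. confidence is **high** iff both terminal signals are present and the pool
   window matches; genes that fail the screen but have an annotated
   *A. thaliana* AGP ortholog are **candidates** (rescue never demotes a
   high-confidence call).

Dipeptide repeats (AP/PA/SP/TP) are reported in residues: twice the number
of (possibly overlapping) occurrences, so every count is even and "APA"
contains one AP and one PA. The printed repeat columns of the source table
are all even, which motivates this convention; an occurrence count would be
half these values.

The Lys-rich domain rule formalises "a short (~16 aa) Lys-rich stretch
flanked by AGP glycomodules": a window of 10–20 residues with ≥ 4 Lys and
Lys fraction ≥ 0.25, whose two adjacent 20-residue flanks lie entirely
within the sequence and have PAST ≥ 0.50. Among qualifying windows the
highest Lys fraction wins (ties: leftmost, then shortest). Windows clipped
at the termini are disqualified — a terminal Lys run has no glycomodule on
one side. All five parameters are configurable since only the approximate
domain length is established.

## Terminal-signal heuristics

External predictors (SignalP; big-PI and PSORT for GPI) are web services.
The package defines documented hydropathy heuristics sufficient for
synthetic-data testing, plus an adapter for normalised external evidence
with the strict consensus rule: when external GPI evidence is supplied at
all, both predictors must agree positively; supplying only one is rejected
as ambiguous rather than silently mixed with the built-in.

Built-in signal peptide: a hydrophobic core of ≥ 6 residues with mean
Kyte–Doolittle hydropathy ≥ 1.6 starting in the first 35 residues, followed
by the first downstream position whose −3 and −1 residues are small/neutral
(A, G, S, C, T, V), at most at residue 50. Built-in GPI signal: an ω-site
in the last 40 residues (small residue at ω and ω+2), a hydrophilic spacer
of 4–12 residues (mean hydropathy ≤ 0) and a terminal hydrophobic stretch
of ≥ 8 residues (mean ≥ 1.0). The Kyte–Doolittle table is embedded as a
constant. These heuristics capture the coarse architecture of real signals
but none of the position-specific weighting of the dedicated predictors;
real genome screens should supply external evidence tables.

## Retention accounting

The retained-proportion definition — retained copies with an ortholog over
3 × ancestral genes, lineage-I-specific genes excluded, genes lost in
*B. rapa* kept in the denominator, orphan *B. rapa* genes (no ortholog)
excluded from numerators, percentages rounded half away from zero — is the
unique simple formula that reproduces all published family percentages
(48/58/33 %) and the LF figure (25/40 → 63 %) from the packaged table, and
is adopted as canonical. Note the combined-family figure computed this way
is 61/120 → 51 %, not the published rounder 50 %; the per-family numbers
are treated as authoritative. Per-subgenome numerators count only
chromosome-placed copies of that subgenome; scaffold-located genes count in
whole-genome numerators only.

Systematic names follow the *A. thaliana* ortholog number with `.1/.2/.3`
suffixes in subgenome order LF → MF1 → MF2 → unplaced (ties by gene id);
orphans get fresh numbers after the largest annotated ortholog number. One
historical name in the source data orders a family differently (MF2 before
MF1); the implementation documents its own ordering as canonical rather
than reproducing each historical label.

## Phylogeny

Distances are Poisson-corrected, d = −ln(1 − p), with p computed under
pairwise deletion (columns gap-free in both rows) and uniform rates — no
gamma correction, matching the stated tree-building settings. Trees come
from Studier–Keppler neighbor joining with a deterministic tie-break
(lexicographically smallest label pair at equal Q); negative branch lengths
are clamped to zero with the deficit logged. Bootstrap support is the
percentage of column-resampled replicate trees containing each original
bipartition; replicates that produce a saturated pair are skipped and
logged. Maximum-likelihood trees are out of scope.

Clade calling: a clade is a maximal subtree with support ≥ 50 (configurable;
no numeric definition of "high support" is established) containing at least
two ortholog groups; groups in no such subtree are orphans. The stored tree
is unrooted, so clades are read off a midpoint-rooted copy with supports
looked up per unrooted split — a family straddling the stored trifurcation
is still found. Alignments are inputs (aligned FASTA); synthetic families
are substitution-only so alignment is the identity.

## Ka/Ks

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor correction,
chosen because it is fully specified and checkable against an independent
enumeration oracle. Per sense codon, each of the nine single-nucleotide
changes contributes 1/3 site to the synonymous or nonsynonymous total;
changes to stop codons count in neither, so site totals fall below 3 for
stop-adjacent codons. Differences are averaged uniformly over the minimal
mutational pathways that avoid stops (with a fall-back to all pathways in
the rare case every path is blocked). S and N are averaged over the two
sequences; pS = Sd/S and pN = Nd/N are corrected by d = −(3/4)·ln(1−4p/3);
ω = dN/dS, flagged `undefined` at dS = 0 and `saturated` at p ≥ 3/4.
Standard genetic code only; no transition/transversion or codon-frequency
weighting (those belong to ML codon models, which are out of scope).

Protein-guided codon alignment projects each protein column onto one codon
column, drops columns gapped in either row, trims a terminal stop, and
verifies the CDS translation against the protein row (mismatches error with
the position).

Group comparisons use one-way ANOVA (scipy) with Tukey-HSD post-hoc letters
(statsmodels pairwise HSD; compact letters from maximal cliques of the
non-significance graph) at α = 0.05.

## Expression

2^−ΔΔCt with replicate aggregation as the mean of per-replicate ΔCt (not of
fold changes), normalised to the water control at the same timepoint. The
regulation rule uses a 2-fold default cutoff (configurable — no published
numeric cutoff exists): up at FC ≥ 2 at either 4 or 12 HAT, down at ≤ 0.5;
onset is the earliest qualifying timepoint; qualifying at 4 but not 12 HAT
is a recovered (transient) response. "Normalize genes" is interpreted as
mean-centering followed by scaling to unit root-mean-square; similarity is
centred Pearson correlation (rows are already centred), distance 1 − r;
linkage is centroid (cluster centroid = mean of member rows in normalised
space, ties broken by input order). Centroid linkage can produce dendrogram
inversions; they are reported as-is.

## Synthetic data

The generators are pure functions of their spec (seed included) and emit
ground-truth sidecars:

* **Planted proteomes** build bodies from Pro-anchored dipeptide motifs
  (PA/PS/PT/AP/SP/TP with ~10 % GN dilution), so every other residue is Pro
  and no body window can imitate a hydrophobic signal core; terminal
  signals are fixed sequences satisfying the built-in heuristics with
  margin. Planted classicals have PAST ≥ 0.55 and length ≥ 100, peptides
  55–85 aa — deliberately off the decision boundaries, so perfect
  precision/recall on plants shows the decision logic is correct, not that
  boundary cases on real proteomes are resolved. Each decoy violates
  exactly one criterion (extra domain, low PAST, missing SP, missing GPI).
* **Codon pairs** evolve by proposal–acceptance (synonymous proposals
  always accepted, nonsynonymous with probability ω, stop-creating
  rejected) until the realised synonymous divergence reaches the target dS.
  Because proposals are uniform over single-nucleotide changes, the
  realised nonsynonymous/synonymous rate ratio is ω by construction, giving
  an exact per-replicate oracle without matrix exponentiation. Multiple
  hits at one site occur and are handled by the JC correction downstream.
* **Synteny fixtures** retain each non-lineage-specific ancestral gene
  independently per subgenome with the spec probabilities
  (default 0.7/0.45/0.35 for LF/MF1/MF2, 500 ancestral genes — the
  fractionation gradient at a size where binomial error is ~2 points).
* **Ct tables** plant log2 effects as Ct shifts (Ct = baseline − effect +
  Gaussian noise, default σ = 0.2 cycles, 3 replicates); the reference
  gene and the water control carry no effect.

What the synthetic data does **not** emulate: real proteome length/composition
distributions, indels (and hence alignment uncertainty), rate variation
across sites and lineages, codon-usage bias, amplification-efficiency
differences between primer pairs. Green tests on plants demonstrate the
algorithms implement their definitions, not that the heuristics match
SignalP/big-PI on real sequences.

## Problem sizes and tolerances in the test suite

Simulation-based checks use 200-protein proteomes, 300-codon pairs with 50
replicates per ω (recovery asserted within ±0.1 of truth), 50 random 5–8
taxon additive trees for NJ topology recovery, 500 ancestral genes for
retention recovery (within 3 points), and 50–200 bootstrap replicates on
4-taxon alignments — sizes at which the stochastic assertions hold with
comfortable margin under the fixed seeds baked into the tests. The NG86
implementation is checked for exact equality (to float tolerance) against a
brute-force enumeration oracle on random codon pairs; neighbor joining is
cross-checked against an independent library implementation on random
matrices.

## Known limitations

* The heuristic signal predictors are deliberately coarse; real screens
  should feed external predictor tables through the evidence adapters.
* Hyp-glycosylation ("Hyp contiguity") scoring beyond PAST bias is not
  implemented.
* Clade counts depend on the support threshold and on how the tree is
  rooted for display; only the clade/orphan *rule* is fixed, not any
  particular published clade count.
* The Ka/Ks estimator is NG86; published values computed with other PAML
  models are expected to differ in the second decimal.
* Fold-change calls have no replicate-variance filter; a gene with one
  noisy replicate can cross the cutoff. The planted-data tests use effect
  sizes (≥ 2 log2 units) well above the default noise.
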