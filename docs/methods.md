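# Methods

This note documents the models, parameter choices and numerical decisions
behind `napmut`, and what the synthetic-data tests do and do not establish
about real data.

## Change reconstruction

**Model.**  Ancestral states are reconstructed marginally at every internal
node by the pruning algorithm plus an outside pass, under a reversible
nucleotide model.  The default is HKY with empirical base frequencies
(from the at-risk census) and a transition/transversion parameter κ set by
a method-of-moments match: κ̂ = (observed transition / transversion
difference ratio) × (transversion flux weight / transition flux weight),
where the flux weights are the HKY instantaneous-rate terms
π_Aπ_G + π_Cπ_T (transitions) and π_Aπ_C + π_Aπ_T + π_Cπ_G + π_Gπ_T
(transversions).  κ̂ is clipped to [0.05, 100]; JC, K80 and GTR with
supplied parameters are available through the same interface.  Rate
matrices are scaled to one expected substitution per unit branch length;
transition matrices use `scipy.linalg.expm`.  Per-site likelihood vectors
are rescaled by their maximum during both passes; posteriors are
normalised per node and site, so the rescaling cancels exactly.  Exactness
is verified against brute-force enumeration over all internal-state
assignments on trees with ≤ 6 leaves (agreement < 1e-10).

**Which baseml settings the original analysis used is unknown**; the model
is therefore pluggable and nothing downstream depends on more than the
marginal posteriors.

**Filters.**  A change is called iff
(a) the Hartigan parsimony count of the column on the rooted tree
(outgroup included) is exactly 1;
(b) the marginal posterior of the ancestral base at the node above the
event branch is ≥ 0.9 (default, tunable);
(c) the call survives support collapsing: every internal node with
bootstrap support < 98 (default) is collapsed into its parent, and the
count must remain 1 with the derived clade still present as a clade.
Collapsing is our operationalisation of "not dependent on poorly
supported topology"; it is the conservative standard reading, and the
threshold semantics are monotone (raising either threshold can only
remove calls).  The event branch is located as the stem of the clade of
derived-state leaves; when both state classes are clades (the split sits
at the root), the clade *not* containing the outgroup is taken as derived
— outgroup polarisation — and the call is discarded if that is ambiguous.
Sites where the event falls on the outgroup branch or the ingroup stem
produce no ingroup polymorphism and are intrinsically undetectable; the
parameter-recovery tests therefore measure recall against events on
branches below the ingroup ancestor (precision is measured against all
calls).  Multi-hit sites are discarded by filter (a) by design.

**Site filters.**  Columns with any gap or ambiguity in any strain
(outgroup included) are dropped entirely; columns varying only in the
outgroup are kept in the at-risk census but yield no change.  The
uniqueness mask cuts the reference into 300 nt windows offset by 10 nt
and maps each window back against the genome (both strands) allowing ≤ 2
mismatches; windows hitting a second locale are masked.  Matching is
exact via pigeonhole seeding (a ≤2-mismatch match must contain one of
three 100-mer window slices verbatim) followed by Hamming verification,
and is checked against a naive all-pairs scan.  A window matching its own
reverse complement at the same locale (a perfect palindrome) is not
counted as a second locale.

## Mutability and odds ratios

Mutability is `n_changes / n_at_risk` per mutation type × stratum × site
class.  At-risk bases are read off the reference strain; a change is
counted toward a denominator only when its ancestral base equals the
reference base there, preserving `n_changes ≤ n_at_risk`.  Strand-specific
types (12) express genic sites on their gene's sense strand; intergenic
sites have no transcriptional strand and enter only strand-collapsed
("couple") summaries, where each duplex site is counted once under its
pyrimidine label.  Odds ratios use Woolf log-scale 95% intervals with the
Haldane–Anscombe +0.5 on all four cells when any cell is zero (the
literature offers several CI choices; Woolf+Haldane is the simplest that
behaves at zero cells).  A double-zero contrast is flagged undefined
rather than reported as 1.  Strata with empty denominators are omitted
with a warning, never divided through.

The expected-false-positive FDR is min(1, α·m/k), flagged undefined at
k = 0.  It is a coarse panel-level summary, not a per-test correction.

## Methylation contexts

CCWGG (W = A/T) is the Dcm methylation motif; its second cytosine is
5-methylated and deaminates to thymine, a lesion repaired by the
stationary-phase-specific VSP pathway.  CCWHH (H = A/C/T) preserves the
local neighbourhood but is never methylated.  Both strands are scanned
with overlapping matches; focal sites are strand-resolved, and the two
motif classes are disjoint by construction (position four of CCWGG is G,
excluded from H).  Context mutability counts only strand-matched C→T
events exactly at focal positions.

The permutation test keeps each NAP × motif-class mutation total fixed
and reallocates each mutation to the late- or early-bound category
independently with probability proportional to the context counts
(binomial, not hypergeometric — nothing in the procedure implies
without-replacement).  "Conform" uses strict inequalities; ties count
against conformity (conservative).  The Monte-Carlo p is add-one
corrected, (k+1)/(n+1), so it is never zero.  An exact oracle multiplies
per-combination conform probabilities (allocations are independent) and
refuses state spaces beyond a configurable bound.  Note that the
all-conform probability is *not* monotone in the mutation totals under
strict-inequality conformity (with equal contexts it is P(Binom(m,½) >
m/2): ¼ at m = 2 but ½ at m = 3), so no such monotonicity is asserted.

## Classifier randomization test

Datasets are one per strand-specific mutation type: at-risk 4-fold sites
(2-fold added for transitions), outcome changed/unchanged, features =
per-protein binding category plus confounders (per-phase expression,
leading/lagging strand, origin distance, local GC, degeneracy class).
The unchanged class is subsampled without replacement to exactly 5× the
changed class.  The forest uses depth ≤ 10, K features per split
(default 2; K is tuned by maximising the across-dataset mean of per-dataset
min–max-normalised OOB-AUC profiles, ties to the smallest K), and a 5:1
minority-class weight; the reference forest size is 10,000 trees, scaled
to 500 in tests and the bundled pipeline (OOB-AUC variance at 500 trees is
well inside the asserted bands).  Performance is the AUC of out-of-bag
predicted probabilities; rows without any out-of-bag vote are excluded
explicitly, because scikit-learn's weighted bootstrap can keep heavily
weighted rows in nearly every sample and silently reports probability 0
for voteless rows.  OOB estimates are pessimistically biased near the
null (each row is scored by trees that excluded it), which cancels in the
randomization comparison but means a raw null OOB-AUC sits slightly below
0.5 at small n.

Randomization shuffles all binding columns as one block with a single row
permutation per replicate, preserving the inter-protein joint
distribution (independent per-column shuffles would destroy it and
overstate binding information); confounders are untouched.  The observed
AUC is summarised against R shuffled refits (reference R = 50, scaled to
6–8 in the calibration tests, which only needs a mean/SD estimate) as
z = (AUC_obs − mean)/sd and one-tailed p = 1 − Φ(z): only a drop upon
randomization is informative, regardless of the sign of the
binding–mutability association.  Zero-spread randomized AUCs equal to the
observed value give z = 0, p = 0.5; otherwise zero spread is flagged
undefined.

## Synthetic-data generator

The generator emulates the study conditions rather than *E. coli* biology
in detail:

* **Tree**: random joins over n strains, exponential branch lengths
  (mean 0.02 substitutions/site), one outgroup on a 3× longer branch,
  bootstrap supports from a high (98–100) / low (50–97) mixture with a
  configurable low fraction (default 0.2) so the support filter has both
  classes to act on.
* **Genome**: i.i.d. sequence at configurable GC (default 0.5),
  non-overlapping genes of 300–900 bp on random strands, third-position
  degeneracy from the standard genetic code.  Circular coordinates,
  0-based half-open throughout.
* **Binding**: per (protein, phase) interval sets; interval lengths
  geometric with mean 200 bp (the real length distribution is not
  published; this is an explicit arbitrary default), coverage 5% per
  phase by default.  The latest assayed phase anchors each protein;
  earlier phases re-use `overlap^(d/3)` of the anchor's bases (d = phase
  distance) and top up outside the anchor, so the realised
  stationary↔mid-exponential sharing equals the configured overlap and
  closer phases share more.  Fis exists only in the exponential phases.
* **Evolution**: at most one Bernoulli event per site per branch with
  probability rate × branch length × binding modifier × CCWGG-context
  multiplier; the ≥ 0.5-probability regime is rejected because the
  downstream single-event logic is meaningless there.  Default rates are
  transition-biased with C:G→T:A dominant, echoing enterobacterial 4-fold
  spectra.  No indels, recombination, rate heterogeneity or codon-usage
  realism — so passing tests demonstrate correctness of the machinery
  and calibration under the model's own assumptions, not robustness to
  alignment error, HGT or selection on real genomes.
* **Logistic site table**: a direct shortcut drawing changed/unchanged
  outcomes from a logistic model over the feature set, baseline change
  probability 3% (matching what sequence evolution realises at default
  rates), so classifier properties can be tested against exact known
  effect sizes without sequence evolution.

Determinism: every operation is reproducible byte-for-byte from its
(config, seed); the pipeline derives per-stage seeds by hashing the
global seed with the stage name.

## Problem sizes in tests

The acceptance suite uses 50 kb / 8 strains for change-calling recovery,
150 kb / 12 strains for the spectrum rank test (couple-level event counts
large enough that only one adjacent rank swap is plausible), 200
replicates of 110,000-site tables for odds-ratio coverage, 100,000
permutation replicates, and 500-tree forests with 40 null runs (3,000
sites) and 20 power runs (30,000 sites).  `scripts/acceptance.py` repeats
the same measurements at somewhat smaller replicate counts and records
the problem size alongside every value.

## Known limitations

* Filter (c) is one reading of support-dependence; it does not claim to
  reproduce the original bookkeeping node for node.
* Marginal (not joint) reconstruction; no among-site rate variation.
* The uniqueness mask indexes every 100-mer in a Python dict, which is
  comfortable to a few megabases but not engineered for large genomes.
* Real-data mode expects gap-free per-block FASTA plus a block index; it
  does not parse Mauve XMFA directly.
* Binding occupancy is binary; no peak strength weighting.
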