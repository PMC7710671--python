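# Methods

## The question the package answers

Multi-marker phylogenies of groups with sparse sequence sampling often
contain one contested internal branch on which the markers disagree. The
canonical symptom: the concatenated (supermatrix) tree resolves the branch
one way, but removing a single gene flips it. This package quantifies that
situation directly. Given two candidate topologies that differ at the
contested branch — T1, typically the unconstrained maximum-likelihood tree
of the supermatrix, and T2, the alternative in which two named clades are
forced to be sisters — it computes, for every alignment column, the
difference in site log-likelihood

    ΔSLS(i) = ln L_i(T1) − ln L_i(T2)

under a single GTR+Γ model, and aggregates it per marker:

    ΔGLS(g) = Σ_{i ∈ g} ΔSLS(i).

A positive ΔGLS means the marker as a whole supports T1; the magnitude is
the strength of that support on the log-likelihood scale. Because the
per-gene values sum exactly to the total log-likelihood difference of the
two trees, the statistic decomposes the supermatrix result into additive
per-marker contributions: one strongly biased gene can visibly dominate
several weakly informative ones. The per-gene proportions of sites with
ΔSLS above, below, and within a tie threshold ±ε complement the sums: a
gene can have most sites weakly favouring one topology while a minority of
large-|ΔSLS| sites drives its total the other way.

## Likelihood model

Site likelihoods use the general time-reversible model with discrete-gamma
rate variation (GTR+Γ):

- Six symmetric exchangeabilities (AC, AG, AT, CG, CT, GT), with GT ≡ 1;
  stationary base frequencies π estimated empirically from the alignment
  (missing characters excluded, floored at 1e-6 and renormalised). The
  generator is normalised to mean rate one, so branch lengths are expected
  substitutions per site.
- Gamma rate variation with shape α, discretised into k equal-weight
  categories (default k = 4) whose rates are the *means* of the
  inter-quantile bins of the mean-one gamma distribution, computed through
  the incomplete-gamma identity rather than quadrature. Rates are strictly
  increasing and renormalised to mean one.
- No invariant-sites class; no partitioned (per-gene) models. One joint
  model is fitted on the supermatrix and used for both topologies, so ΔSLS
  differences reflect topology, not model differences.

Transition matrices come from the symmetrised eigendecomposition of the
generator (exact for reversible Q); the eigensystem is computed once per
model and reused for every branch and rate category.

## Pruning engine

Per-site likelihoods are computed by Felsenstein pruning over unique site
patterns (columns compressed by multiplicity and expanded back to site
order, since ΔSLS is reported per site). Missing and ambiguous characters
(`-`, `?`, `N`, and partial IUPAC codes) enter as tip partials with ones at
every compatible state; a fully missing column therefore has likelihood one
and ΔSLS exactly zero. Underflow is handled with per-node scaling factors
accumulated in log space, shared across gamma categories within a node so
the category mixture stays valid.

Branch lengths are optimised coordinate-wise: for a reversible model the
likelihood as a function of one edge length factorises into
`(π ⊙ F) · P(t) · D`, with D the post-order partial below the edge and F
the "outside" partial from a pre-order pass, so each trial length costs one
4×4 product per category. Each edge gets a bounded scalar search (Brent,
bounds [1e-8, 50] substitutions/site), sweeps run in postorder, and the
engine recomputes both passes after each accepted update; convergence is
declared when a full sweep improves total lnL by less than `tol`
(default 1e-4; 100-pass cap with a warning flag). Model fitting alternates
a bounded derivative-free Powell search over (log exchangeabilities, log α)
with branch-length sweeps until the joint improvement falls below `tol`.
Every optimiser starts from a deterministic point; nothing in fitting is
randomised.

## Topologies and constraints

All topology semantics are unrooted: a clade is a split (some edge
separates exactly that taxon set from the rest), and a sisterhood
constraint on clades X and Y holds when X, Y and X ∪ Y are each splits.
T2 is built from T1 by pruning the Y subtree and regrafting it onto the
stem edge of X; the stem is bisected (s/2 either side of the new ancestor)
and Y keeps its stem length. This length-splitting rule is an arbitrary but
documented convention — branch lengths are re-optimised per topology before
any likelihood is reported, so it only sets the search start. An optional
greedy NNI hill-climb (canonical edge order, five adjacent branch lengths
re-optimised per candidate, constraint-violating moves rejected) can refine
T2 locally; it is deterministic and never decreases the starting lnL. NNI
rather than SPR keeps the refinement local and reproducible; the package
deliberately does not attempt a full tree search.

Whether the original analysis re-optimised branch lengths per topology or
froze them is not observable from the outputs it reports; this
implementation re-optimises both per topology (the conservative choice —
each hypothesis is shown at its best), and `optimize_branch_lengths` can be
skipped by the caller to freeze lengths for sensitivity analysis.

## Tie threshold

ε defaults to 1e-6 on the lnL scale and is configurable and echoed in every
output header. It exists to keep floating-point noise on uninformative
sites (constant columns, fully missing blocks) out of the support
proportions. Sites that are missing for all members of one clade are not
specially excluded: they yield near-zero ΔSLS and land in the tie class by
themselves.

## Sequence-inclusion filter

Supermatrix assembly keeps, per marker, sequences whose ungapped length L
(characters outside `{-, ?, N}`) satisfies L ≥ 0.45 × alignment length OR
L ≥ 250. The connective is deliberately the permissive OR — consistent
with maximising taxon sampling — but both the connective (`combine="and"`)
and the strictness of the absolute cut-off (`strict_greater=True` for
> 250) are switches, because the verbal rule "and/or … larger than" admits
both readings. Concatenation takes the union of taxa in first-seen order
and pads absent markers with `?`, which is preserved in files (provenance:
`?` = marker never sequenced, `-` = alignment gap) but treated identically
to `-` and `N` everywhere downstream.

## Alignment statistics

A column is *variable* when, after discarding everything outside
{A,C,G,T}, at least two states remain; *parsimony-informative* when at
least two states each occur in at least two taxa. Treating ambiguity codes
as missing is the default because it makes the counts reproducible under
one stated rule; a strict-IUPAC mode (a column is variable only when no
single nucleotide is compatible with all of its characters) is available
because published counts from different programs differ in exactly this
respect, and both modes are reported when checking against deposited
matrices.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
with defaults chosen as the reference study conditions:

- 12 taxa: clade A (4), clade B (3), clade C (3), outgroup (2); clade
  subtrees are pectinate with every uncontested edge at 0.05
  substitutions/site (a mid-range depth for a family-level multi-locus
  alignment).
- Five markers of unequal length: one 1,000-site gene evolved on the
  AB topology with a 0.1-long contested internode (the strong,
  "rpb2-like" marker) and four genes of 400-800 sites evolved on the AC
  topology with a 0.01 internode (markers with little signal for the
  contested branch).
- A GTR+Γ model with transition-favouring exchangeabilities
  (AG = 4, CT = 5), mildly unequal frequencies and α = 0.5 — strong rate
  heterogeneity typical of mixed coding/ribosomal concatenates.
- Missingness is block-structured: whole taxon×marker sequences are
  replaced by `?` with a per-block probability, because that is how
  markers are actually absent from sparse supermatrices (a species
  sequenced for one or two of five loci), not site-wise. The CLI
  `simulate` default of 0.6 mimics a matrix where many taxa carry only one
  or two markers; a gene is never left with zero taxa (offending masks are
  resampled, and probability 1 therefore errors by construction).
- One global seed expands into per-gene streams via
  `SeedSequence(entropy=seed, spawn_key=(gene_index,))`, so appending a
  gene never changes earlier genes' data.

What the generator does *not* emulate: incomplete lineage sorting (each
gene's tree is one of exactly two fixed topologies, not a coalescent
draw), indels and alignment error (gaps appear only through missingness
blocks), inter-gene model heterogeneity beyond a branch-length scale
multiplier, and base-composition drift across the tree. Passing the
recovery tests therefore shows that the pipeline detects and attributes
topological signal correctly *when the generating process matches the
analysis model*; it does not certify robustness to the ways real markers
violate that model.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on simulated data at
deliberately desk-scale sizes: engine-vs-enumeration checks on all 3-5-taxon
topologies with six sites; signal recovery at the 12-taxon five-marker
conditions over 20 seeds; the star-tree null (contested internode zero,
where mean ΔGLS must vanish) over 100 replicates of an 8-taxon single-gene
configuration; parameter recovery at 5,000 sites. The deposited 107-taxon
supermatrix check runs only when the TreeBase matrix is placed in `data/`
(it is too large to redistribute inside the package); without it, that
single check reports its absence as a failure rather than silently passing.

## Known limitations

- RELL resampling is a diagnostic, not a calibrated topology test; the
  package intentionally omits AU/SH/KH machinery.
- The NNI climb finds local optima only and is meant for refinement around
  a supplied topology, not de-novo search.
- One joint model across markers means per-gene rate/composition
  differences are absorbed by the gamma mixture; strongly heterogeneous
  concatenates may inflate |ΔSLS| at sites of atypical genes.
- Branch lengths are clamped to [1e-8, 50]; datasets genuinely pushing
  those bounds (identical sequences, saturated markers) sit at the clamp.
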