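# Methods

This note documents the models, conventions and numerical choices behind
`paleofam`, and what the simulator does and does not emulate.

## Family identification

A protein is scanned for maximal runs matching `S P{3,}`: one serine
followed by three or more prolines counts as exactly one repeat unit, so
`SPPPPPP` is a single unit rather than several overlapping SP3/SP4 units.
Maximal-run counting is deterministic and conservative; the default
membership threshold is two units. Hydroxyproline is post-translational,
so genomic protein sequences carry plain proline and the scan needs no
modified alphabet. Domain annotations (e.g. IPR006706, extensin-2) are
ingested from a TSV and attached as subfamily labels; by default they do
not gate membership — whether a signature domain should be required *in
addition to* the motif is genuinely ambiguous, so both behaviours are
supported (`require_domain`), with motif-only as the default.

## Homology

Nucleotide homology uses exact Smith–Waterman local alignment with affine
gaps (default match +1, mismatch −2, gap open −5, extend −2; a gap of
length L scores `open + (L−1)·extend`). Inputs are gene-family scale, so
no heuristic seeding is needed. Significance is a Karlin–Altschul
E-value, E = K·m·n·exp(−λ_KA·score); for the default scheme λ_KA solves
the ungapped stationarity equation (¼)e^λ + (¾)e^(−2λ) = 1, giving
λ_KA = ln((3+√21)/2) ≈ 1.3328, and K = 0.3 was calibrated by simulation
on random uniform sequences. E-values only gate the tandem-duplication
rule (E ≤ 10⁻²⁵), which is dominated by the score exponent, so the
precision of K is immaterial.

Paralogs are within-species pairs aligning over **more than** 300 bp
(the wording is read strictly; configurable) at ≥ 40 % identity, with
identity counted over all alignment columns including gaps — a
conservative denominator chosen so the threshold is exactly reproducible.
Paralog groups are connected components of kept pairs. Orthologs are
reciprocal best hits (best = highest score, ties broken by identity, then
aligned length, then lexicographic subject id, for determinism) over more
than 300 bp; the output is a partial one-to-one matching.

Protein pairs are aligned globally under BLOSUM62 with gap-opening
penalty 2.0 and gap-extension penalty 0.2.

## dN/dS and Ks (NG86)

Codon alignments are built by back-translating the protein alignment onto
the coding sequences (terminal stop codons are stripped at load; internal
stops are rejected with their position). Site counts follow Nei–Gojobori
(1986): each codon position contributes the fraction of its three
single-base changes that are synonymous; mutations creating stop codons
count as nonsynonymous in site counting. Differences in multi-hit codons
are averaged with equal weights over all orderings of the changed
positions, excluding pathways through stop codons unless every pathway is
blocked. Proportions pS = Sd/S and pN = Nd/N are corrected for multiple
hits with Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is outside the
model's domain and flags the distance as saturated (infinite). ω = dN/dS
is reported only when dS is positive and finite; saturated or
zero-divergence pairs are excluded from ω summaries and listed.

ω classification uses a neutral band of ±0.1 around 1: purifying below,
positive above, neutral inside; purifying calls with ω > 0.9 carry a
weak-evidence flag (purifying selection "not evident"). NG86 is a
counting estimator: its ω values differ numerically from
maximum-likelihood codon models (codeml-style pairwise estimates), which
are deliberately out of scope; every report notes the estimator.

## Median-Ks clustering and dating

A paralog group is clustered by the published five-step agglomeration:
all genes start as singleton clusters; the pair of clusters with the
smallest between-cluster Ks is merged, where the Ks between multi-member
clusters is the **median** over all cross pairs; the merge's median Ks
becomes the node height; repeat to a single cluster. scipy's linkage
methods do not implement this median-of-cross-pairs rule (its "median"
method is WPGMC), so the agglomeration is implemented directly and
validated against an independent step-by-step re-execution.

Numerical conventions: even-sized medians are the mean of the two middle
values; undefined/saturated Ks entries are excluded from medians, and a
merge whose cross pairs are all undefined is an error naming the stranded
clusters rather than a guess; ties on the smallest Ks merge the pair
whose lexicographically smallest member sorts first. Median linkage can
invert heights; node records keep raw heights while Newick branch lengths
(parent height − child height, leaves at height 0) are clamped at zero
with a warning. Nodes — not individual pairs — are dated:
T = Ks_node / (2λ) with λ = 1.5 × 10⁻⁸ synonymous substitutions per site
per year.

## Synteny, duplication mechanisms, retention matrix

Anchors (homolog pairs with chromosome ranks) are chained per chromosome
pair into syntenic blocks: strictly monotone ranks on both sides (both
orientations tried), consecutive anchors within 10 ranks on both sides,
at least 5 anchors, extracted greedily longest-first with each anchor in
at most one block. These defaults stand in for the block inventory of
the public synteny databases, whose exact parameters are not published;
precomputed anchor tables can be ingested instead. A block's median Ks
(over anchors with defined Ks) assigns it to a WGD event through closed,
non-overlapping calibration intervals per species; block medians above a
saturation threshold (default 1.9) are labelled indistinguishable among
the ancient events rather than assigned.

Tandem duplicates are same-chromosome pairs within a 100-kb start-to-start
window (strand-agnostic; only the window is specified by the rule) whose
alignment E-value is ≤ 10⁻²⁵. Mechanism classification is exhaustive and
exclusive with precedence SWGD > TD > OTHER: block membership is stronger
positional evidence than proximity.

The retention matrix rows are ancestral loci: connected components of
genes linked by block anchors, extended by raw homolog anchors so that
tandem and dispersed copies join the locus of their paralogs (the analog
of assigning a non-collinear paralog to an ancestral gene through its
paralogy); a family member with no surviving homolog is its own locus.
Columns are per-species duplication slots, one per expected
post-baseline copy (2 per duplication, 3 per triplication). Observed
genes fill slots as E (member) or N (non-member); same-chromosome genes
within the tandem window collapse to one occupant (a tandem array
descends from one post-WGD copy), and occupants anchored in more blocks
take slots first. An empty slot is L when a block covering another copy
of the locus pairs with a chromosome of the species that lacks a locus
gene in the covered span, and B otherwise. The slot interpolation is a
design choice: the distinction between "gene lost, block retained" and an
annotation gap cannot be made sharper without gene-level alignment
evidence.

## The simulator

The generator emulates the study design the pipeline targets: several
lineages descending from a common ancestor, a WGD shared by two of them
(default 50 My ago), a lineage-specific WGD (10 My ago), and an
undisturbed baseline lineage — giving expected multiplicities 4:2:1. An
ancestral chromosome carries 25 family genes interleaved among 75
background genes (background context is what makes collinear blocks
detectable). At each WGD every chromosome is copied with gene order
preserved; each new family copy is retained (p = 0.45), subfunctionalized
(p = 0.30; its repeat serines are mutated so it no longer classifies) or
lost; background copies are retained with p = 0.6; contiguous segments of
new copies (geometric length, mean 20 genes) are dropped wholesale with
p = 0.12, creating the block-lost state. Tandem (2 × 10⁻⁹/gene/year) and
dispersed (1 × 10⁻⁹/gene/year) duplications insert copies adjacent to, or
away from, their source. Retention and loss probabilities are not
measurable from the study system and were chosen once for test power —
enough surviving copies in every state to score — rather than fitted to
any genome.

Sequence divergence is a per-site Poisson process: each single-base
change proceeds at rate λ/3 if synonymous and ω·λ/3 (ω = 0.15) if
nonsynonymous, with changes to stop codons forbidden and
synonymous/nonsynonymous status recomputed from the current codon after
every substitution. A fully synonymous site therefore evolves at λ and a
pair split t years ago has expected Ks = 2λt. Two modelling choices keep
the truth log observable:

- **Motif protection.** Nonsynonymous changes are disallowed inside the
  repeat spans of retained members — the strong purifying selection such
  families show. Without it, ω = 0.15 destroys most motifs within 50 My
  and "retained member" would not be a scorable truth state.
  Subfunctionalized copies evolve free of the constraint.
- **Fourfold-degenerate composition.** Generated residues outside the
  motif come from fourfold-degenerate codon boxes (A, G, P, T, V, and
  TC*-serine — also the small-residue composition typical of these
  cell-wall protein backbones). Twofold-degenerate synonymous sites
  saturate at pS = 3/2 per NG86 site, outside the Jukes–Cantor model, and
  would bias recovered Ks upward by ~30 % at Ks ≈ 1.5; the fourfold
  composition keeps the synonymous process inside the estimator's model
  so that recovery tests measure the pipeline, not a model mismatch.

The simulator does not model gene conversion, transposable elements,
chromosome fission/fusion, rate heterogeneity across sites or lineages,
codon-usage bias beyond the composition above, insertions/deletions, or
expression-level subfunctionalization (subfunctionalization is exactly
motif loss, which is what the classifier can observe). Passing recovery
tests therefore show that the pipeline's inference is correct under its
own model assumptions — not that those assumptions hold in any real
genome. One RNG stream (numpy `default_rng(seed)`) drives all draws;
identical configurations produce byte-identical outputs.

## Problem sizes

The end-to-end recovery tests run the default simulation (100 ancestral
genes, three lineages, ~570 surviving genes, ~1500 anchor pairs) and the
full pipeline on one CPU in about a minute; oracle-equivalence suites use
instances small enough for exhaustive enumeration (≤ 5 codons, ≤ 14
anchors, 8 genes) where brute force is exact.
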