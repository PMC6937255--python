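# Methods

This note documents the models, parameter choices and numerical decisions
behind `ligperox`, and what the synthetic study conditions do and do not
establish about real data.

## Residue anchors and mature numbering

All diagnostic coordinates are in *mature numbering*: position 1 is the
first residue of the processed protein. The reference supplied to the
signature detector must therefore already be mature; signal-peptide
prediction is out of scope. Of the anchor coordinates only the Mn²⁺
oxidation triad (35, 39, 179) is canonical; the catalytic tryptophan (171),
active-site histidines (46, 173), eight cysteines and nine Ca²⁺ ligands
ship as configuration (`ResidueAnchors`, JSON-serialisable) tied to the
synthetic reference, because no printed coordinates exist for them. The
triad accepts E or D at each of its three sites — the conservative reading
of "three acidic residues" — and the functional type is gated only by the
triad and the tryptophan; His/Cys/Ca counts are reported as supporting
evidence. "Generic peroxidase"-like sequences carry no special rule and
type as `none`.

## Pairwise alignment

Global alignment with affine gaps runs through biopython's
`PairwiseAligner`: BLOSUM62, gap cost `11 + 1·k` for a length-*k* gap, end
gaps penalised. `X` is accepted and rescored to 0 against everything.
Among co-optimal alignments the aligner's first traceback is returned; this
is deterministic for fixed inputs. Correctness is pinned by an independent
oracle that enumerates *every* alignment of small sequence pairs by plain
recursion and takes the maximum — the dynamic program must match it
exactly.

Anchor transfer walks the alignment columns; an anchor aligned to a query
gap maps to "absent". Present mappings are strictly increasing by
construction.

## Sub-class profiles

A profile is one log-odds row per alignment column. With `n` non-gap
residues in a column, counts `c_a`, pseudocount parameter `pc` (default 1),
the model probability is `p_a = (c_a + n·pc/20) / (n·(1+pc))` — each
observed row contributes `pc/20` to every residue. Probabilities are
floored at 1e-6 so scores stay finite when pseudocounts are disabled.
Column score: `w_j · log(p_a / q_a)` against the Robinson–Robinson
background `q`.

Downweighting: a column is *family-conserved* when every cluster alignment
agrees on the modal residue and each cluster's modal frequency is ≥ 0.9
(configurable). Such columns get weight `w_j = 0.1` by default — they still
anchor the alignment register but barely discriminate; weight 0 would erase
them entirely and 1 recovers the unweighted profile. Columns with > 50%
gaps are insert-like: weight and scores 0. Generalized-profile machinery
from PROSITE is intentionally not reproduced; the downweighted log-odds
profile captures the construction principle with a documented formula.

Scanning is a global affine-gap DP of the query against the profile columns
(numba-compiled; gap costs are position-independent and unweighted, which
is what makes an all-zero-weight profile score every equal-length query
identically). Classification takes the best-scoring profile; ties break to
the alphabetically first label so the outcome is invariant to profile
order.

**Unclassified threshold.** Each profile's threshold is calibrated on a
seeded sample of 1000 random background sequences of family-typical length:
a Gumbel distribution is fitted to the null scores — the standard model for
profile-scan score tails — and the threshold is its (1 − α/P) quantile with
α = 0.01 family-wise over the P profiles (Bonferroni). Two deliberate
choices here: the correction over profiles keeps the *joint* chance that a
random sequence clears any threshold at ~1% (per-profile 1% cutoffs would
compound to nearly P%), and the parametric tail avoids the large
order-statistic noise of an empirical quantile at the 99.9th percentile of
a 1000-point sample. True family sequences score several hundred log-odds
units above these thresholds, so the calibration affects only the rejection
of non-family input.

## Trees and clusters

`nj_tree` is classical neighbor joining (scikit-bio) over any symmetric
zero-diagonal matrix; the packaged distance is `1 − identity` over shared
non-gap columns. Maximum-likelihood phylogenetics is out of scope by
design: the tree is a desk-scale instrument for cluster validation and
paralog pairing, and NJ is consistent on additive matrices, which the tests
verify against both the generating topologies and an exhaustive
least-squares topology search. `define_clusters` midpoint-roots the tree
and recursively splits out every child clade holding at least
`min_support_size` leaves; a node with no such child becomes one cluster.
The parameter is therefore the expected minimum cluster size (1 dissolves
the tree into leaves; larger than the leaf count yields one cluster).

## Gene structures and cintrons

Coordinates are GFF3: 1-based, inclusive, strand ±, exons stored 5′→3′ in
transcript orientation, CDS including the stop codon (protein length =
CDS/3 − 1). An intron is (codon, phase) with phase = upstream CDS nt mod 3;
"after codon i, phase 0" sits between codons i and i+1. Extraction is
strand-aware and exact: the structure writer/extractor round trip
reproduces every planted (codon, phase, length).

Cintron identity is the *exact* (alignment column, phase) pair; fuzzy
window matching is not reimplemented, but a ±k-column tolerance (default 0)
exists for sensitivity analysis, merging same-phase groups left to right.
The conservation rate of a cintron in a class divides by **all** genes of
that class present in the alignment, not only intron-bearing ones, and
"conserved" requires a rate strictly above 0.5 in at least one class —
exactly 50% does not qualify. "Specific" cintrons are conserved in exactly
one class with rates below 0.1 (configurable) everywhere else; "universal"
ones are conserved in every class.

## Duplication typing

"Successive duplicated genes" is operationalised as rank adjacency: TD
requires the same scaffold and at most `max_intervening` (default 0)
annotated genes between the copies; ranks count *all* annotated genes on
the scaffold, so spacer genes matter. A base-pair threshold is deliberately
not the default because gene density varies; the rank rule is the direct
reading of "successive". Cross-scaffold pairs are labelled
"WGD (cross-scaffold)": coordinate-wise that is all the data supports, and
biologically such pairs may be dispersed duplicates. Pairing is
distance-based (patristic or identity), not bootstrap-based, since ML trees
are out of scope: per round, all mutual-nearest-neighbor pairs among
unpaired leaves of a cluster are taken together — so two sequential
duplications yield both pairs at the first level — same-species MNN pairs
become events, cross-species ones retire.

## Life-style association

The CcP rule is a hard predicate per species: consistent iff
(CII = 0 ∧ CcP = 2) ∨ (CII ≥ 1 ∧ CcP = 1). The association between
trophism and CII presence is an artifact-added inference (the source
procedure states it qualitatively): trophism codes map to
{lignin-associated, other} — default lignin side {NPP, HPP, WR}, the
mapping fully configurable — and the one-sided p-value permutes the binary
presence labels, implemented through the exact hypergeometric equivalent of
label permutation, with the Haldane-corrected odds ratio as statistic and
`p = (1 + #{perm ≥ obs}) / (1 + n)`. Permutation p-values are discretely
conservative, so measured type-I error sits at or below nominal.

## Synthetic data: what it emulates and what it does not

The generator is the study bench, not a phylogenetic simulator. Mutation is
i.i.d. substitution from the background at non-anchor sites (replacements
always differ from the original, so substitution counts are binomial);
anchor sites are never touched and anchor neighborhoods (±2) are protected
from the optional short indels so mature numbering stays recoverable.
Sub-class consensus sequences diverge from the reference at 50% of free
columns by default, with 30% of free columns held family-conserved; these
divergence levels are free parameters of the bench, not claims about real
families. Intron presets encode the two reported lineage regimes —
ascomycete-like (2 introns, 74 nt) and basidiomycete-like (8 introns,
54 nt); each class carries a planted 4-position intron pattern at carriage
0.9, truncated when the target mean is smaller, plus Poisson private
introns topping up to the target mean. Duplication directives place copies
by construction (adjacent / behind ≥ 6 spacers / next scaffold) with 2%
extra substitutions so pairs stay mutually nearest. All randomness in a
call flows from one integer seed through a single generator; equal seeds
give byte-identical files.

Passing tests on this bench show the *procedure* is implemented correctly
and is recoverable under the stated noise; they do not show that real
families satisfy the bench's assumptions (no rate heterogeneity, no
alignment error, no annotation error, single species per layout).

## Problem sizes and defaults

The packaged study conditions: 9 sub-classes × 20 sequences of length 350
at substitution rate 0.15; 1000 null sequences for threshold calibration;
200 genes for intron-regime checks; a 6-event duplication layout
(3 TD + 2 SD + 1 WGD) at substitution rate 0.1; 200-species tables at 10%
rule violation; 100 null tables × 499 permutations for the type-I check;
additive matrices on 4–8 taxa for NJ validation. These sizes were chosen as
the smallest at which the binomial tolerances in the tests are meaningful.

## Known limitations

No ML phylogenetics, bootstrap or model selection; no phylogenetically
corrected association test; no intron gain/loss reconstruction; no
splice-site or transposable-element analysis; cintron matching is exact by
default; the pipeline's duplication stage reports *all* same-species
mutual-nearest pairs, so on a single-species bench many reported pairs are
ordinary within-class neighbors rather than planted duplications — planted
events are evaluated by identity, not by count.
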