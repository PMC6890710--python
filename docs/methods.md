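# Methods

This note records the models, estimators, and design choices behind
each module, and what the synthetic-data validation does and does not
establish about real data.

## Ks estimation (ksdist, codons)

Paralog divergence is estimated with the Nei–Gojobori (1986) counting
method plus the Jukes–Cantor multiple-hit correction, chosen over
likelihood codon models because every intermediate quantity is defined
by finite enumeration and therefore verifiable against brute force:

* **Sites.** For each codon position, the synonymous fraction is the
  share of non-stop single-nucleotide mutants that preserve the amino
  acid; stop mutants are excluded from the denominator (per-position
  rescaling), so s + n = 3 exactly for every sense codon.
* **Differences.** For a codon pair differing at m positions, all m!
  orderings of the changes are walked; orderings through a stop codon
  are discarded; Sd/Nd are the path averages. If every ordering is
  blocked (rare), the column is excluded entirely — from sites as well
  as counts — which preserves symmetry under swapping the sequences.
* **Correction.** pS = Sd/S with S averaged over the two sequences;
  Ks = −(3/4)ln(1 − (4/3)pS). At pS ≥ 3/4 the logarithm is undefined:
  the pair is flagged saturated and excluded from the histogram rather
  than extrapolated.

Pair discovery is a seeded similarity search: shared-5-mer counts per
diagonal bucket nominate candidates, which are verified by local
alignment. The local aligner scores identity directly (match +2,
mismatch −1, gap open −8, extend −2) because the acceptance gate is
percent identity over aligned columns; substitution-matrix scoring
(e.g. BLOSUM62) optimizes a different objective and lets unrelated
sequences assemble long gap-stitched alignments that cross an identity
threshold they do not meaningfully meet. Seeded search trades
completeness below ~45% identity for speed, as similarity-search tools
do; `exhaustive=True` aligns every pair and is used to cross-check the
heuristic in tests. Back-translation uses a global BLOSUM62 protein
alignment; codon columns containing gaps, ambiguity codes, or
unscorable codons are dropped.

**Mode estimator.** The distribution mode is read from a Gaussian KDE
at the Silverman bandwidth rather than as the argmax of the 0.05-bin
histogram. At a few hundred retained pairs the peak spans several
bins with near-equal expected counts, so the raw argmax jitters by
multiples of the bin width and is not a consistent location estimator;
the KDE mode is. The histogram itself is unchanged and is what the
report displays.

## SiZer (sizer)

The significance map follows the canonical construction: Gaussian
kernel density-derivative estimate with plug-in standard error from
the sample variance of the kernel-derivative summands; effective
sample size ess(x, h) = Σᵢ K_h(x−Xᵢ)/K_h(0) with cells below 5 marked
sparse; per bandwidth row, m(h) = n / mean(ess over non-sparse x)
independent blocks give the simultaneous quantile
q = Φ⁻¹((1 + (1−α)^(1/m))/2). Defaults: 201 grid points over the Ks
window, 21 log-spaced bandwidths from twice the bin width to half the
data range, α = 0.05.

**Reference bandwidth.** Peaks are read at the row nearest
h = σ̂·(4/(5n))^(1/7), the normal-reference bandwidth that minimizes
the asymptotic MISE of the *first derivative* (for a Gaussian kernel
on Gaussian data, h⁷ = 3R(K′)/(n·μ₂²·R(f‴)) = (4/5)σ⁷/n). Silverman's
density rule (0.9·σ̂·n^(−1/5)) undersmooths a derivative estimate: at
n = 10⁴ it yields per-cell power around 90% exactly at the shoulders
of a standard normal, i.e. visible flickering where the derivative is
plainly nonzero. σ̂ is min(sd, IQR/1.34) throughout. A peak call is
the midpoint between the last significant-increase and first
significant-decrease cell (flat or sparse cells may intervene);
bandwidth support is the fraction of usable rows showing an
overlapping transition, and the primary peak is the most supported
one, ties broken by density at the call.

## MAPS-style tallying (mapscan)

Matching is strict and recursive: a clade of tips from one species
matches that species (so same-species duplicates collapse); an
internal match requires a bifurcation whose children match the pruned
species tree's children in either order; polytomies (including those
created by optional support collapsing) never match. For node N with
sibling S, a gene-tree node contributes to N's denominator when one
child matches S and the other either matches the pruned tree at N (no
duplication) or consists of two sister clades that each match it
(duplication, also counted in the numerator). Trees lacking the
relevant species contribute to no denominator. Rooting uses the
smallest clade containing all outgroup tips; trees without the
outgroup are skipped and counted.

Two consequences worth knowing: (i) counting is exact — on synthetic
trees the numerator equals the planted duplication count; (ii) under
*simultaneous* duplications at nested nodes, a clade duplicated at one
node no longer strictly matches the pruned tree in the other node's
context, so both the denominator and numerator at the deeper node
shrink. Recovered proportions match planted rates exactly only when
one node is planted at a time; the joint run in the worked example
reports 14.7% at the deeper node against a planted 19% for exactly
this reason. Real MAPS analyses share this property of strict subtree
filtering.

## LTR annotation and dating (ltr)

Detection is seed-and-extend on the forward strand (direct repeats
are strand-symmetric): exact 20-mer matches at separations within the
LTR-start distance window are chained per diagonal and extended by an
X-drop walk (match +1, mismatch −2, N −3, drop 20); pair identity is
then computed on a global Needleman–Wunsch alignment (match +1,
mismatch −1, gap open −5, extend −2), with identity defined as matches
over aligned non-gap non-N columns. TG…CA termini are searched near
the extension boundaries — nominally within ±10 bp, and slightly wider
when a target-site-duplication-validated boundary pair exists there,
since the X-drop endpoint can overshoot a boundary past the nominal
vicinity; the motif must be present on both repeat copies, which
rejects decoy dinucleotides inside the TSD. Candidates must carry
identical 5-bp flanking TSDs.

Overlap resolution keeps a conflict-free candidate set by
minimum-conflict-first greedy (ties: identity, then length, then
leftmost). Preferring low-conflict candidates dismantles chimeras
that pair one element's 3′ LTR with a same-family neighbor's 5′ LTR:
the chimera conflicts with two genuine candidates, each of which
conflicts only with it.

Filters: nested candidates (wholly inside another candidate's
internal region) are marked first, and the outer's excised span —
inner element plus one TSD copy — is removed from its body before the
other checks, so an N-gap inside a nested insertion does not
disqualify its host. Gappy bodies (>50 consecutive Ns) are rejected.
Alignable flanks (global identity of the 50-bp windows upstream of
both LTRs, or downstream of both, above 60%) indicate a tandem gene
duplication; this comparison uses stiff gap penalties (open −10,
extend −6) because permissive gaps let two random 50-mers reach ~60%
"identity" and disqualify genuine elements.

Classification: recent = identity ≥ 90% with the motif; ancient =
75–90% identity (motif not required) and not matching any recent
exemplar at 80% identity / 90% coverage (the masking-exclusion step
that keeps young copies out of the ancient library). Exemplars come
from greedy centroid clustering, longest first, on internal sequences
and then on LTRs for elements without usable internals; pairwise
similarity uses exact local alignment below 1.5 kb and a
seed-and-extend estimate above (exact alignment is quadratic in the
multi-kb regime and the clustering decision needs only coverage and
identity of the matching blocks). Masking lowercases merged
seed-and-extend hits of the full exemplar sequences at ≥80% identity
over ≥100 bp.

Dating applies to full-length, high-confidence elements (recent
class, intact motif, no gap flag): p = mismatches over aligned
non-gap non-N columns of the LTR-pair global alignment,
d = −(3/4)ln(1 − (4/3)p), and T = d/(2μ) — the factor 2 because both
repeats accumulate substitutions independently after insertion. The
default μ = 6.5×10⁻⁹ substitutions/site/year is the neutral plant
rate used for relative timing; p ≥ 3/4 is reported as saturated with
no age. T is exactly linear in 1/μ, so ages under a different clock
are a rescaling.

## Synthetic data (synthdata)

The generators exist to make parameter recovery exact, and sacrifice
sequence realism where realism would blur the planted truth.

**Gene families.** Codon evolution is substitution-count driven. The
ancestral alphabet is restricted to the six "pure fourfold" families
{GCN, GGN, GTN, ACN, CCN, TCN} — codons whose only synonymous
single-nucleotide mutants sit at a fourfold third position — plus
frozen ATG/TGG marker codons (the two zero-synonymous-site codons,
default 25% of positions). Consequences: S is exactly the non-marker
codon count in every derived sequence; synonymous evolution (a
Poisson(Ks·S) number of third-position Jukes–Cantor events, multiple
hits allowed) is exactly the four-state process the NG86+JC estimator
inverts, so the estimator is unbiased for the planted Ks; and
nonsynonymous change — a random walk over single-nucleotide moves
within the family set — can never create a stop, never perturbs the
synonymous site count, and is always nonsynonymous. With an
unrestricted alphabet, twofold-degenerate sites follow two-state
dynamics that the four-state correction misreads (≈ +10% bias at
Ks = 1.1) and nonsynonymous change drifts S; both effects would
corrupt the truth the recovery tests aim at. The price: proteins use
an 8-letter alphabet and realized Ka only approximates
ka_ks_ratio × Ks; Ka is not a recovery target. Markers give related
proteins a conserved backbone (unrelated identity ≈ 12%), so the
40%/100-residue pairing gate separates families cleanly. Each family
has a base gene, a WGD duplicate at divergence `wgd_ks` with
probability `wgd_retention` (default 1.1 and 0.3, the study's
conditions), and Poisson(`background_dup_rate`, default 0.5)
small-scale duplicates at divergences uniform on [0.05, 2.5]. Genes
are 300 codons; background GC is 0.38, mirroring the assembly the
analyses target.

**Gene trees.** Each tree copies the species-tree topology; at each
flagged node, independently per occurrence, the whole descendant
clade is duplicated with the node's probability (defaults 0.34 and
0.19 at the two fern nodes). Truth records every duplication event.

**LTR genome.** Elements are TSD + 5′LTR + internal + 3′LTR + TSD on
an i.i.d. background (GC 0.38), drawn from a small number of
independent ancestral families. Each LTR copy receives a
deterministic round(age × rate × length) count of Jukes–Cantor events
at uniform sites (multiple hits allowed): with a fully stochastic
per-site process, binomial sampling noise alone puts the median
relative dating error for 1-kb LTRs over ages U(0, 7) My near 11%, so
a recovery test would measure simulation noise rather than the
estimator; count-driven planting leaves the estimator's own error
(~2–3% median). The 2-bp termini are excluded from mutation —
integrase function constrains them in real elements — making TG…CA a
structural invariant. Nested insertions splice a younger element,
with its own TSD, into a host's internal region (never through an
LTR); N-gap corruption writes a 60–150-N run into the body; and
tandem-duplication decoys plant two identical TG…CA-bounded gene
copies with matching TSD-like 5-mers and largely shared 50-bp flanks,
but copy-private ~15-bp spacers at the copy boundaries (of unequal
length, keeping the shared flanks off the gene pair's diagonal) so
that extension stops at the copies and the pair survives structural
screening to be caught — exactly — by the alignable-flank filter.

**What passing recovery tests does not show.** Real coding sequences
have indels, heterogeneous codon usage, rate variation, and
alignment error; real repeats have internal deletions, truncated
solo LTRs, and deep family nesting — none of which are modeled. The
validation establishes correctness of the estimators and the
pipeline plumbing under the stated models, not robustness to every
artifact of real assemblies.

## Numerical and interface conventions

Coordinates are 0-based half-open internally; emitted GFF3 is 1-based
inclusive with a version pragma. FASTA is 60-column wrapped,
case-preserving. Tables are headered TSV, UTF-8, "." for missing.
Histogram bins are left-closed right-open except the last, which is
closed, so Ks = 2.1 is counted. All randomness flows from
numpy's `default_rng` seeded from the run configuration; identical
configurations reproduce byte-identical outputs, and every CLI run
writes a provenance record (config, versions, seed). Problem sizes in
the analysis scripts and acceptance checks — 500 families, 2,000 gene
trees, 1-Mb genomes with 50 elements — are chosen so each planted
signal is recovered with comfortable statistical margin while a full
run stays in the minutes range on one core.
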