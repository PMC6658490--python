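# Methods

This note records the models and procedures spidrokit implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open. Every empirical number mentioned here is computed by the test suite
or `scripts/acceptance.py`.

## Sequence model and coordinates

A spidroin is modelled as `NTD + unit × k + CTD`: a tandem array of
"ensemble repeat" units flanked by conserved, non-repetitive terminal
domains. All coordinates in the package are 0-based, half-open. Protein
sequences use the 20-letter alphabet with `X` permitted as an ambiguity
character; `X` is excluded from both numerator and denominator of every
composition, since assembled transcripts routinely contain ambiguous
calls and letting them dilute percentages would bias comparisons.

## Alignment and identity

Pairwise affine-gap alignment (a gap run of length *g* costs
`open + (g-1)·extend`) is delegated to Biopython's `PairwiseAligner`; the
package fixes two parameterisations:

* **domain detection** — BLOSUM62, open −10, extend −1, local mode;
* **identity clustering** — match 1, mismatch 0, open −5, extend −1,
  global mode with free end gaps.

The split is deliberate: a 95%-identity threshold should be a plain
identity fraction, not a similarity-matrix artefact. Percent identity is
`100 × matches / columns` with **end-gap columns excluded** from the
denominator and internal gaps counted as mismatches, so a shorter
full-length terminal domain is not penalised for length differences. The
traceback is the engine's first optimal alignment, which is deterministic;
scores are verified against an exhaustive enumeration oracle for short
sequences in the test suite.

The progressive multiple alignment used for repeat units seeds with the
longest sequence, joins the rest in descending identity-to-seed order
(ties: input order), aligns each joiner to the current profile consensus
under the identity scheme, and propagates gaps ("once a gap, always a
gap"). This is adequate for its one use — near-identical tandem units —
and is not intended as a general MSA.

## Terminal-domain detection and clustering

Detection reports at most one NTD and one CTD per query: the best local
hit against a labelled reference library covering ≥ 60 aligned columns at
≥ 40% identity (spidroin termini are conserved at roughly this level
across genera; both thresholds are configurable). A CTD hit must end
within 5 residues of the sequence end, an NTD hit start within 5 of the
start — terminal domains that are not terminal are treated as absent.

Clustering is greedy longest-first centroid clustering: sequences in
descending full-length order (ties: id) join the first cluster whose
centroid CTD identity is ≥ the threshold (default 95.0, inclusive), else
found a new cluster. The representative is the longest member, ties to the
lexicographically smallest id. Member-to-centroid (not complete-linkage)
is the criterion, matching the semantics of greedy incremental clusterers
used for this job in practice. With within-family pairwise divergence
≤ 2% and between-family divergence tens of percent, cluster count equals
family count (parameter-recovery tests).

## Repeat decomposition

The repetitive region is the sequence minus detected NTD prefix and CTD
suffix; a CTD-only partial transcript (the typical spidroin cDNA) keeps
everything 5′ of the CTD; with no hits the whole sequence is used and
flagged. Period detection scores every candidate period *p* in
`[min_period, len/2]` (default `min_period` 10) by shifted identity —
the fraction of positions *i* with `region[i] == region[i+p]` — and picks
the smallest period within 2 percentage points of the maximum. The window
suppresses the harmonics 2p, 3p, … which score as well as p up to noise;
2 points is a free parameter chosen to exceed plausible score jitter at
2% substitution noise without swallowing genuine sub-periods, and lives in
config. A homopolymer makes every period perfect; the smallest-period rule
then returns `min_period` flagged "degenerate". The scorer is vectorised
but definitionally trivial, and is checked against a character-loop oracle
on every fixture.

Units are consecutive period-length windows from the phase offset (the
offset maximising the number of complete units, ties to the smallest);
flanking partial windows are kept, flagged partial, only when they cover
≥ 50% of a unit — shorter fragments carry little evidence and would
distort per-unit statistics. The consensus is the **modal residue per
column** of the unit alignment, computed over full units only; columns
with > 50% gaps are dropped (a modal residue over mostly-gap columns is
meaningless), and ties go to the alphabetically smallest residue so the
output is deterministic. Units whose length deviates from the modal unit
length are reported as outliers rather than re-segmented; no rule for
delimiting irregular units is claimed.

**Identifiability limit.** With exactly two unit copies, a column hit by
one substitution is a 1-1 tie between the true and the mutant residue; no
consensus rule can recover the truth from the data, and the alphabetical
tie-break is right half the time. Recovery simulations therefore count a
few consensus misses at copy number 2 as expected behaviour: in the
benchmark study (unit length ~ U{10..200}, copies ~ U{2..20}, substitution
rate ~ U(0, 0.02], 100 replicates) unit length is recovered essentially
always, while exact consensus recovery loses ~2–7 replicates to copy-2
ties depending on seed. At 7 copies and 2% noise, recovery is ≥ 99/100.

## Motif grammar and classification

Scanning is greedy left-to-right tiling under the precedence
`VSVVSTTVS > GPGPQ > GPGG > GPGX > poly-A > GGX` (longer and more specific
first), so occurrences never overlap and per-class occupancy — percent of
region residues covered — is reproducible. GPGX restricts X to
{G, S, A, Q}; GGX accepts any X; poly-alanine requires a run of ≥ 4
(the conventional spidroin-literature threshold; configurable). The class
call is gated on the CTD family: for MaSp termini, GPGPQ occupancy ≥ 20%
without poly-alanine ⇒ MaSp4; poly-alanine with GPGX-family motifs ⇒
MaSp2; poly-alanine without ⇒ MaSp1; no poly-alanine with GGX dominant
(greater than every other class) ⇒ MaSp5; else other-MaSp. The 20% and
"dominant" cutoffs are this package's operationalisation of qualitative
motif-combination rules; both sit in config.

## Expression

TPM is computed directly from counts and effective lengths and sums to
10^6 per replicate by construction. The spidroin-specific aggregation
scheme: transcripts with byte-identical CTD coding regions collapse to one
representative trimmed to the 3′-most 500 bases still containing the full
CTD coding region (spidroin cDNAs are 3′-anchored by the poly-A tail; a
flag switches ends); TPM is then summed over ≥ 95%-identity CTD clusters,
and spidroin shares are percentages over spidroin clusters only.
Quantification from raw reads (quasi-mapping, equivalence-class EM) is out
of scope; synthetic counts stand in for a quantifier's output.

## Composition prediction

Predicted fiber composition is residue-fraction averaging weighted by
abundance share: `pred_r = Σ_i w_i · percent_{i,r}` with weights
normalised aggregated TPM. Length weighting (`w_i ∝ TPM_i × length_i`) is
available as a switch for sensitivity analysis; the default is the plain
abundance reading. Comparisons to acid-hydrolysis data pool Q+E as Glx
and N+D as Asx, since hydrolysis cannot distinguish them; concordance is
Kendall's τ over the measured top-5 residues. Recovery tests compare the
prediction from computed TPM shares with the truth-weighted mixture over
the same cluster profiles, so the only discrepancy is the multinomial
count draw; its delta-method SD (propagated through the TPM-share map)
sets the 3-SD tolerance.

## GOR secondary structure

GOR-I scores state *s* at position *i* as
`Σ_{d=-8..8} I_s(residue_{i+d}, d) − DC_s` over in-bounds offsets, calling
the argmax with the fixed tie order helix > sheet > turn > coil; decision
constants default to 0. The bundled table
(`data/gor_tables_synthetic.tsv`) is **synthetic**: it has the exact GOR-I
shape (4 states × 20 residues × 17 offsets, centinats) but is constructed
from canonical residue conformational propensities with a distance-tapered
window (half-width 9 for helix/sheet, 5 for the locally determined
turn/coil), not transcribed from the historical tables. Predictions are
therefore qualitatively GOR-like — poly-alanine reads helical, GPG-rich
repeats turn-rich, and the MaSp4-style GPGPQ consensus scores more turn
than a MaSp2-style unit — and fully deterministic, but absolute fractions
are not comparable with outputs of historical GOR-I implementations. The
loader validates table completeness; `build_synthetic_tables()`
regenerates the file; any table of the same shape can be supplied instead.

## Morphometry

Summaries are mean ± sample SD (n−1); two-group comparisons use the
Student pooled-variance two-tailed t-test (via
`scipy.stats.ttest_ind_from_stats`). Pooling rather than Welch was chosen
because recomputing the reference cross-species duct-length comparisons
from their printed n/mean/SD reproduces both published t statistics to
four decimals under pooling and under Welch does not. Duct/sac ratios are
computed per individual and then summarised; single-individual groups are
flagged untestable.

## Synthetic data: what it does and does not show

The generator emulates: motif-grammar-built units per spidroin class
(including a 63-residue GPGPQ-dominated MaSp4-style unit at ~48% GPGPQ
occupancy), family-specific CTDs with controlled within- (default 1%) and
between-family (~25% from a shared base, ~50% pairwise) divergence,
i.i.d. substitution noise on the repetitive region (default 1%),
fixed-codon back-translation, class-scaled log-normal abundances
(MaSp2 > MaSp1 > MaSp4 ≫ MaSp5 > non-MaSp, mirroring major-ampullate
expression structure), and multinomial counts with probability ∝
abundance × length. It does **not** emulate indels, codon usage,
read-level error, chimeric or fragmented assemblies, or genuinely novel
motif vocabularies. Passing recovery tests therefore demonstrates the
machinery is correct under substitution noise and known families; it does
not certify performance on assemblies whose artefacts include indels or
fragmentation, nor that the bundled terminal library (also synthetic,
hand-composed spidroin-flavoured sequences) detects real termini.

## Problem sizes and degenerate inputs

Recovery studies run at 100 replicates (repeats), 50 transcripts × 10^6
reads (expression), and 15 transcripts × 10^6 reads (composition) —
desk-scale sizes at which the quantities of interest are already stable.
Degenerate inputs are handled explicitly: empty FASTA files are valid and
empty; all-zero count libraries, empty alignments spans, single-unit
regions, and zero-pooled-variance equal-mean t-tests raise typed errors;
homopolymer regions are flagged degenerate rather than assigned a
fictitious period.
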