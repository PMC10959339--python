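# Methods

## The substitution model

The QTY code is a fixed map over TM-helix residues: L→Q, V→T, I→T, F→Y; the
reverse code is Q→L, T→I, Y→F. Both are applied only inside annotated
TM_HELIX segments (a `tm_only=False` escape hatch applies them
whole-sequence and is labelled non-canonical). The forward map's image
{Q, T, Y} is disjoint from charged residues, so the design never changes the
ionizable inventory except by adding tyrosine, whose pKa (10.0) is far from
the pI of a typical transporter — this is why QTY variants keep their
isoelectric points nearly unchanged. The reverse of T is I, not V, because
only T↔I is reachable by one nucleotide substitution.

Variation statistics are `100 × TM events / TM residues` and
`100 × events / length`, rounded half-up to two decimals. Note the mass
consequences of the forward map are not uniformly positive: L→Q (+14.97 Da),
V→T (+1.97 Da) and F→Y (+16.00 Da) add mass, but I→T loses 12.05 Da; a net
MW increase for a real transporter reflects its particular TM composition,
not a per-substitution invariant.

## Topology model and region naming

Topologies are sets of non-overlapping 1-based inclusive segments
(TM_HELIX / EXTRACELLULAR / CYTOPLASMIC), UniProt-style. Region resolution
numbers TM helices TM1..TMn by sequence order. Loops between consecutive
helices take their side from any covering EXTRACELLULAR/CYTOPLASMIC
annotation, otherwise by alternation from the previous loop; each side
numbers its loops independently (ECL1, ICL1, ...). Residues before the first
helix with cytoplasmic annotation are N_TERM, after the last C_TERM;
anything else is UNANNOTATED. Summary counts treat UNANNOTATED as "outside
TM", and N/C termini as cytoplasmic (true for these transporters). In the
packaged variant table, locations printed as bare "Intracellular" are
resolved to N_TERM when the structure column reads "N-coil" and to C_TERM
otherwise; the choice only affects terminus naming, never TM membership.

## Physicochemistry

Average residue masses and one water per chain (Expasy-compatible table).
Net charge at a given pH sums Henderson–Hasselbalch terms for the
N-terminus, H, K, R (positive) and C-terminus, D, E, C, Y (negative) with
the Bjellqvist pKa set, including its residue-specific terminal overrides;
cysteine is treated as ionizable with no disulfide correction. The pI is the
bisection root of the charge curve on [0, 14] to 0.001 pH; it is validated
in tests against a 0.001-step grid scan and against an independent
implementation of the same pKa model. Display rounding: kD to one decimal,
pI to two.

## Codon space

The standard genetic code (RNA alphabet; DNA input transcribed). Minimum
nucleotide distance between amino acids is the Hamming minimum over their
codon-set product; single-step paths enumerate all distance-1 codon pairs
with position, base change and transition/transversion class (purine↔purine
or pyrimidine↔pyrimidine = transition). Second-position chemistry classes
follow the canonical grouping (U hydrophobic; C less hydrophobic/hydroxyl;
A hydrophilic; G special), with serine's split codon family reported under
both of its second-position bases. No mutation-rate model is implemented:
statements like "transitions outnumber transversions" are consumed as
background, not computed.

## Variant classification and summaries

Variants parse from compact (`I136T`) or HGVS three-letter (`p.Ile136Thr`)
protein notation. Direction is QTY for (L,Q), (I,T), (V,T), (F,Y); RQTY for
the reverses (including the never-observed (T,V)); OTHER otherwise;
single-SNV accessibility comes from the codon module, so V↔T is the one
mapped pair flagged inaccessible. Effect categories (benign / possibly
damaging / probably damaging) are consumed as given — the upstream
predictor is not re-implemented — and "benign" fractions use the strict
BENIGN category only. "Helical" in summaries means α-, 3/10- or π(5)-helix.
Percentages are reported to one decimal.

The packaged table transcribes the published annotations for the seven
human transporters as printed, including one internally inconsistent row
(DAT T46I located TM9 but structured N-coil) and the one common variant
(VMAT1 I136T, allele frequency 0.728) among 88 rare ones.

## Mutation libraries and score summaries

A library holds all 19 substitutions per selected residue; the default
selector takes every TM-helix position with residue in {L, I, V, F} (the
candidate alphabet is a parameter). Comparator groups are fixed data, not
derived from a polarity predicate: forward L→{D,E,R,K,H,N,S,T,Y},
I→{D,E,R,K,H,N,S,Q,Y}, F→{D,E,R,K,H,N,S,T,Q} (V follows the I pattern);
reverse uses the nonpolar set {A,C,G,I,L,M,F,P,W,V} minus the rQTY target.
Scores live in [0, 1] with "higher = more damaging" semantics. Because such
score distributions are strongly bimodal (a Shapiro–Wilk gate in the tests
rejects normality on ~900 spiked scores), groups are summarized by median
and IQR with type-7 (linear-interpolation) quartiles.

## Statistics

Spearman ρ uses average ranks and the t-approximation p-value. The partial
Spearman coefficient is the standard first-order construction on Spearman
correlations, ρ_xy·z = (ρ_xy − ρ_xz ρ_yz)/√((1−ρ_xz²)(1−ρ_yz²)), with
n − 3 degrees of freedom; it is cross-checked in tests against an
independent partial-correlation implementation. Wilcoxon signed-rank drops
zero differences and switches from the exact null to the
continuity-corrected normal approximation above n = 25. Bootstrap CIs are
95 % percentile intervals (not BCa — simpler and exactly reproducible) over
a seeded generator; no library-global RNG is ever used.

## Alignment pair analysis

For a residue pair, each alignment column with non-gap occupancy ≥ 0.5
(configurable) contributes the two members' frequencies among non-gap
characters, so x + y ≤ 1 per column. Conservation enters either as ConSurf
grades (1–9, consumed from file, never recomputed) or as the internal
fallback 1 − normalized Shannon entropy of the column composition, clearly
tagged as such. The pair correlation reports ρ, the partial ρ given
conservation, and a bootstrap CI over columns. Columns are treated as
exchangeable observations; no phylogenetic correction is attempted, and the
monotonicity assumption behind rank correlation is an assumption, not a
finding — results carry no causal language.

## Structure superposition

CA-only Kabsch superposition: center both matched sets, SVD of the
covariance, sign-correct the smallest singular direction so the rotation is
proper (det = +1), then RMSD over all pairs. There are no outlier-rejection
cycles, so the fit is deterministic and directly comparable against
independent optimizers (tests verify agreement with an SVD-free numerical
rotation search and with a second Kabsch implementation). Near-collinear
point sets are rejected since the optimal rotation is not unique. Trimming
of termini/large loops is explicit, by user-supplied residue ranges.
Published RMSD values for predicted-structure pairs depend on the structure
generator and its alignment protocol and are not reproduced here; with
user-supplied model files the pipeline computes comparable values.

## Synthetic-data generators

All generators take an explicit seed and are byte-deterministic under it.

- **Toy transporter**: alternating loop/TM layout (default 12 TM helices of
  21 residues, 10-residue loops, cytoplasmic N-terminus — the transporter
  architecture). TM positions are L/I/V/F with probability
  `hydrophobic_frac` (default 0.5, the order of magnitude of real TM
  hydrophobic content) and otherwise drawn from residues outside both QTY
  maps so planted substitution counts are exact; loops are uniform over all
  20 residues.
- **Variant tables**: planted QTY/rQTY/other counts (defaults 47/42/0,
  the composition of the natural set) at eligible positions, with
  locations from the topology and effects from a fixed categorical
  distribution.
- **Score tables**: Beta distributions parameterized by (median,
  concentration) via numeric inversion of the median, defaults 0.3 for
  QTY targets vs 0.9 elsewhere — a planted version of the "QTY
  substitutions score less damaging" effect with recoverable medians.
- **Alignments**: per column, a conservation latent c ~ U(0,1) and a
  coupling latent drive the two pair-member frequencies (coupling sign and
  strength planted; confounder weight `confounder_strength`); rows are
  i.i.d. draws from the column distribution. Columns are independent — no
  phylogeny — because the analysis under test treats columns as
  exchangeable.
- **Coordinates**: an idealized α-helical arc (2.3 Å radius, 1.5 Å rise,
  100°/residue, gentle bend to avoid collinearity) and a rigidly
  transformed copy with isotropic Gaussian noise; the expected post-fit
  RMSD is √3·σ.

What passing these tests shows is that each stage recovers structure it is
designed to detect under its own assumptions; it does not show that real
alignments are column-exchangeable, that real effect scores are
Beta-distributed, or that real topology annotations are error-free.

## Problem sizes and numerical choices

Test and acceptance runs use synthetic problem sizes chosen to make planted
effects statistically unambiguous while keeping runs fast: 500 residues per
score-table recovery (median tolerance ±0.05), 400–500 alignment columns
for coupling-sign recovery, 200 points for noise-RMSD checks, 500–1000
bootstrap replicates. The pI bisection tolerance is 0.001 pH; quartiles are
type 7; percentage rounding is half-up to two decimals (variation) or one
decimal (summary percentages).

## Known limitations

- Real UniProt sequences/topologies are not vendored; accession-dependent
  numbers (e.g. subject MW/pI, the 861-residue TM census) require the
  pinned fetch helper and depend on the annotation release.
- The pI model ignores disulfides, phosphorylation and electrostatic
  interactions between sites; it matches the classic single-site model, not
  experiment, to ~0.1 pH at best.
- Effect-score semantics are taken on faith from the upstream predictor;
  the package never judges pathogenicity itself.
- The alignment analysis measures monotone association only; confounder
  removal by partial rank correlation is first-order and cannot rule out
  nonlinear or phylogenetic confounding.
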