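# Methods

This note documents the models, parameter choices and numerical conventions
behind `primerpanel`, and what the synthetic-data tests do and do not
establish about real data.

## Thermodynamic model

**Duplex Tm.** Melting temperatures come from the unified nearest-neighbor
parameter set (the Allawi & SantaLucia dinucleotide ΔH°/ΔS° values with
duplex-initiation and terminal-A·T corrections). The two-state Tm at 1 M
Na+ is ΔH°/(ΔS° + R·ln(C_T/4)) for a non-self-complementary duplex with
primer and complement each at `oligo_conc_uM` (C_T is the total strand
concentration, hence the factor 4). The monovalent-salt dependence is the
Owczarzy (2004) correction applied to 1/Tm using the oligo's GC fraction.
Divalent cations are folded into an effective monovalent concentration by
the von Ahsen square-root equivalence; this is a documented stub, off under
the defaults (0 mM Mg²⁺), not a validated Mg²⁺ model.

**Conditions.** The defaults — 0.25 µM oligo, 50 mM monovalent, 0 mM
divalent, ΔG reported at 37 °C — mirror the defaults of common
oligo-analyzer tools. Published primer-table Tm values rarely state their
conditions; under these defaults the packaged panel's eight non-degenerate
printed Tm values are reproduced within about 1 °C, and the test suite
asserts ±1.5 °C. The implementation agrees with Biopython's independent
nearest-neighbor routine to ~1e-13 °C under matched settings, which the
tests use as a cross-check oracle; the package's own summation is the
implementation.

**Degenerate primers.** A degenerate oligo's Tm is summarized over its
expansions (min/mean/max). Patterns with more than 4096 expansions are
subsampled (1024 draws, fixed internal seed) — the degenerate universal COI
barcode primers have degeneracies of 1024–2048, so they are still expanded
fully. Filtering decisions use the *minimum* Tm over expansions: the
worst-case variant is the one that fails to anneal first.

**Hairpin screen.** Criterion (3) of the design evaluation screens
self-structure with a deliberately coarse model: simple stem-loops only
(Watson–Crick stems ≥ 2 bp, loops ≥ 3 nt; no bulges, internal loops or
dangling ends). ΔG is the sum of stem stacking energies at 37 °C plus a
tabulated hairpin-loop initiation penalty (interpolated between tabulated
sizes, log-extrapolated beyond 30 nt). The reported value is the minimum
over all decompositions, or 0 when no stabilizing (ΔG ≤ 0) structure
exists. A candidate passes iff min ΔG ≥ −1.0 kcal/mol. The published
criterion this operationalizes ("hairpin ΔG less than 1 kcal/mol") is
sign-ambiguous; the chosen reading — no hairpin more stabilizing than
−1 kcal/mol — is a design decision, configurable via
`DesignCriteria.hairpin_dg_threshold`. The model's exhaustive enumerability
is the point: tests verify it against a brute-force enumerator on hundreds
of random oligos.

## Alignment, identity and trees

Global alignment is Gotoh's three-state affine-gap DP (match +1,
mismatch −1, gap open −2, gap extend −0.5 by default; a gap run of length k
costs open + (k−1)·extend). The row recurrences are numpy-vectorized, with
the horizontal gap state computed by a prefix-max transform. Traceback
tie-breaks deterministically: diagonal, then up, then left. Degenerate
IUPAC codes score as a match iff their base sets intersect.

Percent identity is computed after optimal global alignment. The default
denominator excludes terminal gap runs (a fragment against a full-length
marker is scored over the overlap); `all_columns` mode counts everything.
Because co-optimal alignments can differ in identity, the input pair is
canonicalized (lexicographically smallest of the swapped/jointly
reverse-complemented variants) before aligning, making identity symmetric
and strand-invariant by construction. Published inter-species similarity
percentages computed with unstated software conventions should therefore be
expected to differ from these values at the margin; both column-counting
modes are provided.

Distances are p-distances (1 − identity/100). Neighbor joining is the
standard agglomeration with negative branch lengths clamped to zero and
Q-criterion ties broken by label order (runs are deterministic). On
additive matrices NJ is exact, which the tests exploit: 50 random binary
trees (5–8 leaves) are recovered with Robinson–Foulds distance 0 and exact
path lengths. scikit-bio's `nj` serves as an independent oracle on generic
matrices; trees serialize to Newick via scikit-bio's `TreeNode`.

A `reference_anchored_alignment` projects every sequence onto one
reference's coordinates (deletions become gaps; insertions relative to the
reference are dropped and counted in a warning). This is *not* a multiple
aligner: it is adequate for barcode markers where indels are rare, and
externally aligned FASTA bypasses it untouched.

## Diagnostic windows and the seven-factor evaluation

Column profiles record exact per-species base frequencies over
{A, C, G, T, gap}, with degenerate codes contributing fractional weight. A
window qualifies for a target species when (i) every column's target
majority-base frequency meets `min_conservation` (default 0.9) and is not a
gap, (ii) the target consensus differs from *every* non-target consensus at
`min_mismatch_per_nontarget` columns or more (default 2; gap columns never
count as discriminative), and (iii) the 3′-terminal `three_prime_k` columns
(default 3; rightmost for forward sites, leftmost for reverse sites, which
prime leftward after reverse-complementing) contain at least
`min_specific_in_3prime` target-specific columns (default 1). Mismatches
are counted against the non-target *consensus* (species-level design, one
row per species), matching how diagnostic alignments are read; a
raw-sequence re-check is exercised in the tests. Ranking is a total order:
total mismatches, then 3′-specific count (both descending), then leftmost
start, width, and strand role. The published criteria quantify neither the
3′ window nor the mismatch minimum; these defaults are declared choices.

Candidates are all sub-slices of qualifying windows within the length
bounds (reverse-site candidates emitted reverse-complemented, 5′→3′ as
synthesized). The seven factors measured per candidate: length in
[18, 33] bp; 3′-specific count; hairpin min ΔG; GC in [35, 60] %;
discrimination (worst-case per-non-target consensus mismatches); false
priming (best full-length ungapped match identity against any non-target
sequence on either strand — fail at 100 %, i.e. a perfect match, the
weakest reading consistent with specificity; threshold configurable
downward); and Tm compatibility (|Tm − Tm(universal partner)| ≤ 5 °C,
degenerate partners scored at their minimum-expansion Tm). The overall
verdict is the conjunction; tightening any single threshold can only shrink
the passing set (tested as a monotonicity property). Length bounds with
min > max are permitted and diagnosed at assembly as a universal length
failure, so impossible criteria fail loudly rather than silently.

Panel assembly restricts candidates to the interior of the universal
amplicon (so every specific product nests inside the universal product, as
published product sizes imply; overridable), walks candidates in rank
order, and accepts the first that passes all factors, amplifies every
target sequence, and amplifies no non-target sequence. The assembled panel
is finally re-validated as a full specificity matrix and rejected on any
cross-species cell.

## In-silico PCR

Matching is IUPAC set-intersection on 4-bit base masks (degenerate codes on
either side match iff their sets overlap), scanned naively in O(n·m) with
numpy sliding windows — templates are barcode-sized, so no index is
needed. Coordinates are 0-based half-open on the template top strand;
rendered reports are the only place 1-based coordinates appear. The default
`MatchPolicy` allows 2 total mismatches but none in the 3 terminal 3′
bases — a single 3′-terminal mismatch kills a site, reflecting polymerase
extension chemistry.

**Terminal truncation.** Deposited barcode sequences are often partially
primer-trimmed amplicons. By default a primer's 5′ tail may overhang a
template end, with the overhang uncounted as mismatches and counted into
the product length, so a partially trimmed amplicon still reports the full
published product size. The 3′ anchor (the policy's 3′ window) must always
lie on the template: without that constraint any primer whose terminal base
happened to match a template edge would "bind". A consequence worth
stating: a *fully* primer-trimmed deposit (no footprint bases at all)
cannot anchor either primer and reports no product — there is no sound way
to distinguish it from an unrelated sequence end.

Product length is reverse-site end minus forward-site start (both primer
footprints included). Classification runs every panel pair on a sample's
sequences: exactly one amplifying pair calls the species, zero calls
`none`, more than one calls `ambiguous`.

## Synthetic data

The generator emulates a multi-species barcode study: a uniform-random
ancestor of 450 bp (a 16S-like fragment; 700 for COI-like), three species
by default, four sequences per species, conserved 25 bp flanks at both ends
carrying verbatim-planted universal primer sequences, and Jukes–Cantor
substitutions applied site-wise by the exact transition probability —
0.10 expected substitutions/site on each species branch, 0.005 within
species. These rates place inter-species identity near 85–90 %, the regime
reported for congeneric box jellyfish barcodes, with within ≪ between.
Species sit on a star phylogeny by default; a two-clade mode places the
first two species on a shared internal branch to emulate nested clusters.
All draws flow from one seeded generator, so outputs are byte-reproducible.
`between_divergence=0` is permitted (species identical up to within-noise)
for degenerate-case testing.

Held-out samples for classification are modeled as DNA *extracts*: small
pools of template molecules (3 by default) drawn fresh around the true
species consensus. A PCR reaction amplifies if any template copy in the
tube primes, so a private mutation in one molecule's 3′ priming window does
not fail the assay. With single molecules instead of pools, measured
classification accuracy is ~97–99 %: roughly 1 % of single molecules carry
a private mutation inside a specific primer's zero-tolerance 3′ window.
The pooled model is the biologically faithful one; the single-molecule
number is the honest floor.

**What the simulations do not show.** Jukes–Cantor has no
transition/transversion bias, no rate heterogeneity across sites, no
indels, and no sequencing error; flanks are perfectly conserved, so
universal primers always bind exactly. Real markers violate all of these.
Passing the simulated end-to-end sweep (panel designed, specificity matrix
diagonal, held-out extracts classified correctly in ≥ 18/20 seeds)
demonstrates the pipeline's internal correctness and statistical behavior
under its stated model — not that any particular designed panel will work
at the bench, which requires the wet-lab validation this package
deliberately does not model (gel electrophoresis outcomes and the qPCR
sensitivity limit are carried as metadata only, e.g.
`QPCR_SENSITIVITY_LOD_NG = 0.01`).

## Numerical and interface conventions

- Ties everywhere break deterministically (alignment traceback: diagonal >
  up > left; NJ: label order; window ranking: the total order above), so
  identical inputs and seeds give byte-identical outputs.
- Floating-point score comparisons in traceback use a 1e-9 tolerance;
  distance-matrix symmetry is validated with `allclose`.
- Reverse primers are stored 5′→3′ as synthesized (reverse-complement of
  the template top strand); template-strand arithmetic happens only inside
  the in-silico PCR module.
- FASTA headers follow `id|species` (regex-configurable); records without
  the separator are labeled `unknown`.
- Primer tables cross-check the printed `Length` column against the
  sequence and reject on mismatch — the most common transcription error in
  published primer tables.
- When a flat primer table is reloaded as a panel, species-specific primers
  pair with the *last* universal primer of opposite orientation in table
  order; published panels list the shared group-level partner after the
  outer universal pair, and design-written tables have one partner per
  orientation, so the rule covers both.
- CLI exit codes: 0 success, 1 usage/IO error, 2 design infeasible (with a
  per-factor failure summary on stderr). Logs go to stderr, data to files.

## Problem sizes used in the test suite

Simulated sets are 3 species × 4 sequences × 450 bp. The end-to-end sweep
runs 20 seeds with pooled held-out samples (100 samples per species on one
seed, 10 on the rest). Exhaustive oracles run where exhaustion is feasible:
all global alignments for string lengths ≤ 8 (200 random pairs), all
stem-loop decompositions for oligos ≤ 14 nt (200 random cases), 50 random
additive trees for NJ. These sizes were chosen so each oracle remains a
genuinely independent enumeration while the whole suite stays fast enough
to run on every change.
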