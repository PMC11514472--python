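# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `hic-curator`, and what the synthetic validation does and
does not demonstrate.

## Coordinate conventions

All genomic coordinates are zero-based, half-open, in bp. A contact-matrix
bin `b` at resolution `r` covers `[b·r, (b+1)·r)`; a matrix for genome length
`L_g` has `⌈L_g/r⌉` bins per side. Assembly coordinates are the gapless
concatenation of fragments in layout order — gaps (`N` runs) exist only in
FASTA output, matching the contact map, which knows nothing of gaps.
Fragment names carry provenance as `contig:start-end` (native, zero-based,
half-open); splits rewrite both halves' ranges, so any fragment in any edited
document can be resolved back to a slice of the input contigs. This
provenance is what lets the synthetic map provider regenerate a contact map
for an arbitrarily edited document, and what the edit-conservation tests
check (re-sorting fragments by provenance and clearing orientations must
rebuild the input contigs byte for byte).

## Contact store and rendering

Contact counts are stored raw (no balancing or normalisation); matrices must
be symmetric within 1e-9 and non-negative. The on-disk archive is a directory
with a JSON manifest plus one little-endian float32 row-major matrix per
resolution — deliberately trivial, desk-scale, and dependency-free. Readers
for the compressed `.hic` ecosystem are not included.

Quantiles use the 1-based rank convention `k = q·n` on the ascending sort,
returning the order statistic when `k` is integral and linearly interpolating
otherwise (`k < 1` returns the minimum). This equals the Hyndman–Fan type 4
estimator, which the tests exploit as an independent oracle
(`numpy.quantile(..., method="interpolated_inverted_cdf")`).

Tiles hold normalised intensity `min(v, ceiling)/ceiling` as floats; the
white→red ramp (R fixed at 255, G and B falling linearly to 0) is applied
only when writing PNGs, so rendering is exactly reproducible and the tests
compare float grids, not quantised colour. The colour ceiling is the 95th
percentile of each tile's own values; for the global chromosome-assignment
tile the stated convention is Q95 of the whole-genome matrix, and we apply
the same per-tile rule to detection tiles because no separate rule is stated
for them. An all-zero tile falls back to a ceiling of 1.

## Sliding windows

Window length is `700·r` and step `400·r`, giving a 300-bin overlap between
consecutive windows. Windows are generated while their start lies inside the
genome and the last window is clipped at `L_g`, which guarantees the union of
windows is exactly `[0, L_g)` — the property test checks this for arbitrary
`(L_g, r)`. Detection drops any box touching an interior tile edge: the
300-bin overlap guarantees a neighbouring tile sees the same error whole, so
clipped partial detections would only create duplicate, truncated calls.

## Detector contract and call handling

A detector is any callable `Tile -> [Box]` with boxes in pixel space
(top-left origin, corner-encoded, score in [0, 1]). Pixel corners map to bp
by linear interpolation between the tile's genomic window and its pixel
dimensions, rounded to the nearest bp. Since tiles are rendered at one pixel
per bin, the map is exact up to one bin.

Calls are deduplicated across windows and resolutions by transitive
clustering on genomic-rectangle IOU (default threshold 0.5); each cluster
keeps the highest-scoring call, ties broken by larger area then smaller
start. The default length filter (50 kb minimum, unbounded maximum) reflects
typical map resolutions where sub-bin calls are noise; runs on the synthetic
genomes use a 1 kb minimum instead, since their misjoined pieces are 10–50 kb.
Correction acts on the x-axis interval of each call; the y interval is kept
for diagnostics.

## Peak algorithm

The search resolution minimises `|error_length/3 − R|` (ties to the smaller
R): roughly three bins per error balances profile detail against noise. The
error's column strip against the whole genome is extracted; each error-bin
profile is scanned with `scipy.signal.find_peaks` at height `Peak95` (95th
percentile of the strip) and minimum separation equal to the error's width in
bins. Indices inside `[⌊E_s/R⌋−2, ⌊E_e/R⌋+2]` are vetoed (the error's own
rows are trivially its best contacts); the most frequent surviving bin wins,
with ties broken by larger summed strip contact and then smaller index, and
the insertion site is `i·R` (the standard bin-index → coordinate map).

Three completions handle cases the bare recipe cannot:

1. **Resolution fallback.** When every candidate is vetoed — typical for a
   block displaced by only a few bins, where the exclusion band covers its
   true home — the remaining resolutions are tried finest-first, because the
   band's width in bp shrinks with the bin size.
2. **Edge bins.** `find_peaks` never reports array endpoints, so an insertion
   at a genome terminus would be invisible; the first/last genome bin is
   admitted as a candidate when it strictly dominates its inward neighbour.
3. **Fine refinement and snapping.** A coarse winning bin can contain more
   than one fragment boundary. The vote is therefore repeated at the finest
   resolution and kept when it confirms the coarse neighbourhood; the final
   bin-quantised site is snapped to the nearest fragment boundary, measuring
   distance against the whole winning bin (a boundary inside the bin always
   wins) with a tolerance of 2 bins. Without snapping, a bin-rounded site
   could never restore an exact layout.

## Iterative correction

Edits within one iteration are planned against the iteration-start map:
insertion sites are computed first in that frame, then edits are applied in
ascending coordinate order, with every still-pending call interval and
insertion point remapped through each applied edit's piecewise coordinate
shift (moves shift the span between source and target; inversions reflect
inside the block). Planted events are fragment-disjoint, so an interval never
straddles a shifted region; a call that an edit has nevertheless torn apart
is deferred to the next iteration. The map is regenerated between iterations
through the `map_provider` contract — production re-alignment of Hi-C reads
is explicitly out of scope; the synthetic provider recomputes the model map
from fragment provenance, which is exactly what a re-alignment would measure
under the same contact model.

The loop stops when no translocation or inversion calls remain, at
`max_iterations` (default 5), or aborts with a diagnostic after
`stall_patience` (default 2) iterations without a falling error count —
unbounded iteration is unsafe with imperfect detectors. Debris calls are
skipped by default (`debris_mode="skip"`): debris signal is of debated origin
and relegating it is an opt-in (`"adjust"`), which appends the block to a
trailing leftover scaffold.

## Synthetic data generator

The generator emulates the conditions the curation loop faces in practice:

- contigs of uniform random length (default 2–3 contigs of 100–500 kb at
  test scale) with i.i.d. bases at a target GC;
- every contig cut into pieces uniform in 10–50 kb (the last piece of a
  contig may be shorter);
- 60% of pieces selected without replacement; each is either moved to a
  uniformly chosen foreign boundary (translocation) or sign-flipped in place
  (inversion), equiprobably — the move/flip split is our choice; an optional
  debris mode instead zeroes the piece's contact rows/columns;
- expected contacts `s0·(1 + d)^(−α)` with `α = 1`, `s0 = 100`, where `d` is
  the separation in bins of the two bins' *true* genomic positions, times an
  inter-chromosome attenuation of 0.1; optional Poisson sampling. Power-law
  decay with exponent ≈ 1 and strong territory separation is standard Hi-C
  phenomenology; `s0 = 100` keeps Poisson noise at the few-percent level near
  the diagonal, comparable to a well-covered experiment.

Bins take the true position of their centre, so planted inversions produce
anti-diagonal butterfly blocks and translocations off-diagonal bands by
construction. All randomness flows through explicit seeds; every fixture is
a generator call, not a stored file.

The oracle detector emits one perfect box (score 1.0) per event visible in a
tile, using the exact inverse of the pixel→bp map. Across iterations it
re-derives the event list from the current document by anchoring the longest
strictly-increasing subsequence of true start positions over
forward-oriented fragments: non-anchor fragments are inversions when only
their orientation is wrong, translocations otherwise. This diff stays
truthful after partial corrections, where a frozen event list would go stale.

What passing these tests shows: the geometry of the whole pipeline —
tiling, coordinate mapping, peak search, editing, assignment, reporting — is
exact and self-consistent, and insertion-site recovery tolerates Poisson
counting noise. What it does not show: robustness to the biases of real maps
(restriction-site density, mappability, repeats, balancing artefacts,
structural heterozygosity) or to the miss/false-alarm profile of a trained
detector; those enter only through the `Detector` and `map_provider`
contracts.

## Validation scale and measured behaviour

The acceptance suite runs, on one CPU in well under a minute: 1 000-instance
randomized oracle checks per closed-form operation (tolerance 1e-12);
structural fuzzing of the `.assembly` round trip and edit conservation; 100
noisy single-translocation genomes (~0.9 Mb, resolutions 5/10/25/50 kb) for
insertion-site recovery within ±2 bins; 60 end-to-end runs (1, 2 or 5 mixed
events × 20 seeds) checking exact layout restoration and non-decreasing
Pearson correlation between the regenerated and clean maps; and 3-chromosome
assignment recovery within ±1 global bin. These sizes keep every signature
several bins wide at the finest resolution while the full suite stays fast.

Known failure modes, visible in `scripts/acceptance.py` output at some seeds
(~5% of end-to-end runs): a tail piece shorter than the finest bin cannot be
localised by the peak search (its call is skipped, or filtered when below
the length filter), and a block displaced by less than the exclusion-band
width at every resolution has no admissible peak. Both are inherent limits
of bin-level localisation, not of the implementation.

## Report conventions

`R_error`, `R_translocation` and `R_inversion` share one denominator (the
corrected genome length excluding redundant sequence) so the decomposition
`R_error = R_translocation + R_inversion` holds exactly; the variants against
the uncorrected genome size are reported separately with their denominator
labelled, since both conventions circulate. The CC ratio follows the formula
`N_scaffolds/N_chromosomes` (not "chromosome pairs"). GC content counts
unambiguous ACGT bases only. The error-adjustment section exhibits the five
longest calls per category (all when fewer). The JSON schema is versioned and
round-trips losslessly; HTML references only local assets and renders
placeholders with a warning for missing images.

## Other design choices

- Edits never mutate documents; every operation returns a new `AssemblyDoc`,
  enabling a per-iteration audit trail.
- `make_genome` emits a single-scaffold document concatenating all contigs —
  the merged "assembly axis" view a scaffolder hands downstream — which
  chromosome assignment later cuts apart.
- Default FASTA gap is 500 Ns (configurable), the common scaffolding
  convention.
- Chromosome output is ordered genomically; the y-span of chromosome boxes is
  ignored (territories are diagonal blocks).
- Candidate-assembly selection counts only translocations and inversions;
  debris and chromosome boxes are not errors in this sense.
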