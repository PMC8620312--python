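# Methods

## Barcode model

A genome's barcode at a specificity level is the set difference between
its own k-mer set and the union of k-mer sets of an exclusion class:

* **genus** — all plasmids, all host sequences, and every genome whose
  genus label differs from the target's;
* **species** — additionally every other species of the genus;
* **strain** — every genome in the collection except the target itself
  (plus plasmids and host).

Plasmid sequences are excluded wholesale, including the target's own:
plasmids move horizontally, so their k-mers are unreliable markers of a
chromosome's identity.  Host entries (e.g. a human genome) exist so that
barcodes used on host-derived metagenomes cannot count host reads.
Because the exclusion classes are nested, barcodes are nested too
(strain ⊆ species ⊆ genus); this is asserted by property tests on random
collections.

Set subtraction streams one exclusion sequence at a time and never
materialises the exclusion union, so memory scales with the target's
k-mer set rather than the collection; because subtracting a union equals
iterated subtraction, the result is independent of processing order
(tested by permuting collections).  A separate in-package brute-force
enumerator (`brute_force_barcode`) and fully independent oracles in the
test suite pin down the semantics on small inputs.

### K-mer extraction

* *k* = 18 by default: long enough that random collisions are negligible
  against bacterial databases (4¹⁸ ≈ 6.9 × 10¹⁰), short enough to be
  robust to sequencing error at read scale.
* **Canonical mode** (default on) stores min(word, revcomp(word)).
  Shotgun reads come from either strand, so strand-agnostic matching is
  the right default for profiling; `canonical=False` gives literal
  single-strand matching for workflows that digitise one strand only.
  Both modes are tested; canonical barcodes are invariant under
  reverse-complementing every input (tested).
* **Degenerate bases**: any window containing a symbol outside A/C/G/T is
  skipped, rather than erroring or dropping the whole record.  Whole-read
  quality trimming is deliberately out of scope; the profiler applies
  only a minimum-length cutoff (20 b default) and the same window rule.

Internal representation is plain Python strings in hash sets; only set
semantics are contractual, and at the problem sizes the package targets
(tens of genomes, tens of thousands of reads per check) this is fast
enough — the full test suite runs in ~15 s.

### Empty barcodes and cross-links

Empty barcodes are legal outputs (a genome identical to another
collection member at strain level yields one) and are retained with
size 0 and a logged warning, so that dropping them downstream is an
explicit, visible step — the profiler skips them with a warning, and the
distance matrix refuses them by naming the offending genomes.
`clear_cross_links` removes any k-mer occurring in ≥ 2 barcodes from all
of them; the result is pairwise disjoint and idempotent.  At species
level, overlapping barcodes are used as-is by default (overlap between
relatives is informative there); clearing is a flag intended for strain
mode.

## Sørensen distance and neighbor joining

Distances are set-based Sørensen–Dice: D = 1 − 2|A∩B|/(|A|+|B|),
undefined when both sets are empty (raised as an error, not silently 0
or 1).  Distances are stored as fractions; scale bars conventionally
render them as percentages.

Neighbor joining follows Saitou–Nei: minimise
Q(i,j) = (n−2)d(i,j) − r_i − r_j, join, compute limb lengths
l_i = d/2 + (r_i − r_j)/(2(n−2)), reduce with
d(u,m) = (d(i,m)+d(j,m)−d(i,j))/2, and finish the final three nodes with
the closed-form star.  Two choices are pinned because reference
implementations differ silently:

* **ties** in Q are broken by the lexicographically smallest label pair,
  an internal node inheriting the smallest leaf label beneath it — reruns
  are byte-identical even on all-equal matrices;
* **negative branch lengths** (possible on non-additive input) are
  clamped to 0 with the deficit logged.

On additive matrices NJ is exact; tests and the acceptance script verify
topology recovery (Robinson–Foulds 0) and path-length reproduction
(< 10⁻⁹) on random trees up to 12 taxa, plus the 3- and 4-taxon closed
forms.  Only NJ is implemented: distance-based alternatives (e.g.
minimum evolution) produce equivalent trees on this kind of data and
would double the surface without adding information.  Trees are
unrooted, serialised as Newick with 6 significant digits.

## Read scanning and normalization

A read shorter than the cutoff is excluded from the denominator
entirely.  Each retained read is decomposed with the same window rules
as genomes and counts **once** per genome whose barcode it intersects —
per-read counting avoids multiply counting long unique tracks while one
read may legitimately hit several genomes.  No read reassignment (EM or
unique-best) is attempted; with strain-specific cleared barcodes, hits
are already exclusive.

Normalized abundance = percent of marker-carrying reads × C / markers_n.
C is a display constant: 10⁶ per million species-specific markers,
37 000 at strain level (the rounded mean of the retained strain-specific
set sizes in the packaged inventory, so a typical strain has normalized ≈
percent).  The denominator is reads passing the length filter — the
package fixes this convention explicitly since "total reads" is otherwise
ambiguous.

Phylogroup aggregation reports member values, mean, median and quartiles
per group; genomes labeled `singleton` become one-member groups keyed
`singleton:<genome_id>` so lone lineages stay individually visible.

### Trajectory scenarios

For designs with ≥ 3 time points per subject (baseline, post-treatment,
final), each genome × subject series is classified with a relative
threshold θ (default 20 %):

* initial response: decrease / no-change / increase of point 2 vs
  baseline;
* final outcome: **recovery** if the last point is within ±θ of
  baseline, **overshoot** if above baseline·(1+θ), **further-decline** if
  below the baseline band *and* at or below the post-treatment level
  (−θ), otherwise **partial-recovery**.

A zero baseline counts any reappearance as an increase.  Subjects missing
a time point are flagged incomplete and excluded from scenario counts
(with a warning), never silently imputed.

## Group statistics

Mann–Whitney U is the only location test used — abundance distributions
are rarely normal.  U_x counts pairs where x exceeds y (ties ½), so
U_x + U_y = n_x·n_y is an identity (tested).  For groups of ≤ 10 each,
the p-value is exact: the full C(n, n_x) permutation null is enumerated
over the *observed* pooled values, which handles ties without
approximation; the two-sided p doubles the smaller tail, capped at 1.
Larger groups use scipy's tie-corrected normal approximation with
continuity correction.  Default is two-sided; one-sided alternatives are
exposed.

Fold changes are log2((after+ε)/(before+ε)) with ε defaulting to half
the smallest nonzero abundance in the dataset — zeros stay finite, and
the cap they induce is explicit in the output.  The volcano table
averages per-subject fold changes per genome and pairs them with the
Mann–Whitney p across subjects' before/after groups; genomes present in
fewer than half the pairs are excluded with a warning.  Raw p against
α = 0.05 is the default (mirroring standard practice for small panels);
Benjamini–Hochberg correction is available behind a flag via
statsmodels.  Paired designs are compared as two unpaired groups by
default, matching the two-group U-test convention; a Wilcoxon
signed-rank variant was considered and deliberately not made default to
keep a single documented test family.

## Synthetic data

`simulate_pangenome` emits per strain three contigs: a shared core, a
phylogroup-shared accessory block, and a strain-private segment of
length L_u.  Defaults (core 20 kb, accessory 5 kb, private 2 kb, 4
phylogroups) are scaled-down but structurally faithful: real
*L. paracasei* genomes are ~3 Mb with ~10⁶-word species barcodes, while
these sizes give ~2 000-word strain barcodes — the same regime as the
smaller retained strain-specific sets — and keep every end-to-end test
inside seconds on one core.  Segments being separate contigs means no
junction k-mers, so with negligible collision probability the
non-canonical strain barcode is exactly L_u − k + 1 words (asserted by a
window-count oracle).  Sequences are i.i.d. uniform ACGT: no GC bias,
repeats, or gene structure.  Passing tests therefore demonstrate
algorithmic correctness, not robustness to repeat-rich or biased real
genomes.

`simulate_metagenome` draws reads per planted strain proportions,
contigs weighted by admissible start positions, strand uniform,
substitution errors optional (no indels, by the exact-matching
contract), constant placeholder qualities, and the source strain
recorded in each read id.  Everything derives from one
`numpy.random.default_rng(seed)` stream; outputs are byte-reproducible.

The packaged reference inventory (75 genus-level and 47 species-level
rows with phylogroup labels and set sizes) is checksum-guarded at load;
its summary statistics — 31 retained strain-specific sets spanning
11 840–86 180 words with mean 36 794, species-specific sets spanning
1 000 877–1 250 212 — are recomputed from the rows, never hard-coded.

## Degenerate inputs and numerical notes

* k < 2, min_len < k, read_len < k, empty groups, negative abundances,
  non-symmetric matrices: parameter/validation errors, not warnings.
* Both-empty Sørensen pairs raise; single-empty pairs give distance 1.
* Distance matrix symmetry tolerance 10⁻¹²; NJ tie tolerance 10⁻¹² on Q.
* Exact-MWU tail comparisons use a 10⁻⁹ slack so float rank sums never
  flip a tail count.
* Mean barcode-size reporting rounds half-up (not banker's), matching
  how such tables are conventionally printed.

## Known limitations

* No quality trimming, host-read filtering, or adapter handling — the
  profiler assumes upstream QC; host contamination is handled at barcode
  level only.
* Read scanning is exact matching; one substitution inside every
  spanning window hides a marker, so error-rich platforms undercount
  (quantified only for error-free reads in the acceptance checks).
* Pure-Python set machinery targets desk-scale problems; barcoding
  thousands of full genomes would want a disk-backed or 2-bit-packed
  rewrite behind the same API.
* The NJ implementation is O(n³) and intended for ≤ a few hundred taxa.
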