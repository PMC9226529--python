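# Methods

## Coordinate and sequence conventions

All genomic coordinates are 0-based half-open on the top (given) strand.
Nick positions are inter-base coordinates: integer `c` is the bond between
bases `c − 1` and `c`. Sequences are uppercase DNA over `{A, C, G, T, N}`;
the only ambiguity code supported is `N`, since amplicon work rarely needs
more.

## Spacer sites and nicks

SpCas9 sites are NGG-PAM 20-nt protospacers on either strand. The nick is
placed 3 nt 5' of the PAM on the PAM-containing strand (the blunt SpCas9
geometry); the offset is a module constant and every derived coordinate is
expressed through it. Only NGG is accepted (no NAG leniency): the editor
modelled is an SpCas9-nickase prime editor. The sgRNA scaffold is the
canonical SpCas9 scaffold shipped as a configurable constant; no design
invariant depends on its sequence.

## pegRNA assembly

A pegRNA is the exact concatenation `spacer + scaffold + RT template + PBS`
(5'→3'). The primer binding site is the reverse complement of the
`pbs_len` bases immediately 5' of the nick on the nicked strand. The 3'
flap written by reverse transcription is `edit_content + HA`, read 5'→3'
on the nicked strand, where the homology arm (HA) is the `ha_len` bases of
the nicked strand immediately beyond the region being rewritten
(`ha_start`); `rt_template = revcomp(flap)`. On the bottom strand every
rule is the strand mirror of the top-strand rule, and the designer is
validated by a mirror-symmetry property: designing on the
reverse-complemented reference with reflected coordinates swaps the left
and right guides with all sequences reverse-complemented.

## Strategies

* **L-PE3 / R-PE3** — one pegRNA (left = top strand, right = bottom) whose
  flap is `insertion + HA` homologous to sequence beyond the far deletion
  boundary, plus a plain nick sgRNA on the other strand. Nick candidates
  are classified relative to the fragment to be deleted: Type I strictly
  inside (`start < pos ≤ end`), Type II in the HA-pairing window
  (`end < pos ≤ end + ha_len`; the upper bound is closed — "adjacent to the
  3' end" needs a deterministic rule), Type III beyond it, and positions at
  or before the start are out of range. Since only Type II nicks support
  large-fragment deletion, ranking is Type II < Type III < Type I, with
  ascending distance to the HA-proximal boundary inside each class; an
  all-Type-I candidate set is returned in distance order with a warning.
* **Bi-PE-2 / Bi-PE-3** — both guides are pegRNAs. Deletion boundaries are
  snapped to the nearest nicks within `snap_window` (the achieved edit is
  recorded and any snap is warned about). Bi-PE-2 flaps carry only the
  edit, so a Bi-PE-2 replacement produces two flaps that are exact mutual
  reverse complements; Bi-PE-3 appends each flap's HA. For conversion
  edits each flap spans from its nick across every converted position
  (Bi-PE-3 plus HA), so both pegRNAs encode all edits; the two flap
  footprints necessarily overlap, which is recorded as a note.
* **Double insertion** — two identical top-strand inserts (same
  orientation, optionally tag-augmented, e.g. an EcoRV site for digest
  diagnostics) at two nick-snapped points flanking an inner segment; each
  flap is `insert + HA` pointing *into* the segment. Designs are rejected
  when the segment is shorter than the combined HAs, and a note warns when
  it exceeds 150 bp, beyond which insertion efficiency is expected to fall
  off steeply (90-bp segments insert well, ~200-bp poorly, ~370-bp
  undetectably).

Default parameters: `pbs_len = 13`, `ha_len = 25`, `snap_window = 10` nt.
HA length effects are case-dependent in practice, so these are sensible
conventions inside the useful 8–50 bp HA range, not optimality claims; all
are arguments on every designer.

## Expected alleles and digests

For an amplicon of length `X` covering the edit and both PBS footprints,
the desired allele of a deletion `N` with insertion `I` has length
`X − N + I`. Double-insertion designs additionally enumerate the
single-insertion intermediates (`X + t` each, desired `X + 2t`); their
recorded edited spans cover *both* insertion points, because a read over a
single junction cannot distinguish an intermediate from the desired allele.
Digestion cuts at every site occurrence (top strand only for palindromic
sites; both strands otherwise); fragments always sum to the parent length.

Colony classification (for cloned double-insertion amplicons): *accurate*
iff the sequence contains the desired allele's edited span (inserts plus
20-bp flanks) exactly; *inaccurate* iff both inserts are present but the
alignment of that window to the sequence contains at least one indel;
*no_double_insert* otherwise. Substitution-only deviations are deliberately
not called inaccurate — the class is defined by harboured indels — so they
fall into the residual class.

## Read classification

Each read is aligned glocally — read end to end, allele overhangs free —
with unit mismatch and affine gap costs (open 2, extend 1 per base), fixed
so results are bit-for-bit reproducible. The best-scoring allele wins, with
ties preferring an indel-free optimum and then allele list order. A read is
`indel` when its best alignment requires an indel anywhere in the read;
otherwise it takes the allele's label (`desired`, `wt`, `single_side`)
unless its mismatch rate over the read exceeds `max_mm_rate` (default 5%),
which yields `other`. For conversion designs, a read covering at least one
target position is `desired` when all covered targets carry the alternate
base, `wt` when none do, and `imperfect_conversion` in between; mismatch
rate is then assessed over non-target positions. These windows are a
convention of this module: reads are positioned to cover the edited span,
so the span-plus-flank window and the read itself nearly coincide, and the
simpler whole-read rule is used. `junction_flank` (default 10 nt) expresses
the minimum read context around a junction.

Implementation: exact substring match and a unit-cost (edlib) screen
resolve almost every read; both shortcuts are label-equivalent to the
affine rule (a substitutions-only unit-cost optimum is affine-optimal, and
an indel alignment's affine cost is bounded below by its unit cost). The
full affine computation (Biopython PairwiseAligner plus exhaustive gapless
placement) runs only when the unit-cost path contains an indel. The test
suite checks the production classifier read-for-read against an
independent brute-force Gotoh dynamic program.

Frequencies are percentages of all classified reads (malformed FASTQ
records are skipped and counted); the six labels partition the reads, so
percentages sum to 100. An outcome is *detected* only when its percentage
strictly exceeds 0.01. `indel_among_edited` restricts the denominator to
deletion-junction-bearing reads — those whose best allele is the desired
deletion allele — and reports the share carrying extra indels; it is
not-available (None) without junction reads. No quality filtering is
applied by default (none is assumed of the input chemistry); reads are
taken as single-end or pre-merged.

## Gel quantification

`efficiency = 100 · (S_e/L_e) / (S_e/L_e + S_n/L_n)` with signal S and
length L in bp, identical for greyscale and capillary peak-area inputs
(the role field records which). It is scale-invariant, complementary
(`eff(A,B) + eff(B,A) = 100`), monotone in each signal, undefined
(not-available) only when both signals are zero, and no background
subtraction is applied. Tables report 0.1% rounding alongside full
precision.

## Synthetic data

`make_reference` draws uniform A/C/G/T and plants PAM dinucleotides so
each requested (nick, strand) anchor yields a valid site; conflicting or
unplaceable anchors are rejected. `simulate_reads` draws each read's
allele from the requested mixture, positions it to cover the allele's
edited span (or within the span when the span exceeds the read length, as
for the wild-type allele of a large deletion), and applies i.i.d.
substitution errors that always change the base; defaults emulate 150-nt
merged amplicon reads at 0.1%/base error. Errors are substitutions only by
default so that `indel` labels arise solely from indel alleles; an
optional indel-error rate exercises classifier robustness. One RNG stream
per run, keyed by the seed; identical specs give byte-identical FASTQ, and
headers carry the true allele for confusion-matrix tests. `simulate_bands`
sets `S_e ∝ f · L_e · exp(bias_per_kb · (L_n − L_e)/1000)` and
`S_n ∝ (1−f) · L_n`, so zero bias inverts exactly and positive bias with a
smaller edited fragment overestimates — the direction of the known PCR
small-fragment preference.

What the simulations do **not** model: PCR chimeras and UMI-correctable
amplification bias in reads, realistic quality-score profiles, paired-end
structure, NHEJ junction microhomology, or any cell-biology determinants
of editing efficiency. Passing tests therefore demonstrate the
correctness of the design arithmetic and the classifier under the stated
error model, not wet-lab editing rates.

## Problem sizes and numerical choices

The test-suite and acceptance-script workloads use toy references of
0.4–3 kb, 100-seeded design sweeps, 500-read oracle comparisons and
20,000-read mixtures at five desired fractions (0.05%–60%) with 20 seeds,
matching the binomial-recovery tolerance of three standard errors. All
tolerances on floating-point identities are 1e-9 absolute or tighter;
exact string equality is asserted wherever sequences are reconstructed
independently.

## Known limitations

* No off-target scoring, pegRNA secondary-structure / circularization
  prediction, epegRNA motifs or PBS melting-temperature optimisation.
* Variant calling is limited to the expected-allele set; novel alleles
  land in `indel` / `other`.
* The classifier's mismatch and indel windows are declared conventions
  (see above), not reconstructions of any particular published script.
* Indexed access to genome-scale FASTA and compressed formats are out of
  scope; references are held in memory.
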