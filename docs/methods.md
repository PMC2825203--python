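# Methods

## Scope and assumptions

The package characterises **oriented** EST/cDNA sequences: mRNA sense, with
an optional trans-spliced leader at the 5' end and a polyA tail at the 3'
end, as produced by a 5'-oligo-capped, oligo(dT)-primed library. Reverse-
strand ORF scanning exists behind a flag (`forward_only=False`) but is off
by default, because orientation is assumed known. Coordinates throughout are
1-based and inclusive, so reported positions can be read directly against
published residue numbering.

## polyA trimming

The tail is the longest 3' suffix that starts and ends with A and contains
at most one non-A per 10 bases; it is removed when at least `min_run`
(default 8) bases long. The tolerance absorbs isolated base-calling errors
inside genuine tails; requiring the suffix to end in A makes the operation
idempotent (after one trim the sequence ends in a non-A, so no new tail can
qualify). Both the tolerance and `min_run` are configurable.

## Translation and ORF finding

Translation uses the standard genetic code. UGA is normally a stop, but a
ribosome reading a selenoprotein mRNA with a selenocysteine insertion
element decodes UGA as selenocysteine (U); the `readthrough_uga` budget
reproduces this, translating up to that many UGA codons as U before UGA
terminates. UAA/UAG always stop. Codons containing N translate as X.

`find_longest_orf` scans all three frames for ATG-initiated, stop-terminated
frames and returns the longest protein; ties break to the smaller start
position (and to the forward strand when both strands are scanned). ORFs
running off the sequence end are eligible only with `allow_open_end`, since
an EST may genuinely lack its 3' end.

## Global alignment

Needleman–Wunsch with linear scores, default match +1 / mismatch −1 /
gap −1, and a deterministic traceback (diagonal, then up, then left at
ties), so identical inputs always give identical alignments. Identity is
matches divided by alignment columns. The scoring of the original ALIGN
tool behind published percent identities is not known, so those printed
identities are treated as indicative rather than reproduction targets; the
default scorer was validated instead by brute-force enumeration of the
alignment space (test suite) and by the spliced-leader family split it
induces (below).

## Hydropathy: two scales on purpose

* **GRAVY** uses the Eisenberg normalised consensus scale, which behaves
  better than Kyte–Doolittle for extremely hydrophilic sequences. A
  homopolymer's GRAVY equals its scale entry exactly; X residues are
  excluded from numerator and denominator.
* **Charge–hydropathy coordinates** use Kyte–Doolittle rescaled to [0,1] by
  (h+4.5)/9 — the convention of the charge–hydropathy disorder predictors —
  smoothed with a 5-residue window truncated at the ends. The smoothing
  window behind any particular published plot is not recoverable, so the
  window is configurable and individual plot positions are not treated as
  reproduction targets; the folded/unfolded calls are robust to it for the
  strongly hydrophilic proteins of interest.

Selenocysteine maps to cysteine on both scales (configurable).

## Disorder calls

Whole-protein classification uses the empirical boundary
⟨H⟩_b = (⟨R⟩ + 1.151)/2.785; a protein is unfolded iff ⟨H⟩ falls strictly
below the boundary, and points exactly on the line are called folded (the
conservative tie-break). ⟨R⟩ counts only the fully charged side chains
K, R, D, E at neutral pH — histidine and the termini are excluded, matching
common charge–hydropathy-plot practice; a Henderson–Hasselbalch-based charge
is available separately via `net_charge`.

The windowed profile applies the same relation per window
(I = 2.785·⟨H⟩_w − |⟨R⟩_w| − 1.151), default window 51 as in the published
FoldIndex server. Windows are full-length and shifted inward at the termini
(residues near an end share the terminal window), so setting the window to
the protein length gives a uniform index whose sign provably agrees with the
whole-protein classification. Percent disorder is the fraction of residues
with negative index. Machine-learned disorder predictors (VL-XT, IUPred) are
deliberately out of scope: only the charge–hydropathy family is
re-implemented, and published percent-disorder values from unidentified
predictors are not used as acceptance values.

## pI, net charge, molecular weight

Net charge is a Henderson–Hasselbalch sum over D, E, C, Y, H, K, R side
chains and both termini, with the EMBOSS pKa table by default (Sillero as an
alternative); it is strictly decreasing in pH, so pI is found by bisection on
[0, 14] to 0.01 pH. Because published pI values come from unknown pKa
tables, agreement is expected only to a few tenths of a pH unit. Masses are
average (not monoisotopic) residue masses plus one water; selenocysteine
uses the Sec average residue mass; X makes the mass undefined (error).

## Periodicity

A run is a **maximal** arithmetic chain of one residue type with common
difference p: no occurrence of that residue at (first − p) or (last + p).
Maximal-only reporting is a deliberate choice — sub-runs are implied — and
it is exactly what makes interlaced chains (same period, different phase)
come out as separate runs, e.g. lysines at 38, 40, 49, 51, 60, 62 as
{38,49,60} and {40,51,62}. Matching is by exact residue identity; a
residue-class mode (e.g. K/R) is noted as future work. Defaults: period 11
and `min_run` 3 for the Group 3 LEA K11 signature.

## Spliced leaders

The embedded catalogue holds the 12 *A. avenae* leaders (SL1a–d and
Variants 1–8) plus canonical *C. elegans* SL1 and SL2. Variant 8 is stored
without the leading alignment gap of the published table (a 21-mer); the
table's alignment intent is preserved by the global-alignment family test
rather than by padding. Detection scans offsets 0–3 with at most 2
mismatches over the full leader, ranking candidates by (mismatches, offset,
catalogue order); the mismatch budget is this package's policy, since no
threshold separating "variant" from "sequencing error" is published.

Family assignment aligns a variant globally against canonical SL1 and SL2
and takes the higher score (ties → ambiguous). Before freezing the default
scorer it was confirmed — against an independent alignment implementation —
that it assigns Variants 1–4 to SL1 and Variants 5–8 to SL2, the published
split. Novel-leader candidates (5'-terminal 20–24-mers ending in AG scoring
≥ 60% of a canonical leader's self-score) are flagged but never added to the
catalogue automatically.

## LEA rule cascade

The biological identification of a Group 3 LEA protein is narrative —
hydrophilicity, disorder, K11 periodicity, absence of Cys/Trp — and the
classifier codifies it as an explicit, monotone cascade with strict
inequalities (see README). The −0.43 GRAVY threshold is the GRAVY of bovine
serum albumin; the 50% disorder threshold follows the published screen for
"largely disordered" novel proteins; both are fields of `LeaCriteria`.
Compositional-clustering evidence (POPP-style) is an external published
method and is recorded as "not evaluated" rather than folded into the rules.
The screen applied to the embedded table of twelve published novel-EST
(GRAVY, %disorder) pairs flags exactly six — a standing regression test.

## Synthetic data: what it emulates, what it does not

The generator assembles ESTs with the exact anatomy the pipeline assumes —
leader, short 5' UTR, Met-initiated ORF back-translated with uniform seeded
codon choice, 3' UTR, polyA tail — and returns a ground-truth manifest.
Design choices:

* LEA-like proteins draw from a hydrophilic background pool (D/E/N/Q/R
  weighted, no K/C/W) with K11 chains planted in adjacent phases; each
  protein is checked against its own spec (GRAVY strictly below the target
  ceiling, default −1.0, i.e. well below the −0.43 decision threshold;
  unfolded; exact K-run count) and resampled deterministically on failure.
  Margins keep every generated record strictly inside the thresholds it
  targets, so classification recovery must be exact, never borderline.
* Globular decoys draw from a hydrophobic pool (GRAVY > 0, folded).
* UTRs are sampled with every ATG broken, and the assembled EST is verified
  post hoc: polyA trimming recovers the planted tail length exactly, leader
  detection returns the planted leader with zero mismatches, and the longest
  ORF decodes to exactly the planted protein (bounded deterministic
  resampling otherwise).
* Back-translation uses uniform codon choice because no codon-usage table
  for *A. avenae* is available; selenocysteine read-through is emulated by
  inserting U residues encoded as UGA.
* Everything is reproducible byte-for-byte from (spec, seed): one
  `numpy.random.default_rng` stream per call, consumed in a fixed order.

Not emulated: sequencing error, quality values, vector/chimera artefacts,
unoriented reads, realistic codon bias, UTR composition bias. Passing
round-trip tests therefore demonstrates internal consistency of the
pipeline on clean, well-formed ESTs — not robustness to noisy real-world
reads, which would require the out-of-scope error model.

Default study-scale checks run on collections of 200 synthetic ESTs with
class weights 0.4 LEA-like / 0.4 globular / 0.2 no-ORF decoys, protein
lengths 60–120 residues and polyA tails of 10–25 bases; the whole round
trip completes in a few seconds.

## Degenerate inputs and numerical choices

Empty FASTA files yield empty outputs with a warning, never an error; a
record that is entirely polyA trims to an empty sequence (warning). Proteins
shorter than a smoothing window use the whole sequence as one window.
Per-record pipeline failures become `status` values in the report rather
than aborting a batch. pI bisection tolerance is 0.01 pH; report floats are
rounded at fixed precision so reruns are byte-identical.

## Known limitations

* Published transcript lengths may or may not count the spliced leader; the
  report gives cDNA length both with and without it.
* Family assignment of leaders depends on the default scorer; other
  scoring schemes could move a borderline variant between families.
* The disorder percentages of machine-learned predictors are not
  reproducible here by design; only charge–hydropathy-family numbers are.
* Validation against the deposited GenBank records (EF026240/EF026241 etc.)
  requires network access and is therefore not part of the test suite; the
  ORF/physicochemistry code paths they would exercise are covered by the
  synthetic round trips instead.
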