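# Methods

This note documents the models and procedures implemented in `cyclomine`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the problem left the design open.

## Consensus coordinate system

All domain reasoning happens in one integer coordinate system with position
0 at the N-terminal cleavage site of the (first) cyclotide domain and
negative positions upstream; quoted intervals are inclusive.  The shipped
layout is ER [−76,−57], NTPP [−56,−20], NTR [−19,−1], CD [0,30], CTR
[31,38], with the six knot cysteines at consensus positions 4, 8, 13, 20,
22, 27 and the loop-6 N/D cyclization site at 30.  The consensus space holds
a single cyclotide domain; precursors with repeated NTR+CD units reuse the
same coordinates for every repeat.  The NTR series dipeptide sits at
[−9,−8], which is NTR-local positions 11–12 under this layout — the two
numbering conventions describe the same two columns.

## Mining

ORFs are maximal stop-to-stop stretches in all six frames (not
ATG-anchored, so 5′-truncated assemblies keep partial precursors);
transcripts shorter than 200 nt are ignored and N-containing codons
translate to X.  The cystine-knot motif scan reports non-overlapping
placements of six cysteines whose five inner loop lengths fall in the
windows loop1 [2,7], loop2 [3,6], loop3 [2,8], loop4 [1,2], loop5 [3,6]
(loop 6 crosses the domain boundary and is unconstrained at scan time).
These windows span the loop lengths observed across cyclotide subfamilies,
including elongated-loop outliers, and are fully configurable; they stand in
for pattern-database motifs whose exact definitions are maintained
elsewhere.  Overlapping alternative placements are resolved cluster by
cluster, smallest total span first, then leftmost — a deterministic rule the
test suite checks against an exhaustive enumeration oracle.

Similarity filtering is Smith–Waterman (BLOSUM62, blast-style affine gaps:
a gap of length k costs 11 + k) against (a) the bundled mature cyclotides
and (b) the curated precursor prodomains.  The translated-database search
stage this replaces ran at so permissive an E-value that its real filters
were the motif and manual inspection; both are codified here.  The default
thresholds (mature ≥ 67, prodomain ≥ 65) are the smallest integers exceeding
the best score of composition-preserving shuffled decoys scored against the
same references (10,000 mature / 5,000 prodomain shuffles) — i.e. calibrated
to zero false positives on shuffles.  Candidates with five or seven
cysteines have no valid six-cysteine placement; ORFs with ≥ 4 cysteines that
clear a similarity threshold are therefore rescued without a motif hit and
flagged `abnormal_cysteines`.

## Anchoring

Candidates are aligned to the reference alignment treated as a profile:
each column is scored as the frequency-weighted mean BLOSUM62 score of its
observed residues (which doubles as a fallback for residues the bundle
never shows), the six cysteine columns add a +25 bonus for cysteine, and
gap costs are linear and occupancy-scaled (skipping a mostly-gap column is
nearly free).  Rows are weighted per candidate by a softmax (temperature 8
score units) over prodomain Smith–Waterman scores, so the candidate's
nearest curated relatives pin the alignment register — without this, a
profile averaged over subfamilies is ambiguous exactly around the indel
windows that carry the classification signal.  End gaps are free on both
sides, which is what lets partial precursors anchor from their first
covered position.  After alignment the motif cysteines must sit on the six
curated cysteine columns; violations raise `unanchorable` and the candidate
is excluded downstream rather than silently misread.

Repeated NTR+CD units are segmented using the bundle's fixed CD-tail width
(three columns after Cys VI) and each extra repeat is anchored
independently against the NTR..CD sub-profile.  Segmentation assigns every
residue to exactly one domain (insertions inherit the preceding matched
residue's domain), so ER+NTPP+NTR(s)+CD(s)+CTR always reconstructs the full
protein — a property test.

Loop decomposition cuts one CD into six inter-cysteine loops, loop 6
joining the post-Cys VI tail with the pre-Cys I head to mirror the cyclic
backbone.  The N/D cyclization site is the residue on the consensus N/D
column when it is N or D, otherwise the last N/D in loop 6; its absence is
the `missing_ND` flag, a cysteine count ≠ 6 is `uneven_cysteines`, and loop
lengths outside the scan windows are `aberrant_loop_length` — flags, never
errors.

## Classification

Lineage is read from the NTPP indel region: Möbius when the deletion
windows [−56,−54] and [−50,−38] are ≥ 80 % gapped; bracelet when [−50,−38]
is ≥ 50 % occupied.  A third rule assigns bracelet when both flanking
insertion marks of the linear-bracelet signature are present —
(P/A/L)⁻⁴⁹(N/A)⁻⁴⁸ and (D/E)⁻³⁹ around an internal deletion — because that
signature's occupancy falls below both thresholds even though it is
unambiguous bracelet evidence.  The two fractions (80 % gapped, 50 %
occupied) are free parameters standing in for expert judgment in a
classification that was originally manual; they are configurable and
exercised by boundary tests.  Positions outside a partial sequence's
aligned span read as '?' and are excluded from the fractions; a sequence
with no covered indel region is `unclassified` with rationale `partial`.

Subfamily uses the NTR dipeptide: in the Möbius lineage YY → linear,
(Y/F/H)(S/A/Y) → cyclic, split into hybrid vs archetypal by occupancy of
the [−32,−31] insertion; in the bracelet lineage (Q/E/P/K)(D/N) plus the
flanking marks → linear, (H/N/S/T/G/K/P)(L/N/S/F/A) → cyclic; anything else
is `unassigned`.

Molecular series = the NTR dipeptide.  Molecular species are connected
components within a series under "identical [−56,−38] occupancy pattern AND
NTPP residue identity ≥ 0.80", numbered in first-seen input order.
Identity is computed over the full NTPP [−56,−20] at positions where both
sequences have residues: over the indel window alone a Möbius precursor
retains ~3 comparable residues, far too few for a meaningful threshold.
Sequences without full NTPP coverage receive a series but no species.  The
cyclotide-domain sequence is deliberately not part of the species key.
Signature/phylogeny conflicts are resolved by signature alone (phylogenetic
validation is out of scope); the rationale field records fired rules.

Names are tripartite (organism code + per-species rank + species key) with
a shipped code table for the five study organisms (valta, viman, vorie,
viver, vacum) and a deterministic fallback (genus initial + first four
epithet letters); previously published names are reused verbatim, and
previously unnamed precursors take the `prc-` prefix.

## Mass prediction and matching

Monoisotopic constants are fixed to six decimals (proton 1.007276, water
18.010565, hydrogen 1.007825, carbamidomethyl 57.021464; residue masses
from the standard proteomics table).  Cyclic mass = residue sum − 2H per
disulfide; linear adds back the terminal water; comparisons always use
unrounded values and reported masses round to one decimal.  Candidates with
an odd cysteine count default to (n−1)/2 disulfides (one free thiol) and
are flagged.  Mature enumeration produces six N-terminal variants per
domain (offsets −3…+2 around position 0; negative offsets retain NTR
residues) with the C-terminus at the N/D site (cyclic) or the domain end
(linear); X-containing candidates are mass-indeterminate and excluded.

Deconvolution groups isotope envelopes greedily per 0.2-min retention-time
bin: from the most intense unassigned peak outwards on the 1.00336/z grid
(z = 3 tried before 2; spacing tolerance 0.05 Da; ≥ 3 peaks), mono m/z =
leftmost accepted peak — no averagine fitting, matching how such spectra
are read manually.  Charges other than 2 and 3 are never assigned.  Neutral
masses M = z·mz − z·proton merge across charge states within 0.40 Da in the
same rt bin; observations survive only inside 2,700–3,300 Da.  SI is the
summed 3+ envelope intensity of the observation (2+-only observations keep
SI = 0, flagged), binned low < 250 ≤ medium ≤ 1,000 < high — the boundary
values themselves fall in the closed middle bin, which the strict published
inequalities leave undefined.  The alkylation check accepts a partner at
+348.18 Da within 0.75 Da — deliberately wider than the 0.40 Da match
tolerance, because two independently measured masses enter the difference
(the canonical worked spectrum itself deviates by 0.42 Da and is accepted).
Candidate-observation matching is strict `|Δ| < 0.40 Da`, many-to-many,
with the minimal-|Δ| candidate per observation flagged best; cross-level
concordance counts only best matches to avoid inflation by the many-to-many
pairs.

## Synthetic data

The generator emulates the structure every other module assumes: 46
molecular-species templates in 13 series (14 Möbius over 5 series — YS, YA,
FA, HA, YY — and 32 bracelet over 8 — HS, NS, NL, GA, GL, PS, PN, QD), each
with a fixed NTPP signature (species differ at 5–8 barcode positions,
keeping within-series inter-species NTPP identity below the 0.80 species
threshold), the series dipeptide in a common NTR scaffold, and a cyclotide
domain modelled on kalata B1 (Möbius) or cycloviolacin O2 (bracelet) with
species-fixed loop substitutions chosen so every canonical mature mass
stays inside the 2,700–3,300 Da detection window.  Möbius templates carry
1–3 NTR+CD repeats, bracelet templates one.  The published census text
names some series the quoted residue-class rules themselves exclude (HF in
the Möbius-cyclic classes, GP in the bracelet-cyclic classes); the library
substitutes HA and GL so that the closure property — classify(sample(T))
returns T's labels — is exactly satisfiable.  Cyclic YY-series members are
likewise not modelled, since the YY dipeptide rule maps to linear.

Transcripts embed each back-translated CDS (uniform synonymous codons,
stop-flanked) in random UTRs on a random strand; decoys are length-matched
random-codon transcripts; FPKM is i.i.d. log-normal (μ = 5.0, σ = 1.2 on
the log scale, median ≈ 150 — centered on the expression cutoff so both
tiers are populated); organisms rotate round-robin over instances, planting
known section-sharing structure.  Peak lists carry one 2+ and one 3+
envelope per expressed mature peptide with exact 1.00336/z spacing,
geometric intensity decay (ratio 0.8) normalized so the summed envelope
equals the abundance-tier base (low 100, medium 500, high 1500 — hence the
bins recover the planted tier), plus uniform noise peaks.  Mass jitter is a
per-envelope neutral-mass offset (calibration error), not i.i.d. per-peak
noise: per-peak noise at the default 0.05 Da would defeat the 0.05 Da
spacing rule itself, while envelope-level error is what the matching
tolerance is meant to absorb (0.40 Da ≫ 3σ of the combined 2+/3+ error).  A
separate per-peak jitter knob exists and defaults to 0.  One seed drives
everything through deterministic substreams; identical seeds give
byte-identical artifacts.

What the generator does **not** emulate: sequencing errors and chimeric
assemblies, non-cyclotide gene families that share cysteine-rich motifs,
chromatographic peak shapes and co-elution, detector saturation, charge
states outside 2+/3+, PTMs other than carbamidomethylation, and NTPP
variation *within* a molecular species.  Passing the recovery tests
therefore demonstrates internal consistency of the pipeline's rules on
clean, in-model data — not performance on real transcriptomes, where
mining thresholds and the species-identity threshold would face diversity
this generator does not produce.

## Numerical choices and degenerate inputs

Ties in similarity scoring break on lexicographic reference id; motif
placement ties on (span, start, cysteine tuple); the best-match flag on the
lowest candidate index.  Peak tables are sorted (rt, mz) with a stable
sort, non-positive intensities dropped with a logged count, duplicate
(rt, mz) pairs rejected.  Gap character is '-' only.  Empty inputs error
early and loudly; reference-bundle invariant violations (non-injective
column map, missing position 0, broken cysteine columns) are errors, never
repaired.  Sequences with unknown residues (X) survive mining and
classification but are excluded from mass prediction.

## Known limitations

- The reference bundle is synthetic (built from the template library with
  two published mature archetypes); anchoring accuracy on real precursor
  diversity depends on swapping in a curated alignment, for which the
  loader is the supported path.
- Repeat segmentation assumes the bundle's CD-tail width; exotic repeat
  architectures with long inter-domain linkers would need the boundary
  logic generalized.
- The profile aligner is linear-gap and occupancy-scaled, adequate for the
  anchored geometry but not a general profile HMM.
- Abundance bins for peptides lighter than ~2,997 Da cannot be recovered
  from data acquired in a 1,000–2,000 m/z window (their 3+ envelopes fall
  outside it); SI = 0 with a flag is the honest output there.
- E-value statistics, MS/MS identification, retention-time modelling and
  phylogenetics are out of scope.
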