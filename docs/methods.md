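# Methods

## The model

A canonical microRNA precursor is a ~60–120 nt stem-loop. Drosha cleaves the
primary transcript at the base of the stem and Dicer at the loop side; both
cuts leave a 2-nt 3' overhang, so the excised guide and passenger strands
form a duplex whose two 3' ends each protrude ~2 nt past the paired region.
Deep-sequencing reads from a genuine locus therefore stack tightly on both
arms, with homogeneous 5' ends (the 5' cut position determines the seed and
is under selection) and a duplex geometry close to 2 nt at both ends.

`mirhc` evaluates five binary criteria per locus, all computed from exact
(zero-mismatch) read placements on the precursor and a single secondary
structure:

| criterion | quantity | threshold | sense |
|---|---|---|---|
| c1 read depth | summed reads assigned to each mature product | 10 per arm | inclusive (≥) |
| c2 overhang | 3' overhangs of the most-abundant-read duplex | 0–4 nt | inclusive range |
| c3 5' homogeneity | fraction of each arm's reads sharing the modal 5' start | 0.50 | inclusive (≥) |
| c4 energy | MFE / precursor length | −0.2 kcal/mol/nt | strict (<) |
| c5 mature pairing | paired fraction over the union of mature bases | 0.60 | inclusive (≥) |

c4 is deliberately a strict inequality while the others are inclusive; the
boundary tests pin this down (−0.2 exactly fails, −0.205 passes). All
thresholds live in one frozen `Thresholds` record, serializable to YAML, so
a run can be audited and rerun bit-identically.

### Verdicts

HIGH_CONFIDENCE requires all five criteria. Failures are reported in the
order the evidence is naturally judged: c1 failure → INSUFFICIENT_EVIDENCE
(one cannot refute an annotation without reads); else c2/c3 failure →
PATTERN_INCONSISTENT (deep reads whose geometry or 5' heterogeneity argues
against canonical processing); else c4/c5 failure → STRUCTURE_FAIL. The
fourth verdict is our extension: the classical call is three-way, and a
well-read, badly folding locus does not map cleanly onto it, so we keep it
distinct rather than fold it into "inconsistent". The ordering affects only
the explanation, never membership of the high-confidence set. Manual
overrides (a TSV of locus, forced verdict, reason) are applied after
classification and marked MANUAL, mirroring curator promotion of
well-studied loci with atypically variable 5' ends.

## Key procedural choices

**Read counting.** Mapping is exact substring search on the sense strand of
the precursor — c1 is defined over mismatch-free placements, and at hairpin
scale an index would be overhead. Counts are summed across datasets before
thresholding (the per-dataset alternative, requiring one dataset alone to
reach depth, is available behind `--per-dataset`). Reads outside 16–30 nt
are skipped. A read matching k sites on one hairpin carries its full count
at each site and is flagged `multi_hit` in the report; cross-hairpin
multi-mappers count at every hairpin.

**Arm assignment.** A read counts toward a mature product when it overlaps
the mature interval by ≥50% of the read length. This tolerates templated 3'
trimming/tailing (common in isomiRs) while excluding loop fragments; reads
covering the whole terminal loop are tallied separately as loop-spanning
and never contribute to either arm. Ties (equal overlap with both matures)
keep the 5' product; modal-start and most-abundant-read ties break toward
the smaller start, then the lexicographically smaller sequence, so every
statistic is deterministic.

**Loop finding.** The terminal loop is the unpaired interval enclosed by a
pair with no pairs nested inside it. Structures with several terminal loops
are flagged MULTILOOP and the branch closed by the longest stacked helix
run is used; such loci are never called high confidence without a note, but
their energy and pairing metrics are still reported.

**Star inference.** When only one arm is annotated, the second product
required by c1 is constructed by inverting the canonical geometry: the
star's 5' end is the partner of the base 2 nt inside the mature's 3' end,
and its 3' end lies 2 nt past the partner of the mature's 5' end, walking
inward over unpaired terminal bases to the nearest pair before taking
partners. On a perfectly paired stem this is an involution and the
mature/star duplex has exactly (2, 2) overhangs — the closed-form check the
tests enforce. After inference the read stack is re-assigned so star-arm
reads count toward c1.

**Overhang measurement.** Real duplex ends are imperfect, so each overhang
is measured against the nearest paired base at or 3' of the partner
product's 5' end, bridging at most 5 unpaired nt (configurable); beyond
that the overhang is undefined and c2 fails with the reason recorded. c2 is
judged on the most abundant read from each arm — the observed products —
because the reads, not the annotation, are the evidence of where processing
occurred; the annotated-pair geometry can be computed alongside.

**Structures.** Precomputed dot-bracket input (RNAfold text dialect) takes
precedence over de novo folding; `--refold` forces recomputation. Folding
is delegated to ViennaRNA (Python bindings, falling back to the `RNAfold`
executable) at the engine's default temperature and parameter set, which
the run log records. The package asserts only the contract it needs: valid
dot-bracket of equal length, MFE ≤ 0 whenever a pair can form.

## The synthetic-data generator

`mirhc.simulate` builds loci whose ground truth is known by construction:
the 3' arm is the reverse complement of the 5' arm (a perfect stem), the
loop is poly-A so it cannot pair under any reasonable model, the
dot-bracket is written down rather than folded, and matures are placed so
the requested duplex overhangs hold exactly. Read stacks place
⌈modal_fraction × n⌉ reads at the mature 5' end and spread the rest over
nearby offsets; a rigid shift of the 3p reads distorts the duplex geometry
by a chosen amount. Defaults describe a clean canonical locus: 30-bp stem,
8-nt loop, GC fraction 0.6, 22-nt matures, (2, 2) overhangs, 100 reads per
arm, 90% modal fraction, ±2 nt offset noise, and a supplied energy of
−0.35 kcal/mol/nt, typical of a well-paired precursor. The supplied MFE
keeps structure-dependent tests independent of any folding engine; one test
runs the real engine on a pure-GC stem to confirm the end-to-end energy
path.

What the generator does **not** emulate: sequencing error, adapter
contamination, non-templated tailing, expression variation across tissues,
cross-mapping between paralogues, and non-canonical biogenesis (mirtrons,
Dicer-independent loci). Passing tests therefore demonstrate that the
criteria and their boundaries are implemented exactly, not that the
classifier's sensitivity/specificity on real libraries matches any
particular corpus — corpus-level results depend entirely on which read sets
are collated.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally and 1-based inclusive in GFF3
output. T→U and uppercase normalization happen once at ingestion; any other
character is an error under the strict policy. An arm with zero reads has
an undefined modal fraction: c3 is false, but such loci are already
INSUFFICIENT_EVIDENCE via c1, so the convention never surfaces in a
verdict. Undefined overhangs fail c2 with a note. Fractions are reported to
6 decimals and round-trip through the TSV report exactly at that precision.

## Problem sizes

The test suite and the acceptance script run entirely on generated loci:
boundary sweeps use single loci per parameter value (≤21 points per sweep),
archetype recovery uses 100 seeds per archetype, and the bulk oracle checks
use 500 reads × 50 hairpins and 1,000 randomized aggregation/monotonicity
perturbations. The whole suite completes in a few seconds on one CPU.
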