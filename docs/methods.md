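# Methods

This note documents the models, algorithms, parameters and deliberate
design choices behind `is605scan`, and what its synthetic-data tests do
and do not establish.

## 1. Structural model of the element family

An intact IS605 element is modelled, on the strand that reads the tnpB
ORF forward (the *element strand*), as

```
LE(60) · revcomp(tnpA) · tnpB · RE
```

with tnpA and tnpB divergently oriented, the left end (LE) downstream of
tnpA and the right end (RE) downstream of tnpB. All catalogued decay
states are expressed relative to two reference ORFs:

**tnpA (405 nt reference).** Types are coverage fingerprints, 1-based
closed intervals on the reference: T1 `[1,405]`; T2 `[172,405]`;
T3 `[172,291]`; T4 `[298,405]`; T5 `[1,63] ∪ [347,405]` (122 nt).

**tnpB (1254 nt type-1A reference).** Types are ordered edit lists.
"Insert at position N" means the inserted bases occupy `N..N+len−1` of
the edited ORF; multi-edit types apply edits sequentially, each position
read in the frame left by the preceding edits. The left insert (LI) sits
at 433; the right insert at 1064 of the type-2A frame, i.e. 1000 in the
type-1A frame once the 64-nt LI shift is removed — the pipeline reports
insert positions in the 1A frame for that reason. Realized lengths close
exactly with the catalogued values: 1254 (1A), 1255 (1B), 1382 (2A),
1318 (2B, 2C), 724 (3), 499 (3′), 172 (MISC).

Two catalogued figures do not close arithmetically and are handled
explicitly rather than silently corrected:

* The type-3 length (724) cannot be derived from "1254 + 67 − the
  inter-insert region"; the model therefore honours the printed length,
  placing the absent region (597 nt) between the hybrid insert and the
  right-insert site: `1A[1..432] · HI(67) · 1A[1030..1254]`.
* The type-3′ deletions ("173 at 146" and "52 at 422") are applied
  sequentially. Read that way the 52-nt deletion lands 3′ of the hybrid
  insert (1A position ~1125); read both in the pre-deletion frame it
  would truncate the HI itself, which type-3′ copies demonstrably
  retain. Sequential application is therefore the only self-consistent
  reading, and it still yields the printed 499 nt.
* A catalogued "282 nt" size reduction for type-5 tnpA conflicts with
  405 − 122 = 283; the model uses the interval arithmetic.

**Inserts.** LI = `TCA` + 61-nt core (64 nt); RI = core + `GCT`
(64 nt); HI = `TCA` + core + `GCT` (67 nt). The core carries a 4-nt
motif at core positions 17–20 (ATAA in the LI lineage, TAAT in the RI
lineage) and a 1-nt diagnostic at position 30 (A vs T), nine nucleotides
downstream of the motif's end; the hybrid carries the LI motif with the
RI base — the recombinant signature. Diagnostic positions are counted in
the core frame because the lineages differ in their terminal
trinucleotides, which makes absolute insert-frame offsets ambiguous.

**Ends.** LE 60 nt with one hairpin (10/10 bp stem, 8-nt loop carrying
AAGCT). RE 132 nt (type 1) with three potential hairpins — 8/10, 9/11
and 11/13 bp with 5-, 7- and 8-nt loops, AAGCT in the second loop —
where structures 2 and 3 overlap and are mutually exclusive. The type-2
RE carries a 28-nt insert at position 99 (160 nt total), landing
immediately after nucleotide 21 of structure 2 and nucleotide 8 of
structure 3, disrupting both but not structure 1. A truncated RE remnant
(23 nt) is catalogued as RE_MISC. Published folding energies are carried
as annotations on the hairpin specs; they are never computed or scored.

## 2. Reference realization

The reference sequences themselves are not available as machine-readable
text, so the package generates a seeded *realization*: concrete
sequences satisfying every constraint above. Hairpin-bearing sequences
are produced by a pairing-constraint solver (union–find with complement
parity over stem positions, pinned loop motifs and diagnostics, forced
interior mismatches, i.i.d. fill elsewhere). Guard constraints keep the
designed structures locally optimal: the first flanking pair of each
stem is forced non-complementary (otherwise a chance-complementary flank
would extend a stem into a higher-scoring variant), and loop termini of
loops longer than 5 are kept unpaired. Every candidate is validated with
the package's own hairpin finder (the designed geometries must emerge as
the top-scoring calls) and against cross-similarity limits (no two
distinct components, on either strand, may align locally at ≥ 40, the
ORF scan threshold); failures are redrawn, so the result is a
deterministic function of the seed. Random components (the ORFs, the
28-nt RE insert, the 2.6-kb disruption content) are drawn at 37 % GC.
The IS200 tnpA — a distinct transposase catalogued but deliberately not
further characterized — is realized as an unrelated 420-nt ORF.

Users with the real accession sequences can load them with
`ReferenceRealization.from_fasta`; the pipeline is agnostic to which
realization it runs against.

## 3. Alignment engine

Local alignment is exact Gotoh (affine gaps, cost `open + L·extend`),
numba-compiled, with BLASTN-like defaults `match=2, mismatch=3,
gap_open=5, gap_extend=2`. Tie-breaks are deterministic (lowest start in
the query, then the target). Genome scanning finds all hits by repeated
best-hit masking: a linear-memory pass keeps the best score ending at
each genome column; after each reported hit the matched region is masked
and only the affected column range recomputed, so a scan costs one full
pass plus a small window per hit. Hits below 40 score or 80 % identity
are masked but not reported.

Two conventions matter downstream and differ from naive choices:

* **Identity excludes gap columns.** Bridged internal indels (the
  28/52/64-nt structural events) are evidence of decay structure, not
  dissimilarity; counting them against identity silently discarded
  genuine bridged fragments.
* **Hit ends are trimmed.** A positive-scoring local alignment drags
  chance-match runs from flanking sequence into its ends (up to ~10 nt
  at these scoring ratios), shifting observed breakpoints. Each hit end
  is cut where the kept columns' weight (match +2, mismatch −5, gap 0)
  is maximal, then trimmed to terminal matches. Gap columns are neutral
  so trimming never eats through a real indel. `local_align` itself is
  left untrimmed — it reports the exact Smith–Waterman optimum, which is
  what the brute-force oracle checks.

Because ~10 nt of breakpoint wander survives any honest trimming (a
flank that genuinely continues matching is indistinguishable from
reference sequence), fingerprint matching uses a per-breakpoint
tolerance of **12 nt** (`breakpoint_tol`), and fragment chaining allows
12 nt of model overlap. The nearest tnpA fingerprints are > 100 nt
apart, so this is unambiguous. Fragment chaining bridges genome gaps up
to 3 kb for tnpB (the nested ~2.6 kb disruption) but only 200 nt for
tnpA, which carries deletions, never nested insertions — a larger gap
lets chains reach the next element's tnpA in densely packed genomes.

`extend_boundary` implements the outward end-delimitation walk: ungapped
position-by-position comparison, stopping at the first 15-nt sliding
window under 60 % identity and returning the last position of
similarity; anchor-proximal truncations of up to 12 nt are recovered by
an offset search (decayed ends erode on the ORF side). Inside the
pipeline the left-end status is instead derived from a local alignment
of the LE model against the window upstream of tnpA, which tolerates the
anchor jitter described above; the walk remains the reference behaviour
for end delimitation against arbitrary anchors.

## 4. Locus assembly and classification

The pipeline anchors on tnpB (present at every IS605 locus of this
family), pairs each tnpB locus with the nearest opposite-strand tnpA
group upstream of its 5′ end (≤ 500 nt), extracts the locus region
± 250 nt, and re-characterizes it on the element strand. Fragment CIGARs
are flattened into ungapped blocks; model-frame gaps between consecutive
blocks become insertions (≥ 10 nt), small insertions (1–9 nt, the
type-1B diagnostic), and deletions. Insertions of 50–80 nt are
classified as LI/RI/HI; insertions ≥ 500 nt are recorded as disruptions
(their content is not sub-classified — identifying the nested element
would require external IS libraries). The tnpB decision tree then reads:
disruption ≥ 1 kb with LI only → 2B′; LI∧RI → 2A (plus the 173-nt
deletion at ~151 → 2A′); HI with the inter-insert region absent → 3
(plus the 173-nt deletion at ~146 → 3′); LI only → 2B; RI only → 2C; no
inserts with the 5′102 + 3′70 fingerprint → MISC; full coverage with or
without the single-nucleotide insertion near 465 → 1B / 1A; anything
else → unclassified.

Insert classification aligns the candidate to the 61-nt core
(< 70 % core identity → unknown) and reads the terminal trinucleotides
in the core-anchored frame, allowing one mismatch per trinucleotide.
When the terminals alone are inconclusive — eroded, or cut off by
alignment-boundary jitter — the full four-item lineage signature
(prefix, suffix, motif, diagnostic base) is scored and a unique ≥ 3/4
fit accepted. The ambiguity tie-break everywhere is "fewest unexplained
nucleotides", with runner-ups recorded in the locus evidence.

Right ends are reconstructed from fragments exactly like the ORFs (a
single bridged alignment is fragile: the insert splits the consensus
into a 98-nt and a 34-nt piece, and bridging beats truncation by only a
few points once the short piece carries noise). A ~28-nt insertion near
position 99 → RE_T2; near-full coverage → RE_T1; an anchored remnant →
RE_MISC.

PATE-like relics are clusters of leftover LE/RE hits outside any
assigned element, with no tnpA coverage and at most 100 nt of tnpB. The
LE hairpin is near-palindromic, so a genuine relic also produces a weak
opposite-strand self-hit; clusters are therefore built by position only
and take the strand of their strongest hit. A cluster must contain at
least one hit scoring ≥ 45: the weakest genuine component (the 23-nt RE
stub) scores 46, while background chance matches that strong occur at
~10⁻⁶ per megabase under the scan scoring (Karlin–Altschul with
λ ≈ 0.63, K ≈ 0.1).

Loci are numbered by increasing circular distance
(min of clockwise/counter-clockwise) from the configured origin
(default: position 1; terminus defaults to the antipode — the published
catalog does not print oriC coordinates, so real-genome runs must supply
them). The replichore class of each locus's tnpA strand is Lead iff the
locus lies on the origin→terminus arm and tnpA reads '+', or on the
other arm and reads '−'.

## 5. Hairpin finder

Stem-loops are found by exhaustive enumeration of
(5′ stem, loop, 3′ stem) partitions under Watson–Crick pairing only (no
G·T wobble: these hairpins function in ssDNA transposition
intermediates). Defaults: ≥ 6 paired, stem span ≤ 15, loop 4–8, ≤ 2
interior mismatches, terminal pairs matched. The score is
`2·paired − mismatches − max(0, loop−8)` — a pairing count, not a free
energy. `min_loop` is 4 rather than the biophysical 3 because the
conserved AAGCT loop's termini (A…T) complement: with loop-3 calls
allowed, a Watson–Crick-only scorer would absorb them into the stem and
systematically misreport the catalogued geometries. Calls strictly
contained in a higher-scoring call's span are suppressed. Two structures
are mutually exclusive when their stem intervals overlap (loop overlap
does not exclude); co-realizable subsets are maximal independent sets of
the stem-overlap graph. An insert beginning at position N disrupts a
structure iff N lies strictly inside its span.

## 6. Synthetic genomes

The generator plants elements left to right with per-element minimum
spacing (default 400 nt) on an i.i.d. background (default 34 % GC,
halophile-like); slack is distributed randomly across gaps. Strands are
random unless pinned, or chosen to hit a requested leading/lagging class
given the landed arm. Point mutations use common random numbers: the
per-position uniform draws are derived from (seed, element index) only,
so the mutated position sets are nested across rates and label-recovery
curves over a rate grid are monotone by construction, not by sampling
luck. The catalog-emulating preset plants the full published composition
(23 loci including the IS200 singleton and the locus-13 LE truncation,
locus-15 truncated RE, locus-18 nested disruption, plus one PATE) with
strands chosen to reproduce the published 10-of-22 leading-strand tally.
The PATE truth length is 246 nt — the sum of its printed components
(28 + 58 + 160) — not the "approximately 271" the survey text quotes;
the unaccounted ~25 nt is not locatable from the printed description.

What a green synthetic test establishes: correct recovery of planted
structure under i.i.d. substitution noise on a repeat-free background.
What it does not: robustness to real genomic context — other IS
families, tandem repeats, compositional bias, assembly gaps, real
sequence divergence between element copies — nor correctness of the
reference realization as a stand-in for the real accession sequences.
Runs against the real genome require downloading the accession and
supplying reference FASTA plus origin coordinates.

## 7. Known limitations

* Exact DP scanning is O(genome × model); practical to a few Mb per
  model on one core, not to metagenomes.
* Elements closer than ~250 nt to each other, or overlapping/nested
  IS605 copies, can blur region extraction; the published loci are well
  separated, and simulated spacing below ~300 nt is untested.
* A disrupted type-1A (no LI) has no catalogued name and falls back to
  T1A-with-recorded-disruption rather than a 2B′-style label.
* Replichore assignment needs true origin/terminus positions; defaults
  are only correct for the simulator's convention.
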