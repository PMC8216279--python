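# Methods

## The core model

The hairpin-ribozyme core is modelled as two internal-loop units joined by
four helices. Each unit carries two unpaired strands: for loop A the
cleavage-site strand (standard positions −2…+3, cleavage between −1 and +1)
and the 7–11 strand; for loop B the 20–26 and 36–44 strands. The default
consensus letters are reconstructed from the conservation of the known
natural sequences:

| region | pattern | notes |
|---|---|---|
| −2…+3 | `NN^GNN` | `^` marks the cleavage site; G+1 invariant |
| 7–11 | `RGAAG` | G8 invariant; A9/A10 nearly invariant |
| 20–26 | `RGAAACN` | A22–A24 and C25 invariant |
| 36–44 | `NNAYNUUAN` | A38 invariant; U41/U42 nearly so; position 37 has no established consensus and is left `N` |

Helix length ranges default to h2 ∈ [3, 6] (modal 4 bp), h3 ∈ [4, 7]
(modal 5 bp), h1 and h4 ∈ [3, 15] (their natural lengths vary greatly); the
junction between helices 2 and 3 carries 0–3 unpaired nucleotides; terminal
loops closing an inner helix span 3–8 nt. All ranges and letters are plain
dataclass fields, so the reconstruction is auditable and overridable.

## Permutations

A loop unit in linear form is always `outer-helix open · strand · inner-helix
open · (contents) · inner close · strand · outer close`. *Flipping* a unit
models cutting the circle on the other side of the loop: the two unpaired
strands appear in the opposite order and the outer/inner roles of the
flanking helices swap, while each strand keeps its internal 5′→3′ sequence
(reverse-complementing would describe the wrong molecule). Four arrangements
(A before B, B before A, A nests B, B nests A) × independent flips give 16
distinct descriptors with injective labels `<arrangement>/<flipA>/<flipB>`.
Two of the 16 can be rotationally equivalent when scanned on a circle; they
are deliberately enumerated as distinct linear forms, and duplicate hits are
collapsed at match level.

## Scanning

The scanner enumerates **every** assignment of element lengths satisfying
the descriptor (helix complementarity with G–U allowed by default and a
per-helix mismatch budget, IUPAC letter constraints, length ranges). To
avoid trying every start, candidate starts are derived from occurrences of
the most informative fixed single-strand element (for the default model the
`GAAAC` run at positions 21–25); this is an exact filter — any true match
must place those letters verbatim — and the tests verify equality with an
independent brute-force enumerator on seeded suites. A subject `N` matches
only pattern `N`, so gap-filled assemblies cannot satisfy informative
positions. Circular scanning uses the doubled sequence (seq + first L−1 nt)
with deduplication modulo L; minus-strand hits are reported in plus-strand
coordinates.

Alternative length assignments at one locus (e.g. an outer helix shortened
by one pair) are all returned; `dedupe_matches` keeps one per
(contig, strand, start, permutation) and `collapse_by_cleavage` one per
cleavage site — the site identifies the ribozyme — preferring the maximal
total helix length, then lexicographically smallest spans. Coordinates are
0-based half-open internally and 1-based inclusive in emitted tables.

## Alignment analytics

Stockholm files are read via Biopython (interleaved blocks supported;
`#=GC SS_cons` required) and validated (row lengths, bracket balance).
Unique sequences are ungapped strings after U/T and case normalization.
Conservation profiles are exact per-column counts of A/C/G/U/gap;
"perfectly conserved" means one nucleotide accounts for every row.

Covariation support uses mutual information in bits with the
average-product correction: MI is computed for **all** pairs among the
structure's columns, and pair (i, j) is corrected by
mean(MI_i)·mean(MI_j)/mean(MI). Computing the correction over the full
column-pair matrix (not only the proposed partner pairs) is essential —
otherwise a stem whose pairs all covary would be corrected against itself
and the signal cancelled. Significance is empirical: rows are permuted
independently within each column (destroying pairing, preserving
composition), the corrected statistic is recomputed per replicate, and
p = fraction of replicates ≥ observed (so p can be exactly 0 at finite n);
Benjamini–Hochberg q-values are reported alongside. This statistic is a
deliberately simple, seedable stand-in for phylogeny-aware tests such as
R-scape's; parity with those tests is a non-goal. At the default 1000
shuffles the raw per-pair false-flag rate is near-nominal (measured ≈ 0.07
over 270 null pairs) but, with only ~10 structure pairs per alignment, a
single null alignment can exceed a 5 % flagged *fraction* by chance; the
calibration checks therefore use the BH-corrected flags, whose family-wise
null rate is properly controlled.

Junction lengths count non-gap characters in the columns strictly between
helix 2 and helix 3 (both strand sides handled; the analyses ignore
non-canonical pairs or indels inside the helices). Helix-extension
accounting first excludes rows with any non-WC/GU pair or indel inside
predicted helix 2 or 3, then greedily assigns junction nucleotides to
whichever adjacent helix they extend via a WC/GU pair with the
opposite-strand junction nucleotide; when a single junction pair could stack
on either helix, helix 2 takes the primary assignment and the alternative is
recorded.

## Circularity

End repeats are the longest **exact** prefix = suffix match with length in
[min_len, ⌊L/2⌋] (case- and U/T-insensitive; `N` never matches). Exactness
mirrors the conservative detection rule; an optional mismatch-tolerant mode
is out of scope. The ⌊L/2⌋ cap prevents degenerate overlap; a repeat of
exactly half the contig is a perfect tandem duplication and is *not* excused
by the end-repeat exclusion in the self-similarity screen, so such contigs
are flagged as artifacts. Circles are canonicalized to the
lexicographically smallest rotation (Booth's algorithm), making molecules
comparable across assembly origins. The self-similarity screen is a
k-mer-seeded, ungapped-extension scan (default k = 12, min 50 nt) that flags
contigs where an internal non-end-repeat match covers ≥ 50 % of the contig.

## Annotation

Molecule reports scan the canonical circle on both strands (rotation
invariance is tested), collapse hits per cleavage site, and flag molecules
with hairpin matches on both strands. The coding column is a **declared
heuristic**: longest AUG-to-stop ORF across six frames of the doubled circle
(length excludes the stop codon, capped at the circle length), flagged at
≥ 300 nt. It is not a phylogenetic coding test and makes no claim of
agreement with one. The hammerhead-III-like and twister-P1-like descriptors
are simplified patterns used to exercise the opposite-strand plumbing on
synthetic data; they claim no sensitivity on real sequences.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: circle lengths uniform on
[381, 5170] nt (the observed size range of complete molecules), background
composition uniform over A/C/G/U with an optional GC knob (no composition is
established for the hosts), planted cores realized from the model (helices
exactly complementary, G–U at probability 0.1 per pair, helix lengths capped
at 8 bp for compactness within the allowed ranges, junction lengths weighted
0.55/0.2/0.15/0.1 toward the observed mode of 0), assembler-style
linearization with an exact 123-nt terminal repeat (detection threshold
75 nt), i.i.d. substitution errors (indels excluded by default: assembled
contigs carry few), and motif-free linear decoys.

It does **not** emulate read-level sequencing, coverage gaps, chimeras,
assembler-specific repeat-length dialects, or realistic host-sequence
composition; passing the synthetic tests therefore demonstrates algorithmic
correctness against known truth, not sensitivity or specificity on real
metatranscriptomes.

Two synthetic stand-ins replace reference inputs that cannot be shipped:

- `synthetic_reference_alignment()` — a designed 941-row alignment with the
  published marginal statistics (941 unique sequences; exactly seven
  perfectly conserved core positions; A9 in 940/941 rows; four G–G rows at
  positions 20/44; one/two alternate rows at U42/U41; 364 rows with a
  mismatch or indel in helix 2/3; junction mode 0). The analytics
  *recompute* these numbers from the alignment; what this shows is that the
  analytics measure such properties correctly, not that the real alignment
  was re-analyzed.
- `synthetic_hpr1_construct()` — an 87-nt transcript carrying the core with
  its cleavage site 12 nt from the 5′ end, so locating the site via a
  descriptor match predicts 12-nt and 75-nt cleavage products.

## Problem sizes and numerical choices

The analysis drivers and tests run at desk scale by design: 16-molecule
datasets for scan/circle recovery, 50 decoys for the specificity check,
100 circles × 3 repeat lengths for the round-trip property, 200 rows /
9 pairs / 1000 shuffles for covariation power. All randomness flows through
`numpy.random.default_rng` with explicit seeds; generators are
bit-reproducible under a fixed seed. Degenerate inputs fail loudly
(empty sequences, invalid alphabet, unbalanced structures, boundary
cleavage positions, all-gap columns).

## Known limitations

- The descriptor letters are a reconstruction from reported conservation,
  not the study's original search patterns; no equivalence is claimed.
- The covariation statistic is not R-scape; it has no phylogenetic null.
- The standard-numbering assignment of helix-embedded positions (−5…−3,
  +4) is by adjacency to the loop strands and is a package convention.
- The coding flag, hammerhead/twister patterns and self-similarity screen
  are heuristics for synthetic-data plumbing and coarse triage.
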