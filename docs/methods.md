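# Methods

This document states the model behind each pipeline stage, the parameter
defaults and why they were chosen, the numerical conventions, and what the
built-in stand-ins can and cannot support.

## Six-frame translation and coordinates

Every transcript is translated in frames +1, +2, +3 (forward strand,
offsets 0/1/2) and −1, −2, −3 (the same offsets applied to the reverse
complement). Translation runs **through** internal stop codons, which are
kept as `*` in the frame translation; ORF calling, not translation, decides
where coding stretches end. Ambiguous or partial codons translate to `X`,
and trailing bases that do not fill a codon are trimmed. Translation uses
the standard genetic code (Biopython codon tables; the table id is a
parameter of `six_frame_translate`).

Frame records are named `<accession>_<+k|-k>`. A `CoordinateMap` converts
between protein and forward-strand nucleotide coordinates: protein position
`p` on frame +k occupies nucleotides `[(k−1) + 3(p−1) + 1, (k−1) + 3p]`
(1-based, inclusive); reverse frames apply the same formula on the reverse
complement and report the interval in forward coordinates with
start ≤ end. The map is exact and invertible on codon-aligned intervals,
and the test suite holds it to an independent codon-walk oracle.

## ORF calling

An ORF is the maximal coding stretch within one stop-delimited segment of a
frame translation: from the first ATG (default) or the segment start
(`atg_start=False`) to the residue before the stop. Nested ORFs sharing a
stop are not enumerated. Defaults (`OrfPolicy`): ATG starts, minimum 25
residues (~75 nt, a common ORF-finder floor), unterminated 3′ ORFs allowed
because assembled transcripts are frequently 3′-incomplete.

The reported nucleotide span **excludes** the stop codon, so
`nt_end − nt_start + 1 = 3 × protein_length`; a 951-nt coding stretch
yields a 317-residue protein. "Longest ORF" ties are broken by frame order
+1, +2, +3, −1, −2, −3, then 5′ position, so the choice is deterministic.

## Domain scanning

The unit of scanning is the frame translation (all of it, not just ORFs),
because a domain hit outside any ORF is itself diagnostic (it is reported
and excluded with reason `hit-outside-orf`). Two evidence sources are
supported:

- **NCBI Batch CD-Search tables** (`parse_cdd_hits`): the tab-separated
  dialect with `#` comment lines and `Q#n - >id` query names. Rows whose
  query cannot be parsed are logged and reported, never silently dropped.
  `split_batches` partitions a proteome into seeded, reproducible batches
  of ≤ 4000 records — the upload limit the original workflow worked
  around — and the partition property (nothing lost, nothing duplicated)
  is tested.
- **Built-in profiles** (`builtin_scan`): exact/approximate motifs
  (score = matching positions, threshold = length − max_mismatches) or
  position weight matrices over the 20 standard residues. Windows
  containing `X` or `*` never hit. The scanner is held equal to a
  brute-force window-scoring oracle in the tests.

Target selection (`select_target_hits`) is a case-insensitive substring
match on the domain short name, so `SH2` keeps both specific `SH2` hits and
`SH2 superfamily` hits.

## Homology matching

A hit passes if query coverage ≥ 50%, identity ≥ 30%, and
e-value ≤ 1e−5 — all inclusive; a missing (NaN) coverage fails closed. The
best hit is chosen by lowest e-value, then highest bitscore, then highest
identity. These are deliberately ordinary BLASTp-style thresholds; they are
parameters (`MatchCriteria`), not constants.

External BLASTp tabular output (12- or 13-column `-outfmt 6`) is parsed by
`parse_blast_tab`; coverage comes from the 13th column (`qcovs`) when
present, else from supplied query lengths, else NaN.

The built-in `naive_homology_search` is a labeled stand-in for BLASTp, not
a database search engine: Biopython's `PairwiseAligner`, local mode,
BLOSUM62, gap open −11 / extend −1, with raw scores converted to bitscores
and e-values using standard gapped Karlin–Altschul parameters (λ = 0.267,
K = 0.041) and `E = m·n·2^(−bits)`.

One correction is applied to the optimal local alignment before statistics
are computed: it is trimmed to its **maximal-scoring contiguous segment**
(Kadane's algorithm over per-column substitution scores, with affine gap
runs as atomic events). An optimal local alignment has no X-drop cutoff, so
a strong anchor (e.g. a shared 100-residue domain) can afford to extend
through unrelated sequence at marginally positive score and inflate
coverage and identity; the trimmed segment restores HSP-like statistics.
Limitations remain: one HSP per reference pair, no composition-based score
adjustment, and e-values that are only calibrated to order hits sensibly
within the small synthetic panel.

## Architecture comparison and categories

A transcript's candidate architecture is the ordered list of domain names
of its in-ORF hits along the primary ORF. Against the best reference's
architecture it is:

- `full-match` — equal ordered lists;
- `partial-subsequence` — a proper (possibly gapped) ordered sublist,
  found by greedy leftmost embedding; the missing reference domains are
  reported;
- `disjoint` — anything else (including an empty candidate).

Categories: passing hit + full match → **1**; passing hit + partial →
**2**, with the likely cause attached (`merge-partner`, `frame-split`,
`truncated`); passing hit + disjoint → **2** with reason `review`
(conflicting evidence is surfaced, not hidden); no passing hit → **3**;
domain hit in no ORF → excluded. A full match that nevertheless has a
merge partner keeps category 1 but carries the warning
`full-match-despite-merge-partner`.

## Split transcripts and frameshifts

Two ORF proteins merge when one's suffix equals the other's prefix exactly
over ≥ 8 residues (default `min_merge_overlap`; an exact-overlap junction
shorter than that is too likely by chance in a 20-letter alphabet).
The overlap must be **proper** — shorter than both proteins — because
containment is redundancy, not a junction. Both orders are tried and the
longest junction wins. Candidate partners are transcripts whose best
reference agrees.

A frame-split is declared when the reference domains are covered by in-ORF
hits in ≥ 2 distinct frames of the same transcript, each frame covering a
contiguous, non-overlapping block of the reference order; domains covered
by no frame are reported as the gap. This is the signature of a small
indel: upstream domains readable in one frame, downstream in another.

## Dedup, contamination screen, funnel

Dedup is by exact ORF protein string; the representative is the
lexicographically smallest accession, and the full member list is kept.
The contamination screen removes whole accessions and trims others to a
1-based keep-interval; removal dominates trimming; unknown accessions are
an error, not a no-op; `input = removed + output` always holds.

The funnel report keeps two deliberately different countings: stage counts
(translated records, domain-bearing transcripts, unique ORFs, duplicates
removed, hits outside ORFs, ...) which are **not** a subtraction chain, and
`terminal_bins`, which places every input transcript in exactly one of
`no-domain`, `outside-orf`, `duplicate`, `truncated`, `unique` so the
totals always reconcile.

## The synthetic generator

`synthfix` exists because real assemblies have no ground truth. Design
choices that matter:

- **Domain consensus peptides** are fixed random methionine-free sequences
  (generator seed 20241118, independent of the user's seed), so exact-motif
  profiles detect them and an engineered start codon is always the only
  ATG that matters. Reference panel: five architectures over SH2/SH3/
  Kinase/PH/PI-PLC/C2/SAM/WW/PHA02682 domains.
- **Reverse translation randomizes synonymous codons.** A fixed
  codon-per-residue table produces unnaturally stop-free off-frame
  readings, which creates spurious long ORFs in other frames; randomized
  synonymous choice restores natural ~3/64 stop density off-frame.
- Cassettes are fenced with TAA stops and embedded at a frame-correct
  offset; plants on negative frames embed the reverse complement.
- Error classes: `split` (two transcripts sharing an exact junction, with
  an engineered methionine at the junction so the downstream fragment has
  an ORF), `frameshift` (single-nucleotide deletion upstream of an
  engineered internal ATG, so downstream domains land in a different
  frame), `truncate`, `duplicate` (two identical-protein transcripts),
  `novel` (the domain inside a long unique protein — see below), and
  `outside-orf` (a methionine-free domain cassette with no start codon, so
  the hit lies in no ORF).
- The `novel` plant's padding defaults to 3000 residues. The category-3
  expectation rests on homology coverage < 50%, and a local alignment
  anchored on the shared domain can extend into random padding at
  net-positive score; that extension is bounded by the subject's length
  (largest panel reference ~810 aa), so padding sized against that bound
  makes the coverage failure structural (observed ≈ 11% worst case across
  seeds) rather than marginal.
- Ground truth records, per planted transcript: the expected category, the
  ORF protein, split partners and junction peptides, the merged protein,
  and for frameshifts the frames and domain assignment on each side.

The generator is scoped to what the pipeline tests need: single-plant
cassettes per transcript, uniform random background, no sequencing error
model, no expression levels, no alternative splicing.

## Numerical and reproducibility conventions

All randomness flows from explicit integer seeds through `random.Random`
instances; the same `PlantSpec` yields byte-identical FASTA. Sub-seeds
derived for pipeline stages stay below 2³¹. Positions are 1-based inclusive
throughout the public API; Python half-open intervals appear only
internally. Criteria comparisons are inclusive at the boundary, and e-value
arithmetic is done in log2 space (bitscores) before exponentiation to avoid
underflow for strong matches.

Problem sizes quoted in the acceptance script (96,723 transcripts;
105,191 screened; 4000-record batches) are package choices that demonstrate
behaviour at a realistic survey scale.
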