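# Methods note

This note records the model implemented by `mirsig`, the semantics of the
synthetic-data generators, and the numerical choices that affect results.

## The positional GC-signature model

A signature model (`mirsig.signature.SignatureModel`) over 21-nt sequences
consists of:

- **core G/C positions** {8, 9, 18, 19} and **core A/U positions**
  {5, 7, 10, 15} — the strong positional preferences;
- **loose G/C positions** {2, 3, 4, 6, 21} and **loose A/U positions**
  {17, 20} — weaker preferences, weighted 0.5 in the score;
- a **GC band** of overall GC content, default 40–60% inclusive;
- a sequence **length** of 21 nt (evaluation of other lengths is an error,
  not a silent negative).

`evaluate_signature` reports per-position matches, a score
(core matches + 0.5 × loose matches, maximum 9.5), overall GC, band
membership, and the boolean `has_signature`. The default **core policy is
strict**: `has_signature` requires all eight core positions to match *and*
GC in the band. An `at-least-k` policy is available because the exact
boolean rule used to label reads "with GC signature" in classification
figures is a judgement call; strictness only shrinks the positive class,
so the nesting invariants below hold under either policy. Loose positions
never gate the boolean; they only contribute to the score.

The reference pair `OSA_MIR528_5P` (`UGGAAGGGGCAUGCAGAGGAG`, 13/21 GC =
61.9%) and its m1 variant (positions 7 and 10 mutated to A and U, 11/21 GC
= 52.4%) demonstrates the model: the wild type fails on band and on core
positions 7/10; m1 satisfies all eight core positions inside the band.

## miRNA–target geometry

A 21-nt miRNA pairs antiparallel with a 21-nt target site, so miRNA
position *i* maps to site position *j* = 22 − *i* (an involution;
position 12 ↔ position 10). Star-strand design follows small-RNA duplex
geometry: star positions 1–19 are the reverse complement of guide
positions 1–19 (19 paired bases, guide position *i* ↔ star position
20 − *i*) and the star carries a 2-nt 3′ overhang (`UU`), mirroring the
2-nt 3′ overhang formed by guide positions 20–21. amiR candidates are
ranked by (band membership, signature score, |GC − 0.5|, 5′ U,
sequence) — the last two as deterministic tie-breakers.

Anthocyanin content is computed as
(A530 − 0.25 × A657) × 5 / fresh weight (g). A negative corrected
absorbance is returned as-is with a warning.

## Dinucleotide-preserving shuffling and its boundary artifact

`dinucleotide_shuffle` implements the Euler-path (Altschul–Erickson)
algorithm: treat bases as vertices and adjacent pairs as edges, draw a
uniform last-edge arborescence, and walk an Eulerian path. This preserves
the exact dinucleotide multiset — and therefore also the mononucleotide
counts and the **first and last base** of every sequence. Endpoint pinning
is a mathematical property of any dinucleotide-preserving shuffle, not an
implementation choice, and it has measurable consequences on 21-mers:

- positions 1 and 21 are never randomized;
- positions adjacent to a pinned base remain constrained through the
  dinucleotide multiset. Empirically (one fixed 5,000-sequence
  signature-distributed set, 20 independent shuffles each), position 2
  retains ≈ +3% absolute GC deviation, position 20 ≈ −4%, and — because
  the 3′ terminal base is GC-rich (0.7) in the signature distribution —
  the constraint reaches two positions inward, leaving ≈ +1% at
  position 19. On the 5′ side, where the terminal base is compositionally
  neutral, no deviation is detectable beyond position 2.

Shuffle-null checks therefore assert strict flatness (3 binomial SE)
over positions 4–18, a three-position guard band at each end, and a
coarse erasure bound (< 0.05 deviation, versus ≈ 0.2 positional
deviations in unshuffled signature sets) over all non-pinned positions
2–20, so a surviving signature anywhere outside the pinned bases is still
detected.

Distribution comparisons (e.g., GC of one sequence set versus another)
delegate to `scipy.stats.mannwhitneyu` (two-sided).

## Target-site GC normalization

`background_position_gc` estimates, for each of the 21 site positions,
the background probability of G/C from windows drawn uniformly over all
eligible (sequence, start) pairs of a cDNA pool. `normalized_site_gc`
divides the observed per-position G/C frequency of a set of sites by this
background, and computes the same ratio for the immediately adjacent
upstream and downstream 21-nt windows (out-of-bounds flanks are skipped).
For signature-complementary sites the ratio rises above 1 at target
positions mapped from miRNA core G/C positions and falls below 1 at
positions mapped from core A/U positions, while flank ratios stay near 1.

## Read mapping and abundance classes

Mapping is exact-match on the forward strand (optionally antisense), with
a 16–35-nt read-length filter. Reads are filtered at **RPM strictly
greater than 5**. Abundance summaries report four classes:

- `all_21_24` — mapped reads of 21–24 nt;
- `len_21` — mapped 21-nt reads;
- `band` — mapped 21–24-nt reads whose GC content lies in the model's
  band;
- `band_signature` — mapped 21-nt band reads that carry the signature.

A read mapping to multiple positions of the reference is counted once.
**Choice:** the band class is restricted to the 21–24-nt range. Applying
the GC band to reads of any length would let a read outside 21–24 nt
enter `band` but not `all_21_24`, breaking the nesting invariant
`band_signature ≤ band ≤ all_21_24` that the summaries are meant to
satisfy on every dataset; the range restriction makes the invariant hold
by construction.

## Synthetic-data generators

All generators take an explicit seed or `numpy.random.Generator`; the
same seed reproduces byte-identical output. Defaults are fixed study
conditions, not tuning knobs:

- `signature_pfm(core_strength=0.90, loose_strength=0.70,
  background_gc=0.50)` — a 21×4 positional frequency matrix placing the
  preferred base class with the stated probability at core/loose
  positions (split evenly within {G, C} or {A, U}) and a uniform
  composition elsewhere; `gen_mirnas` samples positions independently
  from it.
- `gen_precursor(mature, arm_gc=0.30, loop_gc=0.30, ...)` — arm5 +
  mature + loop + star + arm3 with exact recorded 1-based spans; the star
  is the designed duplex partner of the mature.
- `gen_dicing_reads(precursor, fidelity=0.8, n, ...)` — a mixture: with
  probability `fidelity` a canonical read (mature or star, 50/50);
  otherwise a variant read whose 5′ end is drawn near a duplex boundary
  (probability 0.7, within ±3 nt of a span start) or uniformly along the
  precursor, with length drawn from weights {20: 0.15, 21: 0.50,
  22: 0.20, 24: 0.15}. Reads are collapsed to unique sequences with
  counts and RPM (RPM sums to 10⁶).
- `gen_target_mrna(mirna, mrna_length=500, background_gc=0.42,
  site_position=240, mismatch_positions=(), ...)` — background sequence
  with a planted site that is the exact reverse complement of the miRNA,
  except at requested site positions where a non-pairing, non-wobble base
  is substituted.
- `gen_signature_read(model, rng)` — a 21-mer satisfying all core
  positions with total G/C count drawn from 9–12 (GC in the band);
  `gen_read_pool(model, signature_frac, n)` plants an exact fraction of
  signature reads (negatives flip one core position, so they fail the
  strict rule by exactly one position).
- `build_paperlike_construct(seed)` — one transcript carrying four stems
  whose matures have fixed compositions: 28% GC, 52% GC with the
  signature, 52% GC scrambled (all core positions violated), and 71% GC.
  `gen_paperlike_reads` assigns stem weights {0.075, 0.70, 0.15, 0.075}
  and per-stem dicing fidelities {0.40, 0.80, 0.50, 0.40}, so the
  signature stem dominates the canonical-read pool (expected exact-mature
  share 0.70 × 0.80 × 0.5 = 0.28).

## Numerical choices

- Positional matrices support `unique` (default) and abundance-weighted
  sequence weighting; summary GC values are means over unique sequences
  unless stated otherwise.
- Site finding (`find_site_naive`) scores Watson–Crick pairs 1 and G:U
  wobbles 0.5 and returns the first maximum along the transcript.
- Acceptance-style quantities are computed at desk scale (500–20,000
  samples) with seeds spawned from a single `--seed` via
  `numpy.random.SeedSequence`; every derived seed is reduced below 2³¹.

## Limitations

- Mapping is exact-match only; no mismatched or gapped alignment, and no
  genome-scale indexing.
- The signature model is positional and independent across positions; it
  does not model secondary structure or pairing energetics, and the site
  finder ignores bulges and target accessibility.
- The conservation module's default species→clade map covers common
  model-organism codes only; analyses of other species require a
  user-supplied clade table.
- Generator read pools are idealized (no sequencing error, no adapter
  artifacts); they are designed for estimator validation, not for
  benchmarking aligners.
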