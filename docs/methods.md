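# Methods

## Problem and model

`broadguide` searches a genome for single guide-RNA sequences with many
binding sites concentrated in large contiguous windows. The pipeline has six
stages:

1. **Extract** — every position on both strands whose flanking bases realize
   the PAM pattern yields a candidate protospacer, *including overlapping
   occurrences*. Identical protospacer+PAM sequences from different loci
   collapse into one guide with multiple origins. Candidates overlapping an
   unknown base (N) are discarded, and an optional GC window filters on the
   full guide sequence.
2. **Map** — for each guide, every end-to-end alignment within a mismatch
   budget (0–3 substitutions, protospacer only) whose adjacent PAM matches
   the pattern exactly is a hit. Enumeration is capped per guide (default
   10,000) with a saturation flag carried into the report.
3. **Window** — hits are assigned to sliding windows of size *k* (default
   step *k*/10) by hit start position (half-open intervals). Windows with
   fewer than `min_hits` hits for a guide (default 5) are dropped —
   singleton and near-singleton guides disappear here.
4. **Score** — window score W = Σ (m−n−g)/L over contained hits; evenness E
   per window.
5. **Select** — per guide, up to `n_bins` non-overlapping windows are chosen
   greedily by W (ties: leftmost start, then chromosome name). Hits inside
   the chosen bins are on-target (*h*), all others off-target (*o*), and the
   aggregate score is
   S = w·E + (h/t)·(W_on/h) − (o/t)·(W_off/o), a zero-hit term contributing 0.
   Guides are ranked by descending S, ties by higher h then sequence.
6. **Pool** — bins across guides are sweep-merged (strict overlap by
   default, or within `region_merge_gap` bases) into regions listing every
   contributing guide.

## Score normalization and the evenness term

Summed window scores grow linearly with hit count, so an aggregate score
built directly from ΣW would be unbounded and dominated by copy number
rather than by targeting specificity. The aggregate score therefore uses
*per-hit means* (W_on/h and W_off/o) inside the on/off weighting, which
bounds S in [−1, +1] when the evenness weight is 0: a guide with only
perfect on-target hits scores exactly +1 regardless of copy number, and one
with only off-target hits scores −1. Raw ΣW per bin is still reported.

No closed form for evenness is standard, so E is defined as the population
standard deviation of on-target hit positions (relative to their bin starts)
divided by k/√12 — the standard deviation of a uniform distribution over the
window — capped at 1. Co-located hits give E = 0; uniformly spread hits
approach 1. The evenness weight defaults to 0 so the score keeps its
[−1, +1] range; setting it to 1 adds E per the aggregate formula and widens
the attainable range to roughly [−1, +2] (the CLI exposes
`--evenness-weight`). Dispersion — the positional standard deviation of hits
in the top bin, in bases — is reported separately and is 0 (flagged) below
two hits.

## The internal mapper

All-occurrence approximate matching of a 20-mer cannot rely on a best-hit
aligner, so the mapper is an exact Hamming-distance enumeration: the
protospacer is split into `max_mismatches + 1` disjoint seed chunks (by the
pigeonhole principle any placement within budget contains one exact chunk),
placements are gathered from a k-mer index of the genome and verified with
vectorized base comparisons. The internal mapper is deliberately ungapped —
gaps in 20-mer alignments are aligner-idiosyncratic — and gapped alignments
enter only through SAM import, where g = inserted+deleted bases,
n = NM − g, and m = matched read bases + PAM length (the PAM is re-verified
exactly against the genome and counts as matched; this convention makes
export→import of internal hits an identity). The PAM is never part of the
mismatch budget. Mismatches are penalized uniformly at every protospacer
position; no seed-region weighting and no position-weighted off-target
models are used, by design.

Thread count parallelizes per-guide mapping only; hits are canonically
sorted (chromosome, start, strand) before any output, so outputs are
byte-identical across thread counts, and the hit cap truncates the canonical
order deterministically.

## Coordinates, windows, degenerate inputs

Internally all intervals are 0-based half-open; reports print 1-based
inclusive `chrom:start-end:strand`; BED outputs use standard BED half-open
columns. Sliding windows start at multiples of the step and generation stops
with the first window reaching the chromosome end (clipped there), so the
windows always cover the chromosome exactly without a redundant trailing
fragment. Hit-to-window membership is by hit start — unambiguous for
fixed-length hits. Soft-masked lowercase bases are uppercased and treated as
ordinary sequence; IUPAC ambiguity codes in input genomes degrade to N;
any other character is a fatal parse error naming the record. Guides with
zero hits are retained in the hit table but never reach the report; empty
runs produce a header-only report and exit successfully.

In region-restricted mode, candidates are extracted only from origins fully
inside the supplied BED regions, hits are still mapped genome-wide, and
target windows are tiled inside the regions only — so selected bins lie
within the regions and every hit outside them counts as off-target. A region
spanning a whole chromosome reproduces the unrestricted run for that
chromosome's guides exactly.

## Synthetic fixtures

The generator plants repeat families — one protospacer+PAM sequence copied
at known loci — into i.i.d. background of chosen GC: clustered copies inside
a declared interval and scattered copies elsewhere, each with a prescribed
number of protospacer substitutions (never in the PAM), on random strands,
never overlapping. The background is rejection-checked so no accidental
exact protospacer copy arises, making the manifest exact ground truth for
t, h, o, mismatch histograms and bin locations. The same seed reproduces the
genome byte-for-byte.

What the fixtures do **not** emulate: real repeat families (Alu, LINE-1,
MITE) with their internal substructure and length variation, GC isochores or
any positional base composition, assembly gaps, and gapped divergence
between copies. Passing tests therefore demonstrate correctness of the
enumeration, scoring and selection machinery on known ground truth — not
that any particular natural genome contains usable multi-targeting guides;
on real genomes the hit-cap saturation and GC filters matter far more than
they do here.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| PAM | NGG, 3′ | Cas9; 5′ PAMs (e.g. TTTV) supported for Cas12-class nucleases |
| protospacer length | 20 nt | guide length L = 20 + PAM length |
| mismatch budget | 3 | substitutions tolerated in the protospacer |
| hit cap | 10,000 | per-guide enumeration ceiling, flagged on saturation |
| window size k | 50 kb | target window; hundreds of kb for broad imaging targets |
| step | k/10 | sliding-window stride (window counts depend on it; logged) |
| min hits | 5 | minimum hits per retained window |
| n bins | 1 | target bins selected per guide |
| evenness weight | 0 | weight of E in S (0 keeps S ∈ [−1, +1]) |
| GC bounds | 0–1 | filter on the full guide sequence (e.g. 0.5–1 for GC-rich designs) |

## Problem sizes in the test and acceptance runs

Routine tests use genomes of 2–20 kb with windows of 2–10 kb so that the
pure-Python brute-force oracle (O(genome × L)) stays authoritative and fast;
the acceptance script uses a 150 kb three-chromosome genome with three
planted families, window size 10 kb, step 1 kb and mismatch budget 3 —
a scaled-down analog of a small eukaryotic genome run that exercises every
stage at full parameter settings. These sizes are the package's chosen test
conditions; all thresholds (min hits 5, budget 0–3, cap 10,000) match the
pipeline defaults above.

## Known limitations

- The internal mapper finds substitution-only hits; guides whose biological
  off-targets involve bulges require external SAM import.
- Greedy bin selection is optimal for well-separated clusters but not in
  general; no set-cover optimization of minimal guide panels is attempted.
- No on-target efficiency prediction (Doench-style) and no chromatin
  awareness: ranking reflects sequence-level multiplicity and specificity
  only.
- Stage caching keys on file path, size and mtime plus parameters; moving a
  genome file without touching it can reuse a stale cache in pathological
  cases (delete the intermediates to force recomputation).
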