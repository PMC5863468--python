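# Methods

## Model

A spaced seed is a binary pattern whose shape Q ⊆ ℕ collects the offsets of
the 1s; weight W = |Q|, span s(Q) = max(Q)+1. The rank vector
m(k) = |{i ∈ Q : i < k}| gives, for every seed position k, the number of
match positions strictly to its left. The Q-gram at position i of a read x
is the W-symbol string x[i+Q]; its Rabin–Karp hash packs the 2-bit encodings
(A=00, C=01, G=10, T=11) into one 64-bit word,

    h(x[i+Q]) = OR_{k∈Q} encode(x[i+k]) << 2·m(k),

first matched symbol in the least-significant bits. No modular reduction is
applied: the hash is the exact 2W-bit word, which is why weight is capped at
32. Debug/printing renders the word MSB-first.

## Incremental computation

If the hash at position i−j is known, the symbols it shares with the hash at
position i are exactly the compatibility set

    C_j = { k−j ∈ Q : k ∈ Q ∧ m(k−j) = m(k) − m(j) }.

The membership condition k−j ∈ Q says the symbol is still a matched symbol
after the shift; the rank condition m(k−j) = m(k) − m(j) says its 2-bit field
lands at the right offset after one uniform right shift of the whole word by
2·m(j) bits. The per-position recurrence is therefore

    reused  = (h[i−j] >> 2·m(j)) & keep_mask_j
    h[i]    = reused  OR  OR_{k ∈ Q\C_j} encode(x[i+k]) << 2·m(k)

with keep_mask_j covering the 2-bit fields {2·m(k) : k ∈ C_j}. The lag is
chosen per lookback window s as ArgBH(s) = argmax_{j∈[1,s]} |C_j|; in steady
state (window s(Q)−1) each position costs W − |C_ArgBH(s(Q)−1)| symbol
encodings instead of W. All C_j sets, reuse plans and the ArgBH table are
precomputed once per seed in O(s(Q)²·W) and never touched per position.

Note |C_j| can be strictly smaller than the overlap |Q ∩ (Q−j)|: an
overlapping position whose left-rank changes under the shift cannot be
carried over (for `10111011`, C_2 keeps {0,4} although the shifted shapes
overlap in three positions). We expose both numbers but draw no conclusion
about when they differ.

For a set S of seeds of equal span L hashed simultaneously, the sets
generalize to ordered pairs,

    C^yz_j = { k−j ∈ Q_y : k ∈ Q_z ∧ m_y(k−j) = m_z(k) − m_z(j) },

and ArgBSH(y,s) maximizes |C^yz_j| over source seeds z and lags j ∈ [1,s].
The rank condition again guarantees that a single uniform right shift by
2·m_z(j) places every kept field at the offset seed y requires, so the
kept-field remapping one might expect in the cross-seed case can never be
needed; correctness is guarded by the oracle-equivalence property tests.
Reuse is restricted to strictly earlier positions (j ≥ 1): same-position
cross-seed reuse would create an ordering dependency within a position and
is deliberately not implemented.

## Numerical and design choices

- **Tie-breaks.** ArgBH ties on |C_j| go to the smallest j (shortest
  dependency, most positions past the transient); ArgBSH ties go to the
  smallest j, then the smallest source-seed index. Plans are therefore
  deterministic functions of the seed set alone.
- **Transient.** Within a segment, position 0 is computed from the
  definition; position i < s(Q)−1 uses ArgBH restricted to window i, reusing
  whatever is available. Steady-state per-symbol statistics are averaged
  over positions i ≥ s(Q)−1 only.
- **Ambiguous bases.** Reads are split into maximal ACGT-only segments
  (case-insensitive); each segment is hashed independently and windows
  overlapping an N or IUPAC code are simply never emitted. This keeps every
  emitted hash valid without per-bit validity tracking. `encode_symbol`
  returns a sentinel rather than raising, so streams never crash mid-read.
- **Validation.** Patterns must start and end with `1`: every published seed
  does, and accepting padding zeros would silently disagree with
  span = max(Q)+1. Weight > 32 is an error, never a truncation.
- **Storage.** The engine emits all hashes of a read anyway, so the output
  array doubles as the lookback window (only the last s(Q)−1 entries are
  read); segments reset the recursion.
- **Degenerate inputs.** Empty sequences, reads shorter than the span, and
  the span-1 seed `1` (empty compatibility table, every position "naive" at
  cost 1) are all well-defined and tested.

## Performance accounting and prediction

Wall-clock speed is hardware-dependent, so the portable proxy is the number
of symbols read and encoded: W per position naively, versus the insertions
the chosen reuse plans actually perform. Under the cost model in which
shifts and insertions cost the same, the predicted steady-state speedup is
W / (W − |C_ArgBH(s(Q)−1)|) for one seed and Σ W_y / Σ (W_y − kept_y) for a
simultaneous set (kept_y from ArgBSH at full window). This ratio is our own
reconstruction consistent with that cost model; the benchmark reports it
next to measured counts, and wall-clock timings are printed as informational
only and never asserted. The benchmark verifies FSH output against the naive
oracle on every read before timing.

## Synthetic data

The simulator emulates the shape of shotgun read sets used to exercise the
engine: a uniform random ACGT genome, reads drawn uniformly with fixed
length (defaults cover the Illumina-like ~80 bp to 454-like ~700 bp range),
and uniform substitution errors at 1% per base (an erroneous base becomes a
uniformly chosen *different* base). Real read sets at this scale run to
10⁵–10⁷ reads; the test and acceptance runs use tens of reads and genomes of
10⁴–2·10⁴ bp, which is already far past the s(Q)−1 transient the statistics
depend on. Omitted on purpose: indels, position-dependent error profiles,
quality values, paired-end structure, and non-uniform genome composition —
the hashing engine is exactly output-equivalent to the naive definition on
*any* input, so error realism affects neither correctness nor the counting
statistics, only read length and composition do. Passing tests on simulated
reads therefore certify the engine's correctness and its encoding counts,
not classification performance on real metagenomes.

## Limitations

- Multi-seed mode requires all seeds to share one span.
- The cyclic-polynomial (rotate/XOR) hash family and canonical
  (strand-symmetric) hashing are out of scope; hashes are strand-specific.
- Seed design (sensitivity or overlap-complexity optimization) is out of
  scope: seeds are inputs.
- The per-position inner loop is pure Python; throughput is adequate for the
  read lengths above but this library optimizes symbol *counts*, not
  wall-clock time.
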