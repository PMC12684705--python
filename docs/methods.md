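# Methods

## Problem and threat model

A client owns a genome (FASTA) or a sequencing read set (FASTQ) and wants to
outsource both storage and exact k-mer search to a server it does not trust
with the plaintext. The adversary is honest-but-curious: the server follows
the protocol but may inspect everything it stores and computes on. The
protocol guarantees that the server sees only ciphertexts — neither the
sequence, nor the query k-mers, nor which windows matched.

## Encrypted search protocol

### Encoding and layout

Bases A, C, G, T are encoded as integers 0–3; padding and every other
character (N, IUPAC codes, gaps) encode as 4. The concatenated source is
split into overlapping chunks (default 256 KB of sequence, overlap
k_max − 1 — the minimum that places every window of length ≤ k_max wholly
inside one chunk). Because consecutive chunk *starts* advance by
chunk_size − (k_max − 1), which equals the per-chunk window count, window
start positions never repeat across chunks; deduplication at decryption is
therefore a safety net, not a correction. The final chunk is right-padded
with k_max − 1 pad symbols so trailing windows exist for every k ≤ k_max.

Each chunk is transposed into k_max *stride vectors*: stride j holds the
j-th character of every sliding window. Strides are segmented into batches
of `slot_count` windows (the SIMD width of one ciphertext) and each stride
segment is encrypted into one ciphertext. FASTQ reads are concatenated with
k_max − 1 pad symbols between reads, so no window over {0..3} can span a
read boundary; Phred qualities travel alongside in the same layout (pads
carry quality 0) when server-side quality aggregation is requested.

A query k-mer of length k ≤ k_max becomes k ciphertexts, each encrypting
the character's code replicated across all slots.

### Server computation

For each (batch, query) pair the server computes the encrypted
sum of squared differences over all windows simultaneously:

    SSD_i = Σ_{j=0}^{k−1} (C_{i+j} − K_j)²

using exactly k homomorphic subtractions, k squarings (each immediately
relinearised) and k − 1 additions. No squaring output feeds another
squaring, so the multiplicative depth is 1 regardless of k — the property
that makes modest lattice parameters sufficient. Window quality sums use
additions only (depth 0). The server's whole interface is three
directories (deploy/, queries/, results/); it never receives secret key
material, and the test suite audits that its code path opens no file
outside those directories.

### Match semantics

SSD_i = 0 if and only if the window equals the query: each term is a
square, so the sum vanishes only when every character matches. Symbols lie
in {0..4} and query characters in {0..3}, so a single term is at most
(4−0)² = 16, and with the default 20-bit plaintext modulus t = 786433 any
k_max ≤ (t−1)/16 is free of slot wraparound — no false zeros are
arithmetically possible. SSD = 0 is equivalent to Hamming distance = 0;
nonzero SSD values are *not* Hamming distances and are reported only as
non-matches. The client decrypts each result vector, takes the zero slots
among the batch's valid windows, and maps slot indices back through the
manifest to record-relative coordinates (0-based, half-open).

## The lattice backend

No FHE library ships with the package's environment, so the backend is
implemented here: a standard scale-by-Δ BFV scheme over
R_q = Z_q[x]/(x^n + 1), restricted to the operations the protocol needs
(no rotations, no modulus switching, no bootstrapping).

* **Batching.** t ≡ 1 (mod 2n) makes x^n + 1 split completely mod t; slot
  encode/decode are inverse/forward negacyclic NTTs mod t. Slot-wise
  addition and multiplication then correspond to ring operations.
* **Keys and encryption.** Ternary secret and encryption randomness,
  discrete-Gaussian errors (σ = 3.2, truncated at 6σ). Encrypt(m) =
  (pk0·u + e1 + Δ·m, pk1·u + e2) with Δ = ⌊q/t⌋.
* **Multiplication.** Ciphertexts are tensored exactly over the integers —
  products are computed by CRT over enough 31-bit NTT-friendly auxiliary
  primes that the signed result is reconstructed exactly — then scaled by
  t/q with rounding. Relinearisation decomposes the quadratic component
  into base-2^w digits (w ≈ ⌈log₂q⌉/4 bits, capped at 60) folded with the
  evaluation key, restoring ciphertext size 2 after every squaring.
* **Noise budget.** The invariant noise budget is computed exactly from
  the secret key as ⌊log₂(q / 2·max|t·v − q·m|)⌋ where v is the decrypted
  phase; decryption is correct while the budget is positive.

The production profile mirrors the common SEAL-style configuration:
degree 8192, a {43,43,44,44,44}-bit coefficient chain (≈218 bits) and the
20-bit batching prime, targeting 128-bit security. Measured on this
implementation, a fresh ciphertext holds ~173 bits of budget and a full
k = 16 SSD evaluation ends with ~125–129 bits — order-of-magnitude
agreement with what a depth-1 circuit at these parameters should leave.
The reduced profiles (degrees 1024 and 2048) exist purely for fast tests:
their chains (120/126 bits) are chosen so that even depth-2 expressions
decrypt correctly, and they make no security claim (`security_bits=0`).
All protocol logic is parameterised by `slot_count`; nothing assumes
degree 8192.

A second backend ("clear") performs the identical slot-wise arithmetic
mod t on plain vectors. It is the deterministic reference the entire
protocol suite runs against first; the lattice backend is then required to
agree with it slot-for-slot on randomized instances.

## Quality filtering (FASTQ)

Three window filters over the k matched bases: minimum, average, and sum
of Phred scores. Sum and average use the server's homomorphic window sums
(depth 0); the average is compared in integer arithmetic as
sum ≥ ⌈k·threshold⌉ to avoid floating point on decrypted integers. The
minimum is a non-linear aggregate whose homomorphic evaluation would
explode the multiplicative depth, so it is computed by a plaintext scan on
the trusted client, which holds the original FASTQ anyway.

## Motif search reduction

Scoring a position weight matrix directly under encryption would require a
private value selection per encrypted base; instead the probabilistic
search is reduced offline to a deterministic k-mer set:

1. **PSSM.** score(j, b) = log₂(((p_jb + c·bg_b)/(1 + c))/bg_b) with
   background-weighted pseudocount c (default 0.1) and log base 2 (bits,
   the motif-scanning convention). Scores are discretised to 1000 integer
   bins over the matrix's score range (FIMO-style); with pseudocount 0 a
   zero-probability cell scores −∞ and is floored to the lowest bin.
2. **Exact p-values.** The discretised score distribution under the
   background is computed by positional convolution (a dynamic program
   over integer score totals); tail sums give P(score ≥ s). This is exact
   for the discretised matrix — verified against exhaustive 4^k
   enumeration to < 1e-9 for k ≤ 8.
3. **Enumeration and FDR.** All 4^k k-mers are scored (guard at k ≤ 16,
   warning above 12), sorted by (p-value, k-mer) — the lexicographic
   tie-break keeps output reproducible — and assigned Benjamini–Hochberg
   q-values with m = 4^k.
4. **Output.** K-mers with q ≤ threshold (or p ≤ threshold with the
   alternative flag) are written as a plain query list plus a detail CSV.

Because p-values are anti-monotone in the discretised score and BH
q-values are monotone in p, every significant set is a score-threshold
set; searching it therefore reports exactly the positions a plaintext
thresholded PSSM scan reports (forward strand). Note that under a uniform
background the tail p-value of the rank-i k-mer is exactly i/4^k, so all
q-values equal 1 — informative q-values require a non-uniform background,
which is the realistic setting (the background is an a-priori model; the
client cannot measure composition on the server's encrypted data). The
search is forward-strand; reverse-complement coverage is an opt-in query
expansion on the client.

## Synthetic data

Fixture genomes are i.i.d. backgrounds at a chosen GC content with exact
k-mer or sampled motif instances planted at recorded coordinates; read
sets draw per-base qualities from a truncated normal (clamped to [2, 41],
Phred+33). The generators are pure functions of their spec (seed
included). They deliberately omit sequencing errors, indels, coverage
structure and quality-by-cycle correlation: the protocol is an exact-match
protocol, so passing tests demonstrate layout, cryptographic and
statistical correctness, not robustness to sequencing noise — a query
differing from the target by one base simply does not match, by design.

## Verification sizes and numerical choices

The acceptance script regenerates everything from its `--seed`: ten
10–60 kb clear-backend fixtures with 10–15 queries each, one 10 kb
lattice-backend fixture (degree-2048 test profile), 100 random
(batch, query) backend-agreement pairs, one full k = 16 SSD at the
production degree-8192 profile, the DP-vs-enumeration and BH checks, and
three FASTQ safety/filter replicates. These sizes are the package's
choice of a thorough-but-quick regression; the protocol itself has no
size-dependent behaviour beyond batch arithmetic.

Numerical conventions: coordinates 0-based half-open (1-based printing is
an output flag); lowercase (soft-masked) bases fold to uppercase; padded
slots in partial batches hold symbol 4 so they can never produce SSD 0;
probability row sums are validated to 1e-3; DP mass conservation to 1e-9.

## Known limitations

* k_max is fixed at encryption time; longer queries require re-encryption,
  and shorter ones pay redundant storage (k_max ciphertexts per batch).
* No server-side match-free block skipping (slot products or
  Fermat-little-theorem zero tests); every batch result is returned.
* The deterministic SSD circuit favours minimal depth over resistance to
  ciphertext side-channel analysis; a randomized variant is out of scope.
* Exact matching only: no mismatches, indels, or degenerate-base queries.
* The lattice backend is a faithful but unaudited implementation; the
  parameter profiles follow standard tables, but no independent security
  review is implied.
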