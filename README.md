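# privkmer

Private exact k-mer search over homomorphically encrypted genomes and
sequencing reads.

## The problem

Outsourcing genomic storage and analysis to a third-party server is often
unavoidable, but genomes are among the most sensitive identifiable data.
`privkmer` lets a client encrypt a genome (FASTA) or read set (FASTQ)
**once**, hand the ciphertexts to an untrusted (honest-but-curious)
server, and then ask "where does this k-mer occur?" without the server
ever learning the sequence, the query, or the answer. A companion utility
reduces position-weight-matrix (PWM) motif searches to significant k-mer
sets so motif scans run through the same encrypted machinery.

## How it works

Bases are encoded A,C,G,T → 0..3 (padding/unknown → 4), chunked, and
transposed into k_max *stride vectors*: stride j holds the j-th character
of every sliding window. Each stride segment of `slot_count` windows is
one SIMD-batched ciphertext under an integer (BFV-style) lattice scheme.
A query k-mer becomes k ciphertexts with the character replicated across
all slots. For every window i — all slots at once — the server computes
the encrypted sum of squared differences

&nbsp;&nbsp;&nbsp;&nbsp;SSD_i = Σ_{j=0}^{k−1} (C_{i+j} − K_j)²,&nbsp;&nbsp;&nbsp;&nbsp;Match(i) ⟺ SSD_i = 0,

with k subtractions, k relinearised squarings and k−1 additions — a
circuit of multiplicative depth 1, which is what keeps the cryptographic
parameters modest (degree 8192, ≈218-bit coefficient chain, 20-bit
plaintext modulus, 128-bit security). Since a single squared difference is
at most 16, the window sum can never wrap a 20-bit slot, so a zero slot
certifies an exact match. Only the client can decrypt; it maps zero slots
back to genomic or read coordinates and, for FASTQ, applies min/avg/sum
Phred-quality filters (sum and average from homomorphic window sums, min
via a client-side scan).

For motif searches, `pwm2kmers` builds a log₂-likelihood PSSM from a
MEME-format PWM and background frequencies, computes the exact
discretised score distribution by dynamic programming (score → p-value),
enumerates all 4^k k-mers, applies a Benjamini–Hochberg correction
(m = 4^k), and writes the q-significant k-mers as a ready-to-encrypt
query list plus a detail CSV.

Two interchangeable backends sit behind one interface: the real lattice
backend, and a "clear" reference backend doing identical slot arithmetic
mod t — the deterministic oracle the whole test suite checks the lattice
backend against. See `docs/methods.md` for the full model, parameter
rationale and limitations.

## Worked example

Search a 20 kb synthetic genome (two planted `GATTACAGATTACA`
occurrences) on the lattice backend, using the reduced degree-2048 test
profile so it runs in under a minute:

```bash
privkmer-client keygen --backend bfv --profile test --keys-dir keys --seed 1
privkmer-client encrypt --input genome.fa --keys-dir keys \
    --deploy-dir deploy --kmax 16 --chunk-size 8192
privkmer-client encrypt-queries --queries queries.txt --keys-dir keys \
    --queries-dir queries --kmax 16
privkmer-server --deploy-dir deploy --queries-dir queries --results-dir results
privkmer-client decrypt --deploy-dir deploy --results-dir results \
    --keys-dir keys --out hits.tsv
privkmer-client verify --input genome.fa --deploy-dir deploy \
    --results-dir results --keys-dir keys
```

which prints

```
keys written to keys (backend=bfv, slots=2048)
deployed 10 batch(es) × 16 strides to deploy
encrypted 2 query k-mer(s) to queries
evaluated 20 (batch, query) task(s) → results
2 match(es) written to hits.tsv
verification OK: encrypted search matches plaintext ground truth
```

and `hits.tsv` contains exactly the planted coordinates (0-based):

```
query_id  query_seq        source_record  position  k   ssd  ...  pass_filter
0         GATTACAGATTACA   chr1           1577      14  0         1
0         GATTACAGATTACA   chr1           9000      14  0         1
```

The absent second query (`ACGTACGTACGTACGT`) correctly yields no rows.
`verify` re-runs a plaintext search client-side and exits non-zero on any
discrepancy. The server's phase report (`results/phase_report.json`)
shows the evaluation is compute-dominated (98.4% compute / 1.6% I/O on
this run). For production deployments use `--profile default`
(degree 8192); for a motif query set, start from
`privkmer-client pwm2kmers --meme motif.meme --q-threshold 0.05
--out-prefix red` and feed `red_kmers.txt` to `encrypt-queries`.

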