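"""Reproducible synthetic inputs: genomes, read sets, motifs, ground truth.

The generators emulate the inputs the search protocol consumes: i.i.d.
background nucleotides at a chosen GC content, planted exact k-mer or
motif-instance occurrences at known coordinates, and FASTQ reads with a
truncated-normal per-base Phred model (clamped to [2, 41], Phred+33).
They produce no sequencing errors and no indels — the protocol is an
exact-match protocol, and the fixtures match it.

Everything is a pure function of the spec (seed included): the same spec
yields byte-identical FASTA/FASTQ/TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .encoding import ALPHABET
from .errors import ConfigurationError

QUAL_MIN, QUAL_MAX = 2, 41


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome with planted occurrences."""

    seed: int = 0
    length: int = 10_000
    gc_content: float = 0.5
    plants: tuple = ()  # (sequence, position | None) pairs
    name: str = "synth_chr1"


@dataclass(frozen=True)
class ReadSetSpec:
    """Parameters of one synthetic FASTQ read set."""

    seed: int = 0
    n_reads: int = 100
    read_length: int = 100
    gc_content: float = 0.5
    plants: tuple = ()  # (sequence, read_index | None, offset | None)
    qual_mean: float = 30.0
    qual_sd: float = 5.0


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A,C,G,T
    return rng.choice(4, size=n, p=probs).astype(np.uint8)


def _to_str(symbols: np.ndarray) -> str:
    return "".join(ALPHABET[s] for s in symbols)


def make_genome(spec: GenomeSpec) -> tuple[str, list[tuple[str, int]]]:
    """Genome string plus ground-truth (sequence, position) plant table.

    Plants with explicit positions go exactly there; positionless plants
    are placed uniformly without overlapping another plant. Over-packed
    plant lists raise a generation error.
    """
    rng = np.random.default_rng(spec.seed)
    symbols = _random_bases(rng, spec.length, spec.gc_content)
    occupied: list[tuple[int, int]] = []
    truth: list[tuple[str, int]] = []

    def clashes(start: int, k: int) -> bool:
        return any(start < e and s < start + k for s, e in occupied)

    for item in spec.plants:
        seq, pos = item
        seq = seq.upper()
        k = len(seq)
        if k > spec.length:
            raise ConfigurationError(f"plant {seq!r} longer than the genome")
        if pos is None:
            for _ in range(1000):
                cand = int(rng.integers(0, spec.length - k + 1))
                if not clashes(cand, k):
                    pos = cand
                    break
            else:
                raise ConfigurationError("cannot place plant without overlap")
        elif pos + k > spec.length:
            raise ConfigurationError(f"plant {seq!r} at {pos} exceeds the genome")
        elif clashes(pos, k):
            raise ConfigurationError(f"plant {seq!r} at {pos} overlaps another plant")
        from .encoding import encode_symbols

        symbols[pos: pos + k] = encode_symbols(seq)
        occupied.append((pos, pos + k))
        truth.append((seq, int(pos)))
    return _to_str(symbols), truth


def write_fasta(path, name: str, sequence: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i: i + width] + "\n")


def write_truth_tsv(path, truth: list[tuple[str, int]]) -> None:
    with open(path, "w") as fh:
        fh.write("query\tposition\n")
        for seq, pos in truth:
            fh.write(f"{seq}\t{pos}\n")


def make_reads(
    spec: ReadSetSpec,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, int]]]:
    """FASTQ triples (id, seq, qual) plus (sequence, read_id, offset) truth."""
    rng = np.random.default_rng(spec.seed)
    reads: list[tuple[str, str, str]] = []
    seqs = [
        _random_bases(rng, spec.read_length, spec.gc_content)
        for _ in range(spec.n_reads)
    ]
    truth: list[tuple[str, str, int]] = []
    from .encoding import encode_symbols

    for item in spec.plants:
        seq, ridx, off = item
        seq = seq.upper()
        k = len(seq)
        if k > spec.read_length:
            raise ConfigurationError(f"plant {seq!r} longer than read_length")
        if ridx is None:
            ridx = int(rng.integers(0, spec.n_reads))
        if off is None:
            off = int(rng.integers(0, spec.read_length - k + 1))
        seqs[ridx][off: off + k] = encode_symbols(seq)
        truth.append((seq, f"read{ridx}", int(off)))
    for i, syms in enumerate(seqs):
        quals = np.rint(
            rng.normal(spec.qual_mean, spec.qual_sd, spec.read_length)
        ).astype(int)
        quals = np.clip(quals, QUAL_MIN, QUAL_MAX)
        qual_str = "".join(chr(q + 33) for q in quals)
        reads.append((f"read{i}", _to_str(syms), qual_str))
    return reads, truth


def write_fastq(path, reads: list[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def sample_queries(
    rng: np.random.Generator, genome: str, n_present: int, n_absent: int,
    k: int,
) -> list[str]:
    """Query mix: k-mers drawn from the genome plus random (likely absent) ones."""
    queries = []
    for _ in range(n_present):
        start = int(rng.integers(0, len(genome) - k + 1))
        sub = genome[start: start + k]
        if any(ch not in ALPHABET for ch in sub):
            sub = _to_str(_random_bases(rng, k, 0.5))
        queries.append(sub)
    for _ in range(n_absent):
        queries.append(_to_str(_random_bases(rng, k, 0.5)))
    return queries


def random_ppm(
    rng: np.random.Generator, width: int, concentration: float = 0.3,
) -> np.ndarray:
    """A width×4 position probability matrix with informative columns.

    Lower ``concentration`` → sharper (more information-rich) positions,
    mimicking a transcription-factor binding motif.
    """
    return rng.dirichlet([concentration] * 4, size=width)


def sample_motif_instance(rng: np.random.Generator, ppm: np.ndarray) -> str:
    return "".join(ALPHABET[rng.choice(4, p=row)] for row in ppm)
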