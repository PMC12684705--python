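"""Deterministic FASTA/FASTQ → SIMD stride-batch encoding with exact coordinates.

Pipeline: text is mapped to integer symbols (A,C,G,T → 0..3; padding and
every unknown character → 4), concatenated per source with pad runs of
k_max−1 between records/reads, split into overlapping chunks, and each
chunk is transposed into k_max *stride vectors*: stride j holds the j-th
character of every sliding window of the chunk. Strides are segmented into
batches of `slot_count` windows — the unit that fits one SIMD ciphertext.

Coordinates are 0-based, half-open throughout. A window starting at
absolute position p lives in exactly one batch (chunks overlap by k_max−1
characters, so window *starts* never repeat); `map_slot_to_coordinate`
inverts the layout back to a record-relative position.
"""

from __future__ import annotations

import hashlib
import json
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO

from .errors import ConfigurationError, FormatError

PAD = 4
ALPHABET = "ACGT"
DEFAULT_CHUNK_SIZE = 262144  # 256 KB of sequence per chunk

_ENCODE_LUT = np.full(256, PAD, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode_symbols(text: str) -> np.ndarray:
    """Map sequence text to symbols {0..4}; case-insensitive, length-preserving."""
    raw = np.frombuffer(text.encode("ascii", errors="replace"), dtype=np.uint8)
    return _ENCODE_LUT[raw].copy()


def decode_symbols(symbols: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[np.asarray(symbols, dtype=np.uint8)].tobytes().decode()


@dataclass
class SourceRecord:
    """One FASTA record or FASTQ read placed in the concatenated coordinate system."""

    name: str
    start: int   # offset in the concatenated symbol vector
    length: int


@dataclass
class EncodedSequence:
    """Concatenated symbol vector with origin metadata.

    Records are separated by runs of k_max−1 pad symbols so that no window
    of length ≤ k_max over {0..3} can span two records.
    """

    symbols: np.ndarray
    source: str                      # "fasta" | "fastq" | "raw"
    records: list[SourceRecord]
    k_max: int
    qualities: Optional[np.ndarray] = None  # aligned to symbols; pads carry 0


def concatenate_records(
    pieces: Iterable[tuple[str, np.ndarray]], k_max: int, source: str,
    quality_pieces: Optional[list[np.ndarray]] = None,
) -> EncodedSequence:
    """Join encoded records with k_max−1 pads between consecutive records.

    No trailing pad run is added here: the chunker right-pads the final
    chunk, which provides the trailing windows for k < k_max.
    """
    pad = np.full(k_max - 1, PAD, dtype=np.uint8) if k_max > 1 else \
        np.zeros(0, dtype=np.uint8)
    records, parts, qparts = [], [], []
    pos = 0
    pieces = list(pieces)
    for idx, (name, syms) in enumerate(pieces):
        records.append(SourceRecord(name, pos, len(syms)))
        parts.append(syms)
        if quality_pieces is not None:
            qparts.append(quality_pieces[idx])
        pos += len(syms)
        if idx + 1 < len(pieces):
            parts.append(pad)
            if quality_pieces is not None:
                qparts.append(np.zeros(len(pad), dtype=np.uint8))
            pos += len(pad)
    symbols = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
    qualities = (
        np.concatenate(qparts) if quality_pieces is not None and qparts else None
    )
    return EncodedSequence(symbols, source, records, k_max, qualities)


def read_fasta(path, k_max: int) -> EncodedSequence:
    """Encode a (multi-record) FASTA file into one padded symbol vector."""
    try:
        recs = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # biopython raises assorted ValueError subclasses
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not recs:
        raise FormatError(f"no FASTA records in {path}")
    return concatenate_records(
        ((r.id, encode_symbols(str(r.seq))) for r in recs), k_max, "fasta"
    )


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Parse FASTQ (Phred+33) into (id, sequence, quality string) triples."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            out.append(
                (rec.id, str(rec.seq), "".join(chr(q + 33) for q in quals))
            )
    except Exception as exc:
        raise FormatError(f"cannot parse FASTQ {path}: {exc}") from exc
    if not out:
        raise FormatError(f"no FASTQ records in {path}")
    return out


def pack_fastq(
    reads: list[tuple[str, str, str]], k_max: int
) -> EncodedSequence:
    """Concatenate reads with k_max−1 pad symbols between them.

    The pad runs guarantee that no k-mer window (k ≤ k_max) over {0..3}
    spans a read boundary. Qualities are carried alongside, aligned to the
    packed positions; pad positions have quality 0.
    """
    pieces, qualities = [], []
    for rid, seq, qual in reads:
        if len(seq) != len(qual):
            raise FormatError(
                f"read {rid}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        pieces.append((rid, encode_symbols(seq)))
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
        if len(q) and (q.min() < 0 or q.max() > 93):
            raise FormatError(f"read {rid}: quality characters outside Phred+33 range")
        qualities.append(q.astype(np.uint8))
    return concatenate_records(pieces, k_max, "fastq", qualities)


@dataclass
class ChunkPlan:
    """Geometry of one chunk of the concatenated source."""

    chunk_index: int
    genomic_start: int  # 0-based offset into the concatenated source
    length: int         # characters, including any tail padding
    overlap: int        # characters shared with the next chunk (k_max−1)


def chunk_sequence(
    symbols: np.ndarray, chunk_size: int, k_max: int, pad_value: int = PAD,
) -> list[tuple[ChunkPlan, np.ndarray]]:
    """Split into overlapping chunks so every ≤k_max window lies in one chunk.

    Consecutive chunks overlap by exactly k_max−1 characters; the final
    chunk is right-padded with k_max−1 pad symbols so trailing windows for
    every k ≤ k_max exist in the stride layout.
    """
    if chunk_size <= k_max:
        raise ConfigurationError(
            f"chunk_size ({chunk_size}) must exceed k_max ({k_max})"
        )
    overlap = k_max - 1
    step = chunk_size - overlap
    tail_pad = np.full(overlap, pad_value, dtype=np.uint8)
    chunks = []
    start = 0
    n = len(symbols)
    while True:
        end = min(start + chunk_size, n)
        piece = symbols[start:end]
        is_last = end >= n
        if is_last:
            piece = np.concatenate([piece, tail_pad]) if overlap else piece.copy()
        plan = ChunkPlan(len(chunks), start, len(piece), overlap)
        chunks.append((plan, piece))
        if is_last:
            break
        start += step
    return chunks


@dataclass
class WindowBatch:
    """One SIMD batch: k_max stride vectors over `slot_count` windows.

    strides[j][i] is the symbol at absolute position window_start + i + j.
    Slots ≥ n_windows are padded with symbol 4 and can never match a
    nucleotide query.
    """

    chunk_index: int
    batch_index: int
    window_start: int  # absolute 0-based coordinate of slot 0's window
    n_windows: int
    strides: np.ndarray  # (k_max, slot_count) uint8


def build_strides(
    chunk_symbols: np.ndarray, k_max: int, slot_count: int,
    chunk_index: int = 0, chunk_start: int = 0, pad_value: int = PAD,
) -> list[WindowBatch]:
    """Transpose a chunk into per-batch stride vectors.

    A chunk of length L yields L − k_max + 1 windows, segmented into
    ⌈windows/slot_count⌉ batches. ``pad_value`` fills slots beyond the
    valid windows (symbol 4 for sequence strides, 0 for quality strides).
    """
    L = len(chunk_symbols)
    if L < k_max:
        raise ConfigurationError(f"chunk of length {L} is shorter than k_max {k_max}")
    n_windows = L - k_max + 1
    batches = []
    padded = np.concatenate(
        [chunk_symbols, np.full(slot_count + k_max, pad_value, dtype=np.uint8)]
    )
    for b, off in enumerate(range(0, n_windows, slot_count)):
        m = min(slot_count, n_windows - off)
        strides = np.empty((k_max, slot_count), dtype=np.uint8)
        for j in range(k_max):
            strides[j] = padded[off + j: off + j + slot_count]
            strides[j, m:] = pad_value
        batches.append(
            WindowBatch(chunk_index, b, chunk_start + off, m, strides)
        )
    return batches


def plan_layout(
    seq: EncodedSequence, chunk_size: int, slot_count: int
) -> list[tuple[ChunkPlan, list[WindowBatch]]]:
    """Chunk the source and build stride batches for every chunk."""
    out = []
    for plan, piece in chunk_sequence(seq.symbols, chunk_size, seq.k_max):
        out.append(
            (plan, build_strides(piece, seq.k_max, slot_count,
                                 plan.chunk_index, plan.genomic_start))
        )
    return out


# -- manifest ------------------------------------------------------------

def build_manifest(
    seq: EncodedSequence, layout, params_dict: dict, backend: str,
    chunk_size: int, with_quality: bool,
) -> dict:
    digest = hashlib.sha256(seq.symbols.tobytes()).hexdigest()
    return {
        "format_version": 1,
        "backend": backend,
        "params": params_dict,
        "source_type": seq.source,
        "source_digest": digest,
        "k_max": seq.k_max,
        "chunk_size": chunk_size,
        "slot_count": params_dict["poly_degree"],
        "total_length": int(len(seq.symbols)),
        "with_quality": with_quality,
        "records": [
            {"name": r.name, "start": r.start, "length": r.length}
            for r in seq.records
        ],
        "chunks": [
            {
                "index": plan.chunk_index,
                "start": plan.genomic_start,
                "length": plan.length,
                "overlap": plan.overlap,
                "batches": [
                    {
                        "index": b.batch_index,
                        "window_start": b.window_start,
                        "n_windows": b.n_windows,
                    }
                    for b in batches
                ],
            }
            for plan, batches in layout
        ],
    }


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def map_slot_to_coordinate(
    manifest: dict, chunk_index: int, batch_index: int, slot: int,
) -> Optional[tuple[str, int, int]]:
    """Invert the layout: (chunk, batch, slot) → (record name, offset, absolute).

    Returns None when the window start falls in an inter-record pad run
    (such a window can never equal a nucleotide query). Raises IndexError
    for a slot beyond the batch's valid windows.
    """
    chunk = manifest["chunks"][chunk_index]
    batch = chunk["batches"][batch_index]
    if slot >= batch["n_windows"]:
        raise IndexError(
            f"slot {slot} out of range (batch has {batch['n_windows']} windows)"
        )
    absolute = batch["window_start"] + slot
    records = manifest["records"]
    starts = [r["start"] for r in records]
    i = bisect_right(starts, absolute) - 1
    if i < 0:
        return None
    rec = records[i]
    offset = absolute - rec["start"]
    if offset >= rec["length"]:
        return None  # inside an inter-record pad run
    return rec["name"], offset, absolute
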