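"""Trusted-side pipeline: encrypt once, query, decrypt, filter, verify.

The client holds all key material and every plaintext artifact. It
performs the one-time encryption of the genome or read set into stride
ciphertexts, encrypts query k-mers (each character replicated across all
SIMD slots), decrypts the server's SSD vectors, maps zero slots back to
coordinates, applies Phred-quality filters, and can verify the whole
encrypted pipeline against its own plaintext ground-truth search.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import encoding, server
from .encoding import (
    ALPHABET,
    EncodedSequence,
    build_manifest,
    encode_symbols,
    load_manifest,
    map_slot_to_coordinate,
    pack_fastq,
    plan_layout,
    read_fasta,
    read_fastq,
    save_manifest,
)
from .errors import (
    ConfigurationError,
    FormatError,
    IncompleteResultsError,
    UsageError,
)
from .he import Context, KeyMaterial
from .monitoring import PhaseTimer

QUALITY_MODES = ("min", "avg", "sum")


@dataclass
class MatchRecord:
    """One certified match: a decrypted zero slot mapped to a coordinate."""

    query_id: str
    query_seq: str
    record_name: str   # FASTA record or FASTQ read id
    position: int      # 0-based offset within the record/read
    absolute: int      # position in the concatenated coordinate system
    k: int
    ssd: int = 0
    min_q: Optional[int] = None
    avg_q: Optional[float] = None
    sum_q: Optional[int] = None       # plaintext window quality sum
    hom_sum_q: Optional[int] = None   # decrypted homomorphic window sum
    pass_filter: bool = True


def detect_input_type(path) -> str:
    text = Path(path).open().read(1)
    if text == ">":
        return "fasta"
    if text == "@":
        return "fastq"
    raise FormatError(f"{path}: neither FASTA ('>') nor FASTQ ('@')")


def load_input(path, k_max: int, input_type: Optional[str] = None) -> EncodedSequence:
    input_type = input_type or detect_input_type(path)
    if input_type == "fasta":
        return read_fasta(path, k_max)
    if input_type == "fastq":
        return pack_fastq(read_fastq(path), k_max)
    raise FormatError(f"unknown input type {input_type!r}")


def encrypt_input(
    path, ctx: Context, keys: KeyMaterial, k_max: int, deploy_dir,
    chunk_size: int = encoding.DEFAULT_CHUNK_SIZE,
    quality_mode: Optional[str] = None,
    input_type: Optional[str] = None,
    timer: Optional[PhaseTimer] = None,
) -> dict:
    """One-time encryption of a genome/read set into a deployment directory.

    Writes ``manifest.json``, the evaluation (relinearisation) key and one
    ciphertext per (chunk, batch, stride). For FASTQ sources with the
    sum/avg quality mode, quality stride ciphertexts are included so the
    server can aggregate window quality sums homomorphically. The secret
    key is never written here.
    """
    if k_max < 1:
        raise ConfigurationError("k_max must be ≥ 1")
    if 16 * k_max >= ctx.params.plain_modulus:
        raise ConfigurationError(
            f"k_max {k_max} risks SSD wraparound at t={ctx.params.plain_modulus}"
        )
    timer = timer or PhaseTimer()
    seq = load_input(path, k_max, input_type)
    with_quality = bool(
        seq.source == "fastq" and quality_mode in ("avg", "sum")
    )
    if quality_mode in ("avg", "sum") and seq.source != "fastq":
        raise ConfigurationError(f"quality mode {quality_mode!r} requires FASTQ input")
    deploy_dir = Path(deploy_dir)
    chunks_dir = deploy_dir / "chunks"
    chunks_dir.mkdir(parents=True, exist_ok=True)
    with timer.phase("encrypt"):
        layout = plan_layout(seq, chunk_size, ctx.slot_count)
        manifest = build_manifest(
            seq, layout, ctx.params.to_dict(), ctx.backend_name,
            chunk_size, with_quality,
        )
        for plan, batches in layout:
            for batch in batches:
                for j in range(k_max):
                    ct = ctx.encrypt_vec(batch.strides[j].astype(np.int64), keys)
                    with timer.io():
                        ctx.save_cipher(
                            ct,
                            chunks_dir
                            / f"c{plan.chunk_index}_b{batch.batch_index}_s{j}.ct",
                        )
        if with_quality:
            _encrypt_quality_strides(seq, ctx, keys, k_max, chunks_dir, timer,
                                     chunk_size)
        with timer.io():
            save_manifest(manifest, deploy_dir / "manifest.json")
            ctx.save_relin_keys(keys, deploy_dir / "relin.key")
    return manifest


def _encrypt_quality_strides(seq, ctx, keys, k_max, chunks_dir, timer,
                             chunk_size) -> None:
    # Same chunk/batch geometry as the symbols; pad slots carry quality 0.
    quals = seq.qualities.astype(np.uint8)
    for plan, piece in encoding.chunk_sequence(quals, chunk_size, k_max,
                                               pad_value=0):
        batches = encoding.build_strides(
            piece, k_max, ctx.slot_count, plan.chunk_index,
            plan.genomic_start, pad_value=0,
        )
        for batch in batches:
            for j in range(k_max):
                ct = ctx.encrypt_vec(batch.strides[j].astype(np.int64), keys)
                with timer.io():
                    ctx.save_cipher(
                        ct,
                        chunks_dir
                        / f"c{plan.chunk_index}_b{batch.batch_index}_q{j}.ct",
                    )


def encrypt_queries(
    kmers: list[str], ctx: Context, keys: KeyMaterial, k_max: int,
    queries_dir, plain_registry_path=None,
) -> list[dict]:
    """Encrypt each k-mer as k constant-slot ciphertexts.

    The queries directory receives only ciphertexts and lengths; the
    id → sequence map (plaintext) is written to ``plain_registry_path``,
    which must live on the trusted side.
    """
    queries_dir = Path(queries_dir)
    queries_dir.mkdir(parents=True, exist_ok=True)
    infos = []
    for idx, kmer in enumerate(kmers):
        kmer = kmer.strip().upper()
        if not kmer or any(ch not in ALPHABET for ch in kmer):
            raise UsageError(
                f"query {idx}: k-mers must be non-empty over {{A,C,G,T}}, got {kmer!r}"
            )
        if len(kmer) > k_max:
            raise UsageError(
                f"query {idx} has length {len(kmer)} > k_max {k_max}; "
                "the deployment cannot answer it"
            )
        qid = str(idx)
        symbols = encode_symbols(kmer)
        for j, sym in enumerate(symbols):
            ct = ctx.encrypt_vec(
                np.full(ctx.slot_count, int(sym), dtype=np.int64), keys
            )
            ctx.save_cipher(ct, queries_dir / f"q{qid}_{j}.ct")
        infos.append({"id": qid, "k": len(kmer), "seq": kmer})
    with open(queries_dir / "queries.json", "w") as fh:
        json.dump(
            {"queries": [{"id": q["id"], "k": q["k"]} for q in infos]}, fh
        )
    if plain_registry_path is not None:
        with open(plain_registry_path, "w") as fh:
            json.dump({"queries": infos}, fh)
    return infos


def decrypt_and_extract(
    results_dir, deploy_dir, ctx: Context, keys: KeyMaterial,
    queries: list[dict],
    quality_mode: Optional[str] = None,
    quality_threshold: Optional[float] = None,
    fastq_path=None,
    timer: Optional[PhaseTimer] = None,
) -> list[MatchRecord]:
    """Decrypt SSD vectors, extract zero slots, map and deduplicate them.

    A slot certifies a match iff its decrypted SSD is exactly zero; with
    queries over {0..3}, pad symbol 4 and 16·k_max < t no false zeros are
    arithmetically possible. Matches in chunk-overlap regions resolve to
    one canonical absolute coordinate.
    """
    results_dir, deploy_dir = Path(results_dir), Path(deploy_dir)
    timer = timer or PhaseTimer()
    with timer.phase("decrypt"):
        with timer.io():
            manifest = load_manifest(deploy_dir / "manifest.json")
        batch_list = [
            (c["index"], b["index"], b["n_windows"])
            for c in manifest["chunks"] for b in c["batches"]
        ]
        missing = [
            str(results_dir / server.result_name(q["id"], ci, bi))
            for q in queries for ci, bi, _ in batch_list
            if not (results_dir / server.result_name(q["id"], ci, bi)).exists()
        ]
        if missing:
            raise IncompleteResultsError(missing)
        qualities = None
        if manifest["source_type"] == "fastq" and fastq_path is not None:
            qualities = pack_fastq(
                read_fastq(fastq_path), manifest["k_max"]
            ).qualities
        records: list[MatchRecord] = []
        seen: set[tuple[str, int]] = set()
        qualsum_cache: dict[tuple[int, int, int], np.ndarray] = {}
        for q in queries:
            for ci, bi, n_windows in batch_list:
                with timer.io():
                    ct = ctx.load_cipher(
                        results_dir / server.result_name(q["id"], ci, bi)
                    )
                ssd = ctx.decrypt_vec(ct, keys)
                zero_slots = np.nonzero(ssd[:n_windows] == 0)[0]
                for slot in zero_slots:
                    coord = map_slot_to_coordinate(manifest, ci, bi, int(slot))
                    if coord is None:
                        continue
                    name, offset, absolute = coord
                    if (q["id"], absolute) in seen:
                        continue
                    seen.add((q["id"], absolute))
                    rec = MatchRecord(
                        query_id=q["id"], query_seq=q.get("seq", ""),
                        record_name=name, position=offset,
                        absolute=absolute, k=q["k"], ssd=int(ssd[slot]),
                    )
                    if qualities is not None:
                        window = qualities[absolute: absolute + q["k"]]
                        rec.min_q = int(window.min())
                        rec.sum_q = int(window.sum())
                        rec.avg_q = rec.sum_q / q["k"]
                    if manifest.get("with_quality"):
                        key = (q["k"], ci, bi)
                        if key not in qualsum_cache:
                            with timer.io():
                                qct = ctx.load_cipher(
                                    results_dir
                                    / server.qualsum_name(q["k"], ci, bi)
                                )
                            qualsum_cache[key] = ctx.decrypt_vec(qct, keys)
                        rec.hom_sum_q = int(qualsum_cache[key][slot])
                    records.append(rec)
    if quality_mode is not None:
        records = filter_by_quality(records, quality_mode, quality_threshold)
    return records


def filter_by_quality(
    records: list[MatchRecord], mode: str, threshold: float,
) -> list[MatchRecord]:
    """Apply a Phred-quality threshold; returns the surviving records.

    ``min`` uses the client-side plaintext scan (non-linear aggregates are
    not computed homomorphically); ``sum`` and ``avg`` use the decrypted
    homomorphic window sums when present, with the average compared in
    integer arithmetic as sum ≥ ⌈k·threshold⌉.
    """
    if mode not in QUALITY_MODES:
        raise ConfigurationError(f"quality mode must be one of {QUALITY_MODES}")
    if threshold is None:
        raise ConfigurationError("quality filtering requires a threshold")
    kept = []
    for rec in records:
        if mode == "min":
            if rec.min_q is None:
                raise ConfigurationError(
                    "min-quality filtering requires the plaintext FASTQ"
                )
            ok = rec.min_q >= threshold
        else:
            total = rec.hom_sum_q if rec.hom_sum_q is not None else rec.sum_q
            if total is None:
                raise ConfigurationError(
                    f"{mode}-quality filtering requires window quality sums"
                )
            bound = (
                math.ceil(rec.k * threshold) if mode == "avg" else threshold
            )
            ok = total >= bound
        rec.pass_filter = bool(ok)
        if ok:
            kept.append(rec)
    return kept


# -- plaintext ground truth -----------------------------------------------

def naive_occurrences(symbols: np.ndarray, query_symbols: np.ndarray) -> list[int]:
    """All 0-based offsets where the window equals the query, by direct scan."""
    k = len(query_symbols)
    if len(symbols) < k:
        return []
    windows = sliding_window_view(symbols, k)
    return np.nonzero((windows == query_symbols).all(axis=1))[0].tolist()


def plaintext_search(
    path, kmers_by_id: dict[str, str], input_type: Optional[str] = None,
) -> dict[str, set[tuple[str, int]]]:
    """Ground-truth forward-strand search on the plaintext input."""
    input_type = input_type or detect_input_type(path)
    if input_type == "fasta":
        from Bio import SeqIO

        pieces = [
            (r.id, encode_symbols(str(r.seq)))
            for r in SeqIO.parse(str(path), "fasta")
        ]
    else:
        pieces = [(rid, encode_symbols(seq)) for rid, seq, _ in read_fastq(path)]
    truth: dict[str, set[tuple[str, int]]] = {}
    for qid, kmer in kmers_by_id.items():
        qsym = encode_symbols(kmer)
        hits = set()
        for name, syms in pieces:
            for off in naive_occurrences(syms, qsym):
                hits.add((name, off))
        truth[qid] = hits
    return truth


def verify_against_plaintext(
    path, queries: list[dict], records: list[MatchRecord],
    input_type: Optional[str] = None,
) -> dict:
    """Compare decrypted matches with the client's own plaintext search.

    Quality filtering is orthogonal to verification: compare unfiltered
    records. For a correct deployment both discrepancy lists are empty.
    """
    truth = plaintext_search(
        path, {q["id"]: q["seq"] for q in queries}, input_type
    )
    found: dict[str, set[tuple[str, int]]] = {q["id"]: set() for q in queries}
    for rec in records:
        found.setdefault(rec.query_id, set()).add(
            (rec.record_name, rec.position)
        )
    report = {"queries": {}, "total_false_positives": 0,
              "total_false_negatives": 0}
    for q in queries:
        qid = q["id"]
        fp = sorted(found.get(qid, set()) - truth[qid])
        fn = sorted(truth[qid] - found.get(qid, set()))
        report["queries"][qid] = {
            "seq": q["seq"],
            "n_expected": len(truth[qid]),
            "n_found": len(found.get(qid, set())),
            "false_positives": fp,
            "false_negatives": fn,
        }
        report["total_false_positives"] += len(fp)
        report["total_false_negatives"] += len(fn)
    report["ok"] = (
        report["total_false_positives"] == 0
        and report["total_false_negatives"] == 0
    )
    return report


def write_results_tsv(records: list[MatchRecord], path,
                      one_based: bool = False) -> None:
    """TSV output, one certified match per line."""
    cols = ["query_id", "query_seq", "source_record", "position", "k",
            "ssd", "min_q", "avg_q", "sum_q", "pass_filter"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in sorted(records, key=lambda r: (r.query_id, r.absolute)):
            pos = r.position + 1 if one_based else r.position
            row = [
                r.query_id, r.query_seq, r.record_name, str(pos), str(r.k),
                str(r.ssd),
                "" if r.min_q is None else str(r.min_q),
                "" if r.avg_q is None else f"{r.avg_q:.2f}",
                "" if r.sum_q is None else str(r.sum_q),
                str(int(r.pass_filter)),
            ]
            fh.write("\t".join(row) + "\n")
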