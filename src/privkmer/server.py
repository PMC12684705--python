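"""Untrusted-side evaluator.

The server sees only ciphertexts: per (batch, query) it computes the
encrypted sum of squared differences

    SSD_i = sum_{j<k} (C_{i+j} - K_j)^2

over every window slot i simultaneously, using exactly k homomorphic
subtractions, k relinearised squarings and k−1 additions — a circuit of
multiplicative depth one. For FASTQ deployments it additionally computes
per-window Phred quality sums (additions only, depth zero).

The server never touches the secret key, plaintext sequences or plaintext
queries; its whole interface is the deploy/queries/results directory
triple populated and consumed by the client.
"""

from __future__ import annotations

import json
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .encoding import load_manifest
from .errors import EvaluationError
from .he import CipherVec, Context, CryptoParams, create_context
from .monitoring import PhaseTimer


@dataclass
class SsdResult:
    """Encrypted SSD vector for every window of one batch, for one query."""

    query_id: str
    chunk_index: int
    batch_index: int
    cipher: CipherVec
    op_counts: dict  # subs/squares/adds spent on this result
    mult_depth: int


def evaluate_ssd(
    ctx: Context, stride_ciphers: list[CipherVec],
    query_ciphers: list[CipherVec], relin_keys,
) -> tuple[CipherVec, dict]:
    """Accumulate sum_j (stride_j − query_j)² over the query's k strides.

    Only strides 0..k−1 are touched; the result ciphertext has size 2 and
    multiplicative depth 1 regardless of k.
    """
    k = len(query_ciphers)
    if k == 0:
        raise EvaluationError("empty query")
    if k > len(stride_ciphers):
        raise EvaluationError(
            f"query length {k} exceeds available strides {len(stride_ciphers)}"
        )
    counts = {"sub": 0, "square": 0, "add": 0}
    acc: Optional[CipherVec] = None
    for j in range(k):
        diff = ctx.he_sub(stride_ciphers[j], query_ciphers[j])
        counts["sub"] += 1
        sq = ctx.he_square_relin(diff, relin_keys)
        counts["square"] += 1
        if acc is None:
            acc = sq
        else:
            acc = ctx.he_add(acc, sq)
            counts["add"] += 1
    return acc, counts


def evaluate_quality_sum(
    ctx: Context, quality_ciphers: list[CipherVec], k: int
) -> CipherVec:
    """Window quality sums: slot i decrypts to sum_{j<k} Q_{i+j}."""
    if k > len(quality_ciphers):
        raise EvaluationError(
            f"k={k} exceeds available quality strides {len(quality_ciphers)}"
        )
    acc = quality_ciphers[0]
    for j in range(1, k):
        acc = ctx.he_add(acc, quality_ciphers[j])
    return acc


def _stride_path(chunks_dir: Path, ci: int, bi: int, j: int, kind: str) -> Path:
    return chunks_dir / f"c{ci}_b{bi}_{kind}{j}.ct"


def result_name(query_id: str, ci: int, bi: int) -> str:
    return f"q{query_id}_c{ci}_b{bi}.bin"


def qualsum_name(k: int, ci: int, bi: int) -> str:
    return f"qualsum_k{k}_c{ci}_b{bi}.bin"


def process_all(
    deploy_dir, queries_dir, results_dir, n_workers: int = 1,
    timer: Optional[PhaseTimer] = None,
) -> dict:
    """Evaluate every (batch, query) pair; idempotent and order-free.

    Output content is independent of ``n_workers`` and of processing
    order: each task writes its own deterministic file. Returns (and
    writes) a completion manifest listing outputs and phase timings.
    """
    deploy_dir, queries_dir = Path(deploy_dir), Path(queries_dir)
    results_dir = Path(results_dir)
    timer = timer or PhaseTimer()
    with timer.phase("evaluate"):
        with timer.io():
            manifest = load_manifest(deploy_dir / "manifest.json")
            with open(queries_dir / "queries.json") as fh:
                queries = json.load(fh)["queries"]
        params = CryptoParams.from_dict(manifest["params"])
        ctx = create_context(params, backend=manifest["backend"])
        with timer.io():
            relin = ctx.load_relin_keys(deploy_dir / "relin.key")
        chunks_dir = deploy_dir / "chunks"
        k_max = manifest["k_max"]
        with_quality = manifest.get("with_quality", False)
        batch_list = [
            (c["index"], b["index"])
            for c in manifest["chunks"] for b in c["batches"]
        ]
        missing = _audit_inputs(
            chunks_dir, queries_dir, batch_list, queries, k_max, with_quality
        )
        if missing:
            raise EvaluationError(
                f"{len(missing)} missing input file(s), e.g. {missing[:3]}"
            )
        results_dir.mkdir(parents=True, exist_ok=True)
        qual_ks = sorted({q["k"] for q in queries}) if with_quality else []

        query_ciphers = {}
        for q in queries:
            with timer.io():
                query_ciphers[q["id"]] = [
                    ctx.load_cipher(queries_dir / f"q{q['id']}_{j}.ct")
                    for j in range(q["k"])
                ]

        outputs: list[str] = []

        def run_batch(task):
            ci, bi = task
            with timer.io():
                strides = [
                    ctx.load_cipher(_stride_path(chunks_dir, ci, bi, j, "s"))
                    for j in range(k_max)
                ]
            names = []
            for q in queries:
                cipher, _ = evaluate_ssd(
                    ctx, strides[: q["k"]], query_ciphers[q["id"]], relin
                )
                name = result_name(q["id"], ci, bi)
                with timer.io():
                    ctx.save_cipher(cipher, results_dir / name)
                names.append(name)
            if qual_ks:
                with timer.io():
                    qstrides = [
                        ctx.load_cipher(_stride_path(chunks_dir, ci, bi, j, "q"))
                        for j in range(k_max)
                    ]
                for k in qual_ks:
                    qs = evaluate_quality_sum(ctx, qstrides, k)
                    name = qualsum_name(k, ci, bi)
                    with timer.io():
                        ctx.save_cipher(qs, results_dir / name)
                    names.append(name)
            return names

        if n_workers > 1:
            with ThreadPoolExecutor(max_workers=n_workers) as pool:
                for names in pool.map(run_batch, batch_list):
                    outputs.extend(names)
        else:
            for task in batch_list:
                outputs.extend(run_batch(task))

    completion = {
        "n_tasks": len(batch_list) * len(queries),
        "outputs": sorted(outputs),
        "timings": timer.report(),
    }
    with open(results_dir / "completion.json", "w") as fh:
        json.dump(completion, fh, indent=1)
    return completion


def _audit_inputs(chunks_dir, queries_dir, batch_list, queries, k_max,
                  with_quality) -> list[str]:
    missing = []
    for ci, bi in batch_list:
        for j in range(k_max):
            p = _stride_path(chunks_dir, ci, bi, j, "s")
            if not os.path.exists(p):
                missing.append(str(p))
            if with_quality:
                pq = _stride_path(chunks_dir, ci, bi, j, "q")
                if not os.path.exists(pq):
                    missing.append(str(pq))
    for q in queries:
        for j in range(q["k"]):
            p = queries_dir / f"q{q['id']}_{j}.ct"
            if not os.path.exists(p):
                missing.append(str(p))
    return missing
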