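"""Motif search → k-mer set reduction.

Direct homomorphic position-weight-matrix scoring is impractical (it
needs a private value selection per encrypted base), so motif searches
are reduced offline to deterministic k-mer sets:

1. a PSSM of log2-likelihood-ratio scores is built from a MEME-format
   position probability matrix and background frequencies, discretised to
   integer bins (FIMO-style);
2. the exact PSSM score distribution under the background model is
   computed by dynamic programming, giving a score → p-value map;
3. all 4^k k-mers are enumerated and scored;
4. p-values get Benjamini–Hochberg q-values over the m = 4^k tests;
5. the k-mers below the significance threshold are written as a plain
   query list (input to the encrypted search) plus a detail CSV.

Because p-values are anti-monotone in the discretised score and BH
q-values are monotone in p, the significant set is always a score-
threshold set: the encrypted search over it finds exactly the positions a
plaintext thresholded PSSM scan would report on the forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .encoding import ALPHABET
from .errors import FormatError, UsageError

UNIFORM_BACKGROUND = np.full(4, 0.25)
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_SCALE_BINS = 1000
ENUMERATION_GUARD = 16
ENUMERATION_WARN = 12


@dataclass
class PPM:
    """Position probability matrix, rows over (A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray  # (k, 4), rows sum to 1

    @property
    def width(self) -> int:
        return len(self.matrix)


@dataclass
class PSSM:
    """Integer-discretised log2 scoring matrix with recovery parameters.

    ``int_matrix[j, b] = round((real[j, b] − offset)·scale)``; a real score
    is recovered from a discretised window total as total/scale + k·offset.
    """

    motif_id: str
    real_matrix: np.ndarray  # (k, 4) log2 likelihood ratios
    int_matrix: np.ndarray   # (k, 4) non-negative ints
    scale: float
    offset: float

    @property
    def width(self) -> int:
        return len(self.real_matrix)

    def int_score(self, symbols: np.ndarray) -> int:
        return int(self.int_matrix[np.arange(self.width), symbols].sum())

    def real_score(self, symbols: np.ndarray) -> float:
        return float(self.real_matrix[np.arange(self.width), symbols].sum())


@dataclass
class ScoreDistribution:
    """Exact tail probabilities P(score ≥ s) of the discretised score."""

    tail: np.ndarray  # tail[s] over s = 0 .. max total

    def p_value(self, int_score: int) -> float:
        s = min(max(int_score, 0), len(self.tail) - 1)
        return float(self.tail[s])


def parse_meme(path) -> tuple[list[PPM], Optional[np.ndarray]]:
    """Parse MEME minimal motif format into PPMs plus file background.

    The letter-probability matrices are kept verbatim (no counts
    round-trip), each row validated to sum to 1 within 1e-3; malformed
    lines are reported with their line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    background = None
    ppms: list[PPM] = []
    i = 0
    saw_version = any(ln.lower().startswith("meme version") for ln in lines[:5])
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            freqs = {tokens[j]: float(tokens[j + 1])
                     for j in range(0, len(tokens) - 1, 2)}
            try:
                background = np.array([freqs[b] for b in ALPHABET])
            except KeyError as exc:
                raise FormatError(
                    f"{path}: background frequencies missing letter {exc}"
                )
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif{len(ppms)}"
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                if lines[i].startswith("MOTIF"):
                    raise FormatError(
                        f"{path}:{i + 1}: motif {motif_id} has no "
                        "letter-probability matrix"
                    )
                i += 1
            if i >= len(lines):
                raise FormatError(
                    f"{path}: motif {motif_id} has no letter-probability matrix"
                )
            header = lines[i]
            width = None
            toks = header.replace("=", " ").split()
            for j, tok in enumerate(toks):
                if tok == "w" and j + 1 < len(toks):
                    width = int(toks[j + 1])
            if width is None:
                raise FormatError(f"{path}:{i + 1}: matrix header lacks a width (w=)")
            i += 1
            rows = []
            for r in range(width):
                if i >= len(lines):
                    raise FormatError(
                        f"{path}: motif {motif_id} matrix truncated at row {r}"
                    )
                try:
                    row = [float(x) for x in lines[i].split()]
                except ValueError:
                    raise FormatError(
                        f"{path}:{i + 1}: non-numeric probability row"
                    )
                if len(row) != 4:
                    raise FormatError(
                        f"{path}:{i + 1}: expected 4 probabilities, got {len(row)}"
                    )
                if abs(sum(row) - 1.0) > 1e-3:
                    raise FormatError(
                        f"{path}:{i + 1}: probability row sums to {sum(row):g}, not 1"
                    )
                if min(row) < 0:
                    raise FormatError(f"{path}:{i + 1}: negative probability")
                rows.append(row)
                i += 1
            ppms.append(PPM(motif_id, np.array(rows)))
            continue
        i += 1
    if not ppms:
        raise FormatError(
            f"no motifs found in {path}"
            + ("" if saw_version else " (missing 'MEME version' header?)")
        )
    return ppms, background


def build_pssm(
    ppm: PPM, background: Optional[np.ndarray] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    scale_bins: int = DEFAULT_SCALE_BINS,
) -> PSSM:
    """Log2-likelihood-ratio PSSM with background-weighted pseudocounts.

    score(j, b) = log2(((p_jb + pseudocount·bg_b)/(1 + pseudocount))/bg_b),
    discretised to ``scale_bins`` integer bins over the matrix score range.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1) > 1e-6:
        raise UsageError("background must be 4 positive frequencies summing to 1")
    p = (ppm.matrix + pseudocount * bg) / (1.0 + pseudocount)
    with np.errstate(divide="ignore"):
        real = np.log2(p / bg)
    finite = np.isfinite(real)
    if not finite.any():
        raise UsageError("PSSM has no finite scores")
    # Zero-probability cells (pseudocount 0) score -inf; they are floored to
    # the finite minimum for discretisation, i.e. the lowest score bin.
    lo, hi = float(real[finite].min()), float(real[finite].max())
    scale = scale_bins / (hi - lo) if hi > lo else 1.0
    int_matrix = np.rint((np.clip(real, lo, hi) - lo) * scale).astype(np.int64)
    return PSSM(ppm.motif_id, real, int_matrix, scale, lo)


def score_distribution(
    pssm: PSSM, background: Optional[np.ndarray] = None
) -> ScoreDistribution:
    """Exact discretised score distribution by positional convolution.

    D_0 = {0: 1}; D_{j+1}[s + int_score(j, b)] += D_j[s] · bg_b.  Tail
    probabilities follow by suffix summation; total mass is conserved to
    floating-point accuracy.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    max_total = int(pssm.int_matrix.max(axis=1).sum())
    dist = np.zeros(max_total + 1)
    dist[0] = 1.0
    top = 0
    for j in range(pssm.width):
        nxt = np.zeros(max_total + 1)
        for b in range(4):
            step = int(pssm.int_matrix[j, b])
            nxt[step: top + step + 1] += dist[: top + 1] * bg[b]
        row_max = int(pssm.int_matrix[j].max())
        top += row_max
        dist = nxt
    tail = np.cumsum(dist[::-1])[::-1]
    return ScoreDistribution(np.minimum(tail, 1.0))


def enumerate_and_score(
    pssm: PSSM, dist: ScoreDistribution, force: bool = False,
) -> pd.DataFrame:
    """Score all 4^k k-mers; columns kmer, score, int_score, p_value.

    Refuses k > 16 without ``force`` (4^k records); warns above 12.
    """
    k = pssm.width
    if k > ENUMERATION_GUARD and not force:
        raise UsageError(
            f"enumerating 4^{k} k-mers is refused without force=True"
        )
    if k > ENUMERATION_WARN:
        warnings.warn(f"enumerating 4^{k} = {4 ** k} k-mers", stacklevel=2)
    n = 4 ** k
    idx = np.arange(n, dtype=np.int64)
    int_scores = np.zeros(n, dtype=np.int64)
    real_scores = np.zeros(n)
    digits = np.empty((k, n), dtype=np.int8)
    for j in range(k):
        d = (idx >> (2 * (k - 1 - j))) & 3
        digits[j] = d
        int_scores += pssm.int_matrix[j, d]
        real_scores += pssm.real_matrix[j, d]
    base = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    kmers = (
        base[digits.astype(np.intp)].T.copy().view(f"S{k}").ravel().astype(str)
    )
    pvals = dist.tail[np.clip(int_scores, 0, len(dist.tail) - 1)]
    return pd.DataFrame(
        {
            "kmer": kmers,
            "score": real_scores,
            "int_score": int_scores,
            "p_value": pvals,
        }
    )


def bh_correct(records: pd.DataFrame) -> pd.DataFrame:
    """Benjamini–Hochberg step-up q-values over m = len(records) tests.

    Records are sorted ascending by (p_value, kmer) — the lexicographic
    tie-break keeps the output reproducible — and q_i = min_{j≥i} m·p_j/j,
    clipped to 1.
    """
    out = records.sort_values(
        ["p_value", "kmer"], kind="mergesort"
    ).reset_index(drop=True)
    m = len(out)
    ranks = np.arange(1, m + 1)
    raw = out["p_value"].to_numpy() * m / ranks
    q = np.minimum.accumulate(raw[::-1])[::-1]
    out["q_value"] = np.minimum(q, 1.0)
    return out


def filter_and_write(
    records: pd.DataFrame, threshold: float, out_prefix: str,
    use_p_value: bool = False,
) -> pd.DataFrame:
    """Write the significant k-mer list (.txt) and detail table (.csv).

    The text file holds one k-mer per line, ready as encrypted-search
    query input; the CSV associates each significant k-mer with its score,
    p-value and q-value.
    """
    if not 0 < threshold <= 1:
        raise UsageError("significance threshold must lie in (0, 1]")
    col = "p_value" if use_p_value else "q_value"
    sig = records[records[col] <= threshold].copy()
    with open(f"{out_prefix}_kmers.txt", "w") as fh:
        for kmer in sig["kmer"]:
            fh.write(kmer + "\n")
    sig[["kmer", "score", "p_value", "q_value"]].to_csv(
        f"{out_prefix}_details.csv", index=False
    )
    return sig


def pwm_to_kmers(
    meme_path, out_prefix: str,
    background: Optional[np.ndarray] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    scale_bins: int = DEFAULT_SCALE_BINS,
    q_threshold: float = 0.05,
    use_p_value: bool = False,
    motif_index: int = 0,
    force: bool = False,
) -> pd.DataFrame:
    """End-to-end reduction for one motif of a MEME file."""
    ppms, file_bg = parse_meme(meme_path)
    bg = background if background is not None else file_bg
    ppm = ppms[motif_index]
    pssm = build_pssm(ppm, bg, pseudocount, scale_bins)
    dist = score_distribution(pssm, bg)
    records = bh_correct(enumerate_and_score(pssm, dist, force=force))
    return filter_and_write(records, q_threshold, out_prefix, use_p_value)


def scan_plaintext(
    symbols: np.ndarray, pssm: PSSM, min_int_score: int
) -> list[int]:
    """Forward-strand positions whose window meets the score threshold.

    Windows containing non-ACGT symbols are skipped. This is the
    reference a significant-k-mer encrypted search is compared against.
    """
    k = pssm.width
    hits = []
    for i in range(len(symbols) - k + 1):
        win = symbols[i: i + k]
        if win.max() > 3:
            continue
        if pssm.int_score(win.astype(np.intp)) >= min_int_score:
            hits.append(i)
    return hits
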