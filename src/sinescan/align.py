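"""Local sequence alignment and e-value statistics.

The search engine is an exact-word seeding stage (default word size 11)
followed by Smith-Waterman-Gotoh gapped alignment of the query against a
window around each seed cluster; subjects at or below
``FULL_DP_MAX_SUBJECT`` are aligned by full DP directly.  Gap cost is
affine: a gap of length L costs ``gap_open + L * gap_extend``.

Hit significance uses the ungapped Karlin-Altschul model
``E = K * m * n * exp(-lambda * score)`` with lambda solved numerically
for the scoring scheme at uniform base frequencies and K a documented
constant; the searched space ``n`` counts both strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqio import revcomp

FULL_DP_MAX_SUBJECT = 1000
DEFAULT_K = 0.62


@dataclass(frozen=True)
class Scoring:
    """Match/mismatch/affine-gap scores (BLASTN-like defaults)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2


def karlin_lambda(scoring: Scoring = Scoring(), freq: float = 0.25) -> float:
    """Solve sum_ij p_i p_j exp(lambda*s_ij) = 1 for the ungapped lambda.

    With uniform base frequencies this reduces to
    ``4*f^2*(4*e^(l*match) + 12*e^(l*mismatch)) = 1``-style balance.
    """
    from scipy.optimize import brentq

    p_match = 4 * freq * freq
    p_mis = 12 * freq * freq

    def f(lam: float) -> float:
        return p_match * math.exp(lam * scoring.match) \
            + p_mis * math.exp(lam * scoring.mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


@dataclass(frozen=True)
class KarlinParams:
    lam: float
    K: float = DEFAULT_K

    @classmethod
    def for_scoring(cls, scoring: Scoring = Scoring()) -> "KarlinParams":
        return cls(lam=karlin_lambda(scoring), K=DEFAULT_K)


def evalue(score: float, query_len: int, subject_len: int,
           karlin: KarlinParams) -> float:
    """Expected number of chance hits: ``K * m * n * exp(-lambda * score)``.

    ``subject_len`` is the searched space (pass genome length x 2 for a
    double-stranded search).  Strictly decreasing in score, linear in each
    length.
    """
    if not (math.isfinite(karlin.lam) and math.isfinite(karlin.K)):
        raise ValueError("non-finite Karlin parameters")
    if karlin.lam <= 0 or karlin.K <= 0:
        raise ValueError("Karlin parameters must be positive")
    if score < 0:
        raise ValueError("score must be >= 0")
    if query_len < 1 or subject_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    # exp underflows around score ~ 530 for lambda ~ 1.33; compute in logs
    log_e = math.log(karlin.K) + math.log(query_len) + math.log(subject_len) \
        - karlin.lam * score
    return math.exp(log_e) if log_e > -700 else 0.0


@dataclass
class AlignmentHit:
    """One local alignment of the query on a subject sequence.

    Subject and query intervals are 0-based half-open; the query interval
    is reported in the original query orientation even for minus-strand
    hits.
    """

    chrom: str
    start: int
    end: int
    strand: str
    qstart: int
    qend: int
    score: int
    evalue: float = math.inf
    pident: float = 0.0
    aln_len: int = 0
    n_ident: int = 0


# ---------------------------------------------------------------------------
# Smith-Waterman-Gotoh
# ---------------------------------------------------------------------------

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
# N (code 4) never matches anything, including itself


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _sw_matrices(q: np.ndarray, s: np.ndarray, sc: Scoring):
    """Row-vectorized Gotoh.  Returns (H, H0, F) int32 matrices.

    H0 excludes the subject-gap state E; chained gaps are dominated by a
    single longer gap under affine costs, so E reduces to a running
    maximum over H0 within the row (exact, not an approximation).
    """
    m, n = len(q), len(s)
    go, ge = sc.gap_open, sc.gap_extend
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    H0 = np.zeros((m + 1, n + 1), dtype=np.int32)
    F = np.full((m + 1, n + 1), -(10 ** 8), dtype=np.int32)
    idx = np.arange(n, dtype=np.int64) * (-ge)
    for i in range(1, m + 1):
        qi = q[i - 1]
        sub = np.where((s == qi) & (qi != 4), sc.match, sc.mismatch).astype(np.int32)
        diag = H[i - 1, :-1] + sub
        F[i, 1:] = np.maximum(H[i - 1, 1:] + go + ge, F[i - 1, 1:] + ge)
        h0 = np.maximum(0, np.maximum(diag, F[i, 1:]))
        H0[i, 1:] = h0
        # E[j] = max_{k<j} H0[k] + go + ge*(j-k), via decayed cummax
        r = np.maximum.accumulate(h0 + idx)  # r[k] = max_{k'<=k} H0[k'] - ge*k'
        e = np.full(n, -(10 ** 8), dtype=np.int64)
        e[1:] = r[:-1] - idx[1:] + go
        H[i, 1:] = np.maximum(h0, e).astype(np.int32)
    return H, H0, F


def _traceback(q: np.ndarray, s: np.ndarray, sc: Scoring,
               H: np.ndarray, H0: np.ndarray, F: np.ndarray,
               i: int, j: int):
    """Walk one optimal path back from (i, j); returns interval + identity."""
    go, ge = sc.gap_open, sc.gap_extend
    n_ident = 0
    aln_len = 0
    end_i, end_j = i, j
    use_h0 = False  # after landing from a subject gap, the cell's E is excluded
    while i > 0 and j > 0:
        h = H0[i, j] if use_h0 else H[i, j]
        if h == 0:
            break
        qi, sj = q[i - 1], s[j - 1]
        sub = sc.match if (qi == sj and qi != 4) else sc.mismatch
        if h == H[i - 1, j - 1] + sub:
            if qi == sj and qi != 4:
                n_ident += 1
            aln_len += 1
            i -= 1
            j -= 1
            use_h0 = False
            continue
        if h == F[i, j]:
            # gap in subject direction i (query letters vs gap)
            length = 1
            while F[i, j] != H[i - length, j] + go + ge * length:
                length += 1
            aln_len += length
            i -= length
            use_h0 = False
            continue
        # subject gap: h came from E; find origin k with H0 value
        k = j - 1
        while H0[i, k] + go + ge * (j - k) != h:
            k -= 1
            if k < 1:
                raise AssertionError("traceback failed to locate gap origin")
        aln_len += j - k
        j = k
        use_h0 = True
    return i, j, end_i, end_j, n_ident, aln_len


def smith_waterman(query: str, subject: str, scoring: Scoring = Scoring()):
    """Best local alignment; returns an :class:`AlignmentHit` or None.

    Plus-strand only; callers handle the reverse complement.
    """
    q, s = encode(query), encode(subject)
    if len(q) == 0 or len(s) == 0:
        raise ValueError("empty sequence")
    H, H0, F = _sw_matrices(q, s, scoring)
    score = int(H.max())
    if score <= 0:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    qs, ss, qe, se, n_ident, aln_len = _traceback(q, s, scoring, H, H0, F,
                                                  int(i), int(j))
    return AlignmentHit(
        chrom="", start=ss, end=se, strand="+", qstart=qs, qend=qe,
        score=score, pident=100.0 * n_ident / aln_len if aln_len else 0.0,
        aln_len=aln_len, n_ident=n_ident,
    )


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _kmer_hashes(enc: np.ndarray, w: int) -> np.ndarray:
    """Base-4 rolling hashes; positions containing N get hash -1."""
    if len(enc) < w:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, w).astype(np.int64)
    powers = 4 ** np.arange(w, dtype=np.int64)
    h = win @ powers
    h[(win == 4).any(axis=1)] = -1
    return h


def _seed_pairs(q_enc: np.ndarray, s_enc: np.ndarray, w: int):
    """(subject_pos, query_pos) pairs of exact w-mer matches."""
    qh = _kmer_hashes(q_enc, w)
    sh = _kmer_hashes(s_enc, w)
    qmap: dict[int, list[int]] = {}
    for qpos, h in enumerate(qh):
        if h >= 0:
            qmap.setdefault(int(h), []).append(qpos)
    if not qmap:
        return []
    qkeys = np.fromiter(qmap.keys(), dtype=np.int64)
    mask = np.isin(sh, qkeys)
    pairs = []
    for spos in np.flatnonzero(mask):
        for qpos in qmap[int(sh[spos])]:
            pairs.append((int(spos), qpos))
    return pairs


def _cluster_windows(pairs, qlen: int, slen: int, word_size: int,
                     band: int = 32, margin: int = 60,
                     min_seeds: int = 1,
                     max_seed_gap: int = 100) -> list[tuple[int, int]]:
    """Group seeds into candidate subject windows by diagonal proximity.

    Seeds join a cluster when they sit within ``band`` diagonals and
    within ``max_seed_gap`` bp of its last seed (seed runs inside a real
    alignment are near-contiguous; a distant chance word match must not
    chain clusters together).  Each window spans its cluster's seed
    extent on the subject plus a fixed margin, so the separate exon
    clusters of a spliced query stay separate windows.  Clusters with
    fewer than ``min_seeds`` seeds are dropped.
    """
    if not pairs:
        return []
    items = sorted((spos - qpos, spos) for spos, qpos in pairs)
    clusters: list[list[tuple[int, int]]] = [[items[0]]]
    for diag, spos in items[1:]:
        pd, ps = clusters[-1][-1]
        if abs(diag - pd) <= band and abs(spos - ps) <= max_seed_gap:
            clusters[-1].append((diag, spos))
        else:
            clusters.append([(diag, spos)])
    windows = []
    for cl in clusters:
        if len(cl) < min_seeds:
            continue
        s_lo = min(s for _, s in cl)
        s_hi = max(s for _, s in cl) + word_size
        start = max(0, s_lo - margin - band)
        end = min(slen, s_hi + margin + band)
        if end > start:
            windows.append((start, end))
    if not windows:
        return []
    # coalesce overlapping windows
    windows.sort()
    merged = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _merge_hits(hits: list[AlignmentHit], overlap_frac: float = 0.5):
    """Subsume hits overlapping > overlap_frac on the subject; best score
    wins, ties broken by leftmost subject start."""
    hits = sorted(hits, key=lambda h: (-h.score, h.start, h.strand))
    kept: list[AlignmentHit] = []
    for h in hits:
        clash = False
        for k in kept:
            ov = min(h.end, k.end) - max(h.start, k.start)
            if ov > 0 and ov > overlap_frac * min(h.end - h.start,
                                                  k.end - k.start):
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end, h.strand))
    return kept


def local_align(query: str, subject: str, scoring: Scoring = Scoring(),
                word_size: int = 11, chrom: str = "",
                karlin: KarlinParams | None = None,
                search_space: int | None = None,
                min_score: int = 0,
                min_cluster_seeds: int = 1) -> list[AlignmentHit]:
    """Find local alignments of ``query`` on both strands of ``subject``.

    For subjects <= 1 kb the full DP runs directly; otherwise seed
    clusters define candidate windows and each window is aligned
    separately (multi-exon queries therefore yield one hit per exon
    cluster).  E-values use ``search_space`` (default: 2 x subject
    length).
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    if karlin is None:
        karlin = KarlinParams.for_scoring(scoring)
    n_space = search_space if search_space is not None else 2 * len(subject)
    qlen = len(query)
    hits: list[AlignmentHit] = []

    def _align_window(qseq: str, win_start: int, win_end: int, strand: str):
        hit = smith_waterman(qseq, subject[win_start:win_end], scoring)
        if hit is None or hit.score < min_score:
            return
        if strand == "-":
            hit.qstart, hit.qend = qlen - hit.qend, qlen - hit.qstart
        hit.chrom = chrom
        hit.start += win_start
        hit.end += win_start
        hit.strand = strand
        hit.evalue = evalue(hit.score, qlen, n_space, karlin)
        hits.append(hit)

    for strand, qseq in (("+", query), ("-", revcomp(query))):
        if len(subject) <= FULL_DP_MAX_SUBJECT:
            _align_window(qseq, 0, len(subject), strand)
        else:
            pairs = _seed_pairs(encode(qseq), encode(subject), word_size)
            for a, b in _cluster_windows(pairs, qlen, len(subject), word_size,
                                         min_seeds=min_cluster_seeds):
                _align_window(qseq, a, b, strand)
    return _merge_hits(hits)
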