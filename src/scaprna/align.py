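"""Semi-global ("glocal") alignment of short RNA tags against reference sets.

The aligner scores a full-length query against a substring of the target:
gaps before or after the query (target overhangs) are free, all other gaps and
mismatches are penalised.  Among equal-score alignments it returns the one
with the smallest extent along the target, ties broken by the smallest target
start.  This is the primitive behind the ordered reference-set cascade used to
recognise known short RNA classes (rRNA, tRNA, snRNA, snoRNA, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ValidationError


@dataclass(frozen=True)
class AlignParams:
    """Scoring for the tag-annotation cascade.

    A candidate alignment is kept when ``score >= min_score_fraction * |query|``
    (alignments scoring strictly less are discarded).  The cascade uses 0.8;
    the genome/transcript mapping step uses 0.9.
    """

    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -1
    end_gap_score: int = 0
    min_score_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.min_score_fraction <= 1):
            raise ValidationError("min_score_fraction must be in (0, 1]")
        if self.match_score <= 0:
            raise ValidationError("match_score must be positive")


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    target_id: str
    score: int
    tstart: int
    tend: int
    target_length: int

    @property
    def extent(self) -> int:
        return self.tend - self.tstart


_BASES = "ACGT"


def _encode_seq(seq: str, ambiguity_offset: int) -> np.ndarray:
    """Encode a DNA string as integer codes.

    Non-ACGT symbols (N and other IUPAC codes) get position-unique codes from
    ``ambiguity_offset`` upward so they never match anything, including each
    other: an N in the query never matches an N in the target.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for i, base in enumerate(_BASES):
        out[arr == ord(base)] = i
    mask = out == -1
    if np.any(mask):
        out[mask] = ambiguity_offset + np.arange(int(mask.sum()), dtype=np.int64)
    return out


def semiglobal_align(
    query: str,
    target: str,
    params: AlignParams = AlignParams(),
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentResult:
    """Align the full query against a substring of the target.

    Dynamic programming over (query position, target position) with free
    leading/trailing target gaps.  Each cell carries the best score together
    with the largest achievable alignment start on the target, which yields
    the smallest extent for every end point; the final answer maximises the
    score, then minimises the extent, then the start.  Zero-extent alignments
    (query aligned entirely against gaps) are only reported when no
    positive-extent alignment achieves the optimal score.
    """
    if not query or not target:
        raise ValidationError("query and target must be non-empty")
    q = _encode_seq(query.upper(), ambiguity_offset=4)
    t = _encode_seq(target.upper(), ambiguity_offset=4 + len(query))
    m, n = len(q), len(t)
    big = np.int64(n + 2)
    gap = np.int64(params.gap_score)
    match = np.int64(params.match_score)
    mismatch = np.int64(params.mismatch_score)

    # enc[j] = score * big + start for the best path to (i, j); ties -> max start
    j_idx = np.arange(n + 1, dtype=np.int64)
    enc = j_idx.copy()  # row 0: score 0, start j (free leading target gaps)
    for i in range(m):
        sub = np.where(t == q[i], match, mismatch).astype(np.int64)
        diag = enc[:-1] + sub * big
        up = enc + gap * big
        new = np.empty(n + 1, dtype=np.int64)
        new[0] = up[0]
        new[1:] = np.maximum(diag, up[1:])
        # left moves (gap in query, consuming target): a chain from column k to
        # column j costs gap*(j-k); rewrite as a running encoded maximum
        chain = np.maximum.accumulate(new - gap * j_idx * big)
        enc = np.maximum(new, chain + gap * j_idx * big)

    scores = enc // big
    starts = enc - scores * big
    best = int(scores.max())
    cand = np.flatnonzero(scores == best)
    extents = cand - starts[cand]
    pos = extents > 0
    if np.any(pos):
        cand, extents = cand[pos], extents[pos]
    order = np.lexsort((starts[cand], extents))
    j = int(cand[order[0]])
    tstart = int(starts[j])
    return AlignmentResult(query_id, target_id, best, tstart, j, n)


def passes_threshold(result: AlignmentResult, query_length: int,
                     params: AlignParams) -> bool:
    """Score-floor rule: alignments scoring strictly below the fraction of the
    query length are discarded, so a score exactly at the floor passes."""
    return result.score >= params.min_score_fraction * query_length


def best_alignment(
    query: str,
    targets: list[tuple[str, str]],
    params: AlignParams = AlignParams(),
    query_id: str = "query",
) -> AlignmentResult | None:
    """Best passing alignment of a query against a list of (id, seq) targets.

    Tie-breaking follows the cascade rules: highest score, then shortest
    target, then shortest extent along the target, then smallest start.
    """
    best: AlignmentResult | None = None
    for target_id, seq in targets:
        res = semiglobal_align(query, seq, params, query_id, target_id)
        if not passes_threshold(res, len(query), params):
            continue
        if best is None:
            best = res
            continue
        key_new = (-res.score, res.target_length, res.extent, res.tstart)
        key_old = (-best.score, best.target_length, best.extent, best.tstart)
        if key_new < key_old:
            best = res
    return best


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp.get(b, "N") for b in reversed(seq.upper()))
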