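"""Reciprocal-best-hit orthology between two proteomes."""
from __future__ import annotations

from Bio import Align

from ..genetics import BLOSUM62


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = BLOSUM62
    aligner.mode = "local"
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _shared_kmers(a: str, b: str, k: int = 4) -> int:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb)


def _best_hits(
    queries: dict[str, str], targets: dict[str, str], prefilter_top: int = 5
) -> dict[str, str | None]:
    """Unique best hit per query (None on tie or no hit)."""
    aligner = _aligner()
    out: dict[str, str | None] = {}
    for qid, qseq in queries.items():
        ranked = sorted(
            targets, key=lambda t: _shared_kmers(qseq, targets[t]), reverse=True
        )
        candidates = [t for t in ranked[:prefilter_top] if _shared_kmers(qseq, targets[t]) > 0]
        if not candidates:
            out[qid] = None
            continue
        scores = {t: float(aligner.score(qseq, targets[t])) for t in candidates}
        top = max(scores.values())
        winners = [t for t, s in scores.items() if s == top]
        out[qid] = winners[0] if len(winners) == 1 else None
    return out


def reciprocal_best_hits(
    proteome_a: dict[str, str], proteome_b: dict[str, str]
) -> list[tuple[str, str]]:
    """(a, b) pairs where each is the other's unique best cross-proteome hit."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    a_best = _best_hits(proteome_a, proteome_b)
    b_best = _best_hits(proteome_b, proteome_a)
    pairs = []
    for a, b in a_best.items():
        if b is not None and b_best.get(b) == a:
            pairs.append((a, b))
    return sorted(pairs)
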