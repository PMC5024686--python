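"""Motif-based identification of candidate transcription factors.

Induced promoters in a response group are expected to share the binding
motif of the responsible TF. This module scans the 68-nt random cores of
each promoter (concatenated; the constant flanks are excluded because they
are shared library-wide and would produce uninformative "shared" hits) on
both strands with JASPAR-style position frequency matrices, calls motifs
shared by every member of a group, and tests whether the promoters carrying
a motif concentrate at the top of the drug-response ranking with a weighted
Kolmogorov-Smirnov running-sum statistic (the GSEA enrichment score) and a
promoter-permutation null.
"""
from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from numpy.lib.stride_tricks import sliding_window_view

from ._dna import encode_bases, reverse_complement

__all__ = [
    "MotifModel",
    "MotifHit",
    "EnrichmentResult",
    "parse_jaspar",
    "write_jaspar",
    "pwm_scan",
    "best_rel_score",
    "shared_motifs",
    "motif_set_enrichment",
    "enrich_all",
]

DEFAULT_REL_THRESHOLD = 0.85
#: Total pseudocount added per matrix column, split equally across the four
#: bases (0.2 each) before log-odds against a uniform 0.25 background.
COLUMN_PSEUDOCOUNT = 0.8
_BASES = "ACGT"


@dataclass(frozen=True)
class MotifHit:
    promoter_id: str
    motif_id: str
    offset: int          # 0-based, forward-strand coordinates
    strand: str          # '+' or '-'
    rel_score: float


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    es: float
    p_perm: float
    fdr: float
    set_size: int


class MotifModel:
    """A position frequency matrix with a relative-score scanning threshold."""

    def __init__(
        self,
        motif_id: str,
        counts: np.ndarray,
        name: str = "",
        rel_score_threshold: float = DEFAULT_REL_THRESHOLD,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x W matrix (rows A, C, G, T)")
        if (counts < 0).any():
            raise ValueError(f"motif {motif_id}: negative count")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError(f"motif {motif_id}: column with zero total count")
        if counts.shape[1] < 4:
            raise ValueError(f"motif {motif_id}: width must be >= 4")
        if not 0 < rel_score_threshold <= 1:
            raise ValueError("rel_score_threshold must lie in (0, 1]")
        self.motif_id = motif_id
        self.name = name or motif_id
        self.counts = counts
        self.rel_score_threshold = float(rel_score_threshold)
        per_base = COLUMN_PSEUDOCOUNT / 4.0
        freq = (counts + per_base) / (counts.sum(axis=0) + COLUMN_PSEUDOCOUNT)
        self.log_odds = np.log2(freq / 0.25)
        self._min = float(self.log_odds.min(axis=0).sum())
        self._max = float(self.log_odds.max(axis=0).sum())

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def rel_scores(self, encoded: np.ndarray) -> np.ndarray:
        """Relative score of every window of an encoded sequence."""
        w = self.width
        windows = sliding_window_view(encoded, w)
        raw = self.log_odds[windows, np.arange(w)].sum(axis=1)
        return (raw - self._min) / (self._max - self._min)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MotifModel({self.motif_id}, W={self.width})"


# ---------------------------------------------------------------------------
# JASPAR I/O (via Bio.motifs)
# ---------------------------------------------------------------------------

def parse_jaspar(text: str, rel_score_threshold: float = DEFAULT_REL_THRESHOLD) -> list[MotifModel]:
    """Parse JASPAR PFM text (bracketed '>'-headed or raw 4-row format)."""
    fmt = "jaspar" if text.lstrip().startswith(">") else "pfm"
    try:
        parsed = bio_motifs.parse(_stdio.StringIO(text), fmt)
        parsed = list(parsed)
    except Exception as exc:
        raise ValueError(f"could not parse JASPAR input: {exc}") from exc
    if not parsed:
        raise ValueError("no motifs found in JASPAR input")
    out = []
    for i, m in enumerate(parsed):
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        motif_id = getattr(m, "matrix_id", None) or m.name or f"motif_{i + 1}"
        out.append(
            MotifModel(
                motif_id=str(motif_id),
                counts=counts,
                name=str(m.name or motif_id),
                rel_score_threshold=rel_score_threshold,
            )
        )
    return out


def write_jaspar(motifs_list: Sequence[MotifModel]) -> str:
    """Serialize motifs in bracketed JASPAR PFM format (round-trip safe)."""
    chunks = []
    for m in motifs_list:
        lines = [f">{m.motif_id} {m.name}"]
        for bi, b in enumerate(_BASES):
            vals = " ".join(f"{v:g}" for v in m.counts[bi])
            lines.append(f"{b} [ {vals} ]")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def pwm_scan(
    seq: str,
    motif: MotifModel,
    both_strands: bool = True,
    threshold: float | None = None,
    promoter_id: str = "",
) -> list[MotifHit]:
    """All positions where the motif's relative score reaches the threshold.

    Relative score is (score - min) / (max - min) over the achievable
    log-odds range, so 1.0 is the best possible match. Reverse-strand hits
    are reported in forward coordinates (offset of the site's leftmost base).
    """
    thr = motif.rel_score_threshold if threshold is None else threshold
    if len(seq) < motif.width:
        raise ValueError("sequence shorter than motif width")
    enc = encode_bases(seq)
    hits: list[MotifHit] = []
    rel = motif.rel_scores(enc)
    for off in np.flatnonzero(rel >= thr):
        hits.append(MotifHit(promoter_id, motif.motif_id, int(off), "+", float(rel[off])))
    if both_strands:
        rc = encode_bases(reverse_complement(seq))
        rel_rc = motif.rel_scores(rc)
        L, w = len(seq), motif.width
        for off in np.flatnonzero(rel_rc >= thr):
            hits.append(
                MotifHit(
                    promoter_id, motif.motif_id, int(L - w - off), "-",
                    float(rel_rc[off]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def best_rel_score(seq: str, motif: MotifModel, both_strands: bool = True) -> float:
    """Best relative score of a motif anywhere on a sequence (either strand)."""
    enc = encode_bases(seq)
    best = float(motif.rel_scores(enc).max())
    if both_strands:
        rc = encode_bases(reverse_complement(seq))
        best = max(best, float(motif.rel_scores(rc).max()))
    return best


def shared_motifs(
    group: Mapping[str, str],
    motifs_list: Sequence[MotifModel],
    both_strands: bool = True,
    threshold: float | None = None,
) -> list[str]:
    """Motifs with at least one hit in *every* promoter of a response group.

    ``group`` maps promoter_id -> scannable sequence (concatenated random
    cores). Returns motif ids sorted by mean best relative score, descending.
    """
    if not group:
        raise ValueError("shared_motifs requires a non-empty group")
    shared: list[tuple[str, float]] = []
    for m in motifs_list:
        thr = m.rel_score_threshold if threshold is None else threshold
        bests = []
        for _pid, seq in group.items():
            b = best_rel_score(seq, m, both_strands)
            if b < thr:
                break
            bests.append(b)
        else:
            shared.append((m.motif_id, float(np.mean(bests))))
    shared.sort(key=lambda t: (-t[1], t[0]))
    return [mid for mid, _ in shared]


# ---------------------------------------------------------------------------
# GSEA-style motif-set enrichment
# ---------------------------------------------------------------------------

def _running_es(member: np.ndarray, weights: np.ndarray) -> float:
    """Signed extreme of the weighted KS running sum for one membership row."""
    return float(_batch_es(member[None, :], weights)[0])


def _batch_es(member: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized enrichment scores for P membership rows over one ranking.

    member: (P, N) boolean; weights: (N,) nonnegative per-position weights
    (used only at member positions). Zero-weight member rows fall back to
    unweighted steps.
    """
    member = np.asarray(member, dtype=bool)
    p, n = member.shape
    k = member.sum(axis=1)
    if (k == 0).any() or (k == n).any():
        raise ValueError("motif set must be non-empty and a strict subset")
    mw = member * weights
    denom = mw.sum(axis=1, keepdims=True)
    # rows whose members all carry zero weight: use unweighted hit steps
    flat = denom[:, 0] == 0
    if flat.any():
        mw[flat] = member[flat].astype(float)
        denom[flat, 0] = k[flat]
    hit = np.cumsum(mw, axis=1) / denom
    miss = np.cumsum(~member, axis=1) / (n - k)[:, None]
    dev = hit - miss
    idx = np.abs(dev).argmax(axis=1)
    return dev[np.arange(p), idx]


def motif_set_enrichment(
    ranking: pd.DataFrame,
    members: Iterable[str],
    motif_id: str = "",
    n_perm: int = 999,
    weight_exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Weighted-KS enrichment of a motif's promoter set in a response ranking.

    ``ranking`` is a frame indexed by promoter_id with a ``score`` column in
    descending order (as produced by the ranking step). Member positions are
    weighted by |log2 score|**exponent; the enrichment score ES in [-1, 1] is
    the signed extreme of the running sum. Significance comes from promoter-
    label permutation: p = (#{|ES_perm| >= |ES_obs|} + 1) / (n_perm + 1), so
    p can never be zero. FDR across a motif panel is applied in
    :func:`enrich_all`.
    """
    ids = np.asarray(ranking.index)
    n = len(ids)
    member = np.isin(ids, list(set(members)))
    k = int(member.sum())
    if k == 0:
        raise ValueError("motif set is empty on this ranking")
    if k == n:
        raise ValueError("motif set equals the whole ranking universe")
    scores = ranking["score"].to_numpy(dtype=float)
    weights = np.abs(np.log2(np.clip(scores, 1e-12, None))) ** weight_exponent
    es = _running_es(member, weights)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # uniform random k-subsets for all permutations at once
    u = rng.random((n_perm, n))
    chosen = np.argpartition(u, k - 1, axis=1)[:, :k]
    perm = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(perm, chosen, True, axis=1)
    es_perm = _batch_es(perm, weights)
    p = (np.count_nonzero(np.abs(es_perm) >= abs(es)) + 1) / (n_perm + 1)
    return EnrichmentResult(
        motif_id=motif_id, es=es, p_perm=float(p), fdr=float("nan"), set_size=k
    )


def enrich_all(
    ranking: pd.DataFrame,
    incidence: Mapping[str, Iterable[str]],
    n_perm: int = 999,
    weight_exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Enrichment of every motif set with Benjamini-Hochberg FDR across motifs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for motif_id in sorted(incidence):
        res = motif_set_enrichment(
            ranking, incidence[motif_id], motif_id, n_perm, weight_exponent, rng
        )
        rows.append(
            {"motif_id": res.motif_id, "es": res.es, "p_perm": res.p_perm,
             "set_size": res.set_size}
        )
    out = pd.DataFrame(rows).set_index("motif_id")
    out["fdr"] = _bh_fdr(out["p_perm"].to_numpy())
    return out.sort_values(["p_perm", "es"], ascending=[True, False])


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
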