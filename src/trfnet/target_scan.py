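"""Seed-weighted complementarity scanning of small RNAs against 3'UTRs.

The scanner performs a Smith-Waterman local alignment of the *reversed*
small RNA against each UTR (the duplex is antiparallel, so the 3' end of the
small RNA meets the 5' side of the site), scoring complementarity rather
than identity: Watson-Crick pairs +5, G:U wobbles +2, mismatches -3, affine
gaps -8/-2. Positions 2-8 from the small RNA's 5' end — the seed region —
have their pair scores and gap penalties scaled by 4, mirroring the seed
emphasis of miRanda-class tools (the seed scale applies to every column of
the dynamic program at those positions, so gapping around a seed mismatch
is no cheaper than taking it). Sites scoring strictly above the threshold (default
140) are reported, best first, with overlaps resolved greedily.

The scoring constants live in :class:`ScanParams` and are the single source
of truth; an exact 17-nt complement scores 7 x 5 x 4 + 10 x 5 = 190.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from numba import njit

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
MASKED = 4  # code for already-claimed UTR positions

WC_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1)}
WOBBLE_PAIRS = {(2, 3), (3, 2)}  # G:U in either orientation


@dataclass(frozen=True)
class ScanParams:
    """Scoring constants of the scanner (defaults documented above)."""

    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_start: int = 2  # 1-based, inclusive, from the sncRNA 5' end
    seed_end: int = 8
    seed_weight: float = 4.0
    threshold: float = 140.0
    max_sites: int = 10


@dataclass(frozen=True)
class TargetSite:
    """One predicted binding site on a UTR (0-based half-open coordinates)."""

    utr_start: int
    utr_end: int
    score: float
    #: (sncRNA position 0-based from 5' end, UTR position, "wc"|"wobble"|"mismatch")
    pairs: tuple = ()
    sncrna_id: Optional[str] = None
    utr_id: Optional[str] = None


def _encode(seq: str, label: str) -> np.ndarray:
    seq = seq.upper()
    bad = sorted({c for c in seq if c not in _CODE})
    if bad:
        raise ValueError(f"{label}: invalid characters {', '.join(bad)}")
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def _pair_table(params: ScanParams) -> np.ndarray:
    """5x5 base-pair score table (query base x UTR base); MASKED kills a cell."""
    tab = np.full((5, 5), params.mismatch)
    for q, u in WC_PAIRS:
        tab[q, u] = params.match
    for q, u in WOBBLE_PAIRS:
        tab[q, u] = params.wobble
    tab[MASKED, :] = -1e9
    tab[:, MASKED] = -1e9
    return tab


def position_weights(n: int, params: ScanParams) -> np.ndarray:
    """Weight per position of the *reversed* query.

    Reversed-query index i holds sncRNA 5'-based position ``n - i`` (1-based);
    seed positions get ``seed_weight``, the rest 1.
    """
    pos = n - np.arange(n)  # 1-based sncRNA position for each reversed index
    return np.where((pos >= params.seed_start) & (pos <= params.seed_end),
                    params.seed_weight, 1.0)


@njit(cache=True)
def _sw_fill(q, u, weights, pair, gap_open, gap_extend):  # pragma: no cover
    n, m = len(q), len(u)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e18)  # gap consuming UTR
    F = np.full((n + 1, m + 1), -1e18)  # gap consuming query
    for i in range(1, n + 1):
        w = weights[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open * w,
                          E[i, j - 1] + gap_extend * w)
            F[i, j] = max(H[i - 1, j] + gap_open * w,
                          F[i - 1, j] + gap_extend * w)
            diag = H[i - 1, j - 1] + weights[i - 1] * pair[q[i - 1], u[j - 1]]
            h = diag
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


def _traceback(H, E, F, q, u, weights, pair, params, i, j):
    """Recover the local alignment ending at (i, j)."""
    pairs = []
    end_j = j
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        diag = H[i - 1, j - 1] + weights[i - 1] * pair[q[i - 1], u[j - 1]]
        if h == diag:
            qu = (int(q[i - 1]), int(u[j - 1]))
            kind = ("wc" if qu in WC_PAIRS
                    else "wobble" if qu in WOBBLE_PAIRS else "mismatch")
            pairs.append((i - 1, j - 1, kind))
            i, j = i - 1, j - 1
        elif h == E[i, j]:
            w = weights[i - 1]
            while j > 0 and E[i, j] == E[i, j - 1] + params.gap_extend * w:
                j -= 1
            j -= 1
        else:
            while i > 0 and F[i, j] == F[i - 1, j] + params.gap_extend * weights[i - 1]:
                i -= 1
            i -= 1
    return j, end_j, list(reversed(pairs))


def best_local_alignment(
    sncrna: str, utr_codes: np.ndarray, params: ScanParams
) -> Optional[TargetSite]:
    """Best-scoring local alignment of the reversed small RNA on the UTR."""
    q_full = _encode(sncrna, "sncRNA")
    q = q_full[::-1].copy()
    weights = position_weights(len(q), params)
    pair = _pair_table(params)
    H, E, F = _sw_fill(q, utr_codes, weights, pair,
                       params.gap_open, params.gap_extend)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    score = float(H[i, j])
    if score <= 0:
        return None
    start, end, raw_pairs = _traceback(H, E, F, q, utr_codes, weights, pair,
                                       params, int(i), int(j))
    n = len(q)
    pairs = tuple((n - 1 - qi, uj, kind) for qi, uj, kind in raw_pairs)
    return TargetSite(utr_start=start, utr_end=end, score=score, pairs=pairs)


def scan_utr(
    sncrna: str,
    utr: str,
    params: ScanParams = ScanParams(),
    sncrna_id: Optional[str] = None,
    utr_id: Optional[str] = None,
) -> list[TargetSite]:
    """All non-overlapping sites with score strictly above the threshold.

    Sites are extracted greedily: the best local alignment is reported, its
    UTR span masked, and the scan repeated, so overlaps resolve by score
    then leftmost position.
    """
    if not 15 <= len(sncrna) <= 50:
        raise ValueError(f"sncRNA length {len(sncrna)} outside [15, 50]")
    if len(utr) < len(sncrna):
        raise ValueError("UTR shorter than the small RNA")
    codes = _encode(utr, "UTR")
    sites: list[TargetSite] = []
    for _ in range(params.max_sites):
        site = best_local_alignment(sncrna, codes, params)
        if site is None or site.score <= params.threshold:
            break
        sites.append(TargetSite(site.utr_start, site.utr_end, site.score,
                                site.pairs, sncrna_id, utr_id))
        codes[site.utr_start:site.utr_end] = MASKED
    return sites


def read_utr_fasta(path: str | Path) -> dict[str, str]:
    """UTRs keyed by mRNA symbol; duplicate ids are an error."""
    utrs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in utrs:
            raise ValueError(f"duplicate UTR id {rec.id!r}")
        utrs[rec.id] = str(rec.seq).upper()
    return utrs


def predict_targets(
    sncrna_seqs: Mapping[str, str],
    utrs: Mapping[str, str],
    params: ScanParams = ScanParams(),
) -> pd.DataFrame:
    """One row per (small RNA, mRNA) pair with at least one site above
    threshold; the best site's score and span are retained."""
    rows = []
    for sid in sorted(sncrna_seqs):
        seq = sncrna_seqs[sid]
        for mid in sorted(utrs):
            utr = utrs[mid]
            if len(utr) < len(seq):
                logger.warning("UTR %s shorter than %s; skipped", mid, sid)
                continue
            sites = scan_utr(seq, utr, params, sncrna_id=sid, utr_id=mid)
            if sites:
                best = sites[0]
                rows.append({"sncrna": sid, "mrna": mid,
                             "best_score": best.score,
                             "utr_start": best.utr_start,
                             "utr_end": best.utr_end,
                             "n_sites": len(sites)})
    return pd.DataFrame(rows, columns=["sncrna", "mrna", "best_score",
                                       "utr_start", "utr_end", "n_sites"])
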