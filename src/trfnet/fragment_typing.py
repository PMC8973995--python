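"""Classification of small-RNA reads into the six tRF/tiRNA classes.

A tRNA gives rise to positionally defined fragment classes:

* **tRF-5** — 5' end of the mature tRNA (D-loop cleavage), 16-28 nt;
* **tRF-3** — 3' end of the mature tRNA including the CCA tail, 16-28 nt;
* **tRF-1** — the precursor's 3' trailer starting at its first base, with the
  pol III poly-U signature;
* **i-tRF** — internal mature fragments that are none of the above;
* **tiRNA-5 / tiRNA-3** — tRNA halves (29-50 nt) from anticodon-loop
  cleavage, anchored at the 5' or 3' terminus respectively.

Classification is a pure function of the alignment coordinates, the
compartment (mature vs trailer) and the reference length, applied in a fixed
rule order so classes are mutually exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .trna import TRNAReference

logger = logging.getLogger(__name__)

TRF5 = "tRF-5"
TRF3 = "tRF-3"
TRF1 = "tRF-1"
ITRF = "i-tRF"
TIRNA5 = "tiRNA-5"
TIRNA3 = "tiRNA-3"
UNCLASSIFIED = "unclassified"

#: the six assignable classes, in canonical display order
FRAGMENT_CLASSES: tuple[str, ...] = (TRF5, TRF3, TRF1, ITRF, TIRNA5, TIRNA3)

_NAME_PREFIX = {
    TRF5: "tRF5",
    TRF3: "tRF3",
    TRF1: "tRF1",
    ITRF: "i-tRF",
    TIRNA5: "tiRNA5",
    TIRNA3: "tiRNA3",
    UNCLASSIFIED: "unclassified",
}

TRF_LEN = (16, 28)
TIRNA_LEN = (29, 50)
MIN_READ_LEN = 14


@dataclass(frozen=True)
class AlignmentHit:
    """Ungapped full-read placement of a read on one tRNA compartment."""

    ref_id: str
    compartment: str  # "mature" | "trailer"
    start: int  # 0-based, half-open on the compartment sequence
    end: int
    mismatches: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentCall:
    read_id: str
    ref_id: str
    compartment: str
    start: int
    end: int
    fragment_class: str
    name: str

    @property
    def length(self) -> int:
        return self.end - self.start


def trim_adapter(read: str, adapter: str, min_overlap: int = 5) -> str:
    """Remove the longest read suffix that exactly matches a prefix of the
    3' adapter, requiring at least ``min_overlap`` bases; at most one trim."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not read:
        return read
    kmax = min(len(read), len(adapter))
    for k in range(kmax, min_overlap - 1, -1):
        if read[-k:] == adapter[:k]:
            return read[:-k]
    return read


def _exact_starts(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


_COMPARTMENT_RANK = {"mature": 0, "trailer": 1}


def align_to_trna(
    read: str,
    refs: Sequence[TRNAReference],
    max_mismatch: int = 0,
) -> Optional[AlignmentHit]:
    """Best ungapped full-read placement across all references.

    The mature compartment is preferred over the trailer; ties are broken by
    fewest mismatches, then mature over trailer, then smallest start, then
    lexicographically smallest reference id. Returns ``None`` when no
    placement has at most ``max_mismatch`` mismatches.
    """
    read = read.upper().replace("U", "T")
    if len(read) < MIN_READ_LEN:
        return None
    best: Optional[tuple[int, int, int, str]] = None
    for ref in refs:
        for compartment in ("mature", "trailer"):
            seq = ref.compartment_seq(compartment)
            if len(seq) < len(read):
                continue
            if max_mismatch == 0:
                starts = _exact_starts(seq, read)
                for s in starts:
                    key = (0, _COMPARTMENT_RANK[compartment], s, ref.id)
                    if best is None or key < best:
                        best = key
            else:
                for s in range(len(seq) - len(read) + 1):
                    mm = 0
                    window = seq[s:s + len(read)]
                    for a, b in zip(read, window):
                        if a != b:
                            mm += 1
                            if mm > max_mismatch:
                                break
                    if mm <= max_mismatch:
                        key = (mm, _COMPARTMENT_RANK[compartment], s, ref.id)
                        if best is None or key < best:
                            best = key
    if best is None:
        return None
    mm, crank, start, ref_id = best
    compartment = "mature" if crank == 0 else "trailer"
    return AlignmentHit(ref_id, compartment, start, start + len(read), mm)


def _anticodon_ok(ref: TRNAReference, cut_site: int, check: bool) -> bool:
    # Halves must be cut in the anticodon loop when the metadata exists;
    # without anticodon_start the positional rule alone decides.
    if not check or ref.anticodon_start is None:
        return True
    ac = ref.anticodon_start
    return ac - 3 <= cut_site < ac + 6


def classify_fragment(
    hit: AlignmentHit,
    ref: TRNAReference,
    cca_slack: int = 1,
    check_anticodon: bool = True,
) -> str:
    """Assign a fragment class by the first matching positional rule.

    ``cca_slack`` lets a 3'-anchored fragment end up to that many bases
    before the mature 3' terminus, tolerating CCA/3'-A trimming variability.
    """
    seq = ref.compartment_seq(hit.compartment)
    if not (0 <= hit.start < hit.end <= len(seq)):
        raise ValueError(
            f"hit {hit.start}-{hit.end} outside {ref.id} {hit.compartment} "
            f"(length {len(seq)})"
        )
    n = hit.length
    if hit.compartment == "trailer":
        return TRF1 if hit.start == 0 else UNCLASSIFIED
    mlen = len(ref.mature_seq)
    at_5p = hit.start == 0
    at_3p = hit.end >= mlen - cca_slack
    if at_5p and TRF_LEN[0] <= n <= TRF_LEN[1]:
        return TRF5
    if at_3p and TRF_LEN[0] <= n <= TRF_LEN[1]:
        return TRF3
    if at_5p and TIRNA_LEN[0] <= n <= TIRNA_LEN[1]:
        if _anticodon_ok(ref, hit.end, check_anticodon):
            return TIRNA5
    elif at_3p and TIRNA_LEN[0] <= n <= TIRNA_LEN[1]:
        if _anticodon_ok(ref, hit.start, check_anticodon):
            return TIRNA3
    if hit.start > 0 and hit.end < mlen:
        return ITRF
    return UNCLASSIFIED


def name_fragment(fragment_class: str, ref_id: str) -> str:
    """Standard fragment name, e.g. ``("tRF-3", "Thr-AGT") -> "tRF3-Thr-AGT"``."""
    try:
        prefix = _NAME_PREFIX[fragment_class]
    except KeyError:
        raise ValueError(f"unknown fragment class {fragment_class!r}") from None
    return f"{prefix}-{ref_id}"


def classify_reads(
    reads: Iterable[tuple[str, str]],
    refs: Sequence[TRNAReference],
    adapter: Optional[str] = None,
    min_overlap: int = 5,
    max_mismatch: int = 0,
    cca_slack: int = 1,
    check_anticodon: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Trim, align and classify ``(read_id, sequence)`` pairs.

    Returns a calls table (one row per aligned read) and the list of read ids
    that failed to align.
    """
    ref_by_id = {r.id: r for r in refs}
    rows, unmapped = [], []
    for read_id, seq in reads:
        if adapter:
            seq = trim_adapter(seq.upper().replace("U", "T"), adapter, min_overlap)
        hit = align_to_trna(seq, refs, max_mismatch=max_mismatch)
        if hit is None:
            unmapped.append(read_id)
            continue
        ref = ref_by_id[hit.ref_id]
        cls = classify_fragment(hit, ref, cca_slack=cca_slack,
                                check_anticodon=check_anticodon)
        rows.append(
            {
                "read_id": read_id,
                "ref_id": hit.ref_id,
                "compartment": hit.compartment,
                "start": hit.start,
                "end": hit.end,
                "length": hit.length,
                "fragment_class": cls,
                "name": name_fragment(cls, hit.ref_id),
            }
        )
    if unmapped:
        logger.info("%d reads did not align to any tRNA reference", len(unmapped))
    columns = ["read_id", "ref_id", "compartment", "start", "end", "length",
               "fragment_class", "name"]
    return pd.DataFrame(rows, columns=columns), unmapped


def read_small_rna_file(path: str | Path) -> list[tuple[str, str]]:
    """Load reads from FASTA or FASTQ (sniffed from the first character)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


@dataclass
class TypeDistribution:
    """Per-class read proportions, overall and per source tRNA.

    Unclassified reads are excluded from the denominators and reported
    separately via ``n_unclassified``.
    """

    overall: pd.Series
    per_ref: pd.DataFrame
    counts: pd.Series
    n_unclassified: int


def type_distribution(
    calls: pd.DataFrame,
    weights: Optional[pd.Series] = None,
) -> TypeDistribution:
    """Fraction of reads per fragment class (Figure-7-style table).

    ``weights`` optionally maps read_id to a count (defaults to 1 per read).
    """
    if calls.empty:
        raise ValueError("no fragment calls to summarize")
    df = calls.copy()
    df["weight"] = 1.0 if weights is None else df["read_id"].map(weights).fillna(0.0)
    unclassified = df[df["fragment_class"] == UNCLASSIFIED]
    assigned = df[df["fragment_class"] != UNCLASSIFIED]
    counts = (
        assigned.groupby("fragment_class")["weight"].sum()
        .reindex(FRAGMENT_CLASSES, fill_value=0.0)
    )
    total = counts.sum()
    overall = counts / total if total > 0 else counts * 0.0
    per_ref = (
        assigned.pivot_table(index="ref_id", columns="fragment_class",
                             values="weight", aggfunc="sum", fill_value=0.0)
        .reindex(columns=FRAGMENT_CLASSES, fill_value=0.0)
    )
    per_ref = per_ref.div(per_ref.sum(axis=1), axis=0)
    return TypeDistribution(
        overall=overall,
        per_ref=per_ref,
        counts=counts,
        n_unclassified=int(unclassified["weight"].sum()),
    )
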