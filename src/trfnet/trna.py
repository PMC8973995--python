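"""tRNA reference sequences: the mature transcript (with its 3' CCA) and the
precursor's 3' trailer, keyed by isotype-anticodon identifiers as used by
GtRNAdb (e.g. ``Thr-AGT``)."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_HEADER_RE = re.compile(
    r"^(?P<id>\S+)\s+(?P<compartment>mature|precursor)"
    r"(?:\s+\[anticodon_start=(?P<ac>\d+)\])?\s*$"
)


@dataclass(frozen=True)
class TRNAReference:
    """One tRNA locus.

    Parameters
    ----------
    id : str
        Isotype-anticodon identifier, e.g. ``"Thr-AGT"``. A numeric suffix
        (``"Thr-AGT-2"``) disambiguates paralogs.
    mature_seq : str
        Mature tRNA sequence (DNA alphabet, upper case), ending in the
        post-transcriptionally added CCA.
    trailer_seq : str
        3' trailing sequence of the precursor transcript (may be empty).
        The precursor is modelled as mature-without-CCA followed by this
        trailer; pol III termination leaves a poly-U (poly-T in DNA) run in it.
    anticodon_start : int, optional
        0-based offset of the first anticodon base on ``mature_seq``. Used
        for the optional anticodon-loop check on tRNA halves.
    """

    id: str
    mature_seq: str
    trailer_seq: str = ""
    anticodon_start: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.mature_seq.endswith("CCA"):
            raise ValueError(f"{self.id}: mature tRNA must end in CCA")
        if not 60 <= len(self.mature_seq) <= 100:
            raise ValueError(
                f"{self.id}: mature length {len(self.mature_seq)} outside [60, 100]"
            )
        if self.anticodon_start is not None and not (
            0 <= self.anticodon_start <= len(self.mature_seq) - 3
        ):
            raise ValueError(f"{self.id}: anticodon_start out of range")

    @property
    def precursor_seq(self) -> str:
        """Precursor 3' region: mature without CCA, then the trailer."""
        return self.mature_seq[:-3] + self.trailer_seq

    def compartment_seq(self, compartment: str) -> str:
        if compartment == "mature":
            return self.mature_seq
        if compartment == "trailer":
            return self.trailer_seq
        raise ValueError(f"unknown compartment {compartment!r}")


def write_reference_fasta(refs: Iterable[TRNAReference], path: str | Path) -> None:
    """Write mature and (where a trailer exists) precursor records.

    Headers follow ``<id> mature|precursor [anticodon_start=N]``.
    """
    records = []
    for ref in refs:
        desc = "mature"
        if ref.anticodon_start is not None:
            desc += f" [anticodon_start={ref.anticodon_start}]"
        records.append(SeqRecord(Seq(ref.mature_seq), id=ref.id, description=desc))
        if ref.trailer_seq:
            records.append(
                SeqRecord(Seq(ref.precursor_seq), id=ref.id, description="precursor")
            )
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path: str | Path) -> list[TRNAReference]:
    """Reconstruct :class:`TRNAReference` objects written by
    :func:`write_reference_fasta`."""
    mature: dict[str, tuple[str, Optional[int]]] = {}
    precursor: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description if rec.description else rec.id
        m = _HEADER_RE.match(header)
        if m is None:
            raise ValueError(f"unparseable tRNA reference header: {header!r}")
        seq = str(rec.seq).upper()
        if m["compartment"] == "mature":
            ac = int(m["ac"]) if m["ac"] is not None else None
            mature[m["id"]] = (seq, ac)
            order.append(m["id"])
        else:
            precursor[m["id"]] = seq
    refs = []
    for rid in order:
        mseq, ac = mature[rid]
        pre = precursor.get(rid, "")
        trailer = pre[len(mseq) - 3:] if pre else ""
        refs.append(TRNAReference(rid, mseq, trailer, ac))
    return refs
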