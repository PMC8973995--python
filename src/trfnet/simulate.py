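"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a 3-vs-3
two-group comparison of a trypsinogen-activation model (treated) against
untreated acinar cells (control), with differential expression planted at the
class-specific fold-change thresholds, small-RNA reads drawn from defined
fragment classes of tRNA references, 3'UTRs carrying exact-complement target
sites, and qPCR Ct tables with a known ddCt shift.

Every generator derives its random stream deterministically from one global
seed, so a fixed configuration reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fragment_typing as ft
from .trna import TRNAReference

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")

# canonical isotype/anticodon pairs used to label simulated references;
# Thr-AGT first so the worked-example locus is always present
_ISOTYPES = [
    ("Thr", "AGT"), ("Met", "CAT"), ("Gly", "GCC"), ("Glu", "CTC"),
    ("Lys", "CTT"), ("Val", "CAC"), ("Asp", "GTC"), ("His", "GTG"),
    ("Leu", "CAA"), ("Ser", "GCT"), ("Arg", "ACG"), ("Ala", "AGC"),
    ("Pro", "AGG"), ("Gln", "CTG"), ("Phe", "GAA"), ("Tyr", "GTA"),
    ("Ile", "AAT"), ("Cys", "GCA"), ("Trp", "CCA"), ("Asn", "GTT"),
]

#: 3' end of the worked-example Thr-AGT mature tRNA: the 17-nt fragment
#: studied in validation experiments, followed by the terminal A of CCA
#: (the fragment itself stops one base short of the CCA terminus).
THR_AGT_FRAGMENT_RNA = "AUCCCAGCGGUGCCUCC"
THR_AGT_INHIBITOR_RNA = "GGAGGCACCGCUGGGAU"


def reverse_complement(seq: str) -> str:
    """Reverse complement; accepts DNA or RNA, returns the DNA alphabet."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults reproduce the emulated design: 3 control vs 3 treated samples,
    planted up/down counts per feature class matching the published DE
    summary (mRNA 172/34, miRNA 11/24, tRF 4/16), a 4-fold planted effect
    with 5% within-group coefficient of variation, and 100 reads per
    fragment class.
    """

    seed: int = 0
    n_trnas: int = 20
    trailer_len: int = 30
    n_mrna: int = 2000
    n_mirna: int = 300
    n_trf: int = 200
    group_sizes: tuple[int, int] = (3, 3)
    planted_up: dict = field(
        default_factory=lambda: {"mRNA": 172, "miRNA": 11, "tRF": 4})
    planted_down: dict = field(
        default_factory=lambda: {"mRNA": 34, "miRNA": 24, "tRF": 16})
    effect_fold: float = 4.0
    noise_cv: float = 0.05
    reads_per_class: int = 100
    site_plant_rate: float = 0.5
    utr_len: int = 200
    sncrna_len: tuple[int, int] = (17, 22)
    ct_noise_sd: float = 0.1
    ct_n_per_group: int = 3
    true_ddct: float = 1.5

    def n_features(self, feature_class: str) -> int:
        return {"mRNA": self.n_mrna, "miRNA": self.n_mirna, "tRF": self.n_trf}[
            feature_class]

    def validate(self) -> None:
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs >= 2 replicates")
        if self.ct_n_per_group < 2:
            raise ValueError("Ct table needs >= 2 samples per group")
        for cls in ("mRNA", "miRNA", "tRF"):
            up = self.planted_up.get(cls, 0)
            down = self.planted_down.get(cls, 0)
            if up < 0 or down < 0:
                raise ValueError("planted counts must be >= 0")
            if up + down > self.n_features(cls):
                raise ValueError(f"{cls}: planted_up + planted_down exceeds features")
            if up + down > 0 and self.effect_fold <= 1:
                raise ValueError("effect_fold must exceed 1 when features are planted")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if any(x < 0 for x in (self.n_trnas, self.trailer_len, self.n_mrna,
                               self.n_mirna, self.n_trf, self.reads_per_class)):
            raise ValueError("counts must be >= 0")
        if not 0 <= self.site_plant_rate <= 1:
            raise ValueError("site_plant_rate must be in [0, 1]")


# stream offsets so each generator owns an independent substream of the seed
_STREAMS = {"trna": 1, "reads": 2, "mRNA": 3, "miRNA": 4, "tRF": 5,
            "sncrna_seq": 6, "utr": 7, "ct": 8, "gmt": 9}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed,
                                                         _STREAMS[stream]]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


@dataclass
class GroundTruth:
    """Everything the generators planted, for downstream verification."""

    de_direction: dict = field(default_factory=dict)  # class -> {feature: up|down|null}
    read_classes: dict = field(default_factory=dict)  # read_id -> (class, ref_id)
    planted_sites: list = field(default_factory=list)  # (utr, start, end, sncrna)
    true_ddct: float = 0.0
    hub_regulator: str = ""

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_direction": self.de_direction,
            "read_classes": self.read_classes,
            "planted_sites": self.planted_sites,
            "true_ddct": self.true_ddct,
            "hub_regulator": self.hub_regulator,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def make_trna_reference(config: SimulationConfig) -> list[TRNAReference]:
    """Simulate ``n_trnas`` tRNA loci.

    Mature sequences are 70-90 nt ending in CCA with the anticodon placed
    mid-sequence; trailers carry a poly-T (poly-U on the transcript) run of
    at least 4 within their first 25 nt, the pol III termination signature
    that marks tRF-1 fragments.
    """
    config.validate()
    rng = _rng(config, "trna")
    refs: list[TRNAReference] = []
    used: dict[str, int] = {}
    for i in range(config.n_trnas):
        isotype, anticodon = _ISOTYPES[i % len(_ISOTYPES)]
        base_id = f"{isotype}-{anticodon}"
        used[base_id] = used.get(base_id, 0) + 1
        rid = base_id if used[base_id] == 1 else f"{base_id}-{used[base_id]}"
        length = int(rng.integers(70, 91))
        body = list(_random_seq(rng, length - 3))
        ac_start = length // 2 - 1
        body[ac_start:ac_start + 3] = list(anticodon)
        mature = "".join(body) + "CCA"
        if rid == "Thr-AGT":
            # embed the worked-example 3' end: the 17-nt fragment then the
            # final A completing the CCA terminus
            tail = dna(THR_AGT_FRAGMENT_RNA) + "A"
            mature = mature[: length - len(tail)] + tail
        trailer = list(_random_seq(rng, config.trailer_len))
        if config.trailer_len >= 4:
            pos = int(rng.integers(0, max(1, min(22, config.trailer_len - 4) + 1)))
            trailer[pos:pos + 4] = list("TTTT")
        refs.append(TRNAReference(rid, mature, "".join(trailer), ac_start))
    return refs


def thr_agt_reference(seed: int = 0) -> TRNAReference:
    """The single worked-example Thr-AGT locus."""
    cfg = SimulationConfig(seed=seed, n_trnas=1)
    return make_trna_reference(cfg)[0]


def _sample_read(rng: np.random.Generator, ref: TRNAReference,
                 fragment_class: str) -> tuple[str, int, int, str]:
    """Draw (sequence, start, end, compartment) obeying the class rule."""
    mature, trailer = ref.mature_seq, ref.trailer_seq
    mlen = len(mature)
    ac = ref.anticodon_start
    if fragment_class == ft.TRF5:
        n = int(rng.integers(16, 29))
        return mature[:n], 0, n, "mature"
    if fragment_class == ft.TRF3:
        n = int(rng.integers(16, 29))
        return mature[mlen - n:], mlen - n, mlen, "mature"
    if fragment_class == ft.TRF1:
        hi = min(28, len(trailer))
        if hi < 16:
            raise ValueError(
                f"cannot draw a tRF-1 from {ref.id}: trailer length "
                f"{len(trailer)} < 16")
        n = int(rng.integers(16, hi + 1))
        return trailer[:n], 0, n, "trailer"
    if fragment_class == ft.ITRF:
        n = int(rng.integers(16, 29))
        # keep clear of both termini (and the CCA slack window) so the
        # fragment can only be internal
        start = int(rng.integers(1, mlen - n - 1))
        return mature[start:start + n], start, start + n, "mature"
    if fragment_class == ft.TIRNA5:
        lo = max(29, (ac or 0) - 3)
        hi = min(50, (ac + 5) if ac is not None else 50, mlen - 2)
        if hi < lo:
            raise ValueError(f"cannot draw a tiRNA-5 from {ref.id}")
        n = int(rng.integers(lo, hi + 1))
        return mature[:n], 0, n, "mature"
    if fragment_class == ft.TIRNA3:
        lo = max(mlen - 50, (ac - 3) if ac is not None else 1)
        hi = min(mlen - 29, (ac + 5) if ac is not None else mlen - 29)
        if hi < lo:
            raise ValueError(f"cannot draw a tiRNA-3 from {ref.id}")
        s = int(rng.integers(lo, hi + 1))
        return mature[s:], s, mlen, "mature"
    raise ValueError(f"unknown fragment class {fragment_class!r}")


def simulate_reads(
    refs: Sequence[TRNAReference],
    config: SimulationConfig,
    adapter: Optional[str] = None,
    classes: Sequence[str] = ft.FRAGMENT_CLASSES,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Draw ``reads_per_class`` reads for each requested class.

    Each read obeys its class's positional rule exactly, so noise-free
    classification round-trips to the truth. When ``adapter`` is given the
    full adapter sequence is appended (for trimming tests).
    """
    if not refs:
        raise ValueError("no tRNA references")
    rng = _rng(config, "reads")
    truth = GroundTruth()
    reads: list[tuple[str, str]] = []
    for cls in classes:
        eligible = [r for r in refs
                    if cls != ft.TRF1 or len(r.trailer_seq) >= 16]
        if not eligible:
            raise ValueError(f"no reference can produce class {cls}")
        for j in range(config.reads_per_class):
            ref = eligible[int(rng.integers(0, len(eligible)))]
            seq, start, end, compartment = _sample_read(rng, ref, cls)
            read_id = f"{ft.name_fragment(cls, ref.id)}|{j}"
            truth.read_classes[read_id] = [cls, ref.id]
            if adapter:
                seq = seq + adapter
            reads.append((read_id, seq))
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Phred+33 FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def _feature_ids(config: SimulationConfig, feature_class: str,
                 refs: Optional[Sequence[TRNAReference]] = None) -> list[str]:
    n = config.n_features(feature_class)
    if feature_class == "mRNA":
        # seed the universe with the transcription-factor fixture symbols so
        # networks can carry TF annotations
        from .network import default_tf_list
        tf = sorted(default_tf_list())[:n]
        return tf + [f"Gene{i + 1:04d}" for i in range(n - len(tf))]
    if feature_class == "miRNA":
        return [f"rno-miR-sim-{i + 1:03d}" for i in range(n)]
    ids = []
    if refs:
        combos = [ft.name_fragment(cls, r.id)
                  for r in refs for cls in ft.FRAGMENT_CLASSES]
        ids = combos[:n]
    while len(ids) < n:
        ids.append(f"tRF-sim-{len(ids) + 1:03d}")
    return ids


def simulate_expression(
    config: SimulationConfig,
    feature_class: str,
    refs: Optional[Sequence[TRNAReference]] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Expression matrix (features x samples) with planted DE structure.

    Null features share a group mean; planted-up features have a
    treated/control mean ratio of ``effect_fold`` and planted-down the
    reciprocal. Within-group values are log-normal with coefficient of
    variation ``noise_cv`` around the group mean.
    """
    config.validate()
    rng = _rng(config, feature_class)
    ids = _feature_ids(config, feature_class, refs)
    n = len(ids)
    n_up = config.planted_up.get(feature_class, 0)
    n_down = config.planted_down.get(feature_class, 0)
    direction = np.array(["null"] * n, dtype=object)
    planted = rng.choice(n, size=n_up + n_down, replace=False)
    direction[planted[:n_up]] = "up"
    direction[planted[n_up:]] = "down"

    base = 10.0 ** rng.uniform(1.0, 3.0, size=n)  # control-group mean
    fold = np.ones(n)
    fold[direction == "up"] = config.effect_fold
    fold[direction == "down"] = 1.0 / config.effect_fold

    n_ctrl, n_trt = config.group_sizes
    sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
    def draw(mean: np.ndarray, k: int) -> np.ndarray:
        z = rng.standard_normal((n, k))
        return mean[:, None] * np.exp(sigma * z - sigma ** 2 / 2)

    values = np.hstack([draw(base, n_ctrl), draw(base * fold, n_trt)])
    columns = [f"S{i + 1}_ctrl" for i in range(n_ctrl)] + \
              [f"S{n_ctrl + i + 1}_trt" for i in range(n_trt)]
    df = pd.DataFrame(values, index=pd.Index(ids, name="feature"),
                      columns=columns)
    truth = GroundTruth()
    truth.de_direction[feature_class] = dict(zip(ids, direction))
    return df, truth


def simulate_sncrna_sequences(
    config: SimulationConfig, sncrna_ids: Sequence[str]
) -> dict[str, str]:
    """Random RNA sequences (5'->3') for the simulated small RNAs."""
    rng = _rng(config, "sncrna_seq")
    lo, hi = config.sncrna_len
    return {sid: rna(_random_seq(rng, int(rng.integers(lo, hi + 1))))
            for sid in sncrna_ids}


def make_utrs(config: SimulationConfig, mrna_ids: Sequence[str]) -> dict[str, str]:
    """I.i.d.-uniform 3'UTR sequences, one per mRNA."""
    rng = _rng(config, "utr")
    return {mid: _random_seq(rng, config.utr_len) for mid in mrna_ids}


def plant_target_sites(
    utrs: dict[str, str],
    sncrna_seqs: dict[str, str],
    target_mrnas: Sequence[str],
    config: SimulationConfig,
    truth: Optional[GroundTruth] = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Embed exact reverse-complement sites into a fraction of target UTRs.

    Each selected UTR (chosen with probability ``site_plant_rate`` from
    ``target_mrnas``) receives the perfect-complement site of one small RNA
    at a uniformly random position; coordinates are recorded as 0-based
    half-open intervals.
    """
    # spawned child stream: planting decisions never perturb the UTR content
    rng = _rng(config, "utr").spawn(1)[0]
    truth = truth or GroundTruth()
    out = dict(utrs)
    snc_ids = sorted(sncrna_seqs)
    for mid in target_mrnas:
        if mid not in out:
            continue
        if rng.random() > config.site_plant_rate:
            continue
        sid = snc_ids[int(rng.integers(0, len(snc_ids)))]
        site = reverse_complement(dna(sncrna_seqs[sid]))
        utr = out[mid]
        if len(site) > len(utr):
            raise ValueError(
                f"site for {sid} ({len(site)} nt) exceeds UTR {mid} "
                f"({len(utr)} nt)")
        start = int(rng.integers(0, len(utr) - len(site) + 1))
        out[mid] = utr[:start] + site + utr[start + len(site):]
        truth.planted_sites.append([mid, start, start + len(site), sid])
    return out, truth


def plant_hub_sites(
    utrs: dict[str, str],
    hub_id: str,
    hub_seq: str,
    target_mrnas: Sequence[str],
    n_targets: int,
    config: SimulationConfig,
    truth: Optional[GroundTruth] = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Plant one regulator's perfect-complement site into ``n_targets`` UTRs,
    creating a known hub for network-recovery checks."""
    rng = _rng(config, "utr").spawn(2)[1]
    truth = truth or GroundTruth()
    truth.hub_regulator = hub_id
    out = dict(utrs)
    site = reverse_complement(dna(hub_seq))
    chosen = [m for m in target_mrnas if m in out][:n_targets]
    for mid in chosen:
        utr = out[mid]
        if len(site) > len(utr):
            raise ValueError(f"site for {hub_id} exceeds UTR {mid}")
        start = int(rng.integers(0, len(utr) - len(site) + 1))
        out[mid] = utr[:start] + site + utr[start + len(site):]
        truth.planted_sites.append([mid, start, start + len(site), hub_id])
    return out, truth


def simulate_ct_table(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """qPCR Ct table: control and treated groups with a known ddCt shift.

    The reference gene (U6-style) sits near Ct 18, the target near Ct 24 in
    the control (calibrator) group; the treated group's target Ct is shifted
    by ``true_ddct`` cycles. Gaussian noise of ``ct_noise_sd`` cycles applies
    to every well.
    """
    config.validate()
    rng = _rng(config, "ct")
    rows = []
    for group, shift in (("control", 0.0), ("treated", config.true_ddct)):
        for i in range(config.ct_n_per_group):
            rows.append({
                "sample": f"{group[:4]}_{i + 1}",
                "group": group,
                "ct_target": 24.0 + shift + rng.normal(0, config.ct_noise_sd),
                "ct_reference": 18.0 + rng.normal(0, config.ct_noise_sd),
            })
    truth = GroundTruth(true_ddct=config.true_ddct)
    return pd.DataFrame(rows), truth


def make_gene_sets(
    config: SimulationConfig,
    mrna_ids: Sequence[str],
    enriched_genes: Optional[Sequence[str]] = None,
    n_terms: int = 20,
    term_size: tuple[int, int] = (10, 60),
) -> dict[str, list[str]]:
    """Synthetic GO/KEGG-style gene sets over the simulated mRNA universe.

    When ``enriched_genes`` is given, one extra term (``TERM_ENRICHED``) is
    built mostly from those genes, giving enrichment a planted positive.
    """
    rng = _rng(config, "gmt")
    sets: dict[str, list[str]] = {}
    ids = list(mrna_ids)
    for t in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        members = rng.choice(ids, size=min(size, len(ids)), replace=False)
        sets[f"TERM_{t + 1:03d}"] = sorted(members)
    if enriched_genes:
        take = list(enriched_genes)[: term_size[1]]
        sets["TERM_ENRICHED"] = sorted(set(take))
    return sets
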