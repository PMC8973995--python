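"""Hypergeometric gene-set enrichment with the conservative EASE variant.

For a gene list of size n drawn from a background of size N, a term with K
members overlapping the list in k genes gets the one-sided upper-tail
hypergeometric p-value P(X >= k). The default ``ease`` mode recomputes the
tail with k reduced by one — the EASE score — which penalises
single-gene overlaps (k = 1 gives p = 1). Enrichment score = -log10(p);
Benjamini-Hochberg q-values are reported but not used for filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSet:
    term: str
    name: str
    members: frozenset[str]
    namespace: str = "GO_BP"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.term}: gene set has no members")


def normalize_symbol(symbol: str) -> str:
    """RGD-style capitalisation: initial capital, rest lower case."""
    s = symbol.strip()
    return s[:1].upper() + s[1:].lower() if s else s


def read_gmt(path: str | Path, namespace: str = "GO_BP") -> list[GeneSet]:
    """GMT: one term per line — term, description, then member symbols."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        members = frozenset(normalize_symbol(g) for g in parts[2:] if g)
        sets.append(GeneSet(parts[0], parts[1], members, namespace))
    return sets


def write_gmt(sets: Iterable[GeneSet] | Mapping[str, Sequence[str]],
              path: str | Path) -> None:
    lines = []
    if isinstance(sets, Mapping):
        sets = [GeneSet(t, t, frozenset(m)) for t, m in sets.items()]
    for gs in sets:
        lines.append("\t".join([gs.term, gs.name, *sorted(gs.members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def _tail_p(k: int, n: int, K: int, N: int, mode: str) -> float:
    # P(X >= k) for X ~ Hypergeom(N, K, n); EASE uses k - 1
    kk = k - 1 if mode == "ease" else k
    return float(hypergeom.sf(kk - 1, N, K, n))


def enrich(
    gene_list: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background: Iterable[str],
    mode: str = "ease",
) -> pd.DataFrame:
    """Enrichment table over all terms with non-zero overlap, p ascending.

    ``mode="fisher"`` gives the exact one-sided Fisher/hypergeometric tail;
    ``mode="ease"`` (default) the conservative EASE variant.
    """
    if mode not in ("ease", "fisher"):
        raise ValueError("mode must be 'ease' or 'fisher'")
    genes = {normalize_symbol(g) for g in gene_list}
    bg = {normalize_symbol(g) for g in background}
    if not genes:
        raise ValueError("empty gene list")
    if not bg:
        raise ValueError("empty background")
    missing = genes - bg
    if missing:
        raise ValueError(f"gene list not contained in background: "
                         f"{sorted(missing)[:5]}...")
    n, N = len(genes), len(bg)
    rows = []
    for gs in gene_sets:
        members = {normalize_symbol(g) for g in gs.members} & bg
        k = len(members & genes)
        if k == 0:
            continue
        K = len(members)
        p = _tail_p(k, n, K, N, mode)
        rows.append({"term": gs.term, "name": gs.name,
                     "namespace": gs.namespace, "k": k, "K": K,
                     "n": n, "N": N, "p_value": p,
                     "enrichment_score": -np.log10(p),
                     "genes": ",".join(sorted(members & genes))})
    df = pd.DataFrame(rows, columns=["term", "name", "namespace", "k", "K",
                                     "n", "N", "p_value", "enrichment_score",
                                     "genes"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values(["p_value", "term"], kind="stable",
                            ignore_index=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


def bubble_table(rows: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Top terms with the quantities a bubble plot encodes: overlap count
    (bubble size) and -log10 p (colour)."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    return rows.head(top_n)[["term", "name", "k", "enrichment_score",
                             "p_value"]].reset_index(drop=True)


def plot_bubble(rows: pd.DataFrame, path: str | Path, top_n: int = 10,
                title: Optional[str] = None) -> None:
    """Bubble chart of the top enriched terms (size = k, colour = score)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = bubble_table(rows, top_n).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(tab) + 1.5))
    sc = ax.scatter(tab["enrichment_score"], range(len(tab)),
                    s=30 * tab["k"], c=tab["enrichment_score"],
                    cmap="viridis")
    ax.set_yticks(range(len(tab)), tab["name"])
    ax.set_xlabel("enrichment score (-log10 p)")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
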