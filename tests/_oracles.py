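"""Independent reference implementations used only to cross-check the
package: a pure-Python local aligner, exact combinatorial tail sums, a
cross-join pair filter and a sums-of-squares ANOVA."""

from __future__ import annotations

from math import comb

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_WC = {(0, 3), (3, 0), (1, 2), (2, 1)}
_WOBBLE = {(2, 3), (3, 2)}


def oracle_best_local_score(sncrna: str, utr_codes, params) -> float:
    """Best local-alignment score of the reversed small RNA on the UTR,
    computed by a plain nested-list dynamic program (no numba, no numpy).

    Scoring: complementarity substitution scores and affine gap penalties,
    both scaled by the seed weight at the current small-RNA position.
    """
    q = [_CODE[c] for c in sncrna.upper()][::-1]
    n, L = len(q), len(sncrna)
    w = [params.seed_weight
         if params.seed_start <= (L - i) <= params.seed_end else 1.0
         for i in range(n)]
    u = list(utr_codes)
    m = len(u)

    def sub(qc, uc):
        if qc >= 4 or uc >= 4:
            return -1e9
        if (qc, uc) in _WC:
            return params.match
        if (qc, uc) in _WOBBLE:
            return params.wobble
        return params.mismatch

    NEG = -1e18
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + params.gap_open * w[i - 1],
                          E[i][j - 1] + params.gap_extend * w[i - 1])
            F[i][j] = max(H[i - 1][j] + params.gap_open * w[i - 1],
                          F[i - 1][j] + params.gap_extend * w[i - 1])
            h = max(0.0,
                    H[i - 1][j - 1] + w[i - 1] * sub(q[i - 1], u[j - 1]),
                    E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best = h
    return best


def exact_hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(overlap >= k) as an exact rational tail sum, cast to float."""
    denom = comb(N, n)
    num = sum(comb(K, i) * comb(N - K, n - i)
              for i in range(k, min(n, K) + 1))
    return num / denom


def cross_join_pair_filter(de_snc, de_mrna, pairs):
    """Brute-force anti-correlation filter over the full cross join."""
    kept = []
    for _, row in pairs.iterrows():
        s, m = row["sncrna"], row["mrna"]
        if s not in de_snc.index or m not in de_mrna.index:
            continue
        a = de_snc.loc[s, "direction"]
        b = de_mrna.loc[m, "direction"]
        if (a == "up" and b == "down") or (a == "down" and b == "up"):
            kept.append((s, m))
    return sorted(kept)


def anova_f_from_sums_of_squares(groups) -> float:
    """One-way ANOVA F computed directly from between/within sums of squares."""
    all_values = [x for g in groups for x in g]
    grand = sum(all_values) / len(all_values)
    ss_between = sum(len(g) * ((sum(g) / len(g)) - grand) ** 2 for g in groups)
    ss_within = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)
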