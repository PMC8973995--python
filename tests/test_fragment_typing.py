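"""Adapter trimming, tRNA alignment and the positional fragment taxonomy."""

import pytest
from hypothesis import given, settings, strategies as st

from trfnet import fragment_typing as ft
from trfnet import simulate as sim
from trfnet.trna import TRNAReference

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _ref(mature_len=80, trailer="T" * 20, ac=None, rid="Thr-AGT"):
    body = ("ACGT" * 30)[: mature_len - 3]
    return TRNAReference(rid, body + "CCA", trailer, ac)


class TestTrimAdapter:
    @pytest.mark.parametrize("k", [5, 10, len(ADAPTER)])
    def test_removes_adapter_prefix(self, k):
        insert = "ACGTACGTCCAGTTAG"
        assert ft.trim_adapter(insert + ADAPTER[:k], ADAPTER) == insert

    def test_no_adapter_unchanged(self):
        assert ft.trim_adapter("ACGTACGT", ADAPTER) == "ACGTACGT"

    def test_read_shorter_than_min_overlap_unchanged(self):
        assert ft.trim_adapter("ACG", ADAPTER, min_overlap=5) == "ACG"

    def test_empty_read_unchanged(self):
        assert ft.trim_adapter("", ADAPTER) == ""

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(insert=st.text(alphabet="ACGT", min_size=0, max_size=40),
           k=st.integers(min_value=5, max_value=len(ADAPTER)))
    def test_result_is_prefix_of_insert(self, insert, k):
        out = ft.trim_adapter(insert + ADAPTER[:k], ADAPTER)
        assert out == insert[: len(out)]
        assert len(out) <= len(insert)


class TestAlign:
    def test_exact_prefix_substring(self):
        ref = _ref()
        hit = ft.align_to_trna(ref.mature_seq[:20], [ref])
        assert (hit.ref_id, hit.compartment, hit.start, hit.end) == \
            (ref.id, "mature", 0, 20)

    def test_smallest_start_wins_tie(self):
        # identical read present at two starts across two references
        a = TRNAReference("Ala-AGC", "G" * 30 + "ACGTACGTACGTACG" + "G" * 32
                          + "CCA", "")
        b = TRNAReference("Val-CAC", "G" * 10 + "ACGTACGTACGTACG" + "G" * 52
                          + "CCA", "")
        hit = ft.align_to_trna("ACGTACGTACGTACG", [a, b])
        assert hit.ref_id == "Val-CAC" and hit.start == 10

    def test_lexicographic_ref_tiebreak(self):
        seq = "C" * 40 + "TTTTAAAACCCCGGGG" + "C" * 21 + "CCA"
        a = TRNAReference("Met-CAT", seq, "")
        b = TRNAReference("Gly-GCC", seq, "")
        hit = ft.align_to_trna("TTTTAAAACCCCGGGG", [a, b])
        assert hit.ref_id == "Gly-GCC"

    def test_mature_preferred_over_trailer(self):
        shared = "ATATCGCGATATCGCG"
        ref = TRNAReference("Ser-GCT", "G" * 30 + shared + "G" * 31 + "CCA",
                            shared + "TTTT")
        hit = ft.align_to_trna(shared, [ref])
        assert hit.compartment == "mature"

    def test_unalignable_read_returns_none(self):
        assert ft.align_to_trna("N" * 14, [_ref()]) is None

    def test_one_mismatch_allowed_when_requested(self):
        ref = _ref()
        read = "G" + ref.mature_seq[1:20]
        assert ft.align_to_trna(read, [ref], max_mismatch=0) is None
        hit = ft.align_to_trna(read, [ref], max_mismatch=1)
        assert hit is not None and hit.mismatches == 1


class TestClassify:
    @pytest.mark.parametrize(
        "start,end,compartment,expected",
        [
            (0, 20, "mature", ft.TRF5),
            (60, 80, "mature", ft.TRF3),
            (0, 20, "trailer", ft.TRF1),
            (15, 35, "mature", ft.ITRF),
            (0, 38, "mature", ft.TIRNA5),
            (42, 80, "mature", ft.TIRNA3),
            (0, 15, "mature", ft.UNCLASSIFIED),  # below the 16-nt floor
            (2, 22, "trailer", ft.UNCLASSIFIED),  # trailer but not its start
        ],
    )
    def test_rule_table(self, start, end, compartment, expected):
        ref = _ref(mature_len=80, trailer="T" * 30, ac=39)
        hit = ft.AlignmentHit(ref.id, compartment, start, end)
        assert ft.classify_fragment(hit, ref) == expected

    def test_cca_slack_accepts_one_base_short(self):
        ref = _ref(mature_len=80)
        hit = ft.AlignmentHit(ref.id, "mature", 62, 79)  # ends 1 nt early
        assert ft.classify_fragment(hit, ref, cca_slack=1) == ft.TRF3
        assert ft.classify_fragment(hit, ref, cca_slack=0) == ft.ITRF

    def test_anticodon_check_rejects_off_loop_halves(self):
        ref = _ref(mature_len=80, ac=39)
        hit = ft.AlignmentHit(ref.id, "mature", 0, 30)  # cut at 30 << loop
        assert ft.classify_fragment(hit, ref) == ft.UNCLASSIFIED
        assert ft.classify_fragment(hit, ref, check_anticodon=False) == ft.TIRNA5

    def test_out_of_bounds_hit_is_error(self):
        ref = _ref()
        with pytest.raises(ValueError, match="outside"):
            ft.classify_fragment(ft.AlignmentHit(ref.id, "mature", 70, 95), ref)

    def test_worked_example_thr_agt(self):
        ref = sim.thr_agt_reference()
        read = sim.dna(sim.THR_AGT_FRAGMENT_RNA)
        hit = ft.align_to_trna(read, [ref])
        assert hit.end == len(ref.mature_seq) - 1  # one base short of CCA
        cls = ft.classify_fragment(hit, ref)
        assert cls == ft.TRF3
        assert ft.name_fragment(cls, ref.id) == "tRF3-Thr-AGT"


class TestNaming:
    @pytest.mark.parametrize("cls,rid,expected", [
        (ft.TRF3, "Thr-AGT", "tRF3-Thr-AGT"),
        (ft.ITRF, "Met-CAT", "i-tRF-Met-CAT"),
        (ft.TIRNA5, "Gly-GCC", "tiRNA5-Gly-GCC"),
        (ft.UNCLASSIFIED, "Gly-GCC", "unclassified-Gly-GCC"),
    ])
    def test_names(self, cls, rid, expected):
        assert ft.name_fragment(cls, rid) == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            ft.name_fragment("tRF-9", "Gly-GCC")


class TestPermutationInvariance:
    def test_read_order_never_changes_calls(self, refs, small_config):
        reads, _ = sim.simulate_reads(refs, small_config)
        calls_fwd, _ = ft.classify_reads(reads, refs)
        calls_rev, _ = ft.classify_reads(list(reversed(reads)), refs)
        fwd = calls_fwd.set_index("read_id").sort_index()
        rev = calls_rev.set_index("read_id").sort_index()
        assert fwd.equals(rev)


class TestTypeDistribution:
    def _calls(self, class_counts):
        rows = []
        for cls, n in class_counts.items():
            for i in range(n):
                rows.append({"read_id": f"{cls}:{i}", "ref_id": "Thr-AGT",
                             "compartment": "mature", "start": 0, "end": 20,
                             "length": 20, "fragment_class": cls,
                             "name": ft.name_fragment(cls, "Thr-AGT")})
        import pandas as pd
        return pd.DataFrame(rows)

    def test_uniform_classes(self):
        calls = self._calls({c: 10 for c in ft.FRAGMENT_CLASSES})
        dist = ft.type_distribution(calls)
        assert all(abs(f - 1 / 6) < 1e-12 for f in dist.overall)

    def test_single_class(self):
        dist = ft.type_distribution(self._calls({ft.TRF3: 7}))
        assert dist.overall[ft.TRF3] == 1.0
        assert dist.overall.drop(ft.TRF3).sum() == 0.0

    def test_weighted_proportions(self):
        # 219 + 507 + 274 reads: the tRF-5 share is 21.9%
        import pandas as pd
        calls = self._calls({ft.TRF5: 1, ft.TRF3: 1, ft.ITRF: 1})
        weights = pd.Series({f"{ft.TRF5}:0": 219, f"{ft.TRF3}:0": 507,
                             f"{ft.ITRF}:0": 274})
        dist = ft.type_distribution(calls, weights=weights)
        assert dist.overall[ft.TRF5] == pytest.approx(0.219)
        assert dist.overall[ft.TRF3] == pytest.approx(0.507)

    def test_fractions_sum_to_one(self, refs, small_config):
        reads, _ = sim.simulate_reads(refs, small_config)
        calls, _ = ft.classify_reads(reads, refs)
        dist = ft.type_distribution(calls)
        assert dist.overall.sum() == pytest.approx(1.0, abs=1e-9)
        assert dist.per_ref.sum(axis=1).tolist() == pytest.approx(
            [1.0] * len(dist.per_ref), abs=1e-9)

    def test_empty_input_is_error(self):
        import pandas as pd
        with pytest.raises(ValueError):
            ft.type_distribution(pd.DataFrame(columns=["fragment_class"]))
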