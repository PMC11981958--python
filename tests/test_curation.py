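import numpy as np
import pandas as pd
import pytest

from ednariver.curation import (
    ASVTable,
    cluster_d1,
    dereplicate,
    filter_asvs,
    identity_matrix,
    lulu_curate,
    replicate_filter,
)
from ednariver.io_formats import RunConfig, SequenceRecord


def _table(rows: dict, seqs: dict) -> ASVTable:
    return ASVTable(
        pd.DataFrame(rows).T,
        {k: SequenceRecord(k, v) for k, v in seqs.items()},
    )


class TestDereplicate:
    def test_identical_reads_collapse(self):
        rec = SequenceRecord("r", "ACGTACGT")
        t = dereplicate([(rec, "S1_r1", 1)] * 3)
        assert len(t.asv_ids) == 1
        assert t.grand_total == 3

    def test_distinct_sequences_stay_separate(self):
        t = dereplicate(
            [
                (SequenceRecord("x", "ACGTACGT"), "S1_r1", 2),
                (SequenceRecord("y", "TTTTACGT"), "S1_r1", 1),
            ]
        )
        assert len(t.asv_ids) == 2

    def test_same_sequence_across_replicates(self):
        rec = SequenceRecord("r", "ACGTACGT")
        t = dereplicate([(rec, "S1_r1", 4), (rec, "S1_r2", 6)])
        assert len(t.asv_ids) == 1
        assert sorted(t.counts.iloc[0].tolist()) == [4, 6]

    def test_ids_ordered_by_abundance(self):
        t = dereplicate(
            [
                (SequenceRecord("x", "AAAA"), "S1_r1", 1),
                (SequenceRecord("y", "TTTT"), "S1_r1", 9),
            ]
        )
        assert t.sequences[t.asv_ids[0]].seq == "TTTT"


class TestClusterD1:
    def test_distance_one_merges_into_most_abundant(self):
        t = _table(
            {"a": {"S1_r1": 10, "S1_r2": 0}, "b": {"S1_r1": 2, "S1_r2": 0}},
            {"a": "AAAA", "b": "AAAT"},
        )
        out = cluster_d1(t)
        assert out.asv_ids == ["a"]
        assert out.total_reads()["a"] == 12

    def test_distant_sequences_stay_separate(self):
        t = _table(
            {"a": {"S1_r1": 10}, "b": {"S1_r1": 2}}, {"a": "AAAA", "b": "TTTT"}
        )
        assert len(cluster_d1(t).asv_ids) == 2

    def test_single_linkage_chains_transitively(self):
        t = _table(
            {"a": {"S1_r1": 10}, "b": {"S1_r1": 3}, "c": {"S1_r1": 1}},
            {"a": "AAAA", "b": "AAAT", "c": "AATT"},
        )
        out = cluster_d1(t)
        assert out.asv_ids == ["a"]
        assert out.total_reads()["a"] == 14

    def test_single_indel_counts_as_one_edit(self):
        t = _table(
            {"a": {"S1_r1": 10}, "b": {"S1_r1": 1}},
            {"a": "ACGTACGT", "b": "ACGACGT"},
        )
        assert len(cluster_d1(t).asv_ids) == 1

    def test_read_conservation(self, rng):
        n = 30
        seqs = {}
        counts = {}
        for i in range(n):
            seqs[f"v{i:02d}"] = "".join(rng.choice(list("ACGT"), size=25))
            counts[f"v{i:02d}"] = {
                "S1_r1": int(rng.integers(0, 50)),
                "S2_r1": int(rng.integers(0, 50)),
            }
        t = _table(counts, seqs)
        assert cluster_d1(t).grand_total == t.grand_total


class TestFilterASVs:
    def _mk(self, reads, length, n_pad_reads=0):
        rows = {"x": {"S1_r1": reads}}
        seqs = {"x": "A" * length}
        if n_pad_reads:
            rows["pad"] = {"S1_r1": n_pad_reads}
            seqs["pad"] = "C" * 170
        return _table(rows, seqs)

    def test_low_read_asv_removed(self):
        t = self._mk(reads=9, length=170)
        assert filter_asvs(t, lambda a: True).asv_ids == []

    def test_passing_asv_retained(self):
        t = self._mk(reads=5000, length=170)
        out = filter_asvs(t, lambda a: True)
        assert out.asv_ids == ["x"]

    @pytest.mark.parametrize("length,kept", [(159, False), (160, True), (200, True), (201, False), (210, False)])
    def test_length_bounds(self, length, kept):
        t = self._mk(reads=100, length=length)
        assert (filter_asvs(t, lambda a: True).asv_ids == ["x"]) is kept

    def test_non_fish_removed(self):
        t = self._mk(reads=100, length=170)
        assert filter_asvs(t, lambda a: False).asv_ids == []

    def test_frequency_uses_prefilter_denominator(self):
        # x has freq 50/100050 < 0.001 over the pre-filter total
        t = self._mk(reads=50, length=170, n_pad_reads=100000)
        out = filter_asvs(t, lambda a: True)
        assert "x" not in out.asv_ids and "pad" in out.asv_ids

    def test_row_order_invariance(self, rng):
        rows = {f"v{i}": {"S1_r1": int(rng.integers(0, 4000))} for i in range(12)}
        seqs = {k: "".join(rng.choice(list("ACGT"), size=170)) for k in rows}
        t1 = _table(rows, seqs)
        shuffled = list(rows)[::-1]
        t2 = ASVTable(t1.counts.loc[shuffled], t1.sequences)
        out1 = filter_asvs(t1, lambda a: True)
        out2 = filter_asvs(t2, lambda a: True)
        assert set(out1.asv_ids) == set(out2.asv_ids)


class TestLulu:
    def _pair_table(self, d_counts, p_counts):
        rows = {"parent": p_counts, "daughter": d_counts}
        seqs = {"parent": "A" * 99 + "C", "daughter": "A" * 100}  # identity 0.99
        return _table(rows, seqs)

    def _ident(self, v):
        return pd.DataFrame(
            [[1.0, v], [v, 1.0]], index=["parent", "daughter"], columns=["parent", "daughter"]
        )

    def test_textbook_daughter_merged(self):
        t = self._pair_table(
            d_counts={"S1_r1": 10, "S2_r1": 0},
            p_counts={"S1_r1": 100, "S2_r1": 80},
        )
        out = lulu_curate(t, self._ident(0.99))
        assert out.asv_ids == ["parent"]
        assert out.grand_total == t.grand_total

    def test_low_identity_pair_kept(self):
        t = self._pair_table(
            d_counts={"S1_r1": 10, "S2_r1": 0},
            p_counts={"S1_r1": 100, "S2_r1": 80},
        )
        out = lulu_curate(t, self._ident(0.80))
        assert set(out.asv_ids) == {"parent", "daughter"}

    def test_cooccurrence_rule_protects_daughter(self):
        # daughter present where parent is absent → co-occurrence 0.5 < 0.95
        t = self._pair_table(
            d_counts={"S1_r1": 10, "S2_r1": 10},
            p_counts={"S1_r1": 100, "S2_r1": 0},
        )
        out = lulu_curate(t, self._ident(0.99))
        assert set(out.asv_ids) == {"parent", "daughter"}

    def test_ratio_rule_protects_locally_dominant(self):
        # daughter out-numbers parent in one shared site
        t = self._pair_table(
            d_counts={"S1_r1": 10, "S2_r1": 50},
            p_counts={"S1_r1": 100, "S2_r1": 20},
        )
        out = lulu_curate(t, self._ident(0.99))
        assert set(out.asv_ids) == {"parent", "daughter"}

    def test_input_order_invariance(self):
        t1 = self._pair_table(
            d_counts={"S1_r1": 10, "S2_r1": 0},
            p_counts={"S1_r1": 100, "S2_r1": 80},
        )
        t2 = ASVTable(t1.counts.loc[["daughter", "parent"]], t1.sequences)
        out1 = lulu_curate(t1, self._ident(0.99))
        out2 = lulu_curate(t2, self._ident(0.99))
        assert set(out1.asv_ids) == set(out2.asv_ids)


class TestReplicateFilter:
    @pytest.mark.parametrize(
        "counts,expected", [((5, 3, 0), 1), ((7, 0, 0), 0), ((0, 0, 0), 0), ((1, 1, 1), 1)]
    )
    def test_two_of_three_rule(self, counts, expected):
        t = _table(
            {"a": {f"S1_r{i + 1}": c for i, c in enumerate(counts)}},
            {"a": "ACGT"},
        )
        inc = replicate_filter(t)
        assert inc.loc["S1", "a"] == expected

    def test_single_replicate_site_raises(self):
        t = _table({"a": {"S1_r1": 5}}, {"a": "ACGT"})
        with pytest.raises(ValueError, match="replicate"):
            replicate_filter(t)


class TestPlantedErrorRecovery:
    def test_curation_recovers_planted_truth(self, small_bundle):
        """d=1 clustering + LULU remove every planted daughter and keep every
        true variant, reproducing the true incidence exactly."""
        from ednariver.curation import curate

        cfg, sim = small_bundle
        b = sim["asv"]
        assert len(b.truth["daughters"]) > 0
        table = ASVTable(b.counts, b.sequences)
        incidence, curated = curate(table, lambda a: True, RunConfig())
        assert set(curated.asv_ids) == set(b.truth["asv_ids"])
        truth = b.true_incidence
        assert incidence.loc[truth.index, truth.columns].equals(truth)
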