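import pytest
from hypothesis import given, settings, strategies as st

from paleofv.io import TabularHit
from paleofv.scaffolds import (
    ScaffoldRecord, busco_envelope, classify_scaffold, gc_content,
    majority_vote_taxonomy, te_intervals,
)


def te_hit(start, end, evalue=1e-20, length=150):
    return TabularHit(
        qseqid="s|c1", sseqid="TE|gypsy", pident=80.0, length=length,
        mismatch=0, gapopen=0, start=start, end=end, strand="+",
        sstart=1, send=length, evalue=evalue, bitscore=100.0,
    )


def record(gc=0.35, coverage=30.0, is_busco=False, sid="s|c1"):
    return ScaffoldRecord(id=sid, length=5000, gc=gc, coverage=coverage, is_busco=is_busco)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATAT", 0.0),
        ("GCGC", 1.0),
        ("ACGTN", 0.5),          # N excluded from numerator and denominator
        ("acgt", 0.5),
    ])
    def test_known_fractions(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_ambiguous_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            gc_content("NNNNRYK")


class TestBuscoEnvelope:
    def test_hand_computed_median_and_mad(self):
        # GC values 0.30..0.38: median 0.34, MAD 0.02 -> k=5 gives +/-0.10
        records = [record(gc=g, sid=f"s|c{i}") for i, g in
                   enumerate([0.30, 0.32, 0.34, 0.36, 0.38])]
        env = busco_envelope(records, k=5.0)
        assert env.gc_low == pytest.approx(0.24)
        assert env.gc_high == pytest.approx(0.44)

    def test_zero_mad_degenerates_to_a_point(self):
        records = [record(gc=0.35, sid=f"s|c{i}") for i in range(5)]
        env = busco_envelope(records)
        assert env.gc_low == env.gc_high == pytest.approx(0.35)
        assert env.gc_ok(0.35) and not env.gc_ok(0.36)

    def test_too_few_reference_scaffolds(self):
        with pytest.raises(ValueError, match=">=5"):
            busco_envelope([record()] * 4)

    def test_zero_coverage_outside_positive_envelope(self):
        records = [record(coverage=c, sid=f"s|c{i}") for i, c in
                   enumerate([28, 29, 30, 31, 32])]
        assert not busco_envelope(records).coverage_ok(0.0)


class TestMajorityVote:
    @pytest.mark.parametrize("labels,expected", [
        (["Insecta", "Insecta", "Viruses"], "Insecta"),
        (["Insecta", "Viruses"], "unassigned"),      # tie -> conservative
        ([], "unassigned"),
        (["a", "a", "b", "b", "c"], "unassigned"),   # plurality is not majority
    ])
    def test_strict_majority_rule(self, labels, expected):
        assert majority_vote_taxonomy(labels) == expected

    @given(st.lists(st.sampled_from(["Insecta", "Viruses", "Bacteria"]), max_size=12))
    @settings(max_examples=100, derandomize=True)
    def test_permutation_invariance(self, labels):
        assert majority_vote_taxonomy(labels) == majority_vote_taxonomy(labels[::-1])
        assert majority_vote_taxonomy(labels) == majority_vote_taxonomy(sorted(labels))


class TestTeIntervals:
    def test_overlapping_hits_merge(self):
        hits = [te_hit(100, 400, evalue=1e-20, length=120),
                te_hit(350, 700, evalue=1e-15, length=150)]
        assert te_intervals(hits) == [(100, 700)]

    def test_boundary_filters_are_strict(self):
        assert te_intervals([te_hit(0, 300, length=100)]) == []       # length > 100 required
        assert te_intervals([te_hit(0, 300, evalue=1e-10)]) == []     # e < 1e-10 required

    def test_book_ended_intervals_merge(self):
        assert te_intervals([te_hit(0, 300), te_hit(300, 600)]) == [(0, 600)]

    @given(st.lists(
        st.tuples(st.integers(0, 60), st.integers(1, 30)), max_size=10,
    ))
    @settings(max_examples=150, derandomize=True)
    def test_matches_base_set_union_oracle(self, raw):
        hits = [te_hit(s, s + w) for s, w in raw]
        merged = te_intervals(hits)
        covered = set()
        for s, w in raw:
            covered |= set(range(s, s + w))
        from_merged = set()
        for a, b in merged:
            assert a < b
            from_merged |= set(range(a, b))
        assert from_merged == covered
        # disjoint and sorted, with no mergeable adjacency left
        for (a1, b1), (a2, b2) in zip(merged, merged[1:]):
            assert b1 < a2


class TestClassifyScaffold:
    @pytest.fixture()
    def envelope(self):
        return busco_envelope(
            [record(gc=g, coverage=c, sid=f"s|b{i}") for i, (g, c) in
             enumerate([(0.33, 28), (0.34, 29), (0.35, 30), (0.36, 31), (0.37, 32)])]
        )

    def test_envelope_similarity_alone_is_evidence(self, envelope):
        ev = classify_scaffold(record(gc=0.35, coverage=30), envelope)
        assert ev.verdict == "endogenized"

    def test_far_outside_envelope_without_genes_is_exogenous(self, envelope):
        ev = classify_scaffold(record(gc=0.70, coverage=300), envelope)
        assert ev.verdict == "likely_exogenous"

    def test_one_metric_out_is_ambiguous(self, envelope):
        ev = classify_scaffold(record(gc=0.35, coverage=300), envelope)
        assert ev.verdict == "ambiguous"

    def test_eukaryotic_gene_rescues_outlier_scaffold(self, envelope):
        ev = classify_scaffold(record(gc=0.70, coverage=300), envelope,
                               gene_labels=["Insecta"])
        assert ev.verdict == "endogenized" and ev.n_eukaryotic_genes == 1

    def test_te_interval_rescues_outlier_scaffold(self, envelope):
        ev = classify_scaffold(record(gc=0.70, coverage=300), envelope,
                               te_hits=[te_hit(0, 400)])
        assert ev.verdict == "endogenized" and ev.n_te_intervals == 1

    def test_adding_eukaryotic_genes_is_monotone(self, envelope):
        # once endogenized, extra eukaryotic labels can never downgrade it
        for base_labels in ([], ["Viruses"], ["Insecta"]):
            before = classify_scaffold(record(), envelope, gene_labels=base_labels)
            after = classify_scaffold(record(), envelope,
                                      gene_labels=base_labels + ["Insecta"])
            if before.verdict == "endogenized":
                assert after.verdict == "endogenized"
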