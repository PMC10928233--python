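"""MMRDness scoring: CIGAR tabulation, length table, score arithmetic, call."""

import math
from collections import Counter

import pysam
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mmrdkit.logic_score import (
    LocusLengthTable,
    LocusObservation,
    build_length_table,
    classify_mmrd,
    mmrdness_score,
    observe_loci,
)
from mmrdkit.ms_catalog import LocusCatalog, MicrosatelliteLocus, filter_by_length, scan_reference
from mmrdkit.sim import SimConfig, sam_header, simulate_locus_reads, simulate_reference


def _make_read(header, contig, start, cigar, seq, name="r"):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = header.get_tid(contig)
    a.reference_start = start
    a.mapping_quality = 60
    a.flag = 0
    a.cigarstring = cigar
    a.query_sequence = seq
    return a


@pytest.fixture
def hand_built_locus():
    # 12-A run at [5, 17) inside a 30-bp contig
    seq = "CGTGC" + "A" * 12 + "GTCCGTACGGTCC"
    ref = {"c1": seq}
    locus = MicrosatelliteLocus("c1", 5, 17, "A")
    return ref, LocusCatalog(loci=[locus]), locus


class TestObserveLoci:
    def test_one_bp_deletion_mid_run_detected(self, hand_built_locus, write_sam_file):
        ref, catalog, locus = hand_built_locus
        header = sam_header(ref)
        seq = ref["c1"]
        read = _make_read(header, "c1", 0, "10M1D19M", seq[:10] + seq[11:])
        path = write_sam_file([read])
        [obs] = observe_loci(path, catalog)
        assert (obs.reads_total, obs.reads_del1, obs.deleted) == (1, 1, True)

    def test_match_only_read_not_deleted(self, hand_built_locus, write_sam_file):
        ref, catalog, _ = hand_built_locus
        header = sam_header(ref)
        read = _make_read(header, "c1", 0, "30M", ref["c1"])
        path = write_sam_file([read])
        [obs] = observe_loci(path, catalog)
        assert (obs.reads_total, obs.reads_del1, obs.deleted) == (1, 0, False)

    def test_two_bp_deletion_does_not_count(self, hand_built_locus, write_sam_file):
        ref, catalog, _ = hand_built_locus
        header = sam_header(ref)
        seq = ref["c1"]
        read = _make_read(header, "c1", 0, "10M2D18M", seq[:10] + seq[12:])
        path = write_sam_file([read])
        [obs] = observe_loci(path, catalog)
        assert (obs.reads_del1, obs.deleted) == (0, False)

    def test_deletion_outside_run_does_not_count(self, hand_built_locus, write_sam_file):
        ref, catalog, _ = hand_built_locus
        header = sam_header(ref)
        seq = ref["c1"]
        read = _make_read(header, "c1", 0, "20M1D9M", seq[:20] + seq[21:])
        path = write_sam_file([read])
        [obs] = observe_loci(path, catalog)
        assert (obs.reads_del1, obs.deleted) == (0, False)

    def test_non_spanning_read_excluded(self, hand_built_locus, write_sam_file):
        ref, catalog, locus = hand_built_locus
        header = sam_header(ref)
        # starts inside the run: no left flank
        read = _make_read(header, "c1", locus.start, "20M", ref["c1"][locus.start:locus.start + 20])
        path = write_sam_file([read])
        assert observe_loci(path, catalog) == []

    def test_zero_slippage_simulation_clean(self, write_sam_file):
        cfg = SimConfig(seed=1, slippage_del_rate=0.0, coverage=2.0)
        ref, truth = simulate_reference(cfg)
        path = write_sam_file(simulate_locus_reads(truth, cfg, ref))
        obs = observe_loci(path, filter_by_length(scan_reference(ref)))
        assert obs and all(o.reads_del1 == 0 for o in obs)

    def test_missing_contig_warns(self, hand_built_locus, write_sam_file):
        ref, catalog, _ = hand_built_locus
        header = sam_header(ref)
        read = _make_read(header, "c1", 0, "30M", ref["c1"])
        path = write_sam_file([read])
        other = LocusCatalog(loci=[MicrosatelliteLocus("cX", 5, 17, "A")])
        with pytest.warns(UserWarning, match="absent"):
            assert observe_loci(path, other) == []

    def test_rate_recovery_single_read_loci(self, write_sam_file):
        # binomial oracle on loci covered by exactly one read
        rate = 0.15
        cfg = SimConfig(
            seed=12,
            slippage_del_rate=rate,
            coverage=1.0,
            locus_count_per_length={L: 400 for L in range(10, 16)},
            genome_length=110_000,
        )
        ref, truth = simulate_reference(cfg)
        path = write_sam_file(simulate_locus_reads(truth, cfg, ref))
        obs = observe_loci(path, filter_by_length(scan_reference(ref)))
        singles = [o for o in obs if o.reads_total == 1]
        frac = sum(o.deleted for o in singles) / len(singles)
        se = math.sqrt(rate * (1 - rate) / len(singles))
        assert abs(frac - rate) <= 3 * se


class TestBuildLengthTable:
    def test_uniform_fractions(self):
        obs = []
        pos = 0
        for L in range(10, 16):
            for i in range(10):
                loc = MicrosatelliteLocus("c", pos, pos + L, "A")
                pos += L + 5
                obs.append(LocusObservation(loc, 1, 1 if i < 2 else 0, i < 2))
        table = build_length_table(obs)
        assert all(table.n_del[L] / table.n_loci[L] == 0.2 for L in range(10, 16))

    def test_empty(self):
        table = build_length_table([])
        assert table.n_loci == {} and table.n_del == {}

    @given(
        st.lists(
            st.tuples(st.integers(10, 15), st.booleans()), min_size=1, max_size=300
        )
    )
    def test_equals_brute_force_groupby(self, rows):
        obs, pos = [], 0
        for L, deleted in rows:
            loc = MicrosatelliteLocus("c", pos, pos + L, "A")
            pos += L + 5
            obs.append(LocusObservation(loc, 1, int(deleted), deleted))
        table = build_length_table(obs)
        assert table.n_loci == dict(Counter(L for L, _ in rows))
        assert table.n_del == {
            L: n for L, n in Counter(L for L, d in rows if d).items()
        }


class TestMMRDnessScore:
    def test_threshold_point_scores_zero(self):
        f = 10 ** (-1.1)
        n = 100_000
        table = LocusLengthTable(
            n_loci={L: n for L in range(10, 16)},
            n_del={L: round(f * n) for L in range(10, 16)},
        )
        res = mmrdness_score(table)
        assert res.score == pytest.approx(0.0, abs=1e-4)

    def test_fraction_point_one_closed_form(self):
        table = LocusLengthTable(
            n_loci={L: 10 for L in range(10, 16)},
            n_del={L: 1 for L in range(10, 16)},
        )
        res = mmrdness_score(table)
        assert res.score == pytest.approx(math.log10(0.1) + 1.1)
        assert res.call == "MMRD"

    def test_hand_computed_mixed_table(self):
        # frozen independently: log10(mean([.03,.05,.08,.12,.15,.20])) + 1.1
        table = LocusLengthTable(
            n_loci={L: 100 for L in range(10, 16)},
            n_del=dict(zip(range(10, 16), [3, 5, 8, 12, 15, 20])),
        )
        res = mmrdness_score(table)
        assert res.score == pytest.approx(0.12118929906993825, abs=1e-12)

    def test_empty_bins_excluded_and_recorded(self):
        table = LocusLengthTable(n_loci={10: 100, 11: 0}, n_del={10: 10})
        res = mmrdness_score(table)
        assert res.provenance["excluded_empty_bins"] == [11]
        assert res.mean_fraction == 0.1

    def test_all_bins_empty_errors(self):
        with pytest.raises(ValueError):
            mmrdness_score(LocusLengthTable(n_loci={10: 0}, n_del={}))

    def test_zero_deletions_sentinel(self):
        table = LocusLengthTable(n_loci={L: 50 for L in range(10, 16)}, n_del={})
        res = mmrdness_score(table)
        assert res.score == -math.inf
        assert res.call == "MMR-proficient"
        assert res.provenance["zero_mean_fraction"]

    def test_pseudocount_avoids_sentinel(self):
        table = LocusLengthTable(n_loci={L: 50 for L in range(10, 16)}, n_del={})
        res = mmrdness_score(table, pseudocount=0.5)
        assert math.isfinite(res.score)

    @given(
        st.dictionaries(
            st.integers(10, 15),
            st.tuples(st.integers(1, 1000), st.floats(0, 1)),
            min_size=1,
        )
    )
    def test_offset_identity(self, bins):
        from hypothesis import assume

        n_del = {L: int(n * f) for L, (n, f) in bins.items()}
        assume(any(d > 0 for d in n_del.values()))  # finite score only
        table = LocusLengthTable(
            n_loci={L: n for L, (n, _) in bins.items()}, n_del=n_del
        )
        res = mmrdness_score(table, offset=1.1)
        assert res.score - res.raw_score == pytest.approx(1.1)

    def test_monotone_in_deletions(self):
        base = dict(zip(range(10, 16), [3, 5, 8, 12, 15, 20]))
        n_loci = {L: 100 for L in range(10, 16)}
        ref_score = mmrdness_score(LocusLengthTable(n_loci, base)).score
        for L in range(10, 16):
            bumped = dict(base)
            bumped[L] += 1
            assert mmrdness_score(LocusLengthTable(n_loci, bumped)).score >= ref_score

    def test_scale_invariance(self):
        n_loci = {L: 100 for L in range(10, 16)}
        n_del = dict(zip(range(10, 16), [3, 5, 8, 12, 15, 20]))
        a = mmrdness_score(LocusLengthTable(n_loci, n_del)).score
        b = mmrdness_score(
            LocusLengthTable(
                {L: 7 * n for L, n in n_loci.items()},
                {L: 7 * n for L, n in n_del.items()},
            )
        ).score
        assert a == pytest.approx(b)


class TestClassify:
    @pytest.mark.parametrize(
        "score,label",
        [(0.3, "MMRD"), (-0.5, "MMR-proficient"), (0.0, "MMR-proficient")],
    )
    def test_sign_rule(self, score, label):
        assert classify_mmrd(score) == label


@pytest.mark.parametrize("seed", range(5))
def test_end_to_end_separates_deficient_from_proficient(seed, write_sam_file):
    counts = {L: 60 for L in range(10, 16)}
    for rate, positive in [(0.20, True), (0.01, False)]:
        cfg = SimConfig(
            seed=seed, slippage_del_rate=rate,
            locus_count_per_length=counts, genome_length=20_000,
        )
        ref, truth = simulate_reference(cfg)
        path = write_sam_file(simulate_locus_reads(truth, cfg, ref), f"{seed}_{rate}.sam")
        obs = observe_loci(path, filter_by_length(scan_reference(ref)))
        res = mmrdness_score(build_length_table(obs))
        assert (res.score > 0) == positive
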