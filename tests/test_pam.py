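import itertools
import json
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamscreen import (
    ConsensusParams,
    build_wheel,
    call_consensus,
    classify_table,
    collect_pams,
    compare_profiles,
    export_logo_matrix,
    export_wheel,
    information_content,
    load_wheel,
    pam_coverage_stats,
    parse_stream,
    profile,
    trim_trailing_n,
)
from pamscreen.simulate import random_dna

NO_CORRECTION = ConsensusParams(apply_correction=False)


def _column_profile(freqs, n=1000):
    """Single-position profile with exact counts n * freqs."""
    counts = np.array([[int(round(f * n)) for f in freqs]])
    return profile(
        [b for b, c in zip("ACGT", counts[0]) for _ in range(c)]
    )


@pytest.fixture(scope="module")
def screen_tables(sorted_screen):
    parsed, stats = parse_stream(sorted_screen["fastq"], sorted_screen["design"])
    calls = classify_table(parsed, sorted_screen["design"])
    return parsed, calls, stats


class TestCollectPams:
    def test_inframe_filter(self, screen_tables):
        parsed, calls, _ = screen_tables
        pams = collect_pams(parsed, calls, which="inframe_only")
        assert len(pams) == (calls["status"] == "inframe").sum()
        any_indel = collect_pams(parsed, calls, which="any_indel")
        assert len(any_indel) == calls["status"].isin(["inframe", "frameshift"]).sum()

    def test_collected_pams_match_simulation_truth(self, design, tmp_path):
        # error-free sorted run: the collected multiset must equal the truth
        # PAMs of the parseable frame-restored reads exactly
        from pamscreen import (
            ErrorModel,
            IndelModel,
            PAMActivityModel,
            SimConfig,
            simulate_screen,
            write_fastq,
        )

        records, truth = simulate_screen(
            design,
            PAMActivityModel(kind="consensus", consensus="N" * 8, p_match=0.4, p_mismatch=0.4),
            IndelModel(),
            ErrorModel(sub_rate=0.0),
            SimConfig(n_reads=4_000, seed=19, sort_mode="gfp_sorted"),
        )
        fastq = tmp_path / "clean_sorted.fastq"
        write_fastq(records, fastq)
        parsed, _ = parse_stream(fastq, design)
        calls = classify_table(parsed, design)
        pams = collect_pams(parsed, calls)
        truth_pams = Counter(
            truth.set_index("read_id").loc[
                parsed[parsed["status"] == "ok"]["read_id"], "pam"
            ]
        )
        assert Counter(pams) == truth_pams

    def test_empty_selection_is_allowed(self, screen_tables):
        parsed, calls, _ = screen_tables
        no_edits = calls.copy()
        no_edits["status"] = "unedited"
        assert collect_pams(parsed, no_edits) == []

    def test_join_mismatch_is_an_error(self, screen_tables):
        parsed, calls, _ = screen_tables
        with pytest.raises(ValueError, match="join"):
            collect_pams(parsed, calls.iloc[:-2])

    def test_min_count_floor(self):
        parsed_pams = ["AA", "AA", "AC"]
        import pandas as pd

        parsed = pd.DataFrame(
            {
                "read_id": ["r1", "r2", "r3"],
                "status": "ok",
                "orientation": "forward",
                "target_region": "ACG",
                "pam": parsed_pams,
            }
        )
        calls = pd.DataFrame({"read_id": ["r1", "r2", "r3"], "status": "inframe"})
        assert collect_pams(parsed, calls, min_count=2) == ["AA", "AA"]


class TestProfile:
    def test_small_example_counts(self):
        prof = profile(["AC", "AG"])
        assert prof.n == 2
        assert prof.frequency(1, "A") == 1.0
        assert prof.frequency(2, "C") == 0.5
        assert prof.frequency(2, "G") == 0.5

    def test_empty_profile(self):
        prof = profile([])
        assert prof.n == 0
        with pytest.raises(ValueError):
            _ = prof.frequencies

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            profile(["AC", "ACG"])

    def test_column_sums_equal_n(self, screen_tables, sorted_screen):
        parsed, calls, _ = screen_tables
        prof = profile(collect_pams(parsed, calls))
        assert (prof.counts.sum(axis=1) == prof.n).all()

    def test_uniform_random_frequencies(self):
        rng = np.random.default_rng(3)
        prof = profile([random_dna(rng, 8) for _ in range(10_000)])
        sd = math.sqrt(0.25 * 0.75 / 10_000)
        assert np.abs(prof.frequencies - 0.25).max() <= 3 * sd


class TestInformationContent:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((1.0, 0.0, 0.0, 0.0), 2.0),
            ((0.25, 0.25, 0.25, 0.25), 0.0),
            ((0.5, 0.5, 0.0, 0.0), 1.0),
        ],
    )
    def test_closed_forms_without_correction(self, freqs, expected):
        prof = _column_profile(freqs)
        ic, _ = information_content(prof, NO_CORRECTION)
        assert ic[0] == pytest.approx(expected, abs=1e-12)

    def test_small_sample_correction_arithmetic(self):
        prof = _column_profile((1.0, 0, 0, 0), n=100)
        ic_corr, _ = information_content(prof, ConsensusParams(apply_correction=True))
        assert ic_corr[0] == pytest.approx(2.0 - 3.0 / (2.0 * math.log(2) * 100))

    def test_heights_sum_to_ic(self):
        prof = _column_profile((0.6, 0.2, 0.15, 0.05))
        ic, heights = information_content(prof, NO_CORRECTION)
        assert heights.sum(axis=1) == pytest.approx(ic)

    def test_empty_profile_is_an_error(self):
        with pytest.raises(ValueError):
            information_content(profile([]))

    @settings(max_examples=200, derandomize=True)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=500), min_size=4, max_size=4)
    )
    def test_bounded_between_zero_and_two(self, counts):
        if sum(counts) == 0:
            counts[0] = 1
        pams = [b for b, c in zip("ACGT", counts) for _ in range(c)]
        ic, _ = information_content(profile(pams))
        assert 0.0 <= ic[0] <= 2.0

    def test_monotone_towards_uniformity(self):
        # interpolate a sharp column towards uniform; IC must decrease
        sharp = np.array([1.0, 0.0, 0.0, 0.0])
        uniform = np.full(4, 0.25)
        previous = 2.1
        for t in np.linspace(0.0, 1.0, 9):
            freqs = (1 - t) * sharp + t * uniform
            ic, _ = information_content(_column_profile(freqs, n=4000), NO_CORRECTION)
            assert ic[0] < previous + 1e-9
            previous = ic[0]


class TestCallConsensus:
    def test_dinucleotide_cc_pattern(self):
        rng = np.random.default_rng(4)
        pams = [
            random_dna(rng, 4) + ("CC" if rng.random() < 0.95 else random_dna(rng, 2)) + random_dna(rng, 2)
            for _ in range(5000)
        ]
        consensus = call_consensus(profile(pams))
        assert consensus == "NNNNCCNN"
        assert trim_trailing_n(consensus) == "NNNNCC"

    def test_gatt_pattern(self):
        rng = np.random.default_rng(5)
        pams = [random_dna(rng, 4) + "GATT" for _ in range(2000)]
        assert call_consensus(profile(pams)) == "NNNNGATT"

    def test_two_base_position_gets_degenerate_symbol(self):
        rng = np.random.default_rng(6)
        pams = []
        for _ in range(4000):
            base5 = "A" if rng.random() < 0.5 / 0.95 else "G"
            if rng.random() < 0.05:
                base5 = random_dna(rng, 1)
            pams.append(random_dna(rng, 4) + base5 + random_dna(rng, 3))
        consensus = call_consensus(profile(pams))
        assert consensus[4] == "R"

    def test_uniform_profile_is_all_n(self):
        pams = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
        assert call_consensus(profile(pams)) == "NNNN"
        assert trim_trailing_n("NNNN") == "NNNN"

    def test_empty_profile_is_an_error(self):
        with pytest.raises(ValueError):
            call_consensus(profile([]))


class TestCoverageStats:
    def test_worked_example(self):
        assert pam_coverage_stats(["AA", "AA", "AC", "AG"]) == (3, 1.0)

    def test_empty_list(self):
        n_unique, median = pam_coverage_stats([])
        assert n_unique == 0 and median is None

    def test_matches_plain_hash_count_oracle(self, sorted_screen):
        pams = list(sorted_screen["truth"]["pam"])
        counts = Counter(pams)
        n_unique, median = pam_coverage_stats(pams)
        assert n_unique == len(counts)
        assert median == float(np.median(sorted(counts.values())))


class TestPamWheel:
    def test_two_pams(self):
        root = build_wheel(["AAAAAAAA", "CCCCCCCC"])
        assert root.count == 2
        assert sorted(c.base for c in root.children) == ["A", "C"]
        assert all(c.count == 1 for c in root.children)

    def test_child_counts_sum_to_parent_everywhere(self, sorted_screen):
        root = build_wheel(list(sorted_screen["truth"]["pam"]))
        stack = [root]
        while stack:
            node = stack.pop()
            if node.children:
                assert sum(c.count for c in node.children) == node.count
            stack.extend(node.children)

    def test_uniform_root_children_balanced(self):
        rng = np.random.default_rng(8)
        root = build_wheel([random_dna(rng, 8) for _ in range(1000)])
        sd = math.sqrt(1000 * 0.25 * 0.75)
        for child in root.children:
            assert abs(child.count - 250) <= 3 * sd

    def test_first_ring_equals_profile_first_column(self, sorted_screen):
        pams = list(sorted_screen["truth"]["pam"])
        prof = profile(pams)
        root = build_wheel(pams)
        for child in root.children:
            base_idx = "ACGT".index(child.base)
            assert child.count == prof.counts[0, base_idx]

    def test_position_order_permutes_tree(self):
        pams = ["AC", "AG", "TG"]
        root = build_wheel(pams, position_order=[2, 1])
        assert sorted(c.base for c in root.children) == ["C", "G"]

    def test_invalid_position_order_rejected(self):
        with pytest.raises(ValueError):
            build_wheel(["ACGT"], position_order=[1, 2, 3])
        with pytest.raises(ValueError):
            build_wheel(["AC"], position_order=[1, 1])

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        root = build_wheel([random_dna(rng, 5) for _ in range(200)])
        path = tmp_path / "wheel.json"
        export_wheel(root, path)
        assert load_wheel(path) == root
        data = json.loads(path.read_text())
        assert data["fraction"] == 1.0


class TestCompareProfiles:
    def test_identical_profiles_near_zero(self):
        rng = np.random.default_rng(11)
        pams = [random_dna(rng, 6) for _ in range(500)]
        enrichment = compare_profiles(profile(pams), profile(pams))
        assert np.abs(enrichment).max() == 0.0

    def test_all_c_position_against_uniform(self):
        rng = np.random.default_rng(12)
        fg = profile([random_dna(rng, 4) + "C" + random_dna(rng, 3) for _ in range(4000)])
        bg = profile([random_dna(rng, 8) for _ in range(4000)])
        enrichment = compare_profiles(fg, bg)
        assert enrichment[4, "ACGT".index("C")] == pytest.approx(2.0, abs=0.15)

    def test_antisymmetric(self):
        rng = np.random.default_rng(13)
        a = profile([random_dna(rng, 5) for _ in range(300)])
        b = profile([random_dna(rng, 5) + "" for _ in range(300)])
        assert np.allclose(compare_profiles(a, b), -compare_profiles(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_profiles(profile(["ACGT"]), profile(["ACG"]))


class TestLogoExport:
    def test_heights_sum_per_position_to_ic(self, tmp_path):
        rng = np.random.default_rng(14)
        prof = profile([random_dna(rng, 4) + "CC" for _ in range(500)])
        path = tmp_path / "logo.tsv"
        table = export_logo_matrix(prof, NO_CORRECTION, path)
        ic, _ = information_content(prof, NO_CORRECTION)
        sums = table.groupby("position")["height_bits"].sum()
        assert np.allclose(sums.values, ic)
        assert path.exists()

    def test_empty_profile_is_an_error(self):
        with pytest.raises(ValueError):
            export_logo_matrix(profile([]))
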