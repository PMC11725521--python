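"""Canonical k-mer counting and the median-count read filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from okit.io_formats import Read
from okit.kmer_filter import (
    FilterThresholds,
    build_count_table,
    canonical_kmers,
    compute_thresholds,
    filter_reads,
    read_profile,
)
from okit.synthetic import random_sequence

_RC = str.maketrans("ACGT", "TGCA")


def naive_canonical_tally(seqs, k):
    """Independent dictionary tally with string-level canonicalization."""
    tally = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) - set("ACGT"):
                continue
            rc = w.translate(_RC)[::-1]
            key = min(w, rc)
            tally[key] = tally.get(key, 0) + 1
    return tally


class TestCanonicalKmers:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("ACGTA", 3, ["ACG", "ACG", "GTA"]),
            ("AAAA", 4, ["AAAA"]),
            ("ACNGT", 3, []),  # every window contains the N
            ("AC", 3, []),  # shorter than k
        ],
    )
    def test_examples(self, seq, k, expected):
        assert canonical_kmers(seq, k) == expected

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=60), st.integers(1, 8))
    @settings(max_examples=200, deadline=None)
    def test_matches_string_canonicalization(self, seq, k):
        got = canonical_kmers(seq, k)
        want = []
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            want.append(min(w, w.translate(_RC)[::-1]))
        assert got == want


class TestCountTable:
    def test_identical_reads_accumulate(self):
        r = Read("a", "A" * 31)
        t = build_count_table([r, Read("b", r.seq)], k=31)
        assert len(t.counts) == 1 and t.total == 2

    def test_window_count(self):
        t = build_count_table([Read("a", random_sequence(40, np.random.default_rng(0)))], k=31)
        assert t.total == 10  # L - k + 1

    def test_matches_naive_oracle_on_random_reads(self, rng):
        reads = [Read(f"r{i}", random_sequence(300, rng)) for i in range(40)]
        t = build_count_table(reads, k=31)
        oracle = naive_canonical_tally([r.seq for r in reads], 31)
        assert dict(t.items_as_words()) == oracle

    def test_empty_input_error(self):
        with pytest.raises(ValueError, match="no reads"):
            build_count_table([], k=31)


class TestProfilesAndThresholds:
    def test_median_odd_even(self):
        # medians computed over per-window counts of a constructed table
        reads = [Read("x", "A" * 33)]  # 3 windows of AAA...A (same canonical kmer)
        t = build_count_table(reads, k=31)
        p = read_profile(reads[0], t)
        assert p.rmkc == 3  # each window of the same kmer counted 3 times

    def test_threshold_arithmetic(self):
        t = compute_thresholds(_profiles_with_rmkc([100, 100, 100]))
        assert (t.mkc, t.lkc, t.hkc) == (100.0, 30.0, 500.0)
        assert t.max_outlier_frac == pytest.approx(0.2)

    def test_even_median_of_rmkc(self):
        profs = _profiles_with_rmkc([10, 1000])
        assert compute_thresholds(profs).mkc == 505.0

    def test_single_profile(self):
        t = compute_thresholds(_profiles_with_rmkc([10]))
        assert (t.mkc, t.lkc, t.hkc) == (10.0, 3.0, 50.0)

    def test_no_usable_profiles_error(self):
        from okit.kmer_filter import ReadKmerProfile

        with pytest.raises(ValueError):
            compute_thresholds([ReadKmerProfile("r", 0, 0.0, 0.0, 0.0)])

    def test_outlier_fractions(self):
        # counts [1,1,1] + [50]*7 against lkc=15, hkc=250
        seq = _seq_with_kmer_counts([1, 1, 1] + [50] * 7)
        reads, probe = seq
        table = build_count_table(reads, k=31)
        prof = read_profile(probe, table, FilterThresholds(mkc=50.0, low_mult=0.3, high_mult=5.0))
        assert prof.frac_low == pytest.approx(0.3)
        assert prof.frac_high == 0.0


def _table_with_counts():
    return build_count_table([Read("t", "A" * 31)], k=31)


def _profiles_with_rmkc(values):
    from okit.kmer_filter import ReadKmerProfile

    return [ReadKmerProfile(f"r{i}", 10, float(v), 0.0, 0.0) for i, v in enumerate(values)]


def _seq_with_kmer_counts(counts):
    """Build a read set where one probe read's windows have the given counts.

    Each window of the probe is a distinct random 31-mer; copies of each
    31-mer are added as standalone reads to reach the requested count.
    """
    rng = np.random.default_rng(7)
    k = 31
    # probe made of distinct non-overlapping kmers: use a long random seq and
    # take its windows as-is (they're unique with overwhelming probability)
    probe_seq = random_sequence(k + len(counts) - 1, rng)
    support = []
    for i, c in enumerate(counts):
        w = probe_seq[i : i + k]
        support += [Read(f"s{i}_{j}", w) for j in range(c - 1)]
    probe = Read("probe", probe_seq)
    return [probe] + support, probe


class TestFilterReads:
    def _setup(self, outlier_windows, total_windows=10):
        counts = [1] * outlier_windows + [50] * (total_windows - outlier_windows)
        reads, probe = _seq_with_kmer_counts(counts)
        table = build_count_table(reads, k=31)
        th = FilterThresholds(mkc=50.0)
        return probe, table, th

    def test_three_of_ten_low_removed(self):
        probe, table, th = self._setup(3)
        kept, removed = filter_reads([probe], table, th)
        assert kept == [] and removed[0][1] == "low_kmer"

    def test_exactly_one_fifth_kept(self):
        probe, table, th = self._setup(2)
        kept, removed = filter_reads([probe], table, th)
        assert kept == [probe] and removed == []

    def test_too_short_removed(self):
        short = Read("tiny", "ACGT")
        table = build_count_table([short], k=31)
        kept, removed = filter_reads([short], table, FilterThresholds(mkc=1.0))
        assert removed[0][1] == "too_short"

    def test_partition_preserves_order_and_count(self, rng):
        reads = [Read(f"r{i}", random_sequence(100, rng)) for i in range(30)]
        table = build_count_table(reads, k=31)
        th = compute_thresholds([read_profile(r, table) for r in reads])
        kept, removed = filter_reads(reads, table, th)
        assert len(kept) + len(removed) == len(reads)
        ids = [r.id for r in kept] + [r.id for r, _ in removed]
        assert sorted(ids) == sorted(r.id for r in reads)

    def test_monotone_in_thresholds(self, rng):
        reads = [Read(f"r{i}", random_sequence(120, rng)) for i in range(40)]
        table = build_count_table(reads, k=31)
        base = FilterThresholds(mkc=3.0, low_mult=0.5, high_mult=2.0)
        loose = FilterThresholds(mkc=3.0, low_mult=0.1, high_mult=10.0)
        kept_base, _ = filter_reads(reads, table, base)
        kept_loose, _ = filter_reads(reads, table, loose)
        assert {r.id for r in kept_base} <= {r.id for r in kept_loose}

    def test_permutation_invariance(self, rng):
        reads = [Read(f"r{i}", random_sequence(150, rng)) for i in range(25)]
        table = build_count_table(reads, k=31)

        def kept_ids(order):
            th = compute_thresholds([read_profile(r, table) for r in order])
            kept, _ = filter_reads(order, table, th)
            return {r.id for r in kept}, th.mkc

        fwd = kept_ids(reads)
        rev = kept_ids(reads[::-1])
        assert fwd == rev


class TestMixtureSeparation:
    """Deep-coverage organelle + trace nuclear mixture: the filter removes
    nuclear and chimeric reads while keeping nearly all organelle reads."""

    def test_nuclear_and_chimeric_reads_removed(self):
        rng = np.random.default_rng(99)
        organelle = random_sequence(20000, rng)
        nuclear = random_sequence(60000, rng)

        def sample(src, n, L, prefix, circular=False):
            out = []
            doubled = src + src if circular else src
            for i in range(n):
                s = int(rng.integers(0, (len(src) - 1 if circular else len(src) - L) + 1))
                out.append(Read(f"{prefix}{i}", doubled[s : s + L]))
            return out

        # the organelle is circular: sampling across the origin avoids
        # artificial low-coverage edges
        organelle_reads = sample(organelle, 500, 2000, "org", circular=True)  # 50x
        nuclear_reads = sample(nuclear, 30, 2000, "nuc")  # 1x
        # NUPT-chimeric: >= 40% nuclear flank around an organelle core
        chimeric = []
        for i in range(30):
            s_o = int(rng.integers(0, len(organelle) - 1000))
            s_n = int(rng.integers(0, len(nuclear) - 1200))
            chimeric.append(
                Read(f"chi{i}", nuclear[s_n : s_n + 600] + organelle[s_o : s_o + 1000] + nuclear[s_n + 600 : s_n + 1200])
            )
        pool = organelle_reads + nuclear_reads + chimeric
        from okit.kmer_filter import build_count_table, compute_thresholds, filter_reads, read_profile

        table = build_count_table(pool, k=31)
        th = compute_thresholds([read_profile(r, table) for r in pool])
        kept, removed = filter_reads(pool, table, th)
        kept_ids = {r.id for r in kept}
        assert not any(i.startswith("nuc") for i in kept_ids)
        n_chi_removed = sum(1 for r, _ in removed if r.id.startswith("chi"))
        assert n_chi_removed >= 0.9 * len(chimeric)
        n_org_kept = sum(1 for i in kept_ids if i.startswith("org"))
        assert n_org_kept >= 0.99 * len(organelle_reads)
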