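"""NUPT/NUMT calling, substitution spectra, enrichment and summaries."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from okit.insertion_analysis import (
    MergedInsertion,
    SubstitutionRecord,
    call_substitutions,
    cytosine_context,
    enrichment_test,
    filter_hsps,
    identity_histogram,
    merge_insertions,
    remove_embedded,
    spectrum,
    summarize,
)
from okit.io_formats import Hsp, PafRecord


def hsp(sstart, send, pident=95.0, length=None, bitscore=500.0, chrom="nuc1"):
    length = length if length is not None else send - sstart
    return Hsp(
        qseqid="org", sseqid=chrom, pident=pident, length=length,
        qstart=0, qend=length, sstart=sstart, send=send,
        evalue=1e-50, bitscore=bitscore, strand="+",
    )


class TestFilterHsps:
    @pytest.mark.parametrize(
        "pident,length,kept",
        [(80.0, 500, False), (95.0, 100, False), (95.0, 101, True), (80.01, 101, True)],
    )
    def test_strict_boundaries(self, pident, length, kept):
        got = filter_hsps([hsp(0, length, pident=pident, length=length)])
        assert bool(got) is kept


class TestRemoveEmbedded:
    def test_contained_dropped(self):
        inner, outer = hsp(100, 500), hsp(50, 600)
        assert remove_embedded([inner, outer]) == [outer]

    def test_partial_overlap_kept(self):
        a, b = hsp(100, 500), hsp(400, 900)
        assert remove_embedded([a, b]) == [a, b]

    def test_shared_endpoint_still_embedded(self):
        inner, outer = hsp(100, 500), hsp(100, 600)
        assert remove_embedded([inner, outer]) == [outer]

    def test_duplicate_keeps_higher_bitscore(self):
        a, b = hsp(100, 500, bitscore=200.0), hsp(100, 500, bitscore=180.0)
        assert remove_embedded([b, a]) == [a]

    def test_union_of_bases_preserved(self, rng):
        hsps = [
            hsp(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 5000, 40), rng.integers(150, 900, 40))
        ]
        before = set()
        for h in hsps:
            before.update(range(h.sstart, h.send))
        after = set()
        for h in remove_embedded(hsps):
            after.update(range(h.sstart, h.send))
        assert before == after


class TestMergeInsertions:
    def test_overlap_merges_with_mean_identity(self):
        merged = merge_insertions([hsp(100, 300, pident=90.0), hsp(250, 400, pident=94.0)], "NUPT")
        (m,) = merged
        assert (m.start, m.end, m.mean_identity, m.n_hsps) == (100, 400, 92.0, 2)

    def test_book_ended_merge(self):
        merged = merge_insertions([hsp(100, 300), hsp(300, 450)], "NUPT")
        assert len(merged) == 1 and merged[0].end == 450

    def test_singleton_passthrough(self):
        (m,) = merge_insertions([hsp(10, 200, pident=88.5)], "NUMT")
        assert (m.start, m.end, m.mean_identity, m.source) == (10, 200, 88.5, "NUMT")

    def test_idempotent_disjoint_sorted(self, rng):
        hsps = [
            hsp(int(s), int(s) + int(l), chrom=f"c{int(c)}")
            for s, l, c in zip(
                rng.integers(0, 20000, 60), rng.integers(120, 2000, 60), rng.integers(0, 3, 60)
            )
        ]
        merged = merge_insertions(hsps, "NUPT")
        # disjoint & sorted per chromosome
        by_chrom = {}
        for m in merged:
            by_chrom.setdefault(m.chrom, []).append(m)
        for ms in by_chrom.values():
            for a, b in zip(ms, ms[1:]):
                assert a.end < b.start
        # idempotent when re-fed as singleton HSPs
        refeed = [hsp(m.start, m.end, pident=m.mean_identity, chrom=m.chrom) for m in merged]
        again = merge_insertions(refeed, "NUPT")
        assert [(m.chrom, m.start, m.end) for m in again] == [
            (m.chrom, m.start, m.end) for m in merged
        ]
        total_hsp = sum(h.send - h.sstart for h in hsps)
        assert sum(m.length for m in merged) <= total_hsp

    @pytest.mark.skipif(shutil.which("bedtools") is None, reason="bedtools unavailable")
    def test_against_bedtools_merge(self, tmp_path, rng):
        """Independent cross-check: interval union must match bedtools merge."""
        hsps = [
            hsp(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 30000, 80), rng.integers(120, 1500, 80))
        ]
        bed = tmp_path / "in.bed"
        bed.write_text(
            "".join(f"nuc1\t{h.sstart}\t{h.send}\n" for h in sorted(hsps, key=lambda h: h.sstart))
        )
        out = subprocess.run(
            ["bedtools", "merge", "-i", str(bed)], capture_output=True, text=True, check=True
        ).stdout
        expected = [
            (f[0], int(f[1]), int(f[2]))
            for f in (line.split("\t") for line in out.strip().splitlines())
        ]
        merged = merge_insertions(hsps, "NUPT")
        assert [(m.chrom, m.start, m.end) for m in merged] == expected


class TestCallSubstitutions:
    def _paf(self, cs, tstart=100, tend=110, strand="+"):
        return PafRecord(
            "q", 10, 0, 10, strand, "org", 1000, tstart, tend, 9, 10, cs=cs
        )

    def test_cs_walk_positions(self):
        org = "A" * 105 + "C" + "G" * 900
        recs = call_substitutions([self._paf(":5*ct:4")], org)
        (r,) = recs
        assert (r.organelle_pos, r.ref, r.alt) == (105, "C", "T")
        assert r.context == "CG"

    def test_minus_strand_positions_and_complement(self):
        # cs walks the revcomp target; pos maps back from tend-1
        org = "A" * 104 + "G" + "A" * 900
        recs = call_substitutions([self._paf(":5*ca:4", strand="-")], org)
        (r,) = recs
        assert r.organelle_pos == 109 - 5
        assert (r.ref, r.alt) == ("G", "T")

    def test_indels_ignored(self):
        org = "ACGT" * 300
        recs = call_substitutions([self._paf(":3+aa:2-tt:3")], org)
        assert recs == []

    def test_missing_cs_errors(self):
        with pytest.raises(ValueError, match="cs tag absent"):
            call_substitutions([self._paf(None)], "ACGT" * 10)


class TestCytosineContext:
    @pytest.mark.parametrize(
        "seq,pos,ref,expected",
        [
            ("AACGA", 2, "C", "CG"),
            ("AACAG", 2, "C", "CHG"),
            ("AACAA", 2, "C", "CHH"),
            ("AACGA", 3, "G", "CG"),  # via reverse complement
            ("ACCTG", 4, "G", "CHG"),  # rc: upstream A->T (H), then C->G
            ("TTGAG", 4, "G", "CHH"),  # rc: both upstream bases H
            ("AAC", 2, "C", "NA"),  # too close to the end
            ("GAA", 0, "G", "NA"),
            ("AATAA", 2, "T", "NA"),  # not a C:G site
        ],
    )
    def test_context_cases(self, seq, pos, ref, expected):
        assert cytosine_context(seq, pos, ref) == expected

    def test_strand_symmetry_of_cg_dyad(self):
        # CG dyad: the C on + strand and the G on - strand share the context
        seq = "TACGT"
        assert cytosine_context(seq, 2, "C") == "CG"
        assert cytosine_context(seq, 3, "G") == "CG"


class TestSpectrum:
    def test_purine_reference_collapsed(self):
        tab = spectrum([SubstitutionRecord(5, "G", "A")])
        assert tab.class_counts["C:G>T:A"] == 1

    def test_all_ct(self):
        subs = [SubstitutionRecord(i, "C", "T") for i in range(100)]
        tab = spectrum(subs)
        assert tab.class_counts["C:G>T:A"] == 100 and tab.total == 100

    def test_reverse_complement_invariance(self):
        """Class counts are unchanged if the organellar genome is
        reverse-complemented and the records remapped."""
        rng = np.random.default_rng(5)
        from okit.synthetic import random_sequence

        org = random_sequence(500, rng)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        subs = []
        for pos in rng.choice(500, size=60, replace=False):
            ref = org[pos]
            alt = rng.permutation([b for b in "ACGT" if b != ref])[0]
            subs.append(SubstitutionRecord(int(pos), ref, alt))
        flipped = [
            SubstitutionRecord(len(org) - 1 - s.organelle_pos, comp[s.ref], comp[s.alt])
            for s in subs
        ]
        assert spectrum(subs).class_counts == spectrum(flipped).class_counts

    def test_denominators_on_aligned_intervals(self):
        org = "ACGACGACGACG"
        tab = spectrum([], org, [(0, 12)])
        # every C is followed by G -> CG context; every G preceded by C -> CG
        assert tab.denominators["CG"] > 0 and tab.denominators["CHH"] == 0


class TestEnrichment:
    def _setup(self):
        genome = {"chr1": 1_000_000}
        anns = [
            MergedInsertion("chr1", s, s + 1000, 95.0, 1, "NUPT")
            for s in range(0, 1_000_000, 100_000)
        ]
        return genome, anns

    def test_maximal_overlap_minimal_p(self):
        genome, anns = self._setup()
        feats = [("chr1", a.start, a.end) for a in anns]
        res = enrichment_test(feats, anns, genome, n_samples=1000, seed=3)
        assert res.fold > 10
        assert res.p_empirical == pytest.approx(1 / 1001)

    def test_disjoint_chromosomes_zero_fold(self):
        genome, anns = self._setup()
        genome["chr2"] = 10_000
        res = enrichment_test([("chr2", 0, 500)], anns, genome, n_samples=200, seed=1)
        assert res.observed_overlap == 0 and res.fold == 0.0

    def test_seed_reproducible(self):
        genome, anns = self._setup()
        feats = [("chr1", 5000, 7000), ("chr1", 800_000, 803_000)]
        a = enrichment_test(feats, anns, genome, n_samples=500, seed=9)
        b = enrichment_test(feats, anns, genome, n_samples=500, seed=9)
        assert (a.null_mean, a.p_empirical, a.ci_low, a.ci_high) == (
            b.null_mean, b.p_empirical, b.ci_low, b.ci_high,
        )

    def test_feature_longer_than_chromosome_errors(self):
        genome, anns = self._setup()
        with pytest.raises(ValueError, match="longer than"):
            enrichment_test([("chr1", 0, 2_000_000)], anns, genome, n_samples=10, seed=0)


class TestSummarize:
    def _table(self, n=10, seed=2):
        rng = np.random.default_rng(seed)
        size = rng.uniform(1e8, 1e10, n)
        return pd.DataFrame(
            {
                "nuclear_genome_size": size,
                "nupt_total_len": size * 1e-4 + rng.normal(0, 1e4, n),
                "numt_total_len": size * 5e-5 + rng.normal(0, 1e4, n),
                "nupt_mean_identity": rng.uniform(85, 99, n),
                "numt_mean_identity": rng.uniform(85, 99, n),
            }
        )

    def test_perfect_correlations(self):
        df = pd.DataFrame(
            {
                "nuclear_genome_size": [1.0, 2.0, 3.0],
                "nupt_total_len": [1.0, 2.0, 3.0],
                "numt_total_len": [-1.0, -2.0, -3.0],
            }
        )
        out = summarize(df)
        assert out["r_nupt_vs_genome"] == pytest.approx(1.0)
        assert out["r_numt_vs_genome"] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        df = self._table()
        out = summarize(df)
        x = df["nupt_total_len"].to_numpy()
        y = df["nuclear_genome_size"].to_numpy()
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out["r_nupt_vs_genome"] == pytest.approx(r, abs=1e-12)

    def test_too_few_rows_undefined(self):
        out = summarize(self._table(n=2))
        assert np.isnan(out["r_nupt_vs_genome"])

    def test_identity_histogram_bins(self):
        ins = [
            MergedInsertion("c", 0, 1000, 98.4, 1, "NUPT"),
            MergedInsertion("c", 2000, 2500, 98.9, 1, "NUPT"),
            MergedInsertion("c", 5000, 5100, 85.2, 1, "NUPT"),
        ]
        df = identity_histogram(ins)
        assert df.loc[df["bin_low"] == 98.0, "cumulative_length"].item() == 1500
        assert df.loc[df["bin_low"] == 85.0, "cumulative_length"].item() == 100
        assert df["cumulative_length"].sum() == 1600
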