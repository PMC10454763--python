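"""Synthetic genomes, mock compositions, read simulation, subsampling."""

import numpy as np
import pytest

import strainsig as ss
from strainsig.errors import InvalidParameterError
from strainsig.io import iter_fastq, write_fasta

from oracles import revcomp_str


class TestGenerateGenomes:
    def test_deterministic_under_seed(self):
        a = ss.generate_genomes(3, 1000, seed=5)
        b = ss.generate_genomes(3, 1000, seed=5)
        assert a == b
        c = ss.generate_genomes(3, 1000, seed=6)
        assert a != c

    def test_disjoint_without_shared_block(self):
        genomes = ss.generate_genomes(2, 5000, shared_block_fraction=0.0, seed=10)
        model, report = ss.build_model(genomes, n=21)
        assert report.common == 0
        assert all(g.unique_count == g.n_t for g in model.genomes)

    def test_shared_block_manufactures_m_equals_k(self):
        k = 4
        genomes = ss.generate_genomes(k, 2000, shared_block_fraction=0.5, seed=11)
        model, report = ss.build_model(genomes, n=21)
        # interior n-grams of the implanted block appear in all k genomes
        assert int((model.counts == k).sum()) >= 1000 - 21
        assert report.common > 0

    def test_parameter_validation(self):
        with pytest.raises(InvalidParameterError):
            ss.generate_genomes(0, 1000)
        with pytest.raises(InvalidParameterError):
            ss.generate_genomes(2, 1000, shared_block_fraction=1.5)
        with pytest.raises(InvalidParameterError):
            ss.generate_genomes(2, 50)


class TestCompositions:
    def test_even_mock_is_one_twelfth_each(self):
        comp = ss.mock_even([f"g{i}" for i in range(12)])
        assert all(p == pytest.approx(1 / 12, abs=1e-12) for _g, p in comp.entries)
        assert sum(p for _g, p in comp.entries) == pytest.approx(1.0, abs=1e-9)
        assert comp.label == "even"

    def test_even_mock_requires_exactly_12(self):
        with pytest.raises(InvalidParameterError):
            ss.mock_even([f"g{i}" for i in range(11)])

    def test_staggered_ladder_spans_900x(self):
        comp = ss.mock_staggered([f"g{i}" for i in range(20)])
        props = comp.proportions
        assert props[-1] / props[0] == pytest.approx(0.18 / 0.0002, rel=1e-9)
        assert np.all(np.diff(props) > 0)
        assert props.sum() == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(InvalidParameterError):
            ss.mock_staggered(["a"] * 3)

    def test_composition_validation(self):
        with pytest.raises(InvalidParameterError):
            ss.CommunityComposition([("a", 0.5), ("b", 0.4)])
        with pytest.raises(InvalidParameterError):
            ss.CommunityComposition([("a", 1.2), ("b", -0.2)])
        with pytest.raises(InvalidParameterError):
            ss.ReadSimParams(n_reads=10, target_coverage=5.0)
        with pytest.raises(InvalidParameterError):
            ss.ReadSimParams(n_reads=10, substitution_rate=0.5)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, toy_genomes):
        gid, seq = toy_genomes[0]
        comp = ss.CommunityComposition([(gid, 1.0)])
        _, reads, _ = ss.simulate_reads(
            toy_genomes, comp, ss.ReadSimParams(n_reads=200, seed=3, paired=False)
        )
        both = seq + "#" + revcomp_str(seq)
        assert all(s in both for _r, s in reads)

    def test_paired_mate2_is_far_end_revcomp(self, toy_genomes):
        gid, seq = toy_genomes[0]
        comp = ss.CommunityComposition([(gid, 1.0)])
        _, m1, m2 = ss.simulate_reads(
            toy_genomes, comp, ss.ReadSimParams(n_reads=50, seed=4)
        )
        fwd = seq
        rev = revcomp_str(seq)
        for (_r1, s1), (_r2, s2) in zip(m1, m2):
            # reconstruct: mate1 starts the fragment on one strand, the
            # reverse complement of mate2 ends it on the same strand
            tail = revcomp_str(s2)
            src = fwd if s1 in fwd else rev
            assert s1 in src
            i = src.index(s1)
            assert src[i + 300 - 150 : i + 300] == tail

    def test_exact_read_count_and_record_count(self, toy_genomes, tmp_path):
        comp = ss.CommunityComposition([(toy_genomes[0][0], 1.0)])
        rep = ss.simulate_reads(
            toy_genomes, comp, ss.ReadSimParams(n_reads=1000, seed=5),
            out1=tmp_path / "a_1.fq", out2=tmp_path / "a_2.fq",
        )
        assert rep.n_fragments == 1000 and rep.n_records == 2000
        assert sum(1 for _ in iter_fastq(tmp_path / "a_1.fq")) == 1000
        assert sum(1 for _ in iter_fastq(tmp_path / "a_2.fq")) == 1000

    def test_multinomial_proportions_within_4_sigma(self, toy_genomes):
        p = 0.75
        n = 30_000
        comp = ss.CommunityComposition([(toy_genomes[0][0], p), (toy_genomes[1][0], 1 - p)])
        rep, _m1, _m2 = ss.simulate_reads(
            toy_genomes, comp, ss.ReadSimParams(n_reads=n, seed=6)
        )
        counts = dict(zip(rep.per_genome["genome_id"], rep.per_genome["reads"]))
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(counts[toy_genomes[0][0]] - n * p) <= 4 * sigma

    def test_coverage_mode_read_count(self, toy_genomes):
        # coverage * total_len / read_len / 2 fragments for paired reads
        comp = ss.CommunityComposition([(g, 0.2) for g, _ in toy_genomes])
        rep, _1, _2 = ss.simulate_reads(
            toy_genomes, comp, ss.ReadSimParams(target_coverage=30, seed=7)
        )
        assert rep.n_fragments == round(30 * 10_000 / 150 / 2)

    def test_substitution_rate_mutates_about_right(self, toy_genomes):
        gid, seq = toy_genomes[0]
        comp = ss.CommunityComposition([(gid, 1.0)])
        _, clean, _ = ss.simulate_reads(
            toy_genomes, comp, ss.ReadSimParams(n_reads=500, seed=8, paired=False)
        )
        _, noisy, _ = ss.simulate_reads(
            toy_genomes, comp,
            ss.ReadSimParams(n_reads=500, seed=8, paired=False, substitution_rate=0.05),
        )
        diffs = sum(
            a != b for (_r, s1), (_q, s2) in zip(clean, noisy) for a, b in zip(s1, s2)
        )
        total = 500 * 150
        assert 0.03 * total < diffs < 0.07 * total

    def test_determinism(self, toy_genomes, tmp_path):
        comp = ss.CommunityComposition([(g, 0.2) for g, _ in toy_genomes])
        params = ss.ReadSimParams(n_reads=100, seed=9, substitution_rate=0.01)
        for name in ("x", "y"):
            ss.simulate_reads(toy_genomes, comp, params,
                              out1=tmp_path / f"{name}_1.fq", out2=tmp_path / f"{name}_2.fq")
        assert (tmp_path / "x_1.fq").read_bytes() == (tmp_path / "y_1.fq").read_bytes()
        assert (tmp_path / "x_2.fq").read_bytes() == (tmp_path / "y_2.fq").read_bytes()

    def test_read_length_longer_than_genome_rejected(self, toy_genomes):
        comp = ss.CommunityComposition([(toy_genomes[0][0], 1.0)])
        with pytest.raises(InvalidParameterError):
            ss.simulate_reads(toy_genomes, comp,
                              ss.ReadSimParams(n_reads=10, read_length=5000, seed=1))


class TestSubsample:
    def _make_pair(self, toy_genomes, tmp_path, n=100):
        comp = ss.CommunityComposition([(g, 0.2) for g, _ in toy_genomes])
        ss.simulate_reads(toy_genomes, comp, ss.ReadSimParams(n_reads=n, seed=12),
                          out1=tmp_path / "in_1.fq", out2=tmp_path / "in_2.fq")
        return tmp_path / "in_1.fq", tmp_path / "in_2.fq"

    def test_fraction_one_is_identity(self, toy_genomes, tmp_path):
        in1, in2 = self._make_pair(toy_genomes, tmp_path)
        ss.subsample_reads(in1, tmp_path / "o_1.fq", in2, tmp_path / "o_2.fq",
                           fraction=1.0, seed=1)
        assert list(iter_fastq(in1)) == list(iter_fastq(tmp_path / "o_1.fq"))
        assert list(iter_fastq(in2)) == list(iter_fastq(tmp_path / "o_2.fq"))

    def test_half_keeps_exactly_half_and_pairs_together(self, toy_genomes, tmp_path):
        in1, in2 = self._make_pair(toy_genomes, tmp_path)
        info = ss.subsample_reads(in1, tmp_path / "o_1.fq", in2, tmp_path / "o_2.fq",
                                  fraction=0.5, seed=2)
        assert info["kept_reads"] == 50
        out1 = list(iter_fastq(tmp_path / "o_1.fq"))
        out2 = list(iter_fastq(tmp_path / "o_2.fq"))
        assert len(out1) == len(out2) == 50
        # subset property, order preserved, mates synchronised
        all1 = list(iter_fastq(in1))
        idx = [all1.index(rec) for rec in out1]
        assert idx == sorted(idx)
        all2 = list(iter_fastq(in2))
        assert [all2[i] for i in idx] == out2

    def test_coverage_mode_converts_to_fraction(self, toy_genomes, tmp_path):
        # 120 fragments of 2x150 over 10 kb -> 3.6x; request 1.2x -> keep 1/3
        comp = ss.CommunityComposition([(g, 0.2) for g, _ in toy_genomes])
        ss.simulate_reads(toy_genomes, comp, ss.ReadSimParams(n_reads=120, seed=13),
                          out1=tmp_path / "c_1.fq", out2=tmp_path / "c_2.fq")
        info = ss.subsample_reads(
            tmp_path / "c_1.fq", tmp_path / "d_1.fq", tmp_path / "c_2.fq",
            tmp_path / "d_2.fq", target_coverage=1.2, total_genome_length=10_000, seed=3,
        )
        assert info["fraction"] == pytest.approx(1 / 3)
        assert info["kept_reads"] == 40

    def test_fraction_out_of_range(self, toy_genomes, tmp_path):
        in1, in2 = self._make_pair(toy_genomes, tmp_path)
        with pytest.raises(InvalidParameterError):
            ss.subsample_reads(in1, tmp_path / "o.fq", fraction=1.5, seed=1)


class TestDegrade:
    def test_identity_at_full_fraction(self, toy_genomes):
        assert ss.degrade_references(toy_genomes, 1.0) == list(toy_genomes)

    def test_prefix_truncation_length(self, toy_genomes):
        out = ss.degrade_references(toy_genomes, 0.5)
        assert all(len(s) == 1000 for _g, s in out)
        assert all(s == full[:1000] for (_g, s), (_h, full) in zip(out, toy_genomes))

    def test_window_mode_deterministic(self, toy_genomes):
        a = ss.degrade_references(toy_genomes, 0.25, seed=5, mode="window")
        b = ss.degrade_references(toy_genomes, 0.25, seed=5, mode="window")
        assert a == b
        assert all(len(s) == 500 for _g, s in a)

    def test_degraded_model_has_smaller_nt(self, toy_genomes, toy_model):
        degraded, _ = ss.build_model(ss.degrade_references(toy_genomes, 0.5), n=21)
        for full, part in zip(toy_model.genomes, degraded.genomes):
            assert part.n_t < full.n_t
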