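from collections import Counter

import numpy as np
import pysam
import pytest

from srnapipe.mapper import (
    PairHmmMapper,
    SeedIndex,
    candidate_locations,
    estimate_error_profile,
    map_reads,
)
from srnapipe.phmm import ErrorProfile
from srnapipe.preprocess import ShortRead
from srnapipe.simdata import generate_reference, revcomp


class TestSeedIndex:
    def test_enumeration_toy_genome(self):
        idx = SeedIndex.build({"c": "ACGTACGT"}, k=4)
        assert [pos for _, pos in idx.lookup("ACGT")] == [0, 4]
        assert idx.lookup("AAAA") == []

    def test_k_longer_than_contigs_rejected(self):
        with pytest.raises(ValueError):
            SeedIndex.build({"c": "ACGT"}, k=12)

    def test_repeat_seeds_hit_both_copies(self, small_config):
        bundle = generate_reference(small_config)
        (_, a0, a1), (_, b0, b1) = bundle.repeat_regions
        idx = SeedIndex.build(bundle.genome, k=12)
        kmer = bundle.genome[small_config.contig_name][a0 : a0 + 12]
        positions = {pos for _, pos in idx.lookup(kmer)}
        assert {a0, b0} <= positions


@pytest.fixture(scope="module")
def bundle_and_index(small_config):
    bundle = generate_reference(small_config)
    return bundle, SeedIndex.build(bundle.genome, k=12)


class TestCandidateLocations:

    def test_unique_read_single_candidate_containing_origin(self, bundle_and_index):
        bundle, idx = bundle_and_index
        mir = bundle.annotation[bundle.annotation.klass == "miRNA"].iloc[0]
        seq = bundle.feature_sequence(mir.feature_id)
        cands = candidate_locations(seq, idx)
        assert len(cands) == 1
        assert cands[0].start <= mir.start and cands[0].end >= mir.end
        assert cands[0].strand == mir.strand

    def test_repeat_read_two_candidates(self, bundle_and_index):
        bundle, idx = bundle_and_index
        (c, a0, a1), _ = bundle.repeat_regions
        seq = bundle.genome[c][a0 + 5 : a0 + 29]
        cands = candidate_locations(seq, idx)
        assert len([x for x in cands if x.strand == "+"]) == 2

    def test_all_n_read_unmapped(self, bundle_and_index):
        _, idx = bundle_and_index
        assert candidate_locations("N" * 20, idx) == []


@pytest.fixture(scope="module")
def mapper(small_config):
    bundle = generate_reference(small_config)
    m = PairHmmMapper(bundle.genome)
    m._bundle = bundle
    return m


class TestMapping:
    def test_error_free_reads_exact_coordinates(self, mapper):
        bundle = mapper._bundle
        prof = ErrorProfile.uniform(60, 0.005)
        mir = bundle.annotation[bundle.annotation.klass == "miRNA"]
        for row in mir.itertuples(index=False):
            res = mapper.map_sequence(bundle.feature_sequence(row.feature_id), prof)
            assert (res.contig, res.start, res.end, res.strand) == (
                row.contig,
                row.start,
                row.end,
                row.strand,
            )
            assert res.mapq == 60 and not res.is_discarded
            assert res.gapless and res.n_mismatch == 0

    def test_repeat_reads_mapq_three_discarded(self, mapper):
        bundle = mapper._bundle
        prof = ErrorProfile.uniform(60, 0.005)
        (c, a0, a1), _ = bundle.repeat_regions
        for off in range(0, a1 - a0 - 24):
            res = mapper.map_sequence(bundle.genome[c][a0 + off : a0 + off + 24], prof)
            assert res.mapq == 3
            assert res.is_discarded

    def test_strand_symmetry(self, mapper):
        bundle = mapper._bundle
        prof = ErrorProfile.uniform(60, 0.005)
        mir = bundle.annotation[bundle.annotation.klass == "miRNA"].iloc[3]
        seq = bundle.feature_sequence(mir.feature_id)
        a = mapper.map_sequence(seq, prof)
        b = mapper.map_sequence(revcomp(seq), prof)
        assert (a.contig, a.start, a.end) == (b.contig, b.start, b.end)
        assert {a.strand, b.strand} == {"+", "-"}


class TestEstimateErrorProfile:
    def _simulated_seq_counts(self, mapper, n_reads, errs, seed):
        """Reads drawn from miRNA loci with per-cycle substitutions."""
        bundle = mapper._bundle
        rng = np.random.default_rng(seed)
        mir = bundle.annotation[bundle.annotation.klass == "miRNA"]
        seqs = [bundle.feature_sequence(f) for f in mir.feature_id]
        bases = np.array(list("ACGT"))
        counts: Counter = Counter()
        for _ in range(n_reads):
            s = list(seqs[rng.integers(len(seqs))])
            for j in range(len(s)):
                if rng.random() < errs[j]:
                    s[j] = rng.choice(bases[bases != s[j]])
            counts["".join(s)] += 1
        return counts

    def test_recovers_background_and_spike(self, mapper):
        errs = np.full(24, 0.01)
        errs[10] = 0.08
        counts = self._simulated_seq_counts(mapper, 8000, errs, seed=21)
        prof, _ = estimate_error_profile(counts, mapper)
        assert prof.sub[10] == pytest.approx(0.08, abs=0.02)
        background = np.delete(prof.sub[:18], 10)
        assert np.all(np.abs(background - 0.01) < 0.01)

    def test_zero_error_reads_hit_pseudocount_floor(self, mapper):
        counts = self._simulated_seq_counts(mapper, 2000, np.zeros(24), seed=22)
        prof, _ = estimate_error_profile(counts, mapper, alpha=1.0)
        n = sum(counts.values())
        # only the pseudocount floor remains: e_j <= 2*alpha/(n_j + 4*alpha)
        assert np.all(prof.sub[:18] <= 2.0 / (n * 0.5 + 4.0))

    def test_fixed_point_converges_in_one_iteration(self, mapper):
        counts = self._simulated_seq_counts(mapper, 2000, np.full(24, 0.01), seed=23)
        prof1, _ = estimate_error_profile(counts, mapper, max_iter=5)
        prof2, _ = estimate_error_profile(counts, mapper, init_profile=prof1)
        assert prof2.iteration == 1

    def test_total_loglik_non_decreasing(self, mapper):
        errs = np.full(24, 0.02)
        counts = self._simulated_seq_counts(mapper, 4000, errs, seed=24)
        _, history = estimate_error_profile(counts, mapper)
        assert all(b >= a - 1e-6 for a, b in zip(history, history[1:]))

    def test_no_confident_reads_returns_init_with_warning(self, mapper):
        init = ErrorProfile.uniform(30, 0.02)
        prof, _ = estimate_error_profile(
            {"N" * 20: 5}, mapper, init_profile=init
        )
        assert prof.warning
        assert np.array_equal(prof.sub, init.sub)


class TestMapReadsSam:
    def test_sam_roundtrip_and_determinism(self, tmp_path, small_config):
        bundle = generate_reference(small_config)
        mapper = PairHmmMapper(bundle.genome)
        prof = ErrorProfile.uniform(60, 0.005)
        mir = bundle.annotation[bundle.annotation.klass == "miRNA"]
        seqs = [bundle.feature_sequence(f) for f in mir.feature_id[:10]]
        reads = [
            ShortRead(f"read{i}", s, "I" * len(s), sample="s")
            for i, s in enumerate(seqs)
        ]
        for name in ("a.sam", "b.sam"):
            tally = map_reads(reads, mapper, prof, tmp_path / name)
        assert tally == {"mapped": 10, "discarded": 0, "unmapped": 0}
        assert (tmp_path / "a.sam").read_text() == (tmp_path / "b.sam").read_text()
        with pysam.AlignmentFile(str(tmp_path / "a.sam")) as fh:
            recs = list(fh)
        assert len(recs) == 10
        for rec in recs:
            assert rec.mapping_quality == 60
            assert rec.cigartuples[0][1] == len(rec.query_sequence)

    def test_empty_input_valid_sam(self, tmp_path, small_config):
        bundle = generate_reference(small_config)
        mapper = PairHmmMapper(bundle.genome)
        prof = ErrorProfile.uniform(60, 0.005)
        tally = map_reads([], mapper, prof, tmp_path / "empty.sam")
        assert tally == {"mapped": 0, "discarded": 0, "unmapped": 0}
        with pysam.AlignmentFile(str(tmp_path / "empty.sam")) as fh:
            assert list(fh) == []
            assert fh.header.nreferences == 1

    def test_discarded_reads_written_as_unmapped_with_tag(
        self, tmp_path, small_config
    ):
        bundle = generate_reference(small_config)
        mapper = PairHmmMapper(bundle.genome)
        prof = ErrorProfile.uniform(60, 0.005)
        (c, a0, a1), _ = bundle.repeat_regions
        seq = bundle.genome[c][a0 : a0 + 24]
        reads = [ShortRead("rep", seq, "I" * len(seq))]
        tally = map_reads(reads, mapper, prof, tmp_path / "rep.sam")
        assert tally["discarded"] == 1
        with pysam.AlignmentFile(str(tmp_path / "rep.sam")) as fh:
            rec = next(iter(fh))
        assert rec.is_unmapped
        assert rec.get_tag("ZD") == 1
        assert rec.get_tag("ZQ") == 3
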