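"""Structural MITE detection: TIR/TSD detectors (with exhaustive-string
oracles), superfamily table, validation, clustering, annotation."""

import numpy as np
import pytest

from tedyn import mite
from tedyn.seqio import revcomp
from tests.conftest import family_id_map, precision, recall


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _brute_force_tir(seq):
    """Exhaustive oracle: longest L in [10,30] with <= 1 mismatch between
    the 5' terminus and the reverse complement of the 3' terminus."""
    best = None
    for L in range(10, min(30, len(seq) // 2) + 1):
        mism = sum(a != b for a, b in zip(seq[:L], revcomp(seq[-L:])))
        if mism <= 1:
            best = (L, mism)
    return best


class TestDetectTir:
    def test_perfect_constructed_tir(self):
        rng = np.random.default_rng(1)
        tir = "CAGTGGTGTC"
        middle = _random_seq(rng, 180)
        seq = tir + middle + revcomp(tir)
        result = mite.detect_tir(seq)
        assert result is not None
        assert result == _brute_force_tir(seq)
        assert result[0] >= 10 and result[1] <= 1

    def test_one_mismatch_in_terminus(self):
        rng = np.random.default_rng(2)
        tir = "CAGTGGTGTC"
        seq = tir + _random_seq(rng, 180) + "GACACCACTA"  # last base mutated
        result = mite.detect_tir(seq)
        assert result == _brute_force_tir(seq)
        assert result[1] == 1 and result[0] >= 10

    def test_matches_exhaustive_oracle_on_random_200mers(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            seq = _random_seq(rng, 200)
            assert mite.detect_tir(seq) == _brute_force_tir(seq)

    def test_short_sequence_returns_none(self):
        assert mite.detect_tir("ACGT" * 5) is None


class TestDetectTsd:
    def test_nine_mer_tsd(self):
        left = "ACGTACGTAC" + "GCTAGCTAG"
        right = "GCTAGCTAG" + "TTTTACGTAC"
        assert mite.detect_tsd(left, right, (9, 10)) == "GCTAGCTAG"

    def test_three_mer_tsd(self):
        assert mite.detect_tsd("ACGTACGTTA", "TTACCCGGGTT", (3,)) == "TTA"

    def test_one_mismatch_is_rejected(self):
        left = "ACGTACGTAC" + "GCTAGCTAG"
        right = "GCTAGCTAC" + "TTTTACGTAC"
        assert mite.detect_tsd(left, right, (9,)) is None

    def test_longest_allowed_length_wins(self):
        tsd = "AACCGGTTAC"
        assert mite.detect_tsd("ACGTACGTAC" + tsd, tsd + "ACGT" * 3) == tsd


class TestClassifySuperfamily:
    @pytest.mark.parametrize(
        "tsd,expected",
        [
            ("TTA", "PIF-Harbinger"),
            ("TAA", "PIF-Harbinger"),
            ("ACGTACGT", "hAT"),
            ("ACGTACGTA", "Mutator"),
            ("ACGTACGTAC", "Mutator"),
            ("ACGT", "unknown"),
            (None, "unknown"),
        ],
    )
    def test_decision_table(self, tsd, expected):
        assert mite.classify_superfamily(tsd) == expected

    def test_total_over_tsd_detector_outputs(self):
        # every detect_tsd output (lengths 3/8/9/10) classifies to a proper
        # superfamily except non-TTA/TAA 3-mers
        rng = np.random.default_rng(4)
        for L in (8, 9, 10):
            tsd = _random_seq(rng, L)
            assert mite.classify_superfamily(tsd) in ("hAT", "Mutator")


class TestValidateMite:
    def test_planted_element_accepted_with_planted_tsd(self, planted_genome):
        _cfg, records, _f, truth = planted_genome
        genome = {r.name: r.sequence for r in records}
        for e in truth.elements_of("genomeA", "MITE")[:20]:
            g = genome[e.chrom]
            res = mite.validate_mite(
                g[e.start : e.end], g[e.start - 20 : e.start], g[e.end : e.end + 20]
            )
            assert isinstance(res, mite.MiteElement)
            assert res.tsd == e.tsd
            assert res.superfamily == e.superfamily

    def test_900bp_candidate_rejected_too_long(self):
        rng = np.random.default_rng(5)
        tir = "CAGTGGTGTCAG"
        seq = tir + _random_seq(rng, 900 - 24) + revcomp(tir)
        tsd = "GCTAGCTAG"
        res = mite.validate_mite(seq, "ACGTACGTAC" + tsd, tsd + "ACGTACGTAC")
        assert isinstance(res, mite.Rejection) and res.reason == "too_long"

    def test_tir_less_candidate_rejected(self):
        rng = np.random.default_rng(6)
        seq = _random_seq(rng, 300)
        while _brute_force_tir(seq) is not None:
            seq = _random_seq(rng, 300)
        tsd = "GCTAGCTAG"
        res = mite.validate_mite(seq, "ACGTACGTAC" + tsd, tsd + "ACGTACGTAC")
        assert isinstance(res, mite.Rejection) and res.reason == "no_tir"


class TestClusterFamilies:
    def _element(self, seq):
        from tedyn.seqio import FeatureInterval

        return mite.MiteElement(
            location=FeatureInterval("x", 0, len(seq), ".", "repeat_region"),
            sequence=seq,
            superfamily="Mutator",
        )

    def test_low_divergence_copies_form_one_family(self, rng):
        seed = _random_seq(rng, 200)
        members = []
        for _ in range(10):
            arr = np.array(list(seed))
            sites = rng.choice(200, size=8, replace=False)  # 4% divergence
            for s in sites:
                arr[s] = rng.choice([c for c in "ACGT" if c != arr[s]])
            members.append(self._element("".join(arr)))
        families = mite.cluster_families(members)
        assert len(families) == 1 and families[0].copy_number == 10

    def test_distant_seeds_form_two_families(self, rng):
        a = _random_seq(rng, 200)
        b = _random_seq(rng, 200)  # ~75% divergent on average
        members = [self._element(a) for _ in range(3)] + [self._element(b) for _ in range(3)]
        assert len(mite.cluster_families(members)) == 2

    def test_threshold_is_inclusive_at_exactly_80pct(self, rng):
        centroid = _random_seq(rng, 100)
        arr = np.array(list(centroid))
        sites = rng.choice(100, size=20, replace=False)
        for s in sites:
            arr[s] = rng.choice([c for c in "ACGT" if c != arr[s]])
        member = "".join(arr)  # exactly 80% identity, same length
        fams = mite.cluster_families([self._element(centroid), self._element(member)])
        assert len(fams) == 1

    def test_family_ids_ordered_by_size(self, rng):
        big_seed = _random_seq(rng, 150)
        small_seed = _random_seq(rng, 150)
        members = [self._element(big_seed) for _ in range(5)]
        members += [self._element(small_seed) for _ in range(2)]
        fams = {f.family_id: f.copy_number for f in mite.cluster_families(members)}
        assert fams == {"DTM1": 5, "DTM2": 2}


class TestAnnotateCopies:
    def test_planted_copies_recovered_full_length(self, planted_genome, planted_mite_annotation):
        """Recall and precision >= 0.95 at planted divergence <= 0.10, all
        planted full copies called full-length."""
        _cfg, _records, _f, truth = planted_genome
        _families, copies = planted_mite_annotation
        truths = truth.elements_of("genomeA", "MITE")
        assert recall(copies, truths) >= 0.95
        assert precision(copies, truths) >= 0.95
        assert all(c.full_length for c in copies)

    def test_family_assignment_matches_truth(self, planted_genome, planted_mite_annotation):
        _cfg, _records, _f, truth = planted_genome
        families, copies = planted_mite_annotation
        fmap = family_id_map(families, truth)
        by_pos = {(c.location.chrom, c.location.start): c.family_id for c in copies}
        hits = 0
        for e in truth.elements_of("genomeA", "MITE"):
            fid = by_pos.get((e.chrom, e.start))
            if fid == fmap[e.family_id]:
                hits += 1
        assert hits / len(truth.elements_of("genomeA", "MITE")) >= 0.95

    def test_truncated_copy_not_full_length(self, rng):
        from tedyn.seqio import GenomeRecord

        seed = _random_seq(rng, 300)
        fam = mite.MiteFamily("DTM1", "Mutator", seed)
        genome_seq = _random_seq(rng, 3000) + seed[120:] + _random_seq(rng, 3000)
        copies = mite.annotate_copies([GenomeRecord("c", genome_seq)], [fam])
        assert len(copies) == 1
        assert not copies[0].full_length  # 60% coverage

    def test_n_genome_yields_no_hits(self):
        from tedyn.seqio import GenomeRecord

        fam = mite.MiteFamily("DTM1", "Mutator", "ACGT" * 50)
        copies = mite.annotate_copies([GenomeRecord("n", "N" * 5000)], [fam])
        assert copies == []

    def test_hard_length_cap(self, planted_mite_annotation):
        _families, copies = planted_mite_annotation
        assert all(len(c.sequence) <= mite.MAX_MITE_LENGTH for c in copies)


class TestScanConservedTerminals:
    def test_constructed_hit_with_9bp_tsd(self, rng):
        tsd = "GATCGATCA"
        body = "GGACTTG" + _random_seq(rng, 300) + "CAGGTCC"
        region = _random_seq(rng, 100) + tsd + body + tsd + _random_seq(rng, 100)
        hits = mite.scan_conserved_terminals(region)
        assert any(h.tsd == tsd and h.strand == "+" for h in hits)

    def test_two_mismatches_in_terminal_no_hit(self, rng):
        tsd = "GATCGATCA"
        body = "GGAGTTA" + _random_seq(rng, 300) + "CAGGTCC"  # 2 mismatches in 5'
        region = _random_seq(rng, 100) + tsd + body + tsd + _random_seq(rng, 100)
        hits = mite.scan_conserved_terminals(region)
        assert not any(h.start == 109 for h in hits)

    def test_random_region_produces_no_qualifying_hit(self, rng):
        region = _random_seq(rng, 4000)
        assert mite.scan_conserved_terminals(region) == []
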