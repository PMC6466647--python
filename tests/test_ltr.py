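"""LTR retrotransposon detection: candidate scanning, structural
validation, family clustering, solo-LTR calling."""

import numpy as np
import pytest

from tedyn import ltr, synthio
from tedyn.seqio import GenomeRecord, revcomp
from tests.conftest import iou, precision, recall


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _make_element(rng, trna, ltr_len=200, internal_len=1500, tsd="GATCA"):
    """Hand-built complete element with all structural features."""
    ltr_seq = "TG" + _rand(rng, ltr_len - 4) + "CA"
    pbs = revcomp(trna[-14:])
    ppt = "AG" * 6
    internal = (
        _rand(rng, 2) + pbs
        + _rand(rng, internal_len - 2 - 14 - 12 - 16)
        + ppt + _rand(rng, 4)
    )
    element = ltr_seq + internal + ltr_seq
    return tsd + element + tsd, element, ltr_seq


@pytest.fixture(scope="module")
def trna():
    rng = np.random.default_rng(77)
    return _rand(rng, 72)


class TestDetectCandidates:
    def test_planted_element_found_near_coordinates(self, planted_genome):
        _cfg, records, _f, truth = planted_genome
        for rec in records:
            cands = ltr.detect_ltr_candidates(rec)
            for e in truth.elements_of("genomeA", "LTR_complete"):
                if e.chrom != rec.name:
                    continue
                assert any(
                    abs(c.ltr5_start - e.start) <= 5 and abs(c.ltr3_end - e.end) <= 5
                    for c in cands
                )

    def test_tandem_duplication_rejected(self, rng):
        repeat = _rand(rng, 300)
        seq = _rand(rng, 2000) + repeat + _rand(rng, 200) + repeat + _rand(rng, 2000)
        assert ltr.detect_ltr_candidates(GenomeRecord("t", seq)) == []

    def test_repeat_free_sequence_yields_nothing(self, rng):
        seq = _rand(rng, 30_000)
        assert ltr.detect_ltr_candidates(GenomeRecord("t", seq)) == []


class TestValidate:
    def test_constructed_element_accepted(self, rng, trna):
        flanked, element, ltr_seq = _make_element(rng, trna)
        seq = _rand(rng, 3000) + flanked + _rand(rng, 3000)
        rec = GenomeRecord("t", seq)
        (cand,) = ltr.detect_ltr_candidates(rec)
        res = ltr.validate_ltr(cand, rec, [trna])
        assert isinstance(res, ltr.LtrElement)
        assert res.tsd == "GATCA"
        assert res.ltr5_seq == ltr_seq and res.ltr3_seq == ltr_seq
        assert res.pbs_found and res.ppt_found

    def test_planted_elements_accepted_with_planted_tsd(self, planted_genome):
        _cfg, records, _f, truth = planted_genome
        trnas = [t.sequence for t in truth.trnas]
        by_chrom = {r.name: r for r in records}
        validated = {}
        for rec in records:
            for e in ltr.detect_and_validate(rec, trnas):
                validated[(rec.name, e.location.start)] = e
        for t in truth.elements_of("genomeA", "LTR_complete"):
            e = validated.get((t.chrom, t.start))
            assert e is not None
            assert e.tsd == t.tsd

    def test_mutated_tsd_rejected(self, rng, trna):
        flanked, element, _l = _make_element(rng, trna, tsd="GATCA")
        # break one base of the right TSD copy
        flanked = flanked[:-5] + "CATCA" if flanked[-5] != "C" else flanked[:-5] + "TATCA"
        seq = _rand(rng, 3000) + flanked + _rand(rng, 3000)
        rec = GenomeRecord("t", seq)
        (cand,) = ltr.detect_ltr_candidates(rec)
        res = ltr.validate_ltr(cand, rec, [trna])
        assert isinstance(res, ltr.Rejection)
        assert res.reason == "no_tsd"

    def test_missing_ppt_rejected(self, rng, trna):
        ltr_seq = "TG" + _rand(rng, 196) + "CA"
        pbs = revcomp(trna[-14:])
        # pyrimidine-only tail upstream of the 3' LTR: no PPT possible
        internal = _rand(rng, 2) + pbs + _rand(rng, 1400) + "CT" * 20
        element = ltr_seq + internal + ltr_seq
        tsd = "GATCA"
        seq = _rand(rng, 3000) + tsd + element + tsd + _rand(rng, 3000)
        rec = GenomeRecord("t", seq)
        (cand,) = ltr.detect_ltr_candidates(rec)
        res = ltr.validate_ltr(cand, rec, [trna])
        assert isinstance(res, ltr.Rejection) and res.reason == "no_ppt"

    def test_empty_trna_set_is_configuration_error(self, rng, trna):
        flanked, *_rest = _make_element(rng, trna)
        seq = _rand(rng, 3000) + flanked + _rand(rng, 3000)
        rec = GenomeRecord("t", seq)
        (cand,) = ltr.detect_ltr_candidates(rec)
        with pytest.raises(ltr.ConfigurationError):
            ltr.validate_ltr(cand, rec, [])


class TestRecovery:
    def test_complete_recall_and_precision(self, planted_genome):
        _cfg, records, _f, truth = planted_genome
        trnas = [t.sequence for t in truth.trnas]
        completes = []
        for rec in records:
            completes.extend(ltr.detect_and_validate(rec, trnas))
        truths = truth.elements_of("genomeA", "LTR_complete")
        assert recall(completes, truths) >= 0.95
        assert precision(completes, truths) >= 0.95

    def test_solo_recall_and_disjointness(self, planted_genome):
        _cfg, records, _f, truth = planted_genome
        trnas = [t.sequence for t in truth.trnas]
        completes = []
        for rec in records:
            completes.extend(ltr.detect_and_validate(rec, trnas))
        families = ltr.cluster_ltr_families(completes)
        solos = []
        for rec in records:
            solos.extend(ltr.detect_solo_ltrs(rec, families, completes))
        truths = truth.elements_of("genomeA", "solo_LTR")
        assert recall(solos, truths, thr=0.8) >= 0.90
        spans = [
            (e.location.chrom, e.location.start, e.location.end) for e in completes
        ]
        for s in solos:
            for chrom, a, b in spans:
                if chrom == s.location.chrom:
                    assert s.location.end <= a or b <= s.location.start

    def test_no_false_completes_on_element_free_genome(self):
        cfg = synthio.SynthConfig(
            seed=13, genome_length=300_000, n_chromosomes=1,
            mite_families=[], ltr_families=[], gene_density=20,
        )
        records, _f, truth = synthio.generate_genome(cfg)
        trnas = [t.sequence for t in truth.trnas]
        assert ltr.detect_and_validate(records[0], trnas) == []


class TestClustering:
    def _solo(self, seq):
        from tedyn.seqio import FeatureInterval

        return ltr.SoloLtr(
            location=FeatureInterval("x", 0, len(seq), "+", "repeat_region"),
            tsd="GATCA", sequence=seq,
        )

    def _complete(self, ltr_seq, total=6000):
        from tedyn.seqio import FeatureInterval

        return ltr.LtrElement(
            location=FeatureInterval("x", 0, total, "+", "repeat_region"),
            ltr5=(0, len(ltr_seq)), ltr3=(total - len(ltr_seq), total),
            internal=(len(ltr_seq), total - len(ltr_seq)),
            tsd="GATCA", pbs_found=True, ppt_found=True,
            ltr5_seq=ltr_seq, ltr3_seq=ltr_seq,
        )

    def test_two_distant_families(self, rng):
        a, b = _rand(rng, 200), _rand(rng, 200)
        fams = ltr.cluster_ltr_families([self._complete(a), self._complete(b)])
        assert len(fams) == 2

    def test_solo_joins_its_family(self, rng):
        a = _rand(rng, 200)
        fams = ltr.cluster_ltr_families([self._complete(a)], [self._solo(a)])
        assert len(fams) == 1
        assert len(fams[0].solo_members) == 1
        assert fams[0].s_over_c == 1.0

    def test_threshold_inclusive_at_75pct(self, rng):
        centroid = _rand(rng, 200)
        arr = np.array(list(centroid))
        sites = rng.choice(200, size=50, replace=False)  # exactly 75% identity
        for s in sites:
            arr[s] = rng.choice([c for c in "ACGT" if c != arr[s]])
        member = "".join(arr)
        fams = ltr.cluster_ltr_families([self._complete(centroid), self._complete(member)])
        assert len(fams) == 1

    def test_family_prefixes_follow_superfamily(self, rng):
        short = self._complete(_rand(rng, 200), total=5400)
        long = self._complete(_rand(rng, 200), total=12_400)
        fams = ltr.cluster_ltr_families([short, long])
        prefixes = sorted(f.family_id[:3] for f in fams)
        assert prefixes == ["RLC", "RLG"]


class TestSuperfamilyProxy:
    @pytest.mark.parametrize(
        "total,expected",
        [(5400, "Copia"), (12_400, "Gypsy"), (8000, "Gypsy"), (7999, "Copia")],
    )
    def test_length_split(self, total, expected, rng):
        from tedyn.seqio import FeatureInterval

        e = ltr.LtrElement(
            location=FeatureInterval("x", 0, total, "+", "repeat_region"),
            ltr5=(0, 200), ltr3=(total - 200, total), internal=(200, total - 200),
            tsd="GATCA", pbs_found=True, ppt_found=True,
            ltr5_seq="TG" + "A" * 196 + "CA", ltr3_seq="TG" + "A" * 196 + "CA",
        )
        assert ltr.classify_superfamily_by_length(e) == expected
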