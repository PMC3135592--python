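"""PTC detection, EJC-competence classification, and batch FASTA annotation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vdjnmd.gene_models import MatureTranscript, splice
from vdjnmd.ptc_annotate import (
    PTC_EJC,
    PTC_FAILSAFE,
    PTC_NEG,
    Annotator,
    EjcParams,
    annotate,
    annotate_fasta,
    annotate_junction,
    classify_ejc,
    find_first_stop,
)
from vdjnmd.vdj_sim import SimParams, sample_junction

STOPS = {"TAA", "TAG", "TGA"}


def _mt(seq, junctions=(), cds=0, canonical=-1):
    return MatureTranscript(
        seq=seq,
        exon_junctions=tuple(junctions),
        cds_start=cds,
        polyA_pos=len(seq) - 1,
        canonical_stop_offset=canonical,
    )


def _oracle(mature, params):
    """Naive codon scan plus naive distance check, independent of annotate()."""
    seq = mature.seq
    pos = None
    for i in range(mature.cds_start, len(seq) - 2, 3):
        if seq[i: i + 3] in STOPS:
            pos = i
            break
    if pos is None or pos == mature.canonical_stop_offset:
        return (True, None, None, None, None, PTC_NEG)
    exon = sum(1 for j in mature.exon_junctions if j <= pos)
    downstream = [j for j in mature.exon_junctions if j >= pos + 3]
    origin = pos + 2 if params.measure_from == "last" else pos
    dist = min(j - origin for j in downstream) if downstream else None
    competent = any(j - origin > params.threshold_nt for j in downstream)
    cls = PTC_EJC if competent else PTC_FAILSAFE
    return (False, pos, exon, dist, mature.polyA_pos - pos, cls)


class TestFindFirstStop:
    def test_stop_at_codon_boundary(self):
        assert find_first_stop(_mt("ATGTAA"), 0) == 3

    def test_no_stop(self):
        assert find_first_stop(_mt("ATGAAA"), 0) is None

    def test_frame_offsets_scan_shifted_codons(self):
        # TAA at position 1 is visible only to frame offset 1
        assert find_first_stop(_mt("ATAAAAA"), 0) is None
        assert find_first_stop(_mt("ATAAAAA"), 1) == 1

    def test_non_dna_characters_rejected(self):
        with pytest.raises(ValueError):
            find_first_stop(_mt("ATGNAA"), 0)

    def test_bad_frame_offset(self):
        with pytest.raises(ValueError):
            find_first_stop(_mt("ATGTAA"), 3)

    @pytest.mark.parametrize("frame_offset", [1, 2])
    def test_fixture_frameshift_stop_in_third_exon(self, fixture, frame_offset):
        t = splice(fixture.model_a)
        pos = find_first_stop(t, frame_offset)
        assert t.exon_junctions[1] <= pos < t.exon_junctions[2]


class TestClassifyEjc:
    def test_far_downstream_junction_is_competent(self):
        assert classify_ejc(100, [203]) is True  # 100 nt upstream

    def test_near_junction_is_not_competent(self):
        assert classify_ejc(100, [132]) is False  # 30 nt upstream

    def test_final_exon_ptc_is_not_competent(self):
        assert classify_ejc(100, [20, 50]) is False

    def test_unsorted_junctions_rejected(self):
        with pytest.raises(ValueError):
            classify_ejc(10, [50, 30])

    def test_any_downstream_junction_suffices(self):
        # nearest junction too close, but a farther one qualifies
        assert classify_ejc(100, [110, 400]) is True

    def test_measurement_conventions_differ_by_two(self):
        pos, junction = 100, 157
        last = EjcParams(threshold_nt=54, measure_from="last")
        first = EjcParams(threshold_nt=56, measure_from="first")
        # distance is 55 from the last base, 57 from the first base
        assert classify_ejc(pos, [junction], last) is True
        assert classify_ejc(pos, [junction], first) is True
        assert classify_ejc(pos, [junction], EjcParams(threshold_nt=55)) is False

    @given(
        pos=st.integers(min_value=0, max_value=500),
        gap=st.integers(min_value=3, max_value=300),
    )
    def test_threshold_sweep_changes_only_window_cases(self, pos, gap):
        """Sweeping the threshold over [50, 55] reclassifies only PTCs whose
        junction distance falls inside that window."""
        junctions = [pos + gap]
        calls = {
            t: classify_ejc(pos, junctions, EjcParams(threshold_nt=t))
            for t in range(50, 56)
        }
        dist = gap - 2  # default last-base convention
        if dist > 55:
            assert all(calls.values())
        elif dist <= 50:
            assert not any(calls.values())
        else:
            assert calls[50] and not calls[55]


class TestAnnotate:
    def test_in_frame_junction_is_ptc_negative(self, fixture):
        ann = annotate_junction(fixture.model_a, fixture.model_a.junction_seq())
        assert ann.productive and ann.nmd_class == PTC_NEG
        assert ann.ptc_pos is None and ann.dist_polyA is None

    @pytest.mark.parametrize("shift", [1, 2])
    def test_frameshift_classes_differ_between_genotypes(self, fixture, shift):
        junction = fixture.model_a.junction_seq() + "A" * shift
        ann_a = annotate_junction(fixture.model_a, junction)
        ann_f = annotate_junction(fixture.model_f, junction)
        assert ann_a.nmd_class == PTC_EJC
        assert ann_a.dist_next_junction > 55
        assert ann_f.nmd_class == PTC_FAILSAFE
        assert ann_f.dist_next_junction is None
        # PTC coordinates and poly(A) distance are genotype-invariant
        assert ann_a.ptc_pos == ann_f.ptc_pos
        assert ann_a.dist_polyA == ann_f.dist_polyA
        assert ann_a.ptc_exon_index == 2
        assert ann_f.ptc_exon_index == 2  # third (and final) exon of F

    def test_matches_bruteforce_oracle_on_random_junctions(self, fixture, rng):
        """Annotator agrees exactly with a naive scan+distance oracle, and
        genotype only ever changes the downstream-junction fields."""
        v, d, j = fixture.segments
        params = SimParams()
        ejc = EjcParams()
        for _ in range(1200):
            event = sample_junction(v, d, j, params, rng)
            for genotype, model in fixture.models.items():
                mature = splice(model.with_junction(event.junction_seq))
                ann = annotate(mature, ejc)
                assert (
                    ann.productive,
                    ann.ptc_pos,
                    ann.ptc_exon_index,
                    ann.dist_next_junction,
                    ann.dist_polyA,
                    ann.nmd_class,
                ) == _oracle(mature, ejc)
            ann_a = annotate_junction(fixture.model_a, event.junction_seq, ejc)
            ann_f = annotate_junction(fixture.model_f, event.junction_seq, ejc)
            assert ann_a.productive == ann_f.productive
            assert ann_a.ptc_pos == ann_f.ptc_pos
            assert ann_a.dist_polyA == ann_f.dist_polyA

    def test_canonical_stop_is_never_a_ptc(self, fixture):
        t = splice(fixture.model_a)
        ann = annotate(t)
        assert ann.productive
        assert t.seq[t.canonical_stop_offset: t.canonical_stop_offset + 3] in STOPS


class TestAnnotateFasta:
    def _write(self, path, records):
        with open(path, "w") as fh:
            for name, seq in records:
                fh.write(f">{name}\n{seq}\n")

    def test_three_frames_on_both_genotypes(self, fixture, tmp_path):
        base = fixture.model_a.junction_seq()
        path = tmp_path / "junctions.fasta"
        self._write(path, [("s0", base), ("s1", base + "A"), ("s2", base + "AA")])
        df_a, rej_a = annotate_fasta(str(path), fixture.model_a)
        df_f, rej_f = annotate_fasta(str(path), fixture.model_f)
        assert rej_a == rej_f == 0
        assert df_a["nmd_class"].tolist() == [PTC_NEG, PTC_EJC, PTC_EJC]
        assert df_f["nmd_class"].tolist() == [PTC_NEG, PTC_FAILSAFE, PTC_FAILSAFE]

    def test_ambiguous_records_are_counted_not_dropped_silently(self, fixture, tmp_path):
        base = fixture.model_a.junction_seq()
        path = tmp_path / "mixed.fasta"
        self._write(path, [("ok", base), ("bad", base[:-1] + "N")])
        df, rejected = annotate_fasta(str(path), fixture.model_a)
        assert rejected == 1
        assert len(df) == 1

    def test_empty_fasta_is_an_error(self, fixture, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError):
            annotate_fasta(str(path), fixture.model_a)

    def test_transcript_mode_agrees_with_junction_mode(self, fixture, tmp_path, rng):
        v, d, j = fixture.segments
        events = [sample_junction(v, d, j, SimParams(), rng) for _ in range(20)]
        jpath = tmp_path / "j.fasta"
        tpath = tmp_path / "t.fasta"
        self._write(jpath, [(f"r{i}", e.junction_seq) for i, e in enumerate(events)])
        self._write(
            tpath,
            [
                (f"r{i}", splice(fixture.model_a.with_junction(e.junction_seq)).seq)
                for i, e in enumerate(events)
            ],
        )
        dj, _ = annotate_fasta(str(jpath), fixture.model_a)
        dt, _ = annotate_fasta(str(tpath), fixture.model_a, mode="transcript")
        assert dj["nmd_class"].tolist() == dt["nmd_class"].tolist()
        assert dj["ptc_pos"].tolist() == dt["ptc_pos"].tolist()

    def test_annotator_cache_is_consistent(self, fixture, rng):
        v, d, j = fixture.segments
        annotator = Annotator(fixture.model_a)
        e = sample_junction(v, d, j, SimParams(), rng)
        first = annotator.annotate_junction(e.junction_seq)
        second = annotator.annotate_junction(e.junction_seq)
        assert first is second
        assert first == annotate_junction(fixture.model_a, e.junction_seq)
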