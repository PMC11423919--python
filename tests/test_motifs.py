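"""Peak calling on residue profiles and refinement to contiguous motifs."""

import numpy as np
import pytest

from fragmap.motifs import (
    Absolute,
    MeanPlusSD,
    NoMotifError,
    PeakRegion,
    Quantile,
    call_peaks,
    interval_jaccard,
    parse_threshold_policy,
    refine_motif,
    report_motifs,
)
from fragmap.scoring import FragmentScore, ResidueProfile
from fragmap.structure_io import AtomRecord, ComplexStructure
from fragmap.scoring import count_interchain_contacts
from fragmap.tiling import BaitSequence, FragmentSpec


def profile_from_values(values) -> ResidueProfile:
    values = np.asarray(values, dtype=float)
    coverage = (~np.isnan(values)).astype(np.int64)
    return ResidueProfile(len(values), values, coverage)


def contact_set_at(fragment: FragmentSpec, residues, n_per_residue=2):
    """Build a ContactSet with contacts at the given global residues."""
    bait_atoms = [
        AtomRecord("A", i, "ALA", "CA", "C",
                   (3.8 * i, 0.0, 0.0), 80.0)
        for i in range(1, fragment.length + 1)
    ]
    rec_atoms = []
    serial = 0
    for g in residues:
        local = fragment.to_local(g)
        for k in range(n_per_residue):
            serial += 1
            rec_atoms.append(
                AtomRecord("B", serial, "ALA", "CA", "C",
                           (3.8 * local, -3.0 - 0.1 * k, 0.0), 80.0)
            )
    st = ComplexStructure(fragment.fragment_id, "A", "B",
                          bait_atoms + rec_atoms,
                          global_start=fragment.start)
    return count_interchain_contacts(st)


def _frag(fid, start, end):
    return FragmentSpec(fid, start, end, "A" * (end - start + 1))


class TestThresholdPolicies:
    def test_parse_strings(self):
        assert parse_threshold_policy("mean_plus_sd:2") == MeanPlusSD(2.0)
        assert parse_threshold_policy("mean_plus_sd") == MeanPlusSD(1.0)
        assert parse_threshold_policy("quantile:0.9") == Quantile(0.9)
        assert parse_threshold_policy("absolute:50") == Absolute(50.0)
        with pytest.raises(ValueError):
            parse_threshold_policy("topk:3")

    def test_resolution(self):
        values = np.array([0.0, 0.0, 10.0, 10.0])
        assert MeanPlusSD(0.0).resolve(values) == 5.0
        assert MeanPlusSD(1.0).resolve(values) == 10.0
        assert Quantile(0.5).resolve(values) == 5.0
        assert Absolute(3.0).resolve(values) == 3.0


class TestCallPeaks:
    def test_one_plateau_per_half(self):
        values = np.zeros(100)
        values[19:25] = 50.0  # residues 20-25
        values[69:80] = 80.0  # residues 70-80
        peaks = call_peaks(profile_from_values(values), [],
                           threshold_policy=Absolute(10.0))
        assert [(p.half, p.start, p.end) for p in peaks] == [
            ("N", 20, 25), ("C", 70, 80)]
        assert peaks[0].peak_score == 50.0

    def test_uniform_profile_returns_whole_halves(self, caplog):
        # degenerate case: sd = 0 so the threshold equals the mean and
        # every residue qualifies; each half is one run, returned whole
        peaks = call_peaks(profile_from_values(np.full(10, 5.0)), [],
                           threshold_policy=MeanPlusSD(1.0))
        assert [(p.half, p.start, p.end) for p in peaks] == [
            ("N", 1, 5), ("C", 6, 10)]

    def test_run_containing_half_maximum_wins(self):
        values = np.zeros(40)
        values[4:7] = 30.0    # run 5-7, below the half max
        values[11:14] = 60.0  # run 12-14 holds the N-half maximum
        values[29:32] = 90.0
        peaks = call_peaks(profile_from_values(values), [],
                           threshold_policy=Absolute(20.0))
        n_peak = peaks[0]
        assert (n_peak.start, n_peak.end) == (12, 14)

    def test_tie_on_maximum_resolved_leftmost(self):
        values = np.zeros(40)
        values[4:7] = 60.0
        values[11:14] = 60.0
        values[29:32] = 90.0
        peaks = call_peaks(profile_from_values(values), [],
                           threshold_policy=Absolute(20.0))
        assert (peaks[0].start, peaks[0].end) == (5, 7)

    def test_half_below_threshold_yields_no_peak(self, caplog):
        values = np.zeros(40)
        values[29:32] = 90.0
        with caplog.at_level("WARNING"):
            peaks = call_peaks(profile_from_values(values), [],
                               threshold_policy=Absolute(20.0))
        assert [p.half for p in peaks] == ["C"]
        assert "below threshold" in caplog.text

    def test_undefined_residues_break_runs(self):
        values = np.full(20, np.nan)
        values[2:5] = 50.0
        values[6:8] = 50.0
        values[14:16] = 70.0
        peaks = call_peaks(profile_from_values(values), [],
                           threshold_policy=Absolute(10.0))
        assert (peaks[0].start, peaks[0].end) == (3, 5)

    def test_raising_absolute_threshold_never_widens_peaks(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 100, 60)
        prof = profile_from_values(values)
        prev_widths = None
        for thr in (10.0, 30.0, 50.0, 70.0):
            peaks = call_peaks(prof, [], threshold_policy=Absolute(thr))
            widths = {p.half: p.end - p.start + 1 for p in peaks}
            if prev_widths is not None:
                for half, w in widths.items():
                    assert w <= prev_widths.get(half, np.inf)
            prev_widths = widths

    def test_supporting_fragments_recorded(self):
        values = np.zeros(100)
        values[29:35] = 50.0
        values[79:85] = 60.0
        frags = [_frag("a", 1, 50), _frag("b", 26, 75), _frag("c", 51, 100)]
        peaks = call_peaks(profile_from_values(values), frags,
                           threshold_policy=Absolute(10.0))
        assert peaks[0].supporting_fragments == ("a", "b")
        assert peaks[1].supporting_fragments == ("c",)

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError, match="split"):
            call_peaks(profile_from_values(np.ones(10)), [], split=10)


class TestRefineMotif:
    def _setup(self, contact_residues, fragment=None, score=1000.0):
        frag = fragment or _frag("F08", 176, 225)
        bait = BaitSequence("bait", "K" * 315)
        cs = contact_set_at(frag, contact_residues)
        scores = {frag.fragment_id: FragmentScore(
            frag.fragment_id, cs.count, 80.0, score)}
        peak = PeakRegion("C", min(contact_residues),
                          max(contact_residues), 100.0,
                          (frag.fragment_id,))
        return peak, {frag.fragment_id: cs}, scores, \
            {frag.fragment_id: frag}, bait

    def test_contiguous_contact_run_becomes_motif(self):
        peak, cs, scores, frags, bait = self._setup(range(197, 210))
        call = refine_motif(peak, cs, scores, frags, bait)
        assert (call.start, call.end, call.length) == (197, 209, 13)
        assert call.name == "MotifB"
        assert call.source_fragment == "F08"
        assert call.mean_per_residue_contacts == pytest.approx(2.0)

    def test_gap_tolerance_merges_and_splits(self):
        residues = list(range(30, 34)) + [35, 36]  # 30-33 and 35-36
        frag = _frag("F01", 1, 50)
        peak, cs, scores, frags, bait = self._setup(residues, frag)
        merged = refine_motif(peak, cs, scores, frags, bait,
                              gap_tolerance=1, min_motif_length=1)
        assert (merged.start, merged.end) == (30, 36)
        split = refine_motif(peak, cs, scores, frags, bait,
                             gap_tolerance=0, min_motif_length=1)
        assert (split.start, split.end) == (30, 33)  # larger total count

    def test_short_runs_discarded(self):
        frag = _frag("F01", 1, 50)
        peak, cs, scores, frags, bait = self._setup([30, 31, 32], frag)
        with pytest.raises(NoMotifError, match="length"):
            refine_motif(peak, cs, scores, frags, bait,
                         min_motif_length=5)

    def test_next_best_run_considered_after_length_filter(self):
        # run 10-12 has the largest count but is too short; 20-25 is taken
        frag = _frag("F01", 1, 50)
        bait = BaitSequence("bait", "K" * 315)
        cs_big = contact_set_at(frag, [10, 11, 12], n_per_residue=5)
        cs_small = contact_set_at(frag, range(20, 26), n_per_residue=1)
        merged_pairs = dict(cs_big.pairs)
        offset = max(r for _, r in merged_pairs) if merged_pairs else 0
        for (b, r), v in cs_small.pairs.items():
            merged_pairs[(b, r + offset)] = v
        cs = type(cs_big)("F01", merged_pairs)
        scores = {"F01": FragmentScore("F01", cs.count, 80.0, 100.0)}
        peak = PeakRegion("N", 5, 30, 50.0, ("F01",))
        call = refine_motif(peak, {"F01": cs}, scores, {"F01": frag}, bait,
                            min_motif_length=5)
        assert (call.start, call.end) == (20, 25)

    def test_highest_scoring_fragment_selected(self):
        bait = BaitSequence("bait", "K" * 315)
        f_lo = _frag("F07", 151, 200)
        f_hi = _frag("F08", 176, 225)
        cs = {
            "F07": contact_set_at(f_lo, range(197, 201)),
            "F08": contact_set_at(f_hi, range(197, 210)),
        }
        scores = {
            "F07": FragmentScore("F07", 4, 80.0, 320.0),
            "F08": FragmentScore("F08", 13, 80.0, 1040.0),
        }
        frags = {"F07": f_lo, "F08": f_hi}
        peak = PeakRegion("C", 190, 215, 1040.0, ("F07", "F08"))
        call = refine_motif(peak, cs, scores, frags, bait)
        assert call.source_fragment == "F08"
        assert (call.start, call.end) == (197, 209)

    def test_no_supporting_contacts_is_error(self):
        bait = BaitSequence("bait", "K" * 315)
        peak = PeakRegion("N", 10, 20, 5.0, ())
        with pytest.raises(NoMotifError, match="no supporting fragment"):
            refine_motif(peak, {}, {}, {}, bait)

    def test_deterministic(self):
        peak, cs, scores, frags, bait = self._setup(range(197, 210))
        first = refine_motif(peak, cs, scores, frags, bait)
        second = refine_motif(peak, cs, scores, frags, bait)
        assert first == second


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((28, 36), (28, 36), 1.0),
            ((28, 36), (40, 50), 0.0),
            ((1, 10), (6, 15), 5 / 15),
            ((201, 209), (197, 209), 9 / 13),
        ],
    )
    def test_values(self, a, b, expected):
        assert interval_jaccard(a, b) == pytest.approx(expected)
        assert interval_jaccard(b, a) == pytest.approx(expected)


class TestReportMotifs:
    def _call(self, bait, name, start, end):
        from fragmap.motifs import MotifCall

        return MotifCall(name, start, end, bait.subsequence(start, end),
                         2.0, "F01")

    def test_two_calls_roundtrip(self, tmp_path):
        from Bio import SeqIO

        bait = BaitSequence("bait", "ACDEFGHIKLMNPQRSTVWY" * 20)
        calls = [self._call(bait, "MotifA", 28, 36),
                 self._call(bait, "MotifB", 197, 209)]
        report_motifs(calls, bait, tmp_path / "m.tsv", tmp_path / "m.fasta",
                      tmp_path / "m.bed")
        records = list(SeqIO.parse(str(tmp_path / "m.fasta"), "fasta"))
        assert [r.id for r in records] == ["MotifA", "MotifB"]
        assert len(records[0].seq) == 9
        assert len(records[1].seq) == 13
        lines = (tmp_path / "m.tsv").read_text().splitlines()
        assert len(lines) == 3
        bed = (tmp_path / "m.bed").read_text().splitlines()
        assert bed[0].split("\t")[1:3] == ["27", "36"]  # 0-based half-open

    def test_zero_calls_writes_header_only(self, tmp_path):
        bait = BaitSequence("bait", "KKKK")
        report_motifs([], bait, tmp_path / "m.tsv", tmp_path / "m.fasta")
        assert (tmp_path / "m.tsv").read_text().startswith("name\t")
        assert (tmp_path / "m.fasta").read_text() == ""

    def test_sequence_mismatch_rejected(self, tmp_path):
        from fragmap.motifs import MotifCall

        bait = BaitSequence("bait", "K" * 50)
        bad = MotifCall("MotifA", 5, 9, "WWWWW", 1.0, "F01")
        with pytest.raises(ValueError, match="does not match"):
            report_motifs([bad], bait, tmp_path / "m.tsv",
                          tmp_path / "m.fasta")


def test_planted_motifs_recovered_across_seeds(clean_runs):
    """Each half's call overlaps its planted segment (Jaccard >= 0.5)."""
    hits = {"N": 0, "C": 0}
    for res in clean_runs.values():
        for half in ("N", "C"):
            if res.jaccard.get(half, 0.0) >= 0.5:
                hits[half] += 1
    n = len(clean_runs)
    assert hits["N"] >= 0.95 * n
    assert hits["C"] >= 0.95 * n
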