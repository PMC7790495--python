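"""Read curation: alignment, indel repair, allele-ID extraction, counting."""

import numpy as np
import pytest
from Bio.Seq import Seq, reverse_complement

from epifit import (
    ReadRecord,
    align_to_reference,
    correct_indels,
    curate_and_count,
    curate_read,
    detect_offtarget_hotspots,
    extract_allele_id,
)
from epifit.curation import STATUS_PASS, STATUS_TOO_SHORT, STATUS_UNALIGNABLE, CurationReport
from epifit.panel import FLAG_MUT, FLAG_UNEXPECTED
from epifit.reference import codon_slice, preferred_codon


def mutate_codon(reference, position, codon):
    sl = codon_slice(position)
    return reference[: sl.start] + codon + reference[sl.stop :]


class TestAlignment:
    def test_identical_read_is_gap_free(self, reference):
        aln = align_to_reference(ReadRecord("r", reference), reference)
        assert aln.edit_distance == 0 and aln.identity == 1.0
        assert (aln.ref_start, aln.ref_end) == (0, len(reference))
        assert aln.orientation == "forward"

    def test_reverse_complement_detected(self, reference):
        aln = align_to_reference(ReadRecord("r", reverse_complement(reference)), reference)
        assert aln.edit_distance == 0 and aln.orientation == "reverse"
        assert aln.sequence == reference

    def test_single_insertion_on_toy_sequences(self):
        # verified against the exhaustive expectation on a short pair:
        # one extra read base gives exactly one 1-bp insertion column
        ref = "ACGTACGTACGTACGTACGTACGTACGT"
        read = ref[:10] + "T" + ref[10:]
        aln = align_to_reference(ReadRecord("r", read), ref)
        assert aln.edit_distance == 1
        assert aln.cigar.count("I") == 1 and "D" not in aln.cigar
        repaired, n_ins, n_del = correct_indels(aln, ref)
        assert repaired == ref and (n_ins, n_del) == (1, 0)

    def test_garbage_read_unalignable(self, reference):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), size=len(reference)))
        assert align_to_reference(ReadRecord("r", junk), reference) is None


class TestIndelCorrection:
    def test_gap_free_alignment_unchanged(self, reference):
        aln = align_to_reference(ReadRecord("r", reference), reference)
        repaired, n_ins, n_del = correct_indels(aln, reference)
        assert repaired == reference and n_ins == n_del == 0

    def test_deletion_filled_from_reference(self, reference):
        # drop one base inside non-focal codon 50
        sl = codon_slice(50)
        read = reference[: sl.start + 1] + reference[sl.start + 2 :]
        aln = align_to_reference(ReadRecord("r", read), reference)
        repaired, _, n_del = correct_indels(aln, reference)
        assert n_del == 1
        assert repaired[sl] == reference[sl]

    def test_random_indel_patterns_restore_reference_span(self, reference):
        # repaired length always equals the aligned reference span, and
        # the repaired ORF translates to a full-length peptide
        rng = np.random.default_rng(7)
        for _ in range(200):
            read = list(reference)
            for _ in range(rng.integers(1, 6)):
                at = int(rng.integers(3, len(read) - 3))
                if rng.random() < 0.5:
                    read.insert(at, "ACGT"[rng.integers(4)])
                else:
                    del read[at]
            aln = align_to_reference(ReadRecord("r", "".join(read)), reference)
            repaired, _, _ = correct_indels(aln, reference)
            assert len(repaired) == aln.ref_end - aln.ref_start
            if (aln.ref_start, aln.ref_end) == (0, len(reference)):
                peptide = str(Seq(repaired).translate())
                assert len(peptide) == len(reference) // 3


class TestAlleleExtraction:
    def test_reference_gives_wt_allele_id(self, panel, reference):
        allele_id, flags, n_off, subs = extract_allele_id(reference, panel, reference)
        assert allele_id == "ETDHSKYDVGGAA"
        assert n_off == 0 and subs == ()

    def test_focal_mutation_flagged_expected(self, panel, reference):
        codon = preferred_codon(103, "K", reference)
        mutated = mutate_codon(reference, 103, codon)
        allele_id, flags, n_off, _ = extract_allele_id(mutated, panel, reference)
        assert allele_id[0] == "K" and flags[0] == FLAG_MUT
        assert n_off == 0

    def test_a234v_counts_as_offtarget(self, panel, reference):
        codon = preferred_codon(234, "V", reference)
        mutated = mutate_codon(reference, 234, codon)
        allele_id, _, n_off, subs = extract_allele_id(mutated, panel, reference)
        assert allele_id == "ETDHSKYDVGGAA"
        assert n_off == 1 and subs == ((234, "V"),)

    def test_silent_offtarget_change_not_counted(self, panel, reference):
        # GCA -> GCG is still alanine at codon 234
        assert reference[codon_slice(234)] == "GCA"
        mutated = mutate_codon(reference, 234, "GCG")
        _, _, n_off, _ = extract_allele_id(mutated, panel, reference)
        assert n_off == 0

    def test_n_in_focal_codon_gives_x_and_unexpected(self, panel, reference):
        sl = codon_slice(103)
        mutated = reference[: sl.start] + "GNA" + reference[sl.stop :]
        allele_id, flags, _, _ = extract_allele_id(mutated, panel, reference)
        assert allele_id[0] == "X" and flags[0] == FLAG_UNEXPECTED

    def test_stop_at_focal_locus_flagged(self, panel, reference):
        mutated = mutate_codon(reference, 103, "TAA")
        allele_id, flags, _, _ = extract_allele_id(mutated, panel, reference)
        assert allele_id[0] == "*" and flags[0] == FLAG_UNEXPECTED


class TestCurateAndCount:
    def test_copies_of_reference_count_exactly(self, panel, reference):
        reads = [ReadRecord(f"r{i}", reference) for i in range(10)]
        table, report = curate_and_count({"t0": reads}, reference, panel)
        assert table.df.loc["ETDHSKYDVGGAA", "t0"] == 10
        assert report.n_too_short["t0"] == report.n_unalignable["t0"] == 0

    def test_truncated_reads_are_too_short(self, panel, reference):
        # stop before the last focal codon (329)
        reads = [ReadRecord("r", reference[: codon_slice(320).stop])]
        call = curate_read(reads[0], reference, panel)
        assert call.status == STATUS_TOO_SHORT

    def test_empty_timepoint_is_an_error(self, panel, reference):
        with pytest.raises(ValueError, match="c1"):
            curate_and_count(
                {"t0": [ReadRecord("r", reference)], "c1": []}, reference, panel
            )

    def test_round_trip_zero_error(self, panel, reference):
        """Encoded alleles with no sequencing error re-curate exactly."""
        from epifit.simulate import _preset_truth
        from dataclasses import replace

        import epifit as ef

        truth = replace(
            _preset_truth("null"),
            per_base_error=0.0,
            indel_rate=0.0,
            offtarget_rate=0.0,
            timepoints={"t0": (0, 400), "c1": (1, 300)},
        )
        rng = np.random.default_rng(3)
        library = ef.generate_library(truth, 500, rng)
        reads = ef.sequence_reads(library, truth, rng)
        # ground truth from the read ids (read_id encodes the source clone)
        expected = {
            tp: {}
            for tp in reads
        }
        for tp, recs in reads.items():
            for rec in recs:
                clone = int(rec.read_id.split("/")[1])
                aid = library["allele_id"].iloc[clone]
                expected[tp][aid] = expected[tp].get(aid, 0) + 1
        table, report = curate_and_count(reads, reference, panel)
        for tp, want in expected.items():
            got = table.df[table.df[tp] > 0][tp].to_dict()
            assert got == want
        assert sum(report.n_too_short.values()) == 0

    def test_focal_error_rate_matches_binomial_expectation(self, panel, reference):
        """At 0.3% per-base error, the read fraction with >=1 focal-codon
        base error matches 1-(1-e)^(3*13) within Monte-Carlo tolerance."""
        from epifit.simulate import _preset_truth, _clone_sequence
        from dataclasses import replace

        import epifit as ef

        e = 0.003
        truth = replace(
            _preset_truth("null"),
            per_base_error=e,
            indel_rate=0.0,
            offtarget_rate=0.0,
            timepoints={"t0": (0, 3000)},
        )
        rng = np.random.default_rng(11)
        library = ef.generate_library(truth, 400, rng)
        reads = ef.sequence_reads(library, truth, rng)["t0"]
        sequences = [
            _clone_sequence(c, truth, reference) for _, c in library.iterrows()
        ]
        focal = [codon_slice(p) for p in panel.positions]
        n_hit = 0
        for rec in reads:
            clone = int(rec.read_id.split("/")[1])
            seq = rec.sequence
            if seq not in (sequences[clone],):  # maybe reverse strand
                fwd = reverse_complement(seq)
                seq = fwd if sum(a != b for a, b in zip(fwd, sequences[clone])) <= sum(
                    a != b for a, b in zip(seq, sequences[clone])
                ) else seq
            n_hit += any(seq[sl] != sequences[clone][sl] for sl in focal)
        p_expected = 1 - (1 - e) ** (3 * 13)
        se = np.sqrt(p_expected * (1 - p_expected) / len(reads))
        assert abs(n_hit / len(reads) - p_expected) < 4 * se


class TestHotspots:
    def _report(self, spectrum, n_pass):
        report = CurationReport()
        report.n_pass["t0"] = n_pass
        report.mismatch_spectrum.update(spectrum)
        return report

    def test_uniform_spectrum_yields_nothing(self):
        spectrum = {(pos, "V"): 3 for pos in range(2, 100)}
        assert detect_offtarget_hotspots(self._report(spectrum, 1000)) == []

    def test_spiked_position_returned_first(self):
        spectrum = {(pos, "V"): 2 for pos in range(2, 100)}
        spectrum[(234, "V")] = 100
        hits = detect_offtarget_hotspots(self._report(spectrum, 1000))
        assert hits[0][:2] == (234, "V")
        assert hits[0][2] == pytest.approx(0.1)

    def test_injected_a234v_hotspot_detected_in_reads(self, panel, reference):
        from epifit.simulate import _preset_truth
        from dataclasses import replace

        import epifit as ef

        truth = replace(
            _preset_truth("null"),
            indel_rate=0.0,
            hotspot=(234, "GTA", 0.05),  # A234V in 5% of clones
            timepoints={"t0": (0, 2000)},
        )
        rng = np.random.default_rng(5)
        library = ef.generate_library(truth, 1000, rng)
        reads = ef.sequence_reads(library, truth, rng)
        _, report = curate_and_count(reads, reference, panel)
        hits = detect_offtarget_hotspots(report)
        assert hits and hits[0][:2] == (234, "V")
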