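"""Anchor search, directional tract scans, and flank-indel QC."""

import numpy as np
import pytest

from polytg import reference
from polytg.abif import ChromatogramRead
from polytg.detect import (
    FlankAnchors,
    detect_forward_tract,
    detect_reverse_tract,
    find_anchor,
    flank_indel_check,
)
from polytg.errors import AmbiguousAnchorError, AnchorNotFoundError
from polytg.model import SearchSpace, enumerate_genotypes, parse_genotype
from polytg.synthetic import SimulationSpec, simulate_read
from polytg.trace import orient_reverse, relative_intensities

from conftest import profile_from_rows

UP15 = reference.UPSTREAM_FLANK


def truncate_read(read: ChromatogramRead, n_bases: int) -> ChromatogramRead:
    peaks = read.peak_locations[:n_bases]
    cut = int(peaks[-1]) + 1
    return ChromatogramRead(
        sample_name=read.sample_name,
        direction=read.direction,
        called_bases=read.called_bases[:n_bases],
        peak_locations=peaks,
        traces={b: t[:cut] for b, t in read.traces.items()},
    )


class TestFindAnchor:
    def make_profile(self, seq):
        return profile_from_rows(list(seq))

    def test_exact_match_found(self, cfg):
        prof = self.make_profile("CCATT" + UP15 + "TGTGT")
        assert find_anchor(prof, UP15) == 5

    def test_random_sequence_not_found(self, cfg):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        prof = self.make_profile(seq)
        with pytest.raises(AnchorNotFoundError):
            find_anchor(prof, UP15)

    @pytest.mark.parametrize("n_mut,found", [(1, True), (2, True), (3, False)])
    def test_mismatch_tolerance_boundary(self, n_mut, found):
        mutated = list(UP15)
        for i in range(n_mut):  # flank has no 'N', flip to a different base
            mutated[2 + 4 * i] = "A" if mutated[2 + 4 * i] != "A" else "G"
        prof = self.make_profile("CCATT" + "".join(mutated) + "CGCGA")
        if found:
            assert find_anchor(prof, UP15, max_mismatch=2) == 5
        else:
            with pytest.raises(AnchorNotFoundError):
                find_anchor(prof, UP15, max_mismatch=2)

    def test_duplicate_anchor_is_ambiguous(self):
        prof = self.make_profile(UP15 + "ACCGA" + UP15)
        with pytest.raises(AmbiguousAnchorError):
            find_anchor(prof, UP15)

    def test_uninformative_positions_match_anything(self, cfg):
        rows = list("CCATT" + UP15 + "CGCGA")
        rows[7] = None  # inside the anchor window
        prof = profile_from_rows(rows)
        assert find_anchor(prof, UP15) == 5

    def test_anchors_unique_across_simulated_amplicons(self, cfg, anchors, pipeline):
        """The 15 bp flanks must not recur in the profiles the pipeline
        anchors on (homozygotes: both anchors in both directions; for
        heterozygotes only the in-register anchor of each direction is
        clean, which is exactly the one each scan uses)."""
        for label in ("(TG)8T3/(TG)8T3", "(TG)16T11/(TG)16T11"):
            _, _, prof_f, prof_r = pipeline(label)
            for prof in (prof_f, prof_r):
                find_anchor(prof, anchors.upstream15)  # raises if absent/ambiguous
                find_anchor(prof, anchors.downstream15)
        _, _, prof_f, prof_r = pipeline("(TG)12T5/(TG)11T9")
        find_anchor(prof_f, anchors.upstream15)
        find_anchor(prof_r, anchors.downstream15)


class TestForwardDetection:
    def test_noiseless_homozygote_exact_window(self, pipeline):
        tract_f, _, _, _ = pipeline("(TG)11T7/(TG)11T7")
        assert tract_f.length == 29 and tract_f.fully_detected

    def test_het_window_spans_longer_allele(self, pipeline):
        tract_f, _, _, _ = pipeline("(TG)12T5/(TG)11T9")
        assert tract_f.length == 31 and tract_f.fully_detected

    def test_truncated_read_partial_detection(self, cfg, anchors):
        read = simulate_read(SimulationSpec(genotype="(TG)11T7/(TG)11T7"), "forward")
        anchor_end = reference.LAYOUT.tract_start  # called == template, noiseless
        read = truncate_read(read, anchor_end + 10)
        prof = relative_intensities(read, cfg)
        tract = detect_forward_tract(prof, anchors, cfg)
        assert not tract.fully_detected
        assert tract.length == 10

    def test_low_signal_gap_does_not_shrink_window(self, cfg, anchors):
        read = simulate_read(SimulationSpec(genotype="(TG)11T7/(TG)11T7"), "forward")
        start = reference.LAYOUT.tract_start
        for base_idx in (start + 24, start + 25):  # two poly-T positions
            peak = int(read.peak_locations[base_idx])
            for b in "ACGT":
                read.traces[b][peak] = 0
        prof = relative_intensities(read, cfg)
        tract = detect_forward_tract(prof, anchors, cfg)
        assert tract.length == 29 and tract.fully_detected
        assert not tract.informative_mask[24] and not tract.informative_mask[25]


class TestReverseDetection:
    def test_noiseless_homozygote_exact_window(self, pipeline):
        _, tract_r, _, _ = pipeline("(TG)11T7/(TG)11T7")
        assert tract_r.length == 29 and tract_r.fully_detected

    def test_het_window_spans_shorter_allele(self, pipeline):
        """Right-aligned superposition: the shorter allele's upstream flank
        adenine terminates the leftward scan at the shorter length."""
        _, tract_r, _, _ = pipeline("(TG)12T5/(TG)11T9")
        assert tract_r.length == 29 and tract_r.fully_detected

    def test_no_terminator_within_cap_flags_partial(self, cfg, anchors):
        spec = SimulationSpec(
            genotype="(TG)11T7/(TG)11T7",
            context_5p="C" * 20 + "G" * 30 + "T" * 60,  # no adenine upstream
        )
        read = simulate_read(spec, "reverse")
        prof = orient_reverse(relative_intensities(read, cfg))
        tract = detect_reverse_tract(prof, anchors, cfg)
        assert not tract.fully_detected

    def test_detected_lengths_symmetric_across_grid(self, pipeline):
        """Noiseless homozygotes over a grid sample: both directions detect
        exactly 2m + n."""
        for g in enumerate_genotypes(SearchSpace(min_t=3, max_t=11, min_tg=8, max_tg=16)):
            if not g.is_homozygous:
                continue
            if (g.allele_a.m + g.allele_a.n) % 3:  # sample a third of the grid
                continue
            tract_f, tract_r, _, _ = pipeline(g.label)
            assert tract_f.length == tract_r.length == g.allele_a.length

    def test_het_window_lengths_bracket_allele_lengths(self, pipeline):
        """Noiseless heterozygotes: forward spans the longer allele,
        reverse the shorter; neither overshoots by more than 2."""
        for label in ("(TG)10T5/(TG)11T7", "(TG)8T3/(TG)16T11", "(TG)12T7/(TG)13T5"):
            g = parse_genotype(label)
            lo, hi = g.allele_a.length, g.allele_b.length
            tract_f, tract_r, _, _ = pipeline(label)
            assert tract_f.length == max(lo, hi)
            assert tract_r.length == min(lo, hi)


class TestFlankIndelQC:
    def test_clean_homozygote_not_flagged(self, cfg, anchors, pipeline):
        _, _, prof_f, prof_r = pipeline("(TG)11T7/(TG)11T7")
        assert not flank_indel_check(prof_f, anchors.upstream15, cfg).flagged
        assert not flank_indel_check(prof_r, anchors.downstream15, cfg).flagged

    def test_duplication_flags_reverse_side_anchor(self, cfg, anchors):
        """A heterozygous 4 bp duplication downstream of the tract smears
        the downstream anchor in the reverse chromatogram."""
        dup_at = reference.LAYOUT.tract_end + 40
        spec = SimulationSpec(genotype="(TG)11T7/(TG)11T7", extra_duplication=(dup_at, 4))
        rev = orient_reverse(
            relative_intensities(simulate_read(spec, "reverse"), cfg)
        )
        fwd = relative_intensities(simulate_read(spec, "forward"), cfg)
        assert flank_indel_check(rev, anchors.downstream15, cfg).flagged
        assert not flank_indel_check(fwd, anchors.upstream15, cfg).flagged

    def test_exactly_three_dirty_positions_not_flagged(self, cfg, anchors):
        def profile_with_dirty(k):
            rows = []
            for i, b in enumerate(UP15):
                if i < k:
                    other = "A" if b != "A" else "C"
                    rows.append({b: 0.6, other: 0.4})
                else:
                    rows.append(b)
            return profile_from_rows(rows + list("CCGAC"))

        assert not flank_indel_check(profile_with_dirty(3), UP15, cfg, anchor_start=0).flagged
        assert flank_indel_check(profile_with_dirty(4), UP15, cfg, anchor_start=0).flagged
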