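"""C2H2 annotation, helix-relative numbering, and profile scoring.

The published helix-relative labels for the CLAMP N-terminal finger
(H138 at -1 through T150 at +12, with helix position +1 at residue
139) are the ground truth for the numbering convention; the synthetic
CLAMP-like fragment in conftest places those residues at the published
coordinates.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fingermap import (
    Alignment,
    DataError,
    annotate_c2h2,
    atypicality_score,
    build_profile,
    dna_binding_residues,
    helix_position,
    information_content,
    residue_at_position,
    sample_alignment,
    ProfileSpec,
)
from fingermap.shift_io import AMINO_ACIDS

from conftest import CLAMP_LIKE_FRAGMENT, CLAMP_LIKE_START, TANDEM_FINGERS

# the nine published labels, from helix_start = 139
PUBLISHED_LABELS = {
    138: -1, 139: 1, 141: 3, 142: 4, 143: 5, 144: 6, 146: 8, 147: 9, 150: 12,
}


class TestAnnotate:
    def test_clamp_like_fragment(self, clamp_like_annotation):
        ann = clamp_like_annotation
        assert ann.helix_start == 139
        assert ann.his2 == 149  # the zinc-binding histidine H149
        assert ann.residue_type(149) == "H"

    def test_all_alanine_no_match(self):
        assert annotate_c2h2("A" * 40) == []

    def test_tandem_fingers_two_annotations(self):
        anns = annotate_c2h2(TANDEM_FINGERS, start=1)
        assert len(anns) == 2
        assert anns[0].his2 < anns[1].cys1
        assert anns[0].end < anns[1].start
        # both fingers anchor his1 at helix position +7
        for ann in anns:
            assert int(helix_position(ann.his1, ann)) == 7

    def test_short_sequence_errors(self):
        with pytest.raises(DataError, match="too short"):
            annotate_c2h2("CAACH")


class TestHelixPosition:
    @pytest.mark.parametrize("residue,expected", sorted(PUBLISHED_LABELS.items()))
    def test_published_labels(self, clamp_like_annotation, residue, expected):
        assert int(helix_position(residue, clamp_like_annotation)) == expected

    def test_no_zero_position(self, clamp_like_annotation):
        values = {
            int(helix_position(r, clamp_like_annotation))
            for r in range(clamp_like_annotation.start, clamp_like_annotation.end + 1)
        }
        assert 0 not in values

    def test_outside_span_errors(self, clamp_like_annotation):
        with pytest.raises(DataError, match="outside"):
            helix_position(200, clamp_like_annotation)

    def test_round_trip_bijection(self, clamp_like_annotation):
        ann = clamp_like_annotation
        for r in range(ann.start, ann.end + 1):
            pos = helix_position(r, ann)
            assert residue_at_position(ann, pos) == r

    def test_position_zero_rejected(self, clamp_like_annotation):
        with pytest.raises(DataError):
            residue_at_position(clamp_like_annotation, 0)

    def test_string_rendering(self, clamp_like_annotation):
        assert str(helix_position(146, clamp_like_annotation)) == "+8"
        assert str(helix_position(138, clamp_like_annotation)) == "-1"


class TestDnaBindingResidues:
    def test_clamp_like_positions(self, clamp_like_annotation):
        dna = dna_binding_residues(clamp_like_annotation)
        assert set(dna) == {-1, 1, 2, 3, 6}
        assert dna[-1] == (138, "H")
        assert dna[1] == (139, "L")
        assert dna[3] == (141, "L")
        assert dna[6] == (144, "A")

    def test_synthetic_helix_start_arithmetic(self):
        anns = annotate_c2h2(TANDEM_FINGERS, start=1)
        ann = anns[0]
        hs = ann.helix_start
        dna = dna_binding_residues(ann)
        assert [dna[p][0] for p in (-1, 1, 2, 3, 6)] == [hs - 1, hs, hs + 1, hs + 2, hs + 5]


class TestProfile:
    def test_single_sequence_no_pseudocount(self):
        aln = Alignment(["a"], ["ACD"])
        prof = build_profile(aln, pseudocount=0.0)
        assert prof.probability(0, "A") == 1.0
        assert prof.probability(1, "C") == 1.0
        assert prof.probability(2, "A") == 0.0

    def test_pseudocount_arithmetic(self):
        # column {A, A}, lam = 1, uniform q: p(A) = (2 + 0.05) / 3
        aln = Alignment(["a", "b"], ["A", "A"])
        prof = build_profile(aln, pseudocount=1.0)
        assert prof.probability(0, "A") == pytest.approx(2.05 / 3)
        assert prof.probability(0, "C") == pytest.approx(0.05 / 3)

    def test_columns_sum_to_one(self):
        spec = ProfileSpec(
            columns=[np.random.default_rng(3).dirichlet(np.ones(20)) for _ in range(6)],
            n_sequences=40,
            seed=3,
        )
        prof = build_profile(sample_alignment(spec))
        assert np.allclose(prof.columns.sum(axis=1), 1.0, atol=1e-9)

    def test_gaps_excluded_and_all_gap_flagged(self):
        aln = Alignment(["a", "b"], ["A-", "C-"])
        prof = build_profile(aln, pseudocount=0.0)
        assert prof.probability(0, "A") == 0.5
        assert prof.all_gap_columns == [1]
        assert np.allclose(prof.columns[1], prof.background)

    def test_ic_point_mass_and_uniform(self):
        aln = Alignment(["a", "b"], ["CA", "CG"])
        prof = build_profile(aln, pseudocount=0.0)
        ic = information_content(prof)
        assert ic[0] == pytest.approx(math.log2(20))
        uniform = Alignment(["x"], ["A"])
        p = build_profile(uniform, pseudocount=1e12)  # drowns the count: ~uniform
        assert information_content(p)[0] == pytest.approx(0.0, abs=1e-6)

    def test_ic_nonnegative(self):
        rng = np.random.default_rng(9)
        spec = ProfileSpec(
            columns=[rng.dirichlet(np.ones(20) * 0.3) for _ in range(10)],
            n_sequences=25,
            seed=9,
        )
        prof = build_profile(sample_alignment(spec))
        assert np.all(information_content(prof) >= -1e-12)


class TestAtypicality:
    def _finger_profile(self, clamp_like_annotation, peak=0.6):
        """Profile over the finger width with a favoured residue per column."""
        ann = clamp_like_annotation
        width = ann.end - ann.start + 1
        rng = np.random.default_rng(17)
        cols = []
        for c in range(width):
            col = np.full(20, (1 - peak) / 19)
            col[rng.integers(0, 20)] = peak
            cols.append(col / col.sum())
        prof = build_profile(
            sample_alignment(ProfileSpec(columns=cols, n_sequences=200, seed=18))
        )
        cmap = {p: residue_at_position(ann, p) - ann.start for p in (-1, 1, 2, 3, 6)}
        return prof, cmap

    def test_score_zero_when_p_equals_background(self, clamp_like_annotation):
        ann = clamp_like_annotation
        width = ann.end - ann.start + 1
        uniform = np.full(20, 0.05)
        from fingermap.zf_domain import PositionProfile

        prof = PositionProfile(np.tile(uniform, (width, 1)), uniform, 1.0)
        cmap = {p: residue_at_position(ann, p) - ann.start for p in (-1, 1, 2, 3, 6)}
        score = atypicality_score(ann, prof, cmap, n_samples=0)
        assert score.total == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(0.0) for v in score.per_position.values())

    def test_known_log_odds(self, clamp_like_annotation):
        # query probability 0.01 vs background 0.05 -> log2(0.2)
        ann = clamp_like_annotation
        width = ann.end - ann.start + 1
        from fingermap.zf_domain import PositionProfile
        from fingermap.shift_io import AMINO_ACIDS as AAS

        uniform = np.full(20, 0.05)
        cols = np.tile(uniform, (width, 1))
        cmap = {p: residue_at_position(ann, p) - ann.start for p in (-1, 1, 2, 3, 6)}
        col = cmap[1]
        aa = ann.residue_type(residue_at_position(ann, 1))
        idx = AAS.index(aa)
        cols[col] = (1 - 0.01) / 19
        cols[col, idx] = 0.01
        prof = PositionProfile(cols, uniform, 1.0)
        score = atypicality_score(ann, prof, cmap, n_samples=0)
        assert score.per_position[1] == pytest.approx(math.log2(0.2), abs=1e-12)

    def test_argmax_query_maximal(self, clamp_like_annotation):
        prof, cmap = self._finger_profile(clamp_like_annotation)
        ann = clamp_like_annotation
        # build the columnwise most-probable query sequence
        best_total = 0.0
        for p, col in cmap.items():
            best_total += float(np.max(np.log2(prof.columns[col] / prof.background)))
        score = atypicality_score(ann, prof, cmap, n_samples=0)
        assert score.total <= best_total + 1e-12

    def test_unmapped_position_errors(self, clamp_like_annotation):
        prof, cmap = self._finger_profile(clamp_like_annotation)
        del cmap[6]
        with pytest.raises(DataError, match="position 6"):
            atypicality_score(clamp_like_annotation, prof, cmap)

    def test_null_percentile_uniform(self, clamp_like_annotation):
        """Percentile of profile-sampled queries is ~U(0,1) under the null.

        Uses a diffuse (Dirichlet) profile so the null total-score
        distribution is effectively continuous, and the same mid-rank
        tie handling as the scoring routine.
        """
        ann = clamp_like_annotation
        width = ann.end - ann.start + 1
        rng = np.random.default_rng(55)
        cols = [rng.dirichlet(np.ones(20)) for _ in range(width)]
        from fingermap.zf_domain import PositionProfile

        prof = PositionProfile(np.array(cols), np.full(20, 0.05), 1.0)
        cmap = {p: residue_at_position(ann, p) - ann.start for p in (-1, 1, 2, 3, 6)}
        logodds = np.log2(prof.columns / prof.background)
        n = 2000
        ref = np.zeros(n)
        query = np.zeros(n)
        for p, col in cmap.items():
            ref += logodds[col, rng.choice(20, size=n, p=prof.columns[col])]
            query += logodds[col, rng.choice(20, size=n, p=prof.columns[col])]
        ref_sorted = np.sort(ref)
        less = np.searchsorted(ref_sorted, query, side="left")
        leq = np.searchsorted(ref_sorted, query, side="right")
        percentiles = (less + 0.5 * (leq - less)) / n
        from scipy import stats

        ks = stats.kstest(percentiles, "uniform")
        assert ks.pvalue > 0.01
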