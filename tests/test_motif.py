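"""Count/probability/information matrices, chi-square filtering, logos."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinamotif import motif, synthetic
from kinamotif._alphabet import AA_INDEX, AMINO_ACIDS, offset_to_row
from kinamotif.exceptions import KinamotifError, TooFewPeptidesError
from kinamotif.motif import (
    Background,
    background_from_dataset,
    build_logo,
    build_profile,
    chisq_cell,
    count_matrix,
    information_matrix,
    kinase_class,
    position_information,
    probability_matrix,
)
from kinamotif.seqio import CenteredPeptide

LOG2_20 = math.log2(20)


def chi2_sf_df1(stat: float) -> float:
    """Independent closed-form survival function for chi-square, df=1."""
    return math.erfc(math.sqrt(stat / 2.0))


class TestCountMatrix:
    def test_j_counted_separately(self):
        peps = [CenteredPeptide("JJJJJJSTYJJJJ")] * 2
        cm = count_matrix(peps)
        assert cm.counts[offset_to_row(0), AA_INDEX["S"]] == 2
        assert cm.counts[offset_to_row(1), AA_INDEX["T"]] == 2
        assert cm.counts[offset_to_row(2), AA_INDEX["Y"]] == 2
        assert cm.counts.sum() == 6
        assert cm.j_counts[offset_to_row(-6)] == 2
        assert cm.effective_n[offset_to_row(-6)] == 0

    def test_single_peptide_unit_mass(self):
        cm = count_matrix([CenteredPeptide("ACDEFGSIKLMNP")])
        assert (cm.counts.sum(axis=1) == 1).all()
        assert (cm.j_counts == 0).all()

    def test_empty_rejected(self):
        with pytest.raises(KinamotifError):
            count_matrix([])

    def test_column_totals_invariant(self, rng):
        from conftest import random_peptide
        peps = [random_peptide(rng, n_j_prefix=int(rng.integers(0, 6)))
                for _ in range(40)]
        cm = count_matrix(peps)
        assert (cm.counts.sum(axis=1) + cm.j_counts == cm.n).all()


class TestBackground:
    def test_degenerate_composition(self):
        peps = [CenteredPeptide("AAAAAASAAAAAA")] * 5
        bg = background_from_dataset(peps)
        assert bg.b[AA_INDEX["A"]] > 0.99
        assert bg.b.min() >= motif.BACKGROUND_FLOOR / 2
        assert bg.b.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_residue_symmetry(self):
        peps = [CenteredPeptide("AAAAAASAAAAAA"), CenteredPeptide("CCCCCCSCCCCCC")]
        bg = background_from_dataset(peps)
        assert bg.b[AA_INDEX["A"]] == pytest.approx(0.5, abs=1e-4)
        assert bg.b[AA_INDEX["C"]] == pytest.approx(0.5, abs=1e-4)

    def test_uniform_law_of_large_numbers(self):
        """Uniform sampling at n=2000 gives each b(i) within 3 SE of 0.05."""
        pwm = synthetic.GeneratorPWM(
            "U", synthetic._uniform_pwm("ST"), "ST")
        peps = synthetic.sample_peptides(pwm, 2000, seed=42)
        bg = background_from_dataset(peps)
        n_obs = 2000 * 12  # 12 flank positions
        se = math.sqrt(0.05 * 0.95 / n_obs)
        assert np.all(np.abs(bg.b - 0.05) < 3 * se)

    def test_center_excluded(self):
        peps = [CenteredPeptide("ACDEFGSIKLMNP")]
        bg = background_from_dataset(peps)
        assert bg.b[AA_INDEX["S"]] < 0.01  # S only at center here


class TestProbabilityMatrix:
    def test_single_peptide_point_mass(self):
        cm = count_matrix([CenteredPeptide("ACDEFGSIKLMNP")])
        pm = probability_matrix(cm)
        assert pm.p.max() == 1.0
        assert (pm.p.sum(axis=1) == 1.0).all()

    def test_arithmetic(self):
        peps = [CenteredPeptide("RRRRRRSAAAAAA")] * 15 + [
            CenteredPeptide("KKKKKKSAAAAAA")] * 15
        pm = probability_matrix(count_matrix(peps))
        assert pm.p[offset_to_row(-3), AA_INDEX["R"]] == pytest.approx(0.5)

    def test_all_j_column_unusable_even_with_pseudocount(self):
        cm = count_matrix([CenteredPeptide("JJJJJJSTYJJJJ")])
        pm = probability_matrix(cm, pseudocount=1.0)
        row = offset_to_row(-6)
        assert not pm.usable[row]
        assert pm.p[row].sum() == 0.0

    def test_negative_pseudocount_rejected(self):
        cm = count_matrix([CenteredPeptide("ACDEFGSIKLMNP")])
        with pytest.raises(KinamotifError):
            probability_matrix(cm, pseudocount=-0.1)


class TestPositionInformation:
    def test_closed_forms(self):
        single = np.zeros(20); single[0] = 1.0
        assert position_information(single) == pytest.approx(LOG2_20, abs=1e-9)
        uniform = np.full(20, 0.05)
        assert position_information(uniform) == pytest.approx(0.0, abs=1e-9)
        two = np.zeros(20); two[0] = two[1] = 0.5
        assert position_information(two) == pytest.approx(LOG2_20 - 1, abs=1e-9)

    def test_unusable_column_zero(self):
        assert position_information(np.zeros(20)) == 0.0

    def test_bad_sum_rejected(self):
        with pytest.raises(KinamotifError):
            position_information(np.full(20, 0.06))

    @given(st.lists(st.floats(0.01, 10.0), min_size=20, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_and_height_decomposition(self, raw):
        p = np.array(raw); p /= p.sum()
        R = position_information(p)
        assert -1e-9 <= R <= LOG2_20 + 1e-9
        # heights sum back to R
        assert (p * R).sum() == pytest.approx(R, abs=1e-9)


class TestChisqCell:
    def test_hand_arithmetic_extreme(self):
        stat, p, direction = chisq_cell(30, 30, 0.05)
        assert stat == pytest.approx(570.0, abs=1e-9)
        assert p < 1e-4 and direction == "enriched"

    def test_hand_arithmetic_small(self):
        stat, p, direction = chisq_cell(2, 30, 0.05)
        expected = 0.25 / 1.5 + 0.25 / 28.5
        assert stat == pytest.approx(expected, rel=1e-12)
        assert stat == pytest.approx(0.1754, abs=1e-4)
        assert p == pytest.approx(0.675, abs=1e-3)
        assert direction == "enriched"

    def test_exact_expectation_is_null(self):
        stat, p, direction = chisq_cell(3, 60, 0.05)
        assert stat == 0.0 and p == 1.0 and direction == "none"

    @pytest.mark.parametrize("observed,n,b", [
        (o, n, b)
        for o in (0, 1, 5, 15, 30)
        for n in (30, 100)
        for b in (0.01, 0.05, 0.2)
    ])
    def test_p_matches_independent_oracle(self, observed, n, b):
        stat, p, _ = chisq_cell(observed, n, b)
        oracle = chi2_sf_df1(stat)
        assert p == pytest.approx(oracle, rel=1e-10, abs=1e-300)

    def test_monotone_in_deviation(self):
        stats = [chisq_cell(o, 100, 0.05)[0] for o in range(5, 31, 5)]
        assert all(b > a for a, b in zip(stats, stats[1:]))

    def test_observed_exceeding_n_rejected(self):
        with pytest.raises(KinamotifError):
            chisq_cell(31, 30, 0.05)


class TestBuildLogo:
    def test_sharp_motif_all_flanks_enriched(self):
        peps = [CenteredPeptide("RRRRRRSAAAAAA")] * 30
        lm = build_logo(count_matrix(peps), Background.uniform(), alpha=1e-4)
        cells = lm.logo_cells()
        for off in range(-6, 0):
            assert (off, "R") in cells
        for off in range(1, 7):
            assert (off, "A") in cells
        assert not any(off == 0 for off, _ in cells)
        assert not any(off == 0 for off, _ in lm.antilogo_cells())

    def test_uniform_input_mostly_empty(self):
        pwm = synthetic.GeneratorPWM("U", synthetic._uniform_pwm("ST"), "ST")
        peps = synthetic.sample_peptides(pwm, 30, seed=3)
        lm = build_logo(count_matrix(peps), Background.uniform(), alpha=1e-4)
        assert lm.logo == [] and lm.antilogo == []

    def test_logo_antilogo_disjoint_and_directed(self, rng):
        pwm = synthetic.preset_pwm("acidophilic", 0.9)
        peps = synthetic.sample_peptides(pwm, 150, seed=9)
        cm = count_matrix(peps)
        bg = background_from_dataset(peps)
        lm = build_logo(cm, bg, alpha=1e-3)
        assert lm.logo_cells() & lm.antilogo_cells() == set()
        eff = cm.effective_n
        for cell in lm.logo:
            row = offset_to_row(cell.offset)
            obs = cm.counts[row, AA_INDEX[cell.residue]]
            assert obs > eff[row] * bg.b[AA_INDEX[cell.residue]]
        for cell in lm.antilogo:
            row = offset_to_row(cell.offset)
            obs = cm.counts[row, AA_INDEX[cell.residue]]
            assert obs < eff[row] * bg.b[AA_INDEX[cell.residue]]
            assert cell.height > 0

    def test_bad_alpha_rejected(self):
        peps = [CenteredPeptide("RRRRRRSAAAAAA")]
        with pytest.raises(KinamotifError):
            build_logo(count_matrix(peps), Background.uniform(), alpha=0.0)


class TestKinaseClass:
    @pytest.mark.parametrize("centers,expected", [
        ("SST", "ST"), ("YYY", "Y"), ("SY", "ST"), ("SYY", "Y"),
    ])
    def test_majority_rule(self, centers, expected):
        peps = [CenteredPeptide("AAAAAA" + c + "AAAAAA") for c in centers]
        assert kinase_class(peps) == expected


class TestBuildProfile:
    def test_identical_peptides_saturated_heights(self):
        peps = [CenteredPeptide("ACDEFGSIKLMNP")] * 30
        prof = build_profile("X", peps, background=Background.uniform())
        h = prof.information.heights
        for row, ch in enumerate("ACDEFGSIKLMNP"):
            assert h[row, AA_INDEX[ch]] == pytest.approx(LOG2_20, abs=1e-9)
        assert h.sum() == pytest.approx(13 * LOG2_20, abs=1e-6)

    def test_min_n_enforced(self):
        peps = [CenteredPeptide("ACDEFGSIKLMNP")] * 29
        with pytest.raises(TooFewPeptidesError) as exc:
            build_profile("X", peps)
        assert exc.value.n == 29 and exc.value.min_n == 30

    def test_dominant_residue_recovered(self):
        pwm = synthetic.preset_pwm("basophilic", 0.9)
        peps = synthetic.sample_peptides(pwm, 200, seed=5)
        prof = build_profile("PKAlike", peps, background=Background.uniform())
        h = prof.information.heights
        top = AMINO_ACIDS[int(np.argmax(h[offset_to_row(-3)]))]
        assert top in "RK"

    def test_probability_and_information_invariants(self, rng):
        """Columns sum to 1, 0 <= R <= log2 20, heights sum to R."""
        from conftest import random_peptide
        peps = [random_peptide(rng) for _ in range(60)]
        prof = build_profile("R", peps, background=Background.uniform())
        p = prof.probabilities.p
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(prof.information.R >= -1e-12)
        assert np.all(prof.information.R <= LOG2_20 + 1e-12)
        assert np.allclose(prof.information.heights.sum(axis=1),
                           prof.information.R, atol=1e-9)
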