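import numpy as np
import pytest

from epiqtl.core_map import (ChromosomeMap, GenotypeMatrix, LinkageMap,
                             kosambi_r_from_d)
from epiqtl.qtl_prob import (ConditionalProbMatrix, DegenerateCorrectionError,
                             MultipointEngine, correct_conditional_probs,
                             expected_dummies, insert_virtual_markers,
                             multipoint_qtl_probs, position_fitness)
from epiqtl.sdl_model import FitnessTriple, ViabilityParams, marginal_fitness


def flank_oracle(code_left, code_right, d_left, d_right):
    """Posterior of the 3 genotype classes at an interior position given
    two flanking codominant markers, by exhaustive enumeration of the
    female and male strand allele configurations (Kosambi r per strand
    and interval, no selection)."""
    rl, rr = kosambi_r_from_d(d_left), kosambi_r_from_d(d_right)

    def strand(a_left, a_mid, a_right):
        p = 0.5
        p *= rl if a_left != a_mid else 1 - rl
        p *= rr if a_mid != a_right else 1 - rr
        return p

    compat = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}
    post = np.zeros(3)
    for fl, ml in compat[code_left]:
        for fr, mr in compat[code_right]:
            for fm in (0, 1):
                for mm in (0, 1):
                    p = strand(fl, fm, fr) * strand(ml, mm, mr)
                    post[fm + mm] += p
    return post / post.sum()


@pytest.fixture(scope="module")
def three_marker_setup():
    lmap = LinkageMap([ChromosomeMap("1", ["L", "M", "R"],
                                     np.array([0.0, 10.0, 20.0]))])

    def genotypes_for(code_left, code_right):
        codes = np.array([[code_left, 5, code_right]], dtype=np.int8)
        return GenotypeMatrix(codes, ["i1"], ["L", "M", "R"])

    return lmap, genotypes_for


class TestMultipointProbs:
    def test_codominant_marker_is_deterministic(self, three_marker_setup):
        lmap, gfor = three_marker_setup
        for code, expected in [(0, [1, 0, 0]), (1, [0, 1, 0]), (2, [0, 0, 1])]:
            g = GenotypeMatrix(np.array([[code, code, code]], dtype=np.int8),
                               ["i1"], ["L", "M", "R"])
            cpm = multipoint_qtl_probs(g, lmap, "1", 10.0)
            assert np.allclose(cpm.probs3[0, 0], expected)

    def test_all_missing_gives_mendelian_prior(self):
        lmap = LinkageMap([ChromosomeMap("1", ["a", "b"], [0.0, 20.0])])
        g = GenotypeMatrix(np.array([[5, 5]], dtype=np.int8), ["i1"],
                           ["a", "b"])
        cpm = multipoint_qtl_probs(g, lmap, "1", 10.0)
        assert np.allclose(cpm.probs3[0, 0], [0.25, 0.5, 0.25])

    @pytest.mark.parametrize("cl,cr", [(0, 0), (0, 2), (1, 1), (2, 1), (0, 1)])
    @pytest.mark.parametrize("query,dl,dr", [(10.0, 10.0, 10.0),
                                             (5.0, 5.0, 15.0)])
    def test_interior_position_matches_enumeration_oracle(
            self, cl, cr, query, dl, dr):
        lmap = LinkageMap([ChromosomeMap("1", ["L", "R"],
                                         np.array([0.0, 20.0]))])
        g = GenotypeMatrix(np.array([[cl, cr]], dtype=np.int8), ["i1"],
                           ["L", "R"])
        cpm = multipoint_qtl_probs(g, lmap, "1", query)
        oracle = flank_oracle(cl, cr, dl, dr)
        assert np.allclose(cpm.probs3[0, 0], oracle, atol=1e-12)

    def test_dominant_code_excludes_one_homozygote(self, three_marker_setup):
        lmap, _ = three_marker_setup
        g = GenotypeMatrix(np.array([[3, 5, 5]], dtype=np.int8), ["i1"],
                           ["L", "M", "R"])
        p = multipoint_qtl_probs(g, lmap, "1", 0.0).probs3[0, 0]
        assert p[2] == 0.0
        assert p[0] == pytest.approx(1 / 3)
        assert p[1] == pytest.approx(2 / 3)

    def test_rows_sum_to_one_everywhere(self, distorted_dataset):
        g, y, lmap, _ = distorted_dataset
        eng = MultipointEngine(lmap.chromosomes[0], g,
                               extra_positions=np.arange(0.5, 100, 7.0))
        post = eng.posteriors()
        assert np.allclose(post.sum(axis=2), 1.0, atol=1e-10)

    def test_pair_joint_consistent_with_marginals(self, distorted_dataset):
        g, y, lmap, _ = distorted_dataset
        eng = MultipointEngine(lmap.chromosomes[0], g,
                               extra_positions=[22.5, 27.5])
        joint = eng.pair_joint(22.5, 27.5)
        post = eng.posteriors()
        iA, iB = eng.locus_index(22.5), eng.locus_index(27.5)
        assert np.allclose(joint.sum(axis=2), post[:, iA], atol=1e-9)
        assert np.allclose(joint.sum(axis=1), post[:, iB], atol=1e-9)

    def test_position_outside_span_rejected(self, three_marker_setup):
        lmap, gfor = three_marker_setup
        with pytest.raises(ValueError, match="span"):
            multipoint_qtl_probs(gfor(0, 0), lmap, "1", 25.0)


class TestInsertVirtualMarkers:
    def test_five_cm_gap_at_unit_step(self):
        lmap = LinkageMap([ChromosomeMap("1", ["a", "b"], [0.0, 5.0])])
        grid = insert_virtual_markers(lmap, max_gap=1.0)
        assert np.allclose(grid.positions["1"], [0, 1, 2, 3, 4, 5])
        assert grid.is_virtual["1"].tolist() == [False, True, True, True,
                                                 True, False]

    def test_small_gap_untouched(self):
        lmap = LinkageMap([ChromosomeMap("1", ["a", "b"], [0.0, 0.8])])
        grid = insert_virtual_markers(lmap, max_gap=1.0)
        assert np.allclose(grid.positions["1"], [0.0, 0.8])

    def test_spacing_bound_and_even_spacing(self):
        lmap = LinkageMap([ChromosomeMap("1", ["a", "b"], [0.0, 7.0])])
        grid = insert_virtual_markers(lmap, max_gap=2.0)
        pos = grid.positions["1"]
        gaps = np.diff(pos)
        assert np.all(gaps <= 2.0 + 1e-12)
        assert np.allclose(gaps, gaps[0])

    def test_invalid_gap_rejected(self, small_map):
        with pytest.raises(ValueError):
            insert_virtual_markers(small_map, max_gap=0.0)


class TestPositionFitness:
    def test_overlap_reduces_to_marginal_fitness(self):
        params = ViabilityParams(0.4, 0.7, 0.3, kosambi_r_from_d(10.0))
        at_sdl1 = position_fitness(params, (20.0, 30.0), 20.0)
        marg = marginal_fitness(params, "A")
        assert at_sdl1.f2 == pytest.approx(marg.f2, abs=1e-12)
        assert at_sdl1.f4 == pytest.approx(marg.f4, abs=1e-12)
        at_sdl2 = position_fitness(params, (20.0, 30.0), 30.0)
        margB = marginal_fitness(params, "B")
        assert at_sdl2.f4 == pytest.approx(margB.f4, abs=1e-12)

    def test_neutral_params_give_unity_everywhere(self):
        params = ViabilityParams(1, 1, 1, 0.1)
        for pos in (0.0, 25.0, 80.0):
            assert position_fitness(params, (20.0, 30.0), pos).is_neutral

    def test_unlinked_position_tends_to_neutral(self):
        params = ViabilityParams(0.2, 0.2, 0.2, kosambi_r_from_d(10.0))
        far = position_fitness(params, (20.0, 30.0), 2000.0)
        assert far.f2 == pytest.approx(1.0, abs=1e-3)

    def test_other_chromosome_is_neutral(self):
        params = ViabilityParams(0.2, 0.2, 0.2, 0.1)
        ft = position_fitness(params, (20.0, 30.0), 25.0,
                              qtl_chrom_same=False)
        assert ft.is_neutral

    def test_between_sdl_matches_three_point_enumeration(self):
        """Independent oracle: enumerate male haplotypes over the three
        ordered loci explicitly."""
        u = v = x = 0.5
        r1 = kosambi_r_from_d(5.0)   # 20 -> 25
        r2 = kosambi_r_from_d(5.0)   # 25 -> 30
        qQ = qq = 0.0
        for s1 in (0, 1):
            for m in (0, 1):
                for s2 in (0, 1):
                    p = 0.5
                    p *= r1 if s1 != m else 1 - r1
                    p *= r2 if m != s2 else 1 - r2
                    w = {(0, 0): 1.0, (0, 1): v, (1, 0): u, (1, 1): x}[(s1, s2)]
                    if m == 0:
                        qQ += w * p
                    else:
                        qq += w * p
        expected = (qq / qQ)
        params = ViabilityParams(u, v, x, kosambi_r_from_d(10.0))
        ft = position_fitness(params, (20.0, 30.0), 25.0)
        assert ft.f2 == pytest.approx(expected, abs=1e-12)
        assert ft.f4 == pytest.approx(expected, abs=1e-12)
        assert ft.f3 == 1.0


class TestCorrection:
    def test_neutral_fitness_is_identity(self):
        p = np.array([[0.25, 0.5, 0.25], [0.1, 0.2, 0.7]])
        out = correct_conditional_probs(p, FitnessTriple(1.0, 1.0, 1.0))
        assert np.array_equal(out, p)

    def test_lethal_class_removed_and_renormalized(self):
        out = correct_conditional_probs(np.array([[0.25, 0.5, 0.25]]),
                                        FitnessTriple(1.0, 1.0, 0.0))
        assert np.allclose(out, [[1 / 3, 2 / 3, 0.0]])

    def test_worked_weighted_renormalization(self):
        out = correct_conditional_probs(
            np.array([[0.25, 0.5, 0.25]]),
            FitnessTriple(0.555556, 1.0, 0.555556))
        assert np.allclose(out, [[0.321429, 0.5, 0.178571]], atol=1e-6)

    def test_idempotent_through_neutral_pass(self):
        ft = FitnessTriple(0.6, 1.0, 0.6)
        p = np.array([[0.2, 0.5, 0.3]])
        once = correct_conditional_probs(p, ft)
        roundtrip = correct_conditional_probs(
            correct_conditional_probs(once, FitnessTriple(1, 1, 1)),
            FitnessTriple(1, 1, 1))
        assert np.allclose(once, roundtrip, atol=1e-15)

    def test_degenerate_row_raises_with_row_report(self):
        with pytest.raises(DegenerateCorrectionError, match="0"):
            correct_conditional_probs(np.array([[0.0, 0.0, 1.0]]),
                                      FitnessTriple(1.0, 1.0, 0.0))

    def test_matrix_variant_matches_three_class_rule(self, distorted_dataset):
        g, y, lmap, _ = distorted_dataset
        cpm = multipoint_qtl_probs(g, lmap, "1", 23.0)
        ft = FitnessTriple(0.5, 1.0, 0.5)
        by_matrix = correct_conditional_probs(cpm, ft).probs3[:, 0, :]
        by_rows = correct_conditional_probs(cpm.probs3[:, 0, :], ft)
        assert np.allclose(by_matrix, by_rows, atol=1e-12)


class TestExpectedDummies:
    def test_dummy_coding(self, distorted_dataset):
        g, y, lmap, _ = distorted_dataset
        cpm = multipoint_qtl_probs(g, lmap, "1", 23.0)
        dm = expected_dummies(cpm)
        p3 = cpm.probs3[:, 0, :]
        assert np.allclose(dm.z[:, 0], p3[:, 0] - p3[:, 2])
        assert np.allclose(dm.w[:, 0], p3[:, 1])
        assert np.all(np.abs(dm.z) <= 1.0) and np.all((dm.w >= 0)
                                                      & (dm.w <= 1))

    def test_worked_values(self):
        cpm = ConditionalProbMatrix(
            chrom="1", positions=np.array([0.0]),
            probs4=np.array([[[0.321429, 0.25, 0.25, 0.178571]]]))
        dm = expected_dummies(cpm)
        assert dm.z[0, 0] == pytest.approx(0.142858, abs=1e-6)
        assert dm.w[0, 0] == pytest.approx(0.5)
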