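import itertools
import math

import numpy as np
import pytest

from funregnet.genome_io import PromoterRecord
from funregnet.pwm_scan import (
    BackgroundModel,
    FrequencyMatrix,
    estimate_background,
    read_cisbp_matrix,
    scan_promoter,
    score_distribution,
    to_log_odds,
)

BASES = "ACGT"
RC = str.maketrans("ACGT", "TGCA")


def promoter(seq, gene_id="g1"):
    return PromoterRecord(gene_id, "c", (0, len(seq)), "+", seq, truncated=False)


def random_matrix(rng, width, matrix_id="Mrand"):
    probs = rng.dirichlet(np.ones(4), size=width)
    return FrequencyMatrix(matrix_id, matrix_id, probs)


def consensus_matrix(word, p=0.97, matrix_id="Mcons"):
    other = (1 - p) / 3
    probs = np.full((len(word), 4), other)
    for i, b in enumerate(word):
        probs[i, BASES.index(b)] = p
    return FrequencyMatrix(matrix_id, matrix_id, probs)


def brute_force_survival(lom, bg):
    """Exact survival over all 4^w words on the same quantized score lattice."""
    w = lom.width
    mass: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=w):
        q = int(sum(lom.qscores[i, b] for i, b in enumerate(word)))
        p = math.prod(bg.probs[b] for b in word)
        mass[q] = mass.get(q, 0.0) + p
    scores = sorted(mass)
    surv = {}
    acc = 0.0
    for s in reversed(scores):
        acc += mass[s]
        surv[s] = acc
    return surv


class TestReadCisbp:
    def test_three_row_matrix_parsed(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text(
            "Pos\tA\tC\tG\tT\n1\t0.25\t0.25\t0.25\t0.25\n"
            "2\t0.97\t0.01\t0.01\t0.01\n3\t0.1\t0.2\t0.3\t0.4\n"
        )
        m = read_cisbp_matrix(p)
        assert m.width == 3
        np.testing.assert_allclose(m.probs.sum(axis=1), 1.0)

    def test_counts_dialect_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("Pos\tA\tC\tG\tT\n1\t8\t0\t0\t0\n")
        with pytest.raises(ValueError, match="not a frequency row"):
            read_cisbp_matrix(p)

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("Pos\tA\tC\tG\tT\n1\t0.25\tx\t0.25\t0.25\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_cisbp_matrix(p)


class TestToLogOdds:
    def test_uniform_position_uniform_bg_scores_zero(self):
        m = FrequencyMatrix("m", "m", np.full((2, 4), 0.25))
        lom = to_log_odds(m, BackgroundModel.uniform(), pseudocount=0.0)
        np.testing.assert_allclose(lom.scores, 0.0, atol=1e-12)

    def test_certain_base_scores_two_bits(self):
        probs = np.array([[1.0, 0.0, 0.0, 0.0]])
        m = FrequencyMatrix("m", "m", probs)
        lom = to_log_odds(m, BackgroundModel.uniform(), pseudocount=1e-9)
        assert lom.scores[0, 0] == pytest.approx(2.0, abs=1e-6)  # log2(1/0.25)
        with pytest.raises(ValueError, match="pseudocount"):
            to_log_odds(m, BackgroundModel.uniform(), pseudocount=0.0)

    def test_larger_pseudocount_shrinks_scores_toward_zero(self, rng):
        m = random_matrix(rng, 5)
        bg = BackgroundModel.uniform()
        s1 = to_log_odds(m, bg, pseudocount=0.01).scores
        s2 = to_log_odds(m, bg, pseudocount=0.02).scores
        assert (np.abs(s2) <= np.abs(s1) + 1e-12).all()


class TestScoreDistribution:
    def test_width_one_point_mass(self):
        probs = np.array([[0.97, 0.01, 0.01, 0.01]])
        m = FrequencyMatrix("m", "m", probs)
        bg = BackgroundModel.uniform()
        lom = to_log_odds(m, bg)
        dist = score_distribution(lom, bg)
        # only A reaches the top score; survival there is bg[A] = 0.25
        assert dist.p_value(int(lom.qscores[0, 0])) == pytest.approx(0.25)

    def test_uniform_matrix_survival_one_at_zero(self):
        m = FrequencyMatrix("m", "m", np.full((4, 4), 0.25))
        bg = BackgroundModel.uniform()
        lom = to_log_odds(m, bg, pseudocount=0.0)
        dist = score_distribution(lom, bg)
        assert dist.p_value(0) == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5, 6])
    @pytest.mark.parametrize("bg_probs", [
        (0.25, 0.25, 0.25, 0.25),
        (0.3, 0.2, 0.2, 0.3),
        (0.1, 0.4, 0.4, 0.1),
    ])
    def test_dp_equals_brute_force_enumeration(self, width, bg_probs, rng):
        """Exact-DP survival equals enumeration over all 4^w words."""
        m = random_matrix(rng, width)
        bg = BackgroundModel(np.array(bg_probs))
        lom = to_log_odds(m, bg)
        dist = score_distribution(lom, bg)
        oracle = brute_force_survival(lom, bg)
        for q, s in oracle.items():
            assert dist.p_value(q) == pytest.approx(s, abs=1e-12)

    def test_pmf_sums_to_one_and_survival_monotone(self, rng):
        m = random_matrix(rng, 8)
        bg = BackgroundModel(np.array([0.2, 0.3, 0.3, 0.2]))
        lom = to_log_odds(m, bg)
        dist = score_distribution(lom, bg)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(dist.survival) <= 1e-15).all()
        assert dist.survival[0] == pytest.approx(1.0)

    def test_granularity_mismatch_rejected(self, rng):
        m = random_matrix(rng, 3)
        bg = BackgroundModel.uniform()
        lom = to_log_odds(m, bg, granularity=0.001)
        with pytest.raises(ValueError, match="granularity"):
            score_distribution(lom, bg, granularity=0.01)


class TestScanPromoter:
    def setup_scan(self, word="GATTACAAG", bg=None):
        bg = bg or BackgroundModel.uniform()
        m = consensus_matrix(word)
        lom = to_log_odds(m, bg)
        dist = score_distribution(lom, bg)
        return m, lom, dist

    def test_short_promoter_empty(self):
        _, lom, dist = self.setup_scan()
        assert scan_promoter(promoter("ACGT"), lom, dist) == []

    def test_planted_site_found_with_oracle_scan(self, rng):
        """A planted consensus word is the unique hit, confirmed by a
        brute-force sliding-window rescan."""
        word = "GATTACAAG"
        _, lom, dist = self.setup_scan(word)
        seq = "".join(BASES[i] for i in rng.integers(4, size=300))
        seq = seq[:100] + word + seq[100 + len(word):]
        hits = scan_promoter(promoter(seq), lom, dist)
        plus = [h for h in hits if h.strand == "+"]
        assert [h.offset for h in plus] == [100]
        assert plus[0].p_value < 1e-4
        assert plus[0].word == word
        # oracle: rescan every window by direct score lookup
        w = lom.width
        for off in range(len(seq) - w + 1):
            q = sum(int(lom.qscores[i, BASES.index(seq[off + i])]) for i in range(w))
            expected_hit = dist.p_value(q) <= 1e-4
            assert (off in [h.offset for h in plus]) == expected_hit

    def test_strand_symmetry(self, rng):
        """Scanning the reverse complement yields mirrored offsets and
        flipped strands."""
        _, lom, dist = self.setup_scan()
        seq = "".join(BASES[i] for i in rng.integers(4, size=200))
        seq = seq[:50] + "GATTACAAG" + seq[59:]
        hits = scan_promoter(promoter(seq), lom, dist)
        rc = seq.translate(RC)[::-1]
        rc_hits = scan_promoter(promoter(rc), lom, dist)
        L, w = len(seq), lom.width
        mirrored = {(L - w - h.offset, "-" if h.strand == "+" else "+") for h in hits}
        assert {(h.offset, h.strand) for h in rc_hits} == mirrored

    def test_non_acgt_windows_skipped(self):
        word = "GATTACAAG"
        _, lom, dist = self.setup_scan(word)
        seq = "N" * 20 + word + "N" * 20
        hits = scan_promoter(promoter(seq), lom, dist)
        assert [h.offset for h in hits if h.strand == "+"] == [20]

    def test_lowering_threshold_never_adds_hits(self, rng):
        _, lom, dist = self.setup_scan()
        seq = "".join(BASES[i] for i in rng.integers(4, size=2000))
        prev = None
        for thr in (1e-2, 1e-3, 1e-4, 1e-6):
            keys = {
                (h.offset, h.strand)
                for h in scan_promoter(promoter(seq), lom, dist, p_threshold=thr)
            }
            if prev is not None:
                assert keys <= prev
            prev = keys


class TestBackground:
    def test_estimate_background_matches_composition(self):
        bg = estimate_background(["AAAA", "CCGG", "TTTT"])
        assert bg.probs.sum() == pytest.approx(1.0)
        assert bg.probs[0] > bg.probs[1]  # more A than C

    def test_zero_entries_guarded(self):
        bg = estimate_background(["AAAA"])
        assert (bg.probs > 0).all()  # pseudocount keeps all bases possible
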