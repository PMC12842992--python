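import numpy as np
import pytest

from fungpcr.interaction import (
    PDOCKQ2_CONSTANTS,
    assess_heterotrimer,
    assess_pair,
    best_of_models,
    interface_contacts,
    interface_residues,
    pdockq2_chain,
    ranking_confidence,
)
from fungpcr.io_formats import AfMetrics
from fungpcr.synthetic import make_af_fixture


def pdockq2_formula(x):
    """Direct evaluation of the published sigmoid (independent oracle)."""
    c = PDOCKQ2_CONSTANTS
    return c["L"] / (1 + np.exp(-c["k"] * (x - c["x0"]))) + c["b"]


class TestRankingConfidence:
    def test_weighted_combination(self):
        assert ranking_confidence(ptm=0.8, iptm=0.9) == pytest.approx(0.88)

    def test_identity_on_equal_inputs(self):
        for x in (0.0, 0.3, 1.0):
            assert ranking_confidence(x, x) == pytest.approx(x)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            ranking_confidence(1.2, 0.5)

    def test_linear_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p, i = rng.uniform(0, 1, 2)
            v = ranking_confidence(p, i)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(0.8 * i + 0.2 * p)


class TestInterfaceDetection:
    def test_designed_contacts_match_brute_force(self, af_pair_good):
        structure, _ = af_pair_good
        contacts = set(interface_contacts(structure, "A", "B"))
        # brute-force all-pairs distance oracle on the CA coordinates
        a = structure[structure.chain_id == "A"].coord
        b = structure[structure.chain_id == "B"].coord
        expected = {
            (i, j)
            for i in range(len(a)) for j in range(len(b))
            if np.linalg.norm(a[i] - b[j]) <= 8.0
        }
        assert contacts == expected
        assert contacts  # the designed patch is non-empty

    def test_detached_chains_no_interface(self):
        structure, _ = make_af_fixture(2, q=1.0, seed=2, detached=True)
        ra, rb = interface_residues(structure, "A", "B")
        assert ra == set() and rb == set()

    def test_missing_chain_errors(self, af_pair_good):
        structure, _ = af_pair_good
        with pytest.raises(ValueError, match="chain 'Z'"):
            interface_residues(structure, "A", "Z")


class TestPdockq2:
    def test_ideal_interface_matches_formula_maximum(self, af_pair_good):
        structure, metrics = af_pair_good
        score, has_if = pdockq2_chain(metrics, structure, "A")
        assert has_if
        # oracle: pLDDT=100 everywhere, interface PAE=1.0
        pae_term = 1.0 / (1.0 + (1.0 / PDOCKQ2_CONSTANTS["d0"]) ** 2)
        assert score == pytest.approx(pdockq2_formula(100.0 * pae_term),
                                      abs=1e-6)

    def test_terrible_pae_near_minimal(self):
        structure, metrics = make_af_fixture(2, q=1.0, seed=5)
        bad = AfMetrics(ptm=metrics.ptm, iptm=metrics.iptm,
                        plddt=metrics.plddt,
                        pae=np.full_like(metrics.pae, 30.0),
                        chain_ranges=metrics.chain_ranges)
        score, _ = pdockq2_chain(bad, structure, "A")
        pae_term = 1.0 / (1.0 + (30.0 / PDOCKQ2_CONSTANTS["d0"]) ** 2)
        assert score == pytest.approx(pdockq2_formula(100.0 * pae_term),
                                      abs=1e-6)
        assert score < 0.02

    def test_no_interface_scores_zero_with_flag(self):
        structure, metrics = make_af_fixture(2, q=1.0, seed=3, detached=True)
        score, has_if = pdockq2_chain(metrics, structure, "A")
        assert score == 0.0 and has_if is False

    def test_monotone_in_uniform_pae_shift(self, af_pair_good):
        structure, metrics = af_pair_good
        scores = []
        for shift in (0.0, 5.0, 10.0, 20.0):
            shifted = AfMetrics(ptm=metrics.ptm, iptm=metrics.iptm,
                                plddt=metrics.plddt,
                                pae=metrics.pae + shift,
                                chain_ranges=metrics.chain_ranges)
            scores.append(pdockq2_chain(shifted, structure, "A")[0])
        assert scores == sorted(scores, reverse=True)

    def test_monotone_in_uniform_plddt(self, af_pair_good):
        structure, metrics = af_pair_good
        scores = []
        for plddt in (40.0, 60.0, 80.0, 100.0):
            m = AfMetrics(ptm=metrics.ptm, iptm=metrics.iptm,
                          plddt=np.full_like(metrics.plddt, plddt),
                          pae=metrics.pae,
                          chain_ranges=metrics.chain_ranges)
            scores.append(pdockq2_chain(m, structure, "A")[0])
        assert scores == sorted(scores)


class TestAssessments:
    def test_good_pair_high_confidence(self, af_pair_good):
        structure, metrics = af_pair_good
        a = assess_pair(metrics, structure)
        assert a.high_confidence_interface is True
        assert a.min_pdockq2 > 0.23
        assert a.tier == "top" and a.plddt_high is True

    def test_bad_pair_rejected(self, af_pair_bad):
        structure, metrics = af_pair_bad
        a = assess_pair(metrics, structure)
        assert a.high_confidence_interface is False
        assert a.tier == "none" and a.plddt_high is False

    def test_min_rule_on_chain_scores(self, af_pair_good):
        structure, metrics = af_pair_good
        a = assess_pair(metrics, structure)
        assert a.min_pdockq2 == pytest.approx(min(a.pdockq2.values()))

    def test_heterotrimer_requires_all_four_chains(self):
        structure, metrics = make_af_fixture(4, q=1.0, seed=6)
        a = assess_heterotrimer(metrics, structure)
        assert len(a.pdockq2) == 4
        assert a.high_confidence_interface is True
        # degrade one chain's interface PAE only -> verdict flips
        pae = metrics.pae.copy()
        lo, hi = metrics.chain_ranges["D"]
        pae[lo - 1:hi, :] = 30.0
        pae[:, lo - 1:hi] = 30.0
        degraded = AfMetrics(ptm=metrics.ptm, iptm=metrics.iptm,
                             plddt=metrics.plddt, pae=pae,
                             chain_ranges=metrics.chain_ranges)
        a2 = assess_heterotrimer(degraded, structure)
        assert a2.pdockq2["D"] < 0.23 < a2.pdockq2["B"]
        assert a2.high_confidence_interface is False

    def test_wrong_chain_count_errors(self, af_pair_good):
        structure, metrics = af_pair_good
        with pytest.raises(ValueError, match="expected 4"):
            assess_heterotrimer(metrics, structure)

    def test_best_of_models_takes_max_confidence(self, af_pair_good,
                                                 af_pair_bad):
        sg, mg = af_pair_good
        sb, mb = af_pair_bad
        best = best_of_models([assess_pair(mb, sb), assess_pair(mg, sg)])
        assert best.tier == "top"


class TestTierBoundaries:
    @pytest.mark.parametrize("q, expected_hc", [(1.0, True), (0.0, False)])
    def test_quality_dial_controls_verdict(self, q, expected_hc):
        structure, metrics = make_af_fixture(2, q=q, seed=8)
        a = assess_pair(metrics, structure)
        assert a.high_confidence_interface is expected_hc
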