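"""EM haplotype frequencies, D'/r2, confidence intervals and Gabriel blocks."""

import numpy as np
import pytest

from divscan import (
    block_haplotypes,
    d_measures,
    dprime_ci,
    gabriel_blocks,
    two_locus_em,
)
from divscan.ld import classify_pair, haplotype_em
from divscan.model import MISSING

from conftest import make_markers, make_model


def template_fixture(freqs, n=200, n_snps=5, noise=0.0, seed=0, templates=None):
    """Genotypes built from haplotype templates at the given frequencies."""
    rng = np.random.default_rng(seed)
    if templates is None:
        templates = np.zeros((len(freqs), n_snps), dtype=np.int8)
        templates[0] = 1  # all-B vs all-a by default
    templates = np.asarray(templates)
    pick = rng.choice(len(freqs), size=(n, 2), p=freqs)
    h1 = templates[pick[:, 0]].copy()
    h2 = templates[pick[:, 1]].copy()
    if noise:
        for h in (h1, h2):
            flip = rng.random(h.shape) < noise
            h[flip] = 1 - h[flip]
    return (h1 + h2).astype(np.int8)


class TestTwoLocusEm:
    def test_phase_known_equals_gamete_counting(self):
        # no double heterozygotes: frequencies are direct counts
        v = np.array([[2, 2], [2, 2], [0, 0], [0, 0], [2, 0], [1, 0]])
        freqs = two_locus_em(v)
        # gametes: BB x4 +.. count: rows (2,2)x2 -> 4 BB; (0,0)x2 -> 4 ab;
        # (2,0) -> 2 Ab; (1,0) -> 1 Ab + 1 ab
        assert freqs == pytest.approx(np.array([4, 3, 0, 5]) / 12)

    def test_em_beats_grid_search(self, rng):
        for seed in range(5):
            v = template_fixture([0.6, 0.4], n=60, n_snps=2, noise=0.1,
                                 seed=seed)
            freqs = two_locus_em(v)
            ll_em = _loglik(v, freqs)
            # grid over the one free parameter with margins fixed
            pA = v[:, 0].mean() / 2
            pB = v[:, 1].mean() / 2
            best = -np.inf
            for fab in np.linspace(0, min(pA, pB), 401):
                f = np.array([fab, pA - fab, pB - fab, 1 - pA - pB + fab])
                if (f < -1e-12).any():
                    continue
                best = max(best, _loglik(v, np.clip(f, 1e-12, None)))
            assert ll_em >= best - 1e-6

    def test_permutation_invariance(self, rng):
        v = template_fixture([0.5, 0.5], n=50, n_snps=2, noise=0.05, seed=3)
        perm = rng.permutation(len(v))
        assert two_locus_em(v) == pytest.approx(two_locus_em(v[perm]), abs=1e-9)

    def test_no_complete_observations_raises(self):
        v = np.full((5, 2), MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            two_locus_em(v)

    def test_loglik_monotone(self):
        v = template_fixture([0.5, 0.3, 0.2], n=80, n_snps=2, noise=0.1,
                             seed=1, templates=[[1, 1], [0, 1], [0, 0]])
        _, trace = haplotype_em(v, return_loglik=True)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


def _loglik(v, f):
    from divscan.ld import _class_probs

    p = np.clip(_class_probs(np.asarray(f, dtype=float)), 1e-300, None)
    return sum(np.log(p[g1, g2]) for g1, g2 in v)


class TestDMeasures:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((0.25, 0.25, 0.25, 0.25), (0.0, 0.0, 0.0)),
            ((0.5, 0.0, 0.0, 0.5), (0.25, 1.0, 1.0)),
            ((0.4, 0.1, 0.1, 0.4), (0.15, 0.6, 0.36)),
        ],
    )
    def test_definitional_values(self, freqs, expected):
        d, dp, r2 = d_measures(freqs)
        assert (d, dp, r2) == pytest.approx(expected)

    def test_monomorphic_locus_flagged_undefined(self):
        d, dp, r2 = d_measures((0.5, 0.5, 0.0, 0.0))  # locus 1 fixed for B
        assert d == 0.0 and np.isnan(dp) and np.isnan(r2)

    def test_r2_one_implies_dprime_one(self, rng):
        for _ in range(50):
            f = rng.dirichlet(np.ones(4))
            d, dp, r2 = d_measures(f)
            if np.isfinite(r2) and r2 > 1 - 1e-9:
                assert dp == pytest.approx(1.0)


class TestDprimeCi:
    def test_perfect_ld_fixture(self):
        v = template_fixture([0.6, 0.4], n=300, n_snps=2, seed=5)
        lo, hi = dprime_ci(v)
        assert hi == pytest.approx(1.0)
        assert lo >= 0.98

    def test_independent_loci_fixture(self, rng):
        v = rng.binomial(2, 0.5, size=(400, 2)).astype(np.int8)
        lo, hi = dprime_ci(v)
        assert hi < 0.9

    def test_bounds_ordered(self, rng):
        for seed in range(8):
            v = template_fixture([0.5, 0.5], n=40, n_snps=2, noise=0.3,
                                 seed=seed)
            if len(set(v[:, 0])) == 1 or len(set(v[:, 1])) == 1:
                continue
            lo, hi = dprime_ci(v)
            assert 0.0 <= lo <= hi <= 1.0

    def test_monomorphic_margin_raises(self):
        v = np.column_stack([np.ones(30, dtype=np.int8) * 2,
                             np.random.default_rng(0).binomial(2, 0.5, 30)])
        with pytest.raises(ValueError):
            dprime_ci(v.astype(np.int8))


class TestGabrielBlocks:
    def test_two_template_fixture_single_block(self):
        v = template_fixture([0.5, 0.5], n=200, n_snps=5, noise=0.01, seed=2)
        markers = make_markers(5, spacing=20_000)
        g = make_model(v, markers=markers)
        blocks = gabriel_blocks(markers, g)
        assert len(blocks) == 1
        assert blocks[0].n_markers == 5
        assert blocks[0].top_hap_freq == pytest.approx(0.5, abs=0.05)

    def test_independent_snps_no_blocks(self):
        found = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            v = rng.binomial(2, rng.uniform(0.2, 0.8, 20),
                             size=(200, 20)).astype(np.int8)
            markers = make_markers(20, spacing=20_000)
            blocks = gabriel_blocks(markers, make_model(v, markers=markers))
            found += len(blocks)
        assert found == 0

    def test_span_cap_blocks_nothing_beyond_500kb(self):
        v = template_fixture([0.5, 0.5], n=200, n_snps=2, noise=0.0, seed=4)
        markers = make_markers(2, spacing=600_000)
        blocks = gabriel_blocks(markers, make_model(v, markers=markers))
        assert blocks == []

    def test_blocks_satisfy_their_definition(self):
        # re-check every reported block with an independent classifier pass
        v = template_fixture([0.6, 0.4], n=150, n_snps=6, noise=0.02, seed=9)
        markers = make_markers(6, spacing=30_000)
        g = make_model(v, markers=markers)
        for b in gabriel_blocks(markers, g):
            idx = b.marker_indices
            informative = strong = 0
            for x in range(len(idx)):
                for y in range(x + 1, len(idx)):
                    lo, hi = dprime_ci(g.values[:, [idx[x], idx[y]]])
                    c = classify_pair(lo, hi)
                    if c != "uninformative":
                        informative += 1
                        strong += c == "strong_ld"
            assert informative >= 3
            assert strong / informative >= 0.95
            lo, hi = dprime_ci(g.values[:, [idx[0], idx[-1]]])
            assert classify_pair(lo, hi) == "strong_ld"

    def test_allele_flip_invariance(self):
        v = template_fixture([0.5, 0.5], n=120, n_snps=4, noise=0.02, seed=6)
        markers = make_markers(4, spacing=30_000)
        b1 = gabriel_blocks(markers, make_model(v, markers=markers))
        v2 = v.copy()
        v2[:, 1] = 2 - v2[:, 1]  # flip allele coding at one SNP
        b2 = gabriel_blocks(markers, make_model(v2, markers=markers))
        assert [(b.start_bp, b.stop_bp, b.n_markers) for b in b1] == \
            [(b.start_bp, b.stop_bp, b.n_markers) for b in b2]
        if b1:
            assert b1[0].top_hap_freq == pytest.approx(b2[0].top_hap_freq,
                                                       abs=1e-6)


class TestBlockHaplotypes:
    def test_phase_unambiguous_equals_enumeration(self):
        # at most one het per individual: phase is known
        v = np.array([[2, 2, 2], [0, 0, 0], [2, 2, 2], [1, 2, 2]])
        haps = block_haplotypes(v)
        d = dict(haps)
        assert d["BBB"] == pytest.approx(5 / 8)
        assert d["aaa"] == pytest.approx(2 / 8)
        assert d["aBB"] == pytest.approx(1 / 8)

    def test_seventy_thirty_fixture(self):
        v = template_fixture([0.7, 0.3], n=200, n_snps=5, noise=0.01, seed=11)
        haps = block_haplotypes(v)
        assert haps[0][1] == pytest.approx(0.7, abs=0.03)

    def test_frequencies_sum_at_most_one(self, rng):
        v = template_fixture([0.4, 0.35, 0.25], n=100, n_snps=4, noise=0.05,
                             seed=8, templates=rng.integers(0, 2, (3, 4)))
        haps = block_haplotypes(v)
        assert sum(f for _, f in haps) <= 1 + 1e-9

    def test_wide_span_truncated_with_warning(self, rng):
        v = rng.binomial(1, 0.5, size=(30, 14)).astype(np.int8)
        with pytest.warns(UserWarning, match="truncated"):
            haps = block_haplotypes(v)
        assert all(len(s) == 12 for s, _ in haps)
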