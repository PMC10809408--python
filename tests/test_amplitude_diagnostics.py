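import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noodiag import (
    AmplitudeSet,
    ExtremeOccupations,
    approx_density_blocks,
    d2_diagnostic,
    extreme_occupations,
    indmax_from_blocks,
    mp2_density_blocks,
    predict_indmax_from_d2,
    sample_amplitudes,
)
from noodiag.errors import DimensionError, InvalidOccupancyError, SymmetryError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def loop_density_corrections(t2, exchange=True):
    """Index-loop contraction of the second-order density corrections."""
    no, nv = t2.shape[0], t2.shape[2]
    occ = np.zeros((no, no))
    vir = np.zeros((nv, nv))
    for i in range(no):
        for j in range(no):
            acc = 0.0
            for k in range(no):
                for a in range(nv):
                    for b in range(nv):
                        tbar = 2.0 * t2[i, k, a, b]
                        if exchange:
                            tbar -= t2[i, k, b, a]
                        acc += tbar * t2[j, k, a, b]
            occ[i, j] = -2.0 * acc
    for a in range(nv):
        for b in range(nv):
            acc = 0.0
            for i in range(no):
                for j in range(no):
                    for c in range(nv):
                        tbar = 2.0 * t2[i, j, a, c]
                        if exchange:
                            tbar -= t2[j, i, a, c]
                        acc += tbar * t2[i, j, b, c]
            vir[a, b] = 2.0 * acc
    return occ, vir


def svd_d2_oracle(t2):
    """Dense-SVD spectral norms of both matricizations."""
    no, nv = t2.shape[0], t2.shape[2]
    per_occ = max(
        np.linalg.svd(t2[i].transpose(1, 0, 2).reshape(nv, no * nv),
                      compute_uv=False)[0]
        for i in range(no)
    )
    compound = np.linalg.svd(t2.reshape(no * no, nv * nv), compute_uv=False)[0]
    return per_occ, compound


class TestAmplitudeSet:
    def test_shape_guard(self):
        with pytest.raises(DimensionError):
            AmplitudeSet(np.zeros((2, 3, 4, 4)))
        with pytest.raises(DimensionError):
            AmplitudeSet(np.zeros((0, 0, 2, 2)))

    def test_asymmetric_input_symmetrized_with_warning(self, rng):
        t2 = rng.standard_normal((2, 2, 3, 3))
        with pytest.warns(UserWarning, match="symmetrizing"):
            amp = AmplitudeSet(t2)
        assert np.allclose(amp.t2, amp.t2.transpose(1, 0, 3, 2))

    def test_sampler_tensor_is_symmetric_and_reproducible(self):
        a = sample_amplitudes(3, 4, scale=0.1, seed=11)
        b = sample_amplitudes(3, 4, scale=0.1, seed=11)
        assert np.array_equal(a.t2, b.t2)
        assert np.array_equal(a.t2, a.t2.transpose(1, 0, 3, 2))


class TestD2:
    def test_zero_amplitudes(self):
        amp = AmplitudeSet(np.zeros((2, 2, 3, 3)))
        assert d2_diagnostic(amp).value == 0.0
        assert d2_diagnostic(amp, "compound").value == 0.0

    def test_single_amplitude_under_both_matricizations(self):
        t2 = np.zeros((2, 2, 2, 2))
        t2[0, 0, 0, 0] = 0.1
        amp = AmplitudeSet(t2)
        assert d2_diagnostic(amp, "ref20").value == pytest.approx(0.1, abs=1e-15)
        assert d2_diagnostic(amp, "compound").value == pytest.approx(0.1, abs=1e-15)

    def test_matches_dense_svd_oracle(self, rng):
        for seed in range(5):
            amp = sample_amplitudes(3, 4, scale=0.2, seed=seed)
            per_occ, compound = svd_d2_oracle(amp.t2)
            assert d2_diagnostic(amp, "ref20").value == pytest.approx(
                per_occ, abs=1e-12
            )
            assert d2_diagnostic(amp, "compound").value == pytest.approx(
                compound, abs=1e-12
            )

    def test_relabeling_invariance(self, rng):
        amp = sample_amplitudes(3, 4, scale=0.1, seed=3)
        perm_o = rng.permutation(3)
        perm_v = rng.permutation(4)
        t2 = amp.t2[np.ix_(perm_o, perm_o, perm_v, perm_v)]
        relabeled = AmplitudeSet(t2)
        for mat in ("ref20", "compound"):
            assert d2_diagnostic(relabeled, mat).value == pytest.approx(
                d2_diagnostic(amp, mat).value, abs=1e-12
            )

    def test_unknown_matricization_rejected(self):
        amp = AmplitudeSet(np.zeros((1, 1, 1, 1)))
        with pytest.raises(ValueError, match="matricization"):
            d2_diagnostic(amp, "frobenius")

    @given(st.floats(0.1, 4.0), st.integers(0, 100))
    @settings(max_examples=25)
    def test_scale_equivariance(self, factor, seed):
        amp = sample_amplitudes(2, 3, scale=0.05, seed=seed)
        scaled = AmplitudeSet(factor * amp.t2)
        assert d2_diagnostic(scaled).value == pytest.approx(
            factor * d2_diagnostic(amp).value, rel=1e-12
        )


class TestDensityBlocks:
    def test_hf_limit(self):
        amp = AmplitudeSet(np.zeros((3, 3, 2, 2)))
        blocks = mp2_density_blocks(amp)
        assert np.array_equal(blocks.occ_block, 2.0 * np.eye(3))
        assert np.array_equal(blocks.vir_block, np.zeros((2, 2)))
        approx = approx_density_blocks(amp)
        assert np.array_equal(approx.occ_block, blocks.occ_block)
        assert np.array_equal(approx.vir_block, blocks.vir_block)

    def test_single_amplitude_hand_contraction(self):
        # t_11^11 = tau: only surviving contraction is the diagonal one,
        # tbar*t = (2tau - tau)*tau = tau^2, so corrections are -+2 tau^2
        tau = 0.1
        t2 = np.zeros((2, 2, 2, 2))
        t2[0, 0, 0, 0] = tau
        blocks = mp2_density_blocks(AmplitudeSet(t2))
        assert blocks.occ_block[0, 0] == pytest.approx(2 - 2 * tau**2, abs=1e-15)
        assert blocks.vir_block[0, 0] == pytest.approx(2 * tau**2, abs=1e-15)
        assert np.trace(blocks.occ_block) + np.trace(blocks.vir_block) == (
            pytest.approx(4.0, abs=1e-15)
        )
        # the approximate blocks drop the exchange part: factor 4 instead of 2
        approx = approx_density_blocks(AmplitudeSet(t2))
        assert approx.occ_block[0, 0] == pytest.approx(2 - 4 * tau**2, abs=1e-15)
        assert approx.vir_block[0, 0] == pytest.approx(4 * tau**2, abs=1e-15)

    @pytest.mark.parametrize("exchange", [True, False])
    def test_contractions_match_loop_oracle(self, exchange):
        build = mp2_density_blocks if exchange else approx_density_blocks
        for seed in range(3):
            amp = sample_amplitudes(3, 4, scale=0.15, seed=seed)
            occ_ref, vir_ref = loop_density_corrections(amp.t2, exchange=exchange)
            blocks = build(amp)
            assert np.allclose(
                blocks.occ_block, 2 * np.eye(3) + occ_ref, atol=1e-12
            )
            assert np.allclose(blocks.vir_block, vir_ref, atol=1e-12)

    def test_trace_conservation(self):
        for seed in range(20):
            amp = sample_amplitudes(4, 5, scale=0.1, seed=seed)
            blocks = mp2_density_blocks(amp)
            total = np.trace(blocks.occ_block) + np.trace(blocks.vir_block)
            assert total == pytest.approx(2 * amp.n_occ, abs=1e-12)


class TestExtremeOccupations:
    def test_hf_limit(self):
        amp = AmplitudeSet(np.zeros((3, 3, 2, 2)))
        x = extreme_occupations(mp2_density_blocks(amp))
        assert (x.n_H, x.n_L) == (2.0, 0.0)

    def test_single_amplitude_rank_one_structure(self):
        tau = 0.1
        t2 = np.zeros((2, 2, 2, 2))
        t2[0, 0, 0, 0] = tau
        occ_ref, vir_ref = loop_density_corrections(t2)
        lam = -occ_ref[0, 0]
        x = extreme_occupations(mp2_density_blocks(AmplitudeSet(t2)))
        assert x.n_H == pytest.approx(2.0 - lam, abs=1e-14)
        assert x.n_L == pytest.approx(vir_ref[0, 0], abs=1e-14)

    def test_matches_eigensolver_oracle(self):
        for seed in range(5):
            amp = sample_amplitudes(3, 4, scale=0.1, seed=seed)
            blocks = mp2_density_blocks(amp)
            x = extreme_occupations(blocks)
            assert x.n_H == pytest.approx(
                float(np.min(np.linalg.eigvalsh(blocks.occ_block))), abs=1e-12
            )
            assert x.n_L == pytest.approx(
                float(np.max(np.linalg.eigvalsh(blocks.vir_block))), abs=1e-12
            )

    def test_non_symmetric_blocks_rejected(self):
        from noodiag import DensityBlocks

        with pytest.raises(SymmetryError):
            DensityBlocks(
                occ_block=np.array([[2.0, 0.1], [0.0, 2.0]]),
                vir_block=np.zeros((2, 2)),
                approximate=False,
            )

    def test_approximation_overestimates_correlation(self):
        for seed in range(50):
            amp = sample_amplitudes(3, 4, scale=0.08, seed=seed)
            full = extreme_occupations(mp2_density_blocks(amp))
            approx = extreme_occupations(approx_density_blocks(amp))
            assert approx.n_H <= full.n_H + 1e-10
            assert approx.n_L >= full.n_L - 1e-10

    def test_overestimation_grows_with_amplitude_scale(self):
        gaps = []
        for scale in (0.01, 0.05, 0.1, 0.2):
            gap = 0.0
            for seed in range(30):
                amp = sample_amplitudes(3, 4, scale=scale, seed=seed)
                gap += (
                    extreme_occupations(mp2_density_blocks(amp)).n_H
                    - extreme_occupations(approx_density_blocks(amp)).n_H
                )
            gaps.append(gap / 30)
        assert all(a < b for a, b in zip(gaps, gaps[1:]))


class TestIndmaxFromBlocks:
    @pytest.mark.parametrize(
        "n_h,n_l,expected",
        [(2.0, 0.0, 0.0), (1.0, 1.0, 0.125), (1.98, 0.02, 0.00495)],
    )
    def test_direct_values(self, n_h, n_l, expected):
        x = ExtremeOccupations(n_H=n_h, n_L=n_l, approximate=False)
        assert indmax_from_blocks(x) == pytest.approx(expected, abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidOccupancyError):
            indmax_from_blocks(ExtremeOccupations(n_H=2.5, n_L=0.0, approximate=False))

    def test_agrees_with_full_spectrum_when_extreme_dominates(self):
        amp = sample_amplitudes(3, 4, scale=0.1, seed=2)
        blocks = mp2_density_blocks(amp)
        from noodiag import natural_occupations, nd_max

        occ_set = natural_occupations(
            0.5 * np.block([
                [blocks.occ_block, np.zeros((3, 4))],
                [np.zeros((4, 3)), blocks.vir_block],
            ])
        )
        x = extreme_occupations(blocks)
        assert indmax_from_blocks(x) == pytest.approx(nd_max(occ_set), abs=1e-12)


class TestD2Bridge:
    def test_zero_at_zero(self):
        assert predict_indmax_from_d2(0.0) == 0.0

    def test_monotone_through_thresholds(self):
        assert predict_indmax_from_d2(0.18) > predict_indmax_from_d2(0.15) > 0

    def test_nondecreasing_on_unit_interval(self):
        grid = np.linspace(0.0, 1.0, 101)
        vals = [predict_indmax_from_d2(x) for x in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_rank_correlation_with_computed_indmax(self):
        from scipy.stats import spearmanr

        d2_vals, indmax_vals = [], []
        for seed in range(120):
            rng = np.random.default_rng(1000 + seed)
            scale = rng.uniform(0.01, 0.12)
            amp = sample_amplitudes(3, 4, scale=scale, seed=2000 + seed)
            d2 = d2_diagnostic(amp).value
            if d2 > 0.4:
                continue
            d2_vals.append(d2)
            indmax_vals.append(
                indmax_from_blocks(extreme_occupations(mp2_density_blocks(amp)))
            )
        assert len(d2_vals) > 80
        rho = spearmanr(d2_vals, indmax_vals).statistic
        assert rho >= 0.9
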