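"""Reweighting: series weights, weighted histograms, free energies, minima."""

import math

import numpy as np
import pytest

from confland import gamd_reweight as gr
from confland import synthetic_data as sd
from confland.errors import ConfigError, DegenerateInputError, InputError

KT = gr.kT_at(300.0)


class TestWeights:
    def test_zero_boost_gives_unit_weight_any_order(self):
        for order in (0, 1, 5, 10):
            assert gr.maclaurin_weights(np.zeros(3), KT, order=order) == pytest.approx(
                [1.0, 1.0, 1.0]
            )

    def test_partial_sum_arithmetic(self):
        w = gr.maclaurin_weights(np.array([KT]), KT, order=2)  # dV/kT = 1
        assert w[0] == pytest.approx(1 + 1 + 0.5, abs=1e-12)

    def test_order_10_close_to_exponential(self):
        w = gr.maclaurin_weights(np.array([KT]), KT, order=10)
        assert abs(w[0] - math.e) < 1e-7

    def test_exact_weights_identities(self):
        assert gr.exact_weights(np.array([0.0]), KT)[0] == 1.0
        assert gr.exact_weights(np.array([KT * math.log(2)]), KT)[0] == pytest.approx(
            2.0
        )

    def test_vectorised_matches_scalar_calls(self):
        dv = np.array([0.0, 0.3, 1.7])
        vec = gr.exact_weights(dv, KT)
        sca = [gr.exact_weights(np.array([v]), KT)[0] for v in dv]
        assert np.array_equal(vec, np.array(sca))

    def test_negative_boost_rejected(self):
        with pytest.raises(InputError):
            gr.maclaurin_weights(np.array([-0.1]), KT)
        with pytest.raises(ConfigError):
            gr.maclaurin_weights(np.array([0.1]), KT, order=-1)


class TestWeightedHistogram:
    def _ensemble(self, cvs):
        return gr.BoostedEnsemble(cv=np.asarray(cvs), dv_total=np.zeros(len(cvs)))

    def test_uniform_weights_equal_raw_frequencies(self):
        ens = self._ensemble([0.1, 0.1, 0.9, 0.9, 0.9])
        hist = gr.reweight_histogram(
            ens, bins=[np.array([0.0, 0.5, 1.0])], weights=np.ones(5)
        )
        assert hist.p.ravel() == pytest.approx([0.4, 0.6])

    def test_weighted_two_bin_arithmetic(self):
        ens = self._ensemble([0.1, 0.2, 0.9])
        hist = gr.reweight_histogram(
            ens, bins=[np.array([0.0, 0.5, 1.0])], weights=np.array([2.0, 2.0, 1.0])
        )
        assert hist.p.ravel() == pytest.approx([0.8, 0.2])

    def test_normalisation_exact(self, harmonic_ensemble):
        w = gr.maclaurin_weights(harmonic_ensemble.dv_total, KT, 10)
        hist = gr.reweight_histogram(harmonic_ensemble, bins=50, weights=w)
        assert abs(hist.p.sum() - 1.0) < 1e-12

    def test_all_zero_weights_degenerate(self):
        ens = self._ensemble([0.1, 0.9])
        with pytest.raises(DegenerateInputError):
            gr.reweight_histogram(ens, bins=4, weights=np.zeros(2))

    def test_constant_boost_shift_changes_nothing(self, harmonic_ensemble):
        w0 = gr.exact_weights(harmonic_ensemble.dv_total, KT)
        w1 = gr.exact_weights(harmonic_ensemble.dv_total + 1.5, KT)
        h0 = gr.reweight_histogram(harmonic_ensemble, bins=40, weights=w0)
        h1 = gr.reweight_histogram(harmonic_ensemble, bins=40, weights=w1)
        assert np.allclose(h0.p, h1.p, atol=1e-12)


class TestFreeEnergy:
    def _landscape_from_p(self, p, counts=None, kT=1.0):
        p = np.asarray(p, dtype=float)
        counts = np.asarray(counts if counts is not None else np.full(p.shape, 100))
        hist = gr.WeightedHistogram(
            edges=(np.arange(p.size + 1, dtype=float),), counts=counts, p=p
        )
        return gr.free_energy(hist, kT=kT)

    def test_equal_probabilities_flat(self):
        L = self._landscape_from_p([0.5, 0.5])
        assert L.free_energy == pytest.approx([0.0, 0.0])

    def test_log_identity(self):
        c = 1.0 / (1.0 + math.exp(-1.0))
        L = self._landscape_from_p([c * math.exp(-1.0), c], kT=1.0)
        assert L.free_energy == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_low_count_bins_masked(self):
        L = self._landscape_from_p([0.5, 0.3, 0.2], counts=[100, 100, 3])
        assert not L.mask[2]
        assert np.isnan(L.free_energy[2])

    def test_harmonic_recovery_within_band(self, harmonic_ensemble):
        """Order-10 reweighted landscape matches V(x) - V_min over F <= 3."""
        w = gr.maclaurin_weights(harmonic_ensemble.dv_total, KT, 10)
        hist = gr.reweight_histogram(harmonic_ensemble, bins=50, weights=w)
        L = gr.free_energy(hist, KT)
        x = hist.centers(0)
        V = 2.0 * (x - 3.0) ** 2
        sel = L.mask & (L.free_energy <= 3.0)
        assert sel.sum() > 5
        err = np.abs(L.free_energy[sel] - (V[sel] - V[L.mask].min()))
        assert err.max() < 0.3

    def test_maclaurin_error_non_increasing_with_order(self, harmonic_ensemble):
        """Mean |PMF error| improves monotonically: order 0 -> 2 -> 10."""
        errors = []
        for order in (0, 2, 10):
            w = gr.maclaurin_weights(harmonic_ensemble.dv_total, KT, order)
            hist = gr.reweight_histogram(harmonic_ensemble, bins=50, weights=w)
            L = gr.free_energy(hist, KT)
            x = hist.centers(0)
            V = 2.0 * (x - 3.0) ** 2
            sel = L.mask & (L.free_energy <= 3.0)
            errors.append(
                float(np.mean(np.abs(L.free_energy[sel] - (V[sel] - V[L.mask].min()))))
            )
        assert errors[0] >= errors[1] >= errors[2]

    def test_order10_matches_exact_oracle(self, harmonic_ensemble):
        """Maclaurin >= 10 equals the exact-exponential landscape per bin."""
        dv = harmonic_ensemble.dv_total
        assert dv.max() / KT < 3.5  # regime where the comparison is stated
        w10 = gr.maclaurin_weights(dv, KT, 10)
        wex = gr.exact_weights(dv, KT)
        edges = None
        h10 = gr.reweight_histogram(harmonic_ensemble, bins=50, weights=w10)
        hex_ = gr.reweight_histogram(
            harmonic_ensemble, bins=list(h10.edges), weights=wex
        )
        L10 = gr.free_energy(h10, KT)
        Lex = gr.free_energy(hex_, KT)
        both = L10.mask & Lex.mask
        assert np.nanmax(np.abs(L10.free_energy[both] - Lex.free_energy[both])) < 1e-3


class TestMinima:
    def test_single_well_located_within_one_bin(self, harmonic_ensemble):
        w = gr.exact_weights(harmonic_ensemble.dv_total, KT)
        hist = gr.reweight_histogram(harmonic_ensemble, bins=50, weights=w)
        L = gr.free_energy(hist, KT)
        minima, flat = gr.locate_minima(L)
        assert not flat
        bin_width = hist.edges[0][1] - hist.edges[0][0]
        assert abs(minima[0].coords[0] - 3.0) <= bin_width

    def test_symmetric_double_well_two_minima(self):
        surf = sd.double_well_1d()
        boost = sd.BoostModel.for_surface(surf, k0_total=0.3)
        ens = sd.gen_boosted_ensemble(surf, boost, 100_000, seed=21)
        w = gr.exact_weights(ens.dv_total, ens.kT)
        hist = gr.reweight_histogram(ens, bins=40, weights=w)
        L = gr.free_energy(hist, ens.kT)
        minima, flat = gr.locate_minima(L, max_minima=2)
        assert len(minima) == 2
        assert abs(minima[0].depth - minima[1].depth) < 0.2
        assert sorted(np.sign(m.coords[0]) for m in minima) == [-1.0, 1.0]

    def test_flat_landscape_flagged(self):
        hist = gr.WeightedHistogram(
            edges=(np.arange(5.0),), counts=np.full(4, 50), p=np.full(4, 0.25)
        )
        L = gr.free_energy(hist, kT=1.0)
        minima, flat = gr.locate_minima(L)
        assert flat and minima == []

    def test_2d_marginalisation_integrates_probability(self):
        surf = sd.two_basin_surface_2d(delta_f=1.0)
        boost = sd.BoostModel.for_surface(surf, k0_total=0.2, grid_points=201)
        ens = sd.gen_boosted_ensemble(surf, boost, 50_000, seed=4)
        w = gr.exact_weights(ens.dv_total, ens.kT)
        hist = gr.reweight_histogram(ens, bins=40, weights=w)
        L = gr.free_energy(hist, ens.kT, min_count=5)
        minima, flat = gr.locate_minima(L, axis=0)
        assert not flat
        # two basins along x near +-1
        xs = sorted(m.coords[0] for m in minima[:2])
        assert xs[0] == pytest.approx(-1.0, abs=0.25)
        assert xs[1] == pytest.approx(1.0, abs=0.25)


class TestIO:
    def test_ensemble_csv_round_trip(self, harmonic_ensemble, tmp_path):
        path = tmp_path / "ens.csv"
        sd.write_ensemble_csv(harmonic_ensemble, path)
        back = gr.read_ensemble_csv(path)
        assert back.n_frames == harmonic_ensemble.n_frames
        assert np.allclose(back.cv, harmonic_ensemble.cv)
        assert np.allclose(back.dv_total, harmonic_ensemble.dv_total)

    def test_landscape_csv_round_trip(self, harmonic_ensemble, tmp_path):
        w = gr.exact_weights(harmonic_ensemble.dv_total, KT)
        hist = gr.reweight_histogram(harmonic_ensemble, bins=30, weights=w)
        L = gr.free_energy(hist, KT)
        path = tmp_path / "pmf.csv"
        gr.write_landscape_csv(L, path)
        back = gr.read_landscape_csv(path, kT=KT)
        assert np.allclose(
            back.free_energy[back.mask], L.free_energy[L.mask], atol=1e-5
        )
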