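"""Deuterium-uptake quantification: maxima, centroids, statistics, fits."""

import numpy as np
import pandas as pd
import pytest

from confland import hdx_pipeline as hdx
from confland import synthetic_data as sd
from confland.errors import InputError, SchemaError

# 11-residue proline-free linker peptide (synthetic sequence, real range)
LINKER = hdx.Peptide(1948, 1958, "AQLEHGYVSAK", 2)


class TestMaxUptake:
    def test_eleven_residue_proline_free_gives_10(self):
        assert hdx.max_uptake(LINKER) == 10

    def test_x_pro_dipeptide_gives_zero(self):
        assert hdx.max_uptake(hdx.Peptide(1, 2, "AP")) == 0

    def test_internal_proline_subtracted(self):
        assert hdx.max_uptake(hdx.Peptide(1, 13, "AQLEHGPYVSAKL")) == 11

    def test_leading_proline_not_double_counted(self):
        # first residue is excluded anyway, so a leading Pro costs nothing extra
        assert hdx.max_uptake(hdx.Peptide(1, 5, "PAGKL")) == 4

    def test_sequence_range_mismatch_rejected(self):
        with pytest.raises(InputError):
            hdx.Peptide(1, 5, "AQL")

    def test_percent_of_max_of_maximum_is_100(self):
        for pep in (LINKER, hdx.Peptide(1, 13, "AQLEHGPYVSAKL")):
            assert hdx.percent_of_max(hdx.max_uptake(pep), pep) == 100.0


class TestCentroids:
    def _m(self, d, ud, z=2):
        return hdx.UptakeMeasurement(
            peptide=hdx.Peptide(1, 11, "AQLEHGYVSAK", z),
            state="apo", exposure_min=1.0, replicate=1,
            centroid_deuterated=d, centroid_undeuterated=ud,
        )

    def test_equal_centroids_zero_uptake(self):
        assert hdx.uptake_from_centroids(self._m(500.0, 500.0)) == 0.0

    def test_delta_mz_times_charge(self):
        assert hdx.uptake_from_centroids(self._m(502.5, 500.0)) == pytest.approx(5.0)

    def test_strongly_negative_flags_swap(self):
        with pytest.warns(UserWarning, match="swapped"):
            hdx.uptake_from_centroids(self._m(499.0, 500.0))

    def test_round_trip_mean_error_vanishes_over_replicates(self):
        truth = sd.HDXGroundTruth(
            rates=[np.array([1.0, 0.4])], plateaus=[np.array([2.0, 2.0])],
            back_exchange=0.0, noise_sd=0.1,
        )
        df = sd.gen_hdx_dataset([LINKER], truth, n_replicates=200, seed=8)
        t2 = df[df.exposure_min == 2.0]["uptake_Da"]
        expect = truth.mean_uptake(0, 2.0)
        assert t2.mean() == pytest.approx(expect, abs=3 * 0.1 / np.sqrt(len(t2)))


class TestWorkedPercentTriple:
    """The linker peptide's uptake fractions: 5.0 -> 50%, 3.5 -> 35%, 2.7 -> 27%."""

    @pytest.mark.parametrize(
        "uptake,percent", [(5.0, 50.0), (3.5, 35.0), (2.7, 27.0)]
    )
    def test_uptake_to_percent(self, uptake, percent):
        assert hdx.percent_of_max(uptake, LINKER) == pytest.approx(percent)


class TestBackExchange:
    def test_zero_fraction_identity(self):
        assert hdx.back_exchange_correct(3.0, 0.0) == 3.0

    def test_quarter_loss_correction(self):
        assert hdx.back_exchange_correct(3.0, 0.25) == pytest.approx(4.0)

    def test_strictly_increasing_in_uptake_and_fraction(self):
        assert hdx.back_exchange_correct(2.0, 0.25) < hdx.back_exchange_correct(
            2.5, 0.25
        )
        assert hdx.back_exchange_correct(2.0, 0.2) < hdx.back_exchange_correct(2.0, 0.3)

    def test_generator_round_trip(self):
        f = 0.25
        truth_lossy = sd.HDXGroundTruth(
            rates=[np.array([1.0])], plateaus=[np.array([2.0])],
            back_exchange=f, noise_sd=0.0,
        )
        observed = truth_lossy.mean_uptake(0, 2.0)
        pristine = 2.0 * (1 - np.exp(-2.0))
        assert hdx.back_exchange_correct(observed, f) == pytest.approx(pristine)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InputError):
            hdx.back_exchange_correct(1.0, 1.0)


class TestReplicates:
    def test_identical_replicates(self):
        s = hdx.summarize_replicates(LINKER, "apo", 1.0, [2.0, 2.0, 2.0])
        assert s.mean_da == 2.0 and s.sem_da == 0.0 and s.n == 3

    def test_hand_computed_sem(self):
        s = hdx.summarize_replicates(LINKER, "apo", 1.0, [1.0, 2.0, 3.0])
        assert s.mean_da == 2.0
        assert s.sem_da == pytest.approx(1.0 / np.sqrt(3), abs=1e-4)  # ~0.5774

    def test_single_replicate_sem_missing(self):
        s = hdx.summarize_replicates(LINKER, "apo", 1.0, [2.0])
        assert s.sem_da is None


class TestCurveFit:
    def test_noiseless_recovery_within_one_percent(self):
        t = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0])
        a_true, k_true = 4.2, 1.3
        u = a_true * (1 - np.exp(-k_true * t))
        fit = hdx.fit_uptake_curve(t, u, plateau_bound=10.0)
        assert not fit.flagged
        assert fit.amplitude_da == pytest.approx(a_true, rel=0.01)
        assert fit.rate_per_min == pytest.approx(k_true, rel=0.01)

    def test_all_zero_uptake_flagged_flat(self):
        fit = hdx.fit_uptake_curve([0.0, 1.0, 2.0], [0.0, 0.0, 0.0], 10.0)
        assert fit.flagged and fit.amplitude_da == 0.0

    def test_recovery_under_replicate_noise(self):
        """A, k within 10% from 3 noisy replicates (sd 0.1 Da), fixed seed."""
        pep = LINKER
        a_true, k_true = 5.0, 1.2
        truth = sd.HDXGroundTruth(
            rates=[np.array([k_true])], plateaus=[np.array([a_true])],
            back_exchange=0.0, noise_sd=0.1,
        )
        df = sd.gen_hdx_dataset([pep], truth, n_replicates=3, seed=13)
        means = df.groupby("exposure_min")["uptake_Da"].mean()
        fit = hdx.fit_uptake_curve(
            means.index.to_numpy(), means.to_numpy(),
            plateau_bound=hdx.max_uptake(pep),
        )
        assert not fit.flagged
        assert fit.amplitude_da == pytest.approx(a_true, rel=0.10)
        assert fit.rate_per_min == pytest.approx(k_true, rel=0.10)

    def test_missing_zero_control_rejected(self):
        with pytest.raises(InputError):
            hdx.fit_uptake_curve([0.5, 1.0, 2.0], [1.0, 2.0, 3.0], 10.0)


class TestDifferential:
    def _summary(self, mean, sem=0.1, state="apo", t=2.0):
        return hdx.UptakeSummary(
            peptide=LINKER, state=state, exposure_min=t, mean_da=mean,
            sem_da=sem, n=3, percent_of_max=None, corrected_da=mean / 0.75,
        )

    def test_identical_states_not_significant(self):
        d = hdx.differential_uptake(self._summary(3.0), self._summary(3.0, state="x"))
        assert d.delta_da == 0.0 and not d.significant

    def test_large_delta_significant(self):
        d = hdx.differential_uptake(
            self._summary(3.0), self._summary(4.5, state="x")
        )
        assert d.delta_da == pytest.approx(1.5) and d.significant

    def test_sem_propagation_sqrt2(self):
        d = hdx.differential_uptake(
            self._summary(3.0, sem=0.1), self._summary(3.0, sem=0.1, state="x")
        )
        assert d.sem_da == pytest.approx(0.1 * np.sqrt(2))

    def test_protection_has_negative_sign(self):
        """An inhibitor that protects a peptide lowers uptake vs apo."""
        pep = LINKER
        apo = sd.HDXGroundTruth(rates=[np.array([2.0])], plateaus=[np.array([5.0])],
                                back_exchange=0.25, noise_sd=0.0)
        inh = sd.HDXGroundTruth(rates=[np.array([0.3])], plateaus=[np.array([5.0])],
                                back_exchange=0.25, noise_sd=0.0)
        df = pd.concat([
            sd.gen_hdx_dataset([pep], apo, 3, seed=1, state="apo"),
            sd.gen_hdx_dataset([pep], inh, 3, seed=2, state="MLi-2"),
        ])
        summaries = hdx.summarize_table(df)
        diff = hdx.differential_table(summaries, "apo")
        assert (diff[diff.exposure_min > 0]["delta_Da"] < 0).all()

    def test_self_differential_identically_zero(self):
        df = sd.gen_hdx_dataset(
            [LINKER],
            sd.HDXGroundTruth(rates=[np.array([1.0])], noise_sd=0.05),
            3, seed=4, state="apo",
        )
        df2 = df.copy()
        df2["state"] = "copy"
        summaries = hdx.summarize_table(pd.concat([df, df2]))
        diff = hdx.differential_table(summaries, "apo")
        assert np.allclose(diff["delta_Da"], 0.0)
        assert not diff["significant"].any()

    def test_missing_reference_names_available_states(self):
        df = sd.gen_hdx_dataset(
            [LINKER], sd.HDXGroundTruth(rates=[np.array([1.0])]), 3, seed=0,
            state="MLi-2",
        )
        with pytest.raises(InputError, match="MLi-2"):
            hdx.differential_table(hdx.summarize_table(df), "apo")


class TestSchema:
    def test_valid_table_passes(self, tmp_path):
        df = sd.gen_hdx_dataset(
            [LINKER], sd.HDXGroundTruth(rates=[np.array([1.0])]), 3, seed=0
        )
        p = tmp_path / "ok.csv"
        df.to_csv(p, index=False)
        assert len(hdx.read_state_data(p)) == len(df)

    def test_missing_column_rejected(self, tmp_path):
        df = sd.gen_hdx_dataset(
            [LINKER], sd.HDXGroundTruth(rates=[np.array([1.0])]), 3, seed=0
        ).drop(columns=["uptake_Da"])
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="uptake_Da"):
            hdx.read_state_data(p)

    def test_sequence_length_mismatch_rejected(self, tmp_path):
        df = sd.gen_hdx_dataset(
            [LINKER], sd.HDXGroundTruth(rates=[np.array([1.0])]), 3, seed=0
        )
        df.loc[0, "sequence"] = "SHORT"
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="length"):
            hdx.read_state_data(p)


class TestStructureMapping:
    def _topology(self, tmp_path):
        geom = sd.ToyGeometry(
            atoms=[sd.ToyAtom(r, "GLY", "CA") for r in range(1948, 1960)],
            coords={"s": np.column_stack([
                np.arange(12) * 3.8, np.zeros(12), np.zeros(12)
            ])},
        )
        ts = sd.gen_toy_trajectory(1, geom, ["s"], noise_sd=0.0, seed=0)
        p = tmp_path / "top.pdb"
        ts.write_pdb(p)
        return p

    def test_single_peptide_covers_and_sentinel_elsewhere(self, tmp_path):
        top = self._topology(tmp_path)
        out = tmp_path / "mapped.pdb"
        pep = hdx.Peptide(1950, 1954, "AQLEH")
        res = hdx.map_uptake_to_structure({pep: 2.0}, top, out)
        assert all(res[r] == 2.0 for r in range(1950, 1955))
        assert 1948 not in res

    def test_overlap_averaged(self, tmp_path):
        top = self._topology(tmp_path)
        out = tmp_path / "mapped.pdb"
        res = hdx.map_uptake_to_structure(
            {hdx.Peptide(1950, 1954, "AQLEH"): 1.0,
             hdx.Peptide(1952, 1956, "LEHGY"): 3.0},
            top, out,
        )
        assert res[1952] == pytest.approx(2.0)
        assert res[1950] == 1.0 and res[1956] == 3.0

    def test_written_bfactors_round_trip(self, tmp_path):
        import warnings

        import MDAnalysis as mda

        top = self._topology(tmp_path)
        out = tmp_path / "mapped.pdb"
        pep = hdx.Peptide(1950, 1954, "AQLEH")
        hdx.map_uptake_to_structure({pep: 1.23}, top, out)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(out))
        vals = {int(r): float(b) for r, b in zip(u.atoms.resids, u.atoms.tempfactors)}
        assert vals[1950] == pytest.approx(1.23, abs=0.01)
        assert vals[1948] == pytest.approx(hdx.UNCOVERED_SENTINEL, abs=0.01)

    def test_out_of_range_peptide_rejected(self, tmp_path):
        top = self._topology(tmp_path)
        with pytest.raises(InputError, match="outside"):
            hdx.map_uptake_to_structure(
                {hdx.Peptide(1, 5, "AQLEH"): 1.0}, top, tmp_path / "x.pdb"
            )
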