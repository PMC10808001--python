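"""Coil sampling, geometry, shift models and GA sub-ensemble selection."""

import numpy as np
import pandas as pd
import pytest

from amphihelix.ensemble import (
    GAParams,
    RgRestraint,
    SchemeParams,
    build_backbones,
    chi_square,
    default_helix_offsets,
    default_sigmas,
    delta_delta_cacb,
    ensemble_propensity,
    ga_select,
    iterate_selection,
    predict_shifts,
    radius_of_gyration,
    sample_coil_ensemble,
    select_with_rg,
    targets_from_table,
    validate_shift_table,
    ShiftTargets,
)
from amphihelix.synth import RC_REFERENCE, synth_shift_dataset


def make_targets(profile):
    """Chain-aligned noiseless targets from a propensity profile."""
    offs = default_helix_offsets()
    sig = default_sigmas()
    nuclei = tuple(offs)
    off = np.array([offs[n] for n in nuclei])
    profile = np.asarray(profile, float)
    sec = profile[:, None] * off[None, :]
    sigma = np.tile(np.array([sig[n] for n in nuclei]), (len(profile), 1))
    return ShiftTargets(nuclei, sec, sigma, off)


class TestGeometry:
    def test_consecutive_ca_distances_ideal(self, rng):
        phi = rng.uniform(-180, 180, size=(3, 40))
        psi = rng.uniform(-180, 180, size=(3, 40))
        ca = build_backbones(phi, psi)[:, :, 1, :]
        d = np.linalg.norm(np.diff(ca, axis=1), axis=2)
        assert d.min() > 3.7 and d.max() < 3.9

    def test_two_point_rg(self):
        assert radius_of_gyration(np.array([[0, 0, 0], [4.0, 0, 0]])) == pytest.approx(2.0)

    def test_coincident_points(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_rigid_motion_invariance(self, rng):
        x = rng.normal(size=(30, 3))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        y = x @ R.T + np.array([5.0, -3.0, 2.0])
        assert radius_of_gyration(y) == pytest.approx(radius_of_gyration(x), abs=1e-9)


class TestCoilSampler:
    def test_fixed_seed_reproducibility(self):
        a = sample_coil_ensemble(30, 3, seed=5)
        b = sample_coil_ensemble(30, 3, seed=5)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.ca, b.ca)

    def test_all_weight_on_alpha_gives_fully_helical(self):
        # narrow basins keep every draw inside the helical box
        bp = {"basins": {
            "beta": {"phi_mean": -120.0, "phi_sd": 1.0, "psi_mean": 135.0, "psi_sd": 1.0},
            "ppii": {"phi_mean": -70.0, "phi_sd": 1.0, "psi_mean": 145.0, "psi_sd": 1.0},
            "alphaR": {"phi_mean": -63.0, "phi_sd": 3.0, "psi_mean": -42.0, "psi_sd": 3.0},
            "alphaL": {"phi_mean": 60.0, "phi_sd": 1.0, "psi_mean": 45.0, "psi_sd": 1.0},
        }}
        pool = sample_coil_ensemble(25, 20, seed=1, basin_params=bp, alpha_weight=1.0)
        assert pool.helical.all()

    def test_no_retained_conformer_violates_clash_cutoff(self):
        pool = sample_coil_ensemble(60, 40, seed=2)
        cutoff = pool.params["clash_cutoff"]
        for ca in pool.ca:
            d2 = ((ca[:, None, :] - ca[None, :, :]) ** 2).sum(-1)
            iu = np.triu_indices(len(ca), 3)
            assert d2[iu].min() >= cutoff**2

    def test_propensity_counts_fraction(self):
        pool = sample_coil_ensemble(20, 50, seed=3)
        prop = ensemble_propensity(pool)
        assert prop == pytest.approx(pool.helical.mean(axis=0))
        assert np.all((prop >= 0) & (prop <= 1))

    def test_coil_propensity_tracks_alpha_weight(self):
        """Helical propensity of an unrestrained pool follows the alpha-R
        mixture weight (within binomial scatter and the clash-resampling
        depletion of compact states)."""
        pool = sample_coil_ensemble(40, 150, seed=4, alpha_weight=0.15)
        assert abs(ensemble_propensity(pool).mean() - 0.15) < 0.06

    def test_basin_frequencies_normalised(self):
        pool = sample_coil_ensemble(25, 30, seed=6)
        freq = pool.basin_frequencies()
        assert freq.sum(axis=1) == pytest.approx(np.ones(25))

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            sample_coil_ensemble(10, 0, seed=1)


class TestSecondaryShifts:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["residue", "aa", "nucleus",
                                           "observed", "rc", "sigma"])

    def test_observed_equal_rc_gives_zero(self):
        t = self._table([
            (1, "A", "CA", 50.0, 50.0, 0.4), (1, "A", "CB", 30.0, 30.0, 0.5),
        ])
        out = delta_delta_cacb(t)
        assert out[0].value == 0.0 and not out[0].ca_only

    def test_substitution_example(self):
        t = self._table([
            (1, "A", "CA", 52.8, 50.0, 0.4), (1, "A", "CB", 29.5, 30.0, 0.5),
        ])
        assert delta_delta_cacb(t)[0].value == pytest.approx(3.3)

    def test_glycine_row_flagged_ca_only(self):
        t = self._table([(1, "G", "CA", 46.0, 45.0, 0.4)])
        out = delta_delta_cacb(t)
        assert out[0].ca_only and out[0].value == pytest.approx(1.0)

    def test_glycine_cb_rejected(self):
        t = self._table([(1, "G", "CB", 30.0, 30.0, 0.5)])
        with pytest.raises(ValueError, match="glycine"):
            validate_shift_table(t)

    def test_missing_rc_names_residue(self):
        t = self._table([
            (7, "A", "CA", 52.0, np.nan, 0.4), (7, "A", "CB", 30.0, 30.0, 0.5),
        ])
        with pytest.raises(ValueError, match="7"):
            delta_delta_cacb(t)

    def test_missing_observation_is_absent_not_zero(self):
        t = self._table([
            (1, "A", "CA", np.nan, 50.0, 0.4), (1, "A", "CB", 30.0, 30.0, 0.5),
            (2, "A", "CA", 50.0, 50.0, 0.4), (2, "A", "CB", 30.0, 30.0, 0.5),
        ])
        out = delta_delta_cacb(t)
        assert [s.residue for s in out] == [2]


class TestForwardModel:
    def _rc_table(self, L):
        rows = []
        for i in range(1, L + 1):
            for nuc, rc in RC_REFERENCE.items():
                rows.append({"residue": i, "aa": "A", "nucleus": nuc,
                             "rc": rc, "sigma": 0.4})
        return pd.DataFrame(rows)

    def test_predicted_shift_interpolates_with_propensity(self):
        L = 12
        rc = self._rc_table(L)
        offs = default_helix_offsets()
        for aw, frac in ((0.0, 0.0), (1.0, 1.0)):
            bp = {"basins": {
                "beta": {"phi_mean": -120.0, "phi_sd": 1.0, "psi_mean": 135.0, "psi_sd": 1.0},
                "ppii": {"phi_mean": -70.0, "phi_sd": 1.0, "psi_mean": 145.0, "psi_sd": 1.0},
                "alphaR": {"phi_mean": -63.0, "phi_sd": 2.0, "psi_mean": -42.0, "psi_sd": 2.0},
                "alphaL": {"phi_mean": 60.0, "phi_sd": 1.0, "psi_mean": 45.0, "psi_sd": 1.0},
            }}
            pool = sample_coil_ensemble(L, 30, seed=1, basin_params=bp, alpha_weight=aw)
            pred = predict_shifts(pool, rc)
            ca = pred[pred["nucleus"] == "CA"]
            assert ca["predicted"].to_numpy() == pytest.approx(
                ca["rc"].to_numpy() + frac * offs["CA"], abs=1e-9
            )

    def test_targets_from_table_round_trip(self):
        profile = np.linspace(0, 1, 9)
        table, truth = synth_shift_dataset(profile, seed=0)
        targets = targets_from_table(table, len(profile))
        assert chi_square(np.asarray(truth["profile"]), targets) == pytest.approx(0.0, abs=1e-18)


class TestGASelection:
    def test_fitness_history_monotone_nonincreasing(self):
        pool = sample_coil_ensemble(20, 200, seed=1)
        targets = make_targets(np.full(20, 0.3))
        res = ga_select(pool, targets, 20, GAParams(max_generations=60), seed=2)
        assert np.all(np.diff(res.fitness_history) <= 1e-12)
        assert len(res.selected_indices) == 20

    def test_flat_forward_model_flat_fitness(self):
        pool = sample_coil_ensemble(15, 100, seed=1)
        targets = make_targets(np.zeros(15))
        targets = ShiftTargets(targets.nuclei, np.zeros_like(targets.secondary),
                               targets.sigma, np.zeros_like(targets.offsets))
        res = ga_select(pool, targets, 10, GAParams(max_generations=30), seed=3)
        assert np.allclose(res.fitness_history, res.fitness_history[0])

    def test_beats_random_restarts_on_realisable_target(self, rng):
        pool = sample_coil_ensemble(18, 300, seed=4)
        true_subset = rng.choice(300, size=30, replace=False)
        profile = pool.helical[true_subset].mean(axis=0)
        targets = make_targets(profile)
        res = ga_select(pool, targets, 30, seed=5)
        best_random = min(
            chi_square(pool.helical[rng.integers(0, 300, 30)].mean(axis=0), targets)
            for _ in range(1000)
        )
        assert res.fitness_history[-1] <= best_random

    def test_m_larger_than_pool_rejected(self):
        pool = sample_coil_ensemble(10, 5, seed=1)
        with pytest.raises(ValueError):
            ga_select(pool, make_targets(np.zeros(10)), 10, seed=1)

    def test_seed_reproducibility(self):
        pool = sample_coil_ensemble(15, 120, seed=9)
        targets = make_targets(np.full(15, 0.2))
        a = ga_select(pool, targets, 12, GAParams(max_generations=40), seed=11)
        b = ga_select(pool, targets, 12, GAParams(max_generations=40), seed=11)
        assert np.array_equal(a.selected_indices, b.selected_indices)


SMALL_SCHEME = SchemeParams(pool_size=400, select_m=25, regen_biased=340,
                            regen_base=60, iterations=3,
                            ga=GAParams(max_generations=120))


class TestIterativeScheme:
    def test_zero_iterations_reduces_to_plain_selection(self):
        targets = make_targets(np.full(20, 0.3))
        scheme = SchemeParams(pool_size=200, select_m=15, regen_biased=100,
                              regen_base=20, iterations=0)
        res = iterate_selection(20, targets, scheme, seed=3)
        assert res.iteration_best and res.propensity_change == []

    def test_rg_weight_zero_identical_to_unrestrained(self):
        targets = make_targets(np.full(15, 0.3))
        plain = iterate_selection(15, targets, SMALL_SCHEME, seed=7)
        restrained = select_with_rg(15, targets, (20.0, 2.0), SMALL_SCHEME,
                                    seed=7, rg_weight=0.0)
        assert np.array_equal(plain.selected_indices, restrained.selected_indices)
        assert plain.fitness_history[-1] == restrained.fitness_history[-1]

    def test_rg_restraint_shifts_selected_mean_upward(self):
        targets = make_targets(np.full(15, 0.3))
        plain = iterate_selection(15, targets, SMALL_SCHEME, seed=7)
        expanded = select_with_rg(
            15, targets, (plain.ensemble_mean_rg * 1.2, 0.3), SMALL_SCHEME,
            seed=7, rg_weight=5.0,
        )
        assert expanded.ensemble_mean_rg > plain.ensemble_mean_rg

    def test_dominant_rg_restraint_reaches_target(self):
        targets = make_targets(np.full(15, 0.3))
        target_rg = 13.0
        res = select_with_rg(15, targets, RgRestraint(target_rg, 1.0),
                             SMALL_SCHEME, seed=8, rg_weight=200.0)
        assert abs(res.ensemble_mean_rg - target_rg) < 1.0

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            SchemeParams(pool_size=10, select_m=20)
        with pytest.raises(ValueError):
            RgRestraint(40.0, 0.0)
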