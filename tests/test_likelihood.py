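"""Chain likelihood, order marginalization and Monte Carlo integration.

The two-event likelihood is checked against an independent transcription of
the uncancelled closed form (interaction probability and containment factors
written out explicitly, as they appear before the algebraic cancellation).
"""

from dataclasses import replace

import numpy as np
import pytest

import comptrack as ct
from comptrack.likelihood import EstimationError


def _gauss(x, mean, sigma):
    return np.exp(-0.5 * ((x - mean) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def uncancelled_two_event_likelihood(
    ev1, ev2, e_gamma, geometry, physics, model, delta_sigma=0.5
):
    """Direct transcription of the two-interaction chain probability.

    Written independently of the engine: the containment factors
    (1 - e^(-mu Lexit)) and the interaction probability are kept explicit
    and divided out exactly where the conditional position densities
    require, instead of being cancelled analytically.
    """
    mu = lambda e: float(physics.mu_clamped(e))
    clamp = lambda e: float(np.clip(e, physics.e_min, physics.e_max))
    Ld = geometry.depth_Ld
    e1, e2 = ev1.energy_keV, ev2.energy_keV
    x1, x2 = ev1.position, ev2.position
    e_prime = e_gamma - e1
    if e_prime <= 0 or e_gamma < e1 + e2 - 4 * delta_sigma:
        return 0.0

    p_interact = 1.0 - np.exp(-mu(e_gamma) * Ld)
    pos1 = mu(e_gamma) * np.exp(-mu(e_gamma) * x1[2]) / p_interact
    p_compton_1 = float(physics.p_compton(clamp(e_gamma)))
    seg = x2 - x1
    seg_len = float(np.linalg.norm(seg))
    direction = seg / seg_len
    theta1 = ct.angle_between(x1, x2, (0, 0, 1.0))
    dep1 = float(model.joint_pdf(e1, theta1, e_gamma))

    lexit1 = geometry.exit_distance(x1, direction)
    contain1 = 1.0 - np.exp(-mu(e_prime) * lexit1)
    pos2 = mu(e_prime) * np.exp(-mu(e_prime) * seg_len) / contain1

    photo = _gauss(e2, e_prime, delta_sigma) * float(physics.p_photo(clamp(e_prime)))
    if e_prime > e2:
        dep_marg = float(model.deposit_pdf(e2, e_prime))
        esc = ct.escape_probability(
            e_prime, e2, x2, direction, geometry, physics, model
        )
        compton = dep_marg * esc * float(physics.p_compton(clamp(e_prime)))
    else:
        compton = 0.0
    return (
        p_interact * pos1 * p_compton_1 * dep1 * contain1 * pos2
        * (photo + compton)
    )


@pytest.fixture(scope="module")
def table1_chain():
    return ct.InteractionChain(0, [
        ct.InteractionEvent(9.670, 6.050, 6.309, 7.1),
        ct.InteractionEvent(9.366, 4.496, 6.310, 3.2),
    ])


@pytest.fixture(scope="module")
def two_event_photo_chain():
    return ct.InteractionChain(1, [
        ct.InteractionEvent(9.670, 6.050, 6.309, 7.1),
        ct.InteractionEvent(9.366, 4.496, 6.310, 52.9),
    ])


class TestChainLikelihood:
    def test_matches_uncancelled_transcription(
        self, table1_chain, two_event_photo_chain, geometry, physics, model
    ):
        for chain in (table1_chain, two_event_photo_chain):
            ev1, ev2 = chain.events
            for e_gamma in (45.0, 55.0, 60.0, 61.3, 80.0, 110.0):
                oracle = uncancelled_two_event_likelihood(
                    ev1, ev2, e_gamma, geometry, physics, model
                )
                value = ct.chain_likelihood(
                    chain, e_gamma, geometry, physics, model
                )
                if oracle > 1e-300:
                    assert value == pytest.approx(oracle, rel=1e-10)
                else:
                    assert value == 0.0

    def test_vector_evaluation_matches_scalars(
        self, table1_chain, geometry, physics, model
    ):
        es = np.array([50.0, 60.0, 70.0])
        curve = ct.chain_likelihood(table1_chain, es, geometry, physics, model)
        for e, v in zip(es, curve):
            assert v == ct.chain_likelihood(table1_chain, e, geometry, physics, model)

    def test_impossible_energy_returns_zero(self, geometry, physics, model):
        chain = ct.InteractionChain(0, [
            ct.InteractionEvent(1, 1, 5.0, 30.0),
            ct.InteractionEvent(2, 2, 9.0, 40.0),
        ])
        # below the total deposit minus the Gaussian slack
        assert ct.chain_likelihood(chain, 50.0, geometry, physics, model) == 0.0

    def test_nonpositive_event_energy_rejected(self, geometry, physics, model):
        chain = ct.InteractionChain(0, [ct.InteractionEvent(1, 1, 5.0, -1.0)])
        with pytest.raises(ValueError):
            ct.chain_likelihood(chain, 60.0, geometry, physics, model)

    def test_no_underflow_for_four_event_chain(self, geometry, physics, model):
        # a kinematically consistent 4-event chain from the simulator itself
        chains = ct.simulate_batch(800, 60.0, geometry, physics, model, seed=77)
        chain = next(
            c for c in chains
            if len(c) == 4 and c.terminated_by == "photoelectric"
        )
        val = ct.chain_likelihood(chain, 60.0, geometry, physics, model)
        assert np.isfinite(val) and val > 0.0


class TestEscapeProbability:
    def test_in_unit_interval_for_random_inputs(self, geometry, physics, model):
        rng = np.random.default_rng(2)
        for _ in range(200):
            e_dep = rng.uniform(0.5, 10.0)
            e_inc = e_dep + rng.uniform(5.0, 80.0)
            z = rng.uniform(0.0, 80.0)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            esc = ct.escape_probability(
                e_inc, e_dep, (0, 0, z), v, geometry, physics, model
            )
            assert 0.0 <= esc <= 1.0

    def test_forced_forward_spike_reduces_to_single_ray(self, geometry, physics):
        # spike posterior on the smallest-angle bin of a fine-angle model:
        # the double quadrature must collapse to exp(-mu (Ld - z) / cos th)
        fine = ct.ComptonModel(theta_step=1e-3)
        weights = np.zeros(len(fine.theta_mid))
        weights[0] = 1.0
        z, e_inc, e_dep = 6.3, 60.0, 5.0
        esc = ct.escape_probability(
            e_inc, e_dep, (0, 0, z), (0, 0, 1.0), geometry, physics, fine,
            theta_weights=weights,
        )
        mu = float(physics.mu_clamped(e_inc - e_dep))
        expected = np.exp(-mu * (geometry.depth_Ld - z) / np.cos(fine.theta_mid[0]))
        assert esc == pytest.approx(expected, rel=1e-9)

    def test_phi_quadrature_redundant_for_beam_aligned(
        self, geometry, physics, model
    ):
        # beam perpendicular to the faces: Lexit independent of phi, so the
        # full double quadrature equals a theta-only quadrature
        z, e_dep = 10.0, 5.0
        e_inc = np.array([40.0, 60.0, 90.0])
        full = ct.escape_probability(
            e_inc, e_dep, (3, 3, z), (0, 0, 1.0), geometry, physics, model,
            phi_nodes=64,
        )
        w = model.joint_pdf(e_dep, model.theta_mid[None, :], e_inc[:, None])
        w = w * model.theta_width
        w /= w.sum(axis=1, keepdims=True)
        exit_l = geometry.exit_distance_z(z, np.cos(model.theta_mid))
        mu = physics.mu_clamped(e_inc - e_dep)
        theta_only = (w * np.exp(-mu[:, None] * exit_l[None, :])).sum(axis=1)
        np.testing.assert_allclose(full, theta_only, rtol=1e-10)

    def test_deposit_above_incident_energy_rejected(self, geometry, physics, model):
        with pytest.raises(ValueError):
            ct.escape_probability(
                10.0, 20.0, (0, 0, 5.0), (0, 0, 1.0), geometry, physics, model
            )


class TestOrderMarginal:
    def test_single_photoelectric_recovers_energy(self, geometry, physics, model):
        chain = ct.InteractionChain(0, [ct.InteractionEvent(5, 5, 6.3, 60.0)])
        res = ct.order_marginal_estimate(chain, geometry, physics, model)
        assert len(res.orders) == 1
        assert res.e_hat_keV == pytest.approx(60.0, abs=0.1)
        assert (res.x_hat_mm, res.y_hat_mm) == (5.0, 5.0)

    def test_three_events_give_six_terms(self, geometry, physics, model):
        chain = ct.InteractionChain(0, [
            ct.InteractionEvent(5, 5, 3.0, 4.1),
            ct.InteractionEvent(6, 5.5, 10.0, 6.2),
            ct.InteractionEvent(7.0, 4.2, 11.0, 49.7),
        ])
        res = ct.order_marginal_estimate(chain, geometry, physics, model)
        assert len(res.orders) == 6
        assert res.curves.shape[0] == 6

    def test_estimate_is_grid_argmax_of_winning_curve(
        self, two_event_photo_chain, geometry, physics, model
    ):
        res = ct.order_marginal_estimate(
            two_event_photo_chain, geometry, physics, model
        )
        rescanned = res.energy_grid[int(np.argmax(res.curves[res.winning_index]))]
        assert res.e_hat_keV == rescanned
        assert res.winning_max == res.curves[res.winning_index].max()

    def test_position_estimate_is_first_event_of_winning_order(
        self, two_event_photo_chain, geometry, physics, model
    ):
        res = ct.order_marginal_estimate(
            two_event_photo_chain, geometry, physics, model
        )
        first = two_event_photo_chain.events[res.winning_order[0]]
        assert res.x_hat_mm == first.x_mm and res.y_hat_mm == first.y_mm

    def test_reversed_order_produces_distinct_curve(
        self, table1_chain, geometry, physics, model
    ):
        # the two permutation terms of the reference two-Compton chain peak
        # at different heights (order identifiability)
        res = ct.order_marginal_estimate(table1_chain, geometry, physics, model)
        maxima = res.curves.max(axis=1)
        assert maxima[0] != maxima[1]
        assert not np.allclose(res.curves[0], res.curves[1])

    def test_spectrum_weighting_shifts_flat_prior_estimate(
        self, geometry, physics, model
    ):
        # a single small Compton deposit is ambiguous under a flat prior; a
        # known narrow spectrum around 60 keV must pull the estimate toward it
        chain = ct.InteractionChain(0, [ct.InteractionEvent(5, 5, 6.3, 5.0)])
        cfg = ct.EstimatorConfig()
        flat = ct.order_marginal_estimate(chain, geometry, physics, model, cfg)
        grid = cfg.energy_grid()
        weights = np.exp(-0.5 * ((grid - 60.0) / 3.0) ** 2)
        weighted = ct.order_marginal_estimate(
            chain, geometry, physics, model, cfg, spectrum_weights=weights
        )
        assert abs(weighted.e_hat_keV - 60.0) < abs(flat.e_hat_keV - 60.0)
        with pytest.raises(ValueError):
            ct.order_marginal_estimate(
                chain, geometry, physics, model, cfg,
                spectrum_weights=np.ones(3),
            )

    def test_too_many_events_raises(self, geometry, physics, model):
        events = [
            ct.InteractionEvent(i, i, 2.0 + i, 1.0) for i in range(7)
        ]
        with pytest.raises(ValueError, match="max_events"):
            ct.order_marginal_estimate(
                ct.InteractionChain(0, events), geometry, physics, model
            )


class TestMonteCarloIntegration:
    def test_zero_noise_single_realization_equals_order_marginal(
        self, two_event_photo_chain, geometry, physics, model
    ):
        cfg = replace(ct.EstimatorConfig(), mc_realizations=1)
        ideal = ct.order_marginal_estimate(
            two_event_photo_chain, geometry, physics, model, cfg
        )
        mc = ct.mc_integrated_estimate(
            two_event_photo_chain, ct.NoiseModel(0, 0, 0, 0),
            geometry, physics, model, cfg, rng=np.random.default_rng(0),
        )
        np.testing.assert_array_equal(ideal.curves, mc.curves)
        assert ideal.e_hat_keV == mc.e_hat_keV

    def test_average_curve_is_mean_of_realizations(
        self, table1_chain, geometry, physics, model
    ):
        cfg = replace(ct.EstimatorConfig(), mc_realizations=20)
        res, per_real = ct.mc_integrated_estimate(
            table1_chain, ct.NoiseModel(), geometry, physics, model, cfg,
            rng=np.random.default_rng(33), return_realizations=True,
        )
        explicit = np.zeros_like(res.curves)
        for curves in per_real:  # independent accumulation
            explicit += curves
        explicit /= len(per_real)
        np.testing.assert_allclose(res.curves, explicit, rtol=1e-12)

    def test_skipped_realizations_counted_and_error_when_all_skipped(
        self, geometry, physics, model
    ):
        chain = ct.InteractionChain(0, [ct.InteractionEvent(5, 5, 6.3, 0.1)])
        cfg = replace(ct.EstimatorConfig(), mc_realizations=5)
        noise = ct.NoiseModel(sigma_E=5.0)
        with pytest.raises(EstimationError):
            ct.mc_integrated_estimate(
                chain, noise, geometry, physics, model, cfg,
                rng=np.random.default_rng(8),
            )

    def test_noise_widens_but_keeps_estimate_close(
        self, two_event_photo_chain, geometry, physics, model
    ):
        cfg = replace(ct.EstimatorConfig(), mc_realizations=100)
        res = ct.mc_integrated_estimate(
            two_event_photo_chain, ct.NoiseModel(), geometry, physics, model,
            cfg, rng=np.random.default_rng(17),
        )
        assert res.e_hat_keV == pytest.approx(60.0, abs=2.0)
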