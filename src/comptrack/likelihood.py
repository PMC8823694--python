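"""Chain likelihood and maximum-likelihood estimation of (E_gamma, x_gamma).

For an ordered candidate chain of n interactions the likelihood of a trial
incident energy factorizes into

* a position factor ``mu e^(-mu l)`` per leg (entry face to first interaction
  along +z, then event-to-event segments), evaluated at the photon energy
  remaining on that leg,
* a Compton type factor and a joint deposit-angle density for every
  non-terminal interaction, whose scattering angle is fixed by the event
  geometry,
* a terminal bracket: either a photoelectric absorption of the full
  remaining energy (energy delta softened to a Gaussian) or a final Compton
  deposit marginalized over the unknown outgoing angle times the probability
  that the scattered photon escapes through a z face.

The per-leg containment factors ``1 - e^(-mu Lexit)`` cancel algebraically
against the conditional position densities; the cancelled form is evaluated
here (the uncancelled transcription is kept as a test oracle).

Observed chains are unordered: the likelihood is evaluated for every
permutation of the events, each term is maximized over the incident-energy
grid, and the term with the largest maximum supplies the estimate.  Limited
detector resolution is handled by Monte Carlo integration: likelihood curves
are averaged over Gaussian-perturbed copies of the observed chain.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field

import numpy as np

from .geometry import BEAM_DIRECTION, DetectorGeometry, direction_z_components, unit_vector
from .physics_tables import CrossSectionTable
from .scattering_model import ComptonModel, deposited_energy
from scipy.special import ndtr

__all__ = [
    "NoiseModel",
    "EstimatorConfig",
    "LikelihoodResult",
    "EstimationError",
    "escape_probability",
    "chain_likelihood",
    "order_marginal_estimate",
    "mc_integrated_estimate",
    "LikelihoodEngine",
    "write_results_csv",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


class EstimationError(RuntimeError):
    """Raised when no valid Monte Carlo realization could be evaluated."""


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian observation noise: energy (keV) and per-axis position (mm)."""

    sigma_E: float = 0.5
    sigma_x: float = 0.010
    sigma_y: float = 0.500
    sigma_z: float = 0.500

    def __post_init__(self) -> None:
        if min(self.sigma_E, self.sigma_x, self.sigma_y, self.sigma_z) < 0:
            raise ValueError("noise sigmas must be non-negative")

    @property
    def is_zero(self) -> bool:
        return max(self.sigma_E, self.sigma_x, self.sigma_y, self.sigma_z) == 0.0


@dataclass(frozen=True)
class EstimatorConfig:
    """Grids and integration controls of the maximum-likelihood estimator.

    ``escape_grid_step`` trades accuracy of the (smooth, expensive) escape
    factor for speed: it is evaluated on an incident-energy subgrid of this
    step and linearly interpolated to the full 0.1-keV grid.  Set to 0 for
    exact evaluation at every grid node.
    """

    energy_min: float = 15.0
    energy_max: float = 120.0
    energy_step: float = 0.1
    phi_nodes: int = 64
    mc_realizations: int = 1500
    delta_sigma: float = 0.5
    max_events: int = 6
    escape_grid_step: float = 1.0
    include_coherent_in_mu: bool = True

    def energy_grid(self) -> np.ndarray:
        n = int(round((self.energy_max - self.energy_min) / self.energy_step))
        return self.energy_min + self.energy_step * np.arange(n + 1)


@dataclass
class LikelihoodResult:
    """Averaged per-permutation likelihood curves and the selected estimate."""

    energy_grid: np.ndarray
    orders: list[tuple[int, ...]]
    curves: np.ndarray  # (n_orders, n_grid), averaged over realizations
    winning_index: int
    e_hat_keV: float
    x_hat_mm: float
    y_hat_mm: float
    z_hat_mm: float
    winning_max: float
    n_events: int
    n_skipped_realizations: int = 0

    @property
    def winning_order(self) -> tuple[int, ...]:
        return self.orders[self.winning_index]


# ----------------------------------------------------------------------
# escape probability
# ----------------------------------------------------------------------

def _phi_grid(phi_nodes: int) -> np.ndarray:
    return 2.0 * np.pi * np.arange(phi_nodes) / phi_nodes


def escape_probability(
    e_incident,
    e_deposited: float,
    position,
    incoming,
    geometry: DetectorGeometry,
    physics: CrossSectionTable,
    model: ComptonModel,
    phi_nodes: int = 64,
    include_coherent_in_mu: bool = True,
    theta_weights=None,
) -> np.ndarray | float:
    """Probability that the photon scattered at ``position`` leaves the slab.

    Double quadrature: the polar angle runs over the model's discretized grid
    weighted by the angle posterior P(theta | E_incident, E_deposited) (or an
    explicit ``theta_weights`` override, normalized over the grid), the
    azimuth over ``phi_nodes`` uniform nodes of the periodic trapezoid rule.
    Vectorized over ``e_incident``.
    """
    e_inc = np.atleast_1d(np.asarray(e_incident, dtype=float))
    scalar = np.ndim(e_incident) == 0
    if np.any(e_inc <= e_deposited):
        raise ValueError("incident energy must exceed the deposited energy")
    z = float(np.asarray(position, dtype=float)[2])
    if not 0.0 <= z <= geometry.depth_Ld:
        raise ValueError("position outside detector slab")
    theta = model.theta_mid
    if theta_weights is None:
        w = model.joint_pdf(e_deposited, theta[None, :], e_inc[:, None]) * (
            model.theta_width[None, :]
        )
        norm = w.sum(axis=1)
        w = np.where(norm[:, None] > 0, w / np.where(norm > 0, norm, 1.0)[:, None], 0.0)
    else:
        w = np.asarray(theta_weights, dtype=float)
        w = np.broadcast_to(w / w.sum(), (len(e_inc), len(theta))).copy()
    dz = direction_z_components(incoming, theta, _phi_grid(phi_nodes))
    exit_l = geometry.exit_distance_z(z, dz)  # (J, P)
    mu = np.asarray(
        physics.mu_clamped(e_inc - e_deposited, include_coherent_in_mu), dtype=float
    )
    trans = np.exp(-mu[:, None, None] * exit_l[None, :, :]).mean(axis=2)  # (M, J)
    out = (w * trans).sum(axis=1)
    return float(out[0]) if scalar else out


# ----------------------------------------------------------------------
# engine
# ----------------------------------------------------------------------

class LikelihoodEngine:
    """Evaluates likelihood curves over the incident-energy grid.

    One engine instance caches the grids and table lookups shared by all
    chains; estimator and simulator are expected to share the same physics
    table and scattering model (self-consistent benchmark).
    """

    def __init__(
        self,
        geometry: DetectorGeometry,
        physics: CrossSectionTable,
        model: ComptonModel,
        config: EstimatorConfig = EstimatorConfig(),
    ):
        self.geometry = geometry
        self.physics = physics
        self.model = model
        self.config = config
        self.grid = config.energy_grid()
        self._mu_grid = physics.mu_clamped(self.grid, config.include_coherent_in_mu)
        self._phi = _phi_grid(config.phi_nodes)
        if config.escape_grid_step and config.escape_grid_step > config.energy_step:
            self._esc_stride = max(
                1, int(round(config.escape_grid_step / config.energy_step))
            )
        else:
            self._esc_stride = 1

    # -- helpers ---------------------------------------------------------
    def _mu(self, energies):
        return self.physics.mu_clamped(energies, self.config.include_coherent_in_mu)

    def _type_probs(self, energies):
        e = np.clip(energies, self.physics.e_min, self.physics.e_max)
        return self.physics.type_probabilities(e)

    def curve_for_order(self, positions: np.ndarray, energies: np.ndarray) -> np.ndarray:
        """Likelihood curve over the energy grid for one ordered chain.

        ``positions``: (n, 3) mm, ``energies``: (n,) keV, in the assumed
        interaction order.

        Evaluation is restricted to the grid region where every non-terminal
        deposit factor is non-negligible (within 12 sigma_1 of its kinematic
        mean); outside that intersection the product of factors is below
        1e-31 of its peak and the curve is reported as exactly 0.
        """
        grid = self.grid
        cfg = self.config
        n = len(energies)
        energies = np.asarray(energies, dtype=float)
        cum = np.cumsum(energies)
        total = cum[-1]
        out = np.zeros(len(grid))

        # trial energies below the total deposit (minus Gaussian slack) or
        # unable to keep the photon alive through the legs are impossible
        valid = (grid > total - energies[-1]) & (
            grid >= total - 4.0 * cfg.delta_sigma
        )

        legs = []
        incoming = BEAM_DIRECTION
        for i in range(n - 1):
            seg = positions[i + 1] - positions[i]
            seg_len = float(np.linalg.norm(seg))
            theta_i = np.arccos(np.clip(np.dot(unit_vector(seg), incoming), -1, 1))
            s_prev = cum[i] - energies[i]
            remaining = np.where(valid, grid - s_prev, self.physics.e_max)
            mean = deposited_energy(remaining, theta_i)
            s1 = np.asarray(self.model.sigma_ed(theta_i, remaining), dtype=float)
            valid &= np.abs(energies[i] - mean) < 12.0 * s1
            legs.append((energies[i], theta_i, seg_len, s_prev))
            incoming = seg / seg_len

        idx = np.flatnonzero(valid)
        if len(idx) == 0:
            return out
        g = grid[idx]

        mu0 = self._mu_grid[idx]
        log_l = np.log(mu0) - mu0 * positions[0, 2]
        for e_i, theta_i, seg_len, s_prev in legs:
            r = g - s_prev
            joint = self.model.joint_pdf(e_i, theta_i, r)
            p_compton = self._type_probs(r)[1]
            mu_leg = self._mu(np.clip(r - e_i, self.physics.e_min * 1e-3, None))
            with np.errstate(divide="ignore"):
                log_l = log_l + np.log(joint) + np.log(p_compton) + (
                    np.log(mu_leg) - mu_leg * seg_len
                )

        bracket = self._terminal_bracket(
            g - (total - energies[-1]), energies[-1], positions[-1], incoming,
            np.ones(len(g), dtype=bool),
        )
        with np.errstate(divide="ignore"):
            log_l = log_l + np.log(bracket)
        out[idx] = np.exp(log_l)
        return out

    def _terminal_bracket(self, remaining, e_n, position, incoming, valid):
        """Photoelectric + Compton-escape closing factor, vectorized on the grid."""
        cfg = self.config
        r_safe = np.where(valid, remaining, self.physics.e_max)
        p_photo, p_compton = self._type_probs(r_safe)
        z_delta = (e_n - remaining) / cfg.delta_sigma
        photo_part = (
            np.exp(-0.5 * z_delta * z_delta) / (cfg.delta_sigma * _SQRT2PI) * p_photo
        )

        joint_w = self._terminal_joint_weights(remaining, r_safe, e_n, valid)
        trans = self._escape_transmission(remaining, e_n, position, incoming, joint_w)
        compton_part = (joint_w * trans).sum(axis=1) * p_compton
        return np.where(valid, photo_part + compton_part, 0.0)

    def _terminal_joint_weights(self, remaining, r_safe, e_n, valid):
        """P(E_n, theta_j | remaining) * dtheta_j on the (grid, theta) plane.

        Fused, masked evaluation of the two-term truncated Gaussian times the
        angle density: entries farther than 9 sigma_1 from the kinematic mean
        are exactly 0 here (their true value is below 1e-17 of the peak).
        """
        model = self.model
        theta = model.theta_mid
        r2 = r_safe[:, None]
        mean = deposited_energy(r2, theta[None, :])
        s1 = np.asarray(model.sigma_ed(theta[None, :], r2), dtype=float)
        s1 = np.broadcast_to(s1, mean.shape)
        dev = e_n - mean
        mask = (
            valid[:, None]
            & (remaining[:, None] > e_n)
            & (np.abs(dev) < 9.0 * s1)
            & (theta[None, :] > 0.0)
        )
        out = np.zeros_like(mean)
        if not mask.any():
            return out
        g_idx, j_idx = np.nonzero(mask)
        m, s1m = mean[g_idx, j_idx], s1[g_idx, j_idx]
        rm = r_safe[g_idx]
        w1, w2 = model.component_weights
        ratio = model.narrow_component_ratio
        dens = np.zeros_like(m)
        for w, s in ((w1, s1m), (w2, ratio * s1m)):
            z = (e_n - m) / s
            mass = ndtr((rm - m) / s) - ndtr(-m / s)
            good = mass > 0
            core = np.exp(-0.5 * z * z) / (s * _SQRT2PI)
            dens += np.where(good, w * core / np.where(good, mass, 1.0), 0.0)
        angle = model._angle_weight(theta[j_idx], rm) / model._angle_norm(rm)
        out[g_idx, j_idx] = dens * angle * model.theta_width[j_idx]
        return out

    def _escape_transmission(self, remaining, e_n, position, incoming, joint_w):
        """phi-averaged exp(-mu Lexit) per (grid energy, theta bin).

        Evaluated on the escape subgrid and linearly interpolated to the full
        grid; theta bins with negligible posterior weight are skipped.
        """
        theta = self.model.theta_mid
        dz = direction_z_components(incoming, theta, self._phi)
        exit_l = self.geometry.exit_distance_z(float(position[2]), dz)  # (J, P)

        col_max = joint_w.max(axis=0)
        active = col_max > 1e-14 * max(col_max.max(), 1e-300)
        out = np.zeros((len(remaining), len(theta)))
        if not np.any(active):
            return out

        if self._esc_stride <= 1 or len(remaining) <= 3:
            sel = np.arange(len(remaining))
        else:
            sel = np.arange(0, len(remaining), self._esc_stride)
            if sel[-1] != len(remaining) - 1:
                sel = np.append(sel, len(remaining) - 1)
        e_esc = remaining[sel] - e_n
        live = e_esc > 0
        mu_esc = self._mu(np.clip(e_esc, self.physics.e_min * 1e-3, None))
        trans_c = np.zeros((len(sel), int(active.sum())))
        if np.any(live):
            trans_c[live] = np.exp(
                -mu_esc[live, None, None] * exit_l[None, active, :]
            ).mean(axis=2)
        if len(sel) == len(remaining):
            out[:, active] = trans_c
        else:
            # linear interpolation along the (ascending) energy axis
            cols = np.flatnonzero(active)
            for k, j in enumerate(cols):
                out[:, j] = np.interp(remaining, remaining[sel], trans_c[:, k])
        return out


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def chain_likelihood(
    ordered_events,
    e_gamma,
    geometry: DetectorGeometry,
    physics: CrossSectionTable,
    model: ComptonModel,
    config: EstimatorConfig | None = None,
):
    """Likelihood of an *ordered* chain at incident energy ``e_gamma``.

    ``ordered_events`` is a sequence of events (objects with position and
    ``energy_keV``, or (x, y, z, E) rows).  ``e_gamma`` may be a scalar or an
    array; evaluation is exact (no escape subgrid).  Returns the likelihood
    value(s), 0 where the trial energy cannot produce the chain.
    """
    positions, energies = _as_arrays(ordered_events)
    if np.any(energies <= 0):
        raise ValueError("event energies must be positive")
    base = config or EstimatorConfig()
    e_arr = np.atleast_1d(np.asarray(e_gamma, dtype=float))
    cfg = _replace_grid(base, e_arr)
    engine = LikelihoodEngine(geometry, physics, model, cfg)
    engine.grid = e_arr
    engine._mu_grid = physics.mu_clamped(e_arr, cfg.include_coherent_in_mu)
    engine._esc_stride = 1
    curve = engine.curve_for_order(positions, energies)
    if not np.all(np.isfinite(curve)):
        raise FloatingPointError("non-finite likelihood value")
    return float(curve[0]) if np.ndim(e_gamma) == 0 else curve


def _replace_grid(cfg: EstimatorConfig, e_arr: np.ndarray) -> EstimatorConfig:
    from dataclasses import replace

    return replace(cfg, escape_grid_step=0.0)


def order_marginal_estimate(
    chain,
    geometry: DetectorGeometry,
    physics: CrossSectionTable,
    model: ComptonModel,
    config: EstimatorConfig = EstimatorConfig(),
    engine: LikelihoodEngine | None = None,
    spectrum_weights=None,
) -> LikelihoodResult:
    """Ideal-detector ML estimate: enumerate orderings, pick largest maximum.

    Evaluates the likelihood term of every permutation of the observed events
    on the energy grid; the estimate is the grid argmax of the winning term
    and the (x, y) of its assumed first interaction.  Ties between terms are
    broken toward the lexicographically first permutation, ties on the grid
    toward the lower energy.

    ``spectrum_weights`` optionally multiplies every likelihood curve by a
    known incident-spectrum density P(E_gamma | S) sampled on the energy grid
    (the estimator itself is flat-prior, matching a uniform benchmark
    spectrum).
    """
    positions, energies = _as_arrays(chain)
    engine = engine or LikelihoodEngine(geometry, physics, model, config)
    n = len(energies)
    if n < 1:
        raise ValueError("chain has no events")
    if n > config.max_events:
        raise ValueError(
            f"chain has {n} events (> max_events={config.max_events}); "
            "truncate or raise max_events"
        )
    orders = list(itertools.permutations(range(n)))
    curves = np.stack([
        engine.curve_for_order(positions[list(p)], energies[list(p)]) for p in orders
    ])
    curves = _apply_spectrum(curves, engine.grid, spectrum_weights)
    return _select(engine.grid, orders, curves, positions, n, 0)


def mc_integrated_estimate(
    chain,
    noise: NoiseModel,
    geometry: DetectorGeometry,
    physics: CrossSectionTable,
    model: ComptonModel,
    config: EstimatorConfig = EstimatorConfig(),
    rng: np.random.Generator | None = None,
    engine: LikelihoodEngine | None = None,
    return_realizations: bool = False,
    spectrum_weights=None,
):
    """Realistic-detector ML estimate via Monte Carlo integration.

    Gaussian perturbations of the observed chain (``config.mc_realizations``
    copies) represent the detector resolution; per-permutation likelihood
    curves are averaged over the copies before the largest-maximum selection.
    Realizations in which any perturbed energy rounds to 0 keV or below are
    skipped and excluded from the average.  Perturbed depths are clipped to
    the detector slab.
    """
    positions, energies = _as_arrays(chain)
    n = len(energies)
    engine = engine or LikelihoodEngine(geometry, physics, model, config)
    if n > config.max_events:
        raise ValueError(
            f"chain has {n} events (> max_events={config.max_events})"
        )
    rng = rng or np.random.default_rng()
    orders = list(itertools.permutations(range(n)))
    n_real = max(1, config.mc_realizations)
    acc = np.zeros((len(orders), len(engine.grid)))
    per_real = [] if return_realizations else None
    n_valid = 0
    n_skipped = 0
    step = model.energy_step
    sig_pos = np.array([noise.sigma_x, noise.sigma_y, noise.sigma_z])
    for _ in range(n_real):
        if noise.is_zero:
            pos_r, e_r = positions, energies
        else:
            e_r = energies + rng.normal(0.0, noise.sigma_E, size=n)
            e_r = np.round(e_r / step) * step
            if np.any(e_r <= 0):
                n_skipped += 1
                continue
            pos_r = positions + rng.normal(0.0, 1.0, size=(n, 3)) * sig_pos
            pos_r[:, 2] = np.clip(pos_r[:, 2], 0.0, geometry.depth_Ld)
        curves_r = np.stack([
            engine.curve_for_order(pos_r[list(p)], e_r[list(p)]) for p in orders
        ])
        acc += curves_r
        n_valid += 1
        if per_real is not None:
            per_real.append(curves_r)
    if n_valid == 0:
        raise EstimationError(
            "all Monte Carlo realizations were skipped (non-positive energies)"
        )
    curves = _apply_spectrum(acc / n_valid, engine.grid, spectrum_weights)
    result = _select(engine.grid, orders, curves, positions, n, n_skipped)
    if return_realizations:
        return result, per_real
    return result


def _apply_spectrum(curves, grid, spectrum_weights):
    """Multiply curves by a known incident-spectrum density on the grid."""
    if spectrum_weights is None:
        return curves
    w = np.asarray(spectrum_weights, dtype=float)
    if w.shape != grid.shape:
        raise ValueError("spectrum weights must be sampled on the energy grid")
    if np.any(w < 0):
        raise ValueError("spectrum weights must be non-negative")
    return curves * w


def _select(grid, orders, curves, positions, n_events, n_skipped) -> LikelihoodResult:
    maxima = curves.max(axis=1)
    win = int(np.argmax(maxima))  # first occurrence = lexicographic tie-break
    first = orders[win][0]
    e_hat = float(grid[int(np.argmax(curves[win]))])
    return LikelihoodResult(
        energy_grid=grid,
        orders=orders,
        curves=curves,
        winning_index=win,
        e_hat_keV=e_hat,
        x_hat_mm=float(positions[first, 0]),
        y_hat_mm=float(positions[first, 1]),
        z_hat_mm=float(positions[first, 2]),
        winning_max=float(maxima[win]),
        n_events=n_events,
        n_skipped_realizations=n_skipped,
    )


def _as_arrays(chain_or_events):
    """Accept an InteractionChain, a list of events, or an (n, 4) array."""
    events = getattr(chain_or_events, "events", chain_or_events)
    if isinstance(events, np.ndarray):
        arr = np.asarray(events, dtype=float)
        return arr[:, :3].copy(), arr[:, 3].copy()
    positions = np.array([
        [ev.x_mm, ev.y_mm, ev.z_mm] for ev in events
    ], dtype=float)
    energies = np.array([ev.energy_keV for ev in events], dtype=float)
    return positions, energies


def write_results_csv(results, chain_ids, path) -> None:
    """Persist estimation results, one row per chain."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "chain_id", "E_hat_keV", "x_hat_mm", "y_hat_mm",
            "winning_order", "n_events", "n_skipped_realizations",
        ])
        for cid, res in zip(chain_ids, results):
            writer.writerow([
                cid, res.e_hat_keV, res.x_hat_mm, res.y_hat_mm,
                "-".join(map(str, res.winning_order)),
                res.n_events, res.n_skipped_realizations,
            ])
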