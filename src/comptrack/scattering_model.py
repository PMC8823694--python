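"""Compton kinematics and the effective scattering model.

The model couples exact single-scatter kinematics with two empirical
surfaces:

* ``P(theta | E_gamma)`` — the polar scattering-angle density.  The default is
  the Klein-Nishina differential cross section converted to a per-angle
  density (x 2 pi sin(theta)), multiplied by a simple incoherent-scattering-
  function suppression factor S(q, Z=14) that removes the unphysical
  low-angle excess for bound electrons, then renormalized on [0, pi].
* ``sigma_Ed(theta, E_gamma)`` — the width of the deposited-energy spread
  around the free-electron Compton value at fixed angle (Doppler broadening
  plus unresolved intermediate Rayleigh deflections).  The default is a
  low-order surface giving widths of order 1 keV at (pi/2, 60 keV).

The deposited energy at fixed angle is modelled as an equal-weight two-term
Gaussian centred on the Compton formula value with widths sigma_1 =
sigma_Ed(theta, E_gamma) and sigma_2 = 0.18 sigma_1, truncated to [0, E_gamma)
and renormalized.  Both surfaces are pluggable: any callables with the same
signatures (or tabulated versions loaded from CSV) can replace the defaults,
e.g. to use distributions fitted to an external Monte Carlo code.

Energies are keV, angles radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import ndtr

__all__ = [
    "ELECTRON_REST_ENERGY_KEV",
    "ComptonModel",
    "ScatterSample",
    "deposited_energy",
    "scattering_angle_for_deposit",
    "kinematic_max_deposit",
    "klein_nishina_theta_weight",
    "incoherent_suppression",
    "model_from_tables",
]

ELECTRON_REST_ENERGY_KEV = 511.0

#: hc in keV * Angstrom, for the momentum-transfer variable of S(q, Z).
_HC_KEV_ANGSTROM = 12.3984


# ----------------------------------------------------------------------
# kinematics
# ----------------------------------------------------------------------

def deposited_energy(e_gamma, theta):
    """Energy transferred to the electron for a scatter at angle ``theta``.

    Single-scatter Compton formula off a free electron at rest:
    ``Ed = E^2 (1 - cos th) / (mec2 + E (1 - cos th))``; monotone increasing
    in theta, reaching the Compton-edge maximum at backscatter.
    """
    e = np.asarray(e_gamma, dtype=float)
    th = np.asarray(theta, dtype=float)
    if np.any((th < 0) | (th > np.pi)):
        raise ValueError("theta must lie in [0, pi]")
    omc = 1.0 - np.cos(th)
    out = e * e * omc / (ELECTRON_REST_ENERGY_KEV + e * omc)
    if out.ndim == 0:
        return float(out)
    return out


def kinematic_max_deposit(e_gamma):
    """Compton-edge deposit (backscatter, theta = pi)."""
    return deposited_energy(e_gamma, np.pi)


def scattering_angle_for_deposit(e_deposit, e_gamma):
    """Invert the Compton formula: angle producing deposit ``e_deposit``.

    Returns NaN where the deposit exceeds the kinematic maximum.
    """
    e = np.asarray(e_gamma, dtype=float)
    ed = np.asarray(e_deposit, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        omc = ELECTRON_REST_ENERGY_KEV * ed / (e * (e - ed))
    cos_th = 1.0 - omc
    out = np.where(
        (ed >= 0) & (ed < e) & (cos_th >= -1.0), np.arccos(np.clip(cos_th, -1, 1)),
        np.nan,
    )
    if out.ndim == 0:
        return float(out)
    return out


# ----------------------------------------------------------------------
# default angular model
# ----------------------------------------------------------------------

def klein_nishina_theta_weight(theta, e_gamma):
    """Unnormalized Klein-Nishina per-angle weight, dsigma/dtheta shape.

    The differential cross section per solid angle is
    ``(r_e^2 / 2) r^2 (r + 1/r - sin^2 th)`` with ``r`` the scattered-to-
    incident energy ratio; the per-angle density carries the solid-angle
    factor ``2 pi sin th``.  Constant prefactors are dropped (the model
    renormalizes).
    """
    th = np.asarray(theta, dtype=float)
    e = np.asarray(e_gamma, dtype=float)
    eps = e / ELECTRON_REST_ENERGY_KEV
    r = 1.0 / (1.0 + eps * (1.0 - np.cos(th)))
    return np.sin(th) * r * r * (r + 1.0 / r - np.sin(th) ** 2)


def incoherent_suppression(theta, e_gamma, x_half=0.55, power=1.7):
    """Smooth S(q, Z)/Z stand-in: suppresses low momentum-transfer scatter.

    ``x = E sin(theta/2) / hc`` (inverse Angstroms) is the standard
    momentum-transfer variable; the factor rises from 0 at x = 0 to 1 at
    large x with half value at ``x_half``, approximating the shape of the
    tabulated incoherent scattering function for silicon.
    """
    th = np.asarray(theta, dtype=float)
    e = np.asarray(e_gamma, dtype=float)
    x = e * np.sin(th / 2.0) / _HC_KEV_ANGSTROM
    u = (x / x_half) ** power
    return u / (1.0 + u)


def _default_angle_weight(theta, e_gamma):
    return klein_nishina_theta_weight(theta, e_gamma) * incoherent_suppression(
        theta, e_gamma
    )


def _default_sigma_ed(theta, e_gamma):
    """Deposit-broadening surface, keV; ~1 keV at (pi/2, 60 keV)."""
    th = np.asarray(theta, dtype=float)
    e = np.asarray(e_gamma, dtype=float)
    return 0.15 + 1.2 * (e / 60.0) * np.sin(th / 2.0)


# ----------------------------------------------------------------------
# model
# ----------------------------------------------------------------------

@dataclass
class ScatterSample:
    """One sampled Compton scatter: deposit (keV) and outgoing angles (rad)."""

    deposited_energy: float
    theta: float
    phi: float


# Gauss-Hermite nodes/weights used for the optional angular smearing kernel.
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(9)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@dataclass
class ComptonModel:
    """Effective Compton scattering distributions for one material.

    Parameters
    ----------
    angle_weight_fn:
        Unnormalized per-angle weight ``w(theta, E)``; renormalized on
        [0, pi] internally.
    sigma_ed_fn:
        Deposit-broadening surface ``sigma_Ed(theta, E)`` in keV, positive on
        (0, pi].
    narrow_component_ratio:
        sigma_2 / sigma_1 of the two-term Gaussian deposit model.
    theta_step:
        Width of the discretized polar-angle bins used for quadrature and
        sampling.
    energy_step:
        Energy discretization of sampled deposits.
    angular_smear_rad:
        Optional Gaussian smearing of the angle weight (stand-in for
        unresolved intermediate Rayleigh deflections); 0 disables it.
    """

    angle_weight_fn: Callable = None
    sigma_ed_fn: Callable = None
    narrow_component_ratio: float = 0.18
    component_weights: tuple[float, float] = (0.5, 0.5)
    theta_step: float = 0.1
    energy_step: float = 0.1
    angular_smear_rad: float = 0.0
    electron_rest_energy: float = ELECTRON_REST_ENERGY_KEV

    theta_mid: np.ndarray = field(init=False, repr=False)
    theta_width: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.angle_weight_fn is None:
            self.angle_weight_fn = _default_angle_weight
        if self.sigma_ed_fn is None:
            self.sigma_ed_fn = _default_sigma_ed
        edges = np.append(np.arange(0.0, np.pi, self.theta_step), np.pi)
        self.theta_mid = 0.5 * (edges[:-1] + edges[1:])
        self.theta_width = np.diff(edges)
        self._norm_cache = None

    # -- angle pdf -------------------------------------------------------
    def _angle_weight(self, theta, e_gamma):
        if self.angular_smear_rad <= 0:
            return self.angle_weight_fn(theta, e_gamma)
        th = np.asarray(theta, dtype=float)
        out = 0.0
        for u, w in zip(_GH_NODES, _GH_WEIGHTS):
            shifted = th + self.angular_smear_rad * u
            shifted = np.abs(shifted)
            shifted = np.where(shifted > np.pi, 2 * np.pi - shifted, shifted)
            out = out + w * self.angle_weight_fn(shifted, e_gamma)
        return out

    def _angle_norm(self, e_gamma):
        """Normalizer of the angle weight, cached on a log-spaced energy grid."""
        if self._norm_cache is None:
            e_grid = np.geomspace(0.2, 250.0, 900)
            th = np.linspace(0.0, np.pi, 2049)
            mid = 0.5 * (th[:-1] + th[1:])
            dx = np.diff(th)
            w = self._angle_weight(mid[None, :], e_grid[:, None])
            self._norm_cache = (np.log(e_grid), np.log(w @ dx))
        log_e, log_n = self._norm_cache
        e = np.asarray(e_gamma, dtype=float)
        return np.exp(np.interp(np.log(np.clip(e, 0.2, 250.0)), log_e, log_n))

    def angle_pdf(self, theta, e_gamma):
        """P(theta | E_gamma): normalized per-angle density on [0, pi]."""
        th = np.asarray(theta, dtype=float)
        if np.any((th < 0) | (th > np.pi)):
            raise ValueError("theta must lie in [0, pi]")
        out = self._angle_weight(th, e_gamma) / self._angle_norm(e_gamma)
        if out.ndim == 0:
            return float(out)
        return out

    # -- deposit pdf at fixed angle --------------------------------------
    def sigma_ed(self, theta, e_gamma):
        return self.sigma_ed_fn(theta, e_gamma)

    def deposit_given_angle_pdf(self, e_deposit, e_gamma, theta):
        """P(E | E_gamma, theta): two-term Gaussian, truncated to [0, E_gamma).

        At theta = 0 the kinematic transfer vanishes; the degenerate spike at
        0 keV is represented by a zero density at any positive deposit.
        """
        e = np.asarray(e_deposit, dtype=float)
        eg = np.asarray(e_gamma, dtype=float)
        th = np.asarray(theta, dtype=float)
        mean = deposited_energy(eg, th)
        s1 = np.asarray(self.sigma_ed(th, eg), dtype=float)
        s2 = self.narrow_component_ratio * s1
        w1, w2 = self.component_weights
        dens = w1 * _truncated_normal_pdf(e, mean, s1, eg) + w2 * (
            _truncated_normal_pdf(e, mean, s2, eg)
        )
        dens = np.where(th == 0.0, 0.0, dens)
        if dens.ndim == 0:
            return float(dens)
        return dens

    # -- joint / marginals ------------------------------------------------
    def joint_pdf(self, e_deposit, theta, e_gamma):
        """P(E, theta | E_gamma) = P(E | E_gamma, theta) P(theta | E_gamma)."""
        return self.deposit_given_angle_pdf(e_deposit, e_gamma, theta) * (
            self.angle_pdf(theta, e_gamma)
        )

    def deposit_pdf(self, e_deposit, e_gamma):
        """P(E | E_gamma) marginalized over the discretized angle grid."""
        e = np.asarray(e_deposit, dtype=float)[..., None]
        eg = np.asarray(e_gamma, dtype=float)[..., None]
        joint = self.joint_pdf(e, self.theta_mid, eg)
        out = joint @ self.theta_width
        if out.ndim == 0:
            return float(out)
        return out

    #: Marginal deposit densities (per keV) below this are treated as
    #: impossible (E, E_gamma) pairs: far beyond the Compton edge plus any
    #: Gaussian tail, where the posterior would be numerical noise.
    impossible_density_floor: float = 1e-30

    def angle_posterior(self, theta, e_gamma, e_deposit):
        """P(theta | E_gamma, E): joint pdf renormalized over the angle grid.

        Returns 0 everywhere when the deposit is impossible for this incident
        energy (marginal below ``impossible_density_floor``); the caller
        treats the chain likelihood as 0 there.
        """
        floor = self.impossible_density_floor
        marginal = self.deposit_pdf(e_deposit, e_gamma)
        joint = self.joint_pdf(e_deposit, theta, e_gamma)
        if np.ndim(marginal) == 0:
            if marginal <= floor:
                return np.zeros_like(np.asarray(theta, dtype=float))
            return joint / marginal
        marginal = np.asarray(marginal)[..., None]
        return np.where(
            marginal > floor, joint / np.where(marginal > floor, marginal, 1.0), 0.0
        )

    # -- sampling ----------------------------------------------------------
    def sample_scatter(self, e_gamma: float, rng: np.random.Generator) -> ScatterSample:
        """Draw (deposit, theta, phi) for one Compton scatter.

        theta is drawn from the discretized angle pdf (bin midpoints), the
        deposit from the two-term Gaussian truncated to (0, E_gamma) and
        rounded to the energy grid with a floor of one grid step, phi
        uniformly on [0, 2 pi).
        """
        if e_gamma <= 2 * self.energy_step:
            raise ValueError("incident energy too low to produce a valid deposit")
        pmf = self.angle_pdf(self.theta_mid, e_gamma) * self.theta_width
        cdf = np.cumsum(pmf)
        cdf /= cdf[-1]
        theta = float(self.theta_mid[np.searchsorted(cdf, rng.random())])
        mean = deposited_energy(e_gamma, theta)
        s1 = float(self.sigma_ed(theta, e_gamma))
        sigmas = (s1, self.narrow_component_ratio * s1)
        weights = np.asarray(self.component_weights)
        for _ in range(1000):
            sigma = sigmas[rng.choice(2, p=weights / weights.sum())]
            draw = rng.normal(mean, sigma)
            if 0.0 < draw < e_gamma:
                break
        else:  # pragma: no cover - pathological surface
            draw = np.clip(mean, self.energy_step, e_gamma - self.energy_step)
        step = self.energy_step
        deposit = np.clip(round(draw / step) * step, step, e_gamma - step)
        phi = float(rng.uniform(0.0, 2.0 * np.pi))
        return ScatterSample(deposited_energy=float(deposit), theta=theta, phi=phi)


def _truncated_normal_pdf(x, mean, sigma, upper):
    """Normal pdf truncated to [0, upper) and renormalized (vectorized)."""
    sigma = np.asarray(sigma, dtype=float)
    z = (x - mean) / sigma
    mass = ndtr((upper - mean) / sigma) - ndtr((0.0 - mean) / sigma)
    core = np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))
    inside = (x >= 0.0) & (x < upper) & (mass > 0.0)
    return np.where(inside, core / np.where(mass > 0, mass, 1.0), 0.0)


# ----------------------------------------------------------------------
# externally fitted tables
# ----------------------------------------------------------------------

def model_from_tables(angle_csv, sigma_csv, **kwargs) -> ComptonModel:
    """Build a ComptonModel from externally fitted CSV tables.

    ``angle_csv`` holds columns (E_gamma_keV, theta_rad, pdf_value) and
    ``sigma_csv`` columns (E_gamma_keV, theta_rad, sigmaEd_keV), each on a
    rectangular (energy x angle) grid.  Values are interpolated bilinearly.
    """
    angle_fn = _bilinear_from_csv(angle_csv)
    sigma_fn = _bilinear_from_csv(sigma_csv)
    return ComptonModel(angle_weight_fn=angle_fn, sigma_ed_fn=sigma_fn, **kwargs)


def _bilinear_from_csv(path) -> Callable:
    data = np.genfromtxt(path, delimiter=",", names=True)
    e_vals = np.unique(data[data.dtype.names[0]])
    th_vals = np.unique(data[data.dtype.names[1]])
    grid = np.asarray(data[data.dtype.names[2]]).reshape(len(e_vals), len(th_vals))
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (e_vals, th_vals), grid, bounds_error=False, fill_value=None
    )

    def fn(theta, e_gamma):
        th, e = np.broadcast_arrays(
            np.asarray(theta, dtype=float), np.asarray(e_gamma, dtype=float)
        )
        pts = np.stack([e.ravel(), th.ravel()], axis=-1)
        return interp(pts).reshape(th.shape)

    return fn
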