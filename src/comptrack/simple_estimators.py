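"""Threshold-plus-Bayes alternative estimator and the per-event baseline.

The alternative method ignores Compton kinematics entirely: events at or
above the 38.3-keV classification threshold (the Compton-edge deposit of a
120-keV photon, i.e. the largest single Compton deposit the spectrum can
produce) are labelled photoelectric, the rest Compton.  With at least one
photoelectric label the incident energy is the plain sum of deposits;
otherwise it is the maximum-posterior incident energy given the *total*
deposit, with the posterior obtained by Bayes inversion of a simulated
P(Etot | E_gamma) table under a uniform incident spectrum.  The position
estimate is the mean position of the Compton-labelled events.

The baseline treats every interaction as its own photon: energy from the
per-event posterior P(E_gamma | E), position from the event itself.  It
mimics a conventional photon-counting detector with no coincidence logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import DetectorGeometry
from .physics_tables import CrossSectionTable
from .scattering_model import ComptonModel, kinematic_max_deposit
from .simulator import simulate_batch

__all__ = [
    "COMPTON_THRESHOLD_KEV",
    "DepositLookup",
    "build_deposit_tables",
    "alternative_estimate",
    "baseline_estimate",
]

#: Compton-edge deposit of a 120-keV photon; classification boundary.
COMPTON_THRESHOLD_KEV = round(kinematic_max_deposit(120.0), 1)


@dataclass
class DepositLookup:
    """Simulated deposit distributions and their Bayes-inverted posteriors.

    ``p_total`` and ``p_event`` are conditional tables P(deposit bin | E_gamma)
    with one column per incident-energy grid node (columns sum to 1); the
    posteriors assume a uniform incident spectrum over the grid range.
    Deposit bins are ``deposit_step`` wide, centred on the energy grid values
    ``deposit_step, 2 deposit_step, ...``.
    """

    incident_grid: np.ndarray
    deposit_step: float
    p_total: np.ndarray  # (n_bins, n_incident)
    p_event: np.ndarray  # (n_bins, n_incident)
    seed: int | None = None
    n_per_energy: int = 0
    posterior_total: np.ndarray = field(init=False, repr=False)
    posterior_event: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.posterior_total = _normalize_rows(self.p_total)
        self.posterior_event = _normalize_rows(self.p_event)

    # -- lookups ---------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.p_total.shape[0]

    def _bin_index(self, deposit_keV: float, table: np.ndarray, label: str) -> int:
        idx = int(round(deposit_keV / self.deposit_step)) - 1
        if not 0 <= idx < self.n_bins:
            warnings.warn(
                f"{label} deposit {deposit_keV} keV outside table support; "
                "using nearest bin"
            )
            idx = min(max(idx, 0), self.n_bins - 1)
        if table[idx].sum() <= 0:
            populated = np.flatnonzero(table.sum(axis=1) > 0)
            if len(populated) == 0:
                raise ValueError("deposit table is empty")
            near = populated[np.argmin(np.abs(populated - idx))]
            warnings.warn(
                f"{label} deposit {deposit_keV} keV never seen in training; "
                "using nearest populated bin"
            )
            idx = int(near)
        return idx

    def map_incident(self, deposit_keV: float, per_event: bool = False,
                     resolution: float = 0.1) -> float:
        """Maximum-posterior incident energy for one deposit value.

        Posterior columns are linearly interpolated onto a ``resolution``-step
        incident-energy grid before the argmax; ties break toward the lower
        energy.
        """
        table = self.posterior_event if per_event else self.posterior_total
        row = table[self._bin_index(deposit_keV, table, "per-event" if per_event
                                    else "total")]
        fine = np.arange(self.incident_grid[0], self.incident_grid[-1] + 1e-9,
                         resolution)
        vals = np.interp(fine, self.incident_grid, row)
        return float(fine[int(np.argmax(vals))])

    # -- persistence -------------------------------------------------------
    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed: {self.seed}\n# n_per_energy: {self.n_per_energy}\n")
            fh.write(f"# deposit_step_keV: {self.deposit_step}\n")
            fh.write("# columns: deposit_bin_keV then P(bin|E) for each "
                     "incident energy\n")
            fh.write("deposit_keV,table," +
                     ",".join(f"{e:g}" for e in self.incident_grid) + "\n")
            for name, tab in (("total", self.p_total), ("event", self.p_event)):
                for i in range(self.n_bins):
                    if tab[i].sum() == 0:
                        continue
                    fh.write(f"{(i + 1) * self.deposit_step:.1f},{name}," +
                             ",".join(f"{v:.8g}" for v in tab[i]) + "\n")

    @classmethod
    def load_csv(cls, path) -> "DepositLookup":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if ":" in line:
                        key, val = line[1:].split(":", 1)
                        meta[key.strip()] = val.strip()
                    continue
                rows.append(line.rstrip("\n"))
        header = rows[0].split(",")
        grid = np.array([float(v) for v in header[2:]])
        step = float(meta.get("deposit_step_keV", 0.1))
        n_bins = int(round(grid[-1] / step))
        p_total = np.zeros((n_bins, len(grid)))
        p_event = np.zeros((n_bins, len(grid)))
        for line in rows[1:]:
            parts = line.split(",")
            idx = int(round(float(parts[0]) / step)) - 1
            target = p_total if parts[1] == "total" else p_event
            target[idx] = [float(v) for v in parts[2:]]
        seed = meta.get("seed")
        return cls(
            incident_grid=grid, deposit_step=step, p_total=p_total,
            p_event=p_event,
            seed=None if seed in (None, "None") else int(seed),
            n_per_energy=int(meta.get("n_per_energy", 0)),
        )


def _normalize_rows(table: np.ndarray) -> np.ndarray:
    sums = table.sum(axis=1, keepdims=True)
    return np.where(sums > 0, table / np.where(sums > 0, sums, 1.0), 0.0)


def build_deposit_tables(
    n_per_energy: int,
    energy_step: float,
    geometry: DetectorGeometry,
    physics: CrossSectionTable,
    model: ComptonModel,
    seed: int | None = None,
    energy_min: float = 15.0,
    energy_max: float = 120.0,
    deposit_step: float = 0.1,
    include_coherent_in_mu: bool = True,
) -> DepositLookup:
    """Simulate monoenergetic batches and histogram their deposits.

    For every incident energy on the [energy_min, energy_max] grid,
    ``n_per_energy`` photons are tracked; the total chain deposit feeds
    P(Etot | E_gamma) and every individual event feeds P(E | E_gamma).
    Photons that leave without interacting produce no observation.
    """
    n_steps = int(round((energy_max - energy_min) / energy_step))
    grid = energy_min + energy_step * np.arange(n_steps + 1)
    n_bins = int(round(energy_max / deposit_step))
    p_total = np.zeros((n_bins, len(grid)))
    p_event = np.zeros((n_bins, len(grid)))
    root = np.random.SeedSequence(seed)
    for j, (e_gamma, ss) in enumerate(zip(grid, root.spawn(len(grid)))):
        chains = simulate_batch(
            n_per_energy, float(e_gamma), geometry, physics, model,
            seed=np.random.default_rng(ss),
            include_coherent_in_mu=include_coherent_in_mu,
        )
        for chain in chains:
            if not chain.events:
                continue
            tot_idx = int(round(chain.total_deposit_keV / deposit_step)) - 1
            if 0 <= tot_idx < n_bins:
                p_total[tot_idx, j] += 1
            for ev in chain.events:
                ev_idx = int(round(ev.energy_keV / deposit_step)) - 1
                if 0 <= ev_idx < n_bins:
                    p_event[ev_idx, j] += 1
    p_total /= np.maximum(p_total.sum(axis=0, keepdims=True), 1.0)
    p_event /= np.maximum(p_event.sum(axis=0, keepdims=True), 1.0)
    return DepositLookup(
        incident_grid=grid, deposit_step=deposit_step,
        p_total=p_total, p_event=p_event,
        seed=seed, n_per_energy=n_per_energy,
    )


def alternative_estimate(
    chain,
    lookup: DepositLookup,
    threshold_keV: float = COMPTON_THRESHOLD_KEV,
) -> tuple[float, float, float]:
    """(E_hat, x_hat, y_hat) of the threshold-plus-Bayes method.

    Multi-event chains in which *every* event exceeds the threshold (possible
    only for unusual or noise-distorted chains) have no Compton-labelled
    event to average; the position falls back to the mean over all events.
    """
    events = getattr(chain, "events", chain)
    if not events:
        raise ValueError("chain has no events")
    energies = np.array([ev.energy_keV for ev in events])
    xy = np.array([[ev.x_mm, ev.y_mm] for ev in events])
    is_photo = energies >= threshold_keV
    if np.any(is_photo):
        e_hat = float(np.round(energies.sum(), 6))
    else:
        e_hat = lookup.map_incident(float(np.round(energies.sum(), 6)))
    if len(events) == 1:
        pos = xy[0]
    elif np.all(is_photo):
        pos = xy.mean(axis=0)
    else:
        pos = xy[~is_photo].mean(axis=0)
    return e_hat, float(pos[0]), float(pos[1])


def baseline_estimate(event, lookup: DepositLookup) -> tuple[float, float, float]:
    """(E_hat, x_hat, y_hat) assuming the single event is a whole photon."""
    e_hat = lookup.map_incident(float(event.energy_keV), per_event=True)
    return e_hat, float(event.x_mm), float(event.y_mm)
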