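"""Monte Carlo simulation of photon interaction chains in the silicon slab.

Each incident photon is tracked interaction by interaction: free path lengths
are sampled from the Beer-Lambert law along the current direction (leaving
through a z face = escape), the interaction type from the relative
photoelectric/Compton cross sections, and Compton scatters from the effective
scattering model.  Photoelectric absorption deposits the full remaining
energy and terminates the chain.  All deposits live on a 0.1-keV grid with a
0.1-keV floor.

Ground truth (incident energy and position, interaction types, true order)
is carried on every simulated chain; estimators must not read it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import BEAM_DIRECTION, DetectorGeometry, scatter_direction
from .physics_tables import CrossSectionTable
from .scattering_model import ComptonModel

__all__ = [
    "InteractionEvent",
    "InteractionChain",
    "simulate_photon",
    "simulate_batch",
    "classify_chain",
    "chain_census",
    "write_chains_jsonl",
    "read_chains_jsonl",
    "write_chains_csv",
    "read_chains_csv",
]

PHOTOELECTRIC = "photoelectric"
COMPTON = "compton"
ESCAPE = "escape"


@dataclass
class InteractionEvent:
    """One registered interaction: position (mm), deposited energy (keV)."""

    x_mm: float
    y_mm: float
    z_mm: float
    energy_keV: float
    true_type: str | None = None
    true_order: int | None = None

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm, self.z_mm])


@dataclass
class InteractionChain:
    """All interactions produced by one incident photon.

    ``events`` are stored in true order for simulated chains; observed chains
    (after noise application) carry a shuffled copy.  ``terminated_by`` is
    'photoelectric' when the full incident energy was absorbed, 'escape' when
    the (possibly scattered) photon left through a z face.
    """

    chain_id: int
    events: list[InteractionEvent] = field(default_factory=list)
    true_e_gamma_keV: float | None = None
    true_x_mm: float | None = None
    true_y_mm: float | None = None
    terminated_by: str | None = None

    def __len__(self) -> int:
        return len(self.events)

    @property
    def total_deposit_keV(self) -> float:
        return round(sum(ev.energy_keV for ev in self.events), 6)

    def positions(self) -> np.ndarray:
        return np.array([[ev.x_mm, ev.y_mm, ev.z_mm] for ev in self.events])

    def energies(self) -> np.ndarray:
        return np.array([ev.energy_keV for ev in self.events])


def simulate_photon(
    e_gamma: float,
    incident_xy,
    geometry: DetectorGeometry,
    physics: CrossSectionTable,
    model: ComptonModel,
    rng: np.random.Generator,
    include_coherent_in_mu: bool = True,
    chain_id: int = 0,
) -> InteractionChain:
    """Track one incident photon of energy ``e_gamma`` entering at ``incident_xy``.

    The photon enters at z = 0 travelling along +z.  Photons whose remaining
    energy falls below the cross-section table floor (or below three energy
    grid steps, where no valid Compton deposit plus remainder exists) are
    absorbed locally: at those energies the photoelectric cross section
    dominates and the mean free path is far below the spatial resolution.
    """
    x0, y0 = float(incident_xy[0]), float(incident_xy[1])
    chain = InteractionChain(
        chain_id=chain_id, true_e_gamma_keV=float(e_gamma),
        true_x_mm=x0, true_y_mm=y0,
    )
    step = model.energy_step
    energy = round(float(e_gamma), 6)
    position = np.array([x0, y0, 0.0])
    direction = BEAM_DIRECTION.copy()
    order = 0
    while True:
        mu = float(physics.mu_clamped(energy, include_coherent_in_mu))
        exit_d = geometry.exit_distance_z(position[2], direction[2])
        free_path = rng.exponential(1.0 / mu)
        if free_path > exit_d:
            chain.terminated_by = ESCAPE
            return chain
        position = position + free_path * direction
        forced_photo = energy < max(physics.e_min, 3 * step)
        if not forced_photo:
            p_photo = float(physics.p_photo(energy))
            forced_photo = rng.random() < p_photo
        if forced_photo:
            chain.events.append(InteractionEvent(
                position[0], position[1], position[2], energy,
                true_type=PHOTOELECTRIC, true_order=order,
            ))
            chain.terminated_by = PHOTOELECTRIC
            return chain
        sample = model.sample_scatter(energy, rng)
        chain.events.append(InteractionEvent(
            position[0], position[1], position[2], sample.deposited_energy,
            true_type=COMPTON, true_order=order,
        ))
        energy = round(energy - sample.deposited_energy, 6)
        direction = scatter_direction(direction, sample.theta, sample.phi)
        order += 1


def simulate_batch(
    n: int,
    e_gamma: float,
    geometry: DetectorGeometry,
    physics: CrossSectionTable,
    model: ComptonModel,
    seed=None,
    include_coherent_in_mu: bool = True,
) -> list[InteractionChain]:
    """Simulate ``n`` incident photons with (x, y) uniform over the incident area.

    ``seed`` may be an integer, a SeedSequence or a Generator; a fixed seed
    reproduces the chain collection exactly.
    """
    if n < 1:
        raise ValueError("need at least one photon")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xy = geometry.sample_incident_position(rng, n)
    return [
        simulate_photon(
            e_gamma, xy[k], geometry, physics, model, rng,
            include_coherent_in_mu=include_coherent_in_mu, chain_id=k,
        )
        for k in range(n)
    ]


def classify_chain(chain: InteractionChain) -> str:
    """Chain-type label from ground-truth interaction types.

    Labels follow the census convention: '0 interactions', 'k Compton',
    '1 photoelectric', or 'k Compton + 1 photoelectric'.
    """
    if not chain.events:
        return "0 interactions"
    types = [ev.true_type for ev in chain.events]
    if any(t is None for t in types):
        raise ValueError("chain lacks ground-truth interaction types")
    n_compton = sum(t == COMPTON for t in types)
    has_photo = types[-1] == PHOTOELECTRIC
    if has_photo and n_compton == 0:
        return "1 photoelectric"
    if has_photo:
        return f"{n_compton} Compton + 1 photoelectric"
    return f"{n_compton} Compton"


def chain_census(chains) -> dict[str, float]:
    """Percentage of incident photons per chain-type label (sums to 100)."""
    counts: dict[str, int] = {}
    for chain in chains:
        label = classify_chain(chain)
        counts[label] = counts.get(label, 0) + 1
    total = len(chains)
    return {k: 100.0 * v / total for k, v in sorted(
        counts.items(), key=lambda kv: -kv[1]
    )}


# ----------------------------------------------------------------------
# chain-record files
# ----------------------------------------------------------------------

def _chain_to_dict(chain: InteractionChain) -> dict:
    return {
        "chain_id": chain.chain_id,
        "truth": {
            "E_gamma_keV": chain.true_e_gamma_keV,
            "x_mm": chain.true_x_mm,
            "y_mm": chain.true_y_mm,
            "terminated_by": chain.terminated_by,
        },
        "events": [
            {
                "x_mm": ev.x_mm, "y_mm": ev.y_mm, "z_mm": ev.z_mm,
                "E_keV": ev.energy_keV,
                "true_type": ev.true_type, "true_order": ev.true_order,
            }
            for ev in chain.events
        ],
    }


def _chain_from_dict(rec: dict) -> InteractionChain:
    truth = rec.get("truth") or {}
    chain = InteractionChain(
        chain_id=rec["chain_id"],
        true_e_gamma_keV=truth.get("E_gamma_keV"),
        true_x_mm=truth.get("x_mm"),
        true_y_mm=truth.get("y_mm"),
        terminated_by=truth.get("terminated_by"),
    )
    for ev in rec.get("events", []):
        chain.events.append(InteractionEvent(
            ev["x_mm"], ev["y_mm"], ev["z_mm"], ev["E_keV"],
            true_type=ev.get("true_type"), true_order=ev.get("true_order"),
        ))
    return chain


def write_chains_jsonl(chains, path) -> None:
    with open(path, "w") as fh:
        for chain in chains:
            fh.write(json.dumps(_chain_to_dict(chain)) + "\n")


def read_chains_jsonl(path) -> list[InteractionChain]:
    with open(path) as fh:
        return [_chain_from_dict(json.loads(line)) for line in fh if line.strip()]


_CSV_FIELDS = [
    "chain_id", "E_gamma_keV", "incident_x_mm", "incident_y_mm",
    "terminated_by", "x_mm", "y_mm", "z_mm", "E_keV", "true_type", "true_order",
]


def write_chains_csv(chains, path) -> None:
    """One event per row; chains with no events emit a single row of blanks."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for chain in chains:
            base = {
                "chain_id": chain.chain_id,
                "E_gamma_keV": chain.true_e_gamma_keV,
                "incident_x_mm": chain.true_x_mm,
                "incident_y_mm": chain.true_y_mm,
                "terminated_by": chain.terminated_by,
            }
            if not chain.events:
                writer.writerow(base)
            for ev in chain.events:
                writer.writerow({
                    **base,
                    "x_mm": ev.x_mm, "y_mm": ev.y_mm, "z_mm": ev.z_mm,
                    "E_keV": ev.energy_keV,
                    "true_type": ev.true_type, "true_order": ev.true_order,
                })


def read_chains_csv(path) -> list[InteractionChain]:
    chains: dict[int, InteractionChain] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cid = int(row["chain_id"])
            if cid not in chains:
                chains[cid] = InteractionChain(
                    chain_id=cid,
                    true_e_gamma_keV=_opt_float(row["E_gamma_keV"]),
                    true_x_mm=_opt_float(row["incident_x_mm"]),
                    true_y_mm=_opt_float(row["incident_y_mm"]),
                    terminated_by=row["terminated_by"] or None,
                )
            if row["E_keV"]:
                chains[cid].events.append(InteractionEvent(
                    float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"]),
                    float(row["E_keV"]),
                    true_type=row["true_type"] or None,
                    true_order=int(row["true_order"]) if row["true_order"] else None,
                ))
    return [chains[k] for k in sorted(chains)]


def _opt_float(s):
    return float(s) if s else None
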