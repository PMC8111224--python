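"""Synthetic titration series and toy charged structures with known ground truth.

The generator emulates a CO-probe FTIR spectroelectrochemical titration: two
overlapping C≡O pseudo-Voigt bands (1963.7 and 1967.2 cm⁻¹) whose areas track
the R4CO and R2CO populations of a sequential three-state redox model on a
25 mV potential grid, plus a broad Lorentzian baseline drift and additive
i.i.d. Gaussian noise.  Every stage of the analysis pipeline (baseline
filtering, shared-shape band fitting, Nernst fitting, global fitting) can
therefore be tested against exact generating parameters without instrument
data.

Toy charged structures provide the analogous ground truth for the
electrostatics: point charges around an Fe–C–O probe whose state-difference
field at the probe midpoint has a closed form.
:func:`calibrated_transition_set` solves small linear systems to build charge
groups whose projected field changes reproduce a given table of target values
at several probe geometries — a worked-example stand-in (synthetic, not the
crystallographic charge model) for transition bookkeeping and combined sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bands import pseudo_voigt
from .electrostatics import (AtomID, ChargeState, ChargedAtom, ChargedStructure,
                             DEFAULT_EPS_R, ProbeGeometry, coulomb_field,
                             place_co_probe, project_field, Transition)
from .errors import ValidationError
from .spectra import SpectralSeries, Spectrum
from .titration import NernstTransition, SPECIES, ThreeStateModel, three_state_populations

#: default electrode potential grid, mV vs Ag/AgCl (25 mV steps)
DEFAULT_POTENTIALS = np.arange(-500.0, 551.0, 25.0)
#: default wavenumber grid around the C≡O region, cm⁻¹ (2 cm⁻¹ resolution)
DEFAULT_WAVENUMBERS = np.arange(1800.0, 2100.1, 2.0)


@dataclass(frozen=True)
class BandSpec:
    """One generated band: shape parameters, maximum area and the species
    whose population scales the area (Beer–Lambert proportionality)."""

    center: float
    fwhm: float = 4.0
    eta: float = 0.2
    max_area: float = 0.1
    species: str = "R4CO"


@dataclass(frozen=True)
class TitrationScenario:
    """Ground-truth description of a synthetic titration experiment.

    Defaults reproduce the reference conditions: bands at 1963.7 (R4CO) and
    1967.2 cm⁻¹ (R2CO), midpoints 102 / 237 mV with apparent n = 1,
    −500…+550 mV in 25 mV steps, 2 cm⁻¹ resolution, noise at peak SNR ≈ 50
    and a broad 300 cm⁻¹-FWHM baseline drift.
    """

    potential_grid: np.ndarray = field(default_factory=lambda: DEFAULT_POTENTIALS.copy())
    bands: tuple[BandSpec, ...] = (
        BandSpec(center=1963.7, species="R4CO"),
        BandSpec(center=1967.2, species="R2CO"),
    )
    species_model: ThreeStateModel = field(default_factory=lambda: ThreeStateModel(
        NernstTransition(102.0), NernstTransition(237.0)))
    noise_sd: float = 4.4e-4
    baseline: tuple[float, float] = (2e-3, 300.0)
    wavenumber_grid: np.ndarray = field(default_factory=lambda: DEFAULT_WAVENUMBERS.copy())
    rng_seed: int = 2021

    def __post_init__(self):
        pot = np.asarray(self.potential_grid, dtype=float)
        nu = np.asarray(self.wavenumber_grid, dtype=float)
        object.__setattr__(self, "potential_grid", pot)
        object.__setattr__(self, "wavenumber_grid", nu)
        object.__setattr__(self, "bands", tuple(self.bands))
        if pot.size < 2 or not (np.diff(pot) > 0).all():
            raise ValidationError("potential_grid must be strictly increasing")
        if nu.size < 16 or not (np.diff(nu) > 0).all():
            raise ValidationError("wavenumber_grid must be strictly increasing (≥16 points)")
        for i, b in enumerate(self.bands):
            if not b.fwhm > 0:
                raise ValidationError(f"bands[{i}].fwhm must be > 0")
            if not 0.0 <= b.eta <= 1.0:
                raise ValidationError(f"bands[{i}].eta must lie in [0, 1]")
            if b.max_area < 0:
                raise ValidationError(f"bands[{i}].max_area must be ≥ 0")
            if b.species not in SPECIES:
                raise ValidationError(f"bands[{i}].species must be one of {SPECIES}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be ≥ 0")
        amp, bw = self.baseline
        if bw <= 0:
            raise ValidationError("baseline FWHM must be > 0")

    def noiseless(self) -> "TitrationScenario":
        return replace(self, noise_sd=0.0)


def _baseline_profile(scenario: TitrationScenario) -> np.ndarray:
    amp, bw = scenario.baseline
    nu = scenario.wavenumber_grid
    center = 0.5 * (nu[0] + nu[-1])
    hw = bw / 2.0
    return amp * hw * hw / ((nu - center) ** 2 + hw * hw)


def noiseless_signal(scenario: TitrationScenario) -> np.ndarray:
    """The exact generated signal matrix (potential × wavenumber), noise off.

    Linear in the bands: each band contributes
    max_area × population(E) × unit-area pseudo-Voigt, plus the baseline.
    """
    nu = scenario.wavenumber_grid
    pops = three_state_populations(scenario.potential_grid, scenario.species_model)
    pop_by_species = dict(zip(SPECIES, pops))
    signal = np.tile(_baseline_profile(scenario), (scenario.potential_grid.size, 1))
    for b in scenario.bands:
        shape = pseudo_voigt(nu, b.center, b.fwhm, b.eta)
        signal += b.max_area * pop_by_species[b.species][:, None] * shape[None, :]
    return signal


def band_area_truth(scenario: TitrationScenario) -> np.ndarray:
    """True band areas (potential × band), the ground truth for fitted traces."""
    pops = three_state_populations(scenario.potential_grid, scenario.species_model)
    pop_by_species = dict(zip(SPECIES, pops))
    return np.stack([b.max_area * pop_by_species[b.species] for b in scenario.bands],
                    axis=1)


def generate_absolute_series(scenario: TitrationScenario) -> SpectralSeries:
    """Potential-resolved absolute spectra with reproducible Gaussian noise."""
    signal = noiseless_signal(scenario)
    rng = np.random.default_rng(scenario.rng_seed)
    if scenario.noise_sd > 0:
        signal = signal + rng.normal(0.0, scenario.noise_sd, size=signal.shape)
    spectra = tuple(
        Spectrum(scenario.wavenumber_grid, row, potential_mV=float(E),
                 reference="Ag/AgCl", temperature_K=298.15)
        for E, row in zip(scenario.potential_grid, signal))
    return SpectralSeries(spectra)


def generate_difference_series(scenario: TitrationScenario,
                               reference_potential: float = -500.0) -> SpectralSeries:
    """Difference spectra against the spectrum at ``reference_potential``.

    The reference shares one noise realization across the whole series,
    mimicking a single measured background; the self-difference at the
    reference potential is exactly zero.
    """
    pot = scenario.potential_grid
    match = np.isclose(pot, reference_potential, atol=1e-6)
    if not match.any():
        raise ValidationError(
            f"reference_potential {reference_potential} mV is not on the grid "
            f"{pot.tolist()}")
    absolute = generate_absolute_series(scenario)
    ref = absolute.data[int(np.argmax(match))]
    return absolute.map(lambda s: s.with_absorbance(s.absorbance - ref))


# ---------------------------------------------------------------------------
# Toy charged structures
# ---------------------------------------------------------------------------


def default_probe(geometry: str = "idealized_linear") -> ProbeGeometry:
    """A convenience probe: Fe at the origin, heme axis along +z."""
    if geometry == "idealized_linear":
        return place_co_probe(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                              "idealized_linear")
    return place_co_probe(np.zeros(3), np.array([0.0, 0.0, 1.0]), "bent",
                          bend_plane=np.array([1.0, 0.0, 0.0]))


@dataclass(frozen=True)
class ToyStructureSpec:
    """Point charges with two named charge states around a CO probe.

    ``charge_placements`` lists (position Å, charge in state A, charge in
    state B); no site may sit at the probe midpoint.
    """

    charge_placements: Sequence[tuple]
    probe: ProbeGeometry = field(default_factory=default_probe)
    eps_r: float = DEFAULT_EPS_R

    def __post_init__(self):
        object.__setattr__(self, "charge_placements", tuple(
            (np.asarray(p, dtype=float), float(qa), float(qb))
            for p, qa, qb in self.charge_placements))
        if not self.eps_r > 0:
            raise ValidationError("eps_r must be > 0")
        mid = self.probe.midpoint
        for i, (pos, _, _) in enumerate(self.charge_placements):
            if np.linalg.norm(pos - mid) <= 1e-6:
                raise ValidationError(
                    f"charge_placements[{i}] coincides with the probe midpoint")


def generate_toy_structure(spec: ToyStructureSpec):
    """Build (structure, state_A, state_B) from a :class:`ToyStructureSpec`."""
    atoms = []
    qa: dict[AtomID, float] = {}
    qb: dict[AtomID, float] = {}
    for i, (pos, a, b) in enumerate(spec.charge_placements):
        atom_id = AtomID("X", "CHG", str(i + 1), "Q")
        atoms.append(ChargedAtom(atom_id, pos))
        qa[atom_id] = a
        qb[atom_id] = b
    structure = ChargedStructure(atoms)
    return structure, ChargeState("state_A", qa), ChargeState("state_B", qb)


def calibrated_transition_set(targets: Mapping[str, Mapping[str, float]],
                              probes: Mapping[str, ProbeGeometry],
                              eps_r: float = DEFAULT_EPS_R):
    """Charge groups whose projected field changes hit given target values.

    ``targets`` maps a transition name to its desired p·ΔE (MV/cm) at each
    probe in ``probes``.  Each group receives one charge site per probe;
    the site charges are the exact solution of the (n_probes × n_probes)
    linear system built from unit-charge fields, so the resulting transitions
    reproduce the targets to numerical precision while everything downstream
    (superposition, sums, reporting) still flows through the Coulomb engine.

    Returns ``(structure, transitions)`` with each transition going from an
    all-zero initial state to the solved charges.
    """
    probe_names = list(probes)
    n_p = len(probe_names)
    mid = np.mean([probes[p].midpoint for p in probe_names], axis=0)
    # mean probe axis and a perpendicular direction, used to place sites so
    # that the per-probe responses are linearly independent
    p_mean = np.mean([probes[p].p for p in probe_names], axis=0)
    p_mean = p_mean / np.linalg.norm(p_mean)
    seed_perp = np.array([1.0, 0.0, 0.0])
    if abs(seed_perp @ p_mean) > 0.9:
        seed_perp = np.array([0.0, 1.0, 0.0])
    perp = seed_perp - (seed_perp @ p_mean) * p_mean
    perp = perp / np.linalg.norm(perp)

    atoms: list[ChargedAtom] = []
    site_ids: dict[str, list[AtomID]] = {}
    for g, name in enumerate(targets):
        dist = 5.0 + 0.5 * g
        ids = []
        for j in range(n_p):
            # site 0 behind the probe along −p, further sites fanned toward perp
            frac = j / max(n_p - 1, 1)
            direction = -np.cos(frac * np.pi / 3) * p_mean + np.sin(frac * np.pi / 3) * perp
            direction = direction / np.linalg.norm(direction)
            atom_id = AtomID("X", "CAL", f"{g + 1}", f"Q{j + 1}")
            atoms.append(ChargedAtom(atom_id, mid + dist * direction))
            ids.append(atom_id)
        site_ids[name] = ids
    structure = ChargedStructure(atoms)

    transitions = []
    for name, per_probe in targets.items():
        ids = site_ids[name]
        M = np.empty((n_p, n_p))
        for i, pname in enumerate(probe_names):
            probe = probes[pname]
            for j, atom_id in enumerate(ids):
                unit = ChargeState("unit", {atom_id: 1.0})
                M[i, j] = project_field(
                    coulomb_field(structure, unit, probe.midpoint, eps_r), probe)
        if np.linalg.cond(M) > 1e6:
            raise ValidationError(
                f"probe geometries too similar to calibrate group {name!r}")
        b = np.array([float(per_probe[p]) for p in probe_names])
        q = np.linalg.solve(M, b)
        initial = ChargeState(f"{name}_initial", {i: 0.0 for i in ids})
        final = ChargeState(f"{name}_final", dict(zip(ids, q)))
        transitions.append(Transition(name, initial, final))
    return structure, transitions
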