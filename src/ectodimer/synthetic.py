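"""Parametric stand-ins for deposited structural and sampling data.

Two generators:

* :func:`build_toy_dimer` -- a schematic two-chain, Cα-only receptor
  ectodomain dimer whose quaternary descriptors (scissor dihedral between
  the ligand-binding heads, membrane-proximal tip separation, per-subunit
  domain-closure angle, leg hinge angle) are realized *exactly* by
  construction, so the generator doubles as the oracle for the descriptor
  pipeline.  The architecture emulated is a compact head (Domains I-III,
  residues 1-501) with an elongated Domain IV leg (residues 501-614) whose
  membrane-proximal tip is the last leg residue.
* :func:`sample_umbrella` -- umbrella-sampling windows drawn from the
  *exact* stationary distribution of a declared 1D potential under a
  harmonic bias (Gaussian / truncated-uniform closed forms; Metropolis only
  for the double-well family), so WHAM recovery tests are fast and
  deterministic up to the seed.

Geometry is schematic, not stereochemically realistic: bond lengths and
domain shapes are placeholders chosen only to make every descriptor
well-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .geometry import dihedral, rotation_about_axis
from .structure_io import ATOM_COLUMNS, DimerMap, EnsembleStructure
from .wham import KCAL_TO_KJ, UmbrellaWindow, kBT

__all__ = [
    "ToyDimerSpec",
    "ToyDimerTruth",
    "ReferenceLeg",
    "InfeasibleSpecError",
    "build_toy_dimer",
    "build_toy_ensemble",
    "HarmonicPotential",
    "FlatPotential",
    "DoubleWellPotential",
    "UmbrellaSpec",
    "sample_umbrella",
]


class InfeasibleSpecError(ValueError):
    """The requested descriptor combination is geometrically unreachable."""


# fixed schematic dimensions (Å); see docs/methods.md
_BOND_SEP = 8.0          # Thr249--Thr249 virtual bond length
_FLANK_DIST = 30.0       # Cα 249 -> Cα 190 within a head
_PIVOT = np.array([3.0, -25.0, 0.0])   # Cα 501, head/leg junction
_LEG_LENGTH = 90.0       # pivot -> tip end-to-end
_LEG_JITTER = 2.0        # helical offset radius along the leg
_DOMAIN_JITTER = 4.0     # spread of domain point clouds
_ARM_LEN = 25.0          # centroid separations realizing the closure angle
_TOPOLOGY_SEED = 0xEC70  # fixed: all specs share one jitter topology


@dataclass(frozen=True)
class ToyDimerSpec:
    """Ground-truth parameters of a schematic ectodomain dimer."""

    scissor_angle: float = 17.0      # degrees, |dihedral| of the 190-249-249-190 pseudo-torsion
    tip_distance: float = 12.0       # Å between the two tip (residue 614) Cα atoms
    hinge_angle_a: float = 0.0       # degrees, leg swing vs the hinge-zero reference leg
    hinge_angle_b: float = 0.0
    closure_angle: float = 78.0      # degrees, Domain I -- II -- III centroid angle
    n_residues_head: int = 501
    n_residues_leg: int = 114
    noise_sd: float = 0.0            # Å, isotropic Gaussian coordinate noise
    seed: int = 0

    def __post_init__(self):
        for name in ("scissor_angle", "tip_distance", "hinge_angle_a",
                     "hinge_angle_b", "closure_angle", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_residues_leg < 2:
            raise ValueError("n_residues_leg must be >= 2")
        if self.n_residues_head < 250:
            raise ValueError("head must reach past the scissor anchors (>= 250 residues)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tip_distance < 0:
            raise ValueError("tip_distance must be >= 0")

    @property
    def tip_residue(self) -> int:
        return self.n_residues_head + self.n_residues_leg - 1


@dataclass(frozen=True)
class ReferenceLeg:
    """Reference frame for hinge measurement: one subunit's head plus its
    hinge-zero leg, with the pivot (head/leg junction Cα)."""

    head_residues: tuple[int, ...]
    head_coords: np.ndarray
    leg_residues: tuple[int, ...]
    leg_coords: np.ndarray
    pivot: np.ndarray


@dataclass(frozen=True)
class ToyDimerTruth:
    """Construction record emitted alongside a toy dimer."""

    spec: ToyDimerSpec
    scissor_signed: float
    dimer_map: DimerMap
    steer_target: np.ndarray
    reference_legs: dict[str, ReferenceLeg] = field(repr=False)


def _zero_sum_jitter(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    pts = rng.normal(scale=scale, size=(n, 3))
    return pts - pts.mean(axis=0)


def _interpolate(a: np.ndarray, b: np.ndarray, n: int, rng: np.random.Generator,
                 scale: float = 1.0) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n + 2)[1:-1, None]
    return a + t * (b - a) + rng.normal(scale=scale, size=(n, 3))


def _head_template(spec: ToyDimerSpec, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Cα positions for residues 1..n_head in the template frame.

    Frame: Cα 249 at the origin, Cα 190 on +y, the partner subunit toward
    +x.  Domain centroids are realized exactly by zero-sum point clouds."""
    n_head = spec.n_residues_head
    half = np.radians(spec.closure_angle / 2.0)
    c2 = np.array([10.0, 20.0, 3.0])            # Domain II (vertex) centroid
    u1 = np.array([np.sin(half), np.cos(half), 0.0])
    u2 = np.array([-np.sin(half), np.cos(half), 0.0])
    c1 = c2 + _ARM_LEN * u1                      # Domain I centroid
    c3 = c2 + _ARM_LEN * u2                      # Domain III centroid

    q190 = np.array([0.0, _FLANK_DIST, 0.0])
    q249 = np.zeros(3)
    pos: dict[int, np.ndarray] = {}

    def clip(lo, hi):
        return range(max(1, lo), min(n_head, hi) + 1)

    # Domain I (7-200): residue 190 pinned; the rest absorb the centroid shift
    dom1 = [r for r in clip(7, 200) if r != 190]
    jit = _zero_sum_jitter(rng, len(dom1), _DOMAIN_JITTER)
    correction = (c1 - q190) / len(dom1)
    for r, j in zip(dom1, jit):
        pos[r] = c1 + j + correction
    pos[190] = q190
    # Domain II part (260-285) and Domain III (317-470): plain zero-sum clouds
    for (lo, hi), c in (((260, 285), c2), ((317, 470), c3)):
        rr = list(clip(lo, hi))
        for r, j in zip(rr, _zero_sum_jitter(rng, len(rr), _DOMAIN_JITTER)):
            pos[r] = c + j
    # connecting stretches; 249 pinned at the origin afterwards
    for (lo, hi), (a, b) in (
        ((1, 6), (c1 + np.array([0.0, 8.0, 0.0]), c1)),
        ((201, 259), (c1, c2)),
        ((286, 316), (c2, c3)),
        ((471, n_head - 1), (c3, _PIVOT)),
    ):
        rr = [r for r in clip(lo, hi) if r not in pos]
        for r, p in zip(rr, _interpolate(a, b, len(rr), rng)):
            pos[r] = p
    pos[249] = q249
    pos[n_head] = _PIVOT.copy()
    return pos


def _leg_template(spec: ToyDimerSpec, rng: np.random.Generator) -> np.ndarray:
    """Leg Cα offsets from the pivot, i = 0..n_leg-1, hinge-zero, pointing -y.

    End points are exact (pivot and tip); interior residues carry a helical
    offset so the leg point set is never collinear (Kabsch stays
    well-conditioned)."""
    n = spec.n_residues_leg
    t = np.arange(n) / (n - 1)
    offsets = np.zeros((n, 3))
    offsets[:, 1] = -_LEG_LENGTH * t
    phase = 2.1 * np.arange(n)
    taper = np.sin(np.pi * t)  # vanishes at both ends
    offsets[:, 0] += _LEG_JITTER * taper * np.cos(phase)
    offsets[:, 2] += _LEG_JITTER * taper * np.sin(phase)
    return offsets


def _subunit_transforms(scissor_deg: float):
    """Global placements of the two subunits.

    Subunit A: rotation by +scissor/2 about the virtual-bond axis (x).
    Subunit B: two-fold rotation about y through the bond midpoint, then
    -scissor/2 about x.  Returns (rot, trans) pairs."""
    half = scissor_deg / 2.0
    rot_a = rotation_about_axis([1.0, 0.0, 0.0], half)
    c2 = np.diag([-1.0, 1.0, -1.0])  # proper two-fold about y
    rot_b = rotation_about_axis([1.0, 0.0, 0.0], -half) @ c2
    tr_b = rotation_about_axis([1.0, 0.0, 0.0], -half) @ np.array([_BOND_SEP, 0.0, 0.0])
    return (rot_a, np.zeros(3)), (rot_b, tr_b)


def _steer_target(spec: ToyDimerSpec) -> np.ndarray:
    """Template-frame leg end-point offset ``s`` from the pivot realizing the
    requested tip separation exactly.

    The two subunits are related by a two-fold rotation about y through the
    virtual-bond midpoint, and both legs are steered to the same template
    offset ``s``, so the global tips sit at C2-related points.  Writing the
    global tip of subunit A as (x, y, z), the separation is
    ``2 * sqrt((x - d/2)^2 + z^2)`` with d the virtual-bond length.  The
    construction places the tips separated purely along the inter-subunit
    axis (z = 0), each on its own side, which pins ``s`` on the sphere of
    radius ``_LEG_LENGTH`` in closed form.  Unreachable separations raise
    :class:`InfeasibleSpecError`.
    """
    half = np.radians(spec.scissor_angle / 2.0)
    length = _LEG_LENGTH
    # global-x condition: tip_x = d/2 - D/2  ->  s_x = d/2 - D/2 - pivot_x
    s_x = _BOND_SEP / 2.0 - spec.tip_distance / 2.0 - _PIVOT[0]
    radius_sq = length**2 - s_x**2
    # global-z condition: (pivot_y + s_y) sin(h) + s_z cos(h) = 0
    m = -_PIVOT[1] * np.sin(half)
    if radius_sq < m**2:
        raise InfeasibleSpecError(
            f"tip separation {spec.tip_distance} Å is unreachable with scissor "
            f"{spec.scissor_angle}° and leg length {length} Å"
        )
    t = np.sqrt(radius_sq - m**2)
    # of the two sphere/line intersections take the leg pointing down (-y)
    s_y = m * np.sin(half) - t * np.cos(half)
    s_z = m * np.cos(half) + t * np.sin(half)
    return np.array([s_x, s_y, s_z])


def _minimal_rotation(from_vec: np.ndarray, to_vec: np.ndarray) -> np.ndarray:
    """Smallest-angle rotation taking one direction onto another."""
    u = from_vec / np.linalg.norm(from_vec)
    v = to_vec / np.linalg.norm(to_vec)
    axis = np.cross(u, v)
    n = np.linalg.norm(axis)
    angle = np.degrees(np.arctan2(n, float(u @ v)))
    if n < 1e-12:
        if u @ v > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about a deterministic perpendicular
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(u, [0.0, 0.0, 1.0])
        return rotation_about_axis(perp, 180.0)
    return rotation_about_axis(axis / n, angle)


_ANCHOR_NAMES = {190: "ILE", 249: "THR", 492: "TRP"}


def build_toy_dimer(spec: ToyDimerSpec) -> tuple[EnsembleStructure, ToyDimerTruth]:
    """Build a two-chain Cα-only dimer realizing ``spec`` exactly.

    Returns the in-memory structure (full float precision; writing to PDB
    quantizes to 3 decimals) and the ground-truth record, including the
    hinge-zero reference legs needed to re-measure the hinge angle.
    Internally inconsistent specs raise :class:`InfeasibleSpecError` rather
    than producing a silently wrong model.
    """
    topo_rng = np.random.default_rng(_TOPOLOGY_SEED)
    head = _head_template(spec, topo_rng)
    leg_offsets = _leg_template(spec, topo_rng)
    steer = _steer_target(spec)
    down = np.array([0.0, -_LEG_LENGTH, 0.0])

    (ra, ta), (rb, tb) = _subunit_transforms(spec.scissor_angle)
    placements = {"A": (ra, ta, spec.hinge_angle_a), "B": (rb, tb, spec.hinge_angle_b)}

    n_head, n_leg = spec.n_residues_head, spec.n_residues_leg
    tip_res = spec.tip_residue
    names = dict(_ANCHOR_NAMES)
    names[tip_res] = "THR"

    rows = []
    reference_legs: dict[str, ReferenceLeg] = {}
    coords_by_chain: dict[str, dict[int, np.ndarray]] = {}
    for chain, (rot, tr, hinge) in placements.items():
        coords: dict[int, np.ndarray] = {}
        for r in range(1, n_head + 1):
            coords[r] = rot @ head[r] + tr
        r_hinge = rotation_about_axis([1.0, 0.0, 0.0], hinge)
        q_ref = _minimal_rotation(r_hinge @ down, steer)  # steering frame
        q_leg = q_ref @ r_hinge
        ref_leg_coords = []
        for i in range(n_leg):
            r = n_head + i
            coords[r] = rot @ (_PIVOT + q_leg @ leg_offsets[i]) + tr
            ref_leg_coords.append(rot @ (_PIVOT + q_ref @ leg_offsets[i]) + tr)
        coords_by_chain[chain] = coords
        head_res = tuple(range(1, n_head + 1))
        reference_legs[chain] = ReferenceLeg(
            head_residues=head_res,
            head_coords=np.array([coords[r] for r in head_res]),
            leg_residues=tuple(range(n_head, n_head + n_leg)),
            leg_coords=np.array(ref_leg_coords),
            pivot=coords[n_head].copy(),
        )

    noise_rng = np.random.default_rng(spec.seed)
    for chain in ("A", "B"):
        coords = coords_by_chain[chain]
        for r in sorted(coords):
            xyz = coords[r]
            if spec.noise_sd > 0:
                xyz = xyz + noise_rng.normal(scale=spec.noise_sd, size=3)
            rows.append(
                (chain, r, "", names.get(r, "GLY"), "CA", "C",
                 xyz[0], xyz[1], xyz[2], False)
            )

    structure = EnsembleStructure(
        [pd.DataFrame(rows, columns=ATOM_COLUMNS)],
        source_format="pdb",
        identifier=f"toy-dimer-s{spec.scissor_angle:g}-t{spec.tip_distance:g}",
    )

    # signed value under the package's dihedral convention (verified exact
    # by the descriptor round trip in the test suite)
    signed = dihedral(
        coords_by_chain["A"][190], coords_by_chain["A"][249],
        coords_by_chain["B"][249], coords_by_chain["B"][190],
    ) if spec.scissor_angle != 0 else 0.0

    truth = ToyDimerTruth(
        spec=spec,
        scissor_signed=signed,
        dimer_map=DimerMap("A", "B", numbering_offset=0),
        steer_target=steer,
        reference_legs=reference_legs,
    )
    return structure, truth


def build_toy_ensemble(
    specs: Sequence[ToyDimerSpec],
) -> tuple[EnsembleStructure, pd.DataFrame]:
    """One multi-model ensemble from a list of specs sharing topology.

    Returns the ensemble (model order = spec order) and a ground-truth table
    with one row per model.
    """
    if not specs:
        raise ValueError("need at least one spec")
    topo = {(s.n_residues_head, s.n_residues_leg) for s in specs}
    if len(topo) > 1:
        raise ValueError(f"specs disagree on chain topology: {sorted(topo)}")
    models = []
    truth_rows = []
    identifier = f"toy-ensemble-{len(specs)}"
    for i, spec in enumerate(specs, start=1):
        st, truth = build_toy_dimer(spec)
        models.append(st.models[0])
        truth_rows.append(
            {
                "model": i,
                "scissor_angle": spec.scissor_angle,
                "scissor_signed": truth.scissor_signed,
                "tip_distance": spec.tip_distance,
                "closure_angle": spec.closure_angle,
                "hinge_angle_a": spec.hinge_angle_a,
                "hinge_angle_b": spec.hinge_angle_b,
                "noise_sd": spec.noise_sd,
                "seed": spec.seed,
            }
        )
    ensemble = EnsembleStructure(models, source_format="pdb", identifier=identifier)
    return ensemble, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# umbrella-sampling data with closed-form window distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicPotential:
    """U(x) = a/2 (x - x0)², a in kJ·mol⁻¹·Å⁻²."""

    curvature: float
    x0: float

    def energy(self, x):
        return 0.5 * self.curvature * (np.asarray(x, float) - self.x0) ** 2


@dataclass(frozen=True)
class FlatPotential:
    """U(x) = 0 on [lo, hi], infinite outside."""

    lo: float
    hi: float

    def energy(self, x):
        x = np.asarray(x, float)
        return np.where((x >= self.lo) & (x <= self.hi), 0.0, np.inf)


@dataclass(frozen=True)
class DoubleWellPotential:
    """U(x) = barrier · ((x - m)² (x - M)²) / ((M - m)/2)⁴, minima at m, M."""

    barrier: float
    minimum_1: float
    minimum_2: float

    def energy(self, x):
        x = np.asarray(x, float)
        half = (self.minimum_2 - self.minimum_1) / 2.0
        return self.barrier * ((x - self.minimum_1) ** 2 * (x - self.minimum_2) ** 2) / half**4


@dataclass(frozen=True)
class UmbrellaSpec:
    """Protocol for synthetic umbrella data.

    Defaults mirror the umbrella protocol used for the receptor-tip PMF:
    20 windows spaced 1 Å apart (centers 8..27 Å) with a harmonic bias of
    1 kcal·mol⁻¹·Å⁻², sampled at 300 K.
    """

    potential: HarmonicPotential | FlatPotential | DoubleWellPotential
    window_centers: tuple[float, ...] = tuple(float(c) for c in range(8, 28))
    force_constant: float = 1.0
    force_constant_unit: str = "kcal_per_mol_A2"
    n_samples: int = 10_000
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.window_centers:
            raise ValueError("need at least one window center")

    @property
    def force_constant_kj(self) -> float:
        if self.force_constant_unit == "kcal_per_mol_A2":
            return self.force_constant * KCAL_TO_KJ
        if self.force_constant_unit == "kJ_per_mol_A2":
            return self.force_constant
        raise ValueError(f"unknown unit {self.force_constant_unit!r}")


def biased_window_moments(
    potential: HarmonicPotential, center: float, k_kj: float, temperature: float
) -> tuple[float, float]:
    """Closed-form mean and sd of a harmonic potential under a harmonic bias."""
    a, k = potential.curvature, k_kj
    mean = (a * potential.x0 + k * center) / (a + k)
    sd = float(np.sqrt(kBT(temperature) / (a + k)))
    return mean, sd


def _sample_window(
    spec: UmbrellaSpec, center: float, rng: np.random.Generator
) -> np.ndarray:
    kt = kBT(spec.temperature)
    k = spec.force_constant_kj
    pot = spec.potential
    if isinstance(pot, HarmonicPotential):
        if k == 0:
            mean, sd = pot.x0, float(np.sqrt(kt / pot.curvature))
        else:
            mean, sd = biased_window_moments(pot, center, k, spec.temperature)
        return rng.normal(mean, sd, size=spec.n_samples)
    if isinstance(pot, FlatPotential):
        if k == 0:
            return rng.uniform(pot.lo, pot.hi, size=spec.n_samples)
        sd = float(np.sqrt(kt / k))
        a, b = (pot.lo - center) / sd, (pot.hi - center) / sd
        return truncnorm.rvs(a, b, loc=center, scale=sd, size=spec.n_samples, random_state=rng)
    if isinstance(pot, DoubleWellPotential):
        return _metropolis(pot, center, k, kt, spec.n_samples, rng)
    raise ValueError(f"unknown potential family {type(pot).__name__}")


def _metropolis(pot, center, k, kt, n, rng, step=0.5, burn_in=2000, thin=5):
    def total(x):
        return pot.energy(x) + 0.5 * k * (x - center) ** 2

    x = center
    e = total(x)
    out = np.empty(n)
    accepted = 0
    total_steps = burn_in + n * thin
    proposals = rng.normal(0.0, step, size=total_steps)
    accept_u = rng.random(total_steps)
    j = 0
    for i in range(total_steps):
        xn = x + proposals[i]
        en = total(xn)
        if en <= e or accept_u[i] < np.exp(-(en - e) / kt):
            x, e = xn, en
            accepted += 1
        if i >= burn_in and (i - burn_in) % thin == 0 and j < n:
            out[j] = x
            j += 1
    _metropolis.last_acceptance_rate = accepted / total_steps
    return out


def sample_umbrella(spec: UmbrellaSpec) -> list[UmbrellaWindow]:
    """Draw one :class:`~ectodimer.wham.UmbrellaWindow` per declared center.

    Harmonic and flat potentials are sampled from the exact stationary
    distribution of potential-plus-bias (no dynamics); the double-well family
    uses Metropolis sampling (acceptance rate recorded on the sampler).
    Output is a pure function of (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    unbiased = spec.force_constant == 0
    windows = []
    for center in spec.window_centers:
        samples = _sample_window(spec, float(center), rng)
        windows.append(
            UmbrellaWindow(
                center=float(center),
                force_constant=spec.force_constant_kj,
                samples=samples,
                unit="kJ_per_mol_A2",
                unbiased=unbiased,
            )
        )
    return windows


def perturbed_spec(spec: ToyDimerSpec, **changes) -> ToyDimerSpec:
    """Convenience: a copy of ``spec`` with fields replaced."""
    return replace(spec, **changes)
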