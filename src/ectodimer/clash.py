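"""Leg grafting, steric-clash detection and hinge-rotation scanning.

The steric argument this module implements: when the scissor rotation
between the two ligand-binding heads is small, keeping the same Domain IV
leg conformation in both subunits would drive the two legs into each other;
the clash is relieved by one leg swinging about the head/leg hinge.  The
tools here let that argument be made quantitatively on any model: transplant
a template leg onto a head by superposing the shared head span, count
inter-leg atomic clashes, and scan hinge rotations for the smallest
clash-free swing.

Clash criteria: the source analyses state no distance threshold, so both
community conventions are exposed -- a Cα-only cutoff (default 4.0 Å, usable
on backbone-only models) and a heavy-atom van der Waals overlap test
(clash when d < r_a + r_b - tolerance, default tolerance 0.6 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import GeometryError, RigidTransform, centroid, kabsch_superpose, rotation_about_axis
from .structure_io import DimerMap, EnsembleStructure, select_calpha

__all__ = [
    "ClashCriterion",
    "ClashPair",
    "ClashReport",
    "GraftResult",
    "HingeScanResult",
    "detect_clashes",
    "graft_leg",
    "hinge_scan",
    "default_hinge_axis",
    "chain_atoms",
]

#: van der Waals radii (Å) for heavy-atom mode
DEFAULT_VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@dataclass(frozen=True)
class ClashCriterion:
    """How two atom sets are tested for steric clashes."""

    mode: str = "calpha"  # or "heavy"
    calpha_cutoff: float = 4.0
    vdw_overlap_tolerance: float = 0.6
    vdw_radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))

    def __post_init__(self):
        if self.mode not in ("calpha", "heavy"):
            raise ValueError(f"mode must be 'calpha' or 'heavy', got {self.mode!r}")
        if not self.calpha_cutoff > 0:
            raise ValueError("calpha_cutoff must be > 0")
        if self.vdw_overlap_tolerance < 0:
            raise ValueError("vdw_overlap_tolerance must be >= 0")


@dataclass(frozen=True)
class ClashPair:
    atom_a: tuple  # (chain, resnum, atom name)
    atom_b: tuple
    distance: float
    overlap: float


@dataclass(frozen=True)
class ClashReport:
    pairs: tuple[ClashPair, ...]
    count: int
    worst_overlap: float

    def __post_init__(self):
        assert self.count == len(self.pairs)


def _atom_arrays(atoms: pd.DataFrame, criterion: ClashCriterion, label: str):
    if criterion.mode == "calpha":
        sub = atoms[atoms["atom"] == "CA"]
        radii = None
    else:
        sub = atoms
        elements = sub["element"].str.upper()
        unknown = sub[~elements.isin(criterion.vdw_radii)]
        if len(unknown):
            row = unknown.iloc[0]
            raise KeyError(
                f"no van der Waals radius for element {row['element']!r} "
                f"(atom {row['atom']} {row['resname']}{row['resnum']} "
                f"chain {row['chain']} in {label})"
            )
        radii = elements.map(criterion.vdw_radii).to_numpy(dtype=float)
    if sub.empty:
        raise ValueError(f"{label}: no atoms to test under mode {criterion.mode!r}")
    coords = sub[["x", "y", "z"]].to_numpy(dtype=float)
    ids = list(zip(sub["chain"], sub["resnum"].astype(int), sub["atom"]))
    return coords, ids, radii


def detect_clashes(
    atoms_a: pd.DataFrame, atoms_b: pd.DataFrame, criterion: ClashCriterion = ClashCriterion()
) -> ClashReport:
    """All clashing atom pairs between two atom tables.

    Cα mode: pairs with Cα--Cα distance below ``calpha_cutoff``.  Heavy-atom
    mode: pairs with distance below r_a + r_b - tolerance.  Candidate pairs
    are found with a k-d tree; ordering is deterministic by input order of
    (atom_a, atom_b).  Symmetric: swapping the sets yields the same pair
    multiset (mirrored).
    """
    ca, ids_a, ra = _atom_arrays(atoms_a, criterion, "set A")
    cb, ids_b, rb = _atom_arrays(atoms_b, criterion, "set B")
    if criterion.mode == "calpha":
        max_cut = criterion.calpha_cutoff
    else:
        max_cut = ra.max() + rb.max() - criterion.vdw_overlap_tolerance
    tree = cKDTree(cb)
    neighbours = tree.query_ball_point(ca, r=max_cut)
    pairs = []
    for i, hits in enumerate(neighbours):
        for j in sorted(hits):
            d = float(np.linalg.norm(ca[i] - cb[j]))
            if criterion.mode == "calpha":
                cutoff = criterion.calpha_cutoff
            else:
                cutoff = ra[i] + rb[j] - criterion.vdw_overlap_tolerance
            if d < cutoff:
                pairs.append(ClashPair(ids_a[i], ids_b[j], d, float(cutoff - d)))
    return ClashReport(
        pairs=tuple(pairs),
        count=len(pairs),
        worst_overlap=max((p.overlap for p in pairs), default=0.0),
    )


def chain_atoms(
    structure: EnsembleStructure,
    model: int,
    chain: str,
    residues: Sequence[int] | None = None,
    exclude_near: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Atom table of one chain, optionally restricted to a residue span and
    excluding residues within ``exclude_near = (residue, margin)`` of a
    junction (used to keep graft seams out of clash counts)."""
    tab = structure.model(model)
    sub = tab[(tab["chain"] == chain) & ~tab["het"]]
    if residues is not None:
        sub = sub[sub["resnum"].isin(set(int(r) for r in residues))]
    if exclude_near is not None:
        junction, margin = exclude_near
        sub = sub[(sub["resnum"] - junction).abs() > margin]
    return sub.reset_index(drop=True)


@dataclass(frozen=True)
class GraftResult:
    """A model with a transplanted leg; grafted atoms are tagged."""

    structure: EnsembleStructure
    transform: RigidTransform
    n_grafted: int
    n_head_pairs: int

    def grafted_atoms(self) -> pd.DataFrame:
        tab = self.structure.models[0]
        return tab[tab["grafted"]]


def graft_leg(
    target: EnsembleStructure,
    target_chain: str,
    template: EnsembleStructure,
    template_chain: str,
    head_span: tuple[int, int],
    leg_span: tuple[int, int],
    target_model: int = 1,
    template_model: int = 1,
) -> GraftResult:
    """Transplant the template chain's leg onto the target chain.

    The template is superposed on the target over the common head-span Cα
    atoms; the resulting rigid transform is applied to every template atom
    in the leg span, which then replaces the target chain's own leg-span
    atoms.  Grafted atoms carry ``grafted=True`` provenance.
    """
    head_res = list(range(head_span[0], head_span[1] + 1))
    sel_t = select_calpha(target, target_model, target_chain, head_res)
    sel_s = select_calpha(template, template_model, template_chain, head_res)
    lt = {r: c for r, c in zip(sel_t.residues, sel_t.coordinates)}
    ls = {r: c for r, c in zip(sel_s.residues, sel_s.coordinates)}
    common = [r for r in head_res if r in lt and r in ls]
    if len(common) < 3:
        raise GeometryError(
            f"only {len(common)} common head residues between template and target"
        )
    transform, _ = kabsch_superpose(
        np.array([ls[r] for r in common]), np.array([lt[r] for r in common])
    )

    leg_lo, leg_hi = leg_span
    tmpl_tab = template.model(template_model)
    leg_atoms = tmpl_tab[
        (tmpl_tab["chain"] == template_chain)
        & tmpl_tab["resnum"].between(leg_lo, leg_hi)
        & ~tmpl_tab["het"]
    ].copy()
    if leg_atoms.empty:
        raise GeometryError("template has no atoms in the leg span")
    moved = transform.apply(leg_atoms[["x", "y", "z"]].to_numpy(dtype=float))
    leg_atoms[["x", "y", "z"]] = moved
    leg_atoms["chain"] = target_chain
    leg_atoms["grafted"] = True

    tgt_tab = target.model(target_model).copy()
    if "grafted" not in tgt_tab.columns:
        tgt_tab["grafted"] = False
    keep = ~(
        (tgt_tab["chain"] == target_chain)
        & tgt_tab["resnum"].between(leg_lo, leg_hi)
        & ~tgt_tab["het"]
    )
    merged = pd.concat([tgt_tab[keep], leg_atoms], ignore_index=True)
    merged = merged.sort_values(["chain", "resnum", "atom"], kind="mergesort").reset_index(
        drop=True
    )
    grafted = EnsembleStructure(
        [merged],
        source_format=target.source_format,
        identifier=f"{target.identifier}+graft",
    )
    return GraftResult(
        structure=grafted,
        transform=transform,
        n_grafted=len(leg_atoms),
        n_head_pairs=len(common),
    )


def default_hinge_axis(
    structure: EnsembleStructure,
    model: int,
    chain: str,
    dimer_map: DimerMap,
    pivot: np.ndarray,
    domain3_span: tuple[int, int] = (317, 470),
    leg_span: tuple[int, int] = (501, 614),
) -> np.ndarray:
    """Hinge axis perpendicular to the (Domain III centroid, pivot, leg
    centroid) plane: the swing that carries the leg toward the head."""
    off = dimer_map.numbering_offset
    d3 = select_calpha(structure, model, chain,
                       range(domain3_span[0] + off, domain3_span[1] + off + 1))
    leg = select_calpha(structure, model, chain,
                        range(leg_span[0] + off, leg_span[1] + off + 1))
    v1 = centroid(d3.coordinates) - pivot
    v2 = centroid(leg.coordinates) - pivot
    axis = np.cross(v2, v1)
    n = np.linalg.norm(axis)
    if n < 1e-9:
        raise GeometryError("degenerate hinge axis: leg and Domain III are collinear")
    return axis / n


@dataclass(frozen=True)
class HingeScanResult:
    angles: tuple[float, ...]
    clash_counts: tuple[int, ...]
    clash_free_angle: float | None  # smallest grid angle with zero clashes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"angle_deg": self.angles, "clash_count": self.clash_counts})


def hinge_scan(
    leg_atoms: pd.DataFrame,
    pivot: np.ndarray,
    axis: np.ndarray,
    other_body: pd.DataFrame,
    angle_grid: Sequence[float],
    criterion: ClashCriterion = ClashCriterion(),
) -> HingeScanResult:
    """Rigidly rotate a leg about (pivot, axis) and count clashes per angle.

    Returns per-angle clash counts against ``other_body`` and the smallest
    grid angle with zero clashes (None if every grid point clashes).
    """
    if len(angle_grid) == 0:
        raise ValueError("angle grid is empty")
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-9:
        raise GeometryError("degenerate hinge axis")
    axis = axis / n
    pivot = np.asarray(pivot, dtype=float).reshape(3)
    base = leg_atoms[["x", "y", "z"]].to_numpy(dtype=float)
    counts = []
    for angle in angle_grid:
        rot = rotation_about_axis(axis, float(angle))
        moved = (base - pivot) @ rot.T + pivot
        rotated = leg_atoms.copy()
        rotated[["x", "y", "z"]] = moved
        counts.append(detect_clashes(rotated, other_body, criterion).count)
    free = [float(a) for a, c in zip(angle_grid, counts) if c == 0]
    return HingeScanResult(
        angles=tuple(float(a) for a in angle_grid),
        clash_counts=tuple(counts),
        clash_free_angle=min(free) if free else None,
    )
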