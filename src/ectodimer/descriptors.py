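"""Quaternary-conformation descriptors for a two-subunit receptor dimer.

Implements the descriptor set used to classify ligand-bound receptor
ectodomain dimers along the tips-juxtaposed <-> tips-separated axis:

* **scissor dihedral** -- the pseudo-torsion about the virtual bond joining
  the Cα atoms of the bond residue (Thr 249) in each subunit, with the Cα
  atoms of the flank residue (Ile 190) completing the four-point dihedral.
  Its magnitude quantifies the rigid-body scissor rotation between the two
  ligand-binding heads (roughly 10-25° across a dimer ensemble).
* **tip separation** -- the Cα--Cα distance between the last leg residue
  (Thr 614) of the two subunits, i.e. between the membrane-proximal tips.
* **closure angle** -- per subunit, the angle at the Domain II centroid
  (residues 260-285) between the Domain I (7-200) and Domain III (317-470)
  Cα centroids; a measure of ligand-binding-site closure.
* **leg hinge angle** -- the rigid swing of the Domain IV leg (residues
  501-614) about the head/leg junction (Cα 501) relative to a reference
  leg conformation.
* **reference RMSD** -- Cα RMSD against a reference structure over a stated
  residue span (canonically 1-501, the head span), after least-squares
  superposition.

All residue numbers are mature numbering; the :class:`~ectodimer.structure_io.DimerMap`
offset translates to author numbering.  Descriptors never use ligand atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    centroid,
    decompose_hinge,
    dihedral,
    kabsch_superpose,
    vertex_angle,
)
from .structure_io import DimerMap, EnsembleStructure, select_calpha, EmptySelectionError

__all__ = [
    "ScissorDefinition",
    "DomainDefinition",
    "DescriptorResult",
    "EnsembleDistanceStats",
    "ConformationReport",
    "scissor_dihedral",
    "tip_separation",
    "closure_angle",
    "leg_hinge_angle",
    "compare_to_reference",
    "ensemble_distance_stats",
    "ensemble_report",
]


@dataclass(frozen=True)
class ScissorDefinition:
    """Residues defining the intersubunit scissor pseudo-torsion."""

    bond_residue: int = 249   # virtual bond joins this residue's Cα in each subunit
    flank_residue: int = 190  # completes the dihedral on each side
    atom: str = "CA"

    def __post_init__(self):
        if self.bond_residue == self.flank_residue:
            raise ValueError("bond and flank residues must differ")


@dataclass(frozen=True)
class DomainDefinition:
    """Fixed residue spans of the ectodomain architecture (mature numbering)."""

    domain1: tuple[int, int] = (7, 200)
    domain2_part: tuple[int, int] = (260, 285)
    domain3: tuple[int, int] = (317, 470)
    head: tuple[int, int] = (1, 501)
    leg: tuple[int, int] = (501, 614)
    tip_residue: int = 614
    linker: tuple[int, int] = (615, 621)
    junction_pair: tuple[int, int] = (619, 623)
    min_coverage: float = 0.5  # fraction of a span's residues required

    def __post_init__(self):
        spans = [self.domain1, self.domain2_part, self.domain3]
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("closure-angle domain spans must not overlap")
        if not self.leg[0] <= self.tip_residue <= self.leg[1]:
            raise ValueError("tip residue must lie inside the leg span")


@dataclass(frozen=True)
class DescriptorResult:
    """One descriptor value with missing-data bookkeeping.

    ``value`` is NaN when ``missing`` is True; a descriptor is flagged
    missing (with a reason), never fabricated.
    """

    name: str
    value: float
    missing: bool = False
    reason: str | None = None
    extras: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def unavailable(cls, name: str, reason: str) -> "DescriptorResult":
        return cls(name=name, value=math.nan, missing=True, reason=reason)


def _span(lo_hi: tuple[int, int]) -> range:
    return range(lo_hi[0], lo_hi[1] + 1)


def _ca(structure, model, chain, mature_residues, dimer_map, atom="CA"):
    author = [r + dimer_map.numbering_offset for r in mature_residues]
    return select_calpha(structure, model, chain, author, atom=atom)


def _single_ca(structure, model, chain, mature_residue, dimer_map, atom="CA"):
    sel = _ca(structure, model, chain, [mature_residue], dimer_map, atom=atom)
    if sel.missing:
        raise EmptySelectionError(
            f"residue {mature_residue} has no {atom} in chain {chain!r}"
        )
    return sel.coordinates[0]


def scissor_dihedral(
    structure: EnsembleStructure,
    model: int,
    dimer_map: DimerMap,
    definition: ScissorDefinition = ScissorDefinition(),
) -> DescriptorResult:
    """Signed intersubunit scissor dihedral; magnitude is the headline value.

    Computed as dihedral(Cα flank_A, Cα bond_A, Cα bond_B, Cα flank_B).
    The sign flips under chain-order swap, so reports carry both the signed
    value (``extras['signed']``) and the absolute value (``value``).
    """
    try:
        p1 = _single_ca(structure, model, dimer_map.chain_a, definition.flank_residue,
                        dimer_map, definition.atom)
        p2 = _single_ca(structure, model, dimer_map.chain_a, definition.bond_residue,
                        dimer_map, definition.atom)
        p3 = _single_ca(structure, model, dimer_map.chain_b, definition.bond_residue,
                        dimer_map, definition.atom)
        p4 = _single_ca(structure, model, dimer_map.chain_b, definition.flank_residue,
                        dimer_map, definition.atom)
    except (LookupError, EmptySelectionError) as exc:
        return DescriptorResult.unavailable("scissor", str(exc))
    signed = dihedral(p1, p2, p3, p4)
    return DescriptorResult("scissor", abs(signed), extras={"signed": signed})


def tip_separation(
    structure: EnsembleStructure,
    model: int,
    dimer_map: DimerMap,
    residue: int = 614,
    atom: str = "CA",
) -> DescriptorResult:
    """Euclidean Cα--Cα distance between the two membrane-proximal tips."""
    try:
        a = _single_ca(structure, model, dimer_map.chain_a, residue, dimer_map, atom)
        b = _single_ca(structure, model, dimer_map.chain_b, residue, dimer_map, atom)
    except (LookupError, EmptySelectionError) as exc:
        return DescriptorResult.unavailable("tip_separation", str(exc))
    return DescriptorResult("tip_separation", float(np.linalg.norm(a - b)))


def closure_angle(
    structure: EnsembleStructure,
    model: int,
    chain: str,
    dimer_map: DimerMap,
    definition: DomainDefinition = DomainDefinition(),
) -> DescriptorResult:
    """Domain I -- Domain II -- Domain III centroid angle for one subunit.

    Requires at least ``definition.min_coverage`` of each span's residues to
    carry a Cα; the coverage fractions are reported either way.
    """
    centroids = []
    coverage = {}
    for key, span in (
        ("domain1", definition.domain1),
        ("domain2_part", definition.domain2_part),
        ("domain3", definition.domain3),
    ):
        residues = list(_span(span))
        try:
            sel = _ca(structure, model, chain, residues, dimer_map)
        except (LookupError, EmptySelectionError) as exc:
            return DescriptorResult.unavailable("closure_angle", str(exc))
        frac = len(sel.residues) / len(residues)
        coverage[key] = frac
        centroids.append(centroid(sel.coordinates))
    if any(f < definition.min_coverage for f in coverage.values()):
        low = {k: round(f, 3) for k, f in coverage.items() if f < definition.min_coverage}
        return replace(
            DescriptorResult.unavailable("closure_angle", f"coverage below threshold: {low}"),
            extras={"coverage": coverage},
        )
    angle = vertex_angle(centroids[0], centroids[1], centroids[2])
    return DescriptorResult("closure_angle", angle, extras={"coverage": coverage})


def leg_hinge_angle(
    structure: EnsembleStructure,
    model: int,
    dimer_map: DimerMap,
    reference_leg,
    chain: str | None = None,
    definition: DomainDefinition = DomainDefinition(),
) -> DescriptorResult:
    """Leg swing angle about the head/leg junction, vs a reference leg.

    ``reference_leg`` provides a head span (for framing), the hinge-zero leg
    coordinates, and the pivot (Cα of the junction residue).  The model is
    first superposed on the reference over the common head Cα set of the
    chosen subunit, then the (moved) model leg is superposed onto the
    reference leg; the rotation part of that second fit, decomposed about
    the pivot, is the hinge angle.  Frame-invariant by construction.
    """
    chain = chain or dimer_map.chain_a
    try:
        head_sel = _ca(structure, model, chain, reference_leg.head_residues, dimer_map)
    except (LookupError, EmptySelectionError) as exc:
        return DescriptorResult.unavailable("hinge_angle", str(exc))
    ref_head_lookup = {
        r: c for r, c in zip(reference_leg.head_residues, reference_leg.head_coords)
    }
    common_head = [r for r in head_sel.residues if r in ref_head_lookup]
    if len(common_head) < 3:
        return DescriptorResult.unavailable("hinge_angle", "fewer than 3 common head residues")
    model_lookup = {r: c for r, c in zip(head_sel.residues, head_sel.coordinates)}
    frame, _ = kabsch_superpose(
        np.array([model_lookup[r] for r in common_head]),
        np.array([ref_head_lookup[r] for r in common_head]),
    )

    leg_residues = list(reference_leg.leg_residues)
    try:
        leg_sel = _ca(structure, model, chain, leg_residues, dimer_map)
    except (LookupError, EmptySelectionError) as exc:
        return DescriptorResult.unavailable("hinge_angle", str(exc))
    if len(leg_sel.residues) / len(leg_residues) < definition.min_coverage:
        return DescriptorResult.unavailable(
            "hinge_angle",
            f"leg coverage {len(leg_sel.residues)}/{len(leg_residues)} below threshold",
        )
    ref_leg_lookup = {r: c for r, c in zip(reference_leg.leg_residues, reference_leg.leg_coords)}
    common_leg = [r for r in leg_sel.residues if r in ref_leg_lookup]
    if len(common_leg) < 3:
        return DescriptorResult.unavailable("hinge_angle", "fewer than 3 common leg residues")
    leg_lookup = {r: c for r, c in zip(leg_sel.residues, leg_sel.coordinates)}
    moved_leg = frame.apply(np.array([leg_lookup[r] for r in common_leg]))
    ref_leg = np.array([ref_leg_lookup[r] for r in common_leg])
    swing, _ = kabsch_superpose(ref_leg, moved_leg)
    hinge = decompose_hinge(swing, reference_leg.pivot)
    return DescriptorResult(
        "hinge_angle",
        hinge.angle,
        extras={"axis": hinge.axis, "pivot": hinge.pivot, "n_leg_atoms": len(common_leg)},
    )


def compare_to_reference(
    structure: EnsembleStructure,
    model: int,
    reference: EnsembleStructure,
    residues: Sequence[int] | tuple[int, int],
    dimer_map: DimerMap,
    reference_map: DimerMap | None = None,
    reference_model: int = 1,
    frame: str = "dimer",
) -> DescriptorResult:
    """Cα RMSD against a reference over a mature-numbering residue span.

    Correspondence is by mature residue number with chains paired
    (chain_a <-> reference chain_a); resolved residue sets are intersected
    and the number of atom pairs used is reported.  ``frame='dimer'`` fits
    over all paired atoms (both subunits); ``frame='subunit_a'`` or
    ``'subunit_b'`` fits on one subunit only and evaluates the deviation
    over all pairs in that fitted frame.
    """
    if isinstance(residues, tuple) and len(residues) == 2 and residues[0] <= residues[1]:
        residues = list(range(residues[0], residues[1] + 1))
    reference_map = reference_map or dimer_map
    pairs = list(zip((dimer_map.chain_a, dimer_map.chain_b),
                     (reference_map.chain_a, reference_map.chain_b)))
    mob, tgt, subunit_sizes = [], [], []
    for chain, ref_chain in pairs:
        try:
            sel_m = _ca(structure, model, chain, residues, dimer_map)
            sel_r = _ca(reference, reference_model, ref_chain, residues, reference_map)
        except (LookupError, EmptySelectionError) as exc:
            return DescriptorResult.unavailable("rmsd", str(exc))
        # back to mature numbering so the two maps' offsets can differ
        lm = {r - dimer_map.numbering_offset: c
              for r, c in zip(sel_m.residues, sel_m.coordinates)}
        lr = {r - reference_map.numbering_offset: c
              for r, c in zip(sel_r.residues, sel_r.coordinates)}
        common = [r for r in lm if r in lr]
        mob.extend(lm[r] for r in common)
        tgt.extend(lr[r] for r in common)
        subunit_sizes.append(len(common))
    n = len(mob)
    if n < 3:
        return DescriptorResult.unavailable("rmsd", f"only {n} common residues")
    mob, tgt = np.array(mob), np.array(tgt)
    if frame == "dimer":
        transform, rmsd = kabsch_superpose(mob, tgt)
    elif frame in ("subunit_a", "subunit_b"):
        k = subunit_sizes[0]
        sl = slice(0, k) if frame == "subunit_a" else slice(k, None)
        transform, _ = kabsch_superpose(mob[sl], tgt[sl])
        moved = transform.apply(mob)
        rmsd = float(np.sqrt(np.mean(np.sum((moved - tgt) ** 2, axis=1))))
    else:
        raise ValueError(f"frame must be dimer, subunit_a or subunit_b, got {frame!r}")
    return DescriptorResult("rmsd", rmsd, extras={"n_atoms": n, "frame": frame})


@dataclass(frozen=True)
class EnsembleDistanceStats:
    """Per-model atom-pair distances over an ensemble, with summary stats."""

    distances: np.ndarray          # one entry per model; NaN where excluded
    excluded_models: tuple[int, ...]
    mean: float
    sd: float
    min: float
    max: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray

    @property
    def n_models_used(self) -> int:
        return int(np.isfinite(self.distances).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model": np.arange(1, len(self.distances) + 1), "distance_A": self.distances}
        )


def ensemble_distance_stats(
    structure: EnsembleStructure,
    dimer_map: DimerMap,
    site_a: tuple[str, int, str],
    site_b: tuple[str, int, str],
    bin_width: float = 1.0,
) -> EnsembleDistanceStats:
    """Distance between two named atoms across every model of an ensemble.

    ``site_a``/``site_b`` are (chain, mature residue number, atom name).
    Models lacking either atom are excluded from the statistics and listed
    in ``excluded_models``; if no model has both atoms this is an error.
    """
    dists = np.full(structure.n_models, np.nan)
    excluded = []
    for m in range(1, structure.n_models + 1):
        try:
            pa = _single_ca(structure, m, site_a[0], site_a[1], dimer_map, site_a[2])
            pb = _single_ca(structure, m, site_b[0], site_b[1], dimer_map, site_b[2])
        except (LookupError, EmptySelectionError):
            excluded.append(m)
            continue
        dists[m - 1] = np.linalg.norm(pa - pb)
    ok = np.isfinite(dists)
    if not ok.any():
        raise EmptySelectionError(
            f"atom pair {site_a}/{site_b} absent from every model of "
            f"{structure.identifier!r}"
        )
    vals = dists[ok]
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(lo, max(hi, lo + bin_width) + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return EnsembleDistanceStats(
        distances=dists,
        excluded_models=tuple(excluded),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        min=float(vals.min()),
        max=float(vals.max()),
        histogram_counts=counts,
        histogram_edges=edges,
    )


@dataclass
class ConformationReport:
    """Per-model descriptor table with juxtaposed<->separated ranking.

    Models are ranked by descending scissor magnitude (the primary ensemble
    coordinate), ties broken by ascending tip separation, then by model
    index for stability.  The extreme models are labelled
    ``juxtaposed-like`` (largest scissor) and ``separated-like`` (smallest).
    """

    table: pd.DataFrame
    identifier: str = ""

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def summary(self) -> str:
        cols = [c for c in ("model", "scissor_abs", "tip_separation", "rank", "label")
                if c in self.table.columns]
        return (
            f"Conformation report for {self.identifier or 'ensemble'} "
            f"({len(self.table)} models)\n"
            + self.table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}")
        )


def ensemble_report(
    structure: EnsembleStructure,
    dimer_map: DimerMap,
    scissor_definition: ScissorDefinition = ScissorDefinition(),
    domain_definition: DomainDefinition = DomainDefinition(),
    references: Mapping[str, tuple[EnsembleStructure, DimerMap]] | None = None,
    reference_legs: Mapping[str, object] | None = None,
) -> ConformationReport:
    """All descriptors for every model, ranked along the conformational axis.

    ``references`` maps a label to (reference structure, its dimer map);
    each contributes an ``rmsd_vs_<label>`` column over the head span.
    ``reference_legs`` maps chain id to a reference leg for hinge angles.
    Missing descriptors propagate as NaN with their reasons collected in a
    ``missing`` column; one missing descriptor never aborts the report.
    """
    rows = []
    for m in range(1, structure.n_models + 1):
        reasons = []

        def grab(res: DescriptorResult) -> float:
            if res.missing and res.reason:
                reasons.append(f"{res.name}: {res.reason}")
            return res.value

        sc = scissor_dihedral(structure, m, dimer_map, scissor_definition)
        row = {
            "model": m,
            "scissor_signed": sc.extras.get("signed", math.nan),
            "scissor_abs": grab(sc),
            "tip_separation": grab(
                tip_separation(structure, m, dimer_map, domain_definition.tip_residue)
            ),
            "closure_angle_a": grab(
                closure_angle(structure, m, dimer_map.chain_a, dimer_map, domain_definition)
            ),
            "closure_angle_b": grab(
                closure_angle(structure, m, dimer_map.chain_b, dimer_map, domain_definition)
            ),
        }
        if reference_legs:
            for chain, ref_leg in reference_legs.items():
                suffix = "a" if chain == dimer_map.chain_a else "b"
                row[f"hinge_angle_{suffix}"] = grab(
                    leg_hinge_angle(structure, m, dimer_map, ref_leg, chain=chain,
                                    definition=domain_definition)
                )
        for label, (ref, ref_map) in (references or {}).items():
            row[f"rmsd_vs_{label}"] = grab(
                compare_to_reference(
                    structure, m, ref, domain_definition.head, dimer_map, ref_map
                )
            )
        row["missing"] = "; ".join(reasons)
        rows.append(row)

    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["scissor_abs", "tip_separation", "model"],
        ascending=[False, True, True],
        kind="mergesort",
        na_position="last",
    )
    # competition ranking: models with equal (scissor, tip) keys tie
    keys = list(zip(order["scissor_abs"], order["tip_separation"]))
    ranks = np.empty(len(order), dtype=int)
    for i, key in enumerate(keys):
        ranks[i] = ranks[i - 1] if i and key == keys[i - 1] else i + 1
    table["rank"] = pd.Series(ranks, index=order.index)
    labels = [""] * len(table)
    distinct = len(set(keys)) > 1
    if distinct and table["scissor_abs"].notna().any():
        labels[order.index[0]] = "juxtaposed-like"
        labels[order.index[-1]] = "separated-like"
    table["label"] = labels
    return ConformationReport(table=table, identifier=structure.identifier)
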