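"""Coordinate file I/O and residue-numbering validation.

Structures are read with gemmi (PDB and mmCIF, single- or multi-model) into a
lightweight ensemble container: one pandas table of atom records per model.
Residue numbering follows the mature-receptor convention for EGFR (signal
peptide excluded); deposited entries may be shifted by the 24-residue signal
sequence, so the dimer map carries an explicit integer offset and is validated
against residue-name anchors (Ile 190, Thr 249, Trp 492, Thr 614, Ile 619,
Ala 623) rather than trusted blindly.  Numbering drift is the chief silent
failure mode of this kind of analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "EnsembleStructure",
    "DimerMap",
    "CalphaSelection",
    "AnchorCheck",
    "DimerMapValidation",
    "StructureIOError",
    "EmptyStructureError",
    "EmptySelectionError",
    "MATURE_ANCHORS",
    "STANDARD_AA",
    "read_structure",
    "write_structure",
    "structure_from_records",
    "select_calpha",
    "validate_dimer_map",
    "propose_dimer_chains",
    "write_report",
]

#: expected residue names at mature-numbering anchor positions
MATURE_ANCHORS: dict[int, str] = {
    190: "ILE",
    249: "THR",
    492: "TRP",
    614: "THR",
    619: "ILE",
    623: "ALA",
}

#: signal-peptide length: precursor number = mature number + 24
SIGNAL_PEPTIDE_OFFSET = 24

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

ATOM_COLUMNS = ["chain", "resnum", "icode", "resname", "atom", "element", "x", "y", "z", "het"]


class StructureIOError(RuntimeError):
    """Problem reading or writing a coordinate file."""


class EmptyStructureError(StructureIOError):
    """A parsed file contained no atoms."""


class EmptySelectionError(LookupError):
    """An atom selection matched nothing."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: chain, author residue number, names, position in Å."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: tuple[float, float, float]
    model_index: int = 1
    element: str = ""
    hetero: bool = False
    icode: str = ""


@dataclass
class EnsembleStructure:
    """Ordered models of atom records parsed from a PDB/mmCIF file.

    ``models`` holds one DataFrame per model (columns in ``ATOM_COLUMNS``);
    model access throughout the package is 1-based, matching the MODEL records
    of multi-model NMR files.  Topology differences between models of a
    multi-model file are reported in ``topology_mismatches``, never silently
    dropped.
    """

    models: list[pd.DataFrame]
    source_format: str = "pdb"
    identifier: str = ""
    topology_mismatches: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.models:
            raise EmptyStructureError(f"{self.identifier or 'structure'}: no models")
        self.topology_mismatches = list(self.topology_mismatches) + _topology_report(self.models)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def model(self, index: int) -> pd.DataFrame:
        """Return the atom table of model ``index`` (1-based)."""
        if not 1 <= index <= len(self.models):
            raise LookupError(
                f"model {index} out of range 1..{len(self.models)} in {self.identifier!r}"
            )
        return self.models[index - 1]

    def chains(self, model: int = 1) -> list[str]:
        return list(dict.fromkeys(self.model(model)["chain"]))

    def protein_chains(self, model: int = 1) -> list[str]:
        tab = self.model(model)
        keep = tab[~tab["het"] & tab["resname"].isin(STANDARD_AA)]
        return list(dict.fromkeys(keep["chain"]))


def _topology_report(models: Sequence[pd.DataFrame]) -> list[str]:
    if len(models) < 2:
        return []
    keys = [frozenset(zip(m["chain"], m["resnum"], m["atom"])) for m in models]
    ref = keys[0]
    out = []
    for i, k in enumerate(keys[1:], start=2):
        if k != ref:
            extra, missing = len(k - ref), len(ref - k)
            out.append(
                f"model {i} topology differs from model 1 "
                f"({missing} atoms missing, {extra} extra)"
            )
    return out


@dataclass(frozen=True)
class DimerMap:
    """Names the two receptor chains and their numbering convention.

    ``numbering_offset`` is author number minus mature number: 0 for entries
    deposited in mature numbering, +24 when the signal peptide is counted.
    """

    chain_a: str
    chain_b: str
    numbering_offset: int = 0
    anchor_expectations: Mapping[int, str] = field(
        default_factory=lambda: dict(MATURE_ANCHORS)
    )

    def __post_init__(self):
        if self.chain_a == self.chain_b:
            raise ValueError("chain_a and chain_b must differ")

    def author_number(self, mature_number: int) -> int:
        return mature_number + self.numbering_offset


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _best_altloc(atoms: Iterable[gemmi.Atom]) -> list[gemmi.Atom]:
    """Collapse altlocs: highest occupancy wins, ties to the first seen."""
    best: dict[str, gemmi.Atom] = {}
    for atom in atoms:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-9:
            best[atom.name] = atom
    return list(best.values())


def read_structure(path, format: str = "auto") -> EnsembleStructure:
    """Read a PDB or mmCIF coordinate file into an :class:`EnsembleStructure`.

    All ATOM records with coordinates are retained, grouped by model; hetero
    and ligand records are retained and tagged (``het`` column); insertion
    codes are preserved.  ``format`` may be ``pdb``, ``mmcif`` or ``auto``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureIOError(f"no such file: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise ValueError(f"format must be pdb, mmcif or auto, got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureIOError(f"cannot parse {path}: {exc}") from exc

    source_format = "mmcif" if (
        format == "mmcif" or (format == "auto" and path.suffix.lower() in {".cif", ".mmcif"})
    ) else "pdb"

    models: list[pd.DataFrame] = []
    for model in st:
        rows = []
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H" or residue.name not in STANDARD_AA
                for atom in _best_altloc(residue):
                    pos = atom.pos
                    rows.append(
                        (
                            chain.name,
                            residue.seqid.num,
                            residue.seqid.icode.strip(),
                            residue.name,
                            atom.name,
                            atom.element.name.upper(),
                            pos.x,
                            pos.y,
                            pos.z,
                            het,
                        )
                    )
        if rows:
            models.append(pd.DataFrame(rows, columns=ATOM_COLUMNS))
    if not models:
        raise EmptyStructureError(f"{path}: no atoms with coordinates")
    return EnsembleStructure(models, source_format=source_format, identifier=st.name or path.stem)


def structure_from_records(
    records: Sequence[AtomRecord], identifier: str = "", source_format: str = "pdb"
) -> EnsembleStructure:
    """Build an :class:`EnsembleStructure` from in-memory atom records."""
    by_model: dict[int, list] = {}
    for r in records:
        by_model.setdefault(r.model_index, []).append(
            (r.chain_id, r.residue_number, r.icode, r.residue_name, r.atom_name,
             r.element or r.atom_name[:1], *r.position, r.hetero)
        )
    models = [
        pd.DataFrame(by_model[k], columns=ATOM_COLUMNS) for k in sorted(by_model)
    ]
    return EnsembleStructure(models, source_format=source_format, identifier=identifier)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _to_gemmi(structure: EnsembleStructure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.identifier or "model"
    for i, tab in enumerate(structure.models, start=1):
        model = gemmi.Model(i)
        for chain_name in dict.fromkeys(tab["chain"]):
            chain = gemmi.Chain(str(chain_name))
            sub = tab[tab["chain"] == chain_name]
            for (resnum, icode, resname, het), atoms in sub.groupby(
                ["resnum", "icode", "resname", "het"], sort=False
            ):
                res = gemmi.Residue()
                res.name = str(resname)
                res.seqid = gemmi.SeqId(int(resnum), str(icode) if icode else " ")
                res.het_flag = "H" if het else "A"
                for row in atoms.itertuples():
                    atom = gemmi.Atom()
                    atom.name = row.atom
                    atom.element = gemmi.Element(row.element or row.atom[:1])
                    atom.pos = gemmi.Position(row.x, row.y, row.z)
                    atom.occ = 1.0
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    return st


def write_structure(structure: EnsembleStructure, path, format: str = "pdb") -> Path:
    """Write an ensemble to ``path`` as PDB or mmCIF.

    PDB output uses the format's fixed 3-decimal coordinate columns.  mmCIF
    output writes coordinates at 9 decimals, so an mmCIF round trip preserves
    descriptor values far below any tolerance used in this package.
    """
    path = Path(path)
    if format == "pdb":
        st = _to_gemmi(structure)
        st.setup_entities()
        try:
            st.write_pdb(str(path))
        except (RuntimeError, OSError) as exc:
            raise StructureIOError(f"cannot write {path}: {exc}") from exc
    elif format == "mmcif":
        _write_mmcif(structure, path)
    else:
        raise ValueError(f"format must be pdb or mmcif, got {format!r}")
    return path


def _write_mmcif(structure: EnsembleStructure, path: Path) -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block(structure.identifier or "model")
    loop = block.init_loop(
        "_atom_site.",
        [
            "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
            "label_comp_id", "label_asym_id", "label_entity_id", "label_seq_id",
            "pdbx_PDB_ins_code", "Cartn_x", "Cartn_y", "Cartn_z", "occupancy",
            "B_iso_or_equiv", "auth_seq_id", "auth_asym_id", "pdbx_PDB_model_num",
        ],
    )
    serial = 0
    for mi, tab in enumerate(structure.models, start=1):
        for row in tab.itertuples():
            serial += 1
            loop.add_row(
                [
                    "HETATM" if row.het else "ATOM",
                    str(serial),
                    row.element or row.atom[:1],
                    row.atom,
                    ".",
                    row.resname,
                    row.chain,
                    "1",
                    str(int(row.resnum)),
                    row.icode if row.icode else "?",
                    f"{row.x:.9f}",
                    f"{row.y:.9f}",
                    f"{row.z:.9f}",
                    "1.00",
                    "0.00",
                    str(int(row.resnum)),
                    row.chain,
                    str(mi),
                ]
            )
    try:
        doc.write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise StructureIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# selection and validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalphaSelection:
    """Ordered Cα coordinates for a residue request, with the gaps reported."""

    coordinates: np.ndarray  # (n, 3)
    residues: tuple[int, ...]  # residues found, in request order
    missing: tuple[int, ...]  # requested residues without a Cα


def select_calpha(
    structure: EnsembleStructure,
    model: int,
    chain: str,
    residues: Iterable[int],
    atom: str = "CA",
) -> CalphaSelection:
    """Cα coordinates for the requested residues of one chain of one model.

    Output order follows the request; residues without the named atom are
    listed in ``missing`` (found + missing always partitions the request).
    """
    tab = structure.model(model)
    if chain not in set(tab["chain"]):
        raise LookupError(
            f"chain {chain!r} not in model {model} (has {structure.chains(model)})"
        )
    sub = tab[(tab["chain"] == chain) & (tab["atom"] == atom) & ~tab["het"]]
    lookup: dict[int, np.ndarray] = {}
    for row in sub.itertuples():
        lookup.setdefault(int(row.resnum), np.array([row.x, row.y, row.z]))
    req = [int(r) for r in residues]
    found, coords, missing = [], [], []
    for r in req:
        if r in lookup:
            found.append(r)
            coords.append(lookup[r])
        else:
            missing.append(r)
    if not found:
        raise EmptySelectionError(
            f"none of {len(req)} requested residues has a {atom} atom in chain {chain!r}"
        )
    return CalphaSelection(np.array(coords), tuple(found), tuple(missing))


@dataclass(frozen=True)
class AnchorCheck:
    chain: str
    mature_number: int
    author_number: int
    expected: str
    observed: str | None
    passed: bool


@dataclass(frozen=True)
class DimerMapValidation:
    checks: tuple[AnchorCheck, ...]
    n_pass: int
    n_checked: int
    suggested_offset: int

    @property
    def all_pass(self) -> bool:
        return self.n_checked > 0 and self.n_pass == self.n_checked


def _chain_residue_names(tab: pd.DataFrame, chain: str) -> dict[int, str]:
    sub = tab[(tab["chain"] == chain) & ~tab["het"]]
    return {int(r): str(n) for r, n in zip(sub["resnum"], sub["resname"])}


def _anchor_matches(names: dict[int, str], anchors: Mapping[int, str], offset: int) -> int:
    return sum(1 for m, exp in anchors.items() if names.get(m + offset) == exp)


def validate_dimer_map(
    structure: EnsembleStructure, dimer_map: DimerMap, model: int = 1
) -> DimerMapValidation:
    """Check residue-name anchors under the map's numbering offset.

    Report-only and side-effect free.  Anchors outside a chain's residue span
    are skipped.  The returned ``suggested_offset`` is whichever of 0 or +24
    (signal peptide) maximizes anchor matches over both chains, regardless of
    the offset under test.
    """
    tab = structure.model(model)
    checks: list[AnchorCheck] = []
    score = {0: 0, SIGNAL_PEPTIDE_OFFSET: 0}
    for chain in (dimer_map.chain_a, dimer_map.chain_b):
        names = _chain_residue_names(tab, chain)
        if not names:
            continue
        lo, hi = min(names), max(names)
        for mature, expected in sorted(dimer_map.anchor_expectations.items()):
            author = mature + dimer_map.numbering_offset
            if not lo <= author <= hi:
                continue
            observed = names.get(author)
            checks.append(
                AnchorCheck(chain, mature, author, expected, observed, observed == expected)
            )
        for off in score:
            score[off] += _anchor_matches(names, dimer_map.anchor_expectations, off)
    n_pass = sum(c.passed for c in checks)
    suggested = max(score, key=lambda off: (score[off], -abs(off)))
    return DimerMapValidation(tuple(checks), n_pass, len(checks), suggested)


def propose_dimer_chains(structure: EnsembleStructure, model: int = 1) -> DimerMap:
    """Propose the two largest protein chains as the receptor dimer."""
    tab = structure.model(model)
    sizes = (
        tab[~tab["het"]]
        .groupby("chain")["resnum"]
        .nunique()
        .sort_values(ascending=False)
    )
    if len(sizes) < 2:
        raise LookupError("fewer than two protein chains; cannot propose a dimer")
    a, b = sizes.index[:2]
    return DimerMap(chain_a=str(a), chain_b=str(b))


# ---------------------------------------------------------------------------
# tabular reports
# ---------------------------------------------------------------------------


def write_report(report, path, format: str = "csv") -> Path:
    """Write a descriptor report table to CSV or JSON.

    Accepts a DataFrame or any object with a ``to_frame()`` method.  Numeric
    values are written with 9 significant digits.  Empty reports are refused
    and no file is created.
    """
    frame = report.to_frame() if hasattr(report, "to_frame") else report
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot write report of type {type(report).__name__}")
    if frame.empty:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    if format == "csv":
        path.write_text(frame.to_csv(index=False, float_format="%.12g"))
    elif format == "json":
        payload = json.loads(frame.to_json(orient="records", double_precision=12))
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"format must be csv or json, got {format!r}")
    return path
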