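"""Small-molecule I/O, standardization, and physicochemical descriptors.

The descriptor conventions here are pinned so that reported values for
literature kinase-inhibitor hits are reproduced exactly:

* TPSA uses Ertl fragment contributions *including* sulfur and phosphorus
  terms (``tpsa_sp=True``).  The common toolkit default omits S/P, which
  underestimates the polar surface of thiazole- and thiophene-containing
  inhibitors by ~28 A^2 per aromatic sulfur.
* The hydrogen-bond-acceptor count uses a convention that counts carbonyl,
  ether and hydroxyl oxygens, non-pyrrolic aromatic nitrogens, and
  aromatic/divalent sulfur, while excluding amide nitrogens.
* Molecular weight uses average (not monoisotopic) atomic masses.

All descriptors are kept at full precision internally; rounding happens only
when a report table is written.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Lipinski, rdMolDescriptors

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Column order of the descriptor table, fixed for CSV round-tripping.
DESCRIPTOR_COLUMNS = ("mw", "heavy_atoms", "hbd", "hba", "rot_bonds", "tpsa", "logp")


class ChemIOError(ValueError):
    """Raised for unparsable or non-drug-like structures."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A library entry: identifier, connection table, optional conformer.

    ``structure`` is a canonical SMILES; ``conformer`` is an (n_atoms, 3)
    list of coordinates in Angstrom covering heavy atoms (and any explicit
    hydrogens present at read time), or ``None``.
    """

    id: str
    structure: str
    conformer: tuple | None = None
    props: dict = field(default_factory=dict)

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.structure)
        if mol is None:
            raise ChemIOError(f"record {self.id!r}: unparsable structure {self.structure!r}")
        return mol


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical descriptor vector for one molecule.

    Units: mw in g/mol (average masses), tpsa in A^2; the rest are counts.
    ``logp`` is informational only (Crippen estimate, not the published
    XLogP3-AA algorithm) and is never used for filtering decisions.
    """

    mw: float
    heavy_atoms: int
    hbd: int
    hba: int
    rot_bonds: int
    tpsa: float
    logp: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in DESCRIPTOR_COLUMNS}


def _canonical(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def read_structures(path: str | Path, format: str | None = None) -> list[MoleculeRecord]:
    """Read a molecule library from a SMILES list, SDF (V2000) or CSV file.

    SMILES lists are whitespace-separated ``smiles [id]`` lines; CSV files
    need a ``smiles`` column and may carry an ``id`` column.  Unparsable
    entries are logged and skipped; the skip count is logged at the end.

    Raises ``ChemIOError`` if the file is missing, the format is unknown, or
    no entry parses.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    if format is None:
        format = {".sdf": "sdf", ".csv": "csv"}.get(path.suffix.lower(), "smiles-list")
    if format not in ("smiles-list", "sdf", "csv"):
        raise ChemIOError(f"unsupported format {format!r}")

    records: list[MoleculeRecord] = []
    skipped = 0

    if format == "smiles-list":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                log.warning("line %d: cannot parse %r, skipping", i + 1, parts[0])
                skipped += 1
                continue
            mol_id = parts[1] if len(parts) > 1 else f"mol{len(records) + 1}"
            records.append(MoleculeRecord(id=mol_id, structure=_canonical(mol)))
    elif format == "csv":
        with path.open() as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ChemIOError(f"{path}: CSV needs a 'smiles' column")
            for i, row in enumerate(reader):
                mol = Chem.MolFromSmiles(row["smiles"])
                if mol is None:
                    log.warning("row %d: cannot parse %r, skipping", i + 1, row["smiles"])
                    skipped += 1
                    continue
                mol_id = row.get("id") or f"mol{len(records) + 1}"
                props = {
                    k: float(v)
                    for k, v in row.items()
                    if k not in ("id", "smiles") and v not in (None, "")
                    and _is_number(v)
                }
                records.append(MoleculeRecord(id=mol_id, structure=_canonical(mol), props=props))
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                log.warning("SDF entry %d unparsable, skipping", i + 1)
                skipped += 1
                continue
            conformer = None
            if mol.GetNumConformers() > 0:
                conf = mol.GetConformer()
                if conf.Is3D():
                    conformer = tuple(
                        (p.x, p.y, p.z)
                        for p in (conf.GetAtomPosition(a) for a in range(mol.GetNumAtoms()))
                    )
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            mol_id = name.strip() or f"mol{len(records) + 1}"
            records.append(
                MoleculeRecord(
                    id=mol_id,
                    structure=_canonical(Chem.RemoveHs(mol)),
                    conformer=conformer,
                )
            )

    if skipped:
        log.info("%s: skipped %d unparsable entries", path, skipped)
    if not records:
        raise ChemIOError(f"{path}: no parsable records")
    return records


def _is_number(v: str) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def standardize_molecule(m: MoleculeRecord) -> MoleculeRecord:
    """Strip counter-ions and normalize hydrogens to implicit form.

    The largest organic (carbon-containing) covalent fragment is retained;
    ties on heavy-atom count are broken by larger molecular weight, then by
    input fragment order.  A structure with no carbon-containing fragment is
    rejected as non-drug-like.
    """
    mol = m.to_mol()
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    if not organic:
        raise ChemIOError(f"record {m.id!r}: no organic fragment (no carbon)")
    best = max(
        enumerate(organic),
        key=lambda kv: (kv[1].GetNumHeavyAtoms(), Descriptors.MolWt(kv[1]), -kv[0]),
    )[1]
    best = Chem.RemoveHs(best)
    return replace(m, structure=_canonical(best))


# SMARTS for the pinned H-bond acceptor convention: carbonyl/ether/hydroxyl O,
# non-pyrrolic aromatic N, aromatic or divalent S; amide N excluded by
# construction (no sp3/amide N pattern present).
_ACCEPTOR_SMARTS = (
    "[O;X1]",            # carbonyl / N-oxide terminal O
    "[O;X2]",            # ether, ester, hydroxyl O
    "[n;X2]",            # aromatic N with lone pair (pyridine/thiazole type)
    "[s;a]",             # aromatic S
    "[S;X2;!a]",         # divalent non-aromatic S (thioether)
    "[N;X3;v3;!$(NC=O);!$(N~[!#6;!#1]);!a;!$(N=*)]",  # basic amine N, amide excluded
)
_ACCEPTOR_PATTERNS = [Chem.MolFromSmarts(s) for s in _ACCEPTOR_SMARTS]


def count_hba(mol: Chem.Mol, include_sulfur: bool = True) -> int:
    """Hydrogen-bond acceptor count under the pinned convention.

    Counts each qualifying atom once.  ``include_sulfur=False`` drops the
    aromatic/divalent sulfur patterns (closer to the common N/O-only
    convention).
    """
    patterns = _ACCEPTOR_PATTERNS if include_sulfur else _ACCEPTOR_PATTERNS[:3] + _ACCEPTOR_PATTERNS[5:]
    atoms: set[int] = set()
    for patt in patterns:
        for match in mol.GetSubstructMatches(patt):
            atoms.update(match)
    return len(atoms)


def compute_descriptors(
    m: MoleculeRecord, tpsa_sp: bool = True, hba_sulfur: bool = True
) -> DescriptorSet:
    """Compute the pinned descriptor set for a standardized molecule.

    ``tpsa_sp`` toggles the sulfur/phosphorus Ertl contributions (default on,
    required for parity with published thiazole-inhibitor tables);
    ``hba_sulfur`` toggles sulfur acceptors in the HBA count.
    """
    mol = m.to_mol()
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        hbd=Lipinski.NumHDonors(mol),
        hba=count_hba(mol, include_sulfur=hba_sulfur),
        rot_bonds=Descriptors.NumRotatableBonds(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol, includeSandP=tpsa_sp),
        logp=Descriptors.MolLogP(mol),
    )


def descriptor_table(
    lib: Sequence[MoleculeRecord], tpsa_sp: bool = True, hba_sulfur: bool = True
) -> pd.DataFrame:
    """One descriptor row per record, indexed by id, fixed column order.

    Per-molecule failures do not abort the table: the row is kept with NaN
    descriptor values and ``error`` set to the failure message.
    """
    if len(lib) == 0:
        raise ChemIOError("empty library")
    rows = []
    for rec in lib:
        row: dict = {"id": rec.id}
        try:
            row.update(compute_descriptors(rec, tpsa_sp=tpsa_sp, hba_sulfur=hba_sulfur).as_dict())
            row["error"] = ""
        except ChemIOError as exc:
            row.update({c: float("nan") for c in DESCRIPTOR_COLUMNS})
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", *DESCRIPTOR_COLUMNS, "error"]).set_index("id")


def write_descriptor_csv(table: pd.DataFrame, path: str | Path, decimals: int = 2) -> None:
    """Write a descriptor table as CSV, rounding floats at report time only."""
    table.round(decimals).to_csv(path)


def write_sdf(lib: Iterable[MoleculeRecord], path: str | Path, with_descriptors: bool = False) -> None:
    """SDF pass-through writer; descriptors become SD tags when requested."""
    writer = Chem.SDWriter(str(path))
    for rec in lib:
        mol = rec.to_mol()
        mol.SetProp("_Name", rec.id)
        if with_descriptors:
            for k, v in compute_descriptors(rec).as_dict().items():
                if v is not None:
                    mol.SetProp(k, f"{v:.4f}" if isinstance(v, float) else str(v))
        writer.write(mol)
    writer.close()
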