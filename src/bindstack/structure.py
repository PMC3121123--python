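"""Typed coordinate model for protein-DNA complexes read from PDB files.

Parsing is delegated to Bio.PDB; this module adds the polymer-type
classification, alternate-location and model policies, HETATM handling, a
fixed-column writer for toy fixtures, and the chain map that ties PDB residue
numbering (1-based, with insertion codes) to the 0-based sequence indexing
used by prediction tracks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "Chain",
    "ComplexStructure",
    "PDBFormatError",
    "classify_polymer",
    "read_pdb",
    "write_pdb",
    "STANDARD_AMINO_ACIDS",
    "DNA_RESIDUES",
    "RNA_RESIDUES",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
DNA_RESIDUES = frozenset("DA DC DG DT DI DU".split())
RNA_RESIDUES = frozenset("A C G U I".split())


class PDBFormatError(ValueError):
    """Raised for unparseable or empty PDB input; names the offending line."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coord: np.ndarray  # (3,) Angstrom
    occupancy: float = 1.0
    alt_loc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.isfinite(self.coord).all():
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[AtomRecord]
    polymer_class: str  # protein | dna | rna | other

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.identity} has no atoms")

    @property
    def identity(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def polymer_classes(self) -> set[str]:
        return {r.polymer_class for r in self.residues}


@dataclass
class ComplexStructure:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chain in self.chains:
            seen = set()
            for r in chain.residues:
                if r.identity in seen:
                    raise ValueError(f"duplicate residue identity {r.identity}")
                seen.add(r.identity)

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if "protein" in c.polymer_classes()]

    def nucleic_chains(self, include_rna: bool = False) -> list[Chain]:
        wanted = {"dna", "rna"} if include_rna else {"dna"}
        return [c for c in self.chains if c.polymer_classes() & wanted]

    def protein_residues(self) -> list[ResidueRecord]:
        return [r for c in self.chains for r in c.residues if r.polymer_class == "protein"]

    def nucleic_atoms(self, include_rna: bool = False) -> np.ndarray:
        wanted = {"dna", "rna"} if include_rna else {"dna"}
        coords = [
            a.coord
            for c in self.chains
            for r in c.residues
            if r.polymer_class in wanted
            for a in r.atoms
        ]
        return np.array(coords) if coords else np.empty((0, 3))

    def protein_sequence(self, chain_id: str) -> str:
        for c in self.chains:
            if c.chain_id == chain_id:
                return "".join(
                    seq1(r.res_name, undef_code="X")
                    for r in c.residues
                    if r.polymer_class == "protein"
                )
        raise KeyError(f"no chain {chain_id!r}")

    def chain_map(self) -> pd.DataFrame:
        """Residue numbering map: PDB identity -> 0-based per-chain index.

        For protein chains the index runs over protein residues only, matching
        the coordinate system of sequence-aligned prediction tracks.
        """
        rows = []
        for chain in self.chains:
            idx = 0
            classes = chain.polymer_classes()
            for r in chain.residues:
                if "protein" in classes and r.polymer_class != "protein":
                    continue
                rows.append(
                    {
                        "chain_id": chain.chain_id,
                        "seq_number": r.seq_number,
                        "insertion_code": r.insertion_code,
                        "index": idx,
                        "res_name": r.res_name,
                    }
                )
                idx += 1
        return pd.DataFrame(
            rows, columns=["chain_id", "seq_number", "insertion_code", "index", "res_name"]
        )


def classify_polymer(res_name: str, atom_names: Iterable[str] | None = None,
                     extra_protein: Iterable[str] = (), extra_dna: Iterable[str] = ()) -> str:
    """Classify a residue code as protein, dna, rna or other.

    Pure and total: unknown codes map to "other".  ``extra_protein`` /
    ``extra_dna`` extend the standard code sets (e.g. modified residues a
    caller chooses to whitelist).
    """
    if not res_name:
        raise ValueError("empty residue name")
    name = res_name.strip().upper()
    if name in STANDARD_AMINO_ACIDS or name in set(extra_protein):
        return "protein"
    if name in DNA_RESIDUES or name in set(extra_dna):
        return "dna"
    if name in RNA_RESIDUES:
        return "rna"
    return "other"


def _validate_pdb_text(text: str) -> None:
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6].strip() in ("ATOM", "HETATM"):
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                raise PDBFormatError(
                    f"line {lineno}: malformed coordinate record: {line.rstrip()!r}"
                ) from None
            n_atoms += 1
    if n_atoms == 0:
        first = text.splitlines()[0].rstrip() if text.strip() else "<empty input>"
        raise PDBFormatError(f"no ATOM/HETATM records found (first line: {first!r})")


def _select_altlocs(atoms: Sequence, policy: str) -> list:
    """Resolve alternate locations: one atom per atom name."""
    by_name: dict[str, list] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    chosen = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            chosen.append(group[0])
        elif policy == "occupancy":
            # highest occupancy wins; ties broken by altloc identifier order
            chosen.append(
                min(group, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))
            )
        elif len(policy) == 1:
            kept = [a for a in group if a.get_altloc() in (" ", "", policy)]
            chosen.append(kept[0] if kept else group[0])
        else:
            raise ValueError(f"unknown altloc policy {policy!r}")
    return chosen


def read_pdb(
    source: str | Path | TextIO,
    structure_id: str = "structure",
    model_policy: str | int | None = "first",
    altloc_policy: str = "occupancy",
    include_hetero: bool = False,
    hetero_whitelist: Iterable[str] = (),
    strip_hydrogens: bool = False,
    extra_protein: Iterable[str] = (),
    extra_dna: Iterable[str] = (),
) -> ComplexStructure:
    """Read PDB-format text into a :class:`ComplexStructure`.

    Parameters mirror the policies of the model: first model by default
    (``model_policy=None`` makes a multi-model file an error), alternate
    locations resolved to the highest-occupancy conformer, HETATM records
    excluded unless whitelisted by residue name, hydrogens retained.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    _validate_pdb_text(text)

    parser = PDBParser(QUIET=True)
    bio = parser.get_structure(structure_id, io.StringIO(text))
    models = list(bio.get_models())
    if len(models) > 1:
        if model_policy is None:
            raise ValueError(
                f"file contains {len(models)} models; set model_policy='first' or an index"
            )
        model = models[0] if model_policy == "first" else models[int(model_policy)]
    else:
        model = models[0]

    whitelist = {w.strip().upper() for w in hetero_whitelist}
    chains: list[Chain] = []
    for bio_chain in model:
        chain = Chain(chain_id=bio_chain.id)
        for bio_res in bio_chain:
            hetflag, seq_number, icode = bio_res.id
            is_het = hetflag.strip() != ""
            res_name = bio_res.get_resname().strip()
            if is_het and not include_hetero and res_name not in whitelist:
                continue
            atoms = _select_altlocs(list(bio_res.get_unpacked_list()), altloc_policy)
            records = []
            for a in atoms:
                element = (a.element or "").strip().upper()
                if strip_hydrogens and element in ("H", "D"):
                    continue
                records.append(
                    AtomRecord(
                        serial=a.get_serial_number() or 0,
                        name=a.get_name(),
                        element=element,
                        coord=a.get_coord(),
                        occupancy=float(a.get_occupancy() if a.get_occupancy() is not None else 1.0),
                        alt_loc=a.get_altloc().strip(),
                        is_hetero=is_het,
                    )
                )
            if not records:
                continue
            chain.residues.append(
                ResidueRecord(
                    chain_id=chain.chain_id,
                    seq_number=seq_number,
                    insertion_code=icode.strip(),
                    res_name=res_name,
                    atoms=records,
                    polymer_class=classify_polymer(
                        res_name, extra_protein=extra_protein, extra_dna=extra_dna
                    ),
                )
            )
        if chain.residues:
            chains.append(chain)
    return ComplexStructure(structure_id=structure_id, chains=chains)


def write_pdb(structure: ComplexStructure, target: str | Path | TextIO | None = None) -> str:
    """Write a fixed-column PDB (wwPDB v3.3 ATOM/TER/END) for toy fixtures."""
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if atom.is_hetero else "ATOM  "
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"{record}{serial:>5d} {name}{atom.alt_loc or ' ':1s}"
                    f"{res.res_name:>3s} {chain.chain_id:1s}{res.seq_number:>4d}"
                    f"{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:>5d}      {chain.residues[-1].res_name:>3s} "
                     f"{chain.chain_id:1s}{chain.residues[-1].seq_number:>4d}")
        serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if target is not None:
        if isinstance(target, (str, Path)):
            Path(target).write_text(text)
        else:
            target.write(text)
    return text
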