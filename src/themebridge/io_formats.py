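"""Readers and writers for the formats the pipeline touches.

Domain databases are FASTA with structured headers ``>id|lineage|fgroup``
(lineage and family labels carried inline); themes are aligned FASTA;
structures are PDB text (parsed through gemmi, first model only, altloc
blank-or-'A'); hit and bridge tables are TSV.

Internally all sequence intervals are 0-based half-open; anything written
for humans is 1-based inclusive.  Structure residues keep PDB author
numbering verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import gemmi
import numpy as np
import pandas as pd

from ._alphabet import is_valid, ALPHABET

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# domain FASTA


@dataclass(frozen=True)
class DomainRecord:
    """One protein domain sequence with its lineage/family labels."""

    id: str
    lineage: str
    fgroup: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("domain id must be non-empty")
        if not self.sequence:
            raise ValueError(f"domain {self.id}: empty sequence")
        if not is_valid(self.sequence):
            bad = sorted({c for c in self.sequence if c not in ALPHABET})
            raise ValueError(f"domain {self.id}: symbols {bad} outside alphabet")


def read_domain_fasta(path) -> list[DomainRecord]:
    """Read a domain database (FASTA, headers ``>id|lineage|fgroup``)."""
    records: list[DomainRecord] = []
    seen: set[str] = set()
    header = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks).upper().rstrip("*")
        rid, lineage, fgroup = header
        if rid in seen:
            raise FormatError(f"{path}: duplicate domain id {rid!r}")
        seen.add(rid)
        try:
            records.append(DomainRecord(rid, lineage, fgroup, seq))
        except ValueError as exc:
            raise FormatError(f"{path}: line {header_line}: {exc}") from None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("|")
                if len(parts) != 3 or not all(parts):
                    raise FormatError(
                        f"{path}: line {lineno}: header must be '>id|lineage|fgroup', "
                        f"got {line!r}"
                    )
                header = tuple(parts)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}: line {lineno}: sequence before header")
                chunks.append(line)
    flush()
    return records


def write_domain_fasta(records: Iterable[DomainRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}|{r.lineage}|{r.fgroup}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# theme MSA


@dataclass(frozen=True)
class ThemeAlignment:
    """An ungapped-core theme as a multiple sequence alignment."""

    theme_id: str
    rows: tuple[str, ...]
    source_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.rows:
            raise ValueError(f"theme {self.theme_id}: no rows")
        w = len(self.rows[0])
        if any(len(r) != w for r in self.rows):
            raise ValueError(f"theme {self.theme_id}: ragged rows")
        if w == 0:
            raise ValueError(f"theme {self.theme_id}: zero-width alignment")
        for r in self.rows:
            body = r.replace("-", "")
            if body and not is_valid(body):
                raise ValueError(f"theme {self.theme_id}: invalid symbols in row")
        for c in range(w):
            if all(r[c] == "-" for r in self.rows):
                raise ValueError(f"theme {self.theme_id}: all-gap column {c}")

    @property
    def width(self) -> int:
        return len(self.rows[0])


def drop_all_gap_columns(theme_id: str, rows: list[str],
                         source_ids: Iterable[str] = ()) -> ThemeAlignment:
    """Build a ThemeAlignment, removing (and logging) all-gap columns."""
    w = len(rows[0])
    keep = [c for c in range(w) if any(r[c] != "-" for r in rows)]
    if len(keep) < w:
        logger.warning("theme %s: removed %d all-gap column(s)",
                       theme_id, w - len(keep))
    rows = ["".join(r[c] for c in keep) for r in rows]
    return ThemeAlignment(theme_id, tuple(rows), tuple(source_ids))


def read_theme_msa(path, theme_id: str | None = None) -> ThemeAlignment:
    """Read one theme from an aligned FASTA file."""
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if ids:
                    rows.append("".join(current))
                ids.append(line[1:].split()[0] if len(line) > 1 else f"row{len(ids)}")
                current = []
            else:
                current.append(line.upper())
    if ids:
        rows.append("".join(current))
    if not rows:
        raise FormatError(f"{path}: no alignment rows")
    if len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path}: ragged alignment rows")
    tid = theme_id or Path(path).stem
    try:
        return drop_all_gap_columns(tid, rows, ids)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_theme_msa(t: ThemeAlignment, path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(t.rows):
            rid = t.source_ids[i] if i < len(t.source_ids) else f"{t.theme_id}_{i}"
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# structures


class Atom(NamedTuple):
    chain: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]
    is_het: bool


@dataclass
class StructureModel:
    """Flat atom list from the first model of a PDB file."""

    atoms: list[Atom] = field(default_factory=list)

    def het_residues(self, resname: str) -> list[list[Atom]]:
        """HETATM residues with the given name, grouped by residue."""
        groups: dict[tuple, list[Atom]] = {}
        for a in self.atoms:
            if a.is_het and a.residue_name == resname:
                groups.setdefault(
                    (a.chain, a.residue_number, a.insertion_code), []
                ).append(a)
        return [groups[k] for k in sorted(groups)]


def read_structure(path) -> StructureModel:
    """Parse PDB text: first model, altloc blank or 'A', author numbering."""
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from None
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            for atom in res:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                pos = atom.pos
                if not all(np.isfinite([pos.x, pos.y, pos.z])):
                    raise FormatError(f"{path}: non-finite coordinates")
                atoms.append(Atom(
                    chain=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or " ").strip(),
                    residue_name=res.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    xyz=(pos.x, pos.y, pos.z),
                    is_het=is_het,
                ))
    if not any(not a.is_het for a in atoms):
        raise FormatError(f"{path}: no ATOM records")
    return StructureModel(atoms)


def write_structure(model: StructureModel, path, remarks: Iterable[str] = ()) -> None:
    """Write a StructureModel as PDB text (ATOM/HETATM + REMARK lines)."""
    with open(path, "w") as fh:
        for r in remarks:
            fh.write(f"REMARK 999 {r}\n")
        serial = 0
        for a in model.atoms:
            serial += 1
            rec = "HETATM" if a.is_het else "ATOM  "
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            x, y, z = a.xyz
            fh.write(
                f"{rec}{serial:5d} {name:<4s} {a.residue_name:<3s} "
                f"{a.chain[:1]:1s}{a.residue_number:4d}{a.insertion_code or ' ':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# hit tables

HITS_COLUMNS = ["theme_id", "domain_id", "lineage", "fgroup", "start", "end",
                "score", "evalue", "coverage", "aln_length"]


def write_hits_table(hits, path) -> None:
    """Write theme hits as TSV; intervals converted to 1-based inclusive."""
    rows = [{
        "theme_id": h.theme_id,
        "domain_id": h.domain_id,
        "lineage": h.lineage,
        "fgroup": h.fgroup,
        "start": h.interval[0] + 1,
        "end": h.interval[1],
        "score": h.score,
        "evalue": h.evalue,
        "coverage": h.coverage,
        "aln_length": h.aln_length,
    } for h in hits]
    df = pd.DataFrame(rows, columns=HITS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_hits_table(path) -> pd.DataFrame:
    """Read a hits TSV back; intervals restored to 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"theme_id": str, "domain_id": str,
                                            "lineage": str, "fgroup": str})
    missing = [c for c in HITS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["start"] = df["start"] - 1
    return df
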