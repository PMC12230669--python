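"""Hierarchical protein assembly container and PDB-format I/O.

A :class:`Structure` is an ordered list of chains; each chain an ordered
list of residues identified by author numbering ``(res_seq, ins_code)``;
each residue an ordered mapping of heavy-atom names to :class:`Atom`
records.  No renumbering is ever applied: assembly models keep the target
numbering of the modelling exercise they come from, and every local score
in this package is keyed by ``(chain_id, res_seq, ins_code)``.

Reading goes through gemmi; only heavy atoms of standard amino-acid
residues from the first model are retained, with alternate locations
other than blank/'A' dropped.  Writing is fixed-column PDB (occupancy
1.00) so that annotated B-factors and coordinates round-trip bytewise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import EmptyStructureError, PDBParseError, RangeError

#: Sentinel for residues that a local score could not evaluate.
UNSCORED = None

# residues recognised as protein; everything else is treated as HETATM
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

ResidueKey = tuple  # (chain_id, res_seq, ins_code)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    bfactor: float = 0.0

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    res_seq: int
    ins_code: str
    res_name: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue(self, res_seq: int, ins_code: str = " ") -> Residue | None:
        for r in self.residues:
            if r.res_seq == res_seq and r.ins_code == ins_code:
                return r
        return None


@dataclass
class Structure:
    label: str
    chains: list[Chain] = field(default_factory=list)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def residue(self, key: ResidueKey) -> Residue | None:
        chain_id, res_seq, ins_code = key
        try:
            return self.chain(chain_id).residue(res_seq, ins_code)
        except KeyError:
            return None

    def residue_keys(self) -> list[ResidueKey]:
        return [
            (c.chain_id, r.res_seq, r.ins_code)
            for c in self.chains
            for r in c.residues
        ]

    def iter_atoms(self):
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms.values():
                    yield c.chain_id, r, a

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def copy(self, label: str | None = None) -> "Structure":
        chains = [
            Chain(
                c.chain_id,
                [
                    Residue(r.res_seq, r.ins_code, r.res_name, dict(r.atoms))
                    for r in c.residues
                ],
            )
            for c in self.chains
        ]
        return Structure(label if label is not None else self.label, chains)


class LocalScoreTrack:
    """Per-residue scores in [0,1] keyed by (chain_id, res_seq, ins_code).

    Residues a metric could not evaluate carry the UNSCORED marker (None);
    they serialize as "X" in QMODE2 records and 0.00 in B-factor columns.
    """

    def __init__(self, entries: dict[ResidueKey, float | None] | None = None):
        self.entries: dict[ResidueKey, float | None] = {}
        if entries:
            for k, v in entries.items():
                self[k] = v

    def __setitem__(self, key: ResidueKey, value: float | None):
        if value is not None:
            if not (0.0 <= value <= 1.0) or not math.isfinite(value):
                raise RangeError(f"local score {value!r} for {key} outside [0,1]")
        self.entries[tuple(key)] = value

    def __getitem__(self, key: ResidueKey) -> float | None:
        return self.entries[tuple(key)]

    def get(self, key: ResidueKey, default=None):
        return self.entries.get(tuple(key), default)

    def __contains__(self, key) -> bool:
        return tuple(key) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def items(self):
        return self.entries.items()

    def scored_items(self):
        return [(k, v) for k, v in self.entries.items() if v is not None]

    def mean(self) -> float | None:
        vals = [v for v in self.entries.values() if v is not None]
        return float(np.mean(vals)) if vals else None


@dataclass
class QARecord:
    """Parsed CASP QA submission (QMODE1 global-only or QMODE2 with locals)."""

    target: str
    mode: int
    models: list[dict] = field(default_factory=list)
    # each model dict: name, global_score, values (list of float|None) for mode 2


# ---------------------------------------------------------------------------
# PDB reading


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if stripped[:2] in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _precheck_atom_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(
                    f"line {lineno}: ATOM record too short ({len(line)} columns)"
                )
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: unparseable coordinate field "
                        f"{line[lo:hi]!r}"
                    ) from None


def read_pdb(text: str, label: str = "model") -> Structure:
    """Parse PDB-format text into a Structure.

    Keeps heavy atoms of standard amino acids from the first MODEL only;
    HETATM records, hydrogens/deuteriums and alternate locations other
    than blank/'A' are dropped.  CASP TS headers (PFRMAT/TARGET/...) are
    tolerated and skipped.
    """
    _precheck_atom_lines(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise EmptyStructureError("no ATOM records found")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            if gres.name not in STANDARD_RESIDUES:
                continue
            ins = gres.seqid.icode if gres.seqid.icode.strip() else " "
            residue = Residue(gres.seqid.num, ins, gres.name)
            for gatom in gres:
                if gatom.element.is_hydrogen:
                    continue
                if gatom.altloc not in ("\x00", "", "A"):
                    continue
                if gatom.name in residue.atoms:
                    continue
                element = gatom.element.name.upper().strip()
                if not element:
                    element = _guess_element(gatom.name)
                pos = gatom.pos
                residue.atoms[gatom.name] = Atom(
                    gatom.name, element, pos.x, pos.y, pos.z, gatom.b_iso
                )
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            chains.append(chain)
    if not chains:
        raise EmptyStructureError("no standard protein atoms found")
    return Structure(label, chains)


def read_pdb_file(path, label: str | None = None) -> Structure:
    from pathlib import Path

    p = Path(path)
    return read_pdb(p.read_text(), label=label if label is not None else p.stem)


# ---------------------------------------------------------------------------
# PDB writing


def _format_atom_name(name: str, element: str) -> str:
    # names of 1-3 chars for 1-letter elements are right-shifted one column
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"[:4]


def write_pdb(
    s: Structure,
    track: LocalScoreTrack | None = None,
    scale: float = 100.0,
) -> str:
    """Serialize a Structure to fixed-column PDB text.

    When a local score track is given, the B-factor column of every atom
    is replaced by ``score * scale`` (the plDDT*100 convention by
    default); UNSCORED residues get 0.00.  Without a track the original
    B-factors are written verbatim.
    """
    if track is not None:
        keys = set(s.residue_keys())
        for key, _ in track.items():
            if key not in keys:
                raise KeyError(f"track residue {key} absent from structure")
    lines: list[str] = []
    serial = 0
    for chain in s.chains:
        for res in chain.residues:
            key = (chain.chain_id, res.res_seq, res.ins_code)
            for atom in res.atoms.values():
                serial += 1
                if track is not None:
                    score = track.get(key)
                    bfac = 0.0 if score is None else score * scale
                else:
                    bfac = atom.bfactor
                lines.append(
                    "ATOM  %5d %s %3s %1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f"
                    "          %2s"
                    % (
                        serial % 100000,
                        _format_atom_name(atom.name, atom.element),
                        res.res_name,
                        chain.chain_id[:1],
                        res.res_seq,
                        res.ins_code,
                        atom.x,
                        atom.y,
                        atom.z,
                        1.00,
                        bfac,
                        atom.element[:2].rjust(2),
                    )
                )
        serial += 1
        last = chain.residues[-1]
        lines.append(
            "TER   %5d      %3s %1s%4d%1s"
            % (serial % 100000, last.res_name, chain.chain_id[:1], last.res_seq,
               last.ins_code)
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# CASP QA exchange format (QMODE1 / QMODE2)


def write_qmode(
    target: str,
    results,
    residue_index: list[ResidueKey] | None = None,
    mode: int = 2,
) -> str:
    """Write CASP QA records.

    ``results`` is a sequence of objects with ``label``, ``global_score``
    and (for mode 2) ``local_track`` attributes, or plain dicts with the
    same keys.  Mode 2 emits one value per residue of ``residue_index``,
    wrapped 20 per line, "X" for UNSCORED residues.
    """
    if mode not in (1, 2):
        raise RangeError(f"QMODE must be 1 or 2, got {mode}")
    if mode == 2 and residue_index is None:
        raise ValueError("mode 2 requires a residue index")
    lines = ["PFRMAT QA", f"TARGET {target}", "MODEL 1", f"QMODE {mode}"]
    for res in results:
        if isinstance(res, dict):
            name = res["label"]
            gscore = res["global_score"]
            track = res.get("local_track")
        else:
            name = res.label
            gscore = res.global_score
            track = getattr(res, "local_track", None)
        if gscore is not None and not 0.0 <= gscore <= 1.0:
            raise RangeError(f"global score {gscore} outside [0,1]")
        head = f"{name} {gscore:.3f}" if gscore is not None else f"{name} X"
        if mode == 1:
            lines.append(head)
            continue
        values = []
        for key in residue_index:
            v = track.get(key) if track is not None else None
            values.append("X" if v is None else f"{v:.2f}")
        for i in range(0, len(values), 20):
            chunk = " ".join(values[i : i + 20])
            lines.append(f"{head} {chunk}" if i == 0 else chunk)
        if not values:
            lines.append(head)
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_qmode2(target, results, residue_index) -> str:
    return write_qmode(target, results, residue_index, mode=2)


def _parse_value(tok: str, context: str) -> float | None:
    from .errors import FormatError

    if tok == "X":
        return None
    try:
        v = float(tok)
    except ValueError:
        raise FormatError(f"{context}: unparseable value {tok!r}") from None
    if not 0.0 <= v <= 1.0:
        raise RangeError(f"{context}: value {v} outside [0,1]")
    return v


def read_qmode(text: str) -> QARecord:
    """Parse a CASP QA submission (inverse of :func:`write_qmode`)."""
    from .errors import FormatError

    target = ""
    mode = None
    body: list[str] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line == "END":
            continue
        if line.startswith("PFRMAT") or line.startswith("MODEL"):
            continue
        if line.startswith("TARGET"):
            target = line.split(maxsplit=1)[1] if " " in line else ""
            continue
        if line.startswith("QMODE"):
            mode = int(line.split()[1])
            continue
        body.append(line)
    if mode is None:
        raise FormatError("missing QMODE line")

    def _is_value(tok: str) -> bool:
        if tok == "X":
            return True
        try:
            float(tok)
            return True
        except ValueError:
            return False

    record = QARecord(target=target, mode=mode)
    current: dict | None = None
    for line in body:
        toks = line.split()
        if not _is_value(toks[0]):  # new model record
            current = {"name": toks[0], "global_score": None, "values": []}
            record.models.append(current)
            gtok = toks[1] if len(toks) > 1 else "X"
            current["global_score"] = _parse_value(gtok, current["name"])
            rest = toks[2:]
        else:
            if current is None:
                raise FormatError("continuation line before any model record")
            rest = toks
        for tok in rest:
            current["values"].append(_parse_value(tok, current["name"]))
    return record


read_qmode2 = read_qmode
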