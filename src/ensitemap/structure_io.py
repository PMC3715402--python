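"""PDB structure and ensemble I/O with van der Waals radii and atom selections.

Structures are plain records of atoms; an :class:`Ensemble` is an ordered list
of same-topology structures (e.g. MD snapshots or NMR models read from a
multi-MODEL PDB file).  Atom selections use a small boolean expression
language over chain, residue number, residue name and atom name, sufficient
to express the fit/cluster selections used throughout the pipeline
(e.g. ``"name CA and resseq 171-427"``).

The reader applies a fixed altloc policy (keep the highest-occupancy
conformer, ties broken by altloc 'A', then blank) so that downstream grid and
RMSD calculations always see a single-conformer geometry.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Ensemble",
    "SelectionExpr",
    "PDBParseError",
    "TopologyError",
    "SelectionError",
    "EmptySelectionError",
    "read_pdb",
    "write_pdb",
    "assign_vdw_radii",
    "select_atoms",
    "parse_selection",
    "load_radius_table",
    "default_radius_table",
]

# Residue key = (chain, resseq, icode); atom key adds (name, altloc).
ResidueKey = tuple[str, int, str]


class PDBParseError(ValueError):
    """Raised for a malformed ATOM/HETATM record; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class TopologyError(ValueError):
    """Raised when MODELs of one file (or members of one ensemble) disagree in topology."""


class SelectionError(ValueError):
    """Raised for a selection expression that does not parse; carries the position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class EmptySelectionError(ValueError):
    """Raised when a caller requires a non-empty selection and got none."""


@dataclass
class AtomRecord:
    """One atom of a structure, PDB-style fields plus an assigned vdW radius."""

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float
    element: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    het: bool = False
    vdw_radius: float | None = None

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.resseq, self.icode)

    @property
    def atom_key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.resseq, self.icode, self.name)

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure:
    """An ordered list of atoms belonging to one model."""

    atoms: list[AtomRecord]
    model_id: int = 1
    label: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) float array."""
        out = np.empty((len(self.atoms), 3), dtype=float)
        for i, a in enumerate(self.atoms):
            out[i, 0] = a.x
            out[i, 1] = a.y
            out[i, 2] = a.z
        return out

    def with_coords(self, xyz: np.ndarray, label: str | None = None) -> "Structure":
        """Copy of this structure with coordinates replaced (topology unchanged)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {xyz.shape} != ({len(self.atoms)}, 3)")
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return Structure(atoms=atoms, model_id=self.model_id,
                         label=self.label if label is None else label)

    def topology_keys(self) -> tuple[tuple[str, int, str, str], ...]:
        return tuple(a.atom_key for a in self.atoms)

    def residues(self) -> Iterator[tuple[ResidueKey, str, list[int]]]:
        """Yield (residue key, resname, atom indices) in order of first appearance."""
        seen: dict[ResidueKey, tuple[str, list[int]]] = {}
        order: list[ResidueKey] = []
        for i, a in enumerate(self.atoms):
            k = a.residue_key
            if k not in seen:
                seen[k] = (a.resname, [])
                order.append(k)
            seen[k][1].append(i)
        for k in order:
            resname, idx = seen[k]
            yield k, resname, idx

    def vdw_radii(self) -> np.ndarray:
        radii = np.empty(len(self.atoms), dtype=float)
        for i, a in enumerate(self.atoms):
            if a.vdw_radius is None:
                raise ValueError(
                    "atom has no vdW radius assigned; call assign_vdw_radii first"
                )
            radii[i] = a.vdw_radius
        return radii


def _topology_hash(keys: Sequence[tuple[str, int, str, str]]) -> str:
    h = hashlib.sha1()
    for k in keys:
        h.update(repr(k).encode())
    return h.hexdigest()


@dataclass
class Ensemble:
    """An ordered list of same-topology structures.

    ``metadata`` carries optional per-member annotations (e.g. centroid rank
    and cluster population after conformational clustering).
    """

    members: list[Structure]
    metadata: list[dict] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        ref = self.members[0].topology_keys()
        for m in self.members[1:]:
            if m.n_atoms != self.members[0].n_atoms:
                raise TopologyError(
                    f"member '{m.label or m.model_id}' has {m.n_atoms} atoms, "
                    f"expected {self.members[0].n_atoms}"
                )
            if m.topology_keys() != ref:
                raise TopologyError(
                    f"member '{m.label or m.model_id}' atom identities differ from member 1"
                )
        if self.metadata is not None and len(self.metadata) != len(self.members):
            raise ValueError("metadata length must match member count")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.members)

    def __getitem__(self, i: int) -> Structure:
        return self.members[i]

    @property
    def topology_hash(self) -> str:
        return _topology_hash(self.members[0].topology_keys())


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "SE", "MG", "ZN", "FE", "NA", "MN", "CU", "NI", "CO", "CA",
    "SI", "LI",
}


def _infer_element(name: str, resname: str) -> str:
    """Guess the element from the atom name (PDB columns 13-16 convention)."""
    stripped = name.strip()
    if not stripped:
        return ""
    # Names like "1HB1" start with a digit -> hydrogen numbering
    alpha = "".join(c for c in stripped if c.isalpha())
    if not alpha:
        return ""
    two = alpha[:2].upper()
    # A name occupying column 13 (4 chars, or explicit 2-letter ion resname)
    # can denote a two-letter element; protein atom names never do.
    if two in _TWO_LETTER_ELEMENTS and (resname.strip().upper() == two or len(name) == 4 and not name[0].isdigit() and not name.startswith(" ")):
        return two
    first = alpha[0].upper()
    if stripped[0].isdigit():
        return "H"
    return first


def _parse_float(text: str, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(lineno, f"unreadable {what} field {text!r}") from None


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(lineno, "ATOM/HETATM record shorter than coordinate fields")
    record = line[0:6].strip()
    try:
        serial = int(line[6:11])
    except ValueError:
        raise PDBParseError(lineno, f"unreadable serial field {line[6:11]!r}") from None
    name = line[12:16]
    altloc = line[16].strip()
    resname = line[17:20].strip()
    chain = line[21].strip()
    try:
        resseq = int(line[22:26])
    except ValueError:
        raise PDBParseError(lineno, f"unreadable residue number {line[22:26]!r}") from None
    icode = line[26].strip()
    x = _parse_float(line[30:38], lineno, "x coordinate")
    y = _parse_float(line[38:46], lineno, "y coordinate")
    z = _parse_float(line[46:54], lineno, "z coordinate")
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
        raise PDBParseError(lineno, "non-finite coordinate")
    occ_field = line[54:60].strip() if len(line) > 54 else ""
    bf_field = line[60:66].strip() if len(line) > 60 else ""
    occupancy = _parse_float(occ_field, lineno, "occupancy") if occ_field else 1.0
    bfactor = _parse_float(bf_field, lineno, "B-factor") if bf_field else 0.0
    element = line[76:78].strip().upper() if len(line) >= 77 else ""
    if not element:
        element = _infer_element(name, resname)
    return AtomRecord(
        serial=serial,
        name=name.strip(),
        altloc=altloc,
        resname=resname,
        chain=chain,
        resseq=resseq,
        icode=icode,
        x=x,
        y=y,
        z=z,
        element=element,
        occupancy=occupancy,
        bfactor=bfactor,
        het=(record == "HETATM"),
    )


def _altloc_rank(altloc: str) -> tuple[int, str]:
    # preference after occupancy: 'A', then blank, then alphabetical
    if altloc == "A":
        return (0, "")
    if altloc == "":
        return (1, "")
    return (2, altloc)


def _apply_altloc_policy(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom key: highest occupancy, tie -> 'A' then blank."""
    best: dict[tuple[str, int, str, str], tuple[int, AtomRecord]] = {}
    order: list[tuple[str, int, str, str]] = []
    for pos, a in enumerate(atoms):
        k = a.atom_key
        if k not in best:
            best[k] = (pos, a)
            order.append(k)
        else:
            _, cur = best[k]
            if (a.occupancy, ) > (cur.occupancy, ) or (
                a.occupancy == cur.occupancy
                and _altloc_rank(a.altloc) < _altloc_rank(cur.altloc)
            ):
                best[k] = (best[k][0], a)  # keep original position
    return [best[k][1] for k in order]


def read_pdb(source: str | Path, label: str | None = None) -> Ensemble:
    """Read a (possibly multi-MODEL) PDB file into an Ensemble.

    One Structure per MODEL, order preserved; a file without MODEL records
    yields a single-member ensemble.  HETATM records are retained and
    flagged via :attr:`AtomRecord.het`.  Raises :class:`PDBParseError` with
    the offending line number for malformed records and
    :class:`TopologyError` when MODELs disagree in atom count or identity.
    """
    path = Path(source)
    text = path.read_text()
    base = label if label is not None else path.stem
    models: list[Structure] = []
    current: list[AtomRecord] = []
    current_id: int | None = None
    saw_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            if current:
                models.append(Structure(_apply_altloc_policy(current),
                                        model_id=current_id or len(models) + 1))
                current = []
            try:
                current_id = int(line[6:].split()[0])
            except (IndexError, ValueError):
                current_id = len(models) + 1
        elif rec == "ENDMDL":
            models.append(Structure(_apply_altloc_policy(current),
                                    model_id=current_id or len(models) + 1))
            current = []
            current_id = None
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
        # TER / REMARK / anything else: ignored
    if current:
        models.append(Structure(_apply_altloc_policy(current),
                                model_id=current_id or len(models) + 1))
    if not models:
        if saw_model:
            raise PDBParseError(1, "file contains MODEL records but no atoms")
        raise PDBParseError(1, "no ATOM/HETATM records found")
    for i, m in enumerate(models):
        m.label = f"{base}" if len(models) == 1 else f"{base}:model{m.model_id}"
    return Ensemble(members=models)


def _format_atom_name(name: str, element: str) -> str:
    """PDB column-13 alignment: one-letter elements start in column 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2 or (name and name[0].isdigit()):
        return f"{name:<4}"
    return f" {name:<3}"


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    record = "HETATM" if a.het else "ATOM  "
    name = _format_atom_name(a.name, a.element)
    altloc = a.altloc if a.altloc else " "
    icode = a.icode if a.icode else " "
    chain = a.chain if a.chain else " "
    return (
        f"{record}{serial % 100000:>5} {name}{altloc}{a.resname:>3} {chain}"
        f"{a.resseq:>4}{icode}   {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2}"
    )


def write_pdb(target: str | Path, data: Ensemble | Structure) -> None:
    """Write a Structure or Ensemble as a standard (multi-MODEL) PDB file."""
    if isinstance(data, Structure):
        members = [data]
    else:
        members = list(data.members)
    lines: list[str] = []
    multi = len(members) > 1
    for m in members:
        if multi:
            lines.append(f"MODEL     {m.model_id:>4}")
        for i, a in enumerate(m.atoms, start=1):
            lines.append(_format_atom_line(a, i))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(target).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# van der Waals radii
# ---------------------------------------------------------------------------

def load_radius_table(path: str | Path) -> dict[str, float]:
    """Load an element -> radius (Å) table from two-column plain text."""
    table: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"radius table line not 'ELEMENT radius': {raw!r}")
        table[parts[0].upper()] = float(parts[1])
    return table


def default_radius_table() -> dict[str, float]:
    """The Bondi van der Waals radius set shipped with the package."""
    ref = resources.files("ensitemap.data").joinpath("bondi_radii.txt")
    with resources.as_file(ref) as p:
        return load_radius_table(p)


def assign_vdw_radii(
    s: Structure,
    table: dict[str, float] | None = None,
    default_radius: float = 1.50,
) -> Structure:
    """Return a copy of ``s`` with every atom's vdW radius filled from ``table``.

    Unknown elements fall back to ``default_radius`` with a warning; this is
    the contract (no error), so grid calculations never stall on exotic atoms.
    """
    if table is None:
        table = default_radius_table()
    table = {k.upper(): v for k, v in table.items()}
    atoms: list[AtomRecord] = []
    unknown: set[str] = set()
    for a in s.atoms:
        element = a.element or _infer_element(a.name, a.resname)
        r = table.get(element.upper())
        if r is None:
            unknown.add(element or "?")
            r = default_radius
        atoms.append(replace(a, element=element, vdw_radius=r))
    if unknown:
        warnings.warn(
            f"no vdW radius for element(s) {sorted(unknown)}; "
            f"using default {default_radius:.2f} Å",
            stacklevel=2,
        )
    return Structure(atoms=atoms, model_id=s.model_id, label=s.label)


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------
#
# expr    := term ("or" term)*
# term    := factor ("and" factor)*
# factor  := "not" factor | "(" expr ")" | primary
# primary := "all" | "hetatm" | "chain" LIST | "name" LIST
#          | "resname" LIST | "resseq" RANGELIST
#
# LIST items are whitespace/comma separated; RANGELIST items are integers or
# inclusive ranges "a-b".  Purely syntactic: no distance terms.

_KEYWORDS = {"and", "or", "not", "chain", "name", "resname", "resseq",
             "all", "hetatm", "(", ")"}


@dataclass(frozen=True)
class _Token:
    text: str
    pos: int


def _tokenize(expr: str) -> list[_Token]:
    tokens: list[_Token] = []
    i = 0
    n = len(expr)
    while i < n:
        c = expr[i]
        if c.isspace() or c == ",":
            i += 1
            continue
        if c in "()":
            tokens.append(_Token(c, i))
            i += 1
            continue
        j = i
        while j < n and not expr[j].isspace() and expr[j] not in "(),":
            j += 1
        tokens.append(_Token(expr[i:j], i))
        i = j
    return tokens


class _Node:
    def mask(self, s: Structure) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class _Bool(_Node):
    op: str
    operands: list[_Node]

    def mask(self, s: Structure) -> np.ndarray:
        masks = [o.mask(s) for o in self.operands]
        if self.op == "and":
            return np.logical_and.reduce(masks)
        if self.op == "or":
            return np.logical_or.reduce(masks)
        return ~masks[0]


@dataclass
class _Field(_Node):
    field: str
    values: frozenset
    ranges: tuple[tuple[int, int], ...] = ()

    def mask(self, s: Structure) -> np.ndarray:
        out = np.zeros(s.n_atoms, dtype=bool)
        for i, a in enumerate(s.atoms):
            if self.field == "chain":
                out[i] = a.chain in self.values
            elif self.field == "name":
                out[i] = a.name in self.values
            elif self.field == "resname":
                out[i] = a.resname in self.values
            elif self.field == "resseq":
                out[i] = any(lo <= a.resseq <= hi for lo, hi in self.ranges)
        return out


@dataclass
class _All(_Node):
    def mask(self, s: Structure) -> np.ndarray:
        return np.ones(s.n_atoms, dtype=bool)


@dataclass
class _Het(_Node):
    def mask(self, s: Structure) -> np.ndarray:
        return np.array([a.het for a in s.atoms], dtype=bool)


class _Parser:
    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", len(self.expr))
        self.i += 1
        return tok

    def parse(self) -> _Node:
        if not self.tokens:
            raise SelectionError("empty selection expression", 0)
        node = self.expr_()
        if self.peek() is not None:
            tok = self.peek()
            raise SelectionError(f"unexpected token {tok.text!r}", tok.pos)
        return node

    def expr_(self) -> _Node:
        operands = [self.term()]
        while (tok := self.peek()) is not None and tok.text == "or":
            self.next()
            operands.append(self.term())
        return operands[0] if len(operands) == 1 else _Bool("or", operands)

    def term(self) -> _Node:
        operands = [self.factor()]
        while (tok := self.peek()) is not None and tok.text == "and":
            self.next()
            operands.append(self.factor())
        return operands[0] if len(operands) == 1 else _Bool("and", operands)

    def factor(self) -> _Node:
        tok = self.next()
        if tok.text == "not":
            return _Bool("not", [self.factor()])
        if tok.text == "(":
            node = self.expr_()
            closing = self.next()
            if closing.text != ")":
                raise SelectionError("expected ')'", closing.pos)
            return node
        if tok.text == "all":
            return _All()
        if tok.text == "hetatm":
            return _Het()
        if tok.text in ("chain", "name", "resname"):
            values = self._value_list(tok)
            return _Field(tok.text, frozenset(values))
        if tok.text == "resseq":
            ranges = self._range_list(tok)
            return _Field("resseq", frozenset(), tuple(ranges))
        raise SelectionError(f"unknown keyword {tok.text!r}", tok.pos)

    def _value_list(self, kw: _Token) -> list[str]:
        values: list[str] = []
        while (tok := self.peek()) is not None and tok.text not in _KEYWORDS:
            values.append(self.next().text)
        if not values:
            raise SelectionError(f"'{kw.text}' needs at least one value", kw.pos)
        return values

    def _range_list(self, kw: _Token) -> list[tuple[int, int]]:
        ranges: list[tuple[int, int]] = []
        while (tok := self.peek()) is not None and tok.text not in _KEYWORDS:
            tok = self.next()
            text = tok.text
            try:
                if "-" in text[1:]:  # allow negative single numbers
                    split_at = text.index("-", 1)
                    lo, hi = int(text[:split_at]), int(text[split_at + 1:])
                else:
                    lo = hi = int(text)
            except ValueError:
                raise SelectionError(f"bad residue range {text!r}", tok.pos) from None
            if lo > hi:
                raise SelectionError(f"descending residue range {text!r}", tok.pos)
            ranges.append((lo, hi))
        if not ranges:
            raise SelectionError(f"'{kw.text}' needs at least one range", kw.pos)
        return ranges


@dataclass(frozen=True)
class SelectionExpr:
    """A parsed atom-selection expression; deterministic on a given Structure."""

    text: str
    _root: _Node = field(compare=False, repr=False, hash=False, default=None)

    def indices(self, s: Structure) -> np.ndarray:
        """Strictly increasing atom indices matched on ``s``."""
        return np.nonzero(self._root.mask(s))[0]

    def __str__(self) -> str:
        return self.text


def parse_selection(expr: str | SelectionExpr) -> SelectionExpr:
    if isinstance(expr, SelectionExpr):
        return expr
    return SelectionExpr(text=expr, _root=_Parser(expr).parse())


def select_atoms(
    s: Structure,
    sel: str | SelectionExpr,
    min_atoms: int = 0,
) -> np.ndarray:
    """Evaluate a selection on a structure, returning increasing atom indices.

    ``min_atoms`` lets callers that need a minimum (e.g. ≥3 atoms for rigid
    fitting) fail with an explicit :class:`EmptySelectionError`.
    """
    expr = parse_selection(sel)
    idx = expr.indices(s)
    if len(idx) < min_atoms:
        raise EmptySelectionError(
            f"selection {expr.text!r} matched {len(idx)} atoms on "
            f"'{s.label or s.model_id}', need at least {min_atoms}"
        )
    return idx
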