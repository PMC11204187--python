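"""Discrete character matrices: parsing, validation, writing, bundled data.

A :class:`CharacterMatrix` is a taxa x characters grid of small integer
states (digits 0-9) with ``?`` as the single missing-data token — the coding
convention of desk-scale morphological cladistics.  Three interchange
dialects are supported: a minimal NEXUS DATA block, a TNT ``xread`` block,
and plain CSV with a header row of character ids.

The subfamily-revision study whose analysis this package reproduces printed
its entire 13-taxon x 24-character wing-venation matrix in the publication;
that matrix ships as a bundled fixture (:func:`bundled_matrix`) together with
taxon metadata (geological age codes, ingroup/outgroup/excluded roles).
"""

from __future__ import annotations

import csv
import hashlib
import io
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "TaxonMeta",
    "MatrixParseError",
    "parse_matrix",
    "write_matrix",
    "bundled_matrix",
    "bundled_taxon_meta",
    "validate",
]

#: Sentinel stored in the cell grid for a '?' entry.
MISSING: int = -1

_STATE_CHARS = "0123456789"


class MatrixParseError(ValueError):
    """Malformed matrix text; carries a line/column location when known."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        where = ""
        if line is not None:
            where = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + where)
        self.line = line
        self.column = column


def _normalize_label(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip())


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of unordered discrete states.

    ``cells[i, j]`` is the state of taxon ``i`` for character ``j`` (0-based
    here; character ids in reports are 1-based), or :data:`MISSING`.
    ``char_defs``, when present, carries one free-text description per
    character (state labels included verbatim).
    """

    taxa: list[str]
    cells: np.ndarray
    char_defs: list[str] | None = None
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.taxa = [_normalize_label(t) for t in self.taxa]
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-d grid")
        if len(self.taxa) != self.cells.shape[0]:
            raise ValueError(
                f"{len(self.taxa)} taxa but {self.cells.shape[0]} matrix rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels after whitespace normalization")
        if any(not t for t in self.taxa):
            raise ValueError("empty taxon label")
        bad = (self.cells < MISSING) | (self.cells > 9)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"state out of range for taxon {self.taxa[i]!r}, character {j + 1}"
            )
        if self.char_defs is not None and len(self.char_defs) != self.n_chars:
            raise ValueError("char_defs length does not match character count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return int(self.cells.shape[1])

    def row(self, taxon: str) -> np.ndarray:
        return self.cells[self.taxa.index(_normalize_label(taxon))]

    def column(self, char_index: int) -> np.ndarray:
        """1-based character column."""
        if not 1 <= char_index <= self.n_chars:
            raise IndexError(f"character index {char_index} out of range")
        return self.cells[:, char_index - 1]

    def column_states(self, char_index: int) -> set[int]:
        col = self.column(char_index)
        return set(int(s) for s in col[col != MISSING])

    @property
    def n_missing(self) -> int:
        return int((self.cells == MISSING).sum())

    def resolve(self, name: str) -> str:
        """Map a taxon name or registered alias to the matrix label."""
        name = _normalize_label(name)
        if name in self.taxa:
            return name
        if name in self.aliases and self.aliases[name] in self.taxa:
            return self.aliases[name]
        raise KeyError(f"unknown taxon {name!r}")

    def subset_columns(self, indices_1based: list[int]) -> "CharacterMatrix":
        cols = [i - 1 for i in indices_1based]
        defs = [self.char_defs[i] for i in cols] if self.char_defs else None
        return CharacterMatrix(list(self.taxa), self.cells[:, cols], defs, dict(self.aliases))

    def checksum(self) -> str:
        """SHA-256 over labels and cells; stable across calls and platforms."""
        digest = hashlib.sha256()
        for t in self.taxa:
            digest.update(t.encode())
            digest.update(b"\x00")
        digest.update(self.cells.tobytes())
        return digest.hexdigest()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and np.array_equal(self.cells, other.cells)
        )


@dataclass(frozen=True)
class TaxonMeta:
    """Geological age and analysis role of one taxon."""

    taxon: str
    age_code: str | None  # J1 (Early Jurassic) .. K1 (Early Cretaceous)
    role: str  # ingroup | outgroup | excluded
    alias: str | None = None

    _AGES = ("J1", "J2", "J3", "K1")
    _ROLES = ("ingroup", "outgroup", "excluded")

    def __post_init__(self):
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        if self.age_code is not None and self.age_code not in self._AGES:
            raise ValueError(f"age_code must be one of {self._AGES}, got {self.age_code!r}")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_matrix(text: str, dialect: str) -> CharacterMatrix:
    """Parse matrix ``text`` in the named dialect (``nexus``/``tnt``/``csv``).

    ``?`` is the only missing symbol; states are single digits.  Errors name
    the offending line (and taxon/character where applicable).
    """
    if dialect == "nexus":
        return _parse_nexus(text)
    if dialect == "tnt":
        return _parse_tnt(text)
    if dialect == "csv":
        return _parse_csv(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_row_symbols(symbols: str, taxon: str, line_no: int) -> list[int]:
    states: list[int] = []
    for col, ch in enumerate(symbols):
        if ch == "?":
            states.append(MISSING)
        elif ch in _STATE_CHARS:
            states.append(int(ch))
        else:
            raise MatrixParseError(
                f"unknown state symbol {ch!r} for taxon {taxon!r}, character {col + 1}",
                line=line_no,
            )
    return states


def _tokenize_label(token: str) -> str:
    if token.startswith("'") and token.endswith("'") and len(token) >= 2:
        return _normalize_label(token[1:-1].replace("''", "'"))
    return _normalize_label(token.replace("_", " "))


_ROW_RE = re.compile(r"^\s*('(?:[^']|'')*'|\S+)\s+([0-9?\s]+?)\s*$")


def _parse_matrix_rows(
    lines: list[tuple[int, str]], n_taxa: int | None, n_chars: int | None
) -> tuple[list[str], np.ndarray]:
    taxa: list[str] = []
    rows: list[list[int]] = []
    for line_no, line in lines:
        m = _ROW_RE.match(line)
        if m is None:
            raise MatrixParseError("cannot parse matrix row", line=line_no, column=1)
        label = _tokenize_label(m.group(1))
        symbols = re.sub(r"\s+", "", m.group(2))
        taxa.append(label)
        rows.append(_parse_row_symbols(symbols, label, line_no))
    if not rows:
        raise MatrixParseError("matrix block contains no rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MatrixParseError(
            f"ragged matrix: row lengths {sorted(widths)} differ across taxa"
        )
    width = widths.pop()
    if n_chars is not None and width != n_chars:
        raise MatrixParseError(f"declared NCHAR={n_chars} but rows have {width} cells")
    if n_taxa is not None and len(rows) != n_taxa:
        raise MatrixParseError(f"declared NTAX={n_taxa} but found {len(rows)} rows")
    return taxa, np.array(rows, dtype=np.int8)


def _parse_nexus(text: str) -> CharacterMatrix:
    lines = text.splitlines()
    if not lines or not lines[0].strip().upper().startswith("#NEXUS"):
        raise MatrixParseError("missing #NEXUS header", line=1, column=1)
    n_taxa = n_chars = None
    in_matrix = False
    matrix_lines: list[tuple[int, str]] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        upper = line.upper()
        if upper.startswith("DIMENSIONS"):
            m_nt = re.search(r"NTAX\s*=\s*(\d+)", upper)
            m_nc = re.search(r"NCHAR\s*=\s*(\d+)", upper)
            n_taxa = int(m_nt.group(1)) if m_nt else None
            n_chars = int(m_nc.group(1)) if m_nc else None
        elif upper.startswith("MATRIX"):
            in_matrix = True
        elif in_matrix:
            if line == ";" or upper.startswith("END"):
                in_matrix = False
            elif line:
                matrix_lines.append((i, line.rstrip(";")))
    if not matrix_lines:
        raise MatrixParseError("no MATRIX block found")
    taxa, cells = _parse_matrix_rows(matrix_lines, n_taxa, n_chars)
    return CharacterMatrix(taxa, cells)


def _parse_tnt(text: str) -> CharacterMatrix:
    lines = text.splitlines()
    header_idx = None
    for i, raw in enumerate(lines):
        if raw.strip().lower().startswith("xread"):
            header_idx = i
            break
    if header_idx is None:
        raise MatrixParseError("missing xread header", line=1, column=1)
    # xread is followed by: optional quoted title, then "nchar ntax"
    rest = lines[header_idx + 1 :]
    dims = None
    body_start = None
    for j, raw in enumerate(rest):
        line = raw.strip()
        if not line or line.startswith("'"):
            continue
        m = re.match(r"^(\d+)\s+(\d+)\s*$", line)
        if m is None:
            raise MatrixParseError(
                "expected 'nchar ntax' after xread", line=header_idx + 2 + j, column=1
            )
        dims = (int(m.group(1)), int(m.group(2)))
        body_start = j + 1
        break
    if dims is None:
        raise MatrixParseError("missing dimensions after xread")
    n_chars, n_taxa = dims
    matrix_lines: list[tuple[int, str]] = []
    for j, raw in enumerate(rest[body_start:]):
        line = raw.strip()
        if not line:
            continue
        if line == ";" or line.startswith("proc"):
            break
        matrix_lines.append((header_idx + body_start + 2 + j, line.rstrip(";")))
    taxa, cells = _parse_matrix_rows(matrix_lines, n_taxa, n_chars)
    return CharacterMatrix(taxa, cells)


def _parse_csv(text: str) -> CharacterMatrix:
    reader = csv.reader(io.StringIO(text))
    rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    if not rows:
        raise MatrixParseError("empty CSV")
    header = rows[0]
    has_header = not _looks_like_data_row(header)
    data_rows = rows[1:] if has_header else rows
    if not data_rows:
        raise MatrixParseError("CSV has a header but no data rows")
    taxa: list[str] = []
    cells: list[list[int]] = []
    for offset, row in enumerate(data_rows):
        line_no = offset + (2 if has_header else 1)
        label = _normalize_label(row[0])
        states: list[int] = []
        for col, cell in enumerate(row[1:], start=1):
            cell = cell.strip()
            if cell == "?":
                states.append(MISSING)
            elif cell.isdigit() and len(cell) == 1:
                states.append(int(cell))
            else:
                raise MatrixParseError(
                    f"unknown state symbol {cell!r} for taxon {label!r}, character {col}",
                    line=line_no,
                )
        taxa.append(label)
        cells.append(states)
    widths = {len(r) for r in cells}
    if len(widths) != 1:
        raise MatrixParseError(
            f"ragged CSV: row lengths {sorted(widths)} differ across taxa"
        )
    return CharacterMatrix(taxa, np.array(cells, dtype=np.int8))


def _looks_like_data_row(row: list[str]) -> bool:
    body = [cell.strip() for cell in row[1:]]
    return bool(body) and all(cell == "?" or (cell.isdigit() and len(cell) == 1) for cell in body)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_matrix(matrix: CharacterMatrix, dialect: str) -> str:
    """Serialize; output is guaranteed to re-parse to an identical matrix."""
    if dialect == "nexus":
        return _write_nexus(matrix)
    if dialect == "tnt":
        return _write_tnt(matrix)
    if dialect == "csv":
        return _write_csv(matrix)
    raise ValueError(f"unknown dialect {dialect!r}")


def _row_string(row: np.ndarray) -> str:
    return "".join("?" if s == MISSING else str(int(s)) for s in row)


def _block_label(label: str) -> str:
    """NEXUS/TNT token: quote when underscores cannot round-trip the label."""
    underscored = label.replace(" ", "_")
    if re.fullmatch(r"[A-Za-z0-9_.\-]+", underscored) and "_" not in label:
        return underscored
    return "'" + label.replace("'", "''") + "'"


def _write_nexus(matrix: CharacterMatrix) -> str:
    states = sorted({int(s) for s in matrix.cells.ravel() if s != MISSING} | {0})
    symbols = "".join(str(s) for s in states)
    labels = [_block_label(t) for t in matrix.taxa]
    pad = max(len(lab) for lab in labels) + 2
    out = io.StringIO()
    out.write("#NEXUS\n")
    out.write("BEGIN DATA;\n")
    out.write(f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};\n")
    out.write(f'    FORMAT SYMBOLS="{symbols}" MISSING=?;\n')
    out.write("    MATRIX\n")
    for lab, row in zip(labels, matrix.cells):
        out.write(f"    {lab.ljust(pad)}{_row_string(row)}\n")
    out.write("    ;\nEND;\n")
    return out.getvalue()


def _write_tnt(matrix: CharacterMatrix) -> str:
    labels = [_block_label(t) for t in matrix.taxa]
    pad = max(len(lab) for lab in labels) + 2
    out = io.StringIO()
    out.write("xread\n")
    out.write(f"{matrix.n_chars} {matrix.n_taxa}\n")
    for lab, row in zip(labels, matrix.cells):
        out.write(f"{lab.ljust(pad)}{_row_string(row)}\n")
    out.write(";\n")
    return out.getvalue()


def _write_csv(matrix: CharacterMatrix) -> str:
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(["taxon"] + [f"c{j + 1}" for j in range(matrix.n_chars)])
    for taxon, row in zip(matrix.taxa, matrix.cells):
        writer.writerow([taxon] + ["?" if s == MISSING else str(int(s)) for s in row])
    return out.getvalue()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(matrix: CharacterMatrix) -> list[str]:
    """Structural findings (warnings, not errors): constant characters,
    all-missing characters, duplicate rows."""
    findings: list[str] = []
    for j in range(1, matrix.n_chars + 1):
        states = matrix.column_states(j)
        if not states:
            findings.append(f"character {j} uninformative: all missing")
        elif len(states) == 1:
            findings.append(f"character {j} constant (state {states.pop()})")
    seen: dict[bytes, str] = {}
    for taxon, row in zip(matrix.taxa, matrix.cells):
        key = row.tobytes()
        if key in seen:
            findings.append(f"identical rows: {seen[key]!r} and {taxon!r}")
        else:
            seen[key] = taxon
    return findings


# ---------------------------------------------------------------------------
# bundled study data
# ---------------------------------------------------------------------------

_GIGANTUS_PRINTED = "Vitmoilus gigantus sp. n."  # spelling as printed
_GIGANTUS_CORRECTED = "Vitimoilus gigantus sp. n."


def _data_text(name: str) -> str:
    return (resources.files("fitchclad.data") / name).read_text()


def bundled_matrix() -> CharacterMatrix:
    """The study's 13-taxon x 24-character wing-venation matrix, transcribed
    cell for cell from the printed table (including the printed spelling of
    the new giant *Vitimoilus* species, aliased to the corrected one).
    Character definitions ride along as free text; the garbled printed
    state listing of character 9 is kept verbatim, the matrix being
    authoritative."""
    matrix = parse_matrix(_data_text("table3.nex"), "nexus")
    matrix.aliases[_GIGANTUS_CORRECTED] = _GIGANTUS_PRINTED
    defs = {}
    for line in _data_text("table2_chars.tsv").splitlines():
        num, _, text = line.partition("\t")
        if num.strip().isdigit():
            defs[int(num)] = text.strip()
    matrix.char_defs = [defs[j] for j in range(1, matrix.n_chars + 1)]
    return matrix


#: checksum of the transcription; bit-stability guard for the fixture
BUNDLED_MATRIX_SHA256 = (
    "f6497d5c2bfb3e013da302ad2bb3dadbbdf39d80147ee7b80853c4e5b8dd03ed"
)


def bundled_taxon_meta() -> list[TaxonMeta]:
    """Geological ages and analysis roles: 11 ingroup taxa, 2 outgroups, and
    the 2 poorly preserved species excluded from the analysis."""
    out: list[TaxonMeta] = []
    for rec in csv.DictReader(io.StringIO(_data_text("table1_taxa.csv"))):
        out.append(
            TaxonMeta(
                taxon=_normalize_label(rec["taxon"]),
                age_code=rec["age_code"] or None,
                role=rec["role"],
                alias=_normalize_label(rec["alias"]) if rec.get("alias") else None,
            )
        )
    return out
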