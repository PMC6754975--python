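"""Character-matrix data model and I/O.

Discrete morphological matrices are small grids of state codes (0-4) over
taxa, with two classes of non-state cells: *missing* (``?``, the character
was not or could not be observed) and *inapplicable* (``-``, the character
does not exist in that taxon, e.g. palp articulation in a palp-less worm).
Both are treated as equivocal by the scoring machinery — a cell compatible
with every observed state of its character — but the distinction is kept at
the I/O layer so the source data survive a round trip.

The bundled study matrix covers 38 polychaete taxa (microphthalmids plus
three outgroup species) scored for 48 unordered subject/predicate
characters.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "CharacterDef",
    "CharacterMatrix",
    "ValidationReport",
    "MatrixParseError",
    "FixtureIntegrityError",
    "parse_nexus",
    "parse_tsv",
    "write_nexus",
    "write_tsv",
    "load_study_matrix",
    "validate_matrix",
]

#: Cell sentinel for unobserved data ("?").
MISSING: int = -1
#: Cell sentinel for inapplicable data ("-").
INAPPLICABLE: int = -2

# Every unicode dash a transcription might plausibly contain.
_DASHES = {"-", "‐", "‑", "‒", "–", "—", "―", "−"}

_MAX_STATES = 5


class MatrixParseError(ValueError):
    """Raised when a matrix document cannot be parsed."""


class FixtureIntegrityError(RuntimeError):
    """Raised when the bundled study matrix fails its own validation."""


def _token_to_code(tok: str) -> int:
    if tok == "?":
        return MISSING
    if tok in _DASHES:
        return INAPPLICABLE
    if len(tok) == 1 and tok.isdigit() and int(tok) < _MAX_STATES:
        return int(tok)
    raise MatrixParseError(f"unrecognized cell symbol {tok!r}")


def _code_to_token(code: int) -> str:
    if code == MISSING:
        return "?"
    if code == INAPPLICABLE:
        return "-"
    return str(code)


@dataclass(frozen=True)
class CharacterDef:
    """Definition of one unordered character: a subject and its predicates.

    ``states[i]`` is the label of state code ``i``.  All characters here are
    unordered and weight 1; the fields exist so the data model states the
    assumption explicitly.
    """

    index: int  # 1-based character number
    subject: str
    states: tuple[str, ...]
    ordered: bool = False
    weight: float = 1.0
    group: str = ""

    @property
    def n_states(self) -> int:
        return len(self.states)


def _default_chardefs(n_chars: int, n_states: int = _MAX_STATES) -> list[CharacterDef]:
    labels = tuple(str(s) for s in range(n_states))
    return [CharacterDef(j + 1, f"char{j + 1}", labels) for j in range(n_chars)]


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of state codes with equivocal-cell sentinels.

    ``cells`` is an ``int8`` array of shape ``(n_taxa, n_chars)`` holding
    state codes ``0..4`` or the sentinels :data:`MISSING` /
    :data:`INAPPLICABLE`.
    """

    taxa: list[str]
    chardefs: list[CharacterDef]
    cells: np.ndarray
    outgroup: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.taxa), len(self.chardefs)):
            raise ValueError(
                f"cells shape {self.cells.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.chardefs)} characters"
            )
        self._row = {t: i for i, t in enumerate(self.taxa)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.chardefs)

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.cells[self._row[taxon]]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} not in matrix") from None

    def cell_token(self, taxon: str, char_index: int) -> str:
        """Symbol of a cell addressed by taxon label and 1-based character."""
        return _code_to_token(int(self.row(taxon)[char_index - 1]))

    def observed_states(self, char_index: int) -> list[int]:
        """Distinct non-equivocal state codes of a character (1-based)."""
        col = self.cells[:, char_index - 1]
        return sorted(int(s) for s in np.unique(col[col >= 0]))

    def subset(self, taxa: list[str]) -> "CharacterMatrix":
        """Row-subset preserving character definitions and outgroup flags."""
        idx = [self._row[t] for t in taxa]
        return CharacterMatrix(
            list(taxa),
            self.chardefs,
            self.cells[idx].copy(),
            [t for t in self.outgroup if t in taxa],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[_code_to_token(int(c)) for c in row] for row in self.cells],
            index=self.taxa,
            columns=[d.index for d in self.chardefs],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and set(self.outgroup) == set(other.outgroup)
            and np.array_equal(self.cells, other.cells)
        )


@dataclass
class ValidationReport:
    """List of (locator, message) invariant violations; empty means valid."""

    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "matrix valid"
        return "\n".join(f"{loc}: {msg}" for loc, msg in self.violations)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_matrix(matrix: CharacterMatrix) -> ValidationReport:
    """Check every data-model invariant and report all violations found."""
    rep = ValidationReport()
    seen: set[str] = set()
    for t in matrix.taxa:
        if t in seen:
            rep.violations.append((f"taxon {t!r}", "duplicate taxon label"))
        seen.add(t)
    indices = [d.index for d in matrix.chardefs]
    if len(set(indices)) != len(indices):
        rep.violations.append(("characters", "duplicate character indices"))
    for d in matrix.chardefs:
        if not 2 <= d.n_states <= _MAX_STATES:
            rep.violations.append(
                (f"character {d.index}", f"{d.n_states} states outside 2..{_MAX_STATES}")
            )
        if d.weight <= 0:
            rep.violations.append((f"character {d.index}", "non-positive weight"))
    for i, taxon in enumerate(matrix.taxa):
        for j, d in enumerate(matrix.chardefs):
            c = int(matrix.cells[i, j])
            if c >= 0 and c >= d.n_states:
                rep.violations.append(
                    (
                        f"taxon {taxon!r}, character {d.index}",
                        f"state {c} out of range for {d.n_states}-state character",
                    )
                )
            elif c < INAPPLICABLE:
                rep.violations.append(
                    (f"taxon {taxon!r}, character {d.index}", f"invalid cell code {c}")
                )
    for t in matrix.outgroup:
        if t not in matrix._row:
            rep.violations.append((f"outgroup {t!r}", "not a matrix taxon"))
    return rep


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def parse_tsv(text: str) -> CharacterMatrix:
    """Parse a tab-separated matrix: first column taxon, one symbol per cell.

    A header row prefixed with ``#`` is ignored.  Any unicode dash maps to
    the inapplicable token, ``?`` to missing.
    """
    taxa: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise MatrixParseError(f"row {lineno}: no cells after taxon label")
        taxon = parts[0].strip()
        try:
            codes = [_token_to_code(p.strip()) for p in parts[1:]]
        except MatrixParseError as e:
            raise MatrixParseError(f"row {lineno} ({taxon!r}): {e}") from None
        if rows and len(codes) != len(rows[0]):
            raise MatrixParseError(
                f"row {lineno} ({taxon!r}): {len(codes)} cells, expected {len(rows[0])}"
            )
        taxa.append(taxon)
        rows.append(codes)
    if not taxa:
        raise MatrixParseError("no taxa")
    cells = np.array(rows, dtype=np.int8)
    return CharacterMatrix(taxa, _default_chardefs(cells.shape[1]), cells)


def write_tsv(matrix: CharacterMatrix, header: bool = True) -> str:
    out = StringIO()
    if header:
        out.write("# taxon\t" + "\t".join(str(d.index) for d in matrix.chardefs) + "\n")
    for i, taxon in enumerate(matrix.taxa):
        toks = [_code_to_token(int(c)) for c in matrix.cells[i]]
        out.write(taxon + "\t" + "\t".join(toks) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

def parse_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS DATA/CHARACTERS block of standard (morphology) data.

    The FORMAT line's MISSING symbol maps to :data:`MISSING` and the GAP
    symbol to :data:`INAPPLICABLE`.
    """
    # normalize exotic dashes so a transcribed document with en-dash cells
    # parses the same as the ASCII original
    for d in _DASHES - {"-"}:
        text = text.replace(d, "-")
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as e:  # dendropy raises several error types
        raise MatrixParseError(f"malformed NEXUS document: {e}") from None
    taxa: list[str] = []
    rows: list[list[int]] = []
    for tax in dmat.taxon_namespace:
        seq = dmat[tax]
        taxa.append(tax.label)
        rows.append([_token_to_code(str(s)) for s in seq.symbols_as_list()])
    if not taxa:
        raise MatrixParseError("no taxa in NEXUS matrix")
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise MatrixParseError(f"duplicate taxon labels: {dupes}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MatrixParseError(f"ragged NEXUS matrix, row widths {sorted(widths)}")
    cells = np.array(rows, dtype=np.int8)
    return CharacterMatrix(taxa, _default_chardefs(cells.shape[1]), cells)


def _nexus_label(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label) and " " not in label:
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(matrix: CharacterMatrix) -> str:
    """Serialize to a NEXUS DATA block; inverse of :func:`parse_nexus`."""
    out = StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};\n")
    out.write('  FORMAT SYMBOLS="01234" MISSING=? GAP=-;\n')
    out.write("  MATRIX\n")
    width = max(len(_nexus_label(t)) for t in matrix.taxa) + 2
    for i, taxon in enumerate(matrix.taxa):
        row = "".join(_code_to_token(int(c)) for c in matrix.cells[i])
        out.write(f"    {_nexus_label(taxon):<{width}}{row}\n")
    out.write("  ;\nEND;\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Bundled study fixture
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("morphpars.data").joinpath(name).read_text(encoding="utf-8")


def load_study_matrix() -> CharacterMatrix:
    """Load the bundled microphthalmid matrix: 38 taxa x 48 characters.

    Character definitions and the three-taxon outgroup flag are attached
    from the fixture metadata; the result is validated and an
    :class:`FixtureIntegrityError` raised if anything is off.
    """
    meta = json.loads(_data_text("microphthalmid_fixture.json"))
    matrix = parse_tsv(_data_text("microphthalmid_matrix.tsv"))

    chardefs: list[CharacterDef] = []
    for line in _data_text("microphthalmid_characters.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        idx, group, subject, states = line.split("\t")
        chardefs.append(
            CharacterDef(
                int(idx),
                subject,
                tuple(s.strip() for s in states.split("|")),
                group=group,
            )
        )
    matrix = CharacterMatrix(matrix.taxa, chardefs, matrix.cells, list(meta["outgroup"]))

    if matrix.n_taxa != meta["n_taxa"] or matrix.n_chars != meta["n_chars"]:
        raise FixtureIntegrityError(
            f"fixture is {matrix.n_taxa}x{matrix.n_chars}, "
            f"expected {meta['n_taxa']}x{meta['n_chars']}"
        )
    if len(matrix.outgroup) != 3:
        raise FixtureIntegrityError("fixture must flag exactly 3 outgroup taxa")
    report = validate_matrix(matrix)
    if not report.ok:
        raise FixtureIntegrityError(f"fixture fails validation:\n{report}")
    return matrix
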