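"""PROSITE-subset motif patterns and scanning of numbered protein sequences.

Calcineurin (CN) recognises its substrates through short linear motifs
(SLiMs) docked outside the active site: the LxVP motif binds a hydrophobic
cleft at the CNA/CNB interface, the PxIxIT motif binds the CNA catalytic
domain, and an [S/T]xxP motif places the phosphoacceptor proline into a
pocket adjacent to the active site.  This module parses the restricted
PROSITE dialect used for those definitions (literal residues, residue sets
in brackets, ``x`` wildcards) and scans protein fragments that carry their
own residue numbering (e.g. an NHE1 tail fragment starting at residue 681).

Coordinates are 1-based and inclusive throughout, expressed in the
protein's own numbering via :attr:`ProteinRecord.start_number`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_VALID_SEQ = set(AA20) | {"X"}

#: sentinel for a match-anything pattern position
WILDCARD = None

Element = Union[frozenset, None]


class PatternParseError(ValueError):
    """Malformed pattern text; ``column`` is the 1-based offending column."""

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


@dataclass(frozen=True)
class ProteinRecord:
    """A protein (fragment) with explicit residue numbering.

    ``start_number`` is the residue number of the first character, so the
    residue number of 1-based string position ``i`` is ``start_number + i - 1``.
    """

    id: str
    sequence: str
    start_number: int = 1

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        bad = set(self.sequence) - _VALID_SEQ
        if bad:
            raise ValueError(
                f"sequence of {self.id!r} contains non-canonical letters {sorted(bad)}"
            )
        if self.start_number < 1:
            raise ValueError("start_number must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.sequence) - 1

    def residue_number(self, i: int) -> int:
        """Residue number of 1-based string position ``i``."""
        return self.start_number + i - 1

    def slice_by_number(self, start: int, end: int) -> str:
        """Sequence slice for residue numbers ``start..end`` inclusive."""
        return self.sequence[start - self.start_number : end - self.start_number + 1]


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of position classes with a designated anchor.

    Each element is either a ``frozenset`` of allowed residues (a literal is
    a singleton set) or :data:`WILDCARD`.  ``anchor_index`` is the 1-based
    index of the biologically reported residue within a match — e.g. the L
    of LxVP (index 3 in the six-position CN definition) or the S/T of
    [S/T]xxP (index 1).
    """

    name: str
    elements: tuple
    anchor_index: int

    def __post_init__(self):
        if not self.elements:
            raise ValueError("pattern must have at least one element")
        if not 1 <= self.anchor_index <= len(self.elements):
            raise ValueError(
                f"anchor_index {self.anchor_index} outside pattern of "
                f"length {len(self.elements)}"
            )

    def __len__(self) -> int:
        return len(self.elements)

    def render(self) -> str:
        """Pattern text; ``parse_pattern(render(...))`` gives an equal pattern."""
        parts = []
        for el in self.elements:
            if el is WILDCARD:
                parts.append("x")
            elif len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("[" + "".join(sorted(el)) + "]")
        return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """A pattern match on a numbered sequence (residue numbers, inclusive)."""

    protein_id: str
    motif_name: str
    start: int
    end: int
    anchor: int
    matched: str

    def __post_init__(self):
        if not self.start <= self.anchor <= self.end:
            raise ValueError("anchor must lie within the hit span")
        if self.end - self.start + 1 != len(self.matched):
            raise ValueError("matched text length disagrees with span")

    @property
    def anchor_letter(self) -> str:
        return self.matched[self.anchor - self.start]


def parse_pattern(text: str, name: str, anchor_index: int) -> MotifPattern:
    """Parse a PROSITE-subset pattern string.

    Supported syntax: literal residues, ``[...]`` residue sets ('/' inside a
    set is ignored, so ``[S/T]`` == ``[ST]``), ``x``/``X`` wildcards, and
    optional ``-`` separators.  Case-insensitive.  Raises
    :class:`PatternParseError` naming the offending column on unbalanced
    brackets, empty sets, or illegal characters.
    """
    if not text:
        raise PatternParseError("empty pattern", 1)
    elements = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        col = i + 1
        if ch == "-":
            i += 1
            continue
        if ch in "xX":
            elements.append(WILDCARD)
            i += 1
            continue
        if ch == "[":
            members = set()
            j = i + 1
            while j < n and text[j] != "]":
                c = text[j].upper()
                if c == "/":
                    j += 1
                    continue
                if c not in AA20:
                    raise PatternParseError(f"illegal residue {text[j]!r} in set", j + 1)
                members.add(c)
                j += 1
            if j >= n:
                raise PatternParseError("unbalanced '[': set never closed", n)
            if not members:
                raise PatternParseError("empty residue set", col)
            elements.append(frozenset(members))
            i = j + 1
            continue
        if ch == "]":
            raise PatternParseError("unbalanced ']'", col)
        c = ch.upper()
        if c in AA20:
            elements.append(frozenset({c}))
            i += 1
            continue
        raise PatternParseError(f"illegal character {ch!r}", col)
    return MotifPattern(name=name, elements=tuple(elements), anchor_index=anchor_index)


def _window_matches(window: str, pattern: MotifPattern) -> bool:
    # 'X' (unknown residue) in the sequence matches only wildcard positions.
    for ch, el in zip(window, pattern.elements):
        if el is WILDCARD:
            continue
        if ch not in el:
            return False
    return True


def scan_sequence(record: ProteinRecord, pattern: MotifPattern) -> list:
    """All (overlapping) matches of ``pattern`` in ``record``, ordered by start.

    Every window of pattern length is tested; degenerate inputs (pattern
    longer than the sequence, empty sequence) yield an empty list.
    """
    m = len(pattern)
    seq = record.sequence
    hits = []
    for i0 in range(len(seq) - m + 1):
        window = seq[i0 : i0 + m]
        if _window_matches(window, pattern):
            start = record.start_number + i0
            hits.append(
                MotifHit(
                    protein_id=record.id,
                    motif_name=pattern.name,
                    start=start,
                    end=start + m - 1,
                    anchor=start + pattern.anchor_index - 1,
                    matched=window,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Built-in motif registry
# ---------------------------------------------------------------------------

#: CN LxVP search definition; anchor = the literal L.
LXVP_CN = parse_pattern("[NQDESRTH]-[YTDFILV]Lx[VPL]X", "LxVP_CN", anchor_index=3)

#: [S/T]xxP substrate motif; anchor = the phosphoacceptor S/T.
STXXP = parse_pattern("[S/T]xxP", "STxxP", anchor_index=1)

#: Convenience default for PxIxIT; no canonical regex exists for this motif
#: and known instances deviate from it, so callers may override it.
PXIXIT = parse_pattern("PxIxIT", "PxIxIT", anchor_index=1)

BUILTIN_PATTERNS = {p.name: p for p in (LXVP_CN, STXXP, PXIXIT)}


# ---------------------------------------------------------------------------
# FASTA I/O — numbering is carried in the header as "id|start=NNN"
# ---------------------------------------------------------------------------

_START_RE = re.compile(r"^(?P<id>.+?)\|start=(?P<start>\d+)$")


def read_fasta(source: Union[str, TextIO]) -> list:
    """Read numbered protein records from FASTA.

    Header grammar: ``>id|start=NNN`` sets the residue number of the first
    character; a plain ``>id`` header defaults to start 1.
    """
    records = []
    for rec in SeqIO.parse(source, "fasta"):
        m = _START_RE.match(rec.id)
        if m:
            records.append(
                ProteinRecord(m.group("id"), str(rec.seq).upper(), int(m.group("start")))
            )
        else:
            records.append(ProteinRecord(rec.id, str(rec.seq).upper(), 1))
    return records


def write_fasta(records: Iterable[ProteinRecord], dest: Union[str, TextIO]) -> None:
    """Write records with ``id|start=NNN`` headers."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}|start={r.start_number}", description="")
        for r in records
    ]
    SeqIO.write(seqrecs, dest, "fasta")
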