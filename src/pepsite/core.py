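"""Coordinate system for proteolytic peptides.

A protein of ``L`` residues carries ``L + 1`` peptide-bond positions indexed
``0..L``.  Bond ``j`` (``1 <= j <= L-1``) is the physical bond between
residues ``j`` and ``j + 1``; bonds ``0`` and ``L`` are virtual bonds
flanking the chain.  A peptide occupying residues ``[s, e]`` (1-based,
inclusive) exposes its N-terminus at bond ``s - 1`` and its C-terminus at
bond ``e``; the bonds it contains internally are ``{s, ..., e - 1}``.

Positions on a protein are labelled ``"ACC[p]_N"`` / ``"ACC[p]_C"`` /
``"ACC[p]_B"`` where ``p`` is the 1-based residue index of the exposed
terminus and the suffix records whether proteolytic products expose their
N-terminus, C-terminus, or both at that residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

Orientation = Literal["N", "C", "B"]

_LABEL_RE = re.compile(r"^(?P<acc>.+)\[(?P<pos>\d+)\]_(?P<orient>[NCB])$")


@dataclass(frozen=True)
class ProteinRecord:
    """A precursor protein: the coordinate frame for all bond positions."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("protein accession must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residue characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_bonds(self) -> int:
        """Number of physical peptide bonds, L - 1."""
        return len(self.sequence) - 1


class ProteinDatabase:
    """An accession-keyed collection of :class:`ProteinRecord`."""

    def __init__(self, records: Iterable[ProteinRecord]):
        self._records: dict[str, ProteinRecord] = {}
        dupes = []
        for rec in records:
            if rec.accession in self._records:
                dupes.append(rec.accession)
            self._records[rec.accession] = rec
        if dupes:
            raise ValueError(f"duplicate accessions in database: {sorted(set(dupes))}")
        if not self._records:
            raise ValueError("protein database is empty")

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._records[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def accessions(self) -> list[str]:
        return list(self._records)


@dataclass(frozen=True)
class PeptideMapping:
    """Placement of one peptide on one protein, 1-based inclusive."""

    peptide: str
    protein: str
    start: int
    end: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end}]")
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError(
                f"span [{self.start}, {self.end}] does not match peptide length "
                f"{len(self.peptide)}"
            )

    @property
    def n_term_bond(self) -> int:
        """Bond exposed at the peptide's N-terminus (``start - 1``)."""
        return self.start - 1

    @property
    def c_term_bond(self) -> int:
        """Bond exposed at the peptide's C-terminus (``end``)."""
        return self.end

    @property
    def internal_bonds(self) -> range:
        """Bond indices contained within the peptide, ``{s, ..., e-1}``."""
        return range(self.start, self.end)


@dataclass(frozen=True)
class PositionLabel:
    """A labelled aa position such as ``IGF2[126]_C``."""

    protein: str
    position: int
    orientation: Orientation

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("aa position is 1-based")
        if self.orientation not in ("N", "C", "B"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def render(self) -> str:
        return f"{self.protein}[{self.position}]_{self.orientation}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "PositionLabel":
        m = _LABEL_RE.match(text)
        if m is None:
            raise ValueError(f"not a position label: {text!r}")
        return cls(m.group("acc"), int(m.group("pos")), m.group("orient"))

    @property
    def terminal_bond(self) -> int:
        """Bond index of the exposed terminus (p-1 for _N, p for _C).

        For a _B label both termini meet between bonds p-1 and p; the
        C-side convention (bond p... ) is not meaningful there, so _B
        returns the boundary bond p used by the step computation.
        """
        if self.orientation == "N":
            return self.position - 1
        return self.position


@dataclass
class LocateResult:
    """Outcome of mapping a peptide list against a protein database."""

    mappings: list[PeptideMapping] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)
    n_ambiguous_dropped: int = 0


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 0-based match offsets of needle in haystack (overlapping)."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_peptides(
    peptides: Sequence[str],
    db: ProteinDatabase,
    ambiguous_policy: Literal["drop", "keep"] = "drop",
    equate_il: bool = False,
) -> LocateResult:
    """Map peptide sequences onto proteins by exact substring search.

    Every exact occurrence in every protein is found.  Peptides matching
    more than one locus (across or within proteins) are flagged ambiguous
    and, under the default ``"drop"`` policy, excluded (with a count) so
    they cannot inflate aa-scores by double counting; ``"keep"`` retains
    all loci flagged.  ``equate_il=True`` treats I and L as equivalent
    (off by default: search engines report them distinctly).
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ValueError(f"unknown ambiguity policy {ambiguous_policy!r}")
    result = LocateResult()
    xlate = str.maketrans("I", "L") if equate_il else None
    seqs = {
        rec.accession: (rec.sequence.translate(xlate) if xlate else rec.sequence)
        for rec in db
    }
    for pep in peptides:
        if not pep:
            raise ValueError("empty peptide sequence")
        pep_u = pep.upper()
        bad = set(pep_u) - AMINO_ACIDS
        if bad:
            result.rejected.append((pep, f"invalid residues {sorted(bad)}"))
            continue
        query = pep_u.translate(xlate) if xlate else pep_u
        loci: list[PeptideMapping] = []
        for acc, seq in seqs.items():
            for off in _find_all(seq, query):
                loci.append(
                    PeptideMapping(pep_u, acc, off + 1, off + len(pep_u))
                )
        if not loci:
            result.unmapped.append(pep)
        elif len(loci) == 1:
            result.mappings.append(loci[0])
        else:
            flagged = [
                PeptideMapping(m.peptide, m.protein, m.start, m.end, ambiguous=True)
                for m in loci
            ]
            if ambiguous_policy == "keep":
                result.mappings.extend(flagged)
            else:
                result.n_ambiguous_dropped += 1
    return result


def label_position(mappings: Sequence[PeptideMapping]) -> PositionLabel:
    """Label the aa position shared by a set of peptide termini.

    All mappings must be on one protein and share a terminal residue:
    peptides ending at residue ``p`` contribute orientation C, peptides
    starting at ``p`` contribute orientation N; if both occur the site is
    labelled B.
    """
    if not mappings:
        raise ValueError("no mappings supplied")
    proteins = {m.protein for m in mappings}
    if len(proteins) != 1:
        raise ValueError(f"mappings span several proteins: {sorted(proteins)}")
    protein = proteins.pop()
    starts = {m.start for m in mappings}
    ends = {m.end for m in mappings}
    shared = (starts | ends)
    candidates = [
        p for p in shared
        if all(m.start == p or m.end == p for m in mappings)
    ]
    if not candidates:
        raise ValueError("mappings do not share a terminal residue")
    p = min(candidates)
    has_n = any(m.start == p for m in mappings)
    has_c = any(m.end == p for m in mappings)
    orientation: Orientation = "B" if (has_n and has_c) else ("N" if has_n else "C")
    return PositionLabel(protein, p, orientation)


def verify_mapping(mapping: PeptideMapping, db: ProteinDatabase) -> bool:
    """Check that the mapped span spells the peptide sequence."""
    rec = db[mapping.protein]
    return rec.sequence[mapping.start - 1 : mapping.end] == mapping.peptide
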