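"""Peptide libraries, cleavage sites, and P4–P4′ windows.

Multiplex substrate profiling digests a defined pool of synthetic peptides
(14-mers in the canonical design) and reads out which backbone bonds the
protease hydrolysed.  This module holds the in-memory representation of such
a library, enumerates its internal peptide bonds, and extracts the
octapeptide (P4–P4′) window around any bond — the unit on which all
downstream specificity statistics operate.

Conventions
-----------
* The library alphabet is the 19 canonical residues minus methionine, plus
  lowercase ``'n'`` for norleucine (the isosteric Met replacement used in
  synthesis to avoid oxidation artifacts).  Methionine in an input file is a
  hard error pointing at the substitution policy.
* Bond indexing is 1-based: bond ``b`` lies between residue ``b`` and residue
  ``b+1``, so a peptide of length ``L`` has bonds ``1 .. L-1``.
* Windows use Schechter–Berger positions P4..P1 (non-prime, N-terminal of the
  cut) and P1′..P4′ (prime side); offsets beyond the peptide termini are
  padded with ``'-'`` and excluded from every frequency count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: 19 canonical residues (no Met) — uppercase, lexicographic.
RESIDUES = "ACDEFGHIKLNPQRSTVWY"
#: Norleucine, written lowercase to distinguish it from Asn ('N').
NORLEUCINE = "n"
#: Full library alphabet (20 symbols).
ALPHABET = RESIDUES + NORLEUCINE
#: Window pad character for positions beyond the peptide termini.
PAD = "-"
#: Ordered subsite labels of an octapeptide window.
POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")
#: Non-prime subsites used for tetrapeptide scoring (N→C order, P1 last).
NONPRIME_POSITIONS = ("P4", "P3", "P2", "P1")

_ALPHABET_SET = frozenset(ALPHABET)


class LibraryError(ValueError):
    """Malformed peptide library input."""


@dataclass(frozen=True)
class PeptideLibraryEntry:
    """One library peptide: an identifier and its sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class CleavageSite:
    """A peptide bond, identified by parent peptide and 1-based bond index.

    Bond ``b`` joins residue ``b`` and residue ``b+1`` of the parent.
    """

    peptide_id: str
    bond_index: int


@dataclass(frozen=True)
class OctapeptideWindow:
    """The 8 residues spanning a cleavage bond: P4 P3 P2 P1 | P1' P2' P3' P4'.

    Positions falling outside the parent peptide are ``'-'``.
    """

    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != 8:
            raise ValueError(f"window must have 8 characters, got {self.residues!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.residues


def _normalise_sequence(raw: str, record_id: str) -> str:
    """Uppercase a sequence except norleucine; validate the alphabet."""
    out = []
    for offset, ch in enumerate(raw, start=1):
        ch = ch if ch == NORLEUCINE else ch.upper()
        if ch in ("M",):
            raise LibraryError(
                f"record {record_id!r} offset {offset}: methionine is not in the "
                "library alphabet; synthetic libraries substitute norleucine "
                "('n') for Met"
            )
        if ch not in _ALPHABET_SET:
            raise LibraryError(
                f"record {record_id!r} offset {offset}: character {ch!r} is "
                f"outside the library alphabet {ALPHABET!r}"
            )
        out.append(ch)
    return "".join(out)


class PeptideLibrary:
    """An ordered collection of uniquely identified peptides.

    Parameters
    ----------
    entries:
        Iterable of :class:`PeptideLibraryEntry`.  Input order is preserved;
        duplicate ids raise :class:`LibraryError`.
    """

    def __init__(self, entries: Iterable[PeptideLibraryEntry]):
        self._entries: list[PeptideLibraryEntry] = []
        self._by_id: dict[str, PeptideLibraryEntry] = {}
        for entry in entries:
            if entry.length < 2:
                raise LibraryError(
                    f"peptide {entry.id!r} has length {entry.length}; need ≥ 2"
                )
            if entry.id in self._by_id:
                raise LibraryError(f"duplicate peptide id {entry.id!r}")
            self._entries.append(entry)
            self._by_id[entry.id] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[PeptideLibraryEntry]:
        return iter(self._entries)

    def __contains__(self, peptide_id: str) -> bool:
        return peptide_id in self._by_id

    def __getitem__(self, peptide_id: str) -> PeptideLibraryEntry:
        try:
            return self._by_id[peptide_id]
        except KeyError:
            raise KeyError(f"unknown peptide id {peptide_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self._entries]

    def n_sites(self) -> int:
        """Total number of internal backbone bonds, Σ (length − 1)."""
        return sum(e.length - 1 for e in self._entries)


def read_library(path: str | Path) -> PeptideLibrary:
    """Read a peptide library from FASTA.

    Sequences are uppercased except for norleucine ``'n'``.  Duplicate ids,
    methionine, or any character outside the library alphabet raise
    :class:`LibraryError` naming the offending record and offset.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise LibraryError(f"no FASTA records found in {path}")
    entries = [
        PeptideLibraryEntry(id=rec.id, sequence=_normalise_sequence(str(rec.seq), rec.id))
        for rec in records
    ]
    return PeptideLibrary(entries)


def write_library(library: PeptideLibrary, path: str | Path) -> None:
    """Write a library to single-line FASTA (stable, byte-reproducible)."""
    records = [
        SeqRecord(Seq(e.sequence), id=e.id, description="") for e in library
    ]
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.seq}\n")


def enumerate_sites(library: PeptideLibrary) -> list[CleavageSite]:
    """Every internal backbone bond of every peptide, in library order.

    The count equals ``Σ_p (length_p − 1)`` — e.g. 2964 for 228 14-mers —
    and is the denominator for "percent of library sites cleaved".
    """
    return [
        CleavageSite(e.id, b)
        for e in library
        for b in range(1, e.length)
    ]


def window(site: CleavageSite, library: PeptideLibrary) -> OctapeptideWindow:
    """The P4–P4′ octapeptide around ``site``, '-'-padded at the termini.

    For bond ``b`` the window covers parent residues ``b-3 .. b+4``
    (1-based); offsets outside ``[1, length]`` become :data:`PAD`.
    """
    entry = library[site.peptide_id]
    if not 1 <= site.bond_index <= entry.length - 1:
        raise ValueError(
            f"bond {site.bond_index} out of range for peptide "
            f"{site.peptide_id!r} of length {entry.length}"
        )
    chars = []
    for offset in range(site.bond_index - 3, site.bond_index + 5):
        if 1 <= offset <= entry.length:
            chars.append(entry.sequence[offset - 1])
        else:
            chars.append(PAD)
    return OctapeptideWindow("".join(chars))


def all_windows(library: PeptideLibrary) -> list[OctapeptideWindow]:
    """Windows of every site in the library — the iceLogo background set."""
    return [window(s, library) for s in enumerate_sites(library)]


def enumerate_tetrapeptide_space(
    alphabet_size: int = 20, alphabet: str = ALPHABET
) -> Iterator[str]:
    """Yield every P4-P3-P2-P1 tetrapeptide over the first ``alphabet_size``
    letters of ``alphabet``, each exactly once (``alphabet_size ** 4`` total).

    This is the positional-scanning combinatorial substrate space: with the
    full 20-letter alphabet it enumerates 160,000 sequences.
    """
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be ≥ 1")
    if alphabet_size > len(alphabet):
        raise ValueError(
            f"alphabet_size {alphabet_size} exceeds alphabet of {len(alphabet)}"
        )
    letters = alphabet[:alphabet_size]
    for combo in itertools.product(letters, repeat=4):
        yield "".join(combo)


def write_site_table(
    library: PeptideLibrary, path: str | Path, sites: Sequence[CleavageSite] | None = None
) -> None:
    """TSV of (peptide_id, bond_index, window) for ``sites`` (default: all)."""
    if sites is None:
        sites = enumerate_sites(library)
    with open(path, "w") as fh:
        fh.write("peptide_id\tbond_index\twindow\n")
        for s in sites:
            fh.write(f"{s.peptide_id}\t{s.bond_index}\t{window(s, library).residues}\n")
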