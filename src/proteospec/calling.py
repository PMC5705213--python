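"""Cleavage-site calling from identified-fragment reports.

The mass-spectrometry search engine reports which library-derived fragment
sequences were observed in each sample.  This module maps fragments back to
the peptide bonds that must have been hydrolysed to produce them, and then
applies the reporting rules of the multiplex profiling assay:

* a site is called for an enzyme at a timepoint only if it is inferred in
  **every** biological replicate of that enzyme at that timepoint
  (replicate intersection), and
* sites seen in **any** no-enzyme-control (NEC) sample — any replicate, any
  timepoint — are blacklisted (conservative NEC subtraction).

"Accumulative" call sets are prefix unions over the sorted timepoint
schedule, so the set at 480 min contains everything called at or before
480 min; accumulative sets are nested over time by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .library import CleavageSite, NORLEUCINE, PeptideLibrary

#: Default incubation schedule (minutes) of the multiplex digestion assay.
DEFAULT_TIMEPOINTS = (60.0, 120.0, 240.0, 480.0)


class FragmentError(ValueError):
    """A fragment that cannot be mapped onto its parent peptide."""


class AmbiguousFragmentError(FragmentError):
    """A fragment occurring at multiple parent offsets with conflicting
    implied cleavage sites."""


@dataclass(frozen=True)
class FragmentRecord:
    """One identified cleavage product in one sample.

    ``sample_label`` is the enzyme name or the no-enzyme-control label;
    ``spectral_count`` is carried through for bookkeeping but calling is
    presence/absence.
    """

    sample_label: str
    replicate: int
    timepoint_min: float
    fragment_sequence: str
    parent_id: str
    spectral_count: int = 1


@dataclass(frozen=True)
class CleavageCallSet:
    """Called sites for one enzyme at one timepoint."""

    enzyme: str
    timepoint_min: float
    sites: frozenset[CleavageSite]
    accumulative: bool


@dataclass(frozen=True)
class OverlapSummary:
    """Shared / unique site counts between two enzymes' call sets."""

    n_a: int
    n_b: int
    n_shared: int

    @property
    def frac_unique_a(self) -> float:
        return (self.n_a - self.n_shared) / self.n_a if self.n_a else 0.0

    @property
    def frac_unique_b(self) -> float:
        return (self.n_b - self.n_shared) / self.n_b if self.n_b else 0.0


def _occurrences(fragment: str, parent: str, map_leu_to_nle: bool) -> list[int]:
    """0-based start offsets where ``fragment`` matches ``parent``.

    With ``map_leu_to_nle`` a fragment 'L' also matches a parent norleucine,
    mirroring database searches that represent norleucine as leucine.
    """
    n, m = len(parent), len(fragment)
    starts = []
    for s in range(n - m + 1):
        ok = True
        for j in range(m):
            p, f = parent[s + j], fragment[j]
            if p == f:
                continue
            if map_leu_to_nle and f == "L" and p == NORLEUCINE:
                continue
            ok = False
            break
        if ok:
            starts.append(s)
    return starts


def infer_sites(
    record: FragmentRecord,
    library: PeptideLibrary,
    map_leu_to_nle: bool = False,
) -> frozenset[CleavageSite]:
    """Cleavage sites implied by one fragment.

    A fragment spanning parent residues ``s..e`` (1-based) implies a cut at
    bond ``s-1`` when it does not start at the N-terminus and at bond ``e``
    when it does not end at the C-terminus; the intact parent implies
    nothing.  A fragment matching at several offsets is an error unless all
    occurrences imply identical site sets.
    """
    parent = library[record.parent_id]
    frag = record.fragment_sequence
    frag = "".join(c if c == NORLEUCINE else c.upper() for c in frag)
    starts = _occurrences(frag, parent.sequence, map_leu_to_nle)
    if not starts:
        raise FragmentError(
            f"fragment {record.fragment_sequence!r} not found in parent "
            f"{record.parent_id!r}"
        )
    site_sets = []
    for s0 in starts:
        s, e = s0 + 1, s0 + len(frag)  # 1-based span
        sites = set()
        if s > 1:
            sites.add(CleavageSite(parent.id, s - 1))
        if e < parent.length:
            sites.add(CleavageSite(parent.id, e))
        site_sets.append(frozenset(sites))
    first = site_sets[0]
    if any(ss != first for ss in site_sets[1:]):
        raise AmbiguousFragmentError(
            f"fragment {frag!r} occurs at multiple offsets of "
            f"{record.parent_id!r} with conflicting implied sites"
        )
    return first


def nec_blacklist(
    records: Iterable[FragmentRecord],
    library: PeptideLibrary,
    nec_label: str = "NEC",
    map_leu_to_nle: bool = False,
) -> frozenset[CleavageSite]:
    """Union of sites seen in any NEC replicate at any timepoint."""
    sites: set[CleavageSite] = set()
    for rec in records:
        if rec.sample_label == nec_label:
            sites |= infer_sites(rec, library, map_leu_to_nle)
    return frozenset(sites)


def call_sites(
    records: Sequence[FragmentRecord],
    library: PeptideLibrary,
    enzyme: str,
    nec_label: str = "NEC",
    timepoints: Sequence[float] | None = None,
    accumulative: bool = True,
    map_leu_to_nle: bool = False,
) -> list[CleavageCallSet]:
    """Filtered cleavage-site sets for ``enzyme``, one per timepoint.

    Per timepoint the called set is ``(∩ over replicates) \\ (∪ NEC)``.
    With ``accumulative=True`` (the reporting default) each returned set is
    the union over all timepoints at or before it.  At least two replicates
    of the enzyme must be present — the intersection rule is undefined
    otherwise.
    """
    enz_records = [r for r in records if r.sample_label == enzyme]
    if not enz_records:
        raise ValueError(f"no records for enzyme {enzyme!r}")
    replicates = sorted({r.replicate for r in enz_records})
    if len(replicates) < 2:
        raise ValueError(
            f"enzyme {enzyme!r} has {len(replicates)} replicate(s); the "
            "replicate-intersection rule needs ≥ 2"
        )
    if timepoints is None:
        timepoints = sorted({r.timepoint_min for r in enz_records})
    else:
        timepoints = sorted(timepoints)

    blacklist = nec_blacklist(records, library, nec_label, map_leu_to_nle)

    # per (replicate, timepoint) inferred site sets
    per_rep_tp: dict[tuple[int, float], set[CleavageSite]] = {
        (rep, tp): set() for rep in replicates for tp in timepoints
    }
    for rec in enz_records:
        key = (rec.replicate, rec.timepoint_min)
        if key in per_rep_tp:
            per_rep_tp[key] |= infer_sites(rec, library, map_leu_to_nle)

    out: list[CleavageCallSet] = []
    running: set[CleavageSite] = set()
    for tp in timepoints:
        instant = set.intersection(*(per_rep_tp[(rep, tp)] for rep in replicates))
        instant -= blacklist
        if accumulative:
            running |= instant
            out.append(CleavageCallSet(enzyme, tp, frozenset(running), True))
        else:
            out.append(CleavageCallSet(enzyme, tp, frozenset(instant), False))
    return out


def overlap_stats(a: CleavageCallSet, b: CleavageCallSet) -> OverlapSummary:
    """Venn counts between two enzymes' accumulative call sets.

    Both sets must be accumulative and at the same timepoint; the unique
    fraction of each side is ``(n − n_shared) / n``.
    """
    if a.timepoint_min != b.timepoint_min:
        raise ValueError(
            f"timepoint mismatch: {a.timepoint_min} vs {b.timepoint_min}"
        )
    if not (a.accumulative and b.accumulative):
        raise ValueError("overlap statistics are defined on accumulative sets")
    shared = a.sites & b.sites
    return OverlapSummary(n_a=len(a.sites), n_b=len(b.sites), n_shared=len(shared))


def pct_of_library(n_sites: int, library: PeptideLibrary) -> float:
    """Percent of the library's total bonds represented by ``n_sites``."""
    return 100.0 * n_sites / library.n_sites()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

FRAGMENT_COLUMNS = [
    "sample_label",
    "replicate",
    "timepoint_min",
    "fragment_sequence",
    "parent_id",
    "spectral_count",
]


def read_fragment_report(path: str | Path) -> list[FragmentRecord]:
    """Read a long-format TSV of identified fragments.

    Required columns: sample_label, replicate, timepoint_min,
    fragment_sequence, parent_id, spectral_count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"fragment_sequence": str, "parent_id": str})
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fragment report {path} missing columns: {missing}")
    return [
        FragmentRecord(
            sample_label=str(row.sample_label),
            replicate=int(row.replicate),
            timepoint_min=float(row.timepoint_min),
            fragment_sequence=str(row.fragment_sequence),
            parent_id=str(row.parent_id),
            spectral_count=int(row.spectral_count),
        )
        for row in df.itertuples(index=False)
    ]


def write_fragment_report(records: Sequence[FragmentRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.sample_label, r.replicate, r.timepoint_min, r.fragment_sequence,
             r.parent_id, r.spectral_count)
            for r in records
        ],
        columns=FRAGMENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_call_sets(call_sets: Sequence[CleavageCallSet], path: str | Path) -> None:
    """TSV of called sites: enzyme, timepoint_min, peptide_id, bond_index."""
    rows = []
    for cs in call_sets:
        for site in sorted(cs.sites):
            rows.append((cs.enzyme, cs.timepoint_min, site.peptide_id, site.bond_index))
    pd.DataFrame(
        rows, columns=["enzyme", "timepoint_min", "peptide_id", "bond_index"]
    ).to_csv(path, sep="\t", index=False)
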