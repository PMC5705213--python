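"""MHC class I peptide cleavage-propensity scoring and assay-library design.

The C-terminus of an MHC class I peptide is generated by proteasomal
cleavage, so a proteasome's P4–P1 preferences shape the displayed
repertoire.  A peptide's cleavage score under an enzyme is the product of
the four non-prime positional frequencies observed in the multiplex
profiling assay, aligned to the peptide's C-terminus (P1 = final residue):

    s_E = f_E(P4, aa[-4]) · f_E(P3, aa[-3]) · f_E(P2, aa[-2]) · f_E(P1, aa[-1])

and the iP-vs-cP selectivity is log2(s_iP / s_cP) with pseudo-frequency
flooring of zero cells.  The module also builds the 7+7 assay peptides
(last 7 residues of the MHC peptide + first 7 residues of the downstream
parent-protein context, scissile bond between positions 7 and 8), selects
score-balanced assay libraries, and contrasts C-terminal residue usage with
a proteome background.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .library import NONPRIME_POSITIONS, NORLEUCINE
from .specificity import FrequencyMatrix, pseudo_floor

#: The 20 canonical residues (MHC peptides and proteomes include Met).
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MhcPeptideRecord:
    """An MHC I peptide with the parent-protein residues that follow it."""

    peptide: str
    parent_context: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.peptide) < 4:
            raise ValueError(
                f"peptide {self.peptide!r} shorter than 4 residues; P4–P1 "
                "scoring needs at least four"
            )


@dataclass(frozen=True)
class CleavageScore:
    s_iP: float
    s_cP: float
    log2_ratio: float
    flag: str = ""


@dataclass(frozen=True)
class ResidueDistribution:
    """Residue fractions at a named position class, with its sample size."""

    fractions: pd.Series
    n: int

    def __post_init__(self) -> None:
        total = float(self.fractions.sum())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"fractions sum to {total}, expected 1")

    @classmethod
    def from_counts(cls, counts: pd.Series) -> "ResidueDistribution":
        n = int(counts.sum())
        if n == 0:
            raise ValueError("empty counts")
        return cls(fractions=counts / n, n=n)

    @classmethod
    def from_cterm(cls, peptides: Sequence[str],
                   alphabet: str = CANONICAL) -> "ResidueDistribution":
        """Distribution of the final (C-terminal) residue over peptides."""
        counts = pd.Series(0, index=list(alphabet), dtype=float)
        for p in peptides:
            counts[p[-1]] += 1
        return cls.from_counts(counts)

    @classmethod
    def from_sequences(cls, sequences: Sequence[str],
                       alphabet: str = CANONICAL) -> "ResidueDistribution":
        """Overall residue composition of a sequence collection."""
        counts = pd.Series(0, index=list(alphabet), dtype=float)
        for s in sequences:
            for ch in s:
                if ch in counts.index:
                    counts[ch] += 1
        return cls.from_counts(counts)


def _positional_frequency(matrix: FrequencyMatrix, position: str, residue: str,
                          met_policy: str) -> tuple[float, float]:
    """(frequency, floor) for one residue at one non-prime position.

    Residues absent from the matrix alphabet (methionine, when the matrix
    comes from a norleucine-substituted library) are handled per
    ``met_policy``: 'nle' maps Met to norleucine, 'error' raises.
    """
    if residue not in matrix.freq.columns:
        if residue == "M" and met_policy == "nle" and NORLEUCINE in matrix.freq.columns:
            residue = NORLEUCINE
        else:
            raise KeyError(
                f"residue {residue!r} absent from matrix alphabet; "
                "use met_policy='nle' to map Met to norleucine"
            )
    return float(matrix.freq.at[position, residue]), pseudo_floor(int(matrix.n_obs[position]))


def cleavage_score(
    peptide: MhcPeptideRecord | str,
    freq_iP: FrequencyMatrix,
    freq_cP: FrequencyMatrix,
    met_policy: str = "nle",
) -> CleavageScore:
    """Product-of-frequencies cleavage propensity of a peptide's C-terminus.

    Only the last four residues enter; the log2 ratio floors zero cells at
    1/(2·n_obs) so it stays finite, flagged when flooring was applied.
    """
    seq = peptide.peptide if isinstance(peptide, MhcPeptideRecord) else peptide
    if len(seq) < 4:
        raise ValueError("cleavage score needs ≥ 4 residues")
    tail = seq[-4:]
    s_ip = s_cp = 1.0
    l2 = 0.0
    flag = ""
    for pos, aa in zip(NONPRIME_POSITIONS, tail):
        fi, floor_i = _positional_frequency(freq_iP, pos, aa, met_policy)
        fc, floor_c = _positional_frequency(freq_cP, pos, aa, met_policy)
        s_ip *= fi
        s_cp *= fc
        if fi <= 0.0 or fc <= 0.0:
            flag = "ratio_floored"
        l2 += math.log2(max(fi, floor_i)) - math.log2(max(fc, floor_c))
    return CleavageScore(s_iP=s_ip, s_cP=s_cp, log2_ratio=l2, flag=flag)


def score_table(
    records: Sequence[MhcPeptideRecord],
    freq_iP: FrequencyMatrix,
    freq_cP: FrequencyMatrix,
    met_policy: str = "nle",
) -> pd.DataFrame:
    """Score every record; columns: source_id, peptide, s_iP, s_cP, log2_ratio."""
    rows = []
    for rec in records:
        sc = cleavage_score(rec, freq_iP, freq_cP, met_policy)
        rows.append((rec.source_id, rec.peptide, sc.s_iP, sc.s_cP, sc.log2_ratio, sc.flag))
    return pd.DataFrame(
        rows, columns=["source_id", "peptide", "s_iP", "s_cP", "log2_ratio", "flag"]
    )


def build_assay_peptide(record: MhcPeptideRecord) -> tuple[str, int]:
    """14-mer assay peptide: MHC peptide's last 7 residues + first 7 context
    residues; the processing site sits at bond 7 (between positions 7 and 8).
    """
    if len(record.peptide) < 7:
        raise ValueError(
            f"peptide {record.peptide!r} shorter than 7 residues"
        )
    if len(record.parent_context) < 7:
        raise ValueError(
            f"parent context for {record.source_id or record.peptide!r} has "
            f"{len(record.parent_context)} residues; need ≥ 7"
        )
    return record.peptide[-7:] + record.parent_context[:7], 7


def select_balanced_library(
    candidates: Sequence[MhcPeptideRecord],
    freq_iP: FrequencyMatrix,
    freq_cP: FrequencyMatrix,
    n: int,
    seed: int,
    n_bins: int = 5,
    met_policy: str = "nle",
) -> list[MhcPeptideRecord]:
    """Score-balanced random sample of ``n`` candidates.

    Candidates are binned by log2-ratio quantiles (``n_bins`` bins; bins
    collapse when scores tie) and drawn equally per bin so the selection is
    not biased toward either enzyme's preference; the remainder is spread
    deterministically starting from the most populous bins.  Reproducible
    under ``seed``.
    """
    if n > len(candidates):
        raise ValueError(f"cannot select {n} from {len(candidates)} candidates")
    ratios = np.array([
        cleavage_score(c, freq_iP, freq_cP, met_policy).log2_ratio for c in candidates
    ])
    # quantile bins on the score values; duplicate edges collapse so few
    # distinct scores yield few (possibly one) effective bins
    probs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    edges = np.unique(np.quantile(ratios, probs)) if len(probs) else np.array([])
    bins = np.searchsorted(edges, ratios, side="left")
    bin_ids = sorted(set(bins.tolist()))
    members = {b: np.flatnonzero(bins == b) for b in bin_ids}

    base, rem = divmod(n, len(bin_ids))
    quotas = {b: base for b in bin_ids}
    # remainder to the most populous bins; ties broken by bin index
    by_size = sorted(bin_ids, key=lambda b: (-len(members[b]), b))
    for b in by_size[:rem]:
        quotas[b] += 1

    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    deficit = 0
    for b in bin_ids:
        avail = members[b]
        take = quotas[b]
        if take > len(avail):
            warnings.warn(
                f"bin {b} holds {len(avail)} candidates but quota is {take}; "
                "redistributing the shortfall", stacklevel=2
            )
            deficit += take - len(avail)
            take = len(avail)
        chosen.extend(rng.choice(avail, size=take, replace=False).tolist())
    if deficit:
        pool = np.array(sorted(set(range(len(candidates))) - set(chosen)))
        chosen.extend(rng.choice(pool, size=deficit, replace=False).tolist())
    return [candidates[i] for i in sorted(chosen)]


def cterm_enrichment(
    mhc_dist: ResidueDistribution, proteome_dist: ResidueDistribution
) -> pd.DataFrame:
    """Per-residue log2 enrichment of MHC C-termini over a proteome background.

    Columns: residue, f_mhc, f_proteome, log2_enrichment, flag.  Zero cells
    on either side are floored at 1/(2·n) of the respective distribution and
    flagged.
    """
    if set(mhc_dist.fractions.index) != set(proteome_dist.fractions.index):
        raise ValueError("distributions must share an alphabet")
    floor_m = pseudo_floor(mhc_dist.n)
    floor_p = pseudo_floor(proteome_dist.n)
    rows = []
    for res in mhc_dist.fractions.index:
        fm = float(mhc_dist.fractions[res])
        fp = float(proteome_dist.fractions[res])
        flag = "floored" if (fm <= 0.0 or fp <= 0.0) else ""
        val = math.log2(max(fm, floor_m)) - math.log2(max(fp, floor_p))
        rows.append((res, fm, fp, val, flag))
    return pd.DataFrame(
        rows, columns=["residue", "f_mhc", "f_proteome", "log2_enrichment", "flag"]
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mhc_table(path: str | Path) -> list[MhcPeptideRecord]:
    """TSV with columns peptide, parent_context, source_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("peptide", "parent_context"):
        if col not in df.columns:
            raise ValueError(f"MHC table {path} missing column {col!r}")
    if "source_id" not in df.columns:
        df["source_id"] = [f"mhc{i}" for i in range(len(df))]
    return [
        MhcPeptideRecord(peptide=r.peptide, parent_context=r.parent_context,
                         source_id=r.source_id)
        for r in df.itertuples(index=False)
    ]


def write_mhc_table(records: Sequence[MhcPeptideRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.peptide, r.parent_context, r.source_id) for r in records],
        columns=["peptide", "parent_context", "source_id"],
    ).to_csv(path, sep="\t", index=False)


def proteome_distribution(path: str | Path,
                          alphabet: str = CANONICAL) -> ResidueDistribution:
    """Residue composition of a proteome FASTA."""
    seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return ResidueDistribution.from_sequences(seqs, alphabet)
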