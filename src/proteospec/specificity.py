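"""Positional specificity statistics: frequency matrices, iceLogo-style
enrichment Z-scores, enzyme difference maps, and exhaustive tetrapeptide
selectivity ranking.

The experimental (cleaved, "positive") window set is compared
position-by-position and residue-by-residue against a reference set — here
the octapeptides of *all* possible cleavage sites in the same library, so
enrichment reflects the protease's choice among the bonds actually on
offer.  The per-cell statistic is the binomial-approximation Z-score used
by iceLogo:

    z = (f_exp − f_ref) / sqrt( f_ref · (1 − f_ref) / n_exp )

with ``n_exp`` the positive set's observation count at that position, and a
two-sided standard-normal p-value.  Terminal-truncation pads are excluded
from counts, so per-position ``n_obs`` varies (e.g. P4 is undefined for the
first three bonds of each peptide).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library import (
    ALPHABET,
    NONPRIME_POSITIONS,
    PAD,
    POSITIONS,
    OctapeptideWindow,
)


@dataclass
class FrequencyMatrix:
    """Position × residue fractions with per-position observation counts.

    ``freq`` is an 8 × |alphabet| DataFrame indexed by subsite label; each
    row sums to 1 over the alphabet (pads excluded from counting).
    """

    freq: pd.DataFrame
    n_obs: pd.Series

    @property
    def alphabet(self) -> tuple[str, ...]:
        return tuple(self.freq.columns)

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(self.freq.index)

    def row(self, position: str) -> pd.Series:
        return self.freq.loc[position]


@dataclass
class EnrichmentResult:
    """Per-(position, residue) enrichment of a positive set over a reference.

    ``table`` columns: position, residue, f_exp, f_ref, n_exp, z_score,
    p_value, fold_change, significant, flag.  ``flag`` marks undefined cells
    ('z_undefined' when f_ref ∈ {0, 1} with f_exp ≠ f_ref, 'ratio_floored'
    when the fold change needed the pseudo-frequency floor).  The reference
    matrix is retained so difference maps can verify a shared background.
    """

    table: pd.DataFrame
    alpha: float
    background: FrequencyMatrix

    def z_matrix(self) -> pd.DataFrame:
        """Positions × residues pivot of the Z-scores."""
        return self.table.pivot(index="position", columns="residue", values="z_score") \
            .reindex(index=list(POSITIONS))


@dataclass
class DifferenceMap:
    """Z-score difference (enzyme A − enzyme B) per position × residue,
    with a joint-significance mask (either input significant)."""

    delta_z: pd.DataFrame
    either_significant: pd.DataFrame


def build_matrix(
    windows: Sequence[OctapeptideWindow], alphabet: str = ALPHABET
) -> FrequencyMatrix:
    """Count residues per subsite over ``windows`` and normalise to fractions.

    Pads never count; duplicated windows count with multiplicity, so the
    fractions are the sampling odds of a random cleavage from the set.
    An all-pad position (degenerate input) is an error.
    """
    if not windows:
        raise ValueError("cannot build a frequency matrix from zero windows")
    letters = list(alphabet)
    counts = pd.DataFrame(0, index=list(POSITIONS), columns=letters, dtype=float)
    for w in windows:
        for pos, ch in zip(POSITIONS, w.residues):
            if ch == PAD:
                continue
            if ch not in counts.columns:
                raise ValueError(f"residue {ch!r} outside alphabet {alphabet!r}")
            counts.at[pos, ch] += 1
    n_obs = counts.sum(axis=1)
    if (n_obs == 0).any():
        empty = list(n_obs.index[n_obs == 0])
        raise ValueError(f"no observations at position(s) {empty}")
    freq = counts.div(n_obs, axis=0)
    return FrequencyMatrix(freq=freq, n_obs=n_obs.astype(int))


def pseudo_floor(n_obs: int) -> float:
    """Pseudo-frequency floor for zero cells in ratio outputs: 1/(2·n_obs)."""
    return 1.0 / (2.0 * n_obs)


def icelogo_enrichment(
    positive: FrequencyMatrix,
    background: FrequencyMatrix,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> EnrichmentResult:
    """iceLogo-style per-cell enrichment of ``positive`` over ``background``.

    z uses the positive set's per-position n; p is the two-sided normal
    tail; ``significant`` is ``p ≤ alpha`` (optionally after
    Benjamini–Hochberg across the cells, off by default to match raw-p logo
    shading).  Cells with f_ref ∈ {0, 1} and f_exp ≠ f_ref have no defined
    z and are flagged, never dropped.
    """
    if positive.alphabet != background.alphabet:
        raise ValueError("positive and background alphabets differ")
    if positive.positions != background.positions:
        raise ValueError("positive and background position sets differ")
    rows = []
    for pos in positive.positions:
        n_exp = int(positive.n_obs[pos])
        if n_exp < 1:
            raise ValueError(f"positive set has no observations at {pos}")
        floor = pseudo_floor(int(background.n_obs[pos]))
        for res in positive.alphabet:
            f_exp = float(positive.freq.at[pos, res])
            f_ref = float(background.freq.at[pos, res])
            flag = ""
            if f_exp == f_ref:
                z, p = 0.0, 1.0
            elif f_ref <= 0.0 or f_ref >= 1.0:
                z, p = math.nan, math.nan
                flag = "z_undefined"
            else:
                se = math.sqrt(f_ref * (1.0 - f_ref) / n_exp)
                z = (f_exp - f_ref) / se
                p = 2.0 * stats.norm.sf(abs(z))
                p = min(max(p, np.nextafter(0, 1)), 1.0)
            if f_ref > 0.0:
                fold = f_exp / f_ref
            else:
                fold = f_exp / floor
                flag = (flag + ";" if flag else "") + "ratio_floored"
            rows.append((pos, res, f_exp, f_ref, n_exp, z, p, fold, flag))
    table = pd.DataFrame(
        rows,
        columns=["position", "residue", "f_exp", "f_ref", "n_exp",
                 "z_score", "p_value", "fold_change", "flag"],
    )
    if bh_correct:
        from .kinetics import storey_qvalues  # λ=0 ≡ BH

        mask = table["p_value"].notna()
        adj = table["p_value"].copy()
        adj.loc[mask] = storey_qvalues(table.loc[mask, "p_value"].to_numpy(), lam=0.0)
        table["significant"] = adj.le(alpha).fillna(False)
    else:
        table["significant"] = table["p_value"].le(alpha).fillna(False)
    return EnrichmentResult(table=table, alpha=alpha, background=background)


def difference_map(enr_a: EnrichmentResult, enr_b: EnrichmentResult) -> DifferenceMap:
    """Per-cell Z-score difference between two enzymes profiled against the
    same background; antisymmetric under swapping the inputs."""
    bg_a, bg_b = enr_a.background, enr_b.background
    if not (bg_a.freq.equals(bg_b.freq) and bg_a.n_obs.equals(bg_b.n_obs)):
        raise ValueError("difference map requires a common background matrix")
    za = enr_a.z_matrix()
    zb = enr_b.z_matrix()
    sig_a = enr_a.table.pivot(index="position", columns="residue",
                              values="significant").reindex(index=list(POSITIONS))
    sig_b = enr_b.table.pivot(index="position", columns="residue",
                              values="significant").reindex(index=list(POSITIONS))
    return DifferenceMap(delta_z=za - zb, either_significant=sig_a | sig_b)


def rank_substrates(
    freq_a: FrequencyMatrix,
    freq_b: FrequencyMatrix,
    alphabet_size: int | None = None,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Exhaustively score the P4–P1 tetrapeptide space under two matrices.

    Each tetrapeptide's score under a matrix is the product of the four
    positional frequencies (P4·P3·P2·P1).  The returned table has columns
    (tetrapeptide, score_a, score_b, log2_ratio), sorted by log2 ratio
    descending with lexicographic tie-break.  The log2 ratio floors zero
    frequencies at ``pseudo`` (default ``1/(2·n_obs)`` per matrix and
    position); the raw scores are not floored.
    """
    if freq_a.alphabet != freq_b.alphabet:
        raise ValueError("matrices must share an alphabet")
    letters = list(freq_a.alphabet)
    if alphabet_size is None:
        alphabet_size = len(letters)
    letters = letters[:alphabet_size]
    positions = list(NONPRIME_POSITIONS)

    fa = np.stack([freq_a.freq.loc[p, letters].to_numpy(float) for p in positions])
    fb = np.stack([freq_b.freq.loc[p, letters].to_numpy(float) for p in positions])
    if pseudo is None:
        floor_a = np.array([pseudo_floor(int(freq_a.n_obs[p])) for p in positions])
        floor_b = np.array([pseudo_floor(int(freq_b.n_obs[p])) for p in positions])
    else:
        floor_a = np.full(len(positions), pseudo)
        floor_b = np.full(len(positions), pseudo)
    la = np.log2(np.maximum(fa, floor_a[:, None]))
    lb = np.log2(np.maximum(fb, floor_b[:, None]))

    A = len(letters)
    # broadcast sums/products over the 4-position grid (P4, P3, P2, P1)
    def grid(values: np.ndarray, combine) -> np.ndarray:
        g = values[0][:, None, None, None]
        g = combine(g, values[1][None, :, None, None])
        g = combine(g, values[2][None, None, :, None])
        g = combine(g, values[3][None, None, None, :])
        return g.reshape(A ** 4)

    score_a = grid(fa, np.multiply)
    score_b = grid(fb, np.multiply)
    log2_ratio = grid(la, np.add) - grid(lb, np.add)

    seqs = ["".join(c) for c in itertools.product(letters, repeat=4)]
    df = pd.DataFrame(
        {"tetrapeptide": seqs, "score_a": score_a, "score_b": score_b,
         "log2_ratio": log2_ratio}
    )
    df = df.sort_values(
        ["log2_ratio", "tetrapeptide"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_enrichment(result: EnrichmentResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: FrequencyMatrix, path: str | Path) -> None:
    """Logo-ready position × residue fraction matrix (TSV), with a trailing
    ``n_obs`` column so the matrix can be re-read losslessly."""
    out = matrix.freq.copy()
    out["n_obs"] = matrix.n_obs
    out.to_csv(path, sep="\t", index_label="position")


def read_matrix(path: str | Path) -> FrequencyMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="position")
    if "n_obs" not in df.columns:
        raise ValueError(f"matrix file {path} lacks the n_obs column")
    n_obs = df.pop("n_obs").astype(int)
    return FrequencyMatrix(freq=df, n_obs=n_obs)


def write_difference_map(dm: DifferenceMap, path: str | Path) -> None:
    dm.delta_z.to_csv(path, sep="\t")


def plot_difference_map(dm: DifferenceMap, path: str | Path, title: str = "") -> None:
    """Diverging heat map of the Z-score difference (positions × residues)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = dm.delta_z.to_numpy(float)
    vmax = np.nanmax(np.abs(data)) or 1.0
    fig, ax = plt.subplots(figsize=(10, 4))
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(dm.delta_z.columns)))
    ax.set_xticklabels(dm.delta_z.columns)
    ax.set_yticks(range(len(dm.delta_z.index)))
    ax.set_yticklabels(dm.delta_z.index)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="ΔZ")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
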