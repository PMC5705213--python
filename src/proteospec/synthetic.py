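"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a multiplexed peptide-library digestion experiment:
a library of random 14-mers (norleucine in place of Met), two proteases
with configurable positional specificity, no-enzyme-control contamination,
detection dropout, and lognormal peak-area noise.  All stochastic outputs
are pure functions of (configuration, seed).

Digestion model
---------------
Each bond ``b`` of a peptide carries a first-order hazard

    k_b = k0 · Π_j  w(j, residue at subsite j of b's window)

with pad positions contributing factor 1.  Within a peptide the bonds
compete for the first cut (products are not re-cleaved; the assay operates
at low conversion), so with ``K = Σ_b k_b`` the probability that bond
``b`` has been cut by time ``t`` is

    P_b(t) = (k_b / K) · (1 − e^(−K·t)),

which conserves probability exactly: Σ_b P_b(t) + P(intact) = 1.
Detection is thresholded on expected conversion with Bernoulli dropout —
a deliberate simplification that exercises the replicate-intersection and
NEC-subtraction rules without modelling ionisation.

Specificity presets
-------------------
``ip_preset`` elevates bulky hydrophobic residues (Trp, Phe, Tyr) at P1;
``cp_preset`` elevates small/polar residues and Arg at P1; both share a
Lys elevation at P2.  The presets are directional caricatures of the two
proteasome isoforms' profiles, not magnitude reconstructions.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import FragmentRecord
from .kinetics import DEFAULT_RATE_TIMEPOINTS, ProgressCurve
from .library import (
    ALPHABET,
    POSITIONS,
    CleavageSite,
    PeptideLibrary,
    PeptideLibraryEntry,
    enumerate_sites,
)
from .mhc import CANONICAL, MhcPeptideRecord
from .specificity import FrequencyMatrix

#: Smallest product length the simulated LC-MS/MS identifies.  Very short
#: fragments are unobservable in practice and would map ambiguously.
MIN_FRAGMENT_LENGTH = 4


@dataclass(frozen=True)
class GroundTruthSpecificity:
    """Position × residue positive preference weights (geometric mean 1 per
    position, making the per-position scale identifiable)."""

    weights: pd.DataFrame

    @classmethod
    def from_weights(cls, raw: pd.DataFrame) -> "GroundTruthSpecificity":
        if (raw <= 0).any().any():
            raise ValueError("weights must be strictly positive")
        log_w = np.log(raw.to_numpy(float))
        norm = np.exp(log_w - log_w.mean(axis=1, keepdims=True))
        return cls(pd.DataFrame(norm, index=raw.index, columns=raw.columns))

    @classmethod
    def uniform(cls, alphabet: str = ALPHABET) -> "GroundTruthSpecificity":
        return cls(pd.DataFrame(1.0, index=list(POSITIONS), columns=list(alphabet)))

    @classmethod
    def from_elevations(
        cls, elevations: Mapping[str, Mapping[str, float]], alphabet: str = ALPHABET
    ) -> "GroundTruthSpecificity":
        """Weights of 1 everywhere except the given {position: {residue: w}}."""
        raw = pd.DataFrame(1.0, index=list(POSITIONS), columns=list(alphabet))
        for pos, res_w in elevations.items():
            for res, w in res_w.items():
                raw.at[pos, res] = w
        return cls.from_weights(raw)

    @classmethod
    def ip_preset(cls) -> "GroundTruthSpecificity":
        """Immunoproteasome-like truth: bulky hydrophobics at P1, Lys at P2."""
        return cls.from_elevations(
            {"P1": {"W": 8.0, "F": 6.0, "Y": 5.0, "L": 3.0}, "P2": {"K": 3.0}}
        )

    @classmethod
    def cp_preset(cls) -> "GroundTruthSpecificity":
        """Constitutive-proteasome-like truth: small/polar residues and Arg
        at P1, Lys at P2."""
        return cls.from_elevations(
            {"P1": {"S": 6.0, "T": 5.0, "Q": 4.5, "R": 3.0, "G": 2.5, "A": 2.5},
             "P2": {"K": 3.0}}
        )

    def p1_preference(self) -> pd.Series:
        """P1 weights normalised to a probability vector."""
        row = self.weights.loc["P1"]
        return row / row.sum()

    def to_frequency_matrix(self, n_obs: int = 1000) -> FrequencyMatrix:
        """The truth expressed as positional frequencies (each row of
        weights normalised to sum 1) — handy for scoring against truth."""
        freq = self.weights.div(self.weights.sum(axis=1), axis=0)
        return FrequencyMatrix(
            freq=freq, n_obs=pd.Series(n_obs, index=freq.index, dtype=int)
        )

    def hazard_multiplier(self, sequence: str, bond: int) -> float:
        """Π of subsite weights for bond ``bond`` of ``sequence`` (pads → 1)."""
        mult = 1.0
        for pos, offset in zip(POSITIONS, range(bond - 3, bond + 5)):
            if 1 <= offset <= len(sequence):
                ch = sequence[offset - 1]
                if ch in self.weights.columns:
                    mult *= float(self.weights.at[pos, ch])
        return mult


@dataclass(frozen=True)
class DigestSimConfig:
    """Conditions of one simulated digestion experiment.

    ``k0`` in min⁻¹; ``detection_threshold`` is the expected conversion a
    bond needs before its products are reported; ``dropout_prob`` is the
    per-reported-fragment miss probability; ``nec_site_rate`` is the
    expected number of spurious no-enzyme-control sites per replicate.
    """

    k0: float = 6.3e-6
    timepoints: tuple[float, ...] = (60.0, 120.0, 240.0, 480.0)
    detection_threshold: float = 0.0075
    dropout_prob: float = 0.05
    nec_site_rate: float = 5.0
    noise_cv: float = 0.10
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_threshold", "dropout_prob", "noise_cv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.k0 is not None and self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if any(t2 <= t1 for t1, t2 in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")


def make_library(n_peptides: int = 228, length: int = 14, seed: int = 0) -> PeptideLibrary:
    """Random peptide library over the 20-symbol alphabet (Met → 'n').

    Residues are drawn uniformly, so marginal frequencies are near-uniform
    (each within 2× of 1/20 once n·length is large).  Deterministic under
    ``seed``.
    """
    if n_peptides < 1 or length < 4:
        raise ValueError("need n_peptides ≥ 1 and length ≥ 4")
    rng = np.random.default_rng(seed)
    letters = np.array(list(ALPHABET))
    width = len(str(n_peptides))
    entries = []
    for i in range(n_peptides):
        seq = "".join(rng.choice(letters, size=length))
        entries.append(PeptideLibraryEntry(id=f"pep{i + 1:0{width}d}", sequence=seq))
    return PeptideLibrary(entries)


def bond_hazards(
    library: PeptideLibrary, truth: GroundTruthSpecificity, k0: float
) -> pd.DataFrame:
    """Ground-truth hazards: columns peptide_id, bond_index, hazard."""
    rows = []
    for entry in library:
        for b in range(1, entry.length):
            rows.append((entry.id, b, k0 * truth.hazard_multiplier(entry.sequence, b)))
    return pd.DataFrame(rows, columns=["peptide_id", "bond_index", "hazard"])


def conversion_table(
    library: PeptideLibrary, truth: GroundTruthSpecificity, k0: float, t: float
) -> pd.DataFrame:
    """Expected per-bond conversion P_b(t) under the competing-risks model."""
    hz = bond_hazards(library, truth, k0)
    out = []
    for pid, grp in hz.groupby("peptide_id", sort=False):
        K = grp["hazard"].sum()
        depletion = 1.0 - math.exp(-K * t)
        conv = grp["hazard"] / K * depletion
        out.append(pd.DataFrame({
            "peptide_id": pid, "bond_index": grp["bond_index"], "conversion": conv
        }))
    return pd.concat(out, ignore_index=True)


def calibrate_k0(
    library: PeptideLibrary,
    truth: GroundTruthSpecificity,
    t_final: float = 480.0,
    target_median_conversion: float = 0.05,
    tol: float = 1e-4,
) -> float:
    """Baseline hazard giving the target median peptide-level conversion.

    The assay runs at low substrate conversion; the calibrated quantity is
    the median over peptides of the consumed fraction ``1 − e^(−K_p·t)`` at
    the final timepoint (per-bond conversion saturates at the hazard share
    ``k_b/K`` and cannot be driven to an arbitrary target).  Solved by
    bisection in log space.
    """
    hz = bond_hazards(library, truth, 1.0)
    totals = hz.groupby("peptide_id", sort=False)["hazard"].sum().to_numpy(float)

    def median_conv(k0: float) -> float:
        return float(np.median(1.0 - np.exp(-k0 * totals * t_final)))

    lo, hi = 1e-10, 10.0
    for _ in range(100):
        mid = math.sqrt(lo * hi)
        m = median_conv(mid)
        if abs(m - target_median_conversion) / target_median_conversion < tol:
            return mid
        if m < target_median_conversion:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _products(sequence: str, bond: int) -> list[str]:
    """Single-cut products of a bond, filtered for detectability."""
    frags = [sequence[:bond], sequence[bond:]]
    return [f for f in frags if len(f) >= MIN_FRAGMENT_LENGTH]


def _unambiguous(fragment: str, parent: str, bond: int) -> bool:
    """True when every occurrence of ``fragment`` in ``parent`` implies the
    same cleavage sites (simulated search engines resolve only unambiguous
    assignments)."""
    n, m = len(parent), len(fragment)
    spans = [s for s in range(n - m + 1) if parent[s:s + m] == fragment]
    implied = set()
    for s in spans:
        sites = []
        if s > 0:
            sites.append(s)
        if s + m < n:
            sites.append(s + m)
        implied.add(tuple(sites))
    return len(implied) == 1


def simulate_digestion(
    library: PeptideLibrary,
    truth: GroundTruthSpecificity,
    config: DigestSimConfig,
    enzyme_label: str,
    stream: int = 0,
) -> list[FragmentRecord]:
    """Fragment records for one enzyme's replicates.

    A bond whose expected conversion reaches ``detection_threshold`` at a
    timepoint contributes its (detectable, unambiguous) single-cut products
    as records at that timepoint, independently thinned per replicate by
    ``dropout_prob``; spectral counts are Poisson draws proportional to
    conversion.
    """
    rng = np.random.default_rng(
        [config.seed, stream, zlib.crc32(enzyme_label.encode()) % (2**31)]
    )
    records: list[FragmentRecord] = []
    hz = bond_hazards(library, truth, config.k0)
    hz_by_pep = {pid: grp for pid, grp in hz.groupby("peptide_id", sort=False)}
    for entry in library:
        grp = hz_by_pep[entry.id]
        k = grp["hazard"].to_numpy(float)
        K = k.sum()
        for rep in range(1, config.n_replicates + 1):
            for t in config.timepoints:
                conv = k / K * (1.0 - math.exp(-K * t))
                for bond, c in zip(grp["bond_index"], conv):
                    if c < config.detection_threshold:
                        continue
                    for frag in _products(entry.sequence, int(bond)):
                        if not _unambiguous(frag, entry.sequence, int(bond)):
                            continue
                        if rng.random() < config.dropout_prob:
                            continue
                        count = max(1, int(rng.poisson(100.0 * c)))
                        records.append(FragmentRecord(
                            sample_label=enzyme_label, replicate=rep,
                            timepoint_min=float(t), fragment_sequence=frag,
                            parent_id=entry.id, spectral_count=count,
                        ))
    return records


def simulate_nec(
    library: PeptideLibrary,
    config: DigestSimConfig,
    nec_label: str = "NEC",
    stream: int = 1,
) -> list[FragmentRecord]:
    """No-enzyme-control records: per replicate, a Poisson number of
    spurious sites drawn uniformly from the library's bonds, reported as
    their products at every timepoint."""
    rng = np.random.default_rng([config.seed, stream])
    sites = enumerate_sites(library)
    records: list[FragmentRecord] = []
    for rep in range(1, config.n_replicates + 1):
        n_spur = rng.poisson(config.nec_site_rate)
        if n_spur == 0:
            continue
        picks = rng.choice(len(sites), size=min(n_spur, len(sites)), replace=False)
        for idx in sorted(picks.tolist()):
            site = sites[idx]
            parent = library[site.peptide_id]
            for frag in _products(parent.sequence, site.bond_index):
                if not _unambiguous(frag, parent.sequence, site.bond_index):
                    continue
                for t in config.timepoints:
                    records.append(FragmentRecord(
                        sample_label=nec_label, replicate=rep,
                        timepoint_min=float(t), fragment_sequence=frag,
                        parent_id=parent.id, spectral_count=1,
                    ))
    return records


def nec_true_sites(
    library: PeptideLibrary, config: DigestSimConfig, stream: int = 1
) -> frozenset[CleavageSite]:
    """The spurious sites :func:`simulate_nec` draws (ground truth for tests)."""
    rng = np.random.default_rng([config.seed, stream])
    sites = enumerate_sites(library)
    chosen: set[CleavageSite] = set()
    for _ in range(config.n_replicates):
        n_spur = rng.poisson(config.nec_site_rate)
        if n_spur == 0:
            continue
        picks = rng.choice(len(sites), size=min(n_spur, len(sites)), replace=False)
        chosen |= {sites[i] for i in picks.tolist()}
    return frozenset(chosen)


def simulate_experiment(
    library: PeptideLibrary,
    truth_a: GroundTruthSpecificity,
    truth_b: GroundTruthSpecificity,
    config: DigestSimConfig,
    label_a: str = "iP",
    label_b: str = "cP",
    nec_label: str = "NEC",
) -> list[FragmentRecord]:
    """Two-enzyme digestion plus the shared no-enzyme control."""
    records = simulate_digestion(library, truth_a, config, label_a, stream=2)
    records += simulate_digestion(library, truth_b, config, label_b, stream=3)
    records += simulate_nec(library, config, nec_label, stream=1)
    return records


def simulate_progress_curves(
    assay_peptides: Mapping[str, str],
    truth_a: GroundTruthSpecificity,
    truth_b: GroundTruthSpecificity,
    label_a: str = "iP",
    label_b: str = "cP",
    bond: int = 7,
    k0: float = 2.0e-4,
    schedule: Sequence[float] = DEFAULT_RATE_TIMEPOINTS,
    noise_cv: float = 0.10,
    n_replicates: int = 4,
    max_area: float = 1.0e6,
    seed: int = 0,
) -> list[ProgressCurve]:
    """Peak-area time courses for the scissile bond of each assay peptide.

    Per peptide and enzyme the cumulative product at ``bond`` follows the
    competing-risks curve scaled to ``max_area``; each replicate's areas
    are multiplied by independent lognormal noise with the given CV.  Both
    product ids ('<id>_N' and '<id>_C') are emitted per replicate.
    """
    rng = np.random.default_rng([seed, 7])
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
    times = tuple(float(t) for t in schedule)
    curves: list[ProgressCurve] = []
    for pid in sorted(assay_peptides):
        seq = assay_peptides[pid]
        for enzyme, truth in ((label_a, truth_a), (label_b, truth_b)):
            k = np.array([
                k0 * truth.hazard_multiplier(seq, b) for b in range(1, len(seq))
            ])
            K = k.sum()
            kb = k[bond - 1]
            mean_curve = (kb / K) * (1.0 - np.exp(-K * np.asarray(times))) * max_area
            for rep in range(1, n_replicates + 1):
                for suffix in ("N", "C"):
                    if noise_cv > 0:
                        noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=len(times))
                    else:
                        noise = np.ones(len(times))
                    curves.append(ProgressCurve(
                        product_id=f"{pid}_{suffix}", substrate_id=pid,
                        enzyme=enzyme, replicate=rep, times=times,
                        areas=tuple(np.maximum(mean_curve * noise, 0.0)),
                    ))
    return curves


def make_proteome(
    n_proteins: int,
    mean_length: int,
    composition: pd.Series | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """I.i.d. protein sequences with a given residue composition.

    Lengths are Poisson around ``mean_length`` (minimum 30).  Returns
    (id, sequence) pairs; empirical frequencies converge to the composition.
    """
    if composition is None:
        composition = pd.Series(1.0 / len(CANONICAL), index=list(CANONICAL))
    if not math.isclose(float(composition.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("composition must sum to 1")
    rng = np.random.default_rng([seed, 11])
    letters = np.array(list(composition.index))
    probs = composition.to_numpy(float)
    out = []
    for i in range(n_proteins):
        length = max(30, int(rng.poisson(mean_length)))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        out.append((f"prot{i + 1}", seq))
    return out


def write_proteome_fasta(proteome: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteome:
            fh.write(f">{pid}\n{seq}\n")


def make_mhc_pool(
    n: int,
    seed: int = 0,
    length_range: tuple[int, int] = (8, 14),
    context_length: int = 10,
    composition: pd.Series | None = None,
) -> list[MhcPeptideRecord]:
    """Random MHC-I-like peptides (8–14-mers over the canonical alphabet)
    with downstream parent-protein context for assay-peptide construction."""
    if composition is None:
        composition = pd.Series(1.0 / len(CANONICAL), index=list(CANONICAL))
    rng = np.random.default_rng([seed, 13])
    letters = np.array(list(composition.index))
    probs = composition.to_numpy(float)
    records = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        pep = "".join(rng.choice(letters, size=length, p=probs))
        ctx = "".join(rng.choice(letters, size=context_length, p=probs))
        records.append(MhcPeptideRecord(peptide=pep, parent_context=ctx,
                                        source_id=f"mhc{i + 1}"))
    return records
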