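"""MHC I cleavage scoring, assay-peptide construction, balanced selection,
and C-terminal residue enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import proteospec as ps
from proteospec.library import POSITIONS
from proteospec.mhc import CANONICAL


def _matrix(alphabet=CANONICAL, n_obs=100):
    k = len(alphabet)
    freq = pd.DataFrame(1.0 / k, index=list(POSITIONS), columns=list(alphabet))
    return ps.FrequencyMatrix(freq=freq, n_obs=pd.Series(n_obs, index=freq.index))


class TestCleavageScore:
    def test_uniform_matrices(self):
        m = _matrix()
        sc = ps.cleavage_score("SIINFEKL", m, m)
        assert sc.s_iP == pytest.approx(0.05 ** 4)
        assert sc.s_cP == pytest.approx(0.05 ** 4)
        assert sc.log2_ratio == pytest.approx(0.0)

    def test_single_cell_drives_ratio(self):
        ip = _matrix()
        cp = _matrix()
        ip.freq.loc["P1", "W"] = 0.20
        cp.freq.loc["P1", "W"] = 0.05
        sc = ps.cleavage_score("KNTFPKW", ip, cp)
        assert sc.log2_ratio == pytest.approx(2.0)

    def test_only_last_four_residues_matter(self):
        rng = np.random.default_rng(0)
        ip, cp = _matrix(), _matrix()
        ip.freq.loc["P1", "L"] = 0.3
        for pep in ("AAAAFEKL", "WWWWFEKL", "FEKL"):
            sc = ps.cleavage_score(pep, ip, cp)
            ref = ps.cleavage_score("FEKL", ip, cp)
            assert sc == ref

    def test_met_maps_to_norleucine_or_errors(self):
        lib_alpha = ps.ALPHABET  # no Met, has 'n'
        ip, cp = _matrix(lib_alpha), _matrix(lib_alpha)
        ip.freq.loc["P1", "n"] = 0.2
        sc = ps.cleavage_score("AAAM", ip, cp, met_policy="nle")
        assert sc.s_iP == pytest.approx(0.2 * (1 / 20) ** 3)
        with pytest.raises(KeyError):
            ps.cleavage_score("AAAM", ip, cp, met_policy="error")

    def test_score_tracks_true_hazard_ratio(self, truth_ip, truth_cp):
        """Scoring a random peptide pool with the generator's own positional
        frequencies must rank peptides like the true non-prime hazard ratio
        at the scissile bond (prime-side effects are absent here, so the
        correlation is high but need not be 1)."""
        pool = ps.make_mhc_pool(300, seed=4)
        ip_m = truth_ip.to_frequency_matrix()
        cp_m = truth_cp.to_frequency_matrix()
        scored, truth_ratio = [], []
        for rec in pool:
            sc = ps.cleavage_score(rec, ip_m, cp_m)
            scored.append(sc.log2_ratio)
            assay, bond = ps.build_assay_peptide(rec)
            num = truth_ip.hazard_multiplier(assay, bond)
            den = truth_cp.hazard_multiplier(assay, bond)
            truth_ratio.append(math.log2(num / den))
        rho = spearmanr(scored, truth_ratio).statistic
        assert rho >= 0.8


class TestBuildAssayPeptide:
    @pytest.mark.parametrize(
        "peptide, context, expected",
        [
            ("HTQVIEL", "ERKFSHQLVK", "HTQVIELERKFSHQ"),
            ("KNTFPKW", "KPGSLASWWWW", "KNTFPKWKPGSLAS"),
            ("XHTQVIEL".replace("X", "A"), "ERKFSHQ", "HTQVIELERKFSHQ"),
        ],
    )
    def test_seven_plus_seven_construction(self, peptide, context, expected):
        seq, bond = ps.build_assay_peptide(
            ps.MhcPeptideRecord(peptide=peptide, parent_context=context)
        )
        assert seq == expected
        assert len(seq) == 14
        assert bond == 7

    def test_short_context_rejected(self):
        rec = ps.MhcPeptideRecord(peptide="HTQVIEL", parent_context="ERK")
        with pytest.raises(ValueError, match="context"):
            ps.build_assay_peptide(rec)


class TestSelectBalancedLibrary:
    def _pool(self, ratios, seed=0):
        """Candidates whose P1 residue fixes their log2 ratio."""
        ip, cp = _matrix(), _matrix()
        ip.freq.loc["P1", "W"] = 0.4
        cp.freq.loc["P1", "W"] = 0.025
        recs = []
        rng = np.random.default_rng(seed)
        for i, hot in enumerate(ratios):
            tail = "W" if hot else "A"
            pep = "".join(rng.choice(list("ACDEFG"), size=8)) + tail
            recs.append(ps.MhcPeptideRecord(pep, "AAAAAAA", f"c{i}"))
        return recs, ip, cp

    def test_same_seed_is_reproducible(self):
        recs, ip, cp = self._pool([i % 2 == 0 for i in range(40)])
        a = ps.select_balanced_library(recs, ip, cp, n=10, seed=11)
        b = ps.select_balanced_library(recs, ip, cp, n=10, seed=11)
        assert [r.source_id for r in a] == [r.source_id for r in b]

    def test_two_extreme_groups_split_evenly(self):
        recs, ip, cp = self._pool([i < 20 for i in range(40)])
        chosen = ps.select_balanced_library(recs, ip, cp, n=10, seed=2)
        n_hot = sum(r.peptide.endswith("W") for r in chosen)
        assert n_hot == 5

    def test_identical_scores_fall_back_to_simple_sample(self):
        recs, ip, cp = self._pool([False] * 30)
        chosen = ps.select_balanced_library(recs, ip, cp, n=7, seed=3)
        assert len(chosen) == 7
        assert len({r.source_id for r in chosen}) == 7

    @staticmethod
    def _jittered(truth, seed):
        """Assay-like continuous frequencies: truth with lognormal jitter
        (a truth-preset matrix has many tied cells, which real estimated
        frequencies never do)."""
        m = truth.to_frequency_matrix()
        rng = np.random.default_rng(seed)
        freq = m.freq * rng.lognormal(0.0, 0.2, size=m.freq.shape)
        freq = freq.div(freq.sum(axis=1), axis=0)
        return ps.FrequencyMatrix(freq=freq, n_obs=m.n_obs)

    def test_selection_mean_tracks_pool_mean(self, truth_ip, truth_cp):
        pool = ps.make_mhc_pool(1000, seed=8)
        ip_m = self._jittered(truth_ip, 81)
        cp_m = self._jittered(truth_cp, 82)
        chosen = ps.select_balanced_library(pool, ip_m, cp_m, n=95, seed=8)
        pool_mean = np.mean([
            ps.cleavage_score(r, ip_m, cp_m).log2_ratio for r in pool
        ])
        sel_mean = np.mean([
            ps.cleavage_score(r, ip_m, cp_m).log2_ratio for r in chosen
        ])
        assert abs(sel_mean - pool_mean) <= 0.1

    def test_per_bin_counts_stable_across_seeds(self, truth_ip, truth_cp):
        pool = ps.make_mhc_pool(200, seed=9)
        ip_m = truth_ip.to_frequency_matrix()
        cp_m = truth_cp.to_frequency_matrix()
        sizes = set()
        for seed in (1, 2, 3):
            chosen = ps.select_balanced_library(pool, ip_m, cp_m, n=20, seed=seed)
            sizes.add(len(chosen))
        assert sizes == {20}

    def test_oversized_request_rejected(self):
        recs, ip, cp = self._pool([True] * 5)
        with pytest.raises(ValueError):
            ps.select_balanced_library(recs, ip, cp, n=6, seed=0)


class TestCtermEnrichment:
    def test_identical_distributions_are_flat(self):
        d = ps.ResidueDistribution(
            fractions=pd.Series({"W": 0.2, "L": 0.5, "K": 0.3}), n=100
        )
        out = ps.cterm_enrichment(d, d)
        assert (out["log2_enrichment"] == 0).all()

    def test_fourfold_depletion_is_minus_two(self):
        mhc = ps.ResidueDistribution(
            fractions=pd.Series({"W": 0.003, "L": 0.497, "K": 0.5}), n=10000
        )
        prot = ps.ResidueDistribution(
            fractions=pd.Series({"W": 0.012, "L": 0.488, "K": 0.5}), n=10000
        )
        out = ps.cterm_enrichment(mhc, prot).set_index("residue")
        assert out.at["W", "log2_enrichment"] == pytest.approx(-2.0)

    def test_absent_residue_floored_and_flagged(self):
        mhc = ps.ResidueDistribution(
            fractions=pd.Series({"W": 0.0, "L": 0.5, "K": 0.5}), n=200
        )
        prot = ps.ResidueDistribution(
            fractions=pd.Series({"W": 0.1, "L": 0.45, "K": 0.45}), n=1000
        )
        out = ps.cterm_enrichment(mhc, prot).set_index("residue")
        assert out.at["W", "flag"] == "floored"
        assert np.isfinite(out.at["W", "log2_enrichment"])
        assert out.at["W", "log2_enrichment"] < 0

    def test_alphabet_mismatch_rejected(self):
        a = ps.ResidueDistribution(fractions=pd.Series({"W": 1.0}), n=10)
        b = ps.ResidueDistribution(fractions=pd.Series({"L": 1.0}), n=10)
        with pytest.raises(ValueError):
            ps.cterm_enrichment(a, b)
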