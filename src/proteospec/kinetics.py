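"""Label-free relative cleavage-rate analysis.

Product peak areas tracked over an incubation time course approximate
first-order progress curves.  The initial rate of each curve is taken from
a least-squares line anchored at the origin over the curve's linear region;
per-substrate iP/cP selectivity is the log2 ratio of mean initial rates,
tested with a two-tailed two-sample Student's t-test on log2-scale
replicate rates and corrected for multiple testing with Storey q-values
(λ = 0, which coincides with Benjamini–Hochberg step-up adjustment).

Linear-region rule
------------------
Initial rates must be estimated before substrate depletion bends the
curve.  The fitted region is the implicit origin point (0, 0) plus the
longest prefix of timepoints whose areas stay at or below half of the
curve's maximum, extended to at least three observed points when the
prefix is shorter.  A curve already at plateau from its first point has no
linear region and is reported as rate 0 with a flag; a negative fitted
slope is clipped at 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Sampling schedule (minutes) of the MHC-peptide cleavage time course.
DEFAULT_RATE_TIMEPOINTS = (15.0, 30.0, 60.0, 120.0, 240.0, 1440.0, 2880.0)


@dataclass(frozen=True)
class ProgressCurve:
    """Peak-area time course for one product in one replicate."""

    product_id: str
    substrate_id: str
    enzyme: str
    replicate: int
    times: tuple[float, ...]
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.areas):
            raise ValueError("times and areas differ in length")
        if len(self.times) < 3:
            raise ValueError("a progress curve needs ≥ 3 timepoints")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(a < 0 for a in self.areas):
            raise ValueError("areas must be ≥ 0")


@dataclass(frozen=True)
class RateEstimate:
    """Initial rate (area per minute) with fit diagnostics."""

    v0: float
    n_points_used: int
    r_squared: float
    flag: str = ""
    product_id: str = ""
    substrate_id: str = ""
    enzyme: str = ""
    replicate: int = 0


@dataclass(frozen=True)
class SelectivityResult:
    """Per-substrate relative cleavage-rate comparison between two enzymes."""

    substrate_id: str
    mean_log2_ratio: float
    p_value: float
    q_value: float = math.nan
    n_replicates_a: int = 0
    n_replicates_b: int = 0
    flag: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.q_value < 0.05)


def initial_rate(
    curve: ProgressCurve,
    linear_frac: float = 0.5,
    min_points: int = 3,
) -> RateEstimate:
    """Initial rate from an origin-anchored least-squares fit.

    The regression is forced through (0, 0) — no product exists before the
    enzyme is added — over the linear region described in the module
    docstring.  ``r_squared`` is the uncentred coefficient of determination
    of the through-origin fit.
    """
    t = np.asarray(curve.times, dtype=float)
    a = np.asarray(curve.areas, dtype=float)
    meta = dict(product_id=curve.product_id, substrate_id=curve.substrate_id,
                enzyme=curve.enzyme, replicate=curve.replicate)

    if np.all(a == 0):
        return RateEstimate(v0=0.0, n_points_used=len(t), r_squared=1.0,
                            flag="all_zero", **meta)

    cutoff = linear_frac * a.max()
    k = 0
    while k < len(a) and a[k] <= cutoff:
        k += 1
    if k == 0:
        # plateau from the first observation: the linear region degenerates
        # to the origin anchor alone
        return RateEstimate(v0=0.0, n_points_used=0, r_squared=0.0,
                            flag="no_linear_region", **meta)
    k = min(max(k, min_points), len(t))
    tt, aa = t[:k], a[:k]

    slope = float(np.dot(tt, aa) / np.dot(tt, tt))
    resid = aa - slope * tt
    ss_tot = float(np.dot(aa, aa))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 0.0
    flag = ""
    if slope < 0:
        slope, flag = 0.0, "negative_slope_clipped"
    return RateEstimate(v0=slope, n_points_used=k, r_squared=max(r2, 0.0),
                        flag=flag, **meta)


def _per_replicate_rates(rates: Sequence[RateEstimate],
                         pair_products: bool) -> dict[int, float]:
    """Average a substrate's product rates within each replicate."""
    by_rep: dict[int, list[float]] = {}
    for r in rates:
        by_rep.setdefault(r.replicate, []).append(r.v0)
    if pair_products:
        return {rep: float(np.mean(v)) for rep, v in by_rep.items()}
    # unpaired: keep every product rate, synthesising pseudo-replicates
    out = {}
    i = 0
    for rep in sorted(by_rep):
        for v in by_rep[rep]:
            out[i] = v
            i += 1
    return out


def selectivity(
    rates_a: Sequence[RateEstimate],
    rates_b: Sequence[RateEstimate],
    pair_products: bool = True,
    substrate_id: str | None = None,
) -> SelectivityResult:
    """Relative cleavage rate of one substrate between two enzymes (pre-FDR).

    Rates of the substrate's two products are averaged within each
    replicate first, then across replicates; the reported statistic is
    ``log2(mean v_a / mean v_b)``.  The p-value is a two-tailed
    equal-variance t-test on log2-scale per-replicate rates (zero rates are
    floored at half the smallest positive rate of the substrate, flagged).
    A substrate quantified in only one enzyme is flagged infinite-selectivity
    and excluded from testing (p = NaN).
    """
    if substrate_id is None:
        pool = rates_a or rates_b
        substrate_id = pool[0].substrate_id if pool else ""
    va = _per_replicate_rates(rates_a, pair_products)
    vb = _per_replicate_rates(rates_b, pair_products)
    na, nb = len(va), len(vb)
    a = np.array(list(va.values()), float)
    b = np.array(list(vb.values()), float)

    mean_a = float(a.mean()) if na else 0.0
    mean_b = float(b.mean()) if nb else 0.0
    if na == 0 or nb == 0 or mean_a == 0.0 or mean_b == 0.0:
        ratio = math.inf if mean_a > 0 else (-math.inf if mean_b > 0 else 0.0)
        return SelectivityResult(substrate_id, ratio, math.nan,
                                 n_replicates_a=na, n_replicates_b=nb,
                                 flag="infinite_selectivity")
    flag = ""
    pooled = np.concatenate([a, b])
    positive = pooled[pooled > 0]
    floor = positive.min() / 2.0
    if (pooled <= 0).any():
        flag = "rate_floored"
    la = np.log2(np.maximum(a, floor))
    lb = np.log2(np.maximum(b, floor))
    ratio = math.log2(mean_a / mean_b)
    if na < 2 or nb < 2:
        return SelectivityResult(substrate_id, ratio, math.nan,
                                 n_replicates_a=na, n_replicates_b=nb,
                                 flag=(flag + ";" if flag else "") + "too_few_replicates")
    if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) and math.isclose(la[0], lb[0]):
        p = 1.0  # identical constant vectors: no evidence of a difference
    else:
        p = float(stats.ttest_ind(la, lb, equal_var=True).pvalue)
        if math.isnan(p):
            p = 1.0
    return SelectivityResult(substrate_id, ratio, p,
                             n_replicates_a=na, n_replicates_b=nb, flag=flag)


def storey_qvalues(p_values: Sequence[float], lam: float = 0.0) -> np.ndarray:
    """Storey q-values with tuning parameter λ.

    π̂0 = min(1, #{p > λ} / ((1 − λ)·m)); q-values are the monotone
    (step-up) adjusted values π̂0·m·p/rank with a cumulative minimum from
    the largest p.  At λ = 0, π̂0 = 1 and the result equals
    Benjamini–Hochberg adjusted p-values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 <= lam < 1:
        raise ValueError("λ must lie in [0, 1)")
    m = p.size
    pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def selectivity_analysis(
    curves: Sequence[ProgressCurve],
    enzyme_a: str,
    enzyme_b: str,
    pair_products: bool = True,
    linear_frac: float = 0.5,
    min_points: int = 3,
    lam: float = 0.0,
    enzyme_scale: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Full per-substrate selectivity table with q-values.

    Fits every curve, forms per-substrate selectivity between the two
    enzymes, and corrects the testable p-values with Storey's method.
    ``enzyme_scale`` optionally multiplies every rate of an enzyme by a
    global activity-normalisation factor (default 1).
    Columns: substrate_id, mean_log2_ratio, p_value, q_value, significant,
    n_replicates_a, n_replicates_b, flag.
    """
    scale = enzyme_scale or {}
    rates: dict[tuple[str, str], list[RateEstimate]] = {}
    for c in curves:
        est = initial_rate(c, linear_frac=linear_frac, min_points=min_points)
        s = scale.get(c.enzyme, 1.0)
        if s != 1.0:
            est = RateEstimate(v0=est.v0 * s, n_points_used=est.n_points_used,
                               r_squared=est.r_squared, flag=est.flag,
                               product_id=est.product_id,
                               substrate_id=est.substrate_id,
                               enzyme=est.enzyme, replicate=est.replicate)
        rates.setdefault((c.substrate_id, c.enzyme), []).append(est)

    substrates = sorted({sid for sid, _ in rates})
    results = [
        selectivity(rates.get((sid, enzyme_a), []), rates.get((sid, enzyme_b), []),
                    pair_products=pair_products, substrate_id=sid)
        for sid in substrates
    ]
    df = pd.DataFrame(
        [(r.substrate_id, r.mean_log2_ratio, r.p_value, r.n_replicates_a,
          r.n_replicates_b, r.flag) for r in results],
        columns=["substrate_id", "mean_log2_ratio", "p_value",
                 "n_replicates_a", "n_replicates_b", "flag"],
    )
    testable = df["p_value"].notna()
    df["q_value"] = np.nan
    if testable.any():
        df.loc[testable, "q_value"] = storey_qvalues(
            df.loc[testable, "p_value"].to_numpy(), lam=lam
        )
    df["significant"] = df["q_value"].lt(0.05).fillna(False)
    return df[["substrate_id", "mean_log2_ratio", "p_value", "q_value",
               "significant", "n_replicates_a", "n_replicates_b", "flag"]]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PEAK_AREA_COLUMNS = ["product_id", "substrate_id", "enzyme", "replicate",
                     "time_min", "area"]


def read_peak_area_table(path: str | Path) -> list[ProgressCurve]:
    """Long-format TSV (product_id, substrate_id, enzyme, replicate,
    time_min, area) → one :class:`ProgressCurve` per series."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_AREA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak-area table {path} missing columns: {missing}")
    curves = []
    keys = ["product_id", "substrate_id", "enzyme", "replicate"]
    for (pid, sid, enz, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_min")
        curves.append(ProgressCurve(
            product_id=str(pid), substrate_id=str(sid), enzyme=str(enz),
            replicate=int(rep), times=tuple(grp["time_min"].astype(float)),
            areas=tuple(grp["area"].astype(float)),
        ))
    return curves


def write_peak_area_table(curves: Sequence[ProgressCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, a in zip(c.times, c.areas):
            rows.append((c.product_id, c.substrate_id, c.enzyme, c.replicate, t, a))
    pd.DataFrame(rows, columns=PEAK_AREA_COLUMNS).to_csv(path, sep="\t", index=False)
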