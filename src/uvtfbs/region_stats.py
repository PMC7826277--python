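"""Goodness-of-fit, homogeneity and G-tests for region summaries.

Cells with expected counts below 5 are pooled deterministically left-to-right
with their neighbour before testing (standard chi-squared practice).  Raw
p-values are reported (no correction), matching the P < 0.05 convention of
the source analyses; a Benjamini-Hochberg column is additionally provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .window_stacking import WindowStack, REGIONS


@dataclass
class RegionSummary:
    motif_id: str
    region: str
    metric: str
    observed_sum: float
    expected_sum: float
    log2_ratio: float
    statistic: float
    p_value: float
    test: str
    significant: bool = False

    def __post_init__(self):
        self.significant = bool(np.isfinite(self.p_value) and self.p_value < 0.05)


def pool_low_expected(
    observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pool adjacent cells left-to-right until every expected cell >= 5.

    A trailing under-threshold cell is merged backwards into the previous
    one.  May return a single cell if totals are small.
    """
    obs_out: list[float] = []
    exp_out: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_out.append(acc_o)
            exp_out.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if exp_out:
            obs_out[-1] += acc_o
            exp_out[-1] += acc_e
        else:
            obs_out, exp_out = [acc_o], [acc_e]
    return np.asarray(obs_out, dtype=float), np.asarray(exp_out, dtype=float)


def _prepare(observed, expected, min_expected):
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have the same shape")
    if np.any(expected < 0) or np.any(observed < 0):
        raise ValueError("counts must be non-negative")
    total_o, total_e = observed.sum(), expected.sum()
    if total_o <= 0 or total_e <= 0:
        return None
    expected = expected * (total_o / total_e)  # scale to observed total
    return pool_low_expected(observed, expected, min_expected)


def chi2_gof(observed, expected, min_expected: float = 5.0) -> tuple[float, float]:
    """Pearson chi-squared goodness of fit; df = ncells - 1 after pooling.

    Returns (nan, nan) when fewer than 2 cells remain after pooling.
    """
    prep = _prepare(observed, expected, min_expected)
    if prep is None:
        return float("nan"), float("nan")
    obs, exp = prep
    if obs.size < 2:
        return float("nan"), float("nan")
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(stat, df=obs.size - 1))
    return stat, p


def g_test(observed, expected, min_expected: float = 5.0) -> tuple[float, float]:
    """Log-likelihood-ratio (G) goodness of fit; df = ncells - 1 after pooling."""
    prep = _prepare(observed, expected, min_expected)
    if prep is None:
        return float("nan"), float("nan")
    obs, exp = prep
    if obs.size < 2:
        return float("nan"), float("nan")
    nz = obs > 0
    stat = float(2.0 * (obs[nz] * np.log(obs[nz] / exp[nz])).sum())
    p = float(stats.chi2.sf(stat, df=obs.size - 1))
    return stat, p


def poisson_g_test(observed: float, expected: float) -> tuple[float, float]:
    """Poisson deviance G-test of one observed count against its expectation.

    G = 2*(O*ln(O/E) - (O - E)), df = 1.  Used for single dipyrimidine-site
    calls where the expectation comes from flank sampling.
    """
    if expected <= 0:
        return float("nan"), float("nan")
    o, e = float(observed), float(expected)
    term = o * np.log(o / e) if o > 0 else 0.0
    stat = float(2.0 * (term - (o - e)))
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=1))


def chi2_homogeneity(counts_t0, counts_t48, min_expected: float = 5.0) -> tuple[float, float]:
    """2 x k contingency chi-squared comparing two timepoint count vectors.

    Columns are pooled left-to-right until the smaller row's expected count
    reaches ``min_expected``.  Returns (nan, nan) when a timepoint has zero
    total or fewer than 2 columns remain.
    """
    c0 = np.asarray(counts_t0, dtype=float)
    c1 = np.asarray(counts_t48, dtype=float)
    if c0.shape != c1.shape:
        raise ValueError("count vectors must have the same shape")
    t0, t1 = c0.sum(), c1.sum()
    if t0 <= 0 or t1 <= 0:
        return float("nan"), float("nan")
    # pool so the *smaller-margin* expected count clears the threshold
    frac = min(t0, t1) / (t0 + t1)
    combined = c0 + c1
    pooled0, pooled1 = [], []
    a0 = a1 = acc = 0.0
    for x0, x1, c in zip(c0, c1, combined):
        a0 += x0
        a1 += x1
        acc += c
        if acc * frac >= min_expected:
            pooled0.append(a0)
            pooled1.append(a1)
            a0 = a1 = acc = 0.0
    if acc > 0 and pooled0:
        pooled0[-1] += a0
        pooled1[-1] += a1
    table = np.array([pooled0, pooled1])
    if table.shape[1] < 2:
        return float("nan"), float("nan")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


_TESTS = {"chi2_gof": chi2_gof, "g_test": g_test}


def region_level_test(
    observed: np.ndarray,
    expected: np.ndarray,
    mask: np.ndarray,
    test: str = "g_test",
) -> tuple[float, float]:
    """Test a region's LEVEL against expectation: 2 cells, region vs rest."""
    o = np.array([observed[mask].sum(), observed[~mask].sum()])
    e = np.array([expected[mask].sum(), expected[~mask].sum()])
    return _TESTS[test](o, e)


def summarize_regions(
    stack: WindowStack,
    observed_track: str = "mutations",
    expected_track: str = "expected_mutations",
    metric: str = "mutations",
    test: str = "g_test",
) -> list[RegionSummary]:
    """One RegionSummary per region for an observed/expected track pair.

    The log2 ratio compares region sums; the significance call asks whether
    the region's share of the window deviates from its expected share
    (2-cell region-vs-rest comparison with the chosen test).
    """
    observed = stack.tracks[observed_track]
    expected = stack.tracks[expected_track]
    out = []
    for region in REGIONS:
        mask = stack.regions.masks[region]
        o, e = float(observed[mask].sum()), float(expected[mask].sum())
        ratio = float(np.log2(o / e)) if o > 0 and e > 0 else float("nan")
        stat, p = region_level_test(observed, expected, mask, test)
        out.append(
            RegionSummary(stack.motif_id, region, metric, o, e, ratio, stat, p, test)
        )
    return out


def summaries_frame(summaries: list[RegionSummary]) -> pd.DataFrame:
    df = pd.DataFrame([vars(s) for s in summaries])
    pvals = df["p_value"].to_numpy()
    fdr = np.full_like(pvals, np.nan, dtype=float)
    ok = np.isfinite(pvals)
    if ok.any():
        fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    df["fdr_bh"] = fdr
    return df
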