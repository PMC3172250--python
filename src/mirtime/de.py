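"""Chi-square differential expression over the time course, with BH FDR.

Each miRNA's per-sample counts are tested for homogeneity against
expectations proportional to per-sample effective depths (a goodness-of-fit
chi-square with ``n_samples - 1`` degrees of freedom); a miRNA whose
expression merely tracks sequencing depth scores 0. Effective depths come
from median-of-ratios size factors refined on the stable majority, so a
minority of strongly induced miRNAs does not drag every flat miRNA into
significance through compositional shift. P values are adjusted across miRNAs by
Benjamini-Hochberg and significance is called at qFDR < alpha (strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class DEResult:
    mirna: str
    chi2: float
    df: int
    p: float
    qfdr: float
    significant: bool
    low_expected: bool = False


def chisq_timecourse_test(
    counts: Sequence[float], totals: Sequence[float]
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of one miRNA's counts against library totals.

    ``expected_i = sum(counts) * total_i / sum(totals)``;
    ``chi2 = sum((obs - exp)^2 / exp)``; df = n_samples - 1; upper-tail p.
    """
    obs = np.asarray(counts, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if obs.shape != tot.shape or obs.ndim != 1:
        raise InputError("counts and totals must be 1-D and equal length")
    if len(obs) < 2:
        raise InputError("need >= 2 samples")
    if (tot <= 0).any():
        raise InputError("library totals must be positive")
    if obs.sum() <= 0:
        raise InputError("all-zero count row is untestable")
    expected = obs.sum() * tot / tot.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios effective depth per sample.

    The ratio of each sample's counts to the per-row geometric mean is
    taken over rows with all-positive counts; the per-sample median is
    robust to a minority of strongly regulated rows, so flat-abundance
    miRNAs are not swept into significance when a few features surge.
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if positive.sum() < 10:
        raise InputError("too few all-positive rows for size factors")
    sub = values[positive]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return factors


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must be finite in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def de_table(
    counts: pd.DataFrame, alpha: float = 0.05, robust: bool = True
) -> pd.DataFrame:
    """Chi-square test for every row of a count matrix.

    Expected counts are proportional to per-sample effective depths:
    median-of-ratios size factors by default (``robust=True``), raw column
    totals otherwise. Returns a DataFrame with columns ``chi2, df, p, qfdr,
    significant, low_expected, untestable`` indexed by miRNA. All-zero rows
    are flagged untestable and excluded from testing/adjustment; rows with
    any expected count below 1 are tested but flagged ``low_expected``.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    raw_totals = counts.sum(axis=0).to_numpy(dtype=float)
    if (raw_totals <= 0).any():
        bad = list(counts.columns[raw_totals <= 0])
        raise InputError(f"zero library total for sample(s) {bad}")
    rows = counts.to_numpy(dtype=float)
    untestable = rows.sum(axis=1) <= 0

    out = pd.DataFrame(
        index=counts.index,
        data={
            "chi2": np.nan,
            "df": counts.shape[1] - 1,
            "p": np.nan,
            "qfdr": np.nan,
            "significant": False,
            "low_expected": False,
            "untestable": untestable,
        },
    )
    testable_idx = np.flatnonzero(~untestable)
    if len(testable_idx) == 0:
        return out
    sub = rows[testable_idx]
    df = counts.shape[1] - 1

    def run_test(totals: np.ndarray):
        expected = sub.sum(axis=1, keepdims=True) * totals / totals.sum()
        chi2 = ((sub - expected) ** 2 / expected).sum(axis=1)
        p = stats.chi2.sf(chi2, df)
        return expected, chi2, p, np.asarray(bh_fdr(p))

    if robust:
        # start from median-of-ratios depths, then refine on the stable
        # majority: depths are re-estimated as column sums over rows not
        # currently called significant (the Poisson MLE given those rows),
        # so abundant flat miRNAs are not rejected for sub-percent depth
        # misfit when a minority of features surges
        totals = size_factors(counts) * raw_totals.mean()
        expected, chi2, p, q = run_test(totals)
        for _ in range(3):
            stable = q >= alpha
            if stable.sum() < 10:
                break
            totals = sub[stable].sum(axis=0)
            expected, chi2, p, q = run_test(totals)
    else:
        expected, chi2, p, q = run_test(raw_totals)
    out.iloc[testable_idx, out.columns.get_loc("chi2")] = chi2
    out.iloc[testable_idx, out.columns.get_loc("p")] = p
    out.iloc[testable_idx, out.columns.get_loc("qfdr")] = q
    out.iloc[testable_idx, out.columns.get_loc("significant")] = q < alpha
    out.iloc[testable_idx, out.columns.get_loc("low_expected")] = (expected < 1).any(
        axis=1
    )
    return out


def select_de(results: pd.DataFrame | Iterable[DEResult], alpha: float = 0.05) -> set[str]:
    """Ids with qfdr strictly below alpha."""
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if isinstance(results, pd.DataFrame):
        q = results["qfdr"]
        return set(results.index[q < alpha])
    return {r.mirna for r in results if r.qfdr < alpha}
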