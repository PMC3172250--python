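"""Inverse miRNA-target pair selection.

Differentially expressed mRNAs are found with the random variance model
(RVM) moderated F-test: per-gene residual variances across the replicated
time-point groups are assumed to follow an inverse-gamma distribution
shared across genes, equivalent to ``s2 * a * b ~ F(df_error, 2a)``. The
hyperparameters (a, b) are fit by maximum likelihood on the observed
residual variances, and each gene's F statistic is moderated by adding
``2/b`` pseudo sum-of-squares and ``2a`` pseudo degrees of freedom to the
error term — stabilizing variance estimates when replication is thin.

Selected mRNAs are then correlated with each category miRNA's time course
over the per-day means (n = 5 day means; two-sided t test on
``t = r * sqrt(n-2) / sqrt(1-r^2)`` with n-2 df). A predicted target is
reported as an *inverse pair* when r < 0 and p < 0.1 (strict), the
signature of repression by an up-regulated miRNA.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .de import bh_fdr
from .errors import ConfigurationError, InputError
from .enrichment import TargetMap
from .network import Category


@dataclass(frozen=True)
class RVMFit:
    """Inverse-gamma variance-prior hyperparameters and fit diagnostics."""

    a: float
    b: float
    loglik: float
    df_error: int


@dataclass(frozen=True)
class InversePair:
    mirna: str
    gene: str
    r: float
    p: float
    category: str


# ---------------------------------------------------------------------------
# RVM moderated F


def _group_stats(
    values: np.ndarray, groups: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-gene between-group MS and residual SS for a one-way layout."""
    labels = pd.Series(groups)
    uniq = list(dict.fromkeys(labels))
    k = len(uniq)
    n = values.shape[1]
    if k < 2:
        raise InputError("need >= 2 time-point groups")
    counts = np.array([(labels == g).sum() for g in uniq])
    if (counts < 2).any():
        raise InputError(
            "need >= 2 replicates per group for a residual variance"
        )
    grand = values.mean(axis=1, keepdims=True)
    ss_between = np.zeros(values.shape[0])
    ss_error = np.zeros(values.shape[0])
    for g, c in zip(uniq, counts):
        cols = (labels == g).to_numpy()
        gm = values[:, cols].mean(axis=1, keepdims=True)
        ss_between += c * ((gm - grand) ** 2).ravel()
        ss_error += ((values[:, cols] - gm) ** 2).sum(axis=1)
    return ss_between, ss_error, k, n - k


def fit_rvm(s2: np.ndarray, df_error: int) -> RVMFit:
    """ML fit of the shared variance prior from residual variances.

    Under the model, ``s2 * a * b ~ F(df_error, 2a)``; the likelihood of an
    observed variance is ``a * b * f_F(a * b * s2; df_error, 2a)``. Optimized
    over (log a, log b) with Nelder-Mead from a moment-based start.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 10:
        raise InputError("too few positive residual variances to fit RVM")

    mean_s2 = float(s2.mean())

    def nll(theta: np.ndarray) -> float:
        a, b = math.exp(theta[0]), math.exp(theta[1])
        x = a * b * s2
        ll = np.log(a * b) + stats.f.logpdf(x, df_error, 2 * a)
        if not np.isfinite(ll).all():
            return 1e12
        return -float(ll.sum())

    # moment start: E[s2] = 1 / (b (a - 1)) for a > 1
    a0 = 3.0
    b0 = 1.0 / (mean_s2 * (a0 - 1.0))
    res = optimize.minimize(
        nll,
        x0=[math.log(a0), math.log(b0)],
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    a, b = math.exp(res.x[0]), math.exp(res.x[1])
    return RVMFit(a=a, b=b, loglik=-float(res.fun), df_error=df_error)


def rvm_adjusted_f(
    expr: pd.DataFrame, groups: Sequence[str] | None = None
) -> tuple[pd.DataFrame, RVMFit]:
    """RVM moderated one-way F-test per gene across time-point groups.

    ``groups`` labels each column with its time point; if omitted, labels
    are parsed from column names of the form ``d<day>_r<replicate>``.
    Returns a per-gene table (F_adj, p, qfdr, s2) and the fitted prior.

    The moderated statistic is
    ``F_adj = MS_between / ((SS_error + 2/b) / (df_error + 2a))`` with null
    distribution ``F(k - 1, df_error + 2a)``.
    """
    if groups is None:
        groups = [re.sub(r"_r\d+$", "", str(c)) for c in expr.columns]
    if len(groups) != expr.shape[1]:
        raise InputError("one group label per column required")
    values = expr.to_numpy(dtype=float)
    ss_between, ss_error, k, df_error = _group_stats(values, groups)
    s2 = ss_error / df_error
    fit = fit_rvm(s2, df_error)
    ms_between = ss_between / (k - 1)
    denom = (ss_error + 2.0 / fit.b) / (df_error + 2.0 * fit.a)
    f_adj = ms_between / denom
    p = stats.f.sf(f_adj, k - 1, df_error + 2.0 * fit.a)
    q = np.asarray(bh_fdr(p))
    table = pd.DataFrame(
        {
            "F_adj": f_adj,
            "p": p,
            "qfdr": q,
            "s2": s2,
            "significant": q < 0.05,
        },
        index=expr.index,
    )
    return table, fit


# ---------------------------------------------------------------------------
# Correlation test


def pearson_corr_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and the two-sided t-test p-value.

    ``t = r * sqrt(n-2) / sqrt(1 - r^2)`` with n-2 degrees of freedom;
    |r| = 1 gives p = 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InputError("series must be 1-D and equal length")
    n = len(xa)
    if n < 3:
        raise InputError("need n >= 3 for a correlation test")
    if xa.std() == 0 or ya.std() == 0:
        raise InputError("correlation undefined for a constant series")
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


# ---------------------------------------------------------------------------
# Pair selection


def collapse_replicates(expr: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns ``d<day>_r<i>`` into per-day means ``d<day>``."""
    day_of = {}
    for c in expr.columns:
        day_of.setdefault(re.sub(r"_r\d+$", "", str(c)), []).append(c)

    def day_key(label: str) -> float:
        m = re.search(r"(\d+(?:\.\d+)?)", label)
        return float(m.group(1)) if m else math.inf

    days = sorted(day_of, key=day_key)
    return pd.DataFrame(
        {d: expr[day_of[d]].mean(axis=1) for d in days}, index=expr.index
    )


def select_inverse_pairs(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    targets: TargetMap,
    de_genes: Iterable[str],
    categories: Sequence[Category],
    p_threshold: float = 0.1,
) -> list[InversePair]:
    """Inverse (r < 0, p < threshold) miRNA-target pairs per category.

    For every category miRNA and every intersected-target gene that is
    differentially expressed, the miRNA's day series is correlated with the
    gene's day-mean series; pairs pass on r < 0 AND p < p_threshold, both
    strict. Output is sorted by category label, then ascending p, then
    (mirna, gene) — invariant to input row order.
    """
    if not 0 <= p_threshold <= 1:
        raise ConfigurationError(f"p_threshold must be in [0, 1], got {p_threshold}")
    mrna_days = collapse_replicates(mrna_expr)
    missing = [c for c in mirna_expr.columns if c not in mrna_days.columns]
    extra = [c for c in mrna_days.columns if c not in mirna_expr.columns]
    if missing or extra:
        raise InputError(
            f"day columns mismatch: missing from mRNA {missing}, "
            f"extra in mRNA {extra}"
        )
    mrna_days = mrna_days[list(mirna_expr.columns)]
    de_genes = set(de_genes)
    out: list[InversePair] = []
    for cat in categories:
        for mirna in sorted(cat.members):
            if mirna not in targets or mirna not in mirna_expr.index:
                continue
            x = mirna_expr.loc[mirna].to_numpy(dtype=float)
            if x.std() == 0:
                continue
            for gene in sorted(targets[mirna] & de_genes):
                if gene not in mrna_days.index:
                    continue
                y = mrna_days.loc[gene].to_numpy(dtype=float)
                if y.std() == 0:
                    continue
                r, p = pearson_corr_test(x, y)
                if r < 0 and p < p_threshold:
                    out.append(
                        InversePair(
                            mirna=mirna, gene=gene, r=r, p=p, category=cat.label
                        )
                    )
    out.sort(key=lambda ip: (ip.category, ip.p, ip.mirna, ip.gene))
    return out


def write_pairs_tsv(pairs: list[InversePair], path) -> None:
    """Write pairs with r and p at 3 decimals, mirroring the report layout."""
    with open(path, "w") as fh:
        fh.write("category\tmirna\tgene\tr\tp\n")
        for ip in pairs:
            fh.write(
                f"{ip.category}\t{ip.mirna}\t{ip.gene}\t{ip.r:.3f}\t{ip.p:.3f}\n"
            )
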