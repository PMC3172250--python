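"""Hierarchical clustering and STEM-style template-profile clustering.

Short time courses (5 points here) cannot support model-based clustering,
so the profile stage follows the Short Time-series Expression Miner recipe:

1. enumerate all candidate temporal templates that start at 0 and change by
   at most ``c`` integer units between consecutive time points;
2. greedily select ``m`` mutually distinct representatives (max-min
   distance, distance = 1 - Pearson correlation);
3. assign each feature's time course — re-anchored to its first time point —
   to the best-correlating template;
4. judge each template's occupancy against a permutation null: time-point
   order is permuted, features are reassigned, and the observed count is
   compared with a binomial tail at the mean permuted occupancy, with BH
   adjustment across templates.

Template shapes are classified as monotone-up (the "profile 6" analogue),
up-then-down ("profile 9"), or other.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, InputError
from .de import bh_fdr

MONOTONE_UP = "monotone_up"
UP_DOWN = "up_down"
OTHER = "other"


@dataclass(frozen=True)
class ProfileTemplate:
    """A model temporal profile; ``vector`` starts at 0 by construction."""

    id: int
    vector: tuple[float, ...]

    @property
    def shape(self) -> str:
        return classify_shape(self)


@dataclass(frozen=True)
class ProfileAssignment:
    mirna: str
    profile: int
    correlation: float


@dataclass(frozen=True)
class ProfileSignificance:
    profile: int
    observed: int
    expected: float
    p: float
    qfdr: float


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree with deterministic leaf order."""

    ids: tuple[str, ...]
    linkage: np.ndarray
    leaf_order: tuple[str, ...]
    heights: tuple[float, ...]


# ---------------------------------------------------------------------------
# Hierarchical clustering (heatmap ordering)


def hier_cluster(
    m: pd.DataFrame, metric: str = "euclidean", linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of matrix rows under the named linkage."""
    values = m.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise InputError("hier_cluster needs >= 2 rows")
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        raise InputError(
            f"non-finite values in rows: {list(m.index[bad])[:10]}"
        )
    # stable row order in the condensed distance matrix makes scipy's
    # agglomeration deterministic; ties then resolve to the smaller index,
    # i.e. the smaller id under the sorted input convention
    Z = hierarchy.linkage(pdist(values, metric=metric), method=linkage)
    order = hierarchy.leaves_list(Z)
    ids = tuple(str(i) for i in m.index)
    return Dendrogram(
        ids=ids,
        linkage=Z,
        leaf_order=tuple(ids[i] for i in order),
        heights=tuple(float(h) for h in Z[:, 2]),
    )


# ---------------------------------------------------------------------------
# Template construction and selection


def gen_candidate_profiles(n_timepoints: int, c: int = 1) -> list[ProfileTemplate]:
    """All profiles starting at 0 with successive integer steps in [-c, c].

    Yields ``(2c+1)**(n_timepoints-1)`` distinct templates, in the
    enumeration order that downstream tie-breaks refer to.
    """
    if n_timepoints < 2:
        raise ConfigurationError("need >= 2 time points")
    if c < 1:
        raise ConfigurationError("unit-change bound c must be >= 1")
    steps = range(-c, c + 1)
    templates = []
    for i, diffs in enumerate(itertools.product(steps, repeat=n_timepoints - 1)):
        vec = (0.0, *itertools.accumulate(diffs))
        templates.append(ProfileTemplate(id=i, vector=tuple(float(v) for v in vec)))
    return templates


def _template_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson correlation; Euclidean fallback when either is constant."""
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return float(np.linalg.norm(u - v))
    r = float(np.corrcoef(u, v)[0, 1])
    return 1.0 - r


def select_distinct_profiles(
    candidates: list[ProfileTemplate], m: int
) -> list[ProfileTemplate]:
    """Greedy max-min selection of ``m`` mutually distinct templates.

    Starts from the flat profile and repeatedly adds the candidate whose
    minimum distance to the chosen set is largest; ties break to the
    earliest candidate in enumeration order. Selected templates are re-id'd
    0..m-1 in selection order (flat template is id 0).
    """
    if m <= 0:
        raise ConfigurationError(f"m must be positive, got {m}")
    if m > len(candidates):
        raise ConfigurationError(
            f"m={m} exceeds {len(candidates)} candidates"
        )
    vecs = [np.asarray(t.vector, dtype=float) for t in candidates]
    flat_pos = next(
        i for i, v in enumerate(vecs) if np.all(v == 0)
    )
    chosen_pos = [flat_pos]
    min_dist = np.array(
        [_template_distance(v, vecs[flat_pos]) for v in vecs]
    )
    min_dist[flat_pos] = -np.inf
    while len(chosen_pos) < m:
        nxt = int(np.argmax(min_dist))  # argmax takes the first maximum: tie-break
        chosen_pos.append(nxt)
        new = np.array([_template_distance(v, vecs[nxt]) for v in vecs])
        min_dist = np.minimum(min_dist, new)
        min_dist[nxt] = -np.inf
    return [
        ProfileTemplate(id=k, vector=candidates[pos].vector)
        for k, pos in enumerate(chosen_pos)
    ]


# ---------------------------------------------------------------------------
# Assignment and permutation significance


def _anchor(values: np.ndarray) -> np.ndarray:
    """Change-from-first-timepoint transform, row-wise."""
    return values - values[:, [0]]


def _assign_matrix(values: np.ndarray, tvecs: np.ndarray) -> np.ndarray:
    """Best-correlating template index per row of an anchored value matrix.

    Constant templates get correlation -inf; constant (zero-variance) rows
    go to the flat template if present, else to template 0. Ties resolve to
    the lower template id.
    """
    n, T = values.shape
    t_sd = tvecs.std(axis=1)
    t_std = np.zeros_like(tvecs)
    nz = t_sd > 0
    t_std[nz] = (tvecs[nz] - tvecs[nz].mean(axis=1, keepdims=True)) / (
        t_sd[nz, None] * math.sqrt(T)
    )
    r_sd = values.std(axis=1)
    rows_nz = r_sd > 0
    v_std = np.zeros_like(values)
    v_std[rows_nz] = (
        values[rows_nz] - values[rows_nz].mean(axis=1, keepdims=True)
    ) / (r_sd[rows_nz, None] * math.sqrt(T))
    corr = v_std @ t_std.T  # rows x templates
    corr[:, ~nz] = -np.inf
    # argmax picks the first (lowest id) on ties
    best = corr.argmax(axis=1)
    flat_candidates = np.flatnonzero(~nz)
    flat_idx = int(flat_candidates[0]) if len(flat_candidates) else 0
    best[~rows_nz] = flat_idx
    return best


def assign_to_profiles(
    m: pd.DataFrame, templates: list[ProfileTemplate]
) -> list[ProfileAssignment]:
    """Assign each row (anchored to t0) to its best-correlating template."""
    tvecs = np.array([t.vector for t in templates], dtype=float)
    if tvecs.shape[1] != m.shape[1]:
        raise InputError(
            f"template length {tvecs.shape[1]} != {m.shape[1]} time points"
        )
    values = _anchor(m.to_numpy(dtype=float))
    best = _assign_matrix(values, tvecs)
    out = []
    for i, mid in enumerate(m.index):
        j = int(best[i])
        row, tv = values[i], tvecs[j]
        if row.std() > 0 and tv.std() > 0:
            corr = float(np.corrcoef(row, tv)[0, 1])
        else:
            corr = 0.0
        out.append(
            ProfileAssignment(
                mirna=str(mid), profile=templates[j].id, correlation=corr
            )
        )
    return out


def profile_significance(
    assignments: list[ProfileAssignment],
    m: pd.DataFrame,
    templates: list[ProfileTemplate],
    n_perm: int | str | list[tuple[int, ...]] = "exact",
    seed: int = 0,
) -> list[ProfileSignificance]:
    """Permutation test of template occupancy.

    For every permutation of time-point order, all rows are re-anchored and
    reassigned; the expected occupancy of a template is its mean count over
    permutations, and ``p = P(Binomial(N, expected/N) >= observed)`` (taken
    as 1 when observed <= expected, the one-sided over-occupancy
    convention). BH adjustment across templates. ``n_perm`` may be
    ``"exact"`` (all orderings), an integer >= 100 of random permutations,
    or an explicit list of index tuples.
    """
    T = m.shape[1]
    if isinstance(n_perm, str):
        if n_perm != "exact":
            raise ConfigurationError(f"unknown n_perm mode {n_perm!r}")
        if T < 3:
            warnings.warn("exact permutation null is trivial with < 3 time points")
        perms = [np.array(p) for p in itertools.permutations(range(T))]
    elif isinstance(n_perm, list):
        perms = [np.asarray(p, dtype=int) for p in n_perm]
        if not perms:
            raise ConfigurationError("empty permutation list")
    else:
        if n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100 (or 'exact')")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(T) for _ in range(n_perm)]

    tvecs = np.array([t.vector for t in templates], dtype=float)
    raw = m.to_numpy(dtype=float)
    N = raw.shape[0]
    K = len(templates)
    id_of = [t.id for t in templates]
    pos_of = {t.id: k for k, t in enumerate(templates)}

    observed = np.zeros(K, dtype=int)
    for a in assignments:
        observed[pos_of[a.profile]] += 1

    perm_counts = np.zeros((len(perms), K))
    for pi, perm in enumerate(perms):
        vals = _anchor(raw[:, perm])
        best = _assign_matrix(vals, tvecs)
        perm_counts[pi] = np.bincount(best, minlength=K)
    expected = perm_counts.mean(axis=0)

    pvals = np.ones(K)
    for k in range(K):
        if observed[k] > expected[k] and N > 0:
            pvals[k] = float(
                stats.binom.sf(observed[k] - 1, N, min(expected[k] / N, 1.0))
            )
    qvals = bh_fdr(pvals)
    return [
        ProfileSignificance(
            profile=id_of[k],
            observed=int(observed[k]),
            expected=float(expected[k]),
            p=float(pvals[k]),
            qfdr=float(qvals[k]),
        )
        for k in range(K)
    ]


# ---------------------------------------------------------------------------
# Shape taxonomy


def classify_shape(t: ProfileTemplate) -> str:
    """monotone_up / up_down / other, from the template vector alone.

    monotone_up: no decreasing step and a positive net change.
    up_down: a rise to an interior maximum (first occurrence), non-increasing
    afterwards, and a final value strictly below the maximum.
    """
    v = np.asarray(t.vector, dtype=float)
    d = np.diff(v)
    if (d >= 0).all() and d.sum() > 0:
        return MONOTONE_UP
    peak = int(np.argmax(v))
    if 0 < peak < len(v) - 1:
        rises = (d[:peak] >= 0).all() and d[:peak].sum() > 0
        falls = (d[peak:] <= 0).all() and v[-1] < v[peak]
        if rises and falls:
            return UP_DOWN
    return OTHER


# ---------------------------------------------------------------------------
# TSV writers


def write_templates_tsv(templates: list[ProfileTemplate], path, m=None, c=None) -> None:
    with open(path, "w") as fh:
        if m is not None or c is not None:
            fh.write(f"# m={m} c={c}\n")
        fh.write("profile\tshape\tvector\n")
        for t in templates:
            vec = ",".join(f"{v:g}" for v in t.vector)
            fh.write(f"{t.id}\t{t.shape}\t{vec}\n")


def write_assignments_tsv(assignments: list[ProfileAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tprofile\tcorrelation\n")
        for a in assignments:
            fh.write(f"{a.mirna}\t{a.profile}\t{a.correlation:.6f}\n")


def write_significance_tsv(sig: list[ProfileSignificance], path) -> None:
    with open(path, "w") as fh:
        fh.write("profile\tobserved\texpected\tp\tqfdr\n")
        for s in sig:
            fh.write(
                f"{s.profile}\t{s.observed}\t{s.expected:.4f}\t{s.p:.6g}\t{s.qfdr:.6g}\n"
            )
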