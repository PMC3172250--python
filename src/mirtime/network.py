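"""miRNA co-expression network, hub selection, and category intersection.

Edges connect miRNA pairs whose expression time courses have
``|Pearson r| >= threshold`` (0.9 by default — with only 5 samples per
tissue an aggressive cutoff is the guard against spurious correlation).
Hubs are nodes with degree >= 20. A *category* (D6/D9/S6/S9 analogue)
is the intersection of hubs with the members of significant temporal
profiles of a given shape in a given tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .profiles import (
    MONOTONE_UP,
    UP_DOWN,
    ProfileAssignment,
    ProfileSignificance,
    ProfileTemplate,
)

#: canonical profile codes for the category label: 6 = monotone up,
#: 9 = up-then-down
SHAPE_CODE = {MONOTONE_UP: "6", UP_DOWN: "9"}


@dataclass(frozen=True)
class Category:
    label: str
    members: frozenset[str]
    provenance: dict = field(default_factory=dict, compare=False)


def correlation_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation between rows; unit diagonal.

    Zero-variance rows are excluded (reported by warning) because their
    correlation is undefined.
    """
    if m.shape[1] < 3:
        raise InputError("correlation needs >= 3 columns")
    values = m.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        dropped = list(m.index[constant])
        warnings.warn(
            f"correlation_matrix: excluded {len(dropped)} zero-variance row(s): "
            f"{dropped[:10]}"
        )
    kept = m.index[~constant]
    r = np.corrcoef(values[~constant])
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=kept, columns=kept)


def build_network(corr: pd.DataFrame, threshold: float = 0.9) -> nx.Graph:
    """Graph with an edge (i, j) iff ``|r_ij| >= threshold`` (inclusive).

    Signed correlations are retained as edge weights; all correlation-matrix
    nodes are present even when isolated.
    """
    if not 0 < threshold <= 1:
        raise ConfigurationError(f"threshold must be in (0, 1], got {threshold}")
    g = nx.Graph()
    g.add_nodes_from(str(i) for i in corr.index)
    values = corr.to_numpy()
    ids = [str(i) for i in corr.index]
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = np.abs(values[iu, ju]) >= threshold
    for i, j in zip(iu[mask], ju[mask]):
        g.add_edge(ids[i], ids[j], r=float(values[i, j]))
    return g


def hub_nodes(net: nx.Graph, min_degree: int = 20) -> set[str]:
    """Nodes with degree >= min_degree (inclusive)."""
    if min_degree < 0:
        raise ConfigurationError(f"min_degree must be >= 0, got {min_degree}")
    return {n for n, d in net.degree() if d >= min_degree}


def make_category(
    tissue: str,
    shape: str,
    templates: list[ProfileTemplate],
    significance: list[ProfileSignificance],
    assignments: list[ProfileAssignment],
    hubs: set[str],
    alpha: float = 0.05,
    min_degree: int = 20,
) -> Category:
    """Intersect significant-profile members of a shape with network hubs.

    The label is the tissue initial plus the canonical shape code
    (e.g. DRG + monotone_up -> "D6"). If no profile of the requested shape
    is significant at qfdr < alpha the category is empty, with a warning.
    """
    if shape not in SHAPE_CODE:
        raise ConfigurationError(
            f"shape must be one of {sorted(SHAPE_CODE)}, got {shape!r}"
        )
    shape_of = {t.id: t.shape for t in templates}
    sig_profiles = {
        s.profile
        for s in significance
        if s.qfdr < alpha and shape_of.get(s.profile) == shape
    }
    label = tissue[0].upper() + SHAPE_CODE[shape]
    if not sig_profiles:
        warnings.warn(
            f"no significant profile of shape {shape} in {tissue}; "
            f"category {label} is empty"
        )
        members: frozenset[str] = frozenset()
    else:
        in_profiles = {a.mirna for a in assignments if a.profile in sig_profiles}
        members = frozenset(in_profiles & set(hubs))
    return Category(
        label=label,
        members=members,
        provenance={
            "tissue": tissue,
            "shape": shape,
            "profiles": sorted(sig_profiles),
            "min_degree": min_degree,
            "alpha": alpha,
        },
    )


# ---------------------------------------------------------------------------
# TSV writers


def write_edges_tsv(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tr\n")
        for u, v, data in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('r', float('nan')):.6f}\n")


def write_category_tsv(categories: list[Category], path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tmirna\n")
        for cat in categories:
            for mid in sorted(cat.members):
                fh.write(f"{cat.label}\t{mid}\n")
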