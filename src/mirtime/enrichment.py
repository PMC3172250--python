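"""Target intersection, hypergeometric GO/KEGG enrichment, term subnetworks.

Targets predicted by two independent programs are intersected per miRNA —
each program has a high false-positive rate, and requiring agreement prunes
decoys at little cost in true targets. Pooled targets per category are then
tested for over-representation in GMT gene sets with the one-sided
hypergeometric (Fisher upper-tail) test, BH-adjusted across terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from scipy import stats

from .de import bh_fdr
from .errors import ConfigurationError, InputError, ParseError
from .network import Category


@dataclass(frozen=True)
class TargetMap:
    """miRNA -> predicted target gene set, for one prediction source."""

    source: str
    targets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "targets",
            {m: frozenset(gs) for m, gs in dict(self.targets).items()},
        )

    def __getitem__(self, mirna: str) -> frozenset[str]:
        return self.targets[mirna]

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def n_pairs(self) -> int:
        return sum(len(gs) for gs in self.targets.values())

    def pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, gs in self.targets.items() for g in gs}


@dataclass(frozen=True)
class AnnotationMap:
    """term id -> (name, gene set) plus the gene universe."""

    terms: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        terms = {
            t: (name, frozenset(genes))
            for t, (name, genes) in dict(self.terms).items()
        }
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "universe", frozenset(self.universe))
        for t, (_, genes) in terms.items():
            if not genes <= self.universe:
                raise InputError(f"term {t!r} has genes outside the universe")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    overlap: int
    term_size: int
    p: float
    qfdr: float
    genes: frozenset[str]


# ---------------------------------------------------------------------------
# Parsing


def parse_targets(path: str | Path, dialect: str = "generic") -> TargetMap:
    """Read a miRNA->gene prediction file.

    dialects:
      * ``generic`` — headerless TSV, columns (miRNA, gene);
      * ``targetscan`` — TSV with a header line; the miRNA column is
        ``miRNA`` (or ``miR Family``) and the gene column ``Gene Symbol``;
      * ``miranda`` — TSV, columns (miRNA, gene), ``#`` comment lines
        skipped.

    miRNA ids are lower-cased; duplicate pairs collapse.
    """
    path = Path(path)
    if dialect not in ("generic", "targetscan", "miranda"):
        raise ConfigurationError(f"unknown target dialect {dialect!r}")
    targets: dict[str, set[str]] = {}

    def add(mirna: str, gene: str, lineno: int) -> None:
        mirna, gene = mirna.strip().lower(), gene.strip()
        if not mirna or not gene:
            raise ParseError(f"{path}:{lineno}: empty miRNA or gene field")
        targets.setdefault(mirna, set()).add(gene)

    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "targetscan":
        header_seen = False
        mir_col = gene_col = 0
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            cols = line.split("\t")
            if not header_seen:
                lowered = [c.strip().lower() for c in cols]
                try:
                    mir_col = (
                        lowered.index("mirna")
                        if "mirna" in lowered
                        else lowered.index("mir family")
                    )
                    gene_col = lowered.index("gene symbol")
                except ValueError:
                    raise ParseError(
                        f"{path}:1: targetscan header must name a miRNA column "
                        "('miRNA' or 'miR Family') and 'Gene Symbol'"
                    ) from None
                header_seen = True
                continue
            add(cols[mir_col], cols[gene_col], lineno)
    else:
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            if dialect == "miranda" and line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 tab-separated columns"
                )
            add(cols[0], cols[1], lineno)
    if not targets:
        warnings.warn(f"empty target prediction file {path}")
    return TargetMap(source=f"{dialect}:{path.name}", targets=targets)


def write_targets_tsv(tmap: TargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mirna in sorted(tmap.targets):
            for gene in sorted(tmap.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


# ---------------------------------------------------------------------------
# Set algebra


def intersect_targets(a: TargetMap, b: TargetMap) -> TargetMap:
    """Per-miRNA intersection; miRNAs absent from either source vanish."""
    out: dict[str, frozenset[str]] = {}
    for mirna in set(a.targets) & set(b.targets):
        common = a.targets[mirna] & b.targets[mirna]
        if common:
            out[mirna] = common
    return TargetMap(source=f"({a.source})&({b.source})", targets=out)


def category_targets(cat: Category, tmap: TargetMap) -> set[str]:
    """Union of predicted targets over a category's miRNAs.

    Members without predictions are counted and reported, then skipped.
    """
    genes: set[str] = set()
    missing = []
    for mirna in sorted(cat.members):
        if mirna in tmap:
            genes |= tmap[mirna]
        else:
            missing.append(mirna)
    if missing:
        warnings.warn(
            f"category {cat.label}: {len(missing)} member(s) without target "
            f"predictions, skipped: {missing[:10]}"
        )
    return genes


# ---------------------------------------------------------------------------
# Enrichment


def hypergeom_enrichment(
    query: Iterable[str], ann: AnnotationMap
) -> list[EnrichmentResult]:
    """One-sided over-representation test of ``query`` in every term.

    With universe size N, term size K, query size n and overlap k,
    ``p = P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``; BH across the
    tested terms (terms with zero overlap are skipped). Query genes outside
    the universe are reported and dropped. Results are sorted by ascending
    p, ties by term id.
    """
    if not ann.universe:
        raise InputError("empty gene universe")
    query = set(query)
    outside = query - ann.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the annotation universe, "
            f"dropped: {sorted(outside)[:10]}"
        )
        query &= ann.universe
    N, n = len(ann.universe), len(query)
    tested: list[tuple[str, str, int, int, float, frozenset[str]]] = []
    for term in sorted(ann.terms):
        name, genes = ann.terms[term]
        overlap = query & genes
        k = len(overlap)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, len(genes), n))
        tested.append((term, name, k, len(genes), min(p, 1.0), frozenset(overlap)))
    qvals = bh_fdr([t[4] for t in tested])
    results = [
        EnrichmentResult(
            term=term,
            name=name,
            overlap=k,
            term_size=K,
            p=p,
            qfdr=float(q),
            genes=genes,
        )
        for (term, name, k, K, p, genes), q in zip(tested, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def go_subnetwork(
    term: str,
    results: list[EnrichmentResult],
    cat: Category,
    tmap: TargetMap,
) -> list[tuple[str, str]]:
    """Bipartite (miRNA, gene) edges for a tested term's contributing genes.

    An edge links every category miRNA whose intersected targets include a
    gene that contributed to the term's overlap.
    """
    by_term = {r.term: r for r in results}
    if term not in by_term:
        raise InputError(f"term {term!r} was not tested (no overlap or absent)")
    contributing = by_term[term].genes
    edges = []
    for mirna in sorted(cat.members):
        if mirna not in tmap:
            continue
        for gene in sorted(tmap[mirna] & contributing):
            edges.append((mirna, gene))
    return edges


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationMap:
    """Read a GMT file (term, description, tab-separated genes).

    By default the universe is the union of all genes in the file; pass
    ``universe`` to override (e.g. the measured gene set).
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs term, description, >=1 gene"
                )
            term, desc, genes = cols[0], cols[1], frozenset(g for g in cols[2:] if g)
            if term in terms:
                raise ParseError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = (desc, genes)
    if universe is None:
        uni = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
    else:
        uni = frozenset(universe)
        terms = {
            t: (name, genes & uni) for t, (name, genes) in terms.items()
        }
        terms = {t: (name, genes) for t, (name, genes) in terms.items() if genes}
    return AnnotationMap(terms=terms, universe=uni)


def write_gmt(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(ann.terms):
            name, genes = ann.terms[term]
            fh.write("\t".join([term, name, *sorted(genes)]) + "\n")


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tname\toverlap\tterm_size\tp\tqfdr\tgenes\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.name}\t{r.overlap}\t{r.term_size}\t"
                f"{r.p:.6g}\t{r.qfdr:.6g}\t{','.join(sorted(r.genes))}\n"
            )
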