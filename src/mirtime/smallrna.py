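"""Small-RNA tag processing: reading, length filtering, classification, miRNA counting.

A *tag* is a unique small-RNA read sequence together with its read count
(multiplicity). Libraries are filtered to the informative length window
(default 18-30 nt), partitioned against reference catalogs of structural
ncRNAs / repeats / exons in a fixed priority order, and the remainder is
counted against a mature-miRNA catalog, optionally tolerating 3' isomiR
trimming/extension of up to 2 nt.

Classification is by exact sequence membership in each catalog, a
desk-scale stand-in for genome alignment that preserves the set-partition
logic of the original read-annotation cascade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

from .errors import CatalogError, ConfigurationError, InputError, ParseError

#: Category labels a tag can be assigned to, in the default exclusion order:
#: structural ncRNAs and masked genomic classes are removed before anything
#: is considered a miRNA candidate.
DEFAULT_PRIORITY: tuple[str, ...] = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "exon",
    "miRNA_mature",
)

#: Label for tags matching no catalog; these stay in the miRNA-discovery pool.
UNMATCHED = "retained_for_mirna-candidate"

_VALID_NT = frozenset("ACGT")


def _normalize_seq(seq: str) -> str:
    s = seq.strip().upper().replace("U", "T")
    if not s or not _VALID_NT.issuperset(s):
        raise ParseError(f"invalid nucleotide sequence {seq!r}")
    return s


@dataclass
class TagLibrary:
    """One sample's small-RNA tags with multiplicities.

    ``tags`` maps unique normalized sequences (U already converted to T) to
    read counts >= 1.
    """

    sample_id: str
    tissue: str = ""
    day: int = 0
    tags: dict[str, int] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return sum(self.tags.values())

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def add(self, seq: str, count: int = 1) -> None:
        if count < 1:
            raise InputError(f"tag count must be >= 1, got {count}")
        s = _normalize_seq(seq)
        self.tags[s] = self.tags.get(s, 0) + count


@dataclass(frozen=True)
class ReferenceCatalog:
    """A category's reference sequences, keyed by identifier.

    For ``miRNA_mature`` the keys are miRNA ids; for other categories ids
    are only bookkeeping labels. Sequence membership queries go through
    :attr:`seq_set`.
    """

    category: str
    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequences", dict(self.sequences)
        )

    @property
    def seq_set(self) -> frozenset[str]:
        return frozenset(self.sequences.values())

    @classmethod
    def from_fasta(cls, category: str, path: str | Path) -> "ReferenceCatalog":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise CatalogError(f"duplicate id {rec.id!r} in catalog {path}")
            seqs[rec.id] = _normalize_seq(str(rec.seq))
        return cls(category=category, sequences=seqs)


@dataclass
class ClassificationReport:
    """Partition of a library's tags over catalog categories.

    Invariant: per-category read counts (including :data:`UNMATCHED`) sum to
    the library read count, and the length histogram sums to the same total.
    ``retained_for_mirna`` counts the reads that continue into miRNA
    quantification: miRNA-matched reads plus unmatched candidates.
    """

    sample_id: str
    tag_counts: dict[str, int]
    read_counts: dict[str, int]
    length_histogram: dict[int, int]
    retained_for_mirna: int


# ---------------------------------------------------------------------------
# Reading


def read_tags(
    path: str | Path,
    format: str = "fasta",
    sample_id: str | None = None,
    tissue: str = "",
    day: int = 0,
) -> TagLibrary:
    """Read a tag library from FASTA, FASTQ, or two-column TSV.

    Identical sequences are collapsed with summed counts and U is
    normalized to T. The TSV dialect is ``sequence<TAB>count``. An empty
    file yields an empty library with a warning.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    lib = TagLibrary(sample_id=sample_id, tissue=tissue, day=day)
    if format in ("fasta", "fastq"):
        try:
            for rec in SeqIO.parse(str(path), format):
                lib.add(str(rec.seq), 1)
        except ValueError as exc:  # malformed record from Bio.SeqIO
            raise ParseError(f"malformed {format} record in {path}: {exc}") from exc
    elif format == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 'sequence<TAB>count', got {line!r}"
                    )
                seq, count_s = parts
                try:
                    count = int(count_s)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: count {count_s!r} is not an integer"
                    ) from None
                try:
                    lib.add(seq, count)
                except (ParseError, InputError) as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
    else:
        raise ConfigurationError(f"unknown tag format {format!r}")
    if lib.n_tags == 0:
        warnings.warn(f"empty tag library read from {path}", stacklevel=2)
    return lib


# ---------------------------------------------------------------------------
# Filtering and summaries


def filter_by_length(lib: TagLibrary, min_len: int, max_len: int) -> TagLibrary:
    """Keep tags with ``min_len <= len <= max_len`` (inclusive bounds)."""
    if not 0 < min_len <= max_len:
        raise ConfigurationError(
            f"invalid length bounds ({min_len}, {max_len}); need 0 < min <= max"
        )
    kept = {s: c for s, c in lib.tags.items() if min_len <= len(s) <= max_len}
    return TagLibrary(
        sample_id=lib.sample_id, tissue=lib.tissue, day=lib.day, tags=kept
    )


def length_histogram(lib: TagLibrary) -> dict[int, float]:
    """Read-weighted length distribution; fractions sum to 1."""
    if lib.n_reads == 0:
        raise InputError(f"empty library {lib.sample_id!r}: no length histogram")
    total = lib.n_reads
    hist: dict[int, float] = {}
    for seq, count in lib.tags.items():
        hist[len(seq)] = hist.get(len(seq), 0) + count
    return {length: reads / total for length, reads in sorted(hist.items())}


def classify_tags(
    lib: TagLibrary,
    catalogs: Sequence[ReferenceCatalog],
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> ClassificationReport:
    """Partition tags over catalogs by first-match in priority order.

    Each tag is assigned to the first category in ``priority`` whose catalog
    contains its exact sequence; tags matching nothing are labelled
    :data:`UNMATCHED` and, together with miRNA matches, make up
    ``retained_for_mirna``.
    """
    by_cat = {c.category: c for c in catalogs}
    for cat in by_cat:
        if cat not in priority:
            raise ConfigurationError(
                f"catalog category {cat!r} missing from priority {tuple(priority)}"
            )
    ordered = [by_cat[c] for c in priority if c in by_cat]
    sets = [(c.category, c.seq_set) for c in ordered]

    tag_counts: dict[str, int] = {}
    read_counts: dict[str, int] = {}
    hist: dict[int, int] = {}
    retained = 0
    for seq, count in lib.tags.items():
        label = UNMATCHED
        for cat, seq_set in sets:
            if seq in seq_set:
                label = cat
                break
        tag_counts[label] = tag_counts.get(label, 0) + 1
        read_counts[label] = read_counts.get(label, 0) + count
        hist[len(seq)] = hist.get(len(seq), 0) + count
        if label in (UNMATCHED, "miRNA_mature"):
            retained += count
    return ClassificationReport(
        sample_id=lib.sample_id,
        tag_counts=tag_counts,
        read_counts=read_counts,
        length_histogram=dict(sorted(hist.items())),
        retained_for_mirna=retained,
    )


# ---------------------------------------------------------------------------
# miRNA counting


def _variant_index(
    mature: ReferenceCatalog, max_trim: int
) -> dict[str, list[tuple[int, str]]]:
    """Map query sequences to (match_score, id) candidates for 3' trims."""
    index: dict[str, list[tuple[int, str]]] = {}
    for mid, seq in mature.sequences.items():
        for k in range(0, max_trim + 1):
            if len(seq) - k < 1:
                break
            trimmed = seq[: len(seq) - k] if k else seq
            # score: number of matched positions
            index.setdefault(trimmed, []).append((len(trimmed), mid))
    return index


def count_mirna(
    lib: TagLibrary,
    mature: ReferenceCatalog,
    allow_3p_variants: bool = True,
    max_shift: int = 2,
) -> dict[str, int]:
    """Count reads per miRNA against a mature catalog.

    A tag is credited to miRNA *m* if it equals m's mature sequence, or (with
    ``allow_3p_variants``) differs from it only at the 3' end by up to
    ``max_shift`` trimmed or appended nucleotides — the dominant isomiR mode.
    Each tag is credited to at most one miRNA; ambiguity is resolved by the
    longest matched stretch, then by lexicographically smallest id.
    """
    if mature.category != "miRNA_mature":
        raise CatalogError(
            f"count_mirna needs a miRNA_mature catalog, got {mature.category!r}"
        )
    ids = list(mature.sequences)
    if len(ids) != len(set(ids)):
        raise CatalogError("duplicate ids in mature catalog")

    max_trim = max_shift if allow_3p_variants else 0
    trim_index = _variant_index(mature, max_trim)
    exact_index = {seq: mid for mid, seq in mature.sequences.items()}

    counts: dict[str, int] = {}
    for tag, count in lib.tags.items():
        candidates: list[tuple[int, str]] = []
        # tag equals a mature sequence or a 3'-trimmed form of one
        candidates.extend(trim_index.get(tag, ()))
        if allow_3p_variants:
            # tag extends a mature sequence by up to max_shift nt at the 3' end
            for k in range(1, max_shift + 1):
                if len(tag) - k < 1:
                    break
                core = tag[: len(tag) - k]
                mid = exact_index.get(core)
                if mid is not None:
                    candidates.append((len(core), mid))
        if not candidates:
            continue
        # longest match wins; ties -> smallest id
        best_score = max(score for score, _ in candidates)
        best_id = min(mid for score, mid in candidates if score == best_score)
        counts[best_id] = counts.get(best_id, 0) + count
    return counts


# ---------------------------------------------------------------------------
# Report I/O


def write_classification_tsv(report: ClassificationReport, path: str | Path) -> None:
    cats = list(report.read_counts)
    with open(path, "w") as fh:
        fh.write("category\tn_tags\tn_reads\n")
        for cat in cats:
            fh.write(f"{cat}\t{report.tag_counts.get(cat, 0)}\t{report.read_counts[cat]}\n")
        fh.write(f"# retained_for_mirna\t\t{report.retained_for_mirna}\n")


def write_counts_tsv(counts: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tcount\n")
        for mid in sorted(counts):
            fh.write(f"{mid}\t{counts[mid]}\n")
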