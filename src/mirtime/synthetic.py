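"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates a two-tissue (dorsal root ganglion and nerve stump),
five-time-point (0, 1, 4, 7, 14 days post-injury) small-RNA study:

* tag libraries whose read-length distribution peaks at 22 nt, drawn from
  disjoint reference catalogs (mature miRNA, rRNA, tRNA, snRNA, snoRNA,
  repeat, exon) plus unannotated sequences;
* miRNA count matrices with negative-binomial noise and two planted
  temporal classes — monotone-up (baseline multiplied by ``effect_size``
  cumulatively at each post-injury day) and up-then-down (rising to a peak
  day, day 7 by default, then falling);
* an mRNA matrix with replicated columns in which true targets decrease as
  their regulator rises (scaled by ``repression_strength``, Gaussian noise
  on the log2 scale);
* two target-prediction maps that both contain every true pair plus
  independent decoys, so that their intersection prunes decoys;
* a GMT annotation in which planted terms are over-represented among true
  target genes.

Every operation is a pure function of the configuration seed: identical
seeds give bitwise-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .smallrna import ReferenceCatalog, TagLibrary

_NT = np.array(list("ACGT"))

#: read fraction per tag category in a generated library
CATEGORY_FRACTIONS: dict[str, float] = {
    "miRNA_mature": 0.40,
    "rRNA": 0.15,
    "tRNA": 0.10,
    "snRNA": 0.04,
    "snoRNA": 0.04,
    "repeat": 0.10,
    "exon": 0.07,
    "other": 0.10,
}


def _rng(seed: int, *key: object) -> np.random.Generator:
    """Independent deterministic stream per (seed, purpose-key)."""
    spawn = tuple(zlib.crc32(str(k).encode()) for k in key)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn))


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults are the conditions the pipeline is demonstrated under:
    300 miRNAs of which 30% carry a planted monotone-up and 18% a planted
    up-down trajectory (fold change 4 per post-injury step, NB dispersion
    0.2) — the composition of responding miRNAs a nerve-injury time course
    shows; 2000 mRNAs with 5 true targets per planted miRNA,
    repression strength 0.8 with 0.25 log2-units of Gaussian noise, and
    30% decoy predictions per target source.
    """

    seed: int = 0
    n_mirna: int = 300
    n_mrna: int = 2000
    timepoints: tuple[int, ...] = (0, 1, 4, 7, 14)
    tissues: tuple[str, ...] = ("DRG", "SN")
    n_planted_up: int = 90
    n_planted_updown: int = 54
    effect_size: float = 4.0
    dispersion: float = 0.2
    library_size: int = 5_000_000
    repression_strength: float = 0.8
    target_fp_rate: float = 0.3
    replicates_per_timepoint: int = 3
    peak_day: int = 7
    targets_per_mirna: int = 5
    mrna_noise_sd: float = 0.25
    n_terms: int = 50
    n_planted_terms: int = 3

    def __post_init__(self) -> None:
        if self.n_planted_up + self.n_planted_updown > self.n_mirna:
            raise ConfigurationError(
                "planted classes exceed n_mirna: "
                f"{self.n_planted_up}+{self.n_planted_updown} > {self.n_mirna}"
            )
        if any(not 0 <= r <= 1 for r in (self.repression_strength,)):
            raise ConfigurationError("repression_strength must be in [0, 1]")
        if not 0 <= self.target_fp_rate < 1:
            raise ConfigurationError("target_fp_rate must be in [0, 1)")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ConfigurationError("timepoints must be strictly increasing")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.effect_size < 1:
            raise ConfigurationError("effect_size must be >= 1")
        if self.replicates_per_timepoint < 2:
            raise ConfigurationError("replicates_per_timepoint must be >= 2")
        if self.peak_day not in self.timepoints:
            raise ConfigurationError(
                f"peak_day {self.peak_day} not in timepoints {self.timepoints}"
            )

    @property
    def samples(self) -> list[str]:
        return [f"{t}_d{d}" for t in self.tissues for d in self.timepoints]


@dataclass
class GroundTruth:
    """What was planted: per-miRNA class, true pairs, enriched terms."""

    planted_profile_of: dict[str, str] = field(default_factory=dict)
    true_pairs: set[tuple[str, str]] = field(default_factory=set)
    enriched_terms: set[str] = field(default_factory=set)


def mirna_ids(cfg: SynthConfig) -> list[str]:
    return [f"rno-mir-s{i:04d}" for i in range(1, cfg.n_mirna + 1)]


def gene_ids(cfg: SynthConfig) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, cfg.n_mrna + 1)]


# ---------------------------------------------------------------------------
# Ground truth


def gen_ground_truth(cfg: SynthConfig) -> GroundTruth:
    """Choose planted miRNA classes and true miRNA->gene pairs (seeded)."""
    rng = _rng(cfg.seed, "truth")
    mirnas = mirna_ids(cfg)
    order = rng.permutation(cfg.n_mirna)
    up = {mirnas[i] for i in order[: cfg.n_planted_up]}
    updown = {
        mirnas[i]
        for i in order[cfg.n_planted_up : cfg.n_planted_up + cfg.n_planted_updown]
    }
    profile_of = {
        m: ("up" if m in up else "updown" if m in updown else "null") for m in mirnas
    }
    genes = gene_ids(cfg)
    planted = sorted(up | updown)
    n_needed = len(planted) * cfg.targets_per_mirna
    if n_needed > cfg.n_mrna:
        raise ConfigurationError(
            f"need {n_needed} distinct target genes but n_mrna={cfg.n_mrna}"
        )
    chosen = rng.choice(cfg.n_mrna, size=n_needed, replace=False)
    true_pairs = set()
    for i, m in enumerate(planted):
        for j in chosen[i * cfg.targets_per_mirna : (i + 1) * cfg.targets_per_mirna]:
            true_pairs.add((m, genes[j]))
    return GroundTruth(planted_profile_of=profile_of, true_pairs=true_pairs)


# ---------------------------------------------------------------------------
# Reference catalogs and tag libraries


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _peaked_lengths(
    rng: np.random.Generator, n: int, lo: int, hi: int, mode: int, sd: float
) -> np.ndarray:
    raw = np.rint(rng.normal(mode, sd, size=n)).astype(int)
    return np.clip(raw, lo, hi)


def gen_reference_catalogs(cfg: SynthConfig) -> dict[str, ReferenceCatalog]:
    """Disjoint per-category sequence catalogs (tag truth is membership).

    Mature miRNA sequences are 20-24 nt with a sharp mode at 22; other
    categories' fragment sequences are 18-30 nt peaked at 22.
    """
    rng = _rng(cfg.seed, "catalogs")
    seen: set[str] = set()

    def fresh(length: int) -> str:
        while True:
            s = _random_seq(rng, int(length))
            if s not in seen:
                seen.add(s)
                return s

    catalogs: dict[str, ReferenceCatalog] = {}
    mir_lens = rng.choice(
        [20, 21, 22, 23, 24], size=cfg.n_mirna, p=[0.08, 0.17, 0.50, 0.17, 0.08]
    )
    catalogs["miRNA_mature"] = ReferenceCatalog(
        "miRNA_mature",
        {mid: fresh(L) for mid, L in zip(mirna_ids(cfg), mir_lens)},
    )
    for cat, n in [
        ("rRNA", 40),
        ("tRNA", 40),
        ("snRNA", 25),
        ("snoRNA", 25),
        ("repeat", 40),
        ("exon", 40),
    ]:
        lens = _peaked_lengths(rng, n, 18, 30, 22, 2.5)
        catalogs[cat] = ReferenceCatalog(
            cat, {f"{cat}_{i:03d}": fresh(L) for i, L in enumerate(lens, 1)}
        )
    return catalogs


def _parse_sample(cfg: SynthConfig, sample: str) -> tuple[str, int]:
    if sample not in cfg.samples:
        raise ConfigurationError(
            f"unknown sample {sample!r}; expected one of {cfg.samples}"
        )
    tissue, day_s = sample.rsplit("_d", 1)
    return tissue, int(day_s)


def gen_tag_library(
    cfg: SynthConfig,
    sample: str,
    catalogs: Mapping[str, ReferenceCatalog] | None = None,
    mirna_counts: Mapping[str, int] | None = None,
) -> TagLibrary:
    """One sample's tag library with a 22-nt length mode.

    Reads are split over categories by :data:`CATEGORY_FRACTIONS`; within a
    category, sequences are drawn from the catalog with long-tailed
    Dirichlet weights. When ``mirna_counts`` is given (the planted count
    matrix column for this sample) those multiplicities are emitted verbatim
    for the mature sequences and the other categories are scaled to keep
    their read fractions; otherwise multiplicities sum to ``library_size``.
    """
    tissue, day = _parse_sample(cfg, sample)
    if catalogs is None:
        catalogs = gen_reference_catalogs(cfg)
    rng = _rng(cfg.seed, "tags", sample)
    lib = TagLibrary(sample_id=sample, tissue=tissue, day=day)

    f_mir = CATEGORY_FRACTIONS["miRNA_mature"]
    if mirna_counts is not None:
        mir_total = int(sum(mirna_counts.values()))
        budget = {
            cat: int(round(mir_total * f / f_mir))
            for cat, f in CATEGORY_FRACTIONS.items()
            if cat != "miRNA_mature"
        }
        for mid, c in mirna_counts.items():
            if c > 0:
                lib.add(catalogs["miRNA_mature"].sequences[mid], int(c))
    else:
        if cfg.library_size == 0:
            return lib
        cats = list(CATEGORY_FRACTIONS)
        split = rng.multinomial(cfg.library_size, [CATEGORY_FRACTIONS[c] for c in cats])
        budget = dict(zip(cats, split))
        n_mir = budget.pop("miRNA_mature")
        seqs = list(catalogs["miRNA_mature"].sequences.values())
        if n_mir and seqs:
            w = rng.dirichlet(np.full(len(seqs), 0.5))
            for s, c in zip(seqs, rng.multinomial(n_mir, w)):
                if c > 0:
                    lib.add(s, int(c))

    other_pool = [
        _random_seq(rng, int(L))
        for L in _peaked_lengths(rng, 200, 10, 35, 22, 4.0)
    ]
    for cat, total in budget.items():
        if total <= 0:
            continue
        pool = (
            other_pool
            if cat == "other"
            else list(catalogs[cat].sequences.values())
        )
        w = rng.dirichlet(np.full(len(pool), 0.5))
        for s, c in zip(pool, rng.multinomial(int(total), w)):
            if c > 0:
                lib.add(s, int(c))
    return lib


# ---------------------------------------------------------------------------
# miRNA counts


def _trajectory_exponents(cfg: SynthConfig, kind: str) -> np.ndarray:
    """Per-day fold-change exponents for a planted class."""
    T = len(cfg.timepoints)
    idx = np.arange(T)
    if kind == "up":
        return idx.astype(float)
    if kind == "updown":
        # transient induction: rise to the peak day, then resolve back to
        # baseline (regeneration completing), reaching it by the last day
        p = cfg.timepoints.index(cfg.peak_day)
        tail = max(T - 1 - p, 1)
        return np.array(
            [float(i) if i <= p else max(p * (1.0 - (i - p) / tail), 0.0) for i in idx]
        )
    return np.zeros(T)


#: lognormal baseline of the stable (null) miRNA pool: a heavy-tailed bulk
#: spanning several orders of magnitude, as real small-RNA libraries where a
#: few abundant miRNAs take most reads and the majority sit near the floor
NULL_BASELINE_LOG_MEAN, NULL_BASELINE_SIGMA = np.log(300.0), 2.5
#: planted monotone-up miRNAs are induced from low basal expression and
#: climb through the stable pool's range; planted transient (up-down)
#: miRNAs start from moderate expression so their rise and return both
#: traverse the upper range. Keeping the two cohorts in different abundance
#: regimes means each moves through the rank distribution instead of
#: shifting as one block (which rank-based normalization would cancel).
UP_BASELINE_LOG_MEAN, UP_BASELINE_SIGMA = np.log(30.0), 0.8
UPDOWN_BASELINE_LOG_MEAN, UPDOWN_BASELINE_SIGMA = np.log(500.0), 0.5


def expected_mirna_means(
    cfg: SynthConfig, tissue: str, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Noise-free expected count matrix (the NB means) for one tissue.

    Null miRNAs sit on flat heavy-tailed baselines (the stable bulk of the
    miRNA pool); planted miRNAs start low and multiply their baseline by
    ``effect_size`` cumulatively along the planted trajectory, so library
    totals grow only modestly across the time course — the compositional
    behaviour of real re-sequenced libraries.
    """
    if tissue not in cfg.tissues:
        raise ConfigurationError(f"unknown tissue {tissue!r}")
    if truth is None:
        truth = gen_ground_truth(cfg)
    rng = _rng(cfg.seed, "baselines", tissue)
    mirnas = mirna_ids(cfg)
    cls = np.array([truth.planted_profile_of[m] for m in mirnas])
    baselines = rng.lognormal(NULL_BASELINE_LOG_MEAN, NULL_BASELINE_SIGMA, cfg.n_mirna)
    baselines = np.where(
        cls == "up",
        rng.lognormal(UP_BASELINE_LOG_MEAN, UP_BASELINE_SIGMA, cfg.n_mirna),
        baselines,
    )
    baselines = np.where(
        cls == "updown",
        rng.lognormal(UPDOWN_BASELINE_LOG_MEAN, UPDOWN_BASELINE_SIGMA, cfg.n_mirna),
        baselines,
    )
    expo = {k: _trajectory_exponents(cfg, k) for k in ("up", "updown", "null")}
    mult = np.array(
        [cfg.effect_size ** expo[truth.planted_profile_of[m]] for m in mirnas]
    )
    weights = baselines[:, None] * mult
    # fixed read budget per sample: a miRNA's mean count is its share of
    # the library's miRNA fraction, as a sequencer allocates a fixed depth
    depth = cfg.library_size * CATEGORY_FRACTIONS["miRNA_mature"]
    mu = pd.DataFrame(
        weights / weights.sum(axis=0, keepdims=True) * depth,
        index=mirnas,
        columns=[f"d{d}" for d in cfg.timepoints],
    )
    return mu, truth


def gen_mirna_counts(
    cfg: SynthConfig, tissue: str, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial miRNA counts with planted temporal classes.

    Planted-up miRNAs multiply their baseline by ``effect_size``
    cumulatively at each post-injury day; up-down miRNAs rise to the peak
    day then fall back; null miRNAs stay flat. Columns are ``d<day>``.
    ``dispersion=0`` degrades the noise to Poisson.
    """
    mu_df, truth = expected_mirna_means(cfg, tissue, truth)
    rng = _rng(cfg.seed, "counts", tissue)
    mu = mu_df.to_numpy()
    mirnas = mu_df.index
    if cfg.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / cfg.dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    df = pd.DataFrame(
        counts.astype(np.int64),
        index=mirnas,
        columns=[f"d{d}" for d in cfg.timepoints],
    )
    return df, truth


# ---------------------------------------------------------------------------
# mRNA expression


def gen_mrna_expression(
    cfg: SynthConfig, truth: GroundTruth, mirna_expr: pd.DataFrame
) -> pd.DataFrame:
    """Replicated log2 mRNA matrix with targets repressed by their regulators.

    A true target's per-day mean is its baseline minus
    ``repression_strength`` times its regulator's expression change from
    day 0 (changes summed over regulators), plus N(0, mrna_noise_sd) per
    replicate. Columns are ``d<day>_r<replicate>``.
    """
    regulators = {m for m, _ in truth.true_pairs}
    missing = sorted(regulators - set(mirna_expr.index))
    if missing:
        raise InputError(f"regulators missing from mirna_expr: {missing[:10]}")
    rng = _rng(cfg.seed, "mrna")
    genes = gene_ids(cfg)
    T = mirna_expr.shape[1]
    base = rng.normal(8.0, 1.0, size=cfg.n_mrna)
    means = np.tile(base[:, None], (1, T))
    gene_pos = {g: i for i, g in enumerate(genes)}
    x = mirna_expr.to_numpy(dtype=float)
    mir_pos = {m: i for i, m in enumerate(mirna_expr.index)}
    for m, g in sorted(truth.true_pairs):
        delta = x[mir_pos[m]] - x[mir_pos[m], 0]
        means[gene_pos[g]] -= cfg.repression_strength * delta
    R = cfg.replicates_per_timepoint
    noise = (
        rng.normal(0.0, cfg.mrna_noise_sd, size=(cfg.n_mrna, T * R))
        if cfg.mrna_noise_sd > 0
        else np.zeros((cfg.n_mrna, T * R))
    )
    values = np.repeat(means, R, axis=1) + noise
    cols = [f"{c}_r{r + 1}" for c in mirna_expr.columns for r in range(R)]
    return pd.DataFrame(values, index=genes, columns=cols)


# ---------------------------------------------------------------------------
# Target predictions and annotation


def gen_target_predictions(truth: GroundTruth, cfg: SynthConfig):
    """Two prediction maps: all true pairs plus independent decoys.

    Each source carries decoys amounting to ``target_fp_rate`` of its
    pairs, drawn independently per source, so the intersection of the two
    maps has fewer decoys in expectation than either alone.
    """
    from .enrichment import TargetMap

    mirnas = mirna_ids(cfg)
    genes = gene_ids(cfg)
    true_pairs = set(truth.true_pairs)
    n_true = len(true_pairs)
    fp = cfg.target_fp_rate
    n_decoy = int(round(fp * n_true / (1.0 - fp))) if n_true else 0
    maps = []
    for source in ("predictorA", "predictorB"):
        rng = _rng(cfg.seed, "targets", source)
        pairs = set(true_pairs)
        total = cfg.n_mirna * cfg.n_mrna
        while len(pairs) < n_true + n_decoy:
            draw = rng.integers(0, total, size=n_decoy + 8)
            for d in draw:
                pair = (mirnas[d // cfg.n_mrna], genes[d % cfg.n_mrna])
                if pair not in pairs:
                    pairs.add(pair)
                    if len(pairs) >= n_true + n_decoy:
                        break
        targets: dict[str, set[str]] = {}
        for m, g in pairs:
            targets.setdefault(m, set()).add(g)
        maps.append(TargetMap(source=source, targets=targets))
    return maps[0], maps[1]


def gen_annotation(cfg: SynthConfig, truth: GroundTruth):
    """GMT-style annotation with terms planted into the true target genes.

    Planted terms draw 70% of their members from true target genes and are
    recorded in ``truth.enriched_terms``; background terms are uniform
    random gene sets.
    """
    from .enrichment import AnnotationMap

    genes = gene_ids(cfg)
    if not genes:
        raise ConfigurationError("empty gene universe (n_mrna = 0)")
    rng = _rng(cfg.seed, "annotation")
    target_genes = sorted({g for _, g in truth.true_pairs})
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    truth.enriched_terms.clear()
    if target_genes:
        for i in range(cfg.n_planted_terms):
            tid = f"PLANTED{i + 1:02d}"
            size = 30
            n_from_targets = min(int(round(0.7 * size)), len(target_genes))
            members = set(
                rng.choice(target_genes, size=n_from_targets, replace=False)
            )
            others = [g for g in genes if g not in members]
            members |= set(
                rng.choice(others, size=size - n_from_targets, replace=False)
            )
            terms[tid] = (f"planted synthetic process {i + 1}", frozenset(members))
            truth.enriched_terms.add(tid)
    for i in range(cfg.n_terms):
        tid = f"TERM{i + 1:04d}"
        size = int(rng.integers(10, 61))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        terms[tid] = (f"background synthetic process {i + 1}", members)
    return AnnotationMap(terms=terms, universe=frozenset(genes))


# ---------------------------------------------------------------------------
# Correlation-matched series (worked-example inputs)


def correlated_series(r: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Two length-n series whose sample Pearson correlation is exactly r.

    Built from an orthonormal basis so the construction is deterministic;
    used to reproduce printed (r, p) rows of the correlation test.
    """
    if not -1 <= r <= 1:
        raise ConfigurationError(f"r must be in [-1, 1], got {r}")
    if n < 3:
        raise ConfigurationError("need n >= 3")
    t = np.arange(n, dtype=float)
    basis, _ = np.linalg.qr(np.column_stack([np.ones(n), t, t**2]))
    u, v = basis[:, 1], basis[:, 2]
    y = r * u + np.sqrt(max(0.0, 1.0 - r * r)) * v
    return u, y


# ---------------------------------------------------------------------------
# Bundled generation and serialization


@dataclass
class SyntheticDataset:
    """Everything one seeded run of the generator produces."""

    cfg: SynthConfig
    truth: GroundTruth
    catalogs: dict[str, ReferenceCatalog]
    tag_libraries: dict[str, TagLibrary]
    mirna_counts: dict[str, pd.DataFrame]
    mirna_norm: dict[str, pd.DataFrame]
    mrna_expr: dict[str, pd.DataFrame]
    targets_a: object
    targets_b: object
    annotation: object


def gen_dataset(cfg: SynthConfig, with_tags: bool = True) -> SyntheticDataset:
    """Generate the full consistent bundle for one seed.

    Tag-library miRNA multiplicities equal the planted count-matrix columns,
    so the read-processing stage recovers the counts exactly.
    """
    from .matrix import log_transform, quantile_normalize

    truth = gen_ground_truth(cfg)
    catalogs = gen_reference_catalogs(cfg)
    mirna_counts: dict[str, pd.DataFrame] = {}
    mirna_norm: dict[str, pd.DataFrame] = {}
    mrna_expr: dict[str, pd.DataFrame] = {}
    tag_libraries: dict[str, TagLibrary] = {}
    for tissue in cfg.tissues:
        counts, _ = gen_mirna_counts(cfg, tissue, truth)
        mirna_counts[tissue] = counts
        mirna_norm[tissue] = quantile_normalize(log_transform(counts))
        mrna_expr[tissue] = gen_mrna_expression(cfg, truth, mirna_norm[tissue])
        if with_tags:
            for day in cfg.timepoints:
                sample = f"{tissue}_d{day}"
                tag_libraries[sample] = gen_tag_library(
                    cfg, sample, catalogs, mirna_counts=counts[f"d{day}"].to_dict()
                )
    targets_a, targets_b = gen_target_predictions(truth, cfg)
    annotation = gen_annotation(cfg, truth)
    return SyntheticDataset(
        cfg=cfg,
        truth=truth,
        catalogs=catalogs,
        tag_libraries=tag_libraries,
        mirna_counts=mirna_counts,
        mirna_norm=mirna_norm,
        mrna_expr=mrna_expr,
        targets_a=targets_a,
        targets_b=targets_b,
        annotation=annotation,
    )


def write_tags_fasta(lib: TagLibrary, path: str | Path) -> None:
    """FASTA with one record per read-collapsed tag; count in the header."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(lib.tags.items()), 1):
            fh.write(f">{lib.sample_id}_t{i:06d}_x{count}\n{seq}\n")


def write_catalog_fasta(cat: ReferenceCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, seq in sorted(cat.sequences.items()):
            fh.write(f">{cid}\n{seq}\n")


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_profile_of": dict(sorted(truth.planted_profile_of.items())),
        "true_pairs": sorted(list(p) for p in truth.true_pairs),
        "enriched_terms": sorted(truth.enriched_terms),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth_json(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        planted_profile_of=payload["planted_profile_of"],
        true_pairs={tuple(p) for p in payload["true_pairs"]},
        enriched_terms=set(payload["enriched_terms"]),
    )
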