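"""End-to-end orchestration: simulate -> process -> matrix -> de -> profiles
-> network -> categories -> enrich -> pairs, with a run manifest.

Every stage reads its inputs from, and materializes its outputs into, the
run directory as plain TSV/FASTA/GMT/JSON, so single-stage re-runs compose
to exactly the monolithic run. The manifest records the tool version, the
full configuration (every default echoed), per-output SHA-256 checksums and
timestamps; checksums are stable for identical inputs + config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import de as de_mod
from . import matrix as mx
from . import network as net_mod
from . import pairs as pairs_mod
from . import profiles as prof_mod
from . import smallrna as sr
from . import synthetic as syn
from .enrichment import (
    TargetMap,
    category_targets,
    hypergeom_enrichment,
    intersect_targets,
    parse_targets,
    read_gmt,
    write_enrichment_tsv,
    write_targets_tsv,
)
from .errors import ConfigurationError, StageError

__version__ = "0.1.0"

log = logging.getLogger("mirtime")

STAGES = (
    "simulate",
    "process",
    "matrix",
    "de",
    "profiles",
    "network",
    "categories",
    "enrich",
    "pairs",
)


@dataclass
class PipelineConfig:
    """All stage parameters plus paths; defaults echo the module defaults."""

    outdir: str = "mirtime_run"
    seed: int = 0
    synth: syn.SynthConfig = field(default_factory=syn.SynthConfig)
    min_len: int = 18
    max_len: int = 30
    pseudocount: float = 1.0
    alpha_de: float = 0.05
    m_templates: int = 15
    c_units: int = 4
    perm: str | int = "exact"
    alpha_profiles: float = 0.05
    corr_threshold: float = 0.9
    min_degree: int = 20
    alpha_enrich: float = 0.05
    p_threshold: float = 0.1
    alpha_mrna_de: float = 0.05

    def __post_init__(self) -> None:
        if isinstance(self.synth, dict):
            self.synth = syn.SynthConfig(**self.synth)
        # one seed drives everything; the synth config inherits it
        if self.synth.seed != self.seed:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    """Shared state for one pipeline invocation over a run directory."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # -- paths ----------------------------------------------------------
    def p(self, *parts: str) -> Path:
        path = self.outdir.joinpath(*parts)
        path.parent.mkdir(parents=True, exist_ok=True)
        return path

    # -- stage bodies ---------------------------------------------------
    def simulate(self) -> list[Path]:
        cfg = self.cfg.synth
        ds = syn.gen_dataset(cfg)
        outputs = []
        for cat, catalog in ds.catalogs.items():
            path = self.p("catalogs", f"{cat}.fasta")
            syn.write_catalog_fasta(catalog, path)
            outputs.append(path)
        for sample, lib in ds.tag_libraries.items():
            path = self.p("tags", f"{sample}.fasta")
            syn.write_tags_fasta(lib, path)
            outputs.append(path)
        for tissue in cfg.tissues:
            path = self.p(f"mrna_{tissue}.tsv")
            mx.write_matrix_tsv(ds.mrna_expr[tissue], path, label="gene")
            outputs.append(path)
        for name, tmap in (("targets_a", ds.targets_a), ("targets_b", ds.targets_b)):
            path = self.p(f"{name}.tsv")
            write_targets_tsv(tmap, path)
            outputs.append(path)
        from .enrichment import write_gmt

        path = self.p("annotation.gmt")
        write_gmt(ds.annotation, path)
        outputs.append(path)
        path = self.p("truth.json")
        syn.write_truth_json(ds.truth, path)
        outputs.append(path)
        return outputs

    def process(self) -> list[Path]:
        cfg = self.cfg
        catalogs = []
        for cat in sr.DEFAULT_PRIORITY:
            fp = self.p("catalogs", f"{cat}.fasta")
            if fp.exists():
                catalogs.append(sr.ReferenceCatalog.from_fasta(cat, fp))
        mature = next(c for c in catalogs if c.category == "miRNA_mature")
        outputs = []
        for tissue in cfg.synth.tissues:
            count_maps = []
            for day in cfg.synth.timepoints:
                sample = f"{tissue}_d{day}"
                fp = self.p("tags", f"{sample}.fasta")
                if not fp.exists():
                    raise StageError(f"process: missing tag file {fp}")
                # tag FASTA headers carry multiplicities (..._x<count>)
                lib = _expand_fasta_counts(fp, sample, tissue, day)
                lib = sr.filter_by_length(lib, cfg.min_len, cfg.max_len)
                report = sr.classify_tags(lib, catalogs)
                sr.write_classification_tsv(
                    report, self.p("reports", f"classification_{sample}.tsv")
                )
                outputs.append(self.p("reports", f"classification_{sample}.tsv"))
                count_maps.append((f"d{day}", sr.count_mirna(lib, mature)))
            counts = mx.build_count_matrix(count_maps)
            path = self.p(f"counts_{tissue}.tsv")
            mx.write_matrix_tsv(counts, path, label="mirna")
            outputs.append(path)
        return outputs

    def matrix(self) -> list[Path]:
        outputs = []
        for tissue in self.cfg.synth.tissues:
            fp = self.p(f"counts_{tissue}.tsv")
            if not fp.exists():
                raise StageError(f"matrix: missing counts file {fp}")
            counts = mx.read_matrix_tsv(fp)
            norm = mx.quantile_normalize(
                mx.log_transform(counts, pseudocount=self.cfg.pseudocount)
            )
            path = self.p(f"norm_{tissue}.tsv")
            mx.write_matrix_tsv(norm, path, label="mirna")
            outputs.append(path)
        return outputs

    def de(self) -> list[Path]:
        outputs = []
        for tissue in self.cfg.synth.tissues:
            fp = self.p(f"counts_{tissue}.tsv")
            if not fp.exists():
                raise StageError(f"de: missing counts file {fp}")
            counts = mx.read_matrix_tsv(fp)
            table = de_mod.de_table(counts, alpha=self.cfg.alpha_de)
            path = self.p(f"de_{tissue}.tsv")
            table.to_csv(path, sep="\t", float_format="%.6g", index_label="mirna")
            outputs.append(path)
        return outputs

    def _de_selected_norm(self, tissue: str) -> pd.DataFrame:
        de_fp = self.p(f"de_{tissue}.tsv")
        norm_fp = self.p(f"norm_{tissue}.tsv")
        for fp in (de_fp, norm_fp):
            if not fp.exists():
                raise StageError(f"missing upstream output {fp}")
        de_table = pd.read_csv(de_fp, sep="\t", index_col=0)
        selected = de_mod.select_de(de_table, self.cfg.alpha_de)
        norm = mx.read_matrix_tsv(norm_fp)
        return norm.loc[sorted(set(norm.index) & selected)]

    def profiles(self) -> list[Path]:
        cfg = self.cfg
        outputs = []
        T = len(cfg.synth.timepoints)
        candidates = prof_mod.gen_candidate_profiles(T, cfg.c_units)
        templates = prof_mod.select_distinct_profiles(candidates, cfg.m_templates)
        for tissue in cfg.synth.tissues:
            expr = self._de_selected_norm(tissue)
            assignments = prof_mod.assign_to_profiles(expr, templates)
            sig = prof_mod.profile_significance(
                assignments, expr, templates, n_perm=cfg.perm, seed=cfg.seed
            )
            prof_mod.write_templates_tsv(
                templates,
                self.p(f"templates_{tissue}.tsv"),
                m=cfg.m_templates,
                c=cfg.c_units,
            )
            prof_mod.write_assignments_tsv(
                assignments, self.p(f"assignments_{tissue}.tsv")
            )
            prof_mod.write_significance_tsv(
                sig, self.p(f"profile_significance_{tissue}.tsv")
            )
            outputs += [
                self.p(f"templates_{tissue}.tsv"),
                self.p(f"assignments_{tissue}.tsv"),
                self.p(f"profile_significance_{tissue}.tsv"),
            ]
            if expr.shape[0] >= 2:
                dend = prof_mod.hier_cluster(mx.zscore_rows(expr))
                path = self.p(f"leaforder_{tissue}.tsv")
                with open(path, "w") as fh:
                    fh.write("mirna\n")
                    for mid in dend.leaf_order:
                        fh.write(f"{mid}\n")
                outputs.append(path)
        return outputs

    def network(self) -> list[Path]:
        outputs = []
        for tissue in self.cfg.synth.tissues:
            expr = self._de_selected_norm(tissue)
            corr = net_mod.correlation_matrix(expr)
            net = net_mod.build_network(corr, self.cfg.corr_threshold)
            hubs = net_mod.hub_nodes(net, self.cfg.min_degree)
            net_mod.write_edges_tsv(net, self.p(f"edges_{tissue}.tsv"))
            path = self.p(f"hubs_{tissue}.txt")
            with open(path, "w") as fh:
                for mid in sorted(hubs):
                    fh.write(f"{mid}\n")
            outputs += [self.p(f"edges_{tissue}.tsv"), path]
        return outputs

    def _read_profile_outputs(self, tissue: str):
        tpl_fp = self.p(f"templates_{tissue}.tsv")
        asg_fp = self.p(f"assignments_{tissue}.tsv")
        sig_fp = self.p(f"profile_significance_{tissue}.tsv")
        for fp in (tpl_fp, asg_fp, sig_fp):
            if not fp.exists():
                raise StageError(f"missing profile output {fp}")
        templates = []
        with open(tpl_fp) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("profile\t"):
                    continue
                pid, _shape, vec = line.rstrip("\n").split("\t")
                templates.append(
                    prof_mod.ProfileTemplate(
                        id=int(pid),
                        vector=tuple(float(v) for v in vec.split(",")),
                    )
                )
        asg_df = pd.read_csv(asg_fp, sep="\t")
        assignments = [
            prof_mod.ProfileAssignment(
                mirna=str(r.mirna), profile=int(r.profile), correlation=float(r.correlation)
            )
            for r in asg_df.itertuples()
        ]
        sig_df = pd.read_csv(sig_fp, sep="\t")
        sig = [
            prof_mod.ProfileSignificance(
                profile=int(r.profile),
                observed=int(r.observed),
                expected=float(r.expected),
                p=float(r.p),
                qfdr=float(r.qfdr),
            )
            for r in sig_df.itertuples()
        ]
        return templates, assignments, sig

    def categories(self) -> list[Path]:
        cats = []
        for tissue in self.cfg.synth.tissues:
            templates, assignments, sig = self._read_profile_outputs(tissue)
            hub_fp = self.p(f"hubs_{tissue}.txt")
            if not hub_fp.exists():
                raise StageError(f"categories: missing hub file {hub_fp}")
            hubs = {l.strip() for l in hub_fp.read_text().splitlines() if l.strip()}
            for shape in (prof_mod.MONOTONE_UP, prof_mod.UP_DOWN):
                cats.append(
                    net_mod.make_category(
                        tissue,
                        shape,
                        templates,
                        sig,
                        assignments,
                        hubs,
                        alpha=self.cfg.alpha_profiles,
                        min_degree=self.cfg.min_degree,
                    )
                )
        path = self.p("categories.tsv")
        net_mod.write_category_tsv(cats, path)
        return [path]

    def _read_categories(self) -> list[net_mod.Category]:
        fp = self.p("categories.tsv")
        if not fp.exists():
            raise StageError("enrich/pairs: missing categories.tsv")
        df = pd.read_csv(fp, sep="\t")
        cats = []
        for label, grp in df.groupby("category", sort=True):
            cats.append(
                net_mod.Category(label=str(label), members=frozenset(grp["mirna"]))
            )
        return cats

    def _intersected_targets(self) -> TargetMap:
        a_fp, b_fp = self.p("targets_a.tsv"), self.p("targets_b.tsv")
        for fp in (a_fp, b_fp):
            if not fp.exists():
                raise StageError(f"missing target prediction file {fp}")
        a = parse_targets(a_fp, "generic")
        b = parse_targets(b_fp, "generic")
        return intersect_targets(a, b)

    def enrich(self) -> list[Path]:
        inter = self._intersected_targets()
        path = self.p("targets_intersected.tsv")
        write_targets_tsv(inter, path)
        outputs = [path]
        gmt_fp = self.p("annotation.gmt")
        if not gmt_fp.exists():
            raise StageError(f"enrich: missing annotation file {gmt_fp}")
        ann = read_gmt(gmt_fp)
        for cat in self._read_categories():
            genes = category_targets(cat, inter)
            results = hypergeom_enrichment(genes, ann) if genes else []
            out = self.p(f"enrichment_{cat.label}.tsv")
            write_enrichment_tsv(results, out)
            outputs.append(out)
        return outputs

    def pairs(self) -> list[Path]:
        cfg = self.cfg
        inter = self._intersected_targets()
        cats = self._read_categories()
        outputs = []
        all_pairs = []
        for tissue in cfg.synth.tissues:
            mrna_fp = self.p(f"mrna_{tissue}.tsv")
            norm_fp = self.p(f"norm_{tissue}.tsv")
            for fp in (mrna_fp, norm_fp):
                if not fp.exists():
                    raise StageError(f"pairs: missing input {fp}")
            mrna = mx.read_matrix_tsv(mrna_fp)
            table, fit = pairs_mod.rvm_adjusted_f(mrna)
            de_path = self.p(f"mrna_de_{tissue}.tsv")
            header = f"# RVM moderated F: a={fit.a:.6g} b={fit.b:.6g} df_error={fit.df_error}\n"
            with open(de_path, "w") as fh:
                fh.write(header)
                table.to_csv(fh, sep="\t", float_format="%.6g", index_label="gene")
            outputs.append(de_path)
            de_genes = set(table.index[table["qfdr"] < cfg.alpha_mrna_de])
            tissue_cats = [c for c in cats if c.label.startswith(tissue[0].upper())]
            norm = mx.read_matrix_tsv(norm_fp)
            all_pairs += pairs_mod.select_inverse_pairs(
                norm, mrna, inter, de_genes, tissue_cats, cfg.p_threshold
            )
        path = self.p("pairs.tsv")
        pairs_mod.write_pairs_tsv(all_pairs, path)
        outputs.append(path)
        return outputs


def run_stage(name: str, cfg: PipelineConfig) -> dict:
    """Execute one stage; returns its manifest fragment."""
    if name not in STAGES:
        raise ConfigurationError(f"unknown stage {name!r}; valid: {list(STAGES)}")
    run = _Run(cfg)
    body = getattr(run, name)
    started = time.time()
    caught: list[str] = []
    log.info("stage %s: start", name)
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            outputs = body()
        caught = [str(w.message) for w in wlist]
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc
    fragment = {
        "outputs": {
            str(p.relative_to(run.outdir)): _sha256(p) for p in sorted(set(outputs))
        },
        "warnings": caught,
        "started": started,
        "finished": time.time(),
    }
    log.info("stage %s: %d output(s), %d warning(s)", name, len(outputs), len(caught))
    return fragment


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order; write and return the run manifest."""
    manifest = {
        "tool": "mirtime",
        "version": __version__,
        "config": cfg.to_dict(),
        "stages": {},
    }
    for name in STAGES:
        manifest["stages"][name] = run_stage(name, cfg)
    path = Path(cfg.outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def manifest_checksums(manifest: dict) -> dict[str, str]:
    """Flatten a manifest to {relative path: sha256}, timestamp-free."""
    out: dict[str, str] = {}
    for frag in manifest["stages"].values():
        out.update(frag["outputs"])
    return out


def _expand_fasta_counts(path: Path, sample: str, tissue: str, day: int):
    """Read a tag FASTA whose headers carry multiplicities (``..._x<count>``)."""
    lib = sr.TagLibrary(sample_id=sample, tissue=tissue, day=day)
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        if "_x" in rec.id:
            tail = rec.id.rsplit("_x", 1)[1]
            if tail.isdigit():
                count = int(tail)
        lib.add(str(rec.seq), count)
    return lib
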