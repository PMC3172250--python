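"""Tag reading, length filtering, classification, and miRNA counting."""

import warnings

import pytest

from mirtime.errors import CatalogError, ConfigurationError, InputError, ParseError
from mirtime.smallrna import (
    DEFAULT_PRIORITY,
    UNMATCHED,
    ReferenceCatalog,
    TagLibrary,
    classify_tags,
    count_mirna,
    filter_by_length,
    length_histogram,
    read_tags,
)
from mirtime.synthetic import SynthConfig, gen_reference_catalogs, gen_tag_library


def _lib(tags: dict[str, int]) -> TagLibrary:
    return TagLibrary(sample_id="s", tags=dict(tags))


class TestReadTags:
    def test_fasta_collapses_identical_sequences(self, tmp_path):
        fp = tmp_path / "x.fasta"
        fp.write_text(">a\nAAAA\n>b\nAAAA\n>c\nACGT\n")
        lib = read_tags(fp, "fasta")
        assert lib.tags == {"AAAA": 2, "ACGT": 1}

    def test_tsv_normalizes_u_to_t(self, tmp_path):
        fp = tmp_path / "x.tsv"
        fp.write_text("ACGU\t5\n")
        lib = read_tags(fp, "tsv")
        assert lib.tags == {"ACGT": 5}

    def test_fastq_counts_every_record(self, tmp_path):
        fp = tmp_path / "x.fastq"
        records = "".join(f"@r{i}\nACGTACGT\n+\nIIIIIIII\n" for i in range(100))
        fp.write_text(records)
        lib = read_tags(fp, "fastq")
        assert lib.n_reads == 100
        assert lib.tags == {"ACGTACGT": 100}

    def test_malformed_tsv_names_line(self, tmp_path):
        fp = tmp_path / "bad.tsv"
        fp.write_text("ACGT\t3\nACGT\n")
        with pytest.raises(ParseError, match=":2"):
            read_tags(fp, "tsv")

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        fp = tmp_path / "empty.fasta"
        fp.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            lib = read_tags(fp, "fasta")
        assert lib.n_tags == 0

    def test_unknown_format_rejected(self, tmp_path):
        fp = tmp_path / "x.bin"
        fp.write_text("x")
        with pytest.raises(ConfigurationError):
            read_tags(fp, "sam")


class TestFilterByLength:
    def test_bounds_are_inclusive(self):
        lib = _lib({"A" * 17: 1, "C" * 18: 2, "G" * 30: 3, "T" * 31: 4})
        kept = filter_by_length(lib, 18, 30)
        assert set(kept.tags) == {"C" * 18, "G" * 30}
        assert kept.tags["C" * 18] == 2

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_by_length(_lib({"ACGT": 1}), 30, 18)

    def test_retained_reads_match_brute_force(self, small_cfg):
        lib = gen_tag_library(small_cfg, "DRG_d0")
        kept = filter_by_length(lib, 18, 30)
        expected = sum(c for s, c in lib.tags.items() if 18 <= len(s) <= 30)
        assert kept.n_reads == expected


class TestLengthHistogram:
    def test_fractions(self):
        hist = length_histogram(_lib({"A" * 21: 5, "C" * 22: 15}))
        assert hist == {21: 0.25, 22: 0.75}

    def test_single_tag(self):
        assert length_histogram(_lib({"ACGTA": 3})) == {5: 1.0}

    def test_empty_library_rejected(self):
        with pytest.raises(InputError):
            length_histogram(_lib({}))


class TestClassifyTags:
    def test_priority_tie_break(self):
        seq = "ACGTACGTACGTACGTAC"
        cats = [
            ReferenceCatalog("repeat", {"r1": seq}),
            ReferenceCatalog("rRNA", {"x1": seq}),
        ]
        report = classify_tags(_lib({seq: 4}), cats)
        assert report.read_counts == {"rRNA": 4}

    def test_empty_catalogs_leave_all_unmatched(self):
        report = classify_tags(_lib({"ACGT": 2, "GGGG": 1}), [])
        assert report.read_counts == {UNMATCHED: 3}
        assert report.retained_for_mirna == 3

    def test_unknown_priority_category_rejected(self):
        cats = [ReferenceCatalog("intron", {"i": "ACGT"})]
        with pytest.raises(ConfigurationError):
            classify_tags(_lib({"ACGT": 1}), cats)

    def test_partition_sums_to_read_count(self, small_cfg):
        catalogs = gen_reference_catalogs(small_cfg)
        lib = gen_tag_library(small_cfg, "SN_d4", catalogs)
        report = classify_tags(lib, list(catalogs.values()))
        assert sum(report.read_counts.values()) == lib.n_reads
        assert sum(report.length_histogram.values()) == lib.n_reads

    def test_disjoint_catalogs_recover_truth(self, small_cfg):
        catalogs = gen_reference_catalogs(small_cfg)
        lib = gen_tag_library(small_cfg, "DRG_d1", catalogs)
        report = classify_tags(lib, list(catalogs.values()))
        # truth is catalog membership; recount independently
        truth_counts: dict[str, int] = {}
        sets = {c: catalogs[c].seq_set for c in catalogs}
        for seq, count in lib.tags.items():
            label = next(
                (c for c in DEFAULT_PRIORITY if c in sets and seq in sets[c]),
                UNMATCHED,
            )
            truth_counts[label] = truth_counts.get(label, 0) + count
        assert report.read_counts == truth_counts

    def test_filter_then_classify_commutes(self, small_cfg):
        catalogs = list(gen_reference_catalogs(small_cfg).values())
        lib = gen_tag_library(small_cfg, "DRG_d7")
        a = classify_tags(filter_by_length(lib, 18, 30), catalogs)
        full = classify_tags(lib, catalogs)
        # classify-then-filter, restricted to retained lengths
        restricted: dict[str, int] = {}
        sets = [(c.category, c.seq_set) for c in catalogs]
        for seq, count in lib.tags.items():
            if not 18 <= len(seq) <= 30:
                continue
            label = next((cat for cat, s in sets if seq in s), UNMATCHED)
            restricted[label] = restricted.get(label, 0) + count
        assert a.read_counts == restricted
        assert sum(full.read_counts.values()) >= sum(a.read_counts.values())


class TestCountMirna:
    MATURE = ReferenceCatalog(
        "miRNA_mature",
        {"mir-1": "ACGTACGTACGTACGTACGTAC", "mir-2": "TTTTGGGGCCCCAAAATTTTGG"},
    )

    def test_exact_match(self):
        counts = count_mirna(_lib({"ACGTACGTACGTACGTACGTAC": 7}), self.MATURE)
        assert counts == {"mir-1": 7}

    def test_unmatched_tag_absent(self):
        counts = count_mirna(_lib({"GGGGGGGGGGGGGGGGGGGG": 3}), self.MATURE)
        assert counts == {}

    def test_3prime_trim_and_extension_variants(self):
        trimmed = "ACGTACGTACGTACGTACGT"  # mir-1 minus 2 nt
        extended = "ACGTACGTACGTACGTACGTACTT"  # mir-1 plus 2 nt
        counts = count_mirna(_lib({trimmed: 2, extended: 3}), self.MATURE)
        assert counts == {"mir-1": 5}

    def test_variants_disabled_requires_exact(self):
        trimmed = "ACGTACGTACGTACGTACGT"
        counts = count_mirna(_lib({trimmed: 2}), self.MATURE, allow_3p_variants=False)
        assert counts == {}

    def test_ambiguity_longest_match_then_lexicographic(self):
        cat = ReferenceCatalog(
            "miRNA_mature",
            {
                "mir-b": "ACGTACGTACGTACGTACGTAC",
                "mir-a": "ACGTACGTACGTACGTACGTAC"[:20],  # shorter prefix form
            },
        )
        # tag equals the longer mature exactly -> longest match wins
        counts = count_mirna(_lib({"ACGTACGTACGTACGTACGTAC": 1}), cat)
        assert counts == {"mir-b": 1}
        # tag equals the 20-mer: exact for mir-a (score 20) and 2-nt trim of
        # mir-b (score 20) -> tie broken to lexicographically smaller id
        counts = count_mirna(_lib({"ACGTACGTACGTACGTACGT": 1}), cat)
        assert counts == {"mir-a": 1}

    def test_wrong_catalog_category_rejected(self):
        with pytest.raises(CatalogError):
            count_mirna(_lib({"ACGT": 1}), ReferenceCatalog("rRNA", {"r": "ACGT"}))

    def test_synthetic_totals_match_planted_counts(self, small_cfg):
        from mirtime.synthetic import gen_mirna_counts

        counts_df, _ = gen_mirna_counts(small_cfg, "DRG")
        catalogs = gen_reference_catalogs(small_cfg)
        lib = gen_tag_library(
            small_cfg, "DRG_d0", catalogs, mirna_counts=counts_df["d0"].to_dict()
        )
        got = count_mirna(lib, catalogs["miRNA_mature"], allow_3p_variants=False)
        expected = {m: c for m, c in counts_df["d0"].items() if c > 0}
        assert got == expected
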