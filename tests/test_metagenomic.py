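"""LCA stage: taxonomy handling, hit filtering, complexity, support folding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from allfoodseq.metagenomic import (
    LcaParams,
    Taxonomy,
    assign_reads,
    parse_m8,
    read_complexity,
    summarize,
)
from allfoodseq.synthgen import M8_COLUMNS


@pytest.fixture(scope="module")
def tax():
    """root -> {Bacteria -> ecoli, Eukaryota -> Mammalia -> Bovinae ->
    {cattle, buffalo}; Mammalia -> pig}."""
    return Taxonomy(
        {
            1: (1, "root", "root"),
            2: (1, "superkingdom", "Bacteria"),
            3: (1, "superkingdom", "Eukaryota"),
            30: (3, "class", "Mammalia"),
            31: (30, "subfamily", "Bovinae"),
            100: (31, "species", "cattle"),
            101: (31, "species", "buffalo"),
            102: (30, "species", "pig"),
            200: (2, "species", "ecoli"),
        }
    )


def hit_row(read, subject, bitscore, pident=99.0):
    return (read, subject, pident, 100, 1, 0, 1, 100, 1, 100, 1e-30, bitscore)


def hits_frame(rows):
    return pd.DataFrame(rows, columns=M8_COLUMNS)


class TestTaxonomy:
    def test_tsv_dialect_roundtrip(self, tax, tmp_path):
        path = tax.to_tsv(tmp_path / "tax.tsv")
        back = Taxonomy.from_tsv(path)
        assert back.parent == tax.parent
        assert back.name == tax.name

    def test_ncbi_dmp_dialect(self, tmp_path):
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        nodes.write_text(
            "1\t|\t1\t|\troot\t|\n2\t|\t1\t|\tspecies\t|\n"
        )
        names.write_text(
            "1\t|\troot\t|\t\t|\tscientific name\t|\n"
            "2\t|\tEscherichia coli\t|\t\t|\tscientific name\t|\n"
            "2\t|\tE. coli K12\t|\t\t|\tsynonym\t|\n"
        )
        t = Taxonomy.from_ncbi_dmp(nodes, names)
        assert t.root == 1
        assert t.name[2] == "Escherichia coli"

    def test_multiple_roots_rejected(self):
        with pytest.raises(ValueError, match="one root"):
            Taxonomy({1: (1, "root", "r"), 2: (2, "root", "r2")})

    def test_dangling_parent_rejected(self):
        with pytest.raises(ValueError, match="not in the taxonomy"):
            Taxonomy({1: (1, "root", "r"), 2: (99, "species", "s")})

    def test_lca_of_sister_species_is_their_genus(self, tax):
        assert tax.lca([100, 101]) == 31  # Bovinae

    def test_lca_idempotent_and_single(self, tax):
        assert tax.lca([100, 100]) == 100
        assert tax.lca([102]) == 102

    def test_lca_across_kingdoms_climbs_to_root(self, tax):
        assert tax.lca([100, 200]) == 1

    @given(st.lists(st.sampled_from([1, 2, 3, 30, 31, 100, 101, 102, 200]),
                    min_size=1, max_size=5))
    def test_lca_order_invariant(self, taxa):
        t = Taxonomy(
            {
                1: (1, "root", "root"),
                2: (1, "superkingdom", "Bacteria"),
                3: (1, "superkingdom", "Eukaryota"),
                30: (3, "class", "Mammalia"),
                31: (30, "subfamily", "Bovinae"),
                100: (31, "species", "cattle"),
                101: (31, "species", "buffalo"),
                102: (30, "species", "pig"),
                200: (2, "species", "ecoli"),
            }
        )
        forward = t.lca(taxa)
        assert forward == t.lca(list(reversed(taxa)))
        assert t.lca([forward]) == forward  # idempotence


class TestComplexity:
    def test_homopolymer_scores_zero(self):
        assert read_complexity("A" * 100) == 0.0

    def test_dinucleotide_repeat(self):
        # two trimers at equal frequency: H = 1 bit over log2(64) = 6
        assert read_complexity("AC" * 50) == pytest.approx(1 / 6, abs=1e-6)

    def test_random_reads_score_high(self, rng):
        scores = [
            read_complexity("".join(rng.choice(list("ACGT"), size=100)))
            for _ in range(1000)
        ]
        assert np.mean(scores) > 0.9

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            read_complexity("AC")

    @given(st.text(alphabet="ACGT", min_size=3, max_size=200))
    def test_score_bounded(self, seq):
        assert 0.0 <= read_complexity(seq) <= 1.0 + 1e-12


class TestParseM8:
    def test_truncates_to_best_three_by_bitscore(self, tmp_path):
        rows = [hit_row("r1", f"s{i}", 100.0 + i) for i in range(5)]
        df = parse_m8(hits_frame(rows), {f"s{i}": 100 for i in range(5)}, 3)
        assert len(df) == 3
        assert list(df["bitscore"]) == [104.0, 103.0, 102.0]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.m8"
        p.write_text("")
        assert parse_m8(p, {}).empty

    def test_tie_at_cutoff_keeps_lexicographically_smallest(self):
        rows = [
            hit_row("r1", "zzz", 100.0),
            hit_row("r1", "aaa", 90.0),
            hit_row("r1", "bbb", 90.0),
            hit_row("r1", "ccc", 90.0),
        ]
        df = parse_m8(hits_frame(rows), {s: 1 for s in ["zzz", "aaa", "bbb", "ccc"]}, 3)
        assert list(df["sseqid"]) == ["zzz", "aaa", "bbb"]

    def test_malformed_line_reports_position(self, tmp_path):
        p = tmp_path / "bad.m8"
        p.write_text(
            "\t".join(map(str, hit_row("r1", "s1", 100.0))) + "\n"
            + "r2\ts1\tnot_a_number\t" + "\t".join(["1"] * 9) + "\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            parse_m8(p, {"s1": 1})

    def test_unknown_subjects_dropped(self, caplog):
        rows = [hit_row("r1", "known", 100.0), hit_row("r1", "mystery", 99.0)]
        df = parse_m8(hits_frame(rows), {"known": 7})
        assert list(df["sseqid"]) == ["known"]


GOOD = "ACGTTAGCCTGATCGAGTCA" * 5  # high-complexity 100-mer


class TestAssign:
    def test_two_sister_species_give_genus(self, tax):
        rows = [hit_row("r1", "sc", 150.0), hit_row("r1", "sb", 150.0)]
        hits = parse_m8(hits_frame(rows), {"sc": 100, "sb": 101})
        out = assign_reads(hits, {"r1": GOOD}, tax)
        assert out.loc["r1", "category"] == "assigned"
        assert out.loc["r1", "taxon_id"] == 31

    def test_min_score_boundary(self, tax):
        hits = parse_m8(hits_frame([hit_row("r1", "sc", 74.9)]), {"sc": 100})
        out = assign_reads(hits, {"r1": GOOD}, tax, LcaParams(min_score=75.0))
        assert out.loc["r1", "category"] == "unassigned"

    def test_top_percent_drops_second_hit(self, tax):
        # best 200, second 197: cutoff at 198 forces assignment to best taxon
        rows = [hit_row("r1", "sc", 200.0), hit_row("r1", "sp", 197.0)]
        hits = parse_m8(hits_frame(rows), {"sc": 100, "sp": 102})
        out = assign_reads(hits, {"r1": GOOD}, tax, LcaParams(top_percent=1.0))
        assert out.loc["r1", "taxon_id"] == 100

    def test_low_complexity_reads_set_aside(self, tax):
        hits = parse_m8(hits_frame([hit_row("r1", "sc", 200.0)]), {"sc": 100})
        out = assign_reads(hits, {"r1": "AT" * 50}, tax, LcaParams(min_complexity=0.44))
        assert out.loc["r1", "category"] == "low_complexity"

    def test_read_without_hits_unassigned(self, tax):
        hits = parse_m8(hits_frame([]), {})
        out = assign_reads(hits, {"r1": GOOD}, tax)
        assert out.loc["r1", "category"] == "unassigned"

    def test_count_conservation(self, tax, rng):
        reads, rows = {}, []
        for i in range(200):
            rid = f"r{i}"
            kind = i % 3
            if kind == 0:
                reads[rid] = "A" * 100  # low complexity
            elif kind == 1:
                reads[rid] = GOOD  # assigned
                rows.append(hit_row(rid, "sc", 150.0))
            else:
                reads[rid] = GOOD  # no hits -> unassigned
        hits = parse_m8(hits_frame(rows), {"sc": 100})
        out = assign_reads(hits, reads, tax)
        summary = summarize(out, tax, LcaParams(min_support=0))
        assert summary.assigned + summary.unassigned + summary.low_complexity == 200


def make_assignments(taxa_counts):
    rows = []
    i = 0
    for tid, n in taxa_counts.items():
        for _ in range(n):
            rows.append((f"r{i}", "assigned", tid))
            i += 1
    return pd.DataFrame(rows, columns=["read_id", "category", "taxon_id"]).set_index(
        "read_id"
    )


class TestSummarize:
    def test_exactly_min_support_reads_folds_into_parent(self, tax):
        # "more than 50" is strict: 50 reads do not keep a species visible
        out = summarize(make_assignments({100: 50, 102: 60}), tax,
                        LcaParams(min_support=50))
        assert 100 not in out.counts.index
        assert out.counts[102] == 60
        # the 50 cattle reads climbed Bovinae -> Mammalia -> ... to root
        assert out.counts.sum() == 110

    def test_all_reads_one_species(self, tax):
        out = summarize(make_assignments({200: 120}), tax, LcaParams(min_support=50))
        assert list(out.counts.items()) == [(200, 120)]

    def test_folding_conserves_reads(self, tax):
        counts = {100: 30, 101: 20, 102: 500, 200: 7, 31: 45}
        out = summarize(make_assignments(counts), tax, LcaParams(min_support=50))
        assert out.counts.sum() == sum(counts.values())

    def test_discard_mode_drops_unsupported(self, tax):
        out = summarize(
            make_assignments({100: 10, 102: 500}), tax,
            LcaParams(min_support=50), fold_unsupported=False,
        )
        assert out.counts.sum() == 500

    def test_abundant_unknown_taxon_flagged_for_promotion(self, tax):
        # a 30%-abundant unexpected species among the unmapped reads
        out = summarize(
            make_assignments({200: 3000, 100: 7000}), tax,
            LcaParams(min_support=50, promote_threshold=1000),
        )
        flagged = {name for _, name, _ in out.promotions}
        assert "ecoli" in flagged
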