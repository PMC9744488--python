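"""Orthology curation, cross-level reconciliation and clade-event calling."""

import numpy as np
import pandas as pd
import pytest

from prnai.phyloprofile import (
    CopyNumberProfile,
    OrthologyGroup,
    Taxonomy,
    call_clade_events,
    copy_number,
    curate_members,
    export_fasta,
    ingest_newick,
    load_orthogroup_tables,
    profile_to_frame,
    read_profile_tsv,
    reconcile_levels,
    render_profile,
)
from prnai.simulate import default_taxonomy, simulate_orthology

TOY_TAXONOMY = Taxonomy.from_indented(
    """\
Root
  CladeA
    sp1
    sp2
    sp3
  CladeB
    sp4
    sp5
"""
)


def resolved_counts(table, taxonomy):
    """Full small-scale pipeline: load -> curate -> count -> reconcile."""
    from prnai.phyloprofile import profile_from_tables

    profile, _ = profile_from_tables(table, taxonomy)
    return profile


class TestLoading:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["level", "og_id", "species",
                                           "protein_id", "length"])

    def test_toy_table(self):
        table = self._table([("Root", "og1", s, f"{s}_p1-PA", 400)
                             for s in ("sp1", "sp2", "sp4")])
        groups = load_orthogroup_tables(table, TOY_TAXONOMY)
        assert len(groups["Root"]["og1"].members) == 3

    def test_unknown_species_rejected(self):
        table = self._table([("Root", "og1", "martian", "m_p1", 400)])
        with pytest.raises(ValueError, match="martian"):
            load_orthogroup_tables(table, TOY_TAXONOMY)

    def test_duplicate_rows_deduplicated_with_warning(self):
        table = self._table([("Root", "og1", "sp1", "sp1_p1-PA", 400)] * 2)
        with pytest.warns(UserWarning, match="duplicate"):
            groups = load_orthogroup_tables(table, TOY_TAXONOMY)
        assert groups["Root"]["og1"].total_members() == 1


class TestCuration:
    def test_longest_isoform_kept(self):
        group = OrthologyGroup("Root", "og", {"sp1": [("g1-PA", 300), ("g1-PB", 250)]})
        curated, log = curate_members(group)
        assert curated.members["sp1"] == [("g1-PA", 300)]
        assert log[0]["protein_id"] == "g1-PB"

    def test_partial_member_removed_at_40pct_bound(self):
        group = OrthologyGroup("Root", "og", {
            "sp1": [("g1-PA", 500)], "sp2": [("g2-PA", 510)],
            "sp3": [("g3-PA", 150)],  # 30% of the ~500 median
        })
        curated, log = curate_members(group)
        assert "sp3" not in curated.members
        assert any("partial" in r["reason"] for r in log)

    def test_oversized_member_removed_at_250pct_bound(self):
        group = OrthologyGroup("Root", "og", {
            "sp1": [("g1-PA", 500)], "sp2": [("g2-PA", 500), ("huge-PA", 1600)],
        })
        curated, _ = curate_members(group)
        assert curated.members["sp2"] == [("g2-PA", 500)]

    def test_curation_reduces_copy_number(self):
        """Redundant isoforms inflate raw counts; curation brings the
        species back to its true locus count."""
        group = OrthologyGroup("Root", "og", {
            "sp1": [("g1-PA", 500), ("g1-PB", 420)],
        })
        curated, _ = curate_members(group)
        counts = copy_number(curated, ["sp1"])
        assert counts["sp1"] == 1

    def test_curation_never_increases_counts(self):
        table, _ = simulate_orthology(seed=9, isoform_rate=0.6, outlier_rate=0.4)
        tax = default_taxonomy()
        for level, groups in load_orthogroup_tables(table, tax).items():
            for g in groups.values():
                curated, _ = curate_members(g)
                raw = copy_number(g, tax.clade_species(level))
                cur = copy_number(curated, tax.clade_species(level))
                assert all(cur[sp] <= raw[sp] for sp in raw)


class TestReconciliation:
    LEVELS = {
        "Root": {"sp1": 1, "sp2": 1, "sp3": 1, "sp4": 1, "sp5": 1},
        "CladeA": {"sp1": 1, "sp2": 1, "sp3": 1},
    }

    def test_agreeing_levels_no_flag(self):
        prof = reconcile_levels(self.LEVELS, TOY_TAXONOMY)
        assert prof.counts == {f"sp{i}": 1 for i in range(1, 6)}
        assert not prof.discordant

    def test_restrictive_level_takes_precedence(self):
        levels = {k: dict(v) for k, v in self.LEVELS.items()}
        levels["Root"]["sp1"] = 3
        levels["CladeA"]["sp1"] = 2
        prof = reconcile_levels(levels, TOY_TAXONOMY)
        assert prof.counts["sp1"] == 2
        assert prof.source_level["sp1"] == "CladeA"

    def test_wider_level_only_presence_flagged_discordant(self):
        levels = {k: dict(v) for k, v in self.LEVELS.items()}
        levels["CladeA"]["sp2"] = 0
        prof = reconcile_levels(levels, TOY_TAXONOMY)
        assert prof.counts["sp2"] == 0
        assert prof.discordant == {"sp2"}

    def test_idempotent(self):
        prof = reconcile_levels(self.LEVELS, TOY_TAXONOMY)
        again = reconcile_levels(
            {lvl: {sp: prof.counts[sp] for sp in counts}
             for lvl, counts in self.LEVELS.items()},
            TOY_TAXONOMY,
        )
        assert again.counts == prof.counts

    def test_resolved_total_never_exceeds_raw(self):
        table, _ = simulate_orthology(seed=2, isoform_rate=0.5, outlier_rate=0.3)
        tax = default_taxonomy()
        prof = resolved_counts(table, tax)
        raw_total = len(table.drop_duplicates(["species", "protein_id"]))
        assert sum(prof.counts.values()) <= raw_total


class TestCladeEvents:
    def test_planted_events_recovered_exactly(self):
        table, truth = simulate_orthology(seed=5)
        tax = default_taxonomy()
        prof = resolved_counts(table, tax)
        losses, dups = call_clade_events(prof, tax)
        assert sorted(l.clade for l in losses) == truth["loss_clades"]
        assert sorted(d.clade for d in dups) == truth["dup_clades"]
        assert sorted(prof.discordant) == truth["discordant_species"]
        assert prof.counts == truth["copy_number"]

    def test_all_single_copy_no_events(self):
        tax = default_taxonomy()
        prof = CopyNumberProfile(
            "fam", {sp: 1 for sp in tax.species},
            {sp: "Metazoa" for sp in tax.species},
        )
        losses, dups = call_clade_events(prof, tax)
        assert losses == [] and dups == []

    def test_duplication_at_80pct_rule(self):
        tax = default_taxonomy()
        counts = {sp: 1 for sp in tax.species}
        hym = tax.clade_species("Hymenoptera")  # 3 species: need >= 80% multi-copy
        counts[hym[0]] = 2
        counts[hym[1]] = 2
        prof = CopyNumberProfile("fam", counts, {sp: "Metazoa" for sp in counts})
        _, dups = call_clade_events(prof, tax)
        assert [d.clade for d in dups] == []  # 2/3 = 67% is below the bar
        counts[hym[2]] = 2
        prof = CopyNumberProfile("fam", counts, {sp: "Metazoa" for sp in counts})
        _, dups = call_clade_events(prof, tax)
        assert [d.clade for d in dups] == ["Hymenoptera"]

    def test_small_clades_not_called_lost(self):
        tax = default_taxonomy()
        counts = {sp: 1 for sp in tax.species}
        for sp in tax.clade_species("Entognatha"):  # only two species sampled
            counts[sp] = 0
        prof = CopyNumberProfile("fam", counts, {sp: "Metazoa" for sp in counts})
        losses, _ = call_clade_events(prof, tax)
        assert losses == []


class TestRenderAndRoundTrip:
    def test_matrix_tsv_round_trip(self, tmp_path):
        table, _ = simulate_orthology(seed=7)
        tax = default_taxonomy()
        prof = resolved_counts(table, tax)
        prof.gene_family = "SID1"
        render_profile(prof, tax, tmp_path / "SID1", formats=("svg",))
        assert (tmp_path / "SID1.svg").exists()
        back = read_profile_tsv(tmp_path / "SID1.tsv")
        assert back.counts == prof.counts
        assert back.discordant == prof.discordant
        assert back.source_level == prof.source_level

    def test_boxes_sorted_by_copy_number(self):
        tax = default_taxonomy()
        prof = CopyNumberProfile(
            "fam",
            {sp: i % 3 for i, sp in enumerate(sorted(tax.species))},
            {sp: "Metazoa" for sp in tax.species},
        )
        df = profile_to_frame(prof, tax)
        for _, sub in df.groupby("clade"):
            ordered = sub.sort_values(["copy_number", "species"])
            assert list(ordered["copy_number"]) == sorted(sub["copy_number"])


class TestSequenceInterfaces:
    def test_fasta_export_round_trip(self, tmp_path):
        from Bio import SeqIO

        group = OrthologyGroup("Root", "og", {
            "sp1": [("p1", 4)], "sp2": [("p2", 5), ("q7", 3)],
        })
        seqs = {"p1": "MKVL", "p2": "MKVLE", "q7": "MML"}
        missing = export_fasta(group, seqs, tmp_path / "fam.fasta")
        assert missing == []
        records = list(SeqIO.parse(str(tmp_path / "fam.fasta"), "fasta"))
        assert sorted(r.id for r in records) == ["sp1|p1", "sp2|p2", "sp2|q7"]

    def test_missing_sequences_listed(self, tmp_path):
        group = OrthologyGroup("Root", "og", {"sp1": [("p1", 4), ("p9", 6)]})
        missing = export_fasta(group, {"p1": "MKVL"}, tmp_path / "fam.fasta")
        assert missing == ["p9"]

    def test_newick_leaves_annotated(self, tmp_path):
        nwk = tmp_path / "t.nwk"
        nwk.write_text("((sp1|p1,sp2|p2),unknown_leaf);")
        with pytest.warns(UserWarning, match="unknown_leaf"):
            tree, annotations = ingest_newick(nwk, TOY_TAXONOMY)
        assert annotations["sp1|p1"] == "CladeA"
        assert "unknown_leaf" not in annotations
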