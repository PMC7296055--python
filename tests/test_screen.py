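"""Host-range screen: table building, ranking, grouping."""

import numpy as np
import pandas as pd
import pytest

from plasmidhost.records import GenomeRecord
from plasmidhost.screen import (
    MetadataMismatchError,
    PlasmidHostScreen,
    assign_groups,
    predict_host_similarity,
    top_fraction,
)
from plasmidhost.simulate import build_scenario, generate_sequence, make_markov_model

from conftest import random_sequence


def meta_for(records, genus_map=None):
    rows = [
        {"accession": r.id, "genus": (genus_map or {}).get(r.id, f"G_{r.id}")}
        for r in records
    ]
    return pd.DataFrame(rows).set_index("accession", drop=False)


class TestPredictHostSimilarity:
    def test_short_chromosome_is_na_at_k4(self):
        # (256 + 1) segments needed at k=4; 300 kb has only 60
        chrom = GenomeRecord(id="c", sequence=random_sequence(300_000, 0))
        plasmid = GenomeRecord(id="p", sequence=random_sequence(20_000, 1),
                               role="plasmid")
        res = predict_host_similarity(plasmid, chrom, 4)
        assert res.na and np.isnan(res.d2_plasmid)
        assert not predict_host_similarity(plasmid, chrom, 2).na

    def test_sub_window_chromosome_is_na(self):
        chrom = GenomeRecord(id="c", sequence=random_sequence(4_000, 2))
        plasmid = GenomeRecord(id="p", sequence=random_sequence(10_000, 3),
                               role="plasmid")
        assert predict_host_similarity(plasmid, chrom, 2).na

    def test_chromosome_concatenation_scores_near_maximal(self):
        # a "plasmid" that is the chromosome itself sits at the segment mean
        hits = 0
        for r in range(20):
            m = make_markov_model(50 + r, order=0, concentration=2.0)
            chrom = GenomeRecord(id="c", sequence=generate_sequence(m, 150_000, 80 + r))
            plasmid = GenomeRecord(id="p", sequence=chrom.sequence, role="plasmid")
            hits += predict_host_similarity(plasmid, chrom, 2).empirical_p >= 0.5
        assert hits >= 18


class TestBuildTableAndFit:
    def test_three_genomes_finite_d2(self):
        genomes = [
            GenomeRecord(id=f"c{i}", sequence=random_sequence(120_000, 100 + i))
            for i in range(3)
        ]
        plasmid = GenomeRecord(id="p", sequence=random_sequence(20_000, 99),
                               role="plasmid")
        screen = PlasmidHostScreen(plasmid, genomes, meta_for(genomes), ks=(2,))
        table = screen.fit().table
        assert len(table) == 3
        assert table["d2_k2"].notna().all()
        assert table["p_k2_frac"].str.endswith("/24").all()

    def test_sub_window_genome_row_all_na(self):
        genomes = [
            GenomeRecord(id="big", sequence=random_sequence(120_000, 104)),
            GenomeRecord(id="tiny", sequence=random_sequence(3_000, 105)),
        ]
        plasmid = GenomeRecord(id="p", sequence=random_sequence(20_000, 106),
                               role="plasmid")
        res = PlasmidHostScreen(plasmid, genomes, meta_for(genomes), ks=(2,)).fit()
        assert np.isnan(res.table.loc["tiny", "d2_k2"])
        assert np.isnan(res.table.loc["tiny", "p_k2"])
        assert res.na_counts() == {2: 1}

    def test_order_independence(self):
        genomes = [
            GenomeRecord(id=f"c{i}", sequence=random_sequence(120_000, 110 + i))
            for i in range(4)
        ]
        plasmid = GenomeRecord(id="p", sequence=random_sequence(20_000, 120),
                               role="plasmid")
        meta = meta_for(genomes)
        t1 = PlasmidHostScreen(plasmid, genomes, meta, ks=(2,)).fit().table
        t2 = PlasmidHostScreen(plasmid, genomes[::-1], meta, ks=(2,)).fit().table
        pd.testing.assert_frame_equal(t1, t2)

    def test_metadata_mismatch_lists_missing(self):
        genomes = [GenomeRecord(id="c0", sequence=random_sequence(20_000, 130))]
        plasmid = GenomeRecord(id="p", sequence="ACGT" * 100, role="plasmid")
        empty_meta = pd.DataFrame({"accession": [], "genus": []}).set_index(
            "accession", drop=False
        )
        with pytest.raises(MetadataMismatchError, match="c0"):
            PlasmidHostScreen(plasmid, genomes, empty_meta, ks=(2,))

    def test_largest_chromosome_and_exclusion_policies(self):
        genomes = [
            GenomeRecord(id="c1", sequence=random_sequence(120_000, 140)),
            GenomeRecord(id="c2", sequence=random_sequence(150_000, 141)),
            GenomeRecord(id="c3", sequence=random_sequence(120_000, 142)),
        ]
        meta = pd.DataFrame(
            {
                "accession": ["c1", "c2", "c3"],
                "genus": ["A", "A", "B"],
                "organism": ["orgA", "orgA", "orgB"],
                "exclude": ["", "", "true"],
            }
        ).set_index("accession", drop=False)
        plasmid = GenomeRecord(id="p", sequence=random_sequence(20_000, 143),
                               role="plasmid")
        screen = PlasmidHostScreen(plasmid, genomes, meta, ks=(2,))
        # c1 dropped (c2 is the larger chromosome of orgA), c3 excluded
        assert [g.id for g in screen.genomes] == ["c2"]


class TestTopFraction:
    def make_table(self, d2s, genera=None):
        accs = [f"c{i}" for i in range(len(d2s))]
        return pd.DataFrame(
            {
                "accession": accs,
                "genus": genera or [f"G{i}" for i in range(len(d2s))],
                "d2_k2": d2s,
            }
        ).set_index("accession", drop=False)

    def test_fraction_of_distinct_values(self):
        table = self.make_table(list(range(10)))
        rows, genera = top_fraction(table, 0.3)
        assert len(rows) == 3
        assert set(rows["accession"]) == {"c0", "c1", "c2"}

    def test_fraction_one_returns_all_non_na(self):
        table = self.make_table([3.0, 1.0, np.nan, 2.0])
        rows, _ = top_fraction(table, 1.0)
        assert set(rows["accession"]) == {"c0", "c1", "c3"}

    def test_ties_broken_by_accession(self):
        # six rows, all d2 equal: brute-force expectation is the
        # lexicographically first ceil(f*6) accessions
        table = self.make_table([5.0] * 6)
        rows, _ = top_fraction(table, 0.5)
        assert sorted(rows["accession"]) == ["c0", "c1", "c2"]

    def test_na_rows_have_no_rank(self):
        table = self.make_table([np.nan, np.nan, 1.0, 2.0])
        rows, _ = top_fraction(table, 0.5)
        assert set(rows["accession"]) == {"c2"}

    def test_errors(self):
        table = self.make_table([np.nan, np.nan])
        with pytest.raises(ValueError):
            top_fraction(table, 0.5)
        with pytest.raises(ValueError):
            top_fraction(self.make_table([1.0]), 0.0)

    def test_genus_membership_is_union_over_qualifying_rows(self):
        table = self.make_table([1, 2, 3, 4], genera=["Ga", "Ga", "Gb", "Gc"])
        _, genera = top_fraction(table, 0.5)
        assert genera == {"Ga"}


class TestAssignGroups:
    def test_partition(self):
        table = pd.DataFrame(
            {
                "accession": list("abcde"),
                "genus": ["G1", "G1", "G2", "G3", ""],
            }
        )
        out = assign_groups(table, {"G1", "G3"})
        assert list(out["group"]) == [
            "Transconjugants", "Transconjugants", "Others", "Transconjugants",
            "Unlabeled",
        ]

    def test_absent_genus_warns_but_labels(self, caplog):
        table = pd.DataFrame({"accession": ["a"], "genus": ["G1"]})
        with caplog.at_level("WARNING"):
            out = assign_groups(table, {"G1", "Ghost"})
        assert list(out["group"]) == ["Transconjugants"]
        assert any("Ghost" in r.message for r in caplog.records)

    def test_empty_genera_rejected(self):
        with pytest.raises(ValueError):
            assign_groups(pd.DataFrame({"genus": []}), set())


class TestEndToEndScenario:
    def test_scenario_groups_and_ranks(self, small_screen_results):
        table = small_screen_results.table
        assert set(table["group"]) == {"Transconjugants", "Others"}
        assert table["d2_k2"].notna().all()
        # ranking by d2 and by empirical P are weakly inverse
        sub = table.sort_values("d2_k2")
        ps = sub["p_k2"].to_numpy()
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_true_host_ranks_top_decile_under_strong_amelioration(self):
        # single experimentally supported host, alpha=0.8: its chromosome
        # should fall in the top 10% of D2 in nearly every replicate
        hits = 0
        for r in range(10):
            b = build_scenario(
                n_transconjugant_hosts=1, n_other_hosts=19,
                chrom_length=350_000, alpha=0.8, seed=300 + r,
            )
            screen = PlasmidHostScreen(
                b.plasmid_record, b.host_records,
                b.metadata.set_index("accession", drop=False), ks=(3,),
            )
            _, genera = screen.fit().top_fraction(0.1, policy="per_k", k=3)
            hits += "Genus000" in genera
        assert hits >= 9

    def test_summary_mentions_counts(self, small_screen_results):
        text = small_screen_results.summary()
        assert "6 chromosomes" in text and "k=2" in text
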