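"""Enrichment-screen analytics: table parsing, control filtering, fold
enrichment, hit calling, and consensus phosphosite scanning."""

import numpy as np
import pandas as pd
import pytest

from adhesio import screen as scr
from adhesio import synthetic as syn
from adhesio import validation as V


def _toy_table(rows):
    cols = ["accession", "gene"] + [
        f"{cond}_t{t}" for cond in scr.CONDITIONS for t in range(1, 5)
    ]
    return pd.DataFrame(rows, columns=cols)


class TestLoadQuantTable:
    def test_toy_tsv_with_column_map(self, tmp_path):
        raw = pd.DataFrame(
            {
                "Majority protein IDs": ["P1", "P2", "P3"],
                "Gene names": ["A", "B", "C"],
                "Intensity C1": [1.0, 2.0, 3.0],
                "Intensity N1": [4.0, 5.0, 6.0],
                "Intensity E1": [7.0, 8.0, 9.0],
            }
        )
        path = tmp_path / "pg.tsv"
        raw.to_csv(path, sep="\t", index=False)
        cmap = {
            "accession": "Majority protein IDs",
            "gene": "Gene names",
            "columns": {
                "Intensity C1": ["ctrl_ATP_PKA", 1],
                "Intensity N1": ["neg_ATPbiotin_noPKA", 1],
                "Intensity E1": ["exp_ATPbiotin_PKA", 1],
            },
        }
        table = scr.load_quant_table(path, cmap)
        assert len(table) == 3
        assert list(table["exp_ATPbiotin_PKA_t1"]) == [7.0, 8.0, 9.0]

    def test_decoy_and_contaminant_rows_dropped(self, tmp_path):
        df = _toy_table(
            [
                ["P1", "A"] + [1.0] * 12,
                ["REV__P2", "B"] + [1.0] * 12,
                ["CON__P3", "C"] + [1.0] * 12,
            ]
        )
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        table = scr.load_quant_table(path)
        assert list(table["accession"]) == ["P1"]

    def test_duplicate_accession_rejected(self, tmp_path):
        df = _toy_table([["P1", "A"] + [1.0] * 12, ["P1", "B"] + [2.0] * 12])
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            scr.load_quant_table(path)

    def test_missing_intensities_read_as_zero(self, tmp_path):
        df = _toy_table([["P1", "A"] + [1.0] * 12])
        df.loc[0, "exp_ATPbiotin_PKA_t2"] = np.nan
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        table = scr.load_quant_table(path)
        assert table.loc[0, "exp_ATPbiotin_PKA_t2"] == 0.0

    def test_unmapped_column_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        _toy_table([["P1", "A"] + [1.0] * 12]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="not present"):
            scr.load_quant_table(
                path,
                {"accession": "accession", "columns": {"nope": ["exp_ATPbiotin_PKA", 1]}},
            )


class TestControlFilter:
    def _protein(self, acc, ctrl, neg, exp):
        return [acc, ""] + list(ctrl) + list(neg) + list(exp)

    def test_majority_control_high_removed(self):
        t = _toy_table(
            [self._protein("P1", [10, 10, 10, 1], [1, 1, 1, 1], [2, 2, 2, 2])]
        )
        assert len(scr.filter_control_enriched(t)) == 0

    def test_control_exclusive_removed(self):
        t = _toy_table([self._protein("P1", [5, 5, 5, 5], [0] * 4, [0] * 4)])
        assert len(scr.filter_control_enriched(t)) == 0

    def test_control_absent_retained(self):
        t = _toy_table([self._protein("P1", [0] * 4, [1] * 4, [9] * 4)])
        assert len(scr.filter_control_enriched(t)) == 1

    def test_minority_control_high_retained(self):
        t = _toy_table(
            [self._protein("P1", [10, 1, 1, 1], [1, 1, 1, 1], [2, 2, 2, 2])]
        )
        assert len(scr.filter_control_enriched(t)) == 1


class TestEnrichment:
    def test_simple_ratio(self):
        t = _toy_table([["P1", ""] + [0] * 4 + [100] * 4 + [300] * 4])
        enr = scr.compute_enrichment(t)
        assert enr.loc[0, "enrichment_t1"] == 3.0

    def test_experimental_only_is_infinite(self):
        t = _toy_table([["P1", ""] + [0] * 4 + [0] * 4 + [500] * 4])
        enr = scr.compute_enrichment(t)
        assert np.isposinf(enr.loc[0, "enrichment_t1"])
        assert enr.loc[0, "n_trials_evaluable"] == 4

    def test_undetected_trial_not_evaluable(self):
        t = _toy_table([["P1", ""] + [0] * 4 + [0, 100, 100, 100] + [0, 300, 300, 300]])
        enr = scr.compute_enrichment(t)
        assert np.isnan(enr.loc[0, "enrichment_t1"])
        assert enr.loc[0, "n_trials_evaluable"] == 3


class TestHitCalling:
    def _enr(self, values):
        df = pd.DataFrame({"accession": [f"P{i}" for i in range(len(values))],
                           "gene": ""})
        arr = np.asarray(values, dtype=float)
        for k in range(arr.shape[1]):
            df[f"enrichment_t{k + 1}"] = arr[:, k]
        df["n_trials_evaluable"] = np.sum(~np.isnan(arr), axis=1)
        return df

    def test_two_passing_trials_is_hit(self):
        enr = self._enr([[7.0, 6.5, 0.9, np.nan]])
        assert scr.call_hits(enr, 6.0, 2).accessions == ["P0"]

    def test_one_passing_trial_is_not_hit(self):
        enr = self._enr([[1.6, 1.4, 1.4, 1.4]])
        assert scr.call_hits(enr, 1.5, 2).accessions == []

    def test_infinite_trials_count_by_default_and_can_be_excluded(self):
        enr = self._enr([[np.inf, np.inf, 1.0, 1.0]])
        assert scr.call_hits(enr, 6.0, 2).accessions == ["P0"]
        assert scr.call_hits(enr, 6.0, 2, count_exclusive=False).accessions == []

    def test_matches_brute_force_on_random_table(self, rng):
        vals = rng.choice(
            [0.5, 1.0, 1.6, 6.5, 20.0, np.nan, np.inf], size=(500, 4)
        )
        enr = self._enr(vals)
        hl = scr.call_hits(enr, 6.0, 2)
        expected = set()
        for i in range(500):
            n = sum(
                1
                for v in vals[i]
                if (not np.isnan(v)) and (np.isinf(v) or v >= 6.0)
            )
            if n >= 2:
                expected.add(f"P{i}")
        assert set(hl.accessions) == expected

    def test_monotonicity_and_nesting(self):
        res = V.hit_list_nesting(seed=11)
        assert res["nested"]
        assert res["monotone_in_threshold"]
        assert res["monotone_in_min_trials"]

    def test_planted_recovery(self):
        res = V.screen_recovery(seed=17)
        assert res["recall"] >= 0.95
        assert res["fdp"] <= 0.05

    def test_sorted_by_descending_median_enrichment(self):
        enr = self._enr([[2.0, 2.0, 2.0, 2.0], [8.0, 8.0, 8.0, 8.0]])
        assert scr.call_hits(enr, 1.5, 2).accessions == ["P1", "P0"]


class TestMotifScan:
    def test_canonical_strong_site(self):
        hits = scr.scan_pka_motifs("AARRASLA")
        assert len(hits) == 1
        h = hits[0]
        assert (h.position, h.tier) == (6, "strong")
        assert h.window[1:5] == "RRAS"

    def test_reporter_substrate_site(self):
        hits = scr.scan_pka_motifs("LRRATLV")
        assert [(h.position, h.tier) for h in hits] == [(5, "strong")]

    def test_no_basic_residues_no_hits(self):
        assert scr.scan_pka_motifs("AAAAASAA") == []

    @pytest.mark.parametrize(
        "seq,tier",
        [("AKRASAA", "moderate"), ("ARAASAA", "moderate"), ("ARRATAA", "strong")],
    )
    def test_tier_assignment(self, seq, tier):
        hits = scr.scan_pka_motifs(seq)
        assert [h.tier for h in hits] == [tier]

    def test_min_tier_strong_filters_moderate(self):
        assert scr.scan_pka_motifs("AKRASAA", min_tier="strong") == []
        assert len(scr.scan_pka_motifs("ARRASAA", min_tier="strong")) == 1

    def test_unknown_residue_never_matches(self):
        assert scr.scan_pka_motifs("AXRASAA") == []
        assert scr.scan_pka_motifs("XXXXSXX") == []

    def test_empty_sequence(self):
        assert scr.scan_pka_motifs("") == []

    def test_scores_ordered_by_determinants(self):
        strong = scr.scan_pka_motifs("ARRASL")[0].score
        moderate = scr.scan_pka_motifs("ARAASL")[0].score
        assert 0 < moderate < strong <= 1.0

    def test_fasta_scan(self, tmp_path):
        fasta = tmp_path / "seqs.fa"
        fasta.write_text(">prot1\nAARRASLA\n>prot2\nAAAAAAAA\n")
        hits = scr.scan_fasta(fasta)
        assert [(h.accession, h.position) for h in hits] == [("prot1", 6)]
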