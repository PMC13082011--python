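"""IP-MS enrichment funnel: fold changes, intersections, surface filter,
ranking, and the competition two-way ANOVA."""

import numpy as np
import pandas as pd
import pytest

from mimiscan.mimicry import (EnrichmentInputs, EpitopeQuery,
                              compute_fold_changes, competition_summary,
                              filter_surface, intersect_enriched,
                              rank_candidates, run_mimicry_funnel)


def make_inputs(rows_per_line, pseudocount=1.0):
    """rows_per_line: {line: {protein: (target, control)}}"""
    tables = {}
    for line, rows in rows_per_line.items():
        tables[line] = pd.DataFrame(
            {
                "rB9": [v[0] for v in rows.values()],
                "control": [v[1] for v in rows.values()],
            },
            index=list(rows.keys()),
        )
    return EnrichmentInputs(tables=tables, pseudocount=pseudocount)


class TestFoldChanges:
    def test_pseudocount_must_be_positive(self):
        with pytest.raises(ValueError, match="pseudocount"):
            make_inputs({"L1": {"P1": (1010.0, 10.0)}}, pseudocount=0.0)

    @pytest.mark.parametrize(
        "target,control,expected_fc,passes",
        [
            (1010.0, 10.0, 1011.0 / 11.0, False),     # ~91.9: below cutoff
            (10100.0, 100.0, 10101.0 / 101.0, True),  # ~100.0099: just above
            (9999.0, 99.0, 100.0, False),             # exactly 100: strict
        ],
    )
    def test_boundary_arithmetic(self, target, control, expected_fc, passes):
        fc = compute_fold_changes(make_inputs({"L1": {"P1": (target, control)}}))
        row = fc.iloc[0]
        assert row["fold_change"] == pytest.approx(expected_fc)
        assert bool(row["passes"]) is passes

    def test_absent_protein_counts_as_zero(self):
        inputs = EnrichmentInputs(
            tables={
                "L1": pd.DataFrame({"rB9": [500.0], "control": [1.0]},
                                   index=["P1"]),
                "L2": pd.DataFrame({"rB9": [400.0], "control": [1.0]},
                                   index=["P2"]),
            }
        )
        fc = compute_fold_changes(inputs)
        missing = fc[(fc["protein"] == "P1") & (fc["cell_line"] == "L2")]
        assert missing["target_intensity"].iloc[0] == 0.0
        assert missing["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_inputs({"L1": {"P1": (-5.0, 1.0)}})


class TestIntersect:
    def setup_method(self):
        self.fc = compute_fold_changes(
            make_inputs({
                "L1": {"both": (1e6, 1.0), "only_l1": (1e6, 1.0),
                       "weak": (50.0, 1.0)},
                "L2": {"both": (1e6, 1.0), "only_l1": (5.0, 1.0),
                       "weak": (50.0, 1.0)},
            })
        )

    def test_mode_all_requires_every_line(self):
        assert intersect_enriched(self.fc, cell_line_mode="all") == {"both"}

    def test_mode_any_keeps_single_line_hits(self):
        assert intersect_enriched(self.fc, cell_line_mode="any") == \
            {"both", "only_l1"}

    def test_raising_cutoff_never_grows_set(self):
        for lo, hi in [(10.0, 100.0), (100.0, 1e4), (1e4, 1e7)]:
            s_lo = intersect_enriched(self.fc, cutoff=lo)
            s_hi = intersect_enriched(self.fc, cutoff=hi)
            assert s_hi <= s_lo


class TestSurfaceFilter:
    def test_exact_and_isoform_matches(self):
        kept = filter_surface({"P12345-2", "Q99999", "A00001"},
                              ["p12345", "q99999"])
        assert kept == {"P12345-2", "Q99999"}

    def test_isoform_stripping_off(self):
        kept = filter_surface({"P12345-2"}, ["P12345"], strip_isoform=False)
        assert kept == set()

    def test_empty_surface_list_warns_empty(self, caplog):
        assert filter_surface({"P1"}, []) == set()


class TestRanking:
    def test_planted_mimic_ranks_first(self, rng):
        query = EpitopeQuery("CSESVPALTAVETGHTS", "CE1")
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = {f"BG{k}": "".join(rng.choice(aa, size=300)) for k in range(20)}
        mimic = "".join(rng.choice(aa, size=300))
        planted = query.sequence[:14] + "AAA"  # 14/17 identity
        seqs["MIMIC"] = mimic[:100] + planted + mimic[117:]
        ranked = rank_candidates(seqs.keys(), seqs, query)
        assert ranked.iloc[0]["candidate"] == "MIMIC"
        assert ranked.iloc[0]["rank"] == 1

    def test_identical_sequences_tie_break_by_id(self):
        query = EpitopeQuery("MKTAYIAK", "q")
        seqs = {"ZZZ": "MKTAYIAKLL", "AAA": "MKTAYIAKLL"}
        ranked = rank_candidates(seqs.keys(), seqs, query)
        assert list(ranked["candidate"]) == ["AAA", "ZZZ"]
        assert ranked["raw_score"].nunique() == 1

    def test_empty_candidate_set(self):
        ranked = rank_candidates([], {}, EpitopeQuery("MKT", "q"))
        assert ranked.empty

    def test_missing_sequence_rejected(self):
        with pytest.raises(KeyError, match="P1"):
            rank_candidates(["P1"], {}, EpitopeQuery("MKT", "q"))


class TestFunnelMonotonicity:
    def test_stage_counts_never_grow(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        proteins = {f"P{k}": "".join(rng.choice(aa, size=120))
                    for k in range(30)}
        target = {p: float(rng.lognormal(5, 2)) for p in proteins}
        tables = {
            line: pd.DataFrame(
                {"rB9": [target[p] * float(rng.lognormal(0, 0.2))
                         for p in proteins],
                 "control": [10.0] * len(proteins)},
                index=list(proteins))
            for line in ("L1", "L2")
        }
        res = run_mimicry_funnel(
            EnrichmentInputs(tables=tables),
            surface_list=list(proteins)[:10],
            sequences=proteins,
            query=EpitopeQuery("MKTAYIAKQRQISFVK", "q"),
        )
        c = res.stage_counts
        assert c["proteins"] >= c["enriched"] >= c["surface"] >= c["ranked"]
        assert res.surface <= res.enriched


class TestCompetitionSummary:
    def test_identical_condition_means_give_null_f(self, rng):
        doses = [0, 25, 50, 100]
        rows = []
        # same replicate values in both conditions: zero condition effect
        base = {(d, r): float(rng.normal()) for d in doses for r in range(3)}
        for cond in ("antigen", "control"):
            for d in doses:
                for r in range(3):
                    rows.append({"readout": base[(d, r)], "condition": cond,
                                 "dose": d})
        tab = competition_summary(pd.DataFrame(rows))
        assert tab.loc["condition", "F"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc["interaction", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_2x2_matches_textbook_sums_of_squares(self):
        # cells: (a1,b1)=(1,2), (a1,b2)=(3,4), (a2,b1)=(5,6), (a2,b2)=(7,8)
        rows = []
        cells = {("a1", "b1"): [1.0, 2.0], ("a1", "b2"): [3.0, 4.0],
                 ("a2", "b1"): [5.0, 6.0], ("a2", "b2"): [7.0, 8.0]}
        for (cond, dose), vals in cells.items():
            for v in vals:
                rows.append({"readout": v, "condition": cond, "dose": dose})
        df = pd.DataFrame(rows)
        tab = competition_summary(df)
        y = df["readout"]
        grand = y.mean()
        # balanced design: SS_A = r*b*sum (mean_Ai - grand)^2 with r=2 reps, b=2
        mean_a = df.groupby("condition")["readout"].mean()
        ss_a = 4 * ((mean_a - grand) ** 2).sum()
        mean_b = df.groupby("dose")["readout"].mean()
        ss_b = 4 * ((mean_b - grand) ** 2).sum()
        assert tab.loc["condition", "sum_sq"] == pytest.approx(ss_a)
        assert tab.loc["dose", "sum_sq"] == pytest.approx(ss_b)
        assert tab.loc["interaction", "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            competition_summary(pd.DataFrame({"readout": [1.0], "dose": [1]}))
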