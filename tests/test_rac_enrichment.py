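"""Background-corrected enrichment, tallies, clustering, DIA differential."""

import numpy as np
import pandas as pd
import pytest

from bpcompete.io_formats import SpectralCountTable
from bpcompete.rac_enrichment import (
    ProteinSets,
    background_corrected_enrichment,
    classify_enriched_sets,
    differential_protein_abundance,
    hierarchical_cluster_order,
    pos_neg_counts,
    row_zscore,
)
from bpcompete.synthetic_data import simulate_dia_quant, simulate_spectral_counts


def make_table(rows, substrates=("WT",)):
    df = pd.DataFrame(rows, columns=["NE", "APT", *substrates]).astype(float)
    df.index = [f"p{i}" for i in range(len(df))]
    roles = {"NE": "NE", "APT": "APT", **{s: "substrate" for s in substrates}}
    return SpectralCountTable(df, roles)


class TestBackgroundCorrection:
    def test_arithmetic_identity(self):
        table = make_table([(3, 1, 4)])
        res = background_corrected_enrichment(table)
        assert res.matrix.loc["p0", "WT"] == pytest.approx(1.0)

    def test_substrate_equal_apt_gives_zero(self):
        table = make_table([(5, 2, 2)])
        res = background_corrected_enrichment(table)
        assert res.matrix.loc["p0", "WT"] == 0.0

    def test_zero_or_missing_ne_excluded(self):
        table = make_table([(0, 1, 4), (np.nan, 1, 4), (2, 1, 4)])
        res = background_corrected_enrichment(table)
        assert list(res.matrix.index) == ["p2"]
        reasons = dict(zip(res.excluded["protein_id"], res.excluded["reason"]))
        assert reasons == {"p0": "zero_NE", "p1": "missing_NE"}

    def test_scaling_all_columns_leaves_enrichment_unchanged(self, rng):
        values = rng.uniform(1, 10, size=(6, 4))
        t1 = make_table(values, substrates=("WT", "dnDEL"))
        t2 = make_table(values * 3.7, substrates=("WT", "dnDEL"))
        r1 = background_corrected_enrichment(t1)
        r2 = background_corrected_enrichment(t2)
        pd.testing.assert_frame_equal(r1.matrix, r2.matrix)

    def test_missing_apt_column_error(self):
        df = pd.DataFrame({"NE": [1.0], "WT": [2.0]}, index=["p0"])
        table = SpectralCountTable(df, {"NE": "NE", "WT": "substrate"})
        with pytest.raises(ValueError, match="APT"):
            background_corrected_enrichment(table)


class TestPosNegCounts:
    def test_all_positive_no_negatives(self):
        matrix = pd.DataFrame(
            {"WT": [1.0, 2.0], "dnDEL": [0.5, 3.0]}, index=["p0", "p1"]
        )
        tallies = pos_neg_counts(matrix, ["p0", "p1"])
        assert (tallies["n_neg"] == 0).all()
        assert (tallies["n_pos"] == 2).all()

    def test_hand_tally_five_proteins(self):
        matrix = pd.DataFrame(
            {
                "WT": [1.0, -1.0, 0.0, 2.0, -3.0],
                "dnDEL": [2.0, 1.0, 1.0, -1.0, -4.0],
            },
            index=[f"p{i}" for i in range(5)],
        )
        # p4 negative everywhere -> excluded by the inclusion rule
        tallies = pos_neg_counts(matrix, [f"p{i}" for i in range(5)])
        assert tallies.loc["WT", "n_pos"] == 2
        assert tallies.loc["WT", "n_neg"] == 1
        assert tallies.loc["WT", "n_zero"] == 1
        assert tallies.loc["dnDEL", "n_pos"] == 3
        assert tallies.loc["dnDEL", "n_neg"] == 1

    def test_tally_conservation(self, rng):
        matrix = pd.DataFrame(
            rng.choice([-1.0, 0.0, 1.0, 2.0], size=(20, 3)),
            index=[f"p{i}" for i in range(20)],
            columns=["a", "b", "c"],
        )
        members = [f"p{i}" for i in range(20)]
        tallies = pos_neg_counts(matrix, members)
        included = matrix.loc[(matrix > 0).any(axis=1)]
        totals = tallies["n_pos"] + tallies["n_neg"] + tallies["n_zero"]
        assert (totals == len(included)).all()


class TestRowZscore:
    def test_closed_form_row(self):
        z = row_zscore(pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}))
        assert z.iloc[0].tolist() == pytest.approx(
            [-1.2247448, 0.0, 1.2247448], abs=1e-6
        )

    def test_constant_row_becomes_zero(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            z = row_zscore(pd.DataFrame({"a": [5.0], "b": [5.0], "c": [5.0]}))
        assert (z.iloc[0] == 0).all()

    def test_rows_standardized(self, rng):
        m = pd.DataFrame(rng.uniform(0, 10, size=(8, 5)))
        z = row_zscore(m)
        assert np.allclose(z.mean(axis=1), 0)
        assert np.allclose(z.std(axis=1, ddof=0), 1)


class TestClustering:
    def test_identical_rows_adjacent(self):
        m = pd.DataFrame(
            {
                "a": [1.0, 9.0, 1.0, 5.0],
                "b": [2.0, 8.0, 2.0, 5.0],
            },
            index=["w", "x", "y", "z"],
        )
        rows, _ = hierarchical_cluster_order(m)
        iw, iy = rows.index("w"), rows.index("y")
        assert abs(iw - iy) == 1

    def test_four_row_toy_dendrogram(self):
        # 1-D values 0, 1, 10, 12: pairs (p0,p1) and (p2,p3) merge first
        m = pd.DataFrame(
            {"a": [0.0, 1.0, 10.0, 12.0], "b": [0.0, 1.0, 10.0, 12.0]},
            index=["p0", "p1", "p2", "p3"],
        )
        rows, _ = hierarchical_cluster_order(m)
        assert {tuple(rows[:2]), tuple(rows[2:])} == {("p0", "p1"), ("p2", "p3")}

    def test_input_row_order_invariance(self, rng):
        m = pd.DataFrame(
            rng.uniform(0, 10, size=(6, 4)),
            index=[f"p{i}" for i in range(6)],
            columns=list("abcd"),
        )
        rows1, cols1 = hierarchical_cluster_order(m)
        shuffled = m.sample(frac=1, random_state=3)
        rows2, cols2 = hierarchical_cluster_order(shuffled)
        assert rows1 == rows2 and cols1 == cols2

    def test_missing_values_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            hierarchical_cluster_order(m)


SETS = ProteinSets(frozenset({"P0000", "P0001"}), frozenset({"P0002"}))


class TestDifferential:
    def test_identical_groups_no_flags(self):
        df = pd.DataFrame(
            {
                "WT_1": [10.0, 20.0],
                "WT_2": [11.0, 21.0],
                "dnDEL_1": [10.0, 20.0],
                "dnDEL_2": [11.0, 21.0],
            },
            index=["P0000", "P0001"],
        )
        table = SpectralCountTable(
            df,
            {c: f"replicate:{c.rsplit('_', 1)[0]}" for c in df.columns},
        )
        out = differential_protein_abundance(table, "dnDEL", "WT", SETS)
        assert (out["log2fc"] == 0).all()
        assert not out["passes_loose"].any()
        assert not out["passes_stringent"].any()

    def test_planted_twofold_passes_stringent(self):
        enriched = {f"P{i:04d}": 1.0 for i in range(5)}  # 2-fold up
        table, truth = simulate_dia_quant(
            n_proteins=40, enriched=enriched, noise_sd=0.05, seed=2
        )
        out = differential_protein_abundance(table, "dnDEL", "WT", SETS)
        flagged = set(out.loc[out["passes_stringent"], "protein_id"])
        assert set(enriched) <= flagged

    def test_missing_value_exclusion_matches_brute_force(self):
        table, _ = simulate_dia_quant(n_proteins=50, missing_fraction=0.1, seed=4)
        out = differential_protein_abundance(table, "dnDEL", "WT")
        brute = int((~table.data.notna().all(axis=1)).sum())
        assert out.attrs["n_excluded_missing"] == brute
        assert len(out) == 50 - brute

    def test_small_group_rejected(self):
        df = pd.DataFrame({"WT_1": [1.0], "dnDEL_1": [1.0], "dnDEL_2": [2.0]},
                          index=["P0000"])
        table = SpectralCountTable(
            df, {c: f"replicate:{c.rsplit('_', 1)[0]}" for c in df.columns}
        )
        with pytest.raises(ValueError, match="< 2 replicate"):
            differential_protein_abundance(table, "dnDEL", "WT")


class TestClassifyEnriched:
    def test_empty_input(self):
        counts = classify_enriched_sets(pd.DataFrame())
        assert all(v == 0 for v in counts.values())

    def test_hand_tallied_fixture(self):
        rows = pd.DataFrame(
            {
                "protein_id": [f"p{i}" for i in range(8)],
                "log2fc": [1.0, 0.9, -0.8, 1.2, -1.1, 0.75, 0.1, 2.0],
                "p_value": [0.001] * 8,
                "category": [
                    "E/U2", "E/U2", "E/U2", "other RBP",
                    "other RBP", "other", "E/U2", "E/U2",
                ],
                "passes_stringent": [
                    True, True, True, True, True, True, False, True,
                ],
            }
        )
        counts = classify_enriched_sets(rows)
        assert counts["enriched_eu2"] == 3
        assert counts["depleted_eu2"] == 1
        assert counts["enriched_rbp"] == 1
        assert counts["depleted_rbp"] == 1
        assert counts["enriched_other"] == 1
        assert sum(counts.values()) == int(rows["passes_stringent"].sum())


def test_planted_spectral_enrichment_positive():
    enrichment_map = {"P0003": ("dnDEL", 4.0), "P0007": ("WT", 2.0)}
    table, truth = simulate_spectral_counts(
        n_proteins=30, enrichment_map=enrichment_map, seed=9
    )
    res = background_corrected_enrichment(table)
    assert res.matrix.loc["P0003", "dnDEL"] > 1.0
    assert res.matrix.loc["P0007", "WT"] > 0.5
    others = res.matrix.drop(index=["P0003", "P0007"])
    assert abs(others.values.mean()) < 0.2
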