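import numpy as np
import pandas as pd
import pytest

from dropscreen.io import CountTable, LibraryManifest
from dropscreen.scoring import (
    aggregate_replicates,
    compute_cs,
    filter_low_pd0,
    gene_med_cs,
    merge_libraries,
    score_screen,
)

from conftest import make_unit_counts


def small_manifest(n_genes=4, guides_per_gene=3, n_nt=4) -> LibraryManifest:
    rows = []
    for gi in range(n_genes):
        g = f"G{gi + 1}"
        for k in range(guides_per_gene):
            rows.append((f"{g}_sg{k + 1}", g, "targeting", "A"))
    for k in range(n_nt):
        rows.append((f"NT_{k + 1}", None, "nontargeting", "A"))
    return LibraryManifest(
        pd.DataFrame(rows, columns=["sgrna_id", "gene", "category", "sublibrary"])
    )


class TestPd0Filter:
    def test_strictly_less_than_boundary(self):
        table = make_unit_counts({f"g{c}": (c, 100) for c in (0, 49, 50, 51)})
        kept = filter_low_pd0(table, threshold=50)
        assert set(kept.counts.index) == {"g50", "g51"}

    def test_pd14_counts_irrelevant_to_filter(self):
        table = make_unit_counts({"a": (100, 0), "b": (100, 1000)})
        kept = filter_low_pd0(table, threshold=50)
        assert set(kept.counts.index) == {"a", "b"}

    def test_multi_unit_table_rejected(self):
        one = make_unit_counts({"a": (100, 100)}, replicate=1)
        two = make_unit_counts({"a": (100, 100)}, replicate=2)
        both = CountTable(
            pd.concat([one.counts, two.counts], axis=1),
            pd.concat([one.samples, two.samples], ignore_index=True),
        )
        with pytest.raises(ValueError, match="single analysis unit"):
            filter_low_pd0(both)


class TestComputeCs:
    def test_identical_timepoints_give_all_zero(self, toy_manifest):
        table = make_unit_counts(
            {"GENEA_sg1": (100, 100), "GENEB_sg1": (70, 70), "NT_1": (55, 55)}
        )
        scores = compute_cs(table, toy_manifest)
        np.testing.assert_allclose(scores["cs"], 0.0, atol=1e-12)

    def test_hand_arithmetic_oracle(self):
        """One depleted guide vs two flat NT controls: with a pseudocount
        of 1 the depth-normalization constant cancels in CS, leaving
        CS = log2(26/101)."""
        manifest = LibraryManifest(
            pd.DataFrame(
                {
                    "sgrna_id": ["g1", "NT_1", "NT_2"],
                    "gene": ["G1", None, None],
                    "category": ["targeting", "nontargeting", "nontargeting"],
                    "sublibrary": "A",
                }
            )
        )
        table = make_unit_counts({"g1": (100, 25), "NT_1": (100, 100), "NT_2": (100, 100)})
        scores = compute_cs(table, manifest).set_index("sgrna_id")
        assert scores.loc["g1", "cs"] == pytest.approx(np.log2(26 / 101), abs=1e-12)

    def test_nt_median_guide_scores_exactly_zero(self, toy_manifest):
        table = make_unit_counts(
            {"GENEA_sg1": (100, 10), "GENEB_sg1": (100, 400), "NT_1": (80, 80)}
        )
        scores = compute_cs(table, toy_manifest).set_index("sgrna_id")
        assert scores.loc["NT_1", "cs"] == 0.0

    def test_no_surviving_nt_is_hard_error(self):
        manifest = small_manifest(n_genes=1, n_nt=0)
        table = make_unit_counts({"G1_sg1": (100, 50), "G1_sg2": (100, 50), "G1_sg3": (100, 50)})
        with pytest.raises(ValueError, match="nontargeting"):
            compute_cs(table, manifest)

    def test_depth_rescaling_leaves_cs_nearly_invariant(self):
        """Multiplying one sample's counts by k>0 shifts every L by the
        same constant, which the NT-median subtraction absorbs up to a
        pseudocount effect that vanishes as counts grow; at typical
        per-guide depths the residual stays below 0.02."""
        manifest = small_manifest(n_genes=40, guides_per_gene=3, n_nt=30)
        rng = np.random.default_rng(0)
        raw = {
            sg: (int(c0), int(c14))
            for sg, c0, c14 in zip(
                manifest.sgrna_ids,
                rng.integers(150, 5000, len(manifest.sgrna_ids)),
                rng.integers(150, 5000, len(manifest.sgrna_ids)),
            )
        }
        table = make_unit_counts(raw)
        base = compute_cs(table, manifest)
        scaled_counts = table.counts.copy()
        pd14_col = [c for c in scaled_counts.columns if c.endswith("PD14")][0]
        scaled_counts[pd14_col] = scaled_counts[pd14_col] * 7
        scaled = compute_cs(CountTable(scaled_counts, table.samples), manifest)
        delta = np.abs(base["cs"].to_numpy() - scaled["cs"].to_numpy())
        assert delta.max() < 0.02


class TestAggregateReplicates:
    def _frame(self, cs: dict[str, float], rep: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sgrna_id": list(cs),
                "gene": [s.split("_")[0] for s in cs],
                "log2fc": list(cs.values()),
                "cs": list(cs.values()),
                "cell_line": "CL",
                "library": "A",
                "replicate": rep,
            }
        )

    def test_mean_across_replicates(self):
        agg = aggregate_replicates(
            [self._frame({"G1_sg1": -2.0}, 1), self._frame({"G1_sg1": -1.0}, 2)]
        ).set_index("sgrna_id")
        assert agg.loc["G1_sg1", "cs"] == -1.5
        assert agg.loc["G1_sg1", "n_reps"] == 2

    def test_guide_filtered_in_one_replicate_keeps_other(self):
        agg = aggregate_replicates(
            [
                self._frame({"G1_sg1": -2.0, "G1_sg2": -0.5}, 1),
                self._frame({"G1_sg1": -1.0}, 2),
            ]
        ).set_index("sgrna_id")
        assert agg.loc["G1_sg2", "cs"] == -0.5
        assert agg.loc["G1_sg2", "n_reps"] == 1

    def test_single_replicate_is_identity(self):
        frame = self._frame({"G1_sg1": -2.0, "G1_sg2": 0.25}, 1)
        agg = aggregate_replicates([frame])
        np.testing.assert_allclose(agg["cs"], frame["cs"])


class TestGeneMedCs:
    def test_odd_count_median(self):
        manifest = small_manifest(n_genes=1, guides_per_gene=3)
        scores = pd.DataFrame(
            {"sgrna_id": ["G1_sg1", "G1_sg2", "G1_sg3"], "gene": "G1", "cs": [-3.0, -2.0, -1.0]}
        )
        out = gene_med_cs(scores, manifest).set_index("gene")
        assert out.loc["G1", "med_cs"] == -2.0
        assert out.loc["G1", "status"] == "scored"

    def test_even_count_takes_mean_of_central_pair(self):
        manifest = small_manifest(n_genes=1, guides_per_gene=6)
        scores = pd.DataFrame(
            {
                "sgrna_id": [f"G1_sg{k}" for k in range(1, 7)],
                "gene": "G1",
                "cs": [-4.0, -2.0, -1.0, 0.0, 1.0, 3.0],
            }
        )
        out = gene_med_cs(scores, manifest).set_index("gene")
        # central order statistics are -1 and 0
        assert out.loc["G1", "med_cs"] == -0.5

    def test_insufficient_guides_not_scored(self):
        manifest = small_manifest(n_genes=1, guides_per_gene=3)
        scores = pd.DataFrame(
            {"sgrna_id": ["G1_sg1", "G1_sg2"], "gene": "G1", "cs": [-3.0, -2.0]}
        )
        out = gene_med_cs(scores, manifest, min_guides=3).set_index("gene")
        assert out.loc["G1", "status"] == "insufficient_guides"
        assert np.isnan(out.loc["G1", "med_cs"])
        assert out.loc["G1", "n_guides_used"] == 2

    def test_nontargeting_guides_never_contribute(self, toy_manifest):
        scores = pd.DataFrame(
            {
                "sgrna_id": ["GENEA_sg1", "NT_1"],
                "gene": ["GENEA", None],
                "cs": [-1.0, -9.0],
            }
        )
        out = gene_med_cs(scores, toy_manifest, min_guides=1).set_index("gene")
        assert out.loc["GENEA", "med_cs"] == -1.0
        assert set(out.index) == {"GENEA", "GENEB"}


class TestMergeLibraries:
    def _half(self, cs: dict[str, float], lib: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sgrna_id": list(cs),
                "gene": "G1",
                "log2fc": list(cs.values()),
                "cs": list(cs.values()),
                "cell_line": "CL",
                "library": lib,
                "n_reps": 2,
            }
        )

    def test_merged_gene_pools_six_guides(self):
        a = self._half({"G1_sg1": -4.0, "G1_sg3": -2.0, "G1_sg5": -1.0}, "A")
        b = self._half({"G1_sg2": 0.0, "G1_sg4": 1.0, "G1_sg6": 3.0}, "B")
        merged = merge_libraries(a, b)
        assert len(merged) == 6

    def test_pooled_median_not_mean_of_half_medians(self):
        """Constructed counterexample: the med.CS of the merged library is
        the median of the pooled six values (-0.5), not the mean of the
        two half-library medians (0.0)."""
        manifest = small_manifest(n_genes=1, guides_per_gene=6)
        a = self._half({"G1_sg1": -4.0, "G1_sg3": -2.0, "G1_sg5": -1.0}, "A")
        b = self._half({"G1_sg2": 0.0, "G1_sg4": 2.0, "G1_sg6": 3.0}, "B")
        pooled = gene_med_cs(merge_libraries(a, b), manifest).set_index("gene")
        assert pooled.loc["G1", "med_cs"] == -0.5
        half_medians = np.mean([np.median(a["cs"]), np.median(b["cs"])])
        assert half_medians == 0.0
        assert pooled.loc["G1", "med_cs"] != pytest.approx(half_medians)

    def test_overlapping_guides_rejected(self):
        a = self._half({"G1_sg1": -1.0}, "A")
        with pytest.raises(ValueError, match="share guide ids"):
            merge_libraries(a, a)

    def test_empty_half_is_identity(self):
        a = self._half({"G1_sg1": -1.0}, "A")
        out = merge_libraries(a, a.iloc[0:0])
        pd.testing.assert_frame_equal(out, a)


class TestPipeline:
    def test_nt_median_is_zero_in_every_replicate_unit(self, default_sim):
        params, manifest, counts, _, _ = default_sim
        from dropscreen.scoring import iter_units

        for (cl, lib, rep), pd0_id, pd14_id in iter_units(counts):
            sub = counts.select_samples([pd0_id, pd14_id])
            scores = compute_cs(filter_low_pd0(sub, manifest), manifest)
            nt = scores[scores["gene"].isna()]["cs"]
            assert np.median(nt) == 0.0

    def test_determinism_bit_identical(self, toy_manifest):
        table = make_unit_counts(
            {"GENEA_sg1": (100, 10), "GENEB_sg1": (100, 400), "NT_1": (80, 80)}
        )
        out1 = score_screen(table, toy_manifest, min_guides=1)
        out2 = score_screen(table, toy_manifest, min_guides=1)
        for cl in out1["gene_scores"]:
            pd.testing.assert_frame_equal(out1["gene_scores"][cl], out2["gene_scores"][cl])

    def test_recovery_tracks_truth_on_essentials(self, default_sim):
        """Gene med.CS tracks the closed-form expected log2 fold-change
        D*s_g*mean(e_i) among essential genes (where the truth varies)."""
        from scipy import stats

        params, _, _, truth, results = default_sim
        g = results.gene_scores["PDX1"]
        scored = g[g["status"] == "scored"].set_index("gene")["med_cs"]
        expected = truth.expected_gene_lfc(params.doublings)
        essentials = [k for k, v in truth.essential_labels.items() if v]
        common = scored.index.intersection(essentials)
        rho = stats.spearmanr(scored.loc[common], expected.loc[common]).statistic
        assert rho >= 0.8
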