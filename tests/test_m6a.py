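"""Gene-level m6A summaries: filtering, merging, mapping, counting, breadth."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from m6abreadth.m6a import (
    build_gene_summary,
    classify_genes,
    compute_breadth,
    count_corrected_conditions,
    filter_perturbed_profiles,
    identify_none_genes,
    map_peaks_to_genes,
    merge_replicates,
)
from conftest import make_profile
from _oracles import interval_union_membership


def _atlas(rows, columns):
    return pd.DataFrame(rows, index=pd.Index([r for r in rows], name="gene_id"), columns=columns) if isinstance(rows, dict) else rows


class TestPerturbationFilter:
    @pytest.mark.parametrize(
        "perturbed, kept",
        [
            ({"METTL3"}, False),
            ({"METTL14"}, False),
            ({"WTAP"}, False),
            ({"ALKBH5"}, False),
            ({"FTO"}, False),
            (set(), True),
            ({"YTHDF2"}, True),      # reader perturbation does not disqualify
            ({"YTHDF2", "FTO"}, False),
        ],
    )
    def test_core_component_rule(self, perturbed, kept):
        p = make_profile("c1", "r1", [("chr1", 0, 10, "+", 1.0)], perturbed=perturbed)
        out = filter_perturbed_profiles([p])
        assert (len(out) == 1) is kept


class TestMergeReplicates:
    def test_single_replicate_identity(self):
        p = make_profile("c1", "r1", [("chr1", 5, 20, "+", 1.0)])
        merged = merge_replicates([p])["c1"]
        assert merged[["start", "end"]].values.tolist() == [[5, 20]]

    def test_disjoint_peaks_both_present(self):
        p1 = make_profile("c1", "r1", [("chr1", 0, 10, "+", 1.0)])
        p2 = make_profile("c1", "r2", [("chr1", 50, 60, "+", 1.0)])
        merged = merge_replicates([p1, p2])["c1"]
        assert len(merged) == 2

    def test_duplicate_peaks_collapse(self):
        p1 = make_profile("c1", "r1", [("chr1", 0, 10, "+", 1.0)])
        p2 = make_profile("c1", "r2", [("chr1", 0, 10, "+", 2.0)])
        merged = merge_replicates([p1, p2])["c1"]
        assert len(merged) == 1

    def test_union_against_membership_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(1, 30)
            starts = rng.integers(0, 500, size=n)
            lengths = rng.integers(1, 60, size=n)
            peaks = [("chr1", int(s), int(s + l), "+", 1.0) for s, l in zip(starts, lengths)]
            half = n // 2 or 1
            p1 = make_profile("c", "r1", peaks[:half])
            p2 = make_profile("c", "r2", peaks[half:]) if peaks[half:] else None
            merged = merge_replicates([p for p in (p1, p2) if p is not None])["c"]
            merged_iv = list(merged[["start", "end"]].itertuples(index=False, name=None))
            raw_iv = [(s, e) for _, s, e, _, _ in peaks]
            for point in rng.integers(0, 600, size=100):
                assert interval_union_membership(merged_iv, point) == interval_union_membership(raw_iv, point)
            # merged intervals are disjoint and sorted
            assert all(merged_iv[i][1] <= merged_iv[i + 1][0] for i in range(len(merged_iv) - 1))


class TestMapping:
    def test_peak_inside_transcript(self, simple_genes):
        merged = {"c1": pd.DataFrame([("chr1", 200, 250, "+")], columns=["contig", "start", "end", "strand"])}
        inc = map_peaks_to_genes(merged, simple_genes)
        assert inc.values.tolist() == [["gA", "c1"]]

    def test_many_peaks_count_once_per_condition(self, simple_genes):
        peaks = pd.DataFrame(
            [("chr1", 100 + 20 * i, 110 + 20 * i, "+") for i in range(5)],
            columns=["contig", "start", "end", "strand"],
        )
        inc = map_peaks_to_genes({"c1": peaks}, simple_genes)
        assert len(inc) == 1  # five peaks, one regulated condition

    def test_opposite_strand_no_overlap_when_stranded(self, simple_genes):
        merged = {"c1": pd.DataFrame([("chr1", 1100, 1150, "+")], columns=["contig", "start", "end", "strand"])}
        assert len(map_peaks_to_genes(merged, simple_genes, stranded=True)) == 0
        assert map_peaks_to_genes(merged, simple_genes, stranded=False)["gene_id"].tolist() == ["gB"]

    def test_dot_strand_matches_both(self, simple_genes):
        merged = {"c1": pd.DataFrame([("chr1", 1100, 1150, ".")], columns=["contig", "start", "end", "strand"])}
        assert map_peaks_to_genes(merged, simple_genes, stranded=True)["gene_id"].tolist() == ["gB"]

    def test_unknown_contig_skipped(self, simple_genes, caplog):
        merged = {"c1": pd.DataFrame([("chrUn", 0, 50, "+")], columns=["contig", "start", "end", "strand"])}
        with caplog.at_level("WARNING"):
            inc = map_peaks_to_genes(merged, simple_genes)
        assert len(inc) == 0
        assert "unknown contig" in caplog.text

    def test_incidence_invariant_to_peak_order(self, simple_genes):
        peaks = pd.DataFrame(
            [("chr1", 400, 450, "+"), ("chr1", 120, 180, "+"), ("chr2", 100, 160, "+")],
            columns=["contig", "start", "end", "strand"],
        )
        inc1 = map_peaks_to_genes({"c": peaks}, simple_genes)
        inc2 = map_peaks_to_genes({"c": peaks.iloc[::-1].reset_index(drop=True)}, simple_genes)
        pd.testing.assert_frame_equal(inc1, inc2)


class TestCorrectedCounts:
    def _counts(self, incidence_pairs, atlas, covered):
        inc = pd.DataFrame(incidence_pairs, columns=["gene_id", "condition_id"])
        return count_corrected_conditions(inc, atlas, covered)

    def test_simple_division(self):
        atlas = pd.DataFrame(
            {"ct1": [1.0], "ct2": [2.0], "ct3": [3.0], "ct4": [1.0], "ct5": [1.0], "ct6": [0.0]},
            index=pd.Index(["g"], name="gene_id"),
        )
        pairs = [("g", f"c{i}") for i in range(10)]
        out = self._counts(pairs, atlas, ["ct1", "ct2", "ct3", "ct4", "ct5"])
        assert out.loc["g", "corrected_conditions"] == pytest.approx(2.0)

    def test_tpm_strictly_greater(self):
        atlas = pd.DataFrame(
            {"ct1": [0.6], "ct2": [0.5], "ct3": [2.0]}, index=pd.Index(["g"], name="gene_id")
        )
        out = self._counts([("g", "c1")], atlas, ["ct1", "ct2", "ct3"])
        assert out.loc["g", "n_expressed_covered_celltypes"] == 2  # TPM must exceed 0.5

    def test_zero_expressed_undefined(self):
        atlas = pd.DataFrame({"ct1": [0.1]}, index=pd.Index(["g"], name="gene_id"))
        out = self._counts([("g", "c1"), ("g", "c2"), ("g", "c3")], atlas, ["ct1"])
        assert math.isnan(out.loc["g", "corrected_conditions"])
        assert classify_genes(out)["g"] == "unexpressed"

    def test_inverse_scaling_in_expressed_celltypes(self):
        # doubling the expressed covered cell types halves corrected exactly
        atlas1 = pd.DataFrame({"a": [2.0], "b": [2.0]}, index=pd.Index(["g"], name="gene_id"))
        atlas2 = pd.DataFrame(
            {"a": [2.0], "b": [2.0], "c": [2.0], "d": [2.0]}, index=pd.Index(["g"], name="gene_id")
        )
        pairs = [("g", f"c{i}") for i in range(6)]
        c1 = self._counts(pairs, atlas1, ["a", "b"]).loc["g", "corrected_conditions"]
        c2 = self._counts(pairs, atlas2, ["a", "b", "c", "d"]).loc["g", "corrected_conditions"]
        assert c1 == pytest.approx(2 * c2)


class TestClassification:
    def _frame(self, corrected, raw=None, n_expr=4):
        n = len(corrected)
        return pd.DataFrame(
            {
                "n_conditions_regulated": raw if raw is not None else [max(1, int(c * n_expr)) for c in corrected],
                "n_expressed_covered_celltypes": [n_expr] * n,
                "corrected_conditions": corrected,
            },
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )

    def test_threshold_boundaries(self):
        counts = self._frame([3.6, 3.5, 1.5, 1.4], raw=[14, 14, 6, 6])
        labels = classify_genes(counts)
        assert labels.tolist() == ["freq", "intermediate", "occa", "occa"]

    def test_zero_conditions_is_none_when_expressed(self):
        counts = pd.DataFrame(
            {
                "n_conditions_regulated": [0],
                "n_expressed_covered_celltypes": [3],
                "corrected_conditions": [0.0],
            },
            index=pd.Index(["g"], name="gene_id"),
        )
        assert classify_genes(counts)["g"] == "none"


class TestNoneGenes:
    def test_expressed_unmethylated_only(self):
        atlas = pd.DataFrame(
            {"ct1": [1.0, 1.0, 0.1]}, index=pd.Index(["expressed_meth", "expressed_un", "silent"], name="gene_id")
        )
        inc = pd.DataFrame([("expressed_meth", "c1")], columns=["gene_id", "condition_id"])
        none = identify_none_genes(inc, atlas, ["ct1"])
        assert list(none) == ["expressed_un"]


class TestBreadth:
    def _profiles_with_scores(self, scores_by_condition, gene=("chr1", 100, 500, "+")):
        profiles = []
        for cond, score in scores_by_condition.items():
            peaks = [(gene[0], 150, 200, gene[3], score)] if score > 0 else []
            profiles.append(make_profile(cond, "r1", peaks))
        return profiles

    def _gene_df(self):
        return pd.DataFrame(
            [("gA", "gA.t1", "chr1", 100, 500, "+")],
            columns=["gene_id", "transcript_id", "contig", "start", "end", "strand"],
        )

    def test_flat_profile_breadth_one(self):
        profiles = self._profiles_with_scores({f"c{i}": 5.0 for i in range(6)})
        b = compute_breadth(profiles, self._gene_df())
        assert b["gA"] == pytest.approx(1.0)

    def test_single_condition_breadth_zero(self):
        scores = {f"c{i}": (7.0 if i == 0 else 0.0) for i in range(6)}
        b = compute_breadth(self._profiles_with_scores(scores), self._gene_df())
        assert b["gA"] == pytest.approx(0.0)

    def test_closed_form_from_transformed_scores(self):
        # choose raw scores whose log10(x+1) are exactly [8, 2, 2, 2]
        raw = {f"c{i}": v for i, v in enumerate([1e8 - 1, 99.0, 99.0, 99.0])}
        b = compute_breadth(self._profiles_with_scores(raw), self._gene_df())
        assert b["gA"] == pytest.approx(1 - 0.75)

    def test_max_over_transcripts_then_replicate_mean(self, simple_genes):
        # gC has two transcripts; peak at 250-260 hits both (sum goes to each),
        # peak at 50-60 hits only t1
        p1 = make_profile("c1", "r1", [("chr2", 250, 260, "+", 4.0), ("chr2", 50, 60, "+", 3.0)])
        p2 = make_profile("c1", "r2", [("chr2", 250, 260, "+", 2.0)])
        _, scores = compute_breadth([p1, p2], simple_genes, return_scores=True)
        # r1: t1 total = 7, t2 total = 4 -> max 7; r2: max 2; mean 4.5
        assert scores.loc["gC", "c1"] == pytest.approx(np.log10(4.5 + 1))

    def test_all_zero_gene_excluded(self, simple_genes):
        p = make_profile("c1", "r1", [("chr1", 200, 260, "+", 1.0)])
        b = compute_breadth([p], simple_genes)
        assert "gB" not in b.dropna().index


class TestEndToEndSummary:
    def test_replicate_union_equivalence_oracle(self, simple_genes):
        """Binary incidence from merged replicates equals gene-wise union of
        per-replicate incidences."""
        rng = np.random.default_rng(7)
        profiles = []
        for cond in ("c1", "c2", "c3"):
            for rep in ("r1", "r2"):
                peaks = []
                for _ in range(rng.integers(0, 8)):
                    contig = rng.choice(["chr1", "chr2"])
                    s = int(rng.integers(0, 1400))
                    strand = rng.choice(["+", "-"])
                    peaks.append((contig, s, s + 50, strand, 1.0))
                profiles.append(make_profile(cond, rep, peaks))
        merged_inc = map_peaks_to_genes(merge_replicates(profiles), simple_genes)
        per_rep = []
        for p in profiles:
            one = map_peaks_to_genes(merge_replicates([p]), simple_genes)
            one["condition_id"] = p.condition_id
            per_rep.append(one)
        union_inc = (
            pd.concat(per_rep).drop_duplicates().sort_values(["gene_id", "condition_id"]).reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(merged_inc, union_inc)

    def test_build_gene_summary_columns(self, simple_genes):
        atlas = pd.DataFrame(
            {"ct1": [1.0, 1.0, 1.0]}, index=pd.Index(["gA", "gB", "gC"], name="gene_id")
        )
        profiles = [make_profile("c1", "r1", [("chr1", 200, 260, "+", 2.0)])]
        out = build_gene_summary(profiles, simple_genes, atlas, ["ct1"])
        assert {"n_conditions_regulated", "n_expressed_covered_celltypes",
                "corrected_conditions", "class_label", "breadth"} <= set(out.columns)
        assert out.loc["gA", "n_conditions_regulated"] == 1
        assert out.loc["gB", "class_label"] == "none"
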