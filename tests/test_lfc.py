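"""Depth normalization, log2 fold changes, and the T0 abundance filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenscore import (
    CountTable,
    GuideLibrary,
    SampleSheet,
    ValidationError,
    compute_guide_lfc,
    filter_guides,
    normalize_depth,
)


def make_counts(values, guides=None, samples=None) -> CountTable:
    arr = np.asarray(values, dtype=np.int64)
    guides = guides or [f"sg{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountTable(
        counts=pd.DataFrame(arr, index=pd.Index(guides, name="guide_id"),
                            columns=samples)
    )


class TestNormalizeDepth:
    def test_proportions_times_scale(self):
        norm = normalize_depth(make_counts([[10], [90]]))
        assert np.allclose(norm.values["s0"], [100000, 900000])

    def test_derived_three_guide_case(self):
        norm = normalize_depth(make_counts([[3], [7], [10]]))
        assert np.allclose(norm.values["s0"], [150000, 350000, 500000])

    def test_column_sums_equal_scale(self):
        rng = np.random.default_rng(0)
        norm = normalize_depth(make_counts(rng.integers(0, 500, (40, 3))))
        assert np.allclose(norm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_column_names_sample(self):
        with pytest.raises(ValidationError, match="s1"):
            normalize_depth(make_counts([[1, 0], [2, 0]]))

    @given(k=st.integers(min_value=2, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, k):
        """Multiplying a column's raw counts by k leaves RPM unchanged."""
        base = make_counts([[5], [15], [80]])
        scaled = make_counts([[5 * k], [15 * k], [80 * k]])
        assert np.allclose(
            normalize_depth(base).values, normalize_depth(scaled).values
        )


class TestComputeGuideLfc:
    def test_equal_abundance_gives_zero(self, small_sheet):
        counts = make_counts(
            [[100, 100, 100]] * 2,
            guides=["g1", "g2"],
            samples=["T0_r1", "MOCK_r1", "DRUG_r1"],
        )
        lfcs = compute_guide_lfc(normalize_depth(counts), small_sheet)
        assert np.allclose(lfcs["lfc"], 0.0)

    def test_derived_log_ratio(self):
        # normalized 100 at T0 vs 400 treated, pseudocount 0.5
        assert np.isclose(np.log2(400.5 / 100.5), 1.9946, atol=1e-4)
        sheet = SampleSheet(
            frame=pd.DataFrame(
                {
                    "condition": ["T0", "DRUG"],
                    "bio_rep": [1, 1],
                    "tech_rep": [1, 1],
                    "t0_ref": ["", "t0"],
                },
                index=pd.Index(["t0", "d"], name="sample_id"),
            )
        )
        counts = make_counts(
            [[100, 400], [900, 600]], guides=["g1", "g2"], samples=["t0", "d"]
        )
        # depth differs between the columns; build norm so values are exact
        norm = normalize_depth(counts, scale=1000)
        lfcs = compute_guide_lfc(norm, sheet).set_index("guide_id")
        assert np.isclose(lfcs.loc["g1", "lfc"], np.log2(400.5 / 100.5))

    def test_zero_treated_count_stays_finite(self):
        sheet = SampleSheet(
            frame=pd.DataFrame(
                {
                    "condition": ["T0", "DRUG"],
                    "bio_rep": [1, 1],
                    "tech_rep": [1, 1],
                    "t0_ref": ["", "t0"],
                },
                index=pd.Index(["t0", "d"], name="sample_id"),
            )
        )
        counts = make_counts(
            [[100, 0], [900, 1000]], guides=["g1", "g2"], samples=["t0", "d"]
        )
        norm = normalize_depth(counts, scale=1000)
        lfcs = compute_guide_lfc(norm, sheet).set_index("guide_id")
        assert np.isclose(lfcs.loc["g1", "lfc"], np.log2(0.5 / 100.5), atol=1e-3)

    def test_antisymmetry_under_role_swap(self):
        """Swapping treated and T0 roles negates the lfc."""
        rng = np.random.default_rng(3)
        vals = rng.integers(10, 1000, (30, 2))
        frame = pd.DataFrame(
            {
                "condition": ["T0", "DRUG"],
                "bio_rep": [1, 1],
                "tech_rep": [1, 1],
                "t0_ref": ["", "a"],
            },
            index=pd.Index(["a", "b"], name="sample_id"),
        )
        fwd = compute_guide_lfc(
            normalize_depth(make_counts(vals, samples=["a", "b"])),
            SampleSheet(frame=frame),
        )
        swapped = frame.copy()
        swapped.loc["a", ["condition", "t0_ref"]] = ["DRUG", "b"]
        swapped.loc["b", ["condition", "t0_ref"]] = ["T0", ""]
        # equalize column depths so the swap is exact, not just approximate
        norm = normalize_depth(make_counts(vals, samples=["a", "b"]))
        rev = compute_guide_lfc(norm, SampleSheet(frame=swapped))
        assert np.allclose(
            fwd.sort_values("guide_id")["lfc"].to_numpy(),
            -rev.sort_values("guide_id")["lfc"].to_numpy(),
        )

    def test_zero_pseudocount_with_zero_count_rejected(self, small_sheet):
        counts = make_counts(
            [[100, 100, 0], [100, 100, 200]],
            guides=["g1", "g2"],
            samples=["T0_r1", "MOCK_r1", "DRUG_r1"],
        )
        with pytest.raises(ValidationError, match="pseudocount"):
            compute_guide_lfc(normalize_depth(counts), small_sheet, pseudocount=0.0)


class TestFilterGuides:
    @pytest.fixture
    def lib(self):
        frame = pd.DataFrame(
            {
                "guide_id": [f"sg{g}_{i}" for g in "AB" for i in range(4)],
                "gene": [g for g in "AB" for _ in range(4)],
            }
        )
        return GuideLibrary(frame=frame)

    def make(self, t0_counts, lib):
        guides = list(lib.guides)
        counts = make_counts(
            np.column_stack([t0_counts, np.full(8, 100), np.full(8, 100)]),
            guides=guides,
            samples=["T0_r1", "MOCK_r1", "DRUG_r1"],
        )
        sheet = SampleSheet(
            frame=pd.DataFrame(
                {
                    "condition": ["T0", "MOCK", "DRUG"],
                    "bio_rep": [1, 1, 1],
                    "tech_rep": [1, 1, 1],
                    "t0_ref": ["", "T0_r1", "T0_r1"],
                },
                index=pd.Index(["T0_r1", "MOCK_r1", "DRUG_r1"],
                               name="sample_id"),
            )
        )
        return counts, sheet

    def test_boundary_29_removed_30_retained(self, lib):
        counts, sheet = self.make([29, 30, 100, 100, 100, 100, 100, 100], lib)
        filt = filter_guides(counts, lib, sheet)
        assert "sgA_0" not in filt.retained_guides
        assert "sgA_1" in filt.retained_guides

    def test_gene_with_two_survivors_excluded(self, lib):
        counts, sheet = self.make([10, 10, 100, 100, 100, 100, 100, 100], lib)
        filt = filter_guides(counts, lib, sheet)
        assert "A" not in filt.retained_genes  # only 2 of 4 guides left
        assert "B" in filt.retained_genes
        assert filt.report["n_guides_removed"] == 2
        assert filt.report["n_genes_removed"] == 1

    def test_exactly_three_survivors_keeps_gene(self, lib):
        counts, sheet = self.make([10, 100, 100, 100, 100, 100, 100, 100], lib)
        filt = filter_guides(counts, lib, sheet)
        assert "A" in filt.retained_genes

    def test_no_t0_sample_rejected(self, lib):
        counts, _ = self.make([100] * 8, lib)
        sheet_no_t0 = pd.DataFrame(
            {
                "condition": ["T0", "MOCK"],
                "bio_rep": [1, 1],
                "tech_rep": [1, 1],
                "t0_ref": ["", "other_t0"],
            },
            index=pd.Index(["other_t0", "MOCK_r1"], name="sample_id"),
        )
        with pytest.raises(ValidationError, match="T0"):
            filter_guides(
                CountTable(counts=counts.counts[["MOCK_r1", "DRUG_r1"]]),
                lib,
                SampleSheet(frame=sheet_no_t0),
            )

    @pytest.mark.parametrize("mode", ["replicate", "global"])
    def test_filter_monotone_in_threshold(self, lib, mode):
        """Raising min_t0_count never enlarges the retained guide set."""
        rng = np.random.default_rng(7)
        counts, sheet = self.make(rng.integers(0, 120, 8), lib)
        prev = None
        for thr in [10, 30, 60, 100]:
            filt = filter_guides(counts, lib, sheet, min_t0_count=thr, mode=mode)
            cur = set(filt.retained_guides)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_replicate_wise_retention(self, lib):
        """A guide failing one replicate's T0 keeps its other replicate."""
        guides = list(lib.guides)
        counts = make_counts(
            np.column_stack([
                [5] + [100] * 7,    # T0_r1: sgA_0 fails here
                [100] * 8,          # T0_r2
                [100] * 8, [100] * 8, [100] * 8, [100] * 8,
            ]),
            guides=guides,
            samples=["T0_r1", "T0_r2", "MOCK_r1", "MOCK_r2", "DRUG_r1", "DRUG_r2"],
        )
        sheet = SampleSheet(
            frame=pd.DataFrame(
                {
                    "condition": ["T0", "T0", "MOCK", "MOCK", "DRUG", "DRUG"],
                    "bio_rep": [1, 2, 1, 2, 1, 2],
                    "tech_rep": [1] * 6,
                    "t0_ref": ["", "", "T0_r1", "T0_r2", "T0_r1", "T0_r2"],
                },
                index=pd.Index(counts.samples, name="sample_id"),
            )
        )
        filt = filter_guides(counts, lib, sheet, mode="replicate")
        assert "sgA_0" in filt.retained_guides
        assert not filt.guide_passes("sgA_0", "T0_r1")
        assert filt.guide_passes("sgA_0", "T0_r2")
        # global mode drops it outright
        filt_g = filter_guides(counts, lib, sheet, mode="global")
        assert "sgA_0" not in filt_g.retained_guides
        # and the lfc table only carries the passing replicate
        lfcs = compute_guide_lfc(normalize_depth(counts), sheet, retained=filt)
        obs = lfcs[lfcs["guide_id"] == "sgA_0"]
        assert set(obs["bio_rep"]) == {2}
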