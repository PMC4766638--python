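"""Roll-up, normalisation and differential-abundance behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlim import quant
from nlim.io_formats import PeptideRecord
from oracles import pooled_t_p_oracle

S = ["r1_114", "r1_116"]  # one highN, one lowN sample


def _pep(protein_ids, values, sequence="PEPK", source="global"):
    return PeptideRecord(
        sequence=sequence,
        protein_ids=protein_ids,
        phospho_sites=[],
        intensities=dict(zip(S, values)),
        source=source,
    )


class TestRollup:
    def test_sums_peptides_per_protein(self):
        raw = quant.rollup(
            [_pep(["P"], (100, 200), "AK"), _pep(["P"], (50, 50), "BK")]
        )
        assert list(raw.loc["P"]) == [150, 250]

    def test_shared_peptide_counts_only_for_first_protein(self):
        raw = quant.rollup([_pep(["P", "Q"], (10, 10), "AK"), _pep(["Q"], (1, 1), "BK")])
        assert list(raw.loc["P"]) == [10, 10]
        assert list(raw.loc["Q"]) == [1, 1]

    def test_empty_input_gives_empty_matrix(self):
        assert quant.rollup([]).empty

    def test_all_zero_peptide_gives_zero_row(self):
        raw = quant.rollup([_pep(["P"], (0, 0), "AK")])
        assert list(raw.loc["P"]) == [0, 0]

    def test_rollup_conserves_total_intensity(self, dataset):
        raw = quant.rollup(dataset.peptides, "global")
        total_peptides = sum(
            sum(p.intensities.values())
            for p in dataset.peptides
            if p.source == "global"
        )
        assert raw.to_numpy().sum() == pytest.approx(total_peptides, rel=1e-12)


class TestNormalize:
    CONDITIONS = pd.Series({"a": "highN", "b": "lowN"})

    def test_log2_then_centre(self):
        raw = pd.DataFrame({"a": [4.0, 8.0, 16.0], "b": [2.0, 2.0, 2.0]}, index=list("xyz"))
        m = quant.normalize(raw, self.CONDITIONS)
        assert list(m.values["a"]) == [-1.0, 0.0, 1.0]
        assert list(m.values["b"]) == [0.0, 0.0, 0.0]

    def test_zeros_become_missing_not_minus_inf(self):
        raw = pd.DataFrame({"a": [0.0, 8.0], "b": [4.0, 4.0]}, index=list("xy"))
        m = quant.normalize(raw, self.CONDITIONS)
        assert np.isnan(m.values.loc["x", "a"])

    def test_entirely_missing_column_is_an_error(self):
        raw = pd.DataFrame({"a": [0.0, 0.0], "b": [4.0, 4.0]}, index=list("xy"))
        with pytest.raises(ValueError, match="entirely missing"):
            quant.normalize(raw, self.CONDITIONS)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0.5, 1e6), min_size=2, max_size=2),
            min_size=2,
            max_size=12,
        )
    )
    def test_every_column_mean_is_zero(self, rows):
        raw = pd.DataFrame(rows, columns=["a", "b"])
        m = quant.normalize(raw, self.CONDITIONS)
        assert np.allclose(m.values.mean(axis=0), 0.0, atol=1e-9)


def _matrix(low, high):
    low_cols = [f"l{i}" for i in range(len(low))]
    high_cols = [f"h{i}" for i in range(len(high))]
    values = pd.DataFrame([list(low) + list(high)], index=["f"], columns=low_cols + high_cols)
    conditions = pd.Series(
        ["lowN"] * len(low) + ["highN"] * len(high), index=values.columns
    )
    return quant.AbundanceMatrix(values=values, conditions=conditions)


class TestDifferential:
    def test_identical_groups_give_null_result(self):
        res = quant.differential(_matrix((1, 1, 1), (1, 1, 1)), alpha=0.05)
        assert res.loc[0, "log2fc"] == 0.0
        assert res.loc[0, "p"] == 1.0
        assert not res.loc[0, "significant"]

    def test_p_matches_textbook_pooled_oracle(self):
        low, high = (2.0, 2.1, 1.9), (1.0, 0.9, 1.1)
        res = quant.differential(_matrix(low, high), alpha=0.05)
        assert res.loc[0, "p"] == pytest.approx(pooled_t_p_oracle(low, high), abs=1e-12)
        assert res.loc[0, "log2fc"] == pytest.approx(1.0)

    def test_swapping_conditions_negates_fc_and_keeps_p(self, rng):
        low = tuple(rng.normal(1, 0.3, 3))
        high = tuple(rng.normal(0, 0.3, 3))
        fwd = quant.differential(_matrix(low, high), alpha=0.05)
        rev = quant.differential(_matrix(high, low), alpha=0.05)
        assert fwd.loc[0, "log2fc"] == pytest.approx(-rev.loc[0, "log2fc"])
        assert fwd.loc[0, "p"] == pytest.approx(rev.loc[0, "p"], abs=1e-14)

    def test_invariant_to_constant_shift_of_all_samples(self, rng):
        low = rng.normal(1, 0.3, 3)
        high = rng.normal(0, 0.3, 3)
        a = quant.differential(_matrix(low, high), alpha=0.05)
        b = quant.differential(_matrix(low + 5.0, high + 5.0), alpha=0.05)
        assert a.loc[0, "p"] == pytest.approx(b.loc[0, "p"], abs=1e-12)

    def test_single_replicate_is_untested(self):
        res = quant.differential(_matrix((1.0,), (0.0, 0.1, 0.2)), alpha=0.05)
        assert res.loc[0, "status"] == "untested"
        assert np.isnan(res.loc[0, "p"])

    def test_degenerate_variance_with_unequal_means(self):
        res = quant.differential(_matrix((2, 2, 2), (1, 1, 1)), alpha=0.05)
        assert res.loc[0, "status"] == "degenerate"
        assert res.loc[0, "p"] == 0.0

    def test_welch_runs_and_differs_with_unequal_variances(self, rng):
        low = rng.normal(1, 1.5, 4)
        high = rng.normal(0, 0.1, 4)
        m = _matrix(low, high)
        student = quant.differential(m, alpha=0.05)
        welch = quant.differential(m, alpha=0.05, welch=True)
        assert student.loc[0, "p"] != welch.loc[0, "p"]


def test_replicate_sd_is_std_of_paired_differences(dataset, protein_matrix):
    res = quant.differential(protein_matrix, alpha=0.001)
    m = protein_matrix
    feature = res.loc[0, "feature_id"]
    diffs = []
    for rep in sorted(set(m.replicates)):
        low = [s for s in m.values.columns if m.replicates[s] == rep and m.conditions[s] == "lowN"]
        high = [s for s in m.values.columns if m.replicates[s] == rep and m.conditions[s] == "highN"]
        diffs.append(m.values.loc[feature, low].mean() - m.values.loc[feature, high].mean())
    assert res.loc[0, "sd"] == pytest.approx(np.std(diffs, ddof=1))


def test_proteome_coverage_percent_rounding():
    assert quant.proteome_coverage(3567, 6448) == 55.3
    with pytest.raises(ValueError):
        quant.proteome_coverage(10, 5)
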