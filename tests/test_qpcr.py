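"""dCt / ddCt arithmetic, pair ratios, and their algebraic invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpair.errors import EstimationError, NormalizationError, ValidationError
from mirpair.qpcr import CtTable, delta_ct, pair_ratio, relative_expression


def ct_table(rows, refs=("REF",), layer="ct_mirna"):
    return CtTable(
        pd.DataFrame(rows, columns=["sample_id", "assay_id", "ct"]),
        reference_assays=refs,
        layer=layer,
    )


class TestCtTable:
    def test_technical_replicates_are_averaged(self):
        t = ct_table([("s1", "A", 24.0), ("s1", "A", 26.0), ("s1", "REF", 20.0)])
        assert t.data.loc[t.data["assay_id"] == "A", "ct"].item() == 25.0

    def test_out_of_range_ct_rejected(self):
        with pytest.raises(ValidationError):
            ct_table([("s1", "A", 46.0), ("s1", "REF", 20.0)])

    def test_reference_required(self):
        with pytest.raises(ValidationError):
            ct_table([("s1", "A", 25.0)], refs=())


class TestDeltaCt:
    def test_single_reference(self):
        t = ct_table([("s1", "T", 25.0), ("s1", "REF", 20.0)])
        out = delta_ct(t)
        assert out["delta_ct"].item() == 5.0

    def test_two_references_averaged(self):
        t = ct_table(
            [("s1", "T", 25.0), ("s1", "G", 20.0), ("s1", "B", 22.0)],
            refs=("G", "B"),
        )
        out = delta_ct(t)
        assert out["delta_ct"].item() == 4.0
        assert out["reference_value"].item() == 21.0

    def test_absent_target_flagged_not_zero(self):
        t = ct_table(
            [("s1", "T", np.nan), ("s1", "REF", 20.0), ("s2", "T", 25.0), ("s2", "REF", 20.0)]
        )
        out = delta_ct(t).set_index("sample_id")
        assert np.isnan(out.at["s1", "delta_ct"])
        assert out.at["s2", "delta_ct"] == 5.0

    def test_missing_reference_names_sample_and_layer(self):
        t = ct_table(
            [("s1", "T", 25.0), ("s1", "REF", 20.0), ("s2", "T", 25.0), ("s2", "REF", np.nan)]
        )
        with pytest.raises(NormalizationError, match="s2"):
            delta_ct(t)

    @settings(max_examples=50, deadline=None)
    @given(
        shift=st.floats(-5, 5),
        cts=st.lists(st.floats(10, 30), min_size=3, max_size=3),
    )
    def test_shift_invariance(self, shift, cts):
        """Adding a constant to every Ct of a sample leaves dCt unchanged."""
        a, b, ref = cts
        base = ct_table([("s1", "A", a), ("s1", "B", b), ("s1", "REF", ref)])
        shifted = ct_table(
            [("s1", "A", a + shift), ("s1", "B", b + shift), ("s1", "REF", ref + shift)]
        )
        np.testing.assert_allclose(
            delta_ct(base)["delta_ct"], delta_ct(shifted)["delta_ct"], atol=1e-9
        )


SHEET = pd.DataFrame(
    {"sample_id": ["c1", "c2", "c3", "t1"], "group": ["CTRL", "CTRL", "CTRL", "CASE"]}
)


def dct_frame(values):
    return pd.DataFrame(
        [(s, "A", v) for s, v in values.items()],
        columns=["sample_id", "assay_id", "delta_ct"],
    )


class TestRelativeExpression:
    def test_ddct_fold_change_arithmetic(self):
        rel = relative_expression(
            dct_frame({"c1": 7.0, "c2": 7.0, "c3": 7.0, "t1": 5.0}), SHEET, "CTRL"
        ).set_index("sample_id")
        assert rel.at["t1", "delta_delta_ct"] == -2.0
        assert rel.at["t1", "fold_change"] == 4.0
        assert rel.at["t1", "log2_fc"] == 2.0

    def test_control_median_sample_has_fold_change_one(self):
        rel = relative_expression(
            dct_frame({"c1": 6.0, "c2": 7.0, "c3": 8.0, "t1": 5.0}), SHEET, "CTRL"
        ).set_index("sample_id")
        assert rel.at["c2", "fold_change"] == 1.0

    def test_empty_control_group_raises(self):
        with pytest.raises(EstimationError):
            relative_expression(dct_frame({"t1": 5.0}), SHEET, "CTRL")


def one_sample_tables(mi, mr):
    dmi = pd.DataFrame([("s1", "miR", mi)], columns=["sample_id", "assay_id", "delta_ct"])
    dmr = pd.DataFrame([("s1", "GENE", mr)], columns=["sample_id", "assay_id", "delta_ct"])
    pairs = pd.DataFrame({"mirna_id": ["miR"], "gene_id": ["GENE"]})
    return dmi, dmr, pairs


class TestPairRatio:
    def test_group_median_style_values(self):
        # plausible single-sample values: a miRNA at dCt 5.88, its target at 1.06
        dmi, dmr, pairs = one_sample_tables(5.88, 1.06)
        r = pair_ratio(dmi, dmr, pairs)
        assert r.loc["miR/GENE", "s1"] == pytest.approx(-4.82)

    def test_equal_dcts_give_zero(self):
        dmi, dmr, pairs = one_sample_tables(3.3, 3.3)
        assert pair_ratio(dmi, dmr, pairs).iloc[0, 0] == 0.0

    def test_unknown_assay_raises(self):
        dmi, dmr, _ = one_sample_tables(1.0, 2.0)
        bad = pd.DataFrame({"mirna_id": ["nope"], "gene_id": ["GENE"]})
        with pytest.raises(ValidationError, match="nope"):
            pair_ratio(dmi, dmr, bad)

    def test_absent_member_gives_absent_cell(self):
        dmi = pd.DataFrame(
            [("s1", "miR", np.nan), ("s2", "miR", 4.0)],
            columns=["sample_id", "assay_id", "delta_ct"],
        )
        dmr = pd.DataFrame(
            [("s1", "GENE", 1.0), ("s2", "GENE", 1.0)],
            columns=["sample_id", "assay_id", "delta_ct"],
        )
        pairs = pd.DataFrame({"mirna_id": ["miR"], "gene_id": ["GENE"]})
        r = pair_ratio(dmi, dmr, pairs)
        assert np.isnan(r.loc["miR/GENE", "s1"])
        assert r.loc["miR/GENE", "s2"] == -3.0

    @settings(max_examples=100, deadline=None)
    @given(mi=st.floats(-10, 20), mr=st.floats(-10, 20))
    def test_antisymmetry_and_ddct_identity(self, mi, mr):
        """r = dCt(mRNA) - dCt(miRNA) equals log2(2**(-ddCt)) and swapping
        the roles negates it."""
        dmi, dmr, pairs = one_sample_tables(mi, mr)
        r = pair_ratio(dmi, dmr, pairs).iloc[0, 0]
        ddct = mi - mr
        assert abs(r - np.log2(2.0 ** (-ddct))) < 1e-12
        # role swap: treat the mRNA table as the miRNA table and vice versa
        as_mirna = dmr.assign(assay_id="miR")   # mRNA values playing the miRNA role
        as_mrna = dmi.assign(assay_id="GENE")   # miRNA values playing the mRNA role
        swapped = pair_ratio(as_mirna, as_mrna, pairs)
        assert abs(swapped.iloc[0, 0] + r) < 1e-12
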