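"""dCt / ddCt relative quantification and the miRNA/mRNA pair-ratio statistic.

Quantitative PCR reports a cycle-threshold (Ct) per sample and assay; lower
Ct means higher abundance. Normalization proceeds in two steps:

* ``dCt = Ct(target) - reference level`` within a sample removes loading
  differences. The reference level is the arithmetic mean of the layer's
  reference-assay Cts (one reference for the miRNA layer, two for the mRNA
  layer; averaging Cts equals a geometric mean on the expression scale).
* ``ddCt = dCt(sample) - median dCt of the control group`` anchors each
  assay to the control; ``2**(-ddCt)`` is the relative fold change.

The discriminating statistic of the downstream analysis is the per-sample
pair ratio ``r = dCt(mRNA) - dCt(miRNA)``, the log2 of the miRNA-to-target
expression ratio: algebraically ``r = log2(2**(-ddCt))`` with
``ddCt = dCt(miRNA) - dCt(mRNA)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, NormalizationError, ValidationError

CT_MAX = 45.0


@dataclass
class CtTable:
    """Per-sample raw Ct values for one assay layer.

    ``data`` holds rows of (sample_id, assay_id, ct); technical replicates
    (duplicate sample/assay rows) are averaged on construction. NaN cts are
    kept and flag an undetermined/absent measurement. Ct values must lie in
    (0, 45] when present.
    """

    data: pd.DataFrame
    reference_assays: tuple[str, ...]
    layer: str = "unspecified"
    _allow_empty: bool = field(default=False, repr=False)

    def __post_init__(self):
        required = {"sample_id", "assay_id", "ct"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"CtTable needs columns {sorted(required)}")
        if not self.reference_assays:
            raise ValidationError("CtTable needs at least one reference assay")
        df = self.data.loc[:, ["sample_id", "assay_id", "ct"]].copy()
        df["ct"] = pd.to_numeric(df["ct"], errors="raise")
        present = df["ct"].dropna()
        if ((present <= 0) | (present > CT_MAX)).any():
            bad = present[(present <= 0) | (present > CT_MAX)]
            raise ValidationError(
                f"Ct values outside (0, {CT_MAX}]: e.g. {bad.iloc[0]!r}"
            )
        # technical-replicate averaging (NaN ignored unless all replicates NaN)
        df = (
            df.groupby(["sample_id", "assay_id"], sort=False, as_index=False)
            .agg(ct=("ct", "mean"))
        )
        if df.empty and not self._allow_empty:
            raise ValidationError("CtTable is empty")
        self.data = df

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))

    @property
    def target_assays(self) -> list[str]:
        refs = set(self.reference_assays)
        return [a for a in dict.fromkeys(self.data["assay_id"]) if a not in refs]


def delta_ct(ct: CtTable) -> pd.DataFrame:
    """Reference-normalize a Ct table.

    Returns rows of (sample_id, assay_id, delta_ct, reference_value) for
    every target assay; the reference value is the arithmetic mean of the
    sample's reference-assay Cts. Target rows with an absent Ct are kept
    with ``delta_ct = NaN`` (flagged absent, excluded downstream).

    Raises
    ------
    NormalizationError
        If any sample lacks a usable reference Ct, naming sample and layer.
    """
    refs = set(ct.reference_assays)
    wide = ct.data.pivot(index="sample_id", columns="assay_id", values="ct")
    missing_refs = refs - set(wide.columns)
    if missing_refs:
        raise NormalizationError(
            f"layer {ct.layer!r}: reference assay(s) {sorted(missing_refs)} absent"
        )
    ref_values = wide[sorted(refs)].mean(axis=1, skipna=False)
    bad = ref_values[ref_values.isna()]
    if not bad.empty:
        raise NormalizationError(
            f"layer {ct.layer!r}: sample {bad.index[0]!r} is missing a reference Ct"
        )
    targets = [a for a in wide.columns if a not in refs]
    out = (
        wide[targets]
        .sub(ref_values, axis=0)
        .reset_index()
        .melt(id_vars="sample_id", var_name="assay_id", value_name="delta_ct")
    )
    out["reference_value"] = out["sample_id"].map(ref_values)
    return out


def relative_expression(
    dct: pd.DataFrame, samples: pd.DataFrame, control_group: str
) -> pd.DataFrame:
    """Per-sample ddCt fold changes against a control group.

    ``ddCt = delta_ct - median(delta_ct over control samples)`` per assay;
    fold change is ``2**(-ddCt)`` and ``log2_fc = -ddCt``.

    Raises
    ------
    EstimationError
        If the control group has no defined delta_ct for some assay.
    """
    merged = dct.merge(samples[["sample_id", "group"]], on="sample_id", how="left")
    ctrl = merged[merged["group"] == control_group]
    anchors = ctrl.groupby("assay_id")["delta_ct"].median()
    missing = [
        a for a in merged["assay_id"].unique()
        if a not in anchors.index or pd.isna(anchors.get(a))
    ]
    if missing:
        raise EstimationError(
            f"control group {control_group!r} has no delta_ct for assay(s) "
            f"{missing[:5]}"
        )
    out = merged.copy()
    out["delta_delta_ct"] = out["delta_ct"] - out["assay_id"].map(anchors)
    out["log2_fc"] = -out["delta_delta_ct"]
    out["fold_change"] = np.exp2(out["log2_fc"])
    return out[
        ["sample_id", "assay_id", "group", "delta_delta_ct", "fold_change", "log2_fc"]
    ]


def pair_ratio(
    dct_mirna: pd.DataFrame, dct_mrna: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample pair-ratio matrix r = dCt(mRNA) - dCt(miRNA).

    ``pairs`` needs columns ``mirna_id`` and ``gene_id`` naming assays
    present in the respective delta-Ct tables. The result has one row per
    pair (index ``"<mirna>/<gene>"``) and one column per sample; cells
    where either member is absent are NaN.

    Raises
    ------
    ValidationError
        If a pair references an assay unknown to either table.
    """
    mi = dct_mirna.pivot(index="assay_id", columns="sample_id", values="delta_ct")
    mr = dct_mrna.pivot(index="assay_id", columns="sample_id", values="delta_ct")
    samples = [s for s in mi.columns if s in set(mr.columns)]
    rows, index = [], []
    for row in pairs[["mirna_id", "gene_id"]].itertuples(index=False):
        if row.mirna_id not in mi.index:
            raise ValidationError(f"pair references unknown miRNA assay {row.mirna_id!r}")
        if row.gene_id not in mr.index:
            raise ValidationError(f"pair references unknown mRNA assay {row.gene_id!r}")
        rows.append(mr.loc[row.gene_id, samples].to_numpy() - mi.loc[row.mirna_id, samples].to_numpy())
        index.append(f"{row.mirna_id}/{row.gene_id}")
    out = pd.DataFrame(rows, index=index, columns=samples)
    out.index.name = "pair_id"
    return out
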