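"""Venn partitioning of DE lists and opposite-direction pair construction.

The integrative step of the analysis: a miRNA and a predicted target gene
form a candidate regulatory pair when both are differentially expressed
and their changes point in *opposite* directions (miRNA up / target down,
or vice versa) — the signature expected of a repressive miRNA-target
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class VennPartition:
    """Three-way partition of two feature sets."""

    only_a: set
    intersection: set
    only_b: set

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.only_a), len(self.intersection), len(self.only_b))

    def to_dict(self) -> dict:
        return {
            "only_a": sorted(self.only_a),
            "intersection": sorted(self.intersection),
            "only_b": sorted(self.only_b),
            "counts": {
                "only_a": len(self.only_a),
                "intersection": len(self.intersection),
                "only_b": len(self.only_b),
            },
        }


def venn_partition(list_a, list_b) -> VennPartition:
    """Disjoint partition (A only, A and B, B only) of two feature sets."""
    a, b = set(list_a), set(list_b)
    return VennPartition(only_a=a - b, intersection=a & b, only_b=b - a)


@dataclass
class PairingResult:
    """Pair table plus coverage bookkeeping.

    ``table`` has one row per mapped (miRNA, gene) with both members in
    their DE lists; ``retained`` is the opposite-direction,
    threshold-passing subset; ``unmatched`` counts map rows whose members
    were absent from the DE lists.
    """

    table: pd.DataFrame
    unmatched: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def retained(self) -> pd.DataFrame:
        if self.table.empty:
            return self.table
        return self.table[
            self.table["opposite_direction"] & self.table["passed_thresholds"]
        ].reset_index(drop=True)


def build_pairs(
    de_mirna: pd.DataFrame,
    de_protein: pd.DataFrame,
    target_map: pd.DataFrame,
    mirna_alpha: float = 0.05,
    protein_alpha: float = 0.05,
    mirna_adjusted: bool = True,
    protein_adjusted: bool = False,
) -> PairingResult:
    """Construct miRNA-target pairs from two DE tables and a target map.

    DE tables need columns ``feature``, ``log2_fc``, ``p`` (and
    ``p_adjusted`` when the corresponding ``*_adjusted`` flag is set); the
    target map needs ``mirna_id`` and ``gene_id``. A row is emitted for
    every mapped pair whose members both appear in their DE lists;
    ``opposite_direction`` is true when the two log2FCs have strictly
    opposite signs (an exact zero has no direction), and
    ``passed_thresholds`` applies the configured significance cutoffs.
    Rows are sorted by miRNA p then gene id; map rows with a member absent
    from both DE lists are counted in ``unmatched``.
    """
    for name, df in (("de_mirna", de_mirna), ("de_protein", de_protein)):
        missing = {"feature", "log2_fc", "p"} - set(df.columns)
        if missing:
            raise ValidationError(f"{name} lacks columns {sorted(missing)}")
    if {"mirna_id", "gene_id"} - set(target_map.columns):
        raise ValidationError("target map needs mirna_id and gene_id columns")
    if de_mirna.empty or de_protein.empty:
        raise ValidationError("DE inputs must be non-empty")

    mi = de_mirna.drop_duplicates("feature").set_index("feature")
    pr = de_protein.drop_duplicates("feature").set_index("feature")
    mi_p = mi["p_adjusted"] if mirna_adjusted else mi["p"]
    pr_p = pr["p_adjusted"] if protein_adjusted else pr["p"]

    rows, unmatched = [], []
    seen = set()
    for rec in target_map[["mirna_id", "gene_id"]].itertuples(index=False):
        key = (rec.mirna_id, rec.gene_id)
        if key in seen:
            continue
        seen.add(key)
        if rec.mirna_id not in mi.index or rec.gene_id not in pr.index:
            unmatched.append(key)
            continue
        m_fc = float(mi.at[rec.mirna_id, "log2_fc"])
        p_fc = float(pr.at[rec.gene_id, "log2_fc"])
        rows.append(
            {
                "mirna_id": rec.mirna_id,
                "mirna_log2fc": m_fc,
                "mirna_p": float(mi_p.at[rec.mirna_id]),
                "gene_id": rec.gene_id,
                "protein_name": pr.at[rec.gene_id, "protein_name"]
                if "protein_name" in pr.columns
                else rec.gene_id,
                "protein_log2fc": p_fc,
                "protein_p": float(pr_p.at[rec.gene_id]),
                "opposite_direction": bool(np.sign(m_fc) * np.sign(p_fc) < 0),
                "passed_thresholds": bool(
                    mi_p.at[rec.mirna_id] < mirna_alpha
                    and pr_p.at[rec.gene_id] < protein_alpha
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "mirna_log2fc", "mirna_p", "gene_id", "protein_name",
            "protein_log2fc", "protein_p", "opposite_direction", "passed_thresholds",
        ],
    )
    if not table.empty:
        table = table.sort_values(
            ["mirna_p", "gene_id", "mirna_id"], kind="mergesort"
        ).reset_index(drop=True)
    return PairingResult(
        table=table,
        unmatched=pd.DataFrame(unmatched, columns=["mirna_id", "gene_id"]),
    )
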