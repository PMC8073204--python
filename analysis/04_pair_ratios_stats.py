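#!/usr/bin/env python
"""qPCR-layer quantification: dCt, per-sample pair ratios, group statistics.

Normalizes both Ct layers, forms the per-sample pair-ratio statistic
r = dCt(mRNA) - dCt(miRNA) for the measured panel, and reports the
late-IUGR vs late-control comparison in the study's Me (Q1; Q3) +
Mann-Whitney format, plus the Spearman correlation matrix of dCt values.
"""

import json
from pathlib import Path

import pandas as pd

from mirpair import io, reference
from mirpair.qpcr import delta_ct, pair_ratio
from mirpair.stats import compare_groups, correlation_matrix, format_p

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "results" / "synthetic_study"
OUT = ROOT / "results"

TEST, CONTROL = "IUGR_gt_34", "N_gt_34"


def main() -> None:
    samples = io.read_sample_sheet(IN / "samples.tsv")
    ct_mi = io.read_ct_table(IN / "ct_mirna.tsv", reference.MIRNA_REFERENCE_ASSAYS, "ct_mirna")
    ct_mr = io.read_ct_table(IN / "ct_mrna.tsv", reference.MRNA_REFERENCE_ASSAYS, "ct_mrna")

    dct_mi, dct_mr = delta_ct(ct_mi), delta_ct(ct_mr)
    pairs = pd.DataFrame(reference.RATIO_PAIRS, columns=["mirna_id", "gene_id"])
    ratios = pair_ratio(dct_mi, dct_mr, pairs)
    io.write_matrix(ratios, OUT / "pair_ratios.tsv")

    groups = samples.set_index("sample_id")["group"]
    rows = []
    for pair_id, values in ratios.iterrows():
        cmp = compare_groups(values, groups[values.index], TEST, CONTROL, variable=pair_id)
        rows.append({"pair_id": pair_id, TEST: cmp.summary_a.formatted,
                     CONTROL: cmp.summary_b.formatted, "u": cmp.u, "p": cmp.p,
                     "p_display": format_p(cmp.p), "method": cmp.method})
    table = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    io.write_table(table, OUT / "pair_comparisons.tsv")

    wide = pd.concat([dct_mi, dct_mr]).pivot(
        index="sample_id", columns="assay_id", values="delta_ct"
    )
    keep = groups[groups.isin([TEST, CONTROL])].index
    corr = correlation_matrix(wide.loc[wide.index.isin(keep)])
    (OUT / "correlation.json").write_text(json.dumps(
        {"rho": corr.rho.round(6).to_dict(),
         "significant": {k: {kk: bool(vv) for kk, vv in v.items()}
                         for k, v in corr.significant.to_dict().items()}}, indent=2))

    sig = table[table["p"] < 0.05]
    print(f"{len(table)} pair ratios compared ({TEST} vs {CONTROL}); "
          f"{len(sig)} significant at 0.05:")
    for row in sig.itertuples():
        print(f"  {row.pair_id}: {getattr(row, TEST)} vs {getattr(row, CONTROL)} "
              f"(p {row.p_display})")


if __name__ == "__main__":
    main()
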