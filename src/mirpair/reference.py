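"""Published summary statistics of the placental-bed IUGR/PE/SGA cohort.

The study this package re-analyses profiled placental-bed biopsies from 57
pregnant women in six groups (early/late intrauterine growth restriction,
early/late preeclampsia, small-for-gestational-age, and gestational-age
matched controls), plus three early-delivery controls used only for the
sequencing/proteomics comparisons. The raw per-sample measurements were
never deposited; what is public are group sizes, clinical outcome counts,
group medians of qPCR dCt values, and the log2 fold changes of the
discriminating miRNAs and their target proteins.

This module embeds those published summaries. They serve two purposes:

* the synthetic-cohort generator uses them as baselines and planted effect
  sizes, so simulated studies look like the real one;
* the clinical bookkeeping (group sizes, outcome percentages) and the
  opposite-direction pairing rule can be recomputed and checked directly.

Group labels are filesystem-safe tokens (``IUGR_lt_34`` for "IUGR < 34").
"""

from __future__ import annotations

import pandas as pd

# --- cohort composition ----------------------------------------------------

#: Six analysis groups with their sample sizes (57 women in total).
GROUP_SIZES: dict[str, int] = {
    "IUGR_lt_34": 10,
    "IUGR_gt_34": 13,
    "PE_lt_34": 12,
    "PE_gt_34": 7,
    "SGA_gt_34": 8,
    "N_gt_34": 7,
}

#: Optional early-delivery control group (used as the control for the
#: deep-sequencing and proteomics comparisons, not part of the 57).
EARLY_CONTROL_GROUP = "N_lt_34"
EARLY_CONTROL_N = 3

#: Human-readable group names.
GROUP_DISPLAY: dict[str, str] = {
    "IUGR_lt_34": "IUGR < 34",
    "IUGR_gt_34": "IUGR > 34",
    "PE_lt_34": "PE < 34",
    "PE_gt_34": "PE > 34",
    "SGA_gt_34": "SGA > 34",
    "N_gt_34": "N > 34",
    "N_lt_34": "N < 34",
}

# --- clinical outcome counts (affected, group size) ------------------------

#: Categorical outcomes reported as N (P%) per group.
CLINICAL_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "proteinuria": {"PE_lt_34": (10, 12), "PE_gt_34": (4, 7)},
    "intraventricular_hemorrhage": {
        "IUGR_lt_34": (2, 10),
        "IUGR_gt_34": (2, 13),
        "SGA_gt_34": (1, 8),
    },
    "respiratory_distress_syndrome": {
        "IUGR_lt_34": (10, 10),
        "IUGR_gt_34": (1, 13),
        "PE_lt_34": (12, 12),
        "PE_gt_34": (3, 7),
        "N_gt_34": (1, 7),
    },
}


def outcome_percentage(outcome: str, group: str) -> float:
    """Prevalence of a categorical outcome in a group, in percent."""
    affected, total = CLINICAL_COUNTS[outcome][group]
    return 100.0 * affected / total


# --- discriminating miRNA / target-protein pairs ---------------------------

#: The 16 miRNA-target rows found by intersecting the placental-bed
#: deep-sequencing hits (early IUGR vs early control) with the proteomics
#: hits of their predicted target genes, requiring opposite directions of
#: change. Columns: miRNA log2FC and p from the count layer, protein log2FC
#: and p from the intensity layer.
DISCRIMINATING_PAIRS = pd.DataFrame(
    [
        ("hsa-miR-1-3p", 1.18, 0.00012, "ANXA2", "Annexin A2 (P07355)", -2.15, 0.0001),
        ("hsa-miR-1-3p", 1.18, 0.00012, "TAGLN2", "Transgelin-2 (P37802)", -2.088, 0.0001),
        ("hsa-miR-1-3p", 1.18, 0.00012, "YWHAZ", "14-3-3 protein zeta/delta (P63104)", -1.032, 0.00193),
        ("hsa-miR-1-3p", 1.18, 0.00012, "FN1", "Fibronectin (P02751)", -6.999, 0.00504),
        ("hsa-miR-199a-3p", 0.72, 0.00026, "FN1", "Fibronectin (P02751)", -6.999, 0.00504),
        ("hsa-miR-199b-3p", 0.72, 0.00027, "FN1", "Fibronectin (P02751)", -6.999, 0.00504),
        ("hsa-miR-185-3p", -0.95, 0.00060, "FLNA", "Filamin-A (P21333)", 0.9255, 0.1388),
        ("hsa-miR-128-3p", 0.80, 0.0024, "FN1", "Fibronectin (P02751)", -6.999, 0.00504),
        ("hsa-miR-140-3p", -0.71, 0.0025, "DSTN", "Destrin (P60981)", 0.878, 0.00531),
        ("hsa-miR-30c-5p", 0.62, 0.0075, "FBN1", "Fibrillin-1 (P35555)", -6.985, 0.0689),
        ("hsa-miR-30c-5p", 0.62, 0.0075, "VIM", "Vimentin (P08670)", -1.695, 0.0012),
        ("hsa-miR-30c-5p", 0.62, 0.0075, "YWHAZ", "14-3-3 protein zeta/delta (P63104)", -1.032, 0.00193),
        ("hsa-miR-28-3p", 0.56, 0.0140, "VIM", "Vimentin (P08670)", -1.695, 0.0012),
        ("hsa-miR-30d-5p", -0.59, 0.02025, "MYH11", "Myosin-11 (P35749)", 1.9163, 0.0001),
        ("hsa-miR-654-3p", 0.57, 0.0421, "FGA", "Fibrinogen alpha chain (P02671)", -7.686, 0.0002243),
        ("hsa-miR-15b-5p", -0.53, 0.0495, "MYL6", "Myosin light polypeptide 6 (P60660)", 1.5447, 0.000172),
    ],
    columns=[
        "mirna_id",
        "mirna_log2fc",
        "mirna_p",
        "gene_id",
        "protein_name",
        "protein_log2fc",
        "protein_p",
    ],
)


def target_map() -> pd.DataFrame:
    """miRNA -> target-gene map of the discriminating pairs (deduplicated)."""
    return (
        DISCRIMINATING_PAIRS[["mirna_id", "gene_id"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )


# --- qPCR assay panel ------------------------------------------------------

#: Reference assays per layer (raw Ct baselines are plausible values for
#: abundant reference transcripts; only dCt values were published).
MIRNA_REFERENCE_ASSAYS: dict[str, float] = {"SNORD68": 20.0}
MRNA_REFERENCE_ASSAYS: dict[str, float] = {"GAPDH": 18.0, "ACTB": 17.0}

#: Baseline dCt of each target assay in the N > 34 control group
#: (published group medians where available; values in cycles, higher dCt
#: means lower expression). Assays without a published control median carry
#: a plausible mid-panel value.
CT_BASELINES_MIRNA: dict[str, float] = {
    "hsa-miR-1-3p": 5.37,
    "hsa-miR-140-3p": -0.88,
    "hsa-miR-15b-5p": 0.77,
    "hsa-miR-199a-3p": 3.89,
    "hsa-miR-199b-3p": 3.58,
    "hsa-miR-28-3p": 4.33,
    "hsa-miR-30c-5p": 4.04,
    "hsa-miR-654-3p": 9.38,
    "hsa-miR-185-3p": 6.73,
    "hsa-miR-128-3p": 7.5,   # not published for the control group
    "hsa-miR-30d-5p": 6.0,   # not published for the control group
}

CT_BASELINES_MRNA: dict[str, float] = {
    "VIM": 1.47,
    "ANXA2": 0.85,
    "FGA": 13.48,
    "MYL6_tv1": 4.06,
    "MYL6_tv2": 4.03,
    "YWHAZ": 8.70,
    "FBN1": 3.28,
    "FLNA": 8.13,
    "MYH11": 8.32,
    "DSTN": 7.0,     # not published for the control group
    "FN1": 6.0,      # not published for the control group
    "TAGLN2": 5.0,   # not published for the control group
}

#: Published group-median dCt shifts relative to the N > 34 control
#: (group median minus control median), per layer. A positive shift on the
#: Ct scale means lower expression in the group.
CT_SHIFTS_MIRNA: dict[str, dict[str, float]] = {
    "IUGR_gt_34": {
        "hsa-miR-1-3p": 1.67,
        "hsa-miR-140-3p": 0.96,
        "hsa-miR-15b-5p": 1.35,
        "hsa-miR-199a-3p": 1.32,
        "hsa-miR-199b-3p": 1.68,
        "hsa-miR-28-3p": 1.55,
        "hsa-miR-30c-5p": 1.68,
        "hsa-miR-654-3p": 1.47,
    },
    "PE_gt_34": {
        "hsa-miR-30c-5p": 1.78,
        "hsa-miR-654-3p": 0.51,
        "hsa-miR-185-3p": 1.15,
    },
    "SGA_gt_34": {
        "hsa-miR-654-3p": 0.36,
        "hsa-miR-15b-5p": 0.32,
        "hsa-miR-185-3p": 1.14,
        "hsa-miR-140-3p": 0.94,
    },
}

CT_SHIFTS_MRNA: dict[str, dict[str, float]] = {
    "IUGR_gt_34": {
        "VIM": -0.41,
        "ANXA2": -0.19,
        "FGA": -4.89,
        "MYL6_tv1": -0.22,
        "MYL6_tv2": -0.41,
        "YWHAZ": -0.63,
        "FBN1": -0.29,
    },
    "PE_gt_34": {
        "FGA": -5.19,
        "FLNA": -0.28,
        "YWHAZ": -0.68,
        "MYH11": 1.07,
    },
    "SGA_gt_34": {
        "FGA": -4.81,
        "MYL6_tv1": -0.39,
    },
}

#: Pairs measured at the qPCR level (mRNA assay per target gene; the MYL6
#: gene has two transcript-variant assays).
RATIO_PAIRS: list[tuple[str, str]] = [
    ("hsa-miR-28-3p", "VIM"),
    ("hsa-miR-30c-5p", "VIM"),
    ("hsa-miR-654-3p", "FGA"),
    ("hsa-miR-15b-5p", "MYL6_tv1"),
    ("hsa-miR-15b-5p", "MYL6_tv2"),
    ("hsa-miR-1-3p", "ANXA2"),
    ("hsa-miR-1-3p", "YWHAZ"),
    ("hsa-miR-1-3p", "TAGLN2"),
    ("hsa-miR-1-3p", "FN1"),
    ("hsa-miR-30c-5p", "FBN1"),
    ("hsa-miR-30c-5p", "YWHAZ"),
    ("hsa-miR-185-3p", "FLNA"),
    ("hsa-miR-128-3p", "FN1"),
    ("hsa-miR-140-3p", "DSTN"),
    ("hsa-miR-199a-3p", "FN1"),
    ("hsa-miR-199b-3p", "FN1"),
    ("hsa-miR-30d-5p", "MYH11"),
]
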