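"""Monte-Carlo calibration and recovery checks of the whole pipeline.

These routines answer two questions about the analysis chain on synthetic
cohorts generated at the study's own group sizes:

* **calibration** — with zero planted effects, do the Mann-Whitney and the
  count-layer DE stage reject at their nominal level?
* **recovery** — are planted Ct shifts, protein fold changes, and a single
  discriminative pair recovered (correct sign / top VIP rank) when the
  effect is large relative to the noise?

All randomness flows through an integer seed; replicate seeds are drawn
from a :class:`numpy.random.SeedSequence` spawned from it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import de_counts, de_proteins
from .plsda import fit_plsda, vip_scores
from .qpcr import delta_ct, pair_ratio, relative_expression
from .stats import mann_whitney
from .synthetic import (
    CohortDesign,
    EffectSpec,
    SimulationParams,
    default_paper_design,
    simulate_study,
    with_seed,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


#: Noise SD of one pair-ratio cell under the default generator settings:
#: two target assays (ct_sd each), one miRNA reference and the mean of two
#: mRNA references (ref_ct_sd each). The per-sample loading offset cancels.
def pair_ratio_noise_sd(params: SimulationParams | None = None) -> float:
    p = params or SimulationParams()
    var = 2 * p.ct_sd**2 + p.ref_ct_sd**2 + (p.ref_ct_sd**2) / 2
    return float(np.sqrt(var))


def null_mann_whitney_rejection(
    seed: int,
    n_reps: int = 200,
    test_group: str = "IUGR_gt_34",
    control_group: str = "N_gt_34",
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of Mann-Whitney on dCt under the global null.

    Each replicate simulates the full-size cohort with zero effects and
    tests every miRNA assay between the two groups.
    """
    rejections = total = 0
    for s in _child_seeds(seed, n_reps):
        study = simulate_study(
            with_seed(default_paper_design(), s), effects=[], layers=("ct",)
        )
        dct = delta_ct(study.ct_mirna)
        grp = study.sample_sheet.set_index("sample_id")["group"]
        for _, sub in dct.groupby("assay_id"):
            g = grp[sub["sample_id"]].to_numpy()
            res = mann_whitney(
                sub.loc[g == test_group, "delta_ct"],
                sub.loc[g == control_group, "delta_ct"],
            )
            rejections += res.p < alpha
            total += 1
    return {"rate": rejections / total, "n_tests": total, "n_reps": n_reps}


def null_de_rejection(
    seed: int,
    n_reps: int = 200,
    n_features: int = 100,
    test_group: str = "IUGR_gt_34",
    control_group: str = "N_gt_34",
    alpha: float = 0.05,
) -> dict:
    """Raw-p rejection rate of the count-layer Welch DE stage under the null."""
    params = SimulationParams(n_background_counts=n_features)
    rejections = total = 0
    for s in _child_seeds(seed, n_reps):
        study = simulate_study(
            with_seed(default_paper_design(), s),
            effects=[],
            params=params,
            layers=("counts",),
            n_decoy_links=0,
        )
        res = de_counts(study.counts, study.sample_sheet, test_group, control_group)
        rejections += int((res.table["p"] < alpha).sum())
        total += len(res.table)
    return {"rate": rejections / total, "n_tests": total, "n_reps": n_reps}


def ct_shift_recovery(
    seed: int,
    n_reps: int = 200,
    shift: float = 1.0,
    noise_sd: float = 0.5,
    assay: str = "hsa-miR-1-3p",
    group: str = "IUGR_gt_34",
    control_group: str = "N_gt_34",
) -> dict:
    """Recovery of a planted dCt shift by the ddCt estimator.

    Plants ``shift`` cycles (default 2x the Ct noise SD) on one miRNA assay
    in one group and checks the sign and size of the recovered group-median
    log2 fold change (which should be about ``-shift``).
    """
    effect = [EffectSpec(assay, "ct_mirna", group, shift, sd=noise_sd)]
    signs = 0
    estimates = []
    for s in _child_seeds(seed, n_reps):
        study = simulate_study(
            with_seed(default_paper_design(), s), effects=effect, layers=("ct",)
        )
        dct = delta_ct(study.ct_mirna)
        rel = relative_expression(dct, study.sample_sheet, control_group)
        sub = rel[(rel["assay_id"] == assay) & (rel["group"] == group)]
        est = sub["log2_fc"].median()
        estimates.append(est)
        signs += np.sign(est) == np.sign(-shift)
    return {
        "sign_rate": signs / n_reps,
        "median_log2fc": float(np.median(estimates)),
        "planted_log2fc": -shift,
        "n_reps": n_reps,
    }


def protein_recovery(
    seed: int,
    n_reps: int = 200,
    effect: float = -2.15,
    sd: float = 0.3,
    n_per_group: int = 3,
) -> dict:
    """Recovery of a planted protein log2FC at sequencing-cohort size (n=3 vs 3)."""
    design = CohortDesign(("CASE", "CTRL"), (n_per_group, n_per_group))
    spec = [EffectSpec("PROT-1", "protein", "CASE", effect, sd=sd)]
    params = SimulationParams(n_background_proteins=50, protein_missing_rate=0.0)
    signs = 0
    estimates = []
    for s in _child_seeds(seed, n_reps):
        study = simulate_study(
            with_seed(design, s), effects=spec, params=params,
            layers=("protein",), n_decoy_links=0,
        )
        res = de_proteins(study.proteins, study.sample_sheet, "CASE", "CTRL")
        est = float(res.table.set_index("feature").at["PROT-1", "log2_fc"])
        estimates.append(est)
        signs += np.sign(est) == np.sign(effect)
    return {
        "sign_rate": signs / n_reps,
        "median_log2fc": float(np.median(estimates)),
        "planted_log2fc": effect,
        "n_reps": n_reps,
    }


def vip_rank_recovery(
    seed: int,
    n_reps: int = 100,
    n_pairs: int = 10,
    n_case: int = 10,
    n_control: int = 7,
    effect_in_sd: float = 2.0,
) -> dict:
    """Rank-1 / VIP>1 recovery of a single planted discriminative pair.

    Simulates the qPCR layer end to end: ``n_pairs`` one-to-one
    miRNA/mRNA assay pairs, of which exactly one miRNA is upregulated in
    the case group by ``effect_in_sd`` pair-ratio noise SDs (the others
    carry no effect). Each replicate runs the package's own chain —
    generator, dCt normalization, pair ratios, two-component PLS-DA — and
    counts how often the planted pair ranks first with VIP above 1.
    """
    shift = effect_in_sd * pair_ratio_noise_sd()
    design = CohortDesign(("CASE", "CTRL"), (n_case, n_control))
    effects = [
        EffectSpec(
            f"mir-p{i + 1}", "ct_mirna", "CASE",
            -shift if i == 0 else 0.0, baseline=5.0,
        )
        for i in range(n_pairs)
    ] + [
        EffectSpec(f"gene-p{i + 1}", "ct_mrna", "CASE", 0.0, baseline=4.0)
        for i in range(n_pairs)
    ]
    pairs = pd.DataFrame(
        {
            "mirna_id": [f"mir-p{i + 1}" for i in range(n_pairs)],
            "gene_id": [f"gene-p{i + 1}" for i in range(n_pairs)],
        }
    )
    planted = "mir-p1/gene-p1"
    hits = 0
    vips = []
    for s in _child_seeds(seed, n_reps):
        study = simulate_study(
            with_seed(design, s), effects=effects, layers=("ct",), n_decoy_links=0
        )
        ratios = pair_ratio(
            delta_ct(study.ct_mirna), delta_ct(study.ct_mrna), pairs
        )
        labels = study.sample_sheet.set_index("sample_id")["group"][ratios.columns]
        model = fit_plsda(ratios.T, labels, n_components=2)
        vip = vip_scores(model).set_index("feature")
        vips.append(float(vip.at[planted, "vip"]))
        hits += vip.at[planted, "rank"] == 1 and vip.at[planted, "vip"] > 1.0
    return {
        "rank1_rate": hits / n_reps,
        "median_vip": float(np.median(vips)),
        "planted_shift_cycles": shift,
        "n_reps": n_reps,
    }
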