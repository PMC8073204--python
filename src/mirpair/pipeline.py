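"""End-to-end orchestration: from input matrices to a pair-level report.

``run_pipeline`` wires the stages together in the order of the emulated
analysis: count-layer DE -> protein-layer DE -> opposite-direction pair
construction -> per-sample pair ratios -> nonparametric group comparisons
-> PLS-DA with VIP ranking. Every artifact is written as TSV/JSON under
the configured output directory together with a run report (record counts,
drop logs, output manifest). The pipeline is deterministic: rerunning with
identical config and inputs reproduces identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io, qpcr, reference
from .de import de_counts, de_proteins
from .errors import ConfigurationError, MirpairError, PipelineError
from .pairing import build_pairs, venn_partition
from .plsda import fit_plsda, score_plot, vip_scores
from .stats import compare_groups, correlation_matrix, format_p
from .synthetic import SimulatedStudy


@dataclass
class PipelineConfig:
    """All inputs, comparisons and thresholds of one pipeline run."""

    samples: str
    counts: str
    proteins: str
    ct_mirna: str
    ct_mrna: str
    target_map: str
    outdir: str = "mirpair_out"
    # DE comparison on the count/protein layers (early-delivery contrast)
    de_test_group: str = "IUGR_lt_34"
    de_control_group: str = "N_lt_34"
    # ratio/PLS comparison on the qPCR layer (late-delivery contrast)
    ratio_test_group: str = "IUGR_gt_34"
    ratio_control_group: str = "N_gt_34"
    mirna_alpha: float = 0.05
    protein_alpha: float = 0.05
    # which p feeds the pairing thresholds (the emulated study's printed
    # miRNA p-values are nominal, so both modes are supported)
    mirna_adjusted: bool = True
    protein_adjusted: bool = False
    vip_cutoff: float = 1.0
    n_components: int = 2
    seed: int = 0
    mirna_reference_assays: tuple[str, ...] = tuple(reference.MIRNA_REFERENCE_ASSAYS)
    mrna_reference_assays: tuple[str, ...] = tuple(reference.MRNA_REFERENCE_ASSAYS)

    def __post_init__(self):
        for name in ("mirna_alpha", "protein_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {a}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Persist every layer of a simulated study as TSV; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_sample_sheet(study.sample_sheet, outdir / "samples.tsv")
    io.write_ct_table(study.ct_mirna, outdir / "ct_mirna.tsv")
    io.write_ct_table(study.ct_mrna, outdir / "ct_mrna.tsv")
    io.write_matrix(study.counts, outdir / "counts.tsv")
    io.write_matrix(study.proteins, outdir / "proteins.tsv")
    io.write_table(study.target_map, outdir / "target_map.tsv")
    io.write_table(study.truth, outdir / "truth.tsv")
    return {
        "samples": str(outdir / "samples.tsv"),
        "counts": str(outdir / "counts.tsv"),
        "proteins": str(outdir / "proteins.tsv"),
        "ct_mirna": str(outdir / "ct_mirna.tsv"),
        "ct_mrna": str(outdir / "ct_mrna.tsv"),
        "target_map": str(outdir / "target_map.tsv"),
    }


def _stage(name):
    """Wrap stage errors with the stage name for the run report."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MirpairError) and not isinstance(
                exc, PipelineError
            ):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written).

    Raises :class:`PipelineError` naming the failing stage on any error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: str(v) for k, v in asdict(config).items()},
                    "stages": {}, "outputs": {}, "drops": {}}

    with _stage("read-inputs"):
        samples = io.read_sample_sheet(config.samples)
        counts = io.read_matrix(config.counts)
        proteins = io.read_matrix(config.proteins)
        ct_mi = io.read_ct_table(
            config.ct_mirna, config.mirna_reference_assays, layer="ct_mirna"
        )
        ct_mr = io.read_ct_table(
            config.ct_mrna, config.mrna_reference_assays, layer="ct_mrna"
        )
        tmap = io.read_target_map(config.target_map)
    report["stages"]["read-inputs"] = {
        "samples": len(samples), "count_features": len(counts),
        "protein_features": len(proteins), "target_map_rows": len(tmap),
    }

    with _stage("de-counts"):
        de_mi = de_counts(
            counts, samples, config.de_test_group, config.de_control_group,
            alpha=config.mirna_alpha,
        )
    with _stage("de-proteins"):
        de_pr = de_proteins(
            proteins, samples, config.de_test_group, config.de_control_group,
        )
    io.write_table(de_mi.table, outdir / "de_mirna.tsv")
    io.write_table(de_pr.table, outdir / "de_protein.tsv")
    report["stages"]["de"] = {
        "mirna_significant": int(de_mi.table["significant"].sum()),
        "protein_significant": int(de_pr.table["significant"].sum()),
    }
    report["drops"]["de-proteins"] = de_pr.dropped.to_dict("records")

    with _stage("venn"):
        venn = venn_partition(
            set(de_mi.table.loc[de_mi.table["significant"], "feature"]),
            set(de_pr.table.loc[de_pr.table["significant"], "feature"]),
        )
    (outdir / "venn.json").write_text(json.dumps(venn.to_dict(), indent=2))

    with _stage("build-pairs"):
        pairing = build_pairs(
            de_mi.table, de_pr.table, tmap,
            mirna_alpha=config.mirna_alpha, protein_alpha=config.protein_alpha,
            mirna_adjusted=config.mirna_adjusted,
            protein_adjusted=config.protein_adjusted,
        )
    io.write_table(pairing.table, outdir / "pairs.tsv")
    report["stages"]["pairing"] = {
        "mapped_pairs": len(pairing.table),
        "retained_pairs": len(pairing.retained),
        "unmatched_map_rows": len(pairing.unmatched),
    }
    report["drops"]["build-pairs"] = pairing.unmatched.to_dict("records")

    with _stage("delta-ct"):
        dct_mi = qpcr.delta_ct(ct_mi)
        dct_mr = qpcr.delta_ct(ct_mr)

    with _stage("pair-ratios"):
        mi_assays = set(dct_mi["assay_id"])
        mr_assays = set(dct_mr["assay_id"])
        ratio_pairs = pd.DataFrame(
            reference.RATIO_PAIRS, columns=["mirna_id", "gene_id"]
        )
        measurable = ratio_pairs[
            ratio_pairs["mirna_id"].isin(mi_assays)
            & ratio_pairs["gene_id"].isin(mr_assays)
        ].reset_index(drop=True)
        skipped = ratio_pairs[~ratio_pairs.index.isin(measurable.index)]
        ratios = qpcr.pair_ratio(dct_mi, dct_mr, measurable)
    io.write_table(dct_mi, outdir / "delta_ct_mirna.tsv")
    io.write_table(dct_mr, outdir / "delta_ct_mrna.tsv")
    io.write_matrix(ratios, outdir / "pair_ratios.tsv")
    report["stages"]["pair-ratios"] = {"pairs": len(ratios), "samples": ratios.shape[1]}
    report["drops"]["pair-ratios"] = skipped.to_dict("records")

    with _stage("group-stats"):
        groups = samples.set_index("sample_id")["group"]
        rows = []
        for pair_id, values in ratios.iterrows():
            cmp = compare_groups(
                values, groups[values.index],
                config.ratio_test_group, config.ratio_control_group,
                variable=pair_id,
            )
            rows.append(
                {
                    "pair_id": pair_id,
                    f"{config.ratio_test_group}": cmp.summary_a.formatted,
                    f"{config.ratio_control_group}": cmp.summary_b.formatted,
                    "u": cmp.u,
                    "p": cmp.p,
                    "p_display": format_p(cmp.p),
                    "method": cmp.method,
                }
            )
        comparisons = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)

        both = groups[groups.isin([config.ratio_test_group, config.ratio_control_group])]
        dct_wide = (
            pd.concat([dct_mi, dct_mr])
            .pivot(index="sample_id", columns="assay_id", values="delta_ct")
        )
        corr = correlation_matrix(dct_wide.loc[dct_wide.index.isin(both.index)])
    io.write_table(comparisons, outdir / "pair_comparisons.tsv")
    corr_payload = {
        "rho": corr.rho.round(6).to_dict(),
        "p": corr.p.round(6).to_dict(),
        "ci_low": corr.ci_low.round(6).to_dict(),
        "ci_high": corr.ci_high.round(6).to_dict(),
        "significant": {
            k: {kk: bool(vv) for kk, vv in v.items()}
            for k, v in corr.significant.to_dict().items()
        },
    }
    (outdir / "correlation.json").write_text(json.dumps(corr_payload, indent=2))
    report["stages"]["group-stats"] = {
        "comparisons": len(comparisons),
        "significant": int((comparisons["p"] < 0.05).sum()),
    }

    with _stage("plsda"):
        keep = groups[
            groups.isin([config.ratio_test_group, config.ratio_control_group])
        ].index
        X = ratios[[s for s in ratios.columns if s in set(keep)]].T
        model = fit_plsda(X, groups[X.index], n_components=config.n_components)
        vip = vip_scores(model)
        scores, sides = score_plot(model)
    io.write_table(vip, outdir / "vip.tsv")
    io.write_table(scores, outdir / "plsda_scores.tsv")
    report["stages"]["plsda"] = {
        "n_components": model.n_components,
        "imputed_cells": model.n_imputed,
        "vip_above_cutoff": int((vip["vip"] > config.vip_cutoff).sum()),
        "class_side_component1": sides,
    }

    report["outputs"] = {
        p.name: _row_count(p)
        for p in sorted(outdir.glob("*.tsv"))
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _row_count(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)
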