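"""Synthetic study generator with known planted effects.

The real study's per-sample measurements were never deposited, so every
downstream stage of this package is exercised on synthetic cohorts whose
ground truth is known. A simulated study mirrors the measured layers of the
original design:

* **qPCR Ct tables** for the miRNA panel (reference SNORD68) and the mRNA
  panel (references GAPDH + ACTB). A target Ct is drawn as
  ``reference level + baseline dCt + group effect + sample offset + noise``;
  the per-sample loading offset is shared by all assays of a layer and is
  removed exactly by dCt normalization, as in real qPCR.
* **small-RNA read counts**: negative binomial with per-sample library-size
  factors drawn log-uniformly, so median-of-ratios normalization can
  recover them.
* **protein intensities**: log-normal with missing-completely-at-random
  cells, as in label-free proteomics output.

Effects are *planted* via :class:`EffectSpec` (cycles on the Ct layers,
log2 fold change on the count/protein layers) and echoed verbatim in the
returned truth table, so tests never reverse-engineer them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .errors import ConfigurationError, ValidationError
from .qpcr import CtTable

LAYERS = ("ct_mirna", "ct_mrna", "counts", "protein")


@dataclass(frozen=True)
class CohortDesign:
    """Group structure of a simulated cohort."""

    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    seed: int = 0

    def __post_init__(self):
        if len(self.groups) != len(set(self.groups)):
            raise ValidationError("group labels must be unique")
        if len(self.groups) != len(self.n_per_group):
            raise ValidationError("groups and n_per_group must align")
        if any(n < 2 for n in self.n_per_group):
            raise ValidationError("every group needs n >= 2")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.groups, self.n_per_group))

    @property
    def total_n(self) -> int:
        return int(sum(self.n_per_group))


@dataclass(frozen=True)
class EffectSpec:
    """One planted effect: a feature shifted in one group.

    ``effect`` is in cycles for the Ct layers (positive = higher dCt =
    lower expression) and in log2 fold change for counts/protein.
    ``baseline`` and ``sd`` override the layer defaults for that feature
    when given.
    """

    feature: str
    layer: str
    group: str
    effect: float
    baseline: float | None = None
    sd: float | None = None

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; one of {LAYERS}")
        if not np.isfinite(self.effect):
            raise ValidationError(f"effect for {self.feature} must be finite")
        if self.sd is not None and self.sd <= 0:
            raise ValidationError(f"dispersion/SD for {self.feature} must be > 0")


@dataclass(frozen=True)
class SimulationParams:
    """Tunable noise and scale parameters of the generator.

    Defaults reflect common practice for the emulated platforms: qPCR
    replicate noise about half a cycle, quarter-cycle noise on abundant
    reference assays, unit-SD per-sample loading offsets (removed by dCt),
    negative-binomial dispersion 0.1 with 0.5-2x library sizes, and
    log-normal protein intensities with 10% missing cells.
    """

    ct_sd: float = 0.5
    ref_ct_sd: float = 0.25
    sample_offset_sd: float = 1.0
    nb_dispersion: float = 0.1
    libsize_log2_range: tuple[float, float] = (-1.0, 1.0)
    protein_sd: float = 0.5
    protein_missing_rate: float = 0.1
    n_background_counts: int = 200
    n_background_proteins: int = 100
    background_count_log2_range: tuple[float, float] = (5.0, 14.0)
    background_protein_log2_range: tuple[float, float] = (20.0, 30.0)
    default_count_log2_mean: float = 8.0
    default_protein_log2_mean: float = 25.0
    default_ct_baseline: float = 5.0

    def __post_init__(self):
        for name in ("ct_sd", "ref_ct_sd", "nb_dispersion", "protein_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 <= self.protein_missing_rate < 1:
            raise ValidationError("protein_missing_rate must be in [0, 1)")


@dataclass
class SimulatedStudy:
    """All layers of one simulated study plus the planted-effect truth."""

    design: CohortDesign
    sample_sheet: pd.DataFrame          # sample_id, group
    ct_mirna: CtTable
    ct_mrna: CtTable
    counts: pd.DataFrame                # features x samples, integer
    proteins: pd.DataFrame              # features x samples, NaN = missing
    target_map: pd.DataFrame            # mirna_id, gene_id
    truth: pd.DataFrame                 # layer, feature, group, effect, baseline, sd

    @property
    def samples(self) -> list[str]:
        return list(self.sample_sheet["sample_id"])


def default_paper_design(seed: int = 0, early_control: bool = False) -> CohortDesign:
    """The six-group cohort of the emulated study (n = 10, 13, 12, 7, 8, 7).

    With ``early_control=True`` the optional seventh group of three
    early-delivery controls is appended (the control arm of the
    sequencing/proteomics comparisons; not part of the 57).
    """
    groups = list(reference.GROUP_SIZES)
    sizes = [reference.GROUP_SIZES[g] for g in groups]
    if early_control:
        groups.append(reference.EARLY_CONTROL_GROUP)
        sizes.append(reference.EARLY_CONTROL_N)
    return CohortDesign(groups=tuple(groups), n_per_group=tuple(sizes), seed=seed)


def default_study_effects() -> list[EffectSpec]:
    """Planted effects calibrated to the published summaries.

    Ct-layer shifts are the published group-median dCt differences versus
    the late control; count and protein effects are the published log2 fold
    changes of the 16 discriminating miRNA/protein features in the early
    IUGR group (versus the early control).
    """
    effects: list[EffectSpec] = []
    for group, shifts in reference.CT_SHIFTS_MIRNA.items():
        for assay, shift in shifts.items():
            effects.append(EffectSpec(assay, "ct_mirna", group, shift))
    for group, shifts in reference.CT_SHIFTS_MRNA.items():
        for assay, shift in shifts.items():
            effects.append(EffectSpec(assay, "ct_mrna", group, shift))
    seen = set()
    for row in reference.DISCRIMINATING_PAIRS.itertuples(index=False):
        if row.mirna_id not in seen:
            seen.add(row.mirna_id)
            effects.append(
                EffectSpec(row.mirna_id, "counts", "IUGR_lt_34", row.mirna_log2fc)
            )
        if row.gene_id not in seen:
            seen.add(row.gene_id)
            effects.append(
                EffectSpec(row.gene_id, "protein", "IUGR_lt_34", row.protein_log2fc)
            )
    return effects


# --- generation internals --------------------------------------------------


def _sample_sheet(design: CohortDesign) -> pd.DataFrame:
    rows = [
        (f"{group}_s{i + 1:02d}", group)
        for group, n in design.sizes.items()
        for i in range(n)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group"])


def _effect_lookup(effects: list[EffectSpec], layer: str):
    """(feature -> group -> effect, feature -> baseline, feature -> sd)."""
    eff: dict[str, dict[str, float]] = {}
    base: dict[str, float] = {}
    sd: dict[str, float] = {}
    for e in effects:
        if e.layer != layer:
            continue
        eff.setdefault(e.feature, {})[e.group] = e.effect
        if e.baseline is not None:
            base.setdefault(e.feature, e.baseline)
        if e.sd is not None:
            sd.setdefault(e.feature, e.sd)
    return eff, base, sd


def _simulate_ct_layer(
    rng: np.random.Generator,
    sheet: pd.DataFrame,
    layer: str,
    assays: dict[str, float],
    references: dict[str, float],
    effects: list[EffectSpec],
    params: SimulationParams,
) -> CtTable:
    eff, base_over, sd_over = _effect_lookup(effects, layer)
    assay_baselines = dict(assays)
    for feature in eff:
        assay_baselines.setdefault(
            feature, base_over.get(feature, params.default_ct_baseline)
        )
    for feature, b in base_over.items():
        assay_baselines[feature] = b

    ref_level = float(np.mean(list(references.values())))
    samples = sheet["sample_id"].to_numpy()
    groups = sheet["group"].to_numpy()
    offsets = rng.normal(0.0, params.sample_offset_sd, size=len(samples))

    rows = []
    for ref_assay, ref_base in references.items():
        cts = ref_base + offsets + rng.normal(0.0, params.ref_ct_sd, size=len(samples))
        rows.extend(zip(samples, [ref_assay] * len(samples), cts))
    for assay in sorted(assay_baselines):
        baseline = assay_baselines[assay]
        noise_sd = sd_over.get(assay, params.ct_sd)
        shift = np.array([eff.get(assay, {}).get(g, 0.0) for g in groups])
        cts = (
            ref_level
            + baseline
            + shift
            + offsets
            + rng.normal(0.0, noise_sd, size=len(samples))
        )
        rows.extend(zip(samples, [assay] * len(samples), cts))

    data = pd.DataFrame(rows, columns=["sample_id", "assay_id", "ct"])
    return CtTable(data, reference_assays=tuple(references), layer=layer)


def _simulate_counts(
    rng: np.random.Generator,
    sheet: pd.DataFrame,
    effects: list[EffectSpec],
    params: SimulationParams,
) -> pd.DataFrame:
    eff, base_over, _ = _effect_lookup(effects, "counts")
    named = sorted(set(eff) | set(base_over))
    background = [f"mir-bg-{i + 1:04d}" for i in range(params.n_background_counts)]
    lo, hi = params.background_count_log2_range
    log2_means = {f: rng.uniform(lo, hi) for f in background}
    for f in named:
        log2_means[f] = base_over.get(f, params.default_count_log2_mean)

    features = named + background
    groups = sheet["group"].to_numpy()
    n_samples = len(groups)
    log2_lo, log2_hi = params.libsize_log2_range
    libsize = np.exp2(rng.uniform(log2_lo, log2_hi, size=n_samples))

    alpha = params.nb_dispersion
    mat = np.empty((len(features), n_samples), dtype=np.int64)
    for i, f in enumerate(features):
        shift = np.array([eff.get(f, {}).get(g, 0.0) for g in groups])
        mu = np.exp2(log2_means[f] + shift) * libsize
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        mat[i] = rng.negative_binomial(n_param, p_param)
    return pd.DataFrame(mat, index=features, columns=sheet["sample_id"])


def _simulate_proteins(
    rng: np.random.Generator,
    sheet: pd.DataFrame,
    effects: list[EffectSpec],
    params: SimulationParams,
) -> pd.DataFrame:
    eff, base_over, sd_over = _effect_lookup(effects, "protein")
    named = sorted(set(eff) | set(base_over))
    background = [f"prot-bg-{i + 1:04d}" for i in range(params.n_background_proteins)]
    lo, hi = params.background_protein_log2_range
    log2_means = {f: rng.uniform(lo, hi) for f in background}
    for f in named:
        log2_means[f] = base_over.get(f, params.default_protein_log2_mean)

    features = named + background
    groups = sheet["group"].to_numpy()
    n_samples = len(groups)
    mat = np.empty((len(features), n_samples))
    for i, f in enumerate(features):
        shift = np.array([eff.get(f, {}).get(g, 0.0) for g in groups])
        sd = sd_over.get(f, params.protein_sd)
        mat[i] = np.exp2(log2_means[f] + shift + rng.normal(0.0, sd, size=n_samples))
    if params.protein_missing_rate > 0:
        mask = rng.random(mat.shape) < params.protein_missing_rate
        mat[mask] = np.nan
    return pd.DataFrame(mat, index=features, columns=sheet["sample_id"])


def _decoy_target_map(
    rng: np.random.Generator, counts: pd.DataFrame, proteins: pd.DataFrame, n_decoys: int
) -> pd.DataFrame:
    """Named pairs plus random decoy links among background features."""
    mapping = reference.target_map()
    bg_mirnas = [f for f in counts.index if f.startswith("mir-bg-")]
    bg_prots = [f for f in proteins.index if f.startswith("prot-bg-")]
    if bg_mirnas and bg_prots and n_decoys > 0:
        decoys = pd.DataFrame(
            {
                "mirna_id": rng.choice(bg_mirnas, size=n_decoys),
                "gene_id": rng.choice(bg_prots, size=n_decoys),
            }
        )
        mapping = pd.concat([mapping, decoys], ignore_index=True).drop_duplicates()
    return mapping.reset_index(drop=True)


def simulate_study(
    design: CohortDesign,
    effects: list[EffectSpec] | None = None,
    params: SimulationParams | None = None,
    layers: tuple[str, ...] = ("ct", "counts", "protein"),
    n_decoy_links: int = 50,
) -> SimulatedStudy:
    """Generate one complete synthetic study.

    Deterministic given ``design.seed``; identical inputs give
    byte-identical outputs. ``layers`` restricts generation (``"ct"``
    covers both Ct tables) for callers that only need part of the study.

    Raises
    ------
    ConfigurationError
        If an effect references a group absent from the design.
    ValidationError
        If an effect or parameter violates its invariant.
    """
    effects = list(effects) if effects is not None else []
    params = params or SimulationParams()
    known = set(design.groups)
    for e in effects:
        if e.group not in known:
            raise ConfigurationError(
                f"effect for {e.feature!r} references unknown group {e.group!r}"
            )

    rng = np.random.default_rng(design.seed)
    sheet = _sample_sheet(design)

    empty_ct = CtTable(
        pd.DataFrame(columns=["sample_id", "assay_id", "ct"]),
        reference_assays=("none",),
        layer="empty",
        _allow_empty=True,
    )
    ct_mirna = ct_mrna = empty_ct
    counts = pd.DataFrame()
    proteins = pd.DataFrame()

    if "ct" in layers:
        ct_mirna = _simulate_ct_layer(
            rng, sheet, "ct_mirna", reference.CT_BASELINES_MIRNA,
            reference.MIRNA_REFERENCE_ASSAYS, effects, params,
        )
        ct_mrna = _simulate_ct_layer(
            rng, sheet, "ct_mrna", reference.CT_BASELINES_MRNA,
            reference.MRNA_REFERENCE_ASSAYS, effects, params,
        )
    if "counts" in layers:
        counts = _simulate_counts(rng, sheet, effects, params)
    if "protein" in layers:
        proteins = _simulate_proteins(rng, sheet, effects, params)

    mapping = _decoy_target_map(rng, counts, proteins, n_decoy_links)

    truth = pd.DataFrame(
        [
            (e.layer, e.feature, e.group, e.effect, e.baseline, e.sd)
            for e in effects
        ],
        columns=["layer", "feature", "group", "effect", "baseline", "sd"],
    )
    return SimulatedStudy(
        design=design,
        sample_sheet=sheet,
        ct_mirna=ct_mirna,
        ct_mrna=ct_mrna,
        counts=counts,
        proteins=proteins,
        target_map=mapping,
        truth=truth,
    )


def with_seed(design: CohortDesign, seed: int) -> CohortDesign:
    """Copy of a design with a different seed."""
    return replace(design, seed=seed)
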