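"""Differential expression for the count (small-RNA) and protein layers.

The count stage is a deliberately simple desk-scale procedure: samples are
normalized by median-of-ratios size factors (the standard count-data
normalization that is robust to a minority of truly changing features),
counts are moved to log2 with a 0.5 pseudocount, and groups are compared
feature-wise with Welch's unequal-variance t-test followed by
Benjamini-Hochberg adjustment. The protein stage applies the same Welch +
BH machinery to log2 intensities, after dropping features observed in
fewer than ``min_present`` samples of either group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import NormalizationError, StatisticsError, ValidationError
from .stats import bh_adjust

PSEUDOCOUNT = 0.5


@dataclass
class DEResultSet:
    """Per-feature DE table plus the drop log of excluded features."""

    table: pd.DataFrame    # feature, log2_fc, p, p_adjusted, direction, ...
    dropped: pd.DataFrame  # feature, reason

    def significant(self, alpha: float | None = None, adjusted: bool = True) -> pd.DataFrame:
        col = "p_adjusted" if adjusted else "p"
        if alpha is None:
            return self.table[self.table["significant"]]
        return self.table[self.table[col] < alpha]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    For each feature with a strictly positive geometric mean across
    samples, form the ratio count/geomean; a sample's factor is the median
    of its ratios. Requires every sample to have at least one usable
    feature.

    Raises
    ------
    NormalizationError
        If a sample has all-zero counts or no positive-geomean feature.
    """
    if counts.empty:
        raise ValidationError("empty count matrix")
    mat = counts.to_numpy(dtype=float)
    zero_samples = np.where(mat.sum(axis=0) == 0)[0]
    if zero_samples.size:
        raise NormalizationError(
            f"sample {counts.columns[zero_samples[0]]!r} has all-zero counts"
        )
    with np.errstate(divide="ignore"):
        log_geomean = np.mean(np.log(mat), axis=1)  # -inf where any zero
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise NormalizationError("no feature has a positive geometric mean")
    ratios = mat[usable] / np.exp(log_geomean[usable])[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise NormalizationError("non-positive size factor; counts too sparse")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _welch_by_group(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    test_group: str,
    control_group: str,
    nan_policy: str = "propagate",
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Vectorized Welch's t across features; returns (log2fc, p, a, b)."""
    by_group = samples.set_index("sample_id")["group"]
    test_ids = [s for s in values.columns if by_group.get(s) == test_group]
    ctrl_ids = [s for s in values.columns if by_group.get(s) == control_group]
    if len(test_ids) < 2 or len(ctrl_ids) < 2:
        raise StatisticsError(
            f"both groups need >= 2 samples (got {len(test_ids)} in "
            f"{test_group!r}, {len(ctrl_ids)} in {control_group!r})"
        )
    a = values[test_ids]
    b = values[ctrl_ids]
    if nan_policy == "omit":
        log2fc = a.mean(axis=1, skipna=True) - b.mean(axis=1, skipna=True)
        res = sps.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    else:
        log2fc = a.mean(axis=1) - b.mean(axis=1)
        res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    return log2fc.to_numpy(), np.asarray(res.pvalue), a, b


def _assemble(
    features: pd.Index,
    log2fc: np.ndarray,
    p: np.ndarray,
    n_test: np.ndarray | int,
    n_control: np.ndarray | int,
    alpha: float,
    adjusted_cutoff: bool,
) -> pd.DataFrame:
    p = np.where(np.isnan(p), 1.0, p)
    padj = bh_adjust(p)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    table = pd.DataFrame(
        {
            "feature": features,
            "log2_fc": log2fc,
            "p": p,
            "p_adjusted": padj,
            "direction": direction,
            "n_test": n_test,
            "n_control": n_control,
        }
    )
    crit = table["p_adjusted"] if adjusted_cutoff else table["p"]
    table["significant"] = crit < alpha
    return table.sort_values(["p", "feature"], kind="mergesort").reset_index(drop=True)


def de_counts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    test_group: str,
    control_group: str,
    alpha: float = 0.05,
) -> DEResultSet:
    """Count-layer differential expression (test vs control group).

    Normalized counts ``y = log2(count / size_factor + 0.5)`` are compared
    with Welch's t-test per feature; ``log2_fc`` is the difference of group
    means of y, p-values are BH-adjusted and significance is flagged at
    ``p_adjusted < alpha``. Sorted by p.
    """
    if counts.index.duplicated().any():
        raise ValidationError("duplicate feature ids in count matrix")
    sf = size_factors(counts)
    y = np.log2(counts.div(sf, axis=1) + PSEUDOCOUNT)
    log2fc, p, a, b = _welch_by_group(y, samples, test_group, control_group)
    table = _assemble(
        counts.index, log2fc, p, a.shape[1], b.shape[1], alpha, adjusted_cutoff=True
    )
    return DEResultSet(table=table, dropped=pd.DataFrame(columns=["feature", "reason"]))


def de_proteins(
    intensities: pd.DataFrame,
    samples: pd.DataFrame,
    test_group: str,
    control_group: str,
    alpha: float = 0.01,
    min_present: int = 2,
) -> DEResultSet:
    """Protein-layer differential expression on log2 intensities.

    Features observed (non-missing) in fewer than ``min_present`` samples
    of either group are dropped and recorded in the drop log. ``log2_fc``
    is the difference of group means of log2 intensity; Welch's t with BH
    adjustment; significance flagged at nominal ``p < alpha`` (the
    convention of the emulated analysis).
    """
    if intensities.empty:
        raise ValidationError("empty intensity matrix")
    if intensities.index.duplicated().any():
        raise ValidationError("duplicate protein ids in intensity matrix")
    vals = intensities.where(intensities > 0)
    y = np.log2(vals)
    by_group = samples.set_index("sample_id")["group"]
    test_ids = [s for s in y.columns if by_group.get(s) == test_group]
    ctrl_ids = [s for s in y.columns if by_group.get(s) == control_group]
    n_test = y[test_ids].notna().sum(axis=1)
    n_ctrl = y[ctrl_ids].notna().sum(axis=1)
    keep = (n_test >= min_present) & (n_ctrl >= min_present)
    dropped = pd.DataFrame(
        {
            "feature": y.index[~keep],
            "reason": [
                f"observed in <{min_present} samples of a group "
                f"(test={t}, control={c})"
                for t, c in zip(n_test[~keep], n_ctrl[~keep])
            ],
        }
    )
    y = y[keep]
    log2fc, p, a, b = _welch_by_group(
        y, samples, test_group, control_group, nan_policy="omit"
    )
    table = _assemble(
        y.index,
        log2fc,
        p,
        n_test[keep].to_numpy(),
        n_ctrl[keep].to_numpy(),
        alpha,
        adjusted_cutoff=False,
    )
    return DEResultSet(table=table, dropped=dropped.reset_index(drop=True))
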