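"""Two-class PLS-DA fitted by NIPALS, with VIP scores and score plots.

Partial least squares discriminant analysis regresses a -1/+1 class code
on an autoscaled feature matrix and extracts components of maximal
class-covarying variance. With a single response the NIPALS weight vector
of each component is the (normalized) covariance direction ``X' y``, so
the fit is deterministic — no random initialization.

Variable importance in projection (VIP) summarizes each feature's
contribution across components, weighted by the explained class variance
``SSY_a = q_a^2 t_a' t_a``:

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

so the mean squared VIP is always 1 (``sum_j VIP_j^2 = p``), and VIP > 1
marks features contributing more than average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StatisticsError, ValidationError


@dataclass
class PLSModel:
    """Fitted two-class PLS-DA model (NIPALS, autoscaled X, centered y)."""

    n_components: int
    weights: np.ndarray      # W, p x A, each column unit norm
    loadings: np.ndarray     # P, p x A
    scores: np.ndarray       # T, n x A, mutually orthogonal columns
    y_loadings: np.ndarray   # q, length A
    x_mean: np.ndarray
    x_scale: np.ndarray
    classes: tuple[str, str]  # (coded -1, coded +1)
    labels: np.ndarray        # per-sample class labels
    feature_names: list[str]
    sample_names: list[str]
    n_imputed: int            # absent cells mean-imputed before scaling


def _code_labels(y) -> tuple[np.ndarray, tuple[str, str]]:
    labels = np.asarray(y)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValidationError(f"PLS-DA needs exactly two classes, got {classes}")
    coded = np.where(labels == classes[0], -1.0, 1.0)
    return coded, (str(classes[0]), str(classes[1]))


def fit_plsda(X: pd.DataFrame, y, n_components: int = 2) -> PLSModel:
    """Fit a PLS-DA model on a samples x features matrix.

    Missing cells are mean-imputed per feature (count recorded on the
    model), columns are autoscaled to mean 0 / SD 1, the class labels are
    coded -1/+1 and centered, and ``n_components`` NIPALS components are
    extracted with deflation of X and y. ``n_components`` exceeding
    ``min(n - 1, p)`` is reduced with a warning.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(X)
    n, p = X.shape
    if n < 4:
        raise ValidationError("PLS-DA needs at least 4 samples")
    coded, classes = _code_labels(y)
    if len(coded) != n:
        raise ValidationError("labels do not match the number of samples")

    mat = X.to_numpy(dtype=float).copy()
    all_absent = np.isnan(mat).all(axis=0)
    if all_absent.any():
        raise ValidationError(
            f"feature(s) with no observed values: {list(X.columns[all_absent])[:5]}"
        )
    n_imputed = int(np.isnan(mat).sum())
    if n_imputed:
        col_means = np.nanmean(mat, axis=0)
        idx = np.where(np.isnan(mat))
        mat[idx] = col_means[idx[1]]

    x_mean = mat.mean(axis=0)
    x_scale = mat.std(axis=0, ddof=1)
    zero_var = x_scale == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} constant feature(s) carry no information",
            stacklevel=2,
        )
        x_scale = np.where(zero_var, 1.0, x_scale)
    Xc = (mat - x_mean) / x_scale
    yc = coded - coded.mean()
    if np.allclose(yc, 0):
        raise ValidationError("single-class response after coding")

    a_max = min(n - 1, p)
    if n_components > a_max:
        warnings.warn(
            f"n_components reduced from {n_components} to {a_max}", stacklevel=2
        )
        n_components = a_max
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    Xr, yr = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise StatisticsError(
                f"component {a + 1}: no residual covariance with the class code"
            )
        w /= norm
        t = Xr @ w
        tt = t @ t
        q_a = (t @ yr) / tt
        p_a = (Xr.T @ t) / tt
        Xr = Xr - np.outer(t, p_a)
        yr = yr - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a

    return PLSModel(
        n_components=n_components,
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=q,
        x_mean=x_mean,
        x_scale=x_scale,
        classes=classes,
        labels=np.asarray(y),
        feature_names=list(map(str, X.columns)),
        sample_names=list(map(str, X.index)),
        n_imputed=n_imputed,
    )


def vip_scores(model: PLSModel) -> pd.DataFrame:
    """Per-feature VIP scores, ranked descending, flagged at VIP > 1.

    Raises
    ------
    StatisticsError
        If the model explains no class variance at all (zero total SSY).
    """
    W, T, q = model.weights, model.scores, model.y_loadings
    ssy = q**2 * np.einsum("ia,ia->a", T, T)
    total = ssy.sum()
    if total <= 0:
        raise StatisticsError("degenerate model: zero explained class variance")
    wnorm2 = W**2 / np.maximum((W**2).sum(axis=0), 1e-300)
    p = W.shape[0]
    vip = np.sqrt(p * (wnorm2 @ ssy) / total)
    out = pd.DataFrame({"feature": model.feature_names, "vip": vip})
    out = out.sort_values("vip", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["above_threshold"] = out["vip"] > 1.0
    return out


def score_plot(model: PLSModel) -> tuple[pd.DataFrame, dict[str, int]]:
    """Component-1/2 score coordinates per sample, plus class cluster sides.

    Returns a frame (sample, t1, t2, group) and a mapping class -> sign of
    its mean component-1 score (which side of zero the class clusters on).

    Raises
    ------
    ValidationError
        If the model has fewer than two components.
    """
    if model.n_components < 2:
        raise ValidationError("score_plot needs a model with >= 2 components")
    frame = pd.DataFrame(
        {
            "sample": model.sample_names,
            "t1": model.scores[:, 0],
            "t2": model.scores[:, 1],
            "group": model.labels,
        }
    )
    sides = {
        cls: int(np.sign(frame.loc[frame["group"] == cls, "t1"].mean()))
        for cls in model.classes
    }
    return frame, sides
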