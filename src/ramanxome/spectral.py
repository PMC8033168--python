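"""Spectral discrimination of non-activated (D0) vs activated (D4) cells.

Operates on background-corrected per-cell compartment mean spectra:

* the 752/786 cm^-1 nucleic-acid peak-ratio test (windowed band means,
  Welch two-sided t-test);
* PCA of the cell spectra with a per-component Welch t-test between
  conditions (first 9 components by default);
* Fisher linear discriminant over selected PC scores, with the decision
  threshold at the midpoint of the projected class means and the
  discriminant back-projected onto the wavenumber axis as a loading
  spectrum;
* leave-one-out confusion counts with D4 as the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import WavenumberAxis

POSITIVE_CLASS = "D4"


# ---------------------------------------------------------------------------
# peak ratio
# ---------------------------------------------------------------------------

def peak_intensity(
    spectrum: np.ndarray,
    axis: WavenumberAxis,
    center: float,
    half_window: float = 4.0,
) -> float:
    """Mean intensity over channels within center ± half_window cm^-1."""
    band = axis.band_indices(center - half_window, center + half_window)
    if band.size == 0:
        raise ValueError(f"window {center}±{half_window} cm^-1 contains no channels")
    return float(np.asarray(spectrum, dtype=np.float64)[band].mean())


@dataclass
class TestResult:
    statistic: float
    p_value: float
    group_means: dict[str, float]
    n_per_group: dict[str, int]
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _welch(a: np.ndarray, b: np.ndarray, alpha: float = 0.05, names=("D0", "D4")) -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch t-test needs >= 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate but well-defined limits
        stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf * np.sign(a.mean() - b.mean()), 0.0)
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        group_means={names[0]: float(a.mean()), names[1]: float(b.mean())},
        n_per_group={names[0]: int(a.size), names[1]: int(b.size)},
        alpha=alpha,
    )


def peak_ratio_test(
    spectra: np.ndarray,
    axis: WavenumberAxis,
    labels: np.ndarray,
    c1: float = 752.0,
    c2: float = 786.0,
    half_window: float = 4.0,
    alpha: float = 0.05,
) -> tuple[np.ndarray, TestResult]:
    """Per-cell intensity ratio I(c1)/I(c2) and a Welch test between groups.

    Cells with a non-positive denominator intensity are excluded from the
    test (ratio NaN) with a warning.
    """
    spectra = np.asarray(spectra, dtype=np.float64)
    labels = np.asarray(labels)
    num = np.array([peak_intensity(s, axis, c1, half_window) for s in spectra])
    den = np.array([peak_intensity(s, axis, c2, half_window) for s in spectra])
    bad = den <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} cell(s) excluded from the peak-ratio test "
            f"(non-positive {c2} cm^-1 intensity)",
            stacklevel=2,
        )
    ratios = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    g0, g1 = groups
    test = _welch(
        ratios[(labels == g0) & ~bad], ratios[(labels == g1) & ~bad], alpha, names=(g0, g1)
    )
    return ratios, test


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCModel:
    """PCA of cell spectra: mean, orthonormal loadings, scores per cell."""

    mean: np.ndarray  # (C,)
    loadings: np.ndarray  # (r, C), rows orthonormal, variance-ordered
    scores: np.ndarray  # (n, r)
    explained_variance_ratio: np.ndarray  # (r,)
    n_keep: int

    @property
    def kept_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_keep]

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        k = self.loadings.shape[0] if n_components is None else n_components
        return self.mean + self.scores[:, :k] @ self.loadings[:k]

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        return (np.asarray(spectra, float) - self.mean) @ self.loadings.T


def fit_pca(spectra: np.ndarray, n_keep: int = 9) -> PCModel:
    """Centered PCA via SVD; components ordered by explained variance.

    Sign convention: each loading's largest-magnitude element is positive.
    """
    X = np.asarray(spectra, dtype=np.float64)
    n, c = X.shape
    rank = min(n - 1, c)
    if n_keep > rank:
        raise ValueError(f"n_keep={n_keep} exceeds min(cells-1, channels)={rank}")
    if n < n_keep + 1:
        raise ValueError("need at least n_keep + 1 cells")
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    flip = np.sign(Vt[np.arange(rank), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = U * s * flip[None, :]
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return PCModel(mean=mean, loadings=Vt, scores=scores, explained_variance_ratio=evr, n_keep=n_keep)


def pc_score_tests(
    pcm: PCModel,
    labels: np.ndarray,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Welch t-test per retained principal component (no multiplicity
    correction by default; ``holm=True`` applies Holm step-down)."""
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    g0, g1 = groups
    if (labels == g0).sum() < 2 or (labels == g1).sum() < 2:
        raise ValueError("each group needs >= 2 cells")
    rows = []
    for j in range(pcm.n_keep):
        t = _welch(pcm.scores[labels == g0, j], pcm.scores[labels == g1, j], alpha, names=(g0, g1))
        rows.append(
            {
                "component": j + 1,
                "statistic": t.statistic,
                "p_value": t.p_value,
                f"mean_{g0}": t.group_means[g0],
                f"mean_{g1}": t.group_means[g1],
            }
        )
    df = pd.DataFrame(rows)
    p = df["p_value"].to_numpy()
    if holm:
        m = p.size
        order = np.argsort(p)
        padj = np.empty(m)
        padj[order] = np.maximum.accumulate((m - np.arange(m)) * p[order])
        df["p_adjusted"] = np.minimum(padj, 1.0)
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = p < alpha
    return df


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDModel:
    """Fisher discriminant over selected PC scores (D4-positive direction)."""

    pc_indices: np.ndarray  # 0-based component indices into the PC model
    coef: np.ndarray  # (len(pc_indices),)
    threshold: float
    ld_scores: np.ndarray  # training cells
    classes: tuple[str, str]  # (negative, positive)
    loading_spectrum: np.ndarray | None = None  # coef-weighted sum of PC loadings

    def project(self, pc_scores: np.ndarray) -> np.ndarray:
        """LD score(s) for full PC-score vectors (rows)."""
        S = np.atleast_2d(np.asarray(pc_scores, float))
        return S[:, self.pc_indices] @ self.coef

    def classify(self, pc_scores: np.ndarray) -> np.ndarray:
        ld = self.project(pc_scores)
        neg, pos = self.classes
        return np.where(ld > self.threshold, pos, neg)


def fit_lda(
    pcm: PCModel | np.ndarray,
    labels: np.ndarray,
    pc_indices=None,
) -> LDModel:
    """Fisher LDA on PC scores: w ∝ S_w^-1 (mu_pos − mu_neg).

    The direction is scaled so the pooled within-class variance of the LD
    scores is 1 and oriented so the positive class (D4) projects high;
    the threshold is the midpoint of the projected class means (equal
    priors). A singular within-class scatter gets a small ridge with a
    warning. When fitted from a PCModel the discriminant is also
    back-projected to the wavenumber axis.
    """
    if isinstance(pcm, PCModel):
        scores, loadings = pcm.scores, pcm.loadings
        if pc_indices is None:
            pc_indices = np.arange(pcm.n_keep)
    else:
        scores, loadings = np.asarray(pcm, float), None
        if pc_indices is None:
            pc_indices = np.arange(scores.shape[1])
    pc_indices = np.asarray(pc_indices, dtype=np.int64)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"expected 2 classes, got {groups}")
    pos = POSITIVE_CLASS if POSITIVE_CLASS in groups else groups[1]
    neg = groups[0] if groups[1] == pos else groups[1]
    S = scores[:, pc_indices]
    a, b = S[labels == neg], S[labels == pos]
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both classes must be present")
    d = b.mean(axis=0) - a.mean(axis=0)
    Sw = (a - a.mean(axis=0)).T @ (a - a.mean(axis=0)) + (b - b.mean(axis=0)).T @ (b - b.mean(axis=0))
    try:
        w = np.linalg.solve(Sw, d)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; adding ridge 1e-8", stacklevel=2)
        ridge = 1e-8 * max(np.trace(Sw) / Sw.shape[0], 1.0)
        w = np.linalg.solve(Sw + ridge * np.eye(Sw.shape[0]), d)
    n = len(a) + len(b)
    s2 = float(w @ Sw @ w) / max(n - 2, 1)
    if s2 > 0:
        w = w / np.sqrt(s2)
    if (b.mean(axis=0) - a.mean(axis=0)) @ w < 0:
        w = -w
    ld = S @ w
    threshold = 0.5 * (ld[labels == neg].mean() + ld[labels == pos].mean())
    loading = w @ loadings[pc_indices] if loadings is not None else None
    return LDModel(
        pc_indices=pc_indices,
        coef=w,
        threshold=float(threshold),
        ld_scores=ld,
        classes=(neg, pos),
        loading_spectrum=loading,
    )


# ---------------------------------------------------------------------------
# leave-one-out validation
# ---------------------------------------------------------------------------

@dataclass
class LOOCVResult:
    """Leave-one-out confusion counts with D4 as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    predictions: pd.DataFrame  # per cell: true label, predicted label, LD score

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def loo_classify(
    spectra: np.ndarray,
    labels: np.ndarray,
    pc_indices=None,
    n_keep: int = 9,
    strict: bool = False,
) -> LOOCVResult:
    """Leave-one-out LDA classification of cells.

    Default scheme: PCA is fit once on all cells and the LDA is refit per
    fold (common chemometrics practice); ``strict=True`` refits the PCA
    inside every fold and projects the held-out spectrum onto the fold's
    loadings.
    """
    X = np.asarray(spectra, dtype=np.float64)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"expected 2 classes, got {groups}")
    if min((labels == g).sum() for g in groups) < 3:
        raise ValueError("need >= 3 cells per class for leave-one-out")
    n = X.shape[0]
    pcm_full = None if strict else fit_pca(X, n_keep=n_keep)
    rows = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_labels = labels[mask]
        if len(set(train_labels)) < 2:
            raise ValueError("training fold lost a class")
        if strict:
            pcm = fit_pca(X[mask], n_keep=n_keep)
            ldm = fit_lda(pcm, train_labels, pc_indices)
            held = pcm.transform(X[i])[..., : pcm.loadings.shape[0]]
        else:
            ldm = fit_lda(
                pcm_full.scores[mask], train_labels,
                pc_indices if pc_indices is not None else np.arange(n_keep),
            )
            held = pcm_full.scores[i][None, :]
        pred = ldm.classify(held)[0]
        rows.append(
            {"true": labels[i], "predicted": pred, "ld_score": float(ldm.project(held)[0])}
        )
    df = pd.DataFrame(rows)
    pos = POSITIVE_CLASS if POSITIVE_CLASS in groups else groups[1]
    is_pos = df["true"] == pos
    pred_pos = df["predicted"] == pos
    return LOOCVResult(
        tp=int((is_pos & pred_pos).sum()),
        fp=int((~is_pos & pred_pos).sum()),
        tn=int((~is_pos & ~pred_pos).sum()),
        fn=int((is_pos & ~pred_pos).sum()),
        predictions=df,
    )
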