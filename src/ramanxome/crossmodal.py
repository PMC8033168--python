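"""Cross-modal linkage of Raman PC scores to transcript read counts.

The transcriptome is bulk (3 replicates per condition) while Raman is
single-cell, so cells are first randomly assigned to balanced
pseudo-replicate groups within each condition and averaged; the group-mean
PC-score vectors R are then regressed on transcript features T by PLS2
(NIPALS), R = T·β. Model validity is assessed by leave-one-out prediction:
each of the six samples is held out in turn, β₋ᵢ is fit on the rest, the
held-out sample's PC scores are predicted as R̂ᵢ = Tᵢ·β₋ᵢ, converted to an
LD score via the spectral discriminant and called D0 or D4. Transcripts are
ranked by Variable Importance in Projection (VIP).

Count features are log2(1 + count), centered per transcript with
training-sample means only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix
from .spectral import LDModel


# ---------------------------------------------------------------------------
# pseudo-replicates
# ---------------------------------------------------------------------------

@dataclass
class PseudoReplicateSet:
    """Random balanced grouping of cells into per-condition bulk samples."""

    assignment: dict  # cell id -> group id (e.g. "D0-1")
    group_means: pd.DataFrame  # group id x PC columns
    group_conditions: dict[str, str]
    seed: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group_means.index)


def make_pseudoreplicates(
    cell_scores: np.ndarray,
    labels: np.ndarray,
    n_groups: int = 3,
    seed: int = 0,
    cell_ids=None,
) -> PseudoReplicateSet:
    """Uniform random balanced partition per condition; deterministic by seed.

    Group sizes within a condition differ by at most one cell; each group's
    response is the arithmetic mean of its member cells' PC-score vectors.
    """
    S = np.asarray(cell_scores, dtype=np.float64)
    labels = np.asarray(labels)
    if cell_ids is None:
        cell_ids = np.arange(S.shape[0])
    cell_ids = np.asarray(cell_ids)
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    means, group_ids, group_conditions = [], [], {}
    for cond in sorted(set(labels)):
        idx = np.nonzero(labels == cond)[0]
        if idx.size < n_groups:
            raise ValueError(f"condition {cond!r} has {idx.size} cells < {n_groups} groups")
        perm = rng.permutation(idx)
        for g, chunk in enumerate(np.array_split(perm, n_groups), start=1):
            gid = f"{cond}-{g}"
            for ci in chunk:
                assignment[cell_ids[ci]] = gid
            means.append(S[chunk].mean(axis=0))
            group_ids.append(gid)
            group_conditions[gid] = cond
    group_means = pd.DataFrame(
        means, index=group_ids, columns=[f"PC{j+1}" for j in range(S.shape[1])]
    )
    return PseudoReplicateSet(
        assignment=assignment,
        group_means=group_means,
        group_conditions=group_conditions,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# count preprocessing
# ---------------------------------------------------------------------------

@dataclass
class CountTransform:
    """log2(1+count) featurisation with training-only per-transcript centering."""

    train_means: pd.Series  # per transcript

    def apply(self, counts: pd.DataFrame, samples) -> pd.DataFrame:
        feats = np.log2(1.0 + counts[list(samples)].T.astype(np.float64))
        return feats - self.train_means.values[None, :]


def preprocess_counts(
    cm: CountMatrix | pd.DataFrame,
    train_samples,
) -> tuple[pd.DataFrame, CountTransform]:
    """Features for the training samples plus the transform for held-out ones.

    Returns (samples x transcripts frame for *train_samples*, transform);
    held-out samples are always centered with the training means, never
    their own.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    train_samples = list(train_samples)
    missing = [s for s in train_samples if s not in counts.columns]
    if missing:
        raise ValueError(f"training samples not in count matrix: {missing}")
    logc = np.log2(1.0 + counts[train_samples].T.astype(np.float64))
    means = logc.mean(axis=0)
    transform = CountTransform(train_means=means)
    return logc - means.values[None, :], transform


# ---------------------------------------------------------------------------
# PLS2 (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """PLS2 regression of multivariate responses on transcript features."""

    A: int  # requested latent components
    n_components: int  # actually extracted (< A when X is exhausted)
    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray  # (p, A) X-weights
    P: np.ndarray  # (p, A) X-loadings
    Q: np.ndarray  # (m, A) Y-loadings
    T_scores: np.ndarray  # (n, A) X-scores
    ssy: np.ndarray  # (A,) response variance captured per component
    B: np.ndarray  # (p, m) coefficient matrix beta
    feature_ids: list = field(default_factory=list)
    response_ids: list = field(default_factory=list)

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        Xa = X.to_numpy(dtype=np.float64) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return (np.atleast_2d(Xa) - self.x_mean) @ self.B + self.y_mean


def fit_pls(T, R, A: int = 2, tol: float = 1e-12, max_iter: int = 1000) -> PLSModel:
    """PLS2 via NIPALS with deflation of both X and Y; deterministic.

    Components are extracted until *A* is reached or the X residual is
    exhausted (noiseless low-rank designs). β is assembled as
    W (PᵀW)⁻¹ Qᵀ on centered data.
    """
    feature_ids = list(T.columns) if isinstance(T, pd.DataFrame) else []
    response_ids = list(R.columns) if isinstance(R, pd.DataFrame) else []
    X = T.to_numpy(dtype=np.float64) if isinstance(T, pd.DataFrame) else np.asarray(T, np.float64)
    Y = R.to_numpy(dtype=np.float64) if isinstance(R, pd.DataFrame) else np.asarray(R, np.float64)
    Y = Y.reshape(Y.shape[0], -1)
    n, p = X.shape
    m = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("T and R must have the same number of samples")
    if A < 0 or A > min(n - 1, p):
        raise ValueError(f"A must be in [0, min(samples-1, features)] = [0, {min(n - 1, p)}]")
    if np.allclose(Y.var(axis=0), 0):
        raise ValueError("responses have zero variance")
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xr, Yr = X - x_mean, Y - y_mean
    x_scale = float(np.abs(Xr).max()) or 1.0
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((m, A))
    Tsc = np.zeros((n, A))
    ssy = np.zeros(A)
    used = 0
    for a in range(A):
        if np.abs(Xr).max() < 1e-12 * x_scale:
            break
        u = Yr[:, int(Yr.var(axis=0).argmax())].copy()
        if np.linalg.norm(u) < 1e-14:
            # Y exhausted; continue along dominant X direction
            u = Xr[:, int(Xr.var(axis=0).argmax())].copy()
        w = t = q = None
        for _ in range(max_iter):
            w = Xr.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-14:
                break
            w /= nw
            t = Xr @ w
            tt = float(t @ t)
            if tt < 1e-14:
                break
            q = Yr.T @ t / tt
            qq = float(q @ q)
            u_new = Yr @ q / qq if qq > 1e-14 else t
            if np.linalg.norm(u_new - u) <= tol * max(np.linalg.norm(u_new), 1e-30):
                u = u_new
                break
            u = u_new
        if w is None or t is None or float(t @ t) < 1e-14:
            break
        tt = float(t @ t)
        p_a = Xr.T @ t / tt
        q_a = Yr.T @ t / tt
        Xr = Xr - np.outer(t, p_a)
        Yr = Yr - np.outer(t, q_a)
        W[:, a], P[:, a], Q[:, a], Tsc[:, a] = w, p_a, q_a, t
        ssy[a] = tt * float(q_a @ q_a)
        used = a + 1
    if used:
        Wu, Pu, Qu = W[:, :used], P[:, :used], Q[:, :used]
        B = Wu @ np.linalg.solve(Pu.T @ Wu, Qu.T)
    else:
        B = np.zeros((p, m))
    return PLSModel(
        A=A,
        n_components=used,
        x_mean=x_mean,
        y_mean=y_mean,
        W=W[:, :used],
        P=P[:, :used],
        Q=Q[:, :used],
        T_scores=Tsc[:, :used],
        ssy=ssy[:used],
        B=B,
        feature_ids=feature_ids,
        response_ids=response_ids,
    )


# ---------------------------------------------------------------------------
# leave-one-out prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    sample_id: str
    condition: str  # true condition of the held-out sample
    r_predicted: pd.Series  # predicted PC-score vector
    residual: float  # ||R_predicted - R_actual||
    ld_score: float | None = None
    group_call: str | None = None


def loo_predict_features(
    features: pd.DataFrame,
    responses: pd.DataFrame,
    A: int = 2,
    ld_model: LDModel | None = None,
    conditions: dict[str, str] | None = None,
) -> list[PredictionResult]:
    """Leave-one-sample-out PLS prediction from an arbitrary feature frame.

    *features* and *responses* share a sample index; responses' columns are
    PC1..PCk in the PCA's component order, so an LDModel's pc_indices
    address them directly. Every training fold must retain both conditions.
    """
    sample_ids = list(responses.index)
    if len(sample_ids) < 3:
        raise ValueError("need >= 3 samples for leave-one-out")
    missing = [s for s in sample_ids if s not in features.index]
    if missing:
        raise ValueError(f"samples missing from the feature frame: {missing}")
    if conditions is None:
        conditions = {s: str(s).rsplit("-", 1)[0] for s in sample_ids}
    results = []
    for sid in sample_ids:
        train = [s for s in sample_ids if s != sid]
        if len({conditions[s] for s in train}) < 2:
            raise ValueError(f"training fold without sample {sid!r} lost a condition")
        pls = fit_pls(features.loc[train], responses.loc[train], A=A)
        r_pred = pls.predict(features.loc[[sid]])[0]
        resid = float(np.linalg.norm(r_pred - responses.loc[sid].to_numpy()))
        ld = call = None
        if ld_model is not None:
            ld = float(ld_model.project(r_pred)[0])
            call = str(ld_model.classify(r_pred)[0])
        results.append(
            PredictionResult(
                sample_id=sid,
                condition=conditions[sid],
                r_predicted=pd.Series(r_pred, index=responses.columns),
                residual=resid,
                ld_score=ld,
                group_call=call,
            )
        )
    return results


def loo_predict(
    counts: CountMatrix,
    responses: pd.DataFrame,
    A: int = 2,
    ld_model: LDModel | None = None,
) -> list[PredictionResult]:
    """Leave-one-sample-out PLS prediction of Raman PC scores from counts.

    Features are log2(1 + count); centering happens inside each PLS fit
    (training samples only, so the held-out sample never centers itself).
    """
    sample_ids = list(responses.index)
    missing = [s for s in sample_ids if s not in counts.counts.columns]
    if missing:
        raise ValueError(f"samples missing from count matrix: {missing}")
    features = np.log2(1.0 + counts.counts[sample_ids].T.astype(np.float64))
    conditions = counts.conditions or None
    return loo_predict_features(features, responses, A=A, ld_model=ld_model, conditions=conditions)


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def vip_scores(pls: PLSModel) -> pd.Series:
    """Variable Importance in Projection, sorted descending.

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/||w_a||)² / Σ_a SSY_a ); the mean of
    VIP² over transcripts is 1 by construction.
    """
    if pls.n_components < 1:
        raise ValueError("VIP requires at least one fitted component")
    W = pls.W
    p = W.shape[0]
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (W**2 / wnorm2) @ pls.ssy
    vip = np.sqrt(p * contrib / pls.ssy.sum())
    idx = pls.feature_ids if pls.feature_ids else np.arange(p)
    return pd.Series(vip, index=idx, name="VIP").sort_values(ascending=False, kind="stable")


def vip_recovery(ranking: pd.Series, informative_ids, n: int = 20) -> float:
    """Fraction of the top-n VIP transcripts that are planted informative:
    |top-n ∩ informative| / min(n, |informative|)."""
    informative = set(informative_ids)
    if not informative:
        return 0.0
    top = set(ranking.index[:n])
    return len(top & informative) / min(n, len(informative))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class CrossModalResult:
    pseudo_replicates: PseudoReplicateSet
    pls: PLSModel  # full six-sample model (VIP source)
    vip: pd.Series
    predictions: list[PredictionResult]

    def calls_correct(self) -> int:
        return sum(1 for r in self.predictions if r.group_call == r.condition)


def crossmodal_analysis(
    cell_scores: np.ndarray,
    labels: np.ndarray,
    counts: CountMatrix,
    ld_model: LDModel | None = None,
    A: int = 2,
    n_groups: int = 3,
    seed: int = 0,
) -> CrossModalResult:
    """Full cross-modal stage against an existing count matrix.

    Pseudo-replicates are paired to count-matrix samples by index order
    within each condition (replicates are exchangeable).
    """
    reps = make_pseudoreplicates(cell_scores, labels, n_groups=n_groups, seed=seed)
    responses = reps.group_means
    if list(responses.index) != list(counts.counts.columns):
        if set(responses.index) != set(counts.counts.columns):
            raise ValueError("pseudo-replicate ids do not match count matrix samples")
        responses = responses.loc[list(counts.counts.columns)]
    X_full, _ = preprocess_counts(counts, list(responses.index))
    pls = fit_pls(X_full, responses, A=A)
    vip = vip_scores(pls)
    preds = loo_predict(counts, responses, A=A, ld_model=ld_model)
    return CrossModalResult(pseudo_replicates=reps, pls=pls, vip=vip, predictions=preds)
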