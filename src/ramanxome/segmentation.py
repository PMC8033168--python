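"""Common k-means segmentation of pooled Raman maps and spectrum extraction.

"Common" k-means clusters the pooled pixel spectra of *all* maps at once
(default k = 10), so cluster identities are shared across cells; clusters are
then assigned to nucleus / cytoplasm / background from their centroid
profiles, per-map compartment mean spectra are extracted, maps with missing
or too-small nuclei (< 3 um equivalent diameter) are discarded, and the
remaining spectra are background-corrected in three steps:

1. subtract a per-spectrum offset (mean intensity in the 1780–1840 cm^-1
   band, clipped to the axis);
2. smooth the background spectrum with a Savitzky–Golay filter (order 2,
   frame 99 channels);
3. subtract the smoothed background from nucleus, cytoplasm and whole-cell
   spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.cluster import kmeans_plusplus

from .io import (
    BACKGROUND,
    COMPARTMENT_CODES,
    CYTOPLASM,
    NUCLEUS,
    HyperMap,
    WavenumberAxis,
    ensure_shared_axis,
)

CELL_COMPARTMENTS = ("nucleus", "cytoplasm")


def pool_spectra(maps: list[HyperMap]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack every pixel spectrum of every map into one (N, C) matrix.

    The index frame maps each row back to (map_id, row, col); pixel order is
    row-major within each map, maps in the given order.
    """
    axis = ensure_shared_axis(maps)
    blocks, idx = [], []
    for m in maps:
        blocks.append(m.cube.reshape(m.n_pixels, len(axis)))
        rows, cols = np.divmod(np.arange(m.n_pixels), m.width)
        idx.append(pd.DataFrame({"map_id": m.map_id, "row": rows, "col": cols}))
    X = np.vstack(blocks).astype(np.float32, copy=False)
    index = pd.concat(idx, ignore_index=True)
    return X, index


@dataclass
class ClusterModel:
    """Pooled k-means result over all maps."""

    k: int
    centroids: np.ndarray  # (k, C) float64
    labels: np.ndarray  # (N,) cluster index per pooled pixel
    index: pd.DataFrame | None  # row -> (map_id, row, col)
    inertia: float
    seed: int
    n_init: int
    n_iter: int
    inertia_path: list[float] = field(default_factory=list)  # best run, per iteration

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def labels_for(self, map_id: str) -> np.ndarray:
        """Cluster-label grid for one map (requires a pixel index)."""
        if self.index is None:
            raise ValueError("cluster model has no pixel index")
        sel = self.index["map_id"].to_numpy() == map_id
        if not sel.any():
            raise KeyError(f"map {map_id!r} not in cluster model")
        sub = self.index[sel]
        h, w = int(sub["row"].max()) + 1, int(sub["col"].max()) + 1
        grid = np.empty((h, w), dtype=np.int64)
        grid[sub["row"].to_numpy(), sub["col"].to_numpy()] = self.labels[sel]
        return grid

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = _sq_distances(np.asarray(X, dtype=np.float32), self.centroids)
        return d.argmin(axis=1)


def _row_sq_norms(X: np.ndarray, chunk: int = 65536) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=np.float64)
    for lo in range(0, X.shape[0], chunk):
        blk = X[lo : lo + chunk].astype(np.float64)
        out[lo : lo + chunk] = np.einsum("ij,ij->i", blk, blk)
    return out


def _partial_distances(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """csq - 2 X C^T: squared distances minus the per-row norm offset.

    The omitted ||x||^2 term is constant per row, so argmin over clusters is
    unaffected; add the precomputed row norms back to get true distances.
    """
    cross = (X @ C.astype(np.float32).T).astype(np.float64)
    csq = np.einsum("ij,ij->i", C, C)
    return csq[None, :] - 2.0 * cross


def _sq_distances(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    d = _partial_distances(X, C) + _row_sq_norms(X)[:, None]
    return np.maximum(d, 0.0)


def _count_distinct_rows(X: np.ndarray, stop_at: int) -> int:
    seen: set[bytes] = set()
    for row in X:
        seen.add(row.tobytes())
        if len(seen) >= stop_at:
            break
    return len(seen)


def common_kmeans(
    pooled: np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
    index: pd.DataFrame | None = None,
    check_distinct: bool = True,
    init_subsample: int | None = 20000,
) -> ClusterModel:
    """Lloyd k-means (Euclidean) with k-means++ starts, best of n_init.

    Deterministic given *seed*. A restart stops when the labels are stable
    or the squared centroid shift drops below ``tol`` times the total pixel
    variance (after which labels and centroids are re-synchronised), so at
    convergence each non-empty centroid equals the mean of its member
    spectra. Within every restart the within-cluster sum of squares is
    asserted non-increasing across Lloyd iterations. Empty clusters are
    re-seeded on the point currently farthest from its centroid. Raises if
    k exceeds the number of distinct spectra.

    ``init_subsample`` caps the number of pixels fed to the k-means++
    seeding (a deterministic random subsample; Lloyd always runs on every
    pixel). The subsample falls back to the full data if it carries fewer
    than k distinct spectra.
    """
    X = np.ascontiguousarray(pooled, dtype=np.float32)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("pooled spectra must be a non-empty 2-D matrix")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"k={k} exceeds the {n} pooled spectra")
    if check_distinct and _count_distinct_rows(X, k) < k:
        raise ValueError(f"k={k} exceeds the number of distinct spectra")

    rng = np.random.default_rng(seed)
    # scale-free stopping: tol is relative to the total variance of the data
    shift_scale = float(np.var(X.astype(np.float64), axis=0).sum())
    xsq = _row_sq_norms(X)
    X_init = X
    if init_subsample is not None and n > init_subsample:
        sub = rng.choice(n, size=init_subsample, replace=False)
        cand = X[np.sort(sub)]
        if _count_distinct_rows(cand, k) >= k:
            X_init = np.ascontiguousarray(cand)
    best: tuple | None = None
    for _ in range(max(1, n_init)):
        init_seed = int(rng.integers(2**31))
        C, _ = kmeans_plusplus(X_init, k, random_state=init_seed)
        C = C.astype(np.float64)
        labels = np.full(n, -1, dtype=np.int64)
        path: list[float] = []

        def lloyd_step(C, prev_labels):
            dpart = _partial_distances(X, C)
            lab = dpart.argmin(axis=1)
            per_point = np.maximum(dpart[np.arange(n), lab] + xsq, 0.0)
            inertia = float(per_point.sum())
            if path:
                # float32 distance round-off can wiggle at the last digit
                assert inertia <= path[-1] * (1 + 1e-6) + 1e-9, "inertia increased"
            path.append(inertia)
            if np.array_equal(lab, prev_labels):
                return C, lab, inertia, True
            newC = C.copy()
            counts = np.bincount(lab, minlength=k)
            for j in range(k):
                if counts[j]:
                    newC[j] = X[lab == j].mean(axis=0, dtype=np.float64)
            if (counts == 0).any():
                for j in np.nonzero(counts == 0)[0]:
                    far = int(per_point.argmax())
                    newC[j] = X[far]
                    per_point[far] = 0.0
            return newC, lab, inertia, False

        for it in range(1, max_iter + 1):
            newC, labels, inertia, stable = lloyd_step(C, labels)
            shift = float(((newC - C) ** 2).sum())
            C = newC
            if stable:
                break
            if shift <= tol * shift_scale:
                # re-synchronise labels and centroids so each centroid is
                # exactly the mean of its members
                C, labels, inertia, _ = lloyd_step(C, labels)
                break
        if best is None or inertia < best[0]:
            best = (inertia, C.copy(), labels.copy(), it, path)
    inertia, C, labels, it, path = best
    return ClusterModel(
        k=k,
        centroids=C,
        labels=labels,
        index=index,
        inertia=inertia,
        seed=seed,
        n_init=n_init,
        n_iter=it,
        inertia_path=path,
    )


# ---------------------------------------------------------------------------
# compartment assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerConfig:
    """Centroid marker scores used to name clusters.

    Cell-vs-background uses a spectral roughness score (mean absolute
    deviation of the centroid from its own Savitzky–Golay smooth): cell
    spectra are peaky, coverslip/PBS background is smooth. Nucleus vs
    cytoplasm uses the nucleic-acid band (786 ± 4 cm^-1 by default). Each
    split is either data-driven (largest gap in the sorted scores; log-gap
    for the roughness score, whose groups differ by orders of magnitude) or
    fixed by an absolute threshold / cluster count.
    """

    nucleic_center: float = 786.0
    nucleic_halfwidth: float = 4.0
    background_method: str = "gap"  # "gap" | "threshold"
    background_threshold: float | None = None
    nucleus_method: str = "gap"  # "gap" | "count"
    n_nucleus: int | None = None
    roughness_order: int = 2
    roughness_frame: int = 99


@dataclass
class CompartmentAssignment:
    mapping: dict[int, str]  # cluster index -> compartment name
    scores: pd.DataFrame  # per-cluster marker scores

    def codes(self) -> np.ndarray:
        """Cluster-index -> compartment-code lookup array."""
        out = np.empty(len(self.mapping), dtype=np.int64)
        for cl, name in self.mapping.items():
            out[cl] = COMPARTMENT_CODES[name]
        return out


def _roughness(centroids: np.ndarray, order: int, frame: int) -> np.ndarray:
    C = centroids.shape[1]
    frame = min(frame, C if C % 2 else C - 1)
    if frame <= order:
        raise ValueError("roughness frame must exceed the polynomial order")
    smooth = savgol_filter(centroids, frame, order, axis=1, mode="interp")
    return np.abs(centroids - smooth).mean(axis=1)


def _largest_gap_split(scores: np.ndarray, log: bool = False) -> np.ndarray:
    """Boolean mask of entries in the upper group of a 1-D largest-gap split."""
    vals = np.log10(scores + 1e-12) if log else scores
    order = np.argsort(vals)
    gaps = np.diff(vals[order])
    cut = int(gaps.argmax())
    upper = np.zeros(scores.size, dtype=bool)
    upper[order[cut + 1:]] = True
    return upper


def assign_compartments(
    model: ClusterModel,
    axis: WavenumberAxis,
    config: MarkerConfig | None = None,
    override: dict[int, str] | None = None,
) -> CompartmentAssignment:
    """Name every cluster nucleus / cytoplasm / background from its centroid.

    Low-signal (smooth) clusters become background; the remaining clusters
    are ranked by nucleic-acid band intensity and the top group becomes
    nucleus, the rest cytoplasm. A manual override map takes precedence.
    Raises if the result classifies every cluster as background.
    """
    cfg = config or MarkerConfig()
    cent = model.centroids
    rough = _roughness(cent, cfg.roughness_order, cfg.roughness_frame)
    band = axis.band_indices(
        cfg.nucleic_center - cfg.nucleic_halfwidth, cfg.nucleic_center + cfg.nucleic_halfwidth
    )
    if band.size == 0:
        raise ValueError("nucleic-acid marker band contains no channels")
    nucleic = cent[:, band].mean(axis=1)

    if cfg.background_method == "threshold":
        if cfg.background_threshold is None:
            raise ValueError("background_method='threshold' needs background_threshold")
        is_cell = rough >= cfg.background_threshold
    elif cfg.background_method == "gap":
        is_cell = _largest_gap_split(rough, log=True) if model.k > 1 else np.ones(1, bool)
    else:
        raise ValueError(f"unknown background_method {cfg.background_method!r}")

    mapping: dict[int, str] = {}
    cell_idx = np.nonzero(is_cell)[0]
    for cl in np.nonzero(~is_cell)[0]:
        mapping[int(cl)] = "background"
    if cell_idx.size == 1:
        mapping[int(cell_idx[0])] = "cytoplasm"
    elif cell_idx.size > 1:
        sub = nucleic[cell_idx]
        if cfg.nucleus_method == "count":
            n_nuc = cfg.n_nucleus if cfg.n_nucleus is not None else max(1, round(cell_idx.size / 3))
            nuc_local = np.argsort(sub)[::-1][:n_nuc]
            is_nuc = np.zeros(cell_idx.size, dtype=bool)
            is_nuc[nuc_local] = True
        elif cfg.nucleus_method == "gap":
            is_nuc = _largest_gap_split(sub)
        else:
            raise ValueError(f"unknown nucleus_method {cfg.nucleus_method!r}")
        for local, cl in enumerate(cell_idx):
            mapping[int(cl)] = "nucleus" if is_nuc[local] else "cytoplasm"

    for cl, name in (override or {}).items():
        if name not in COMPARTMENT_CODES:
            raise ValueError(f"override for cluster {cl}: unknown compartment {name!r}")
        mapping[int(cl)] = name

    if all(name == "background" for name in mapping.values()):
        raise ValueError("degenerate segmentation: every cluster assigned to background")

    scores = pd.DataFrame(
        {
            "roughness": rough,
            "nucleic_786": nucleic,
            "pixels": model.counts(),
            "compartment": [mapping[i] for i in range(model.k)],
        }
    )
    return CompartmentAssignment(mapping=mapping, scores=scores)


def compartment_mask(model: ClusterModel, assignment: CompartmentAssignment, map_id: str) -> np.ndarray:
    """Predicted compartment-code grid for one map."""
    return assignment.codes()[model.labels_for(map_id)]


def pixel_accuracy(
    model: ClusterModel,
    assignment: CompartmentAssignment,
    truth_masks: dict[str, np.ndarray],
) -> float:
    """Fraction of pixels (over all maps) matching the ground-truth masks."""
    good = total = 0
    for map_id, truth in truth_masks.items():
        pred = compartment_mask(model, assignment, map_id)
        good += int((pred == truth).sum())
        total += truth.size
    return good / total


# ---------------------------------------------------------------------------
# per-map compartment spectra, QC, background subtraction
# ---------------------------------------------------------------------------

@dataclass
class CompartmentSpectra:
    """Mean nucleus / cytoplasm / whole-cell / background spectra of one map."""

    map_id: str
    condition: str
    pixel_size: float
    spectra: dict[str, np.ndarray | None]  # compartment name -> mean spectrum
    pixel_counts: dict[str, int]
    corrected: bool = False

    def nucleus_equivalent_diameter(self) -> float:
        """Diameter (um) of a circle with the nucleus pixel area."""
        n_px = self.pixel_counts.get("nucleus", 0)
        return 2.0 * self.pixel_size * np.sqrt(n_px / np.pi)


def extract_compartment_spectra(
    hmap: HyperMap,
    model: ClusterModel,
    assignment: CompartmentAssignment,
) -> CompartmentSpectra:
    """Arithmetic mean spectrum per compartment for one map.

    whole_cell is the mean over the union of nucleus and cytoplasm pixels
    (pixel-count weighting, not the average of the two compartment means).
    Absent compartments get spectrum None and pixel count 0.
    """
    comp_grid = compartment_mask(model, assignment, map_id=hmap.map_id)
    flat = hmap.cube.reshape(hmap.n_pixels, -1).astype(np.float64)
    codes = comp_grid.reshape(-1)
    spectra: dict[str, np.ndarray | None] = {}
    counts: dict[str, int] = {}
    for code, name in ((NUCLEUS, "nucleus"), (CYTOPLASM, "cytoplasm"), (BACKGROUND, "background")):
        sel = codes == code
        counts[name] = int(sel.sum())
        spectra[name] = flat[sel].mean(axis=0) if counts[name] else None
    cell_sel = (codes == NUCLEUS) | (codes == CYTOPLASM)
    counts["whole_cell"] = int(cell_sel.sum())
    spectra["whole_cell"] = flat[cell_sel].mean(axis=0) if counts["whole_cell"] else None
    return CompartmentSpectra(
        map_id=hmap.map_id,
        condition=hmap.condition,
        pixel_size=hmap.pixel_size,
        spectra=spectra,
        pixel_counts=counts,
    )


def qc_filter(
    spectra: list[CompartmentSpectra],
    min_diameter: float = 3.0,
) -> pd.DataFrame:
    """Per-map retain/discard report.

    A map is discarded when it has no nucleus or no cytoplasm pixels
    (``no_compartment_pixels``) or when the nucleus equivalent-circle
    diameter 2·s·sqrt(A_px/pi) is strictly below *min_diameter* um
    (``nucleus_too_small``); diameters at or above the threshold are kept.
    """
    rows = []
    for cs in spectra:
        diam = cs.nucleus_equivalent_diameter()
        if cs.pixel_counts.get("nucleus", 0) == 0 or cs.pixel_counts.get("cytoplasm", 0) == 0:
            reason = "no_compartment_pixels"
        elif diam < min_diameter:
            reason = "nucleus_too_small"
        else:
            reason = "ok"
        rows.append(
            {
                "map_id": cs.map_id,
                "condition": cs.condition,
                "retained": reason == "ok",
                "reason": reason,
                "nucleus_equivalent_diameter_um": diam,
                "nucleus_px": cs.pixel_counts.get("nucleus", 0),
                "cytoplasm_px": cs.pixel_counts.get("cytoplasm", 0),
            }
        )
    return pd.DataFrame(rows)


def subtract_background(
    cs: CompartmentSpectra,
    axis: WavenumberAxis,
    offset_band: tuple[float, float] = (1780.0, 1840.0),
    sg_order: int = 2,
    sg_frame: int = 99,
) -> CompartmentSpectra:
    """Three-step background correction of one map's compartment spectra.

    (1) subtract from every spectrum (nucleus, cytoplasm, whole-cell and
    background) its mean intensity in *offset_band* (clipped to the axis);
    (2) Savitzky–Golay-smooth the offset-corrected background; (3) subtract
    the smoothed background from the three cell spectra. The stored
    background becomes its offset-corrected smooth.
    """
    if cs.corrected:
        raise ValueError(f"map {cs.map_id}: spectra already corrected")
    if sg_frame % 2 == 0 or sg_frame > len(axis) or sg_frame <= sg_order:
        raise ValueError("sg_frame must be odd, > sg_order, and <= the axis length")
    band = axis.band_indices(*offset_band)
    if band.size == 0:
        raise ValueError(f"offset band {offset_band} contains no axis channels")
    if cs.spectra.get("background") is None:
        raise ValueError(f"map {cs.map_id}: no background pixels to subtract")

    def offset(s: np.ndarray) -> np.ndarray:
        return s - s[band].mean()

    bg = savgol_filter(offset(cs.spectra["background"]), sg_frame, sg_order, mode="interp")
    out: dict[str, np.ndarray | None] = {"background": bg}
    for name in ("nucleus", "cytoplasm", "whole_cell"):
        s = cs.spectra.get(name)
        out[name] = offset(s) - bg if s is not None else None
    return replace(cs, spectra=out, corrected=True)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    model: ClusterModel
    assignment: CompartmentAssignment
    raw_spectra: list[CompartmentSpectra]
    corrected_spectra: list[CompartmentSpectra]  # retained maps only
    qc: pd.DataFrame

    def spectra_matrix(self, compartment: str = "nucleus") -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(cells x channels, condition labels, map ids) for retained maps."""
        X, labels, ids = [], [], []
        for cs in self.corrected_spectra:
            s = cs.spectra.get(compartment)
            if s is not None:
                X.append(s)
                labels.append(cs.condition)
                ids.append(cs.map_id)
        return np.asarray(X), np.asarray(labels), ids


def segment_cohort(
    maps: list[HyperMap],
    k: int = 10,
    seed: int = 0,
    n_init: int = 10,
    marker_config: MarkerConfig | None = None,
    override: dict[int, str] | None = None,
    min_nucleus_diameter: float = 3.0,
    offset_band: tuple[float, float] = (1780.0, 1840.0),
    sg_order: int = 2,
    sg_frame: int = 99,
) -> SegmentationResult:
    """Full segmentation stage: pool, cluster, assign, extract, QC, correct."""
    axis = ensure_shared_axis(maps)
    X, index = pool_spectra(maps)
    model = common_kmeans(X, k=k, seed=seed, n_init=n_init, index=index)
    assignment = assign_compartments(model, axis, marker_config, override)
    raw = [extract_compartment_spectra(m, model, assignment) for m in maps]
    qc = qc_filter(raw, min_diameter=min_nucleus_diameter)
    retained = set(qc.loc[qc["retained"], "map_id"])
    corrected = [
        subtract_background(cs, axis, offset_band, sg_order, sg_frame)
        for cs in raw
        if cs.map_id in retained
    ]
    n_discard = len(raw) - len(corrected)
    if n_discard:
        warnings.warn(f"QC discarded {n_discard} of {len(raw)} maps", stacklevel=2)
    return SegmentationResult(
        model=model, assignment=assignment, raw_spectra=raw, corrected_spectra=corrected, qc=qc
    )
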