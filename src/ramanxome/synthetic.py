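"""Synthetic Raman cohorts and matched transcriptomes with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes:

* each map holds one roughly circular cell with a large nucleus, rendered on
  a shared wavenumber axis (default 600–1800 cm^-1 at 1 cm^-1);
* compartment spectra are sums of Gaussian peaks; the nucleus carries the
  nucleic-acid bands at 752 and 786 cm^-1 and immune activation (condition
  ``D4``) multiplies the 786 cm^-1 amplitude by 0.8, the planted condition
  effect the classifier must detect;
* every pixel additionally receives a slowly varying additive baseline and a
  broad coverslip/PBS-like hump in background pixels, so background
  subtraction is non-trivial;
* per-map nuisance variation (baseline scale, overall amplitude, nucleic-acid
  amplitude jitter) emulates focus and biology drift between cells;
* the transcriptome is a negative-binomial count matrix (3 samples per
  condition) in which a designated informative subset has log2-scale means
  affine in the sample's Raman PC-score vector — the planted cross-modal
  link.

Everything is deterministic given a seed; noise_sd = 0 renders are exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    BACKGROUND,
    CYTOPLASM,
    NUCLEUS,
    CountMatrix,
    HyperMap,
    WavenumberAxis,
)

CONDITIONS = ("D0", "D4")

#: default Gaussian peak triples (center cm^-1, FWHM cm^-1, amplitude a.u.)
#: peak positions follow standard cell Raman band assignments (nucleic acids
#: 752/786/1095/1578, phenylalanine 1004, CH2 deformation 1304/1450, amide I
#: 1660); the background is a broad coverslip/PBS hump.
DEFAULT_PEAKS: dict[str, list[tuple[float, float, float]]] = {
    "nucleus": [
        (752.0, 10.0, 0.55),
        (786.0, 10.0, 1.00),
        (1004.0, 8.0, 0.50),
        (1095.0, 14.0, 0.45),
        (1340.0, 16.0, 0.50),
        (1450.0, 18.0, 0.60),
        (1578.0, 12.0, 0.40),
        (1660.0, 20.0, 0.70),
    ],
    "cytoplasm": [
        (752.0, 10.0, 0.35),
        (786.0, 10.0, 0.30),
        (1004.0, 8.0, 0.70),
        (1127.0, 12.0, 0.35),
        (1304.0, 16.0, 0.55),
        (1450.0, 18.0, 0.85),
        (1660.0, 20.0, 0.90),
    ],
    "background": [
        (900.0, 280.0, 0.60),
        (1600.0, 350.0, 0.25),
    ],
}

#: multiplicative condition effects keyed by "<compartment>:<center>".
#: Activation weakens the nucleic-acid 786 cm^-1 band (the headline marker)
#: and mildly remodels cytoplasmic protein/lipid bands, so every compartment
#: carries some condition signal, as in activated B cells.
DEFAULT_CONDITION_EFFECTS: dict[str, dict[str, float]] = {
    "D0": {},
    "D4": {"nucleus:786": 0.8, "cytoplasm:1660": 1.12, "cytoplasm:1304": 1.10},
}

DEFAULT_BASELINE = {
    "offset": 0.15,
    "hump_center": 1150.0,
    "hump_width": 500.0,
    "hump_amplitude": 0.35,
}

#: noise sd giving SNR ~ 10 on the unit-amplitude 786 cm^-1 nucleus peak
DEFAULT_NOISE_SD = 0.1


def peak_key(compartment: str, center: float) -> str:
    return f"{compartment}:{center:g}"


@dataclass(frozen=True)
class Peak:
    center: float  # cm^-1
    width: float  # full width at half maximum, cm^-1
    amplitude: float  # arbitrary intensity units

    def __post_init__(self):
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError(f"peak at {self.center} cm^-1: width and amplitude must be > 0")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-4.0 * np.log(2.0) * (axis - self.center) ** 2 / self.width**2)


@dataclass
class ComponentLibrary:
    """Compartment spectral components, condition effects and baseline."""

    axis: WavenumberAxis
    components: dict[str, list[Peak]]
    condition_effects: dict[str, dict[str, float]]
    baseline: dict[str, float]

    def __post_init__(self):
        lo, hi = self.axis.values[0], self.axis.values[-1]
        for comp, peaks in self.components.items():
            if not peaks:
                raise ValueError(f"compartment {comp!r} has no peaks")
            for p in peaks:
                if not (lo <= p.center <= hi):
                    raise ValueError(
                        f"peak {peak_key(comp, p.center)} lies outside the axis "
                        f"range [{lo:g}, {hi:g}] cm^-1"
                    )
        nuc = {p.center for p in self.components.get("nucleus", [])}
        if not {752.0, 786.0} <= nuc:
            raise ValueError("nucleus component must include the 752 and 786 cm^-1 peaks")
        known = {peak_key(c, p.center) for c, ps in self.components.items() for p in ps}
        for cond, effects in self.condition_effects.items():
            unknown = set(effects) - known
            if unknown:
                raise ValueError(f"condition {cond!r} scales unknown peaks {sorted(unknown)}")

    def component_spectrum(
        self,
        compartment: str,
        condition: str | None = None,
        peak_scales: dict[str, float] | None = None,
    ) -> np.ndarray:
        """Noiseless component spectrum (no baseline) for one compartment."""
        effects = self.condition_effects.get(condition, {}) if condition else {}
        x = self.axis.values
        out = np.zeros_like(x)
        for p in self.components[compartment]:
            key = peak_key(compartment, p.center)
            f = effects.get(key, 1.0)
            if peak_scales:
                f *= peak_scales.get(key, 1.0)
            out += f * p.profile(x)
        return out

    def baseline_spectrum(self, scale: float = 1.0) -> np.ndarray:
        b = self.baseline
        x = self.axis.values
        hump = b["hump_amplitude"] * np.exp(
            -4.0 * np.log(2.0) * (x - b["hump_center"]) ** 2 / b["hump_width"] ** 2
        )
        return scale * (b["offset"] + hump)


def make_component_library(config: dict | None = None) -> ComponentLibrary:
    """Build a component library from an optional config dict.

    Config keys (all optional): ``axis`` ({start, stop, step} or explicit
    list), ``peaks`` (compartment -> list of (center, width, amplitude)),
    ``condition_effects``, ``baseline``.
    """
    config = config or {}
    ax = config.get("axis")
    if ax is None:
        axis = WavenumberAxis.from_range()
    elif isinstance(ax, dict):
        axis = WavenumberAxis.from_range(ax.get("start", 600.0), ax.get("stop", 1800.0), ax.get("step", 1.0))
    else:
        axis = WavenumberAxis(np.asarray(ax, dtype=np.float64))
    peaks_cfg = config.get("peaks", DEFAULT_PEAKS)
    components = {comp: [Peak(*t) for t in triples] for comp, triples in peaks_cfg.items()}
    return ComponentLibrary(
        axis=axis,
        components=components,
        condition_effects=config.get("condition_effects", DEFAULT_CONDITION_EFFECTS),
        baseline=dict(config.get("baseline", DEFAULT_BASELINE)),
    )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """One cell's layout on the pixel grid (all lengths in micrometres)."""

    height: int
    width: int
    pixel_size: float = 0.2
    cell_center: tuple[float, float] = (7.5, 7.5)  # (row, col) in um
    cell_radius: float = 5.0
    nucleus_center: tuple[float, float] = (7.5, 7.5)
    nucleus_radius: float = 3.2
    kidney_notch: tuple[float, float, float] | None = None  # (d_row, d_col, radius)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if min(self.cell_radius, self.nucleus_radius) <= 0:
            raise ValueError("radii must be > 0")
        d = np.hypot(
            self.nucleus_center[0] - self.cell_center[0],
            self.nucleus_center[1] - self.cell_center[1],
        )
        if d + self.nucleus_radius > self.cell_radius + 1e-9:
            raise ValueError("nucleus region must be contained in the cell region")
        extent = (self.height * self.pixel_size, self.width * self.pixel_size)
        for k in (0, 1):
            if self.cell_center[k] - self.cell_radius < -1e-9 or self.cell_center[k] + self.cell_radius > extent[k] + 1e-9:
                raise ValueError("cell region must be contained in the grid")

    def mask(self) -> np.ndarray:
        """Compartment label grid (0 background, 1 cytoplasm, 2 nucleus).

        Pixel (i, j) is sampled at its centre ((i+0.5)·s, (j+0.5)·s); a
        kidney-shaped nucleus is the nucleus disk minus an offset notch disk.
        """
        s = self.pixel_size
        rows = (np.arange(self.height) + 0.5) * s
        cols = (np.arange(self.width) + 0.5) * s
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        d_cell = np.hypot(rr - self.cell_center[0], cc - self.cell_center[1])
        d_nuc = np.hypot(rr - self.nucleus_center[0], cc - self.nucleus_center[1])
        mask = np.full((self.height, self.width), BACKGROUND, dtype=np.int64)
        mask[d_cell <= self.cell_radius] = CYTOPLASM
        in_nucleus = d_nuc <= self.nucleus_radius
        if self.kidney_notch is not None:
            dr, dc, nr = self.kidney_notch
            d_notch = np.hypot(rr - (self.nucleus_center[0] + dr), cc - (self.nucleus_center[1] + dc))
            in_nucleus &= d_notch > nr
        mask[in_nucleus] = NUCLEUS
        return mask

    def true_area_ratio(self) -> float:
        """Nucleus/cell area ratio pi r_n^2 / pi r_c^2 (circular nucleus)."""
        return (self.nucleus_radius / self.cell_radius) ** 2


@dataclass(frozen=True)
class GeometrySampler:
    """Distribution of cell geometries across a cohort."""

    grid: tuple[int, int] = (75, 75)
    pixel_size: float = 0.2
    cell_radius: tuple[float, float] = (4.4, 5.2)
    nucleus_frac: tuple[float, float] = (0.60, 0.68)
    center_jitter: float = 0.4
    kidney_prob: float = 0.0

    @classmethod
    def small(cls) -> "GeometrySampler":
        """Compact 31x31 grids for fast cohorts (same 0.2 um pixel size)."""
        return cls(grid=(31, 31), cell_radius=(2.5, 2.85), nucleus_frac=(0.60, 0.68), center_jitter=0.15)

    def sample(self, rng: np.random.Generator) -> CellGeometry:
        h, w = self.grid
        cr = rng.uniform(*self.cell_radius)
        nr = cr * rng.uniform(*self.nucleus_frac)
        center = (
            h * self.pixel_size / 2 + rng.uniform(-self.center_jitter, self.center_jitter),
            w * self.pixel_size / 2 + rng.uniform(-self.center_jitter, self.center_jitter),
        )
        # nucleus offset, kept strictly inside the cell
        max_off = 0.5 * (cr - nr)
        theta = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0, max_off)
        nucleus_center = (center[0] + off * np.cos(theta), center[1] + off * np.sin(theta))
        notch = None
        if self.kidney_prob > 0 and rng.random() < self.kidney_prob:
            phi = rng.uniform(0, 2 * np.pi)
            notch = (nr * np.cos(phi), nr * np.sin(phi), 0.6 * nr)
        return CellGeometry(
            height=h,
            width=w,
            pixel_size=self.pixel_size,
            cell_center=center,
            cell_radius=cr,
            nucleus_center=nucleus_center,
            nucleus_radius=nr,
            kidney_notch=notch,
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth for a simulated cohort (and, once added, transcriptome)."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    conditions: dict[str, str] = field(default_factory=dict)
    geometries: dict[str, CellGeometry] = field(default_factory=dict)
    noise_sd: float = 0.0
    informative_ids: list[str] = field(default_factory=list)
    B_true: pd.DataFrame | None = None  # informative transcripts x PC columns
    dispersion: float | None = None


def render_cell_map(
    geometry: CellGeometry,
    library: ComponentLibrary,
    condition: str,
    noise_sd: float,
    seed: int,
    *,
    baseline_scale: float = 1.0,
    peak_scales: dict[str, float] | None = None,
    map_id: str = "map",
) -> tuple[HyperMap, np.ndarray]:
    """Render one map: per-pixel spectrum = compartment component (with
    condition effects) + baseline + iid Gaussian noise of sd *noise_sd*."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if condition not in library.condition_effects:
        raise ValueError(f"unknown condition {condition!r}")
    mask = geometry.mask()
    base = library.baseline_spectrum(baseline_scale)
    comp = np.stack(
        [
            library.component_spectrum(name, condition, peak_scales) + base
            for name in ("background", "cytoplasm", "nucleus")
        ]
    ).astype(np.float32)
    cube = comp[mask]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cube = cube + rng.normal(0.0, noise_sd, cube.shape).astype(np.float32)
    hmap = HyperMap(
        map_id=map_id,
        condition=condition,
        pixel_size=geometry.pixel_size,
        cube=cube,
        axis=library.axis,
    )
    return hmap, mask


def simulate_cohort(
    n_d0: int,
    n_d4: int,
    sampler: GeometrySampler | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    library: ComponentLibrary | None = None,
    *,
    baseline_scale_sd: float = 0.03,
    amp_jitter_sd: float = 0.05,
    marker_jitter_sd: float = 0.05,
) -> tuple[list[HyperMap], SyntheticTruth]:
    """Simulate a two-condition cohort of single-cell maps.

    Per-map nuisance variation: baseline scale ~ N(1, baseline_scale_sd),
    a global lognormal amplitude factor (sd amp_jitter_sd) on all cell peaks
    (focus/confluency drift), and an extra lognormal factor (sd
    marker_jitter_sd) on the nucleus 786 cm^-1 band (biological spread of the
    activation marker).
    """
    if n_d0 < 1 or n_d4 < 1:
        raise ValueError("need at least one map per condition")
    sampler = sampler or GeometrySampler()
    library = library or make_component_library()
    rng = np.random.default_rng(seed)
    cell_keys = [
        peak_key(comp, p.center)
        for comp in ("nucleus", "cytoplasm")
        for p in library.components[comp]
    ]
    maps: list[HyperMap] = []
    truth = SyntheticTruth(noise_sd=noise_sd)
    plan = [("D0", i) for i in range(n_d0)] + [("D4", i) for i in range(n_d4)]
    for cond, i in plan:
        map_id = f"{cond}-{i:03d}"
        geom = sampler.sample(rng)
        bscale = 1.0 + rng.normal(0.0, baseline_scale_sd)
        g = float(np.exp(rng.normal(0.0, amp_jitter_sd)))
        scales = {k: g for k in cell_keys}
        scales["nucleus:786"] = g * float(np.exp(rng.normal(0.0, marker_jitter_sd)))
        child_seed = int(rng.integers(2**31))
        hmap, mask = render_cell_map(
            geom,
            library,
            cond,
            noise_sd,
            child_seed,
            baseline_scale=bscale,
            peak_scales=scales,
            map_id=map_id,
        )
        maps.append(hmap)
        truth.masks[map_id] = mask
        truth.conditions[map_id] = cond
        truth.geometries[map_id] = geom
    return maps, truth


def simulate_cell_spectra(
    n_d0: int,
    n_d4: int,
    noise_sd: float,
    seed: int = 0,
    library: ComponentLibrary | None = None,
    compartment: str = "nucleus",
    *,
    amp_jitter_sd: float = 0.05,
    marker_jitter_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly simulate per-cell background-corrected compartment mean
    spectra (bypassing map rendering and segmentation).

    Cell-level noise here plays the role of the residual noise on a
    compartment mean plus unmodelled cell-to-cell variation; used for fast
    classifier characterisation such as SNR sweeps.
    """
    library = library or make_component_library()
    rng = np.random.default_rng(seed)
    labels = np.array(["D0"] * n_d0 + ["D4"] * n_d4)
    keys = [peak_key(compartment, p.center) for p in library.components[compartment]]
    spectra = np.empty((labels.size, len(library.axis)))
    for i, cond in enumerate(labels):
        g = float(np.exp(rng.normal(0.0, amp_jitter_sd)))
        scales = {k: g for k in keys}
        mkey = peak_key(compartment, 786.0)
        if mkey in scales:
            scales[mkey] = g * float(np.exp(rng.normal(0.0, marker_jitter_sd)))
        s = library.component_spectrum(compartment, cond, scales)
        spectra[i] = s + rng.normal(0.0, noise_sd, s.size)
    return spectra, labels


# ---------------------------------------------------------------------------
# planted PC scores and transcriptome
# ---------------------------------------------------------------------------

def planted_cell_scores(
    n_d0: int,
    n_d4: int,
    n_pc: int = 9,
    separation: float = 2.0,
    secondary_sd: float = 0.8,
    jitter_sd: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell PC-score vectors lying exactly in a rank-2 subspace.

    Latent state u = (activation axis: ±separation + jitter, secondary axis:
    N(0, secondary_sd)) mapped into n_pc dimensions by a fixed loading
    matrix. Because every cell lives in the same 2-D subspace, any group
    means derived from these scores are rank-2 as well — the regime in which
    a noiseless linear cross-modal link is exactly recoverable.
    """
    rng = np.random.default_rng(seed)
    labels = np.array(["D0"] * n_d0 + ["D4"] * n_d4)
    sign = np.where(labels == "D0", 1.0, -1.0)
    u = np.column_stack(
        [
            sign * separation + rng.normal(0.0, jitter_sd, labels.size),
            rng.normal(0.0, secondary_sd, labels.size),
        ]
    )
    L = np.zeros((n_pc, 2))
    l0 = np.array([1.0, 0.0, 0.4, 0.25, 0.1, 0.0, 0.0, 0.0, 0.0])
    l1 = np.array([0.0, 1.0, 0.2, 0.0, 0.3, 0.1, 0.0, 0.0, 0.0])
    L[:, 0] = l0[:n_pc] if n_pc <= 9 else np.pad(l0, (0, n_pc - 9))
    L[:, 1] = l1[:n_pc] if n_pc <= 9 else np.pad(l1, (0, n_pc - 9))
    return u @ L.T, labels


def _as_target_frame(raman_pc_targets, sample_ids=None, conditions=None) -> tuple[pd.DataFrame, dict[str, str]]:
    if isinstance(raman_pc_targets, pd.DataFrame):
        targets = raman_pc_targets.copy()
    else:
        arr = np.asarray(raman_pc_targets, dtype=np.float64)
        if sample_ids is None:
            if arr.shape[0] % 2:
                raise ValueError("sample_ids required for an odd number of samples")
            half = arr.shape[0] // 2
            sample_ids = [f"D0-{i+1}" for i in range(half)] + [f"D4-{i+1}" for i in range(half)]
        targets = pd.DataFrame(arr, index=sample_ids)
    if conditions is None:
        conditions = {s: str(s).rsplit("-", 1)[0] for s in targets.index}
    return targets, dict(conditions)


def linked_log_means(
    n_transcripts: int,
    n_informative: int,
    raman_pc_targets,
    seed: int = 0,
    *,
    sample_ids=None,
    base_range: tuple[float, float] = (3.0, 9.0),
    effect_scale: tuple[float, float] = (0.8, 1.8),
    secondary_effect_sd: float = 0.1,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Planted log2-scale expression means, affine in the sample PC vector.

    Target PC columns are standardised across samples before the planted
    coefficients apply, so effect sizes are expressed per standard deviation
    of each Raman axis regardless of the score units. Informative transcripts
    get a main coefficient of magnitude U(effect_scale) (random sign) on the
    first (activation) axis and small N(0, secondary_effect_sd) coefficients
    on the remaining axes; all other transcripts are condition-independent.

    Returns (mu: transcripts x samples log2 means, informative ids,
    B_true: informative x PC-axis planted coefficients).
    """
    if n_informative > n_transcripts:
        raise ValueError("n_informative cannot exceed n_transcripts")
    targets, _ = _as_target_frame(raman_pc_targets, sample_ids)
    Z = targets.to_numpy(dtype=np.float64)
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd_safe = np.where(sd > 1e-12, sd, 1.0)
    Z = (Z - mean) / sd_safe
    Z[:, sd <= 1e-12] = 0.0

    rng = np.random.default_rng(seed)
    width = len(str(n_transcripts))
    ids = [f"T{i:0{width}d}" for i in range(1, n_transcripts + 1)]
    base = rng.uniform(*base_range, n_transcripts)
    informative_idx = np.sort(rng.choice(n_transcripts, size=n_informative, replace=False))
    B = np.zeros((n_informative, Z.shape[1]))
    B[:, 0] = rng.uniform(*effect_scale, n_informative) * rng.choice([-1.0, 1.0], n_informative)
    if Z.shape[1] > 1:
        B[:, 1:] = rng.normal(0.0, secondary_effect_sd, (n_informative, Z.shape[1] - 1))
    mu = np.tile(base[:, None], (1, Z.shape[0]))
    mu[informative_idx] += B @ Z.T
    informative_ids = [ids[i] for i in informative_idx]
    mu_df = pd.DataFrame(mu, index=ids, columns=targets.index)
    B_df = pd.DataFrame(B, index=informative_ids, columns=targets.columns)
    return mu_df, informative_ids, B_df


def simulate_transcriptome(
    n_transcripts: int,
    n_informative: int,
    raman_pc_targets,
    dispersion: float = 0.05,
    seed: int = 0,
    *,
    sample_ids=None,
    conditions: dict[str, str] | None = None,
    base_range: tuple[float, float] = (3.0, 9.0),
    effect_scale: tuple[float, float] = (0.8, 1.8),
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a count matrix linked to per-sample Raman PC-score vectors.

    Counts are negative binomial around mean 2^mu − 1 with a common
    dispersion (var = m + dispersion·m²); dispersion = 0 yields the rounded
    means deterministically. Each sample's counts come from a substream keyed
    by the sample id, so permuting sample order permutes columns only.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    targets, cond_map = _as_target_frame(raman_pc_targets, sample_ids, conditions)
    mu, informative_ids, B_df = linked_log_means(
        n_transcripts,
        n_informative,
        targets,
        seed,
        base_range=base_range,
        effect_scale=effect_scale,
    )
    m = np.maximum(2.0**mu.to_numpy() - 1.0, 0.0)
    counts = np.empty_like(m, dtype=np.int64)
    for j, sid in enumerate(targets.index):
        if dispersion == 0:
            counts[:, j] = np.round(m[:, j]).astype(np.int64)
        else:
            sub = np.random.default_rng(
                np.random.SeedSequence([seed, zlib.crc32(str(sid).encode())])
            )
            r = 1.0 / dispersion
            p = r / (r + m[:, j])
            counts[:, j] = sub.negative_binomial(r, p)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=mu.index, columns=targets.index),
        conditions=cond_map,
    )
    truth = SyntheticTruth(
        informative_ids=informative_ids,
        B_true=B_df,
        dispersion=dispersion,
    )
    return cm, truth


def add_transcriptome_truth(truth: SyntheticTruth, tx_truth: SyntheticTruth) -> SyntheticTruth:
    """Merge transcriptome ground truth into a cohort's truth record."""
    return replace(
        truth,
        informative_ids=tx_truth.informative_ids,
        B_true=tx_truth.B_true,
        dispersion=tx_truth.dispersion,
    )
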