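"""Containers and file formats for hyperspectral cohorts, masks and counts.

Cohort container (version 1)
----------------------------
A cohort is a directory::

    cohort/
        manifest.yaml        # version, format, pixel size, per-map metadata
        axis.tsv             # one wavenumber (cm^-1) per line, shared by all maps
        maps/<map_id>.npz    # cube: float32 (height, width, channels)   [format=npz]
        maps/<map_id>.tsv    # height*width rows x channels, row-major   [format=tsv]
        masks/<map_id>.txt   # optional integer label grid (0 bg, 1 cyto, 2 nucleus)

``npz`` is the default (compact, lossless); ``tsv`` is a plain-text fallback
that is exactly round-trippable for float32 cubes (written with %.9g).

Counts are a tab-separated table: ``transcript_id`` column followed by one
integer column per sample; sample conditions come from a config/sidecar
mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CONTAINER_VERSION = 1

#: compartment label codes shared by masks, truth and segmentation output
BACKGROUND, CYTOPLASM, NUCLEUS = 0, 1, 2
COMPARTMENT_NAMES = {BACKGROUND: "background", CYTOPLASM: "cytoplasm", NUCLEUS: "nucleus"}
COMPARTMENT_CODES = {v: k for k, v in COMPARTMENT_NAMES.items()}


class FormatError(ValueError):
    """Raised when a file does not conform to a documented container format."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Shared spectral axis in cm^-1, strictly increasing.

    The minimum length of 100 guarantees the axis can accommodate the
    99-channel Savitzky–Golay frame used in background subtraction.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 100:
            raise ValueError(f"axis must be 1-D with >= 100 channels, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("axis contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise ValueError("axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(self.values, other.values)

    def __hash__(self):
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    @classmethod
    def from_range(cls, start: float = 600.0, stop: float = 1800.0, step: float = 1.0) -> "WavenumberAxis":
        return cls(np.arange(start, stop + 0.5 * step, step, dtype=np.float64))

    def band_indices(self, low: float, high: float) -> np.ndarray:
        """Channel indices with low <= wavenumber <= high (band clipped to axis)."""
        idx = np.nonzero((self.values >= low) & (self.values <= high))[0]
        return idx


@dataclass
class HyperMap:
    """One cell's Raman map: (height, width, channels) intensity cube."""

    map_id: str
    condition: str
    pixel_size: float  # micrometres per pixel
    cube: np.ndarray  # float32 (height, width, channels)
    axis: WavenumberAxis

    def __post_init__(self):
        self.cube = np.asarray(self.cube, dtype=np.float32)
        if self.cube.ndim != 3:
            raise ValueError("cube must be 3-D (height, width, channels)")
        if self.cube.shape[2] != len(self.axis):
            raise FormatError(
                f"map {self.map_id}: cube has {self.cube.shape[2]} channels "
                f"but axis has {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.cube)):
            raise ValueError(f"map {self.map_id}: cube contains non-finite intensities")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def height(self) -> int:
        return self.cube.shape[0]

    @property
    def width(self) -> int:
        return self.cube.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.cube.shape[0] * self.cube.shape[1]


@dataclass
class CountMatrix:
    """Transcript read counts: non-negative integers, transcripts x samples."""

    counts: pd.DataFrame  # index = transcript ids, columns = sample ids
    conditions: dict[str, str] = field(default_factory=dict)  # sample id -> condition

    def __post_init__(self):
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate transcript ids: {dups[:5]}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError("counts must be integer")
        if (vals < 0).any():
            raise FormatError("counts must be non-negative")
        if self.conditions:
            missing = [s for s in c.columns if s not in self.conditions]
            if missing:
                raise ValueError(f"samples without condition labels: {missing}")
            per = pd.Series({s: self.conditions[s] for s in c.columns}).value_counts()
            if (per < 2).any():
                raise ValueError("each condition needs >= 2 samples")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def ensure_shared_axis(maps: list[HyperMap]) -> WavenumberAxis:
    """Return the common axis of *maps*, refusing mixed axes."""
    if not maps:
        raise ValueError("empty map list")
    axis = maps[0].axis
    for m in maps[1:]:
        if m.axis != axis:
            raise FormatError(f"map {m.map_id} is on a different wavenumber axis; cannot pool")
    return axis


# ---------------------------------------------------------------------------
# single-map files
# ---------------------------------------------------------------------------

def write_hypermap(hmap: HyperMap, path: str | Path, fmt: str | None = None) -> Path:
    """Write one map to *path* (.npz binary or .tsv delimited, by extension)."""
    path = Path(path)
    fmt = fmt or (path.suffix.lstrip(".") or "npz")
    meta = {
        "version": CONTAINER_VERSION,
        "map_id": hmap.map_id,
        "condition": hmap.condition,
        "height": hmap.height,
        "width": hmap.width,
        "pixel_size": hmap.pixel_size,
    }
    if fmt == "npz":
        np.savez_compressed(path, cube=hmap.cube, axis=hmap.axis.values, meta=json.dumps(meta))
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# ramanxome-hypermap v{CONTAINER_VERSION}\n")
            fh.write("# " + json.dumps(meta) + "\n")
            fh.write("\t".join(f"{v:.9g}" for v in hmap.axis.values) + "\n")
            flat = hmap.cube.reshape(hmap.n_pixels, -1)
            np.savetxt(fh, flat, fmt="%.9g", delimiter="\t")
    else:
        raise ValueError(f"unknown hypermap format {fmt!r}")
    return path


def read_hypermap(path: str | Path) -> HyperMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            meta = json.loads(str(z["meta"]))
            _check_version(meta, path)
            cube = z["cube"]
            axis = WavenumberAxis(z["axis"])
    elif path.suffix == ".tsv":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# ramanxome-hypermap"):
                raise FormatError(f"{path}: not a hypermap TSV")
            meta = json.loads(fh.readline().lstrip("# "))
            _check_version(meta, path)
            axis = WavenumberAxis(np.fromstring(fh.readline(), sep="\t"))
            flat = np.loadtxt(fh, delimiter="\t", ndmin=2, dtype=np.float64)
        n_expected = meta["height"] * meta["width"]
        if flat.shape[0] != n_expected:
            raise FormatError(
                f"{path}: header declares {meta['height']}x{meta['width']} pixels "
                f"but file has {flat.shape[0]} rows"
            )
        if flat.shape[1] != len(axis):
            raise FormatError(f"{path}: {flat.shape[1]} channels but axis has {len(axis)}")
        cube = flat.astype(np.float32).reshape(meta["height"], meta["width"], -1)
    else:
        raise ValueError(f"unknown hypermap extension {path.suffix!r}")
    if cube.shape[:2] != (meta["height"], meta["width"]):
        raise FormatError(f"{path}: cube shape {cube.shape[:2]} != declared "
                          f"({meta['height']}, {meta['width']})")
    return HyperMap(
        map_id=meta["map_id"],
        condition=meta["condition"],
        pixel_size=meta["pixel_size"],
        cube=cube,
        axis=axis,
    )


def _check_version(meta: dict, path: Path) -> None:
    if meta.get("version") != CONTAINER_VERSION:
        raise FormatError(f"{path}: unsupported container version {meta.get('version')!r}")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be a 2-D integer grid")
    np.savetxt(path, mask, fmt="%d", delimiter="\t")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    mask = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
    bad = set(np.unique(mask)) - set(COMPARTMENT_NAMES)
    if bad:
        raise FormatError(f"{path}: unknown mask labels {sorted(bad)}")
    return mask


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def write_cohort(
    maps: list[HyperMap],
    path: str | Path,
    masks: dict[str, np.ndarray] | None = None,
    fmt: str = "npz",
    seed: int | None = None,
) -> Path:
    """Write a cohort directory (manifest + axis + per-map files [+ masks])."""
    path = Path(path)
    axis = ensure_shared_axis(maps)
    (path / "maps").mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "axis.tsv", axis.values, fmt="%.9g")
    entries = []
    for m in maps:
        fname = f"maps/{m.map_id}.{fmt}"
        write_hypermap(m, path / fname, fmt=fmt)
        entry = {
            "map_id": m.map_id,
            "condition": m.condition,
            "height": m.height,
            "width": m.width,
            "pixel_size": float(m.pixel_size),
            "file": fname,
        }
        if masks and m.map_id in masks:
            (path / "masks").mkdir(exist_ok=True)
            mname = f"masks/{m.map_id}.txt"
            write_mask(masks[m.map_id], path / mname)
            entry["mask_file"] = mname
        entries.append(entry)
    manifest = {
        "version": CONTAINER_VERSION,
        "format": fmt,
        "n_maps": len(maps),
        "seed": seed,
        "maps": entries,
    }
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_cohort(path: str | Path) -> tuple[list[HyperMap], dict[str, np.ndarray], dict]:
    """Read a cohort directory; returns (maps, masks, manifest)."""
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    _check_version(manifest, path / "manifest.yaml")
    axis = WavenumberAxis(np.loadtxt(path / "axis.tsv", dtype=np.float64))
    maps, masks = [], {}
    for entry in manifest["maps"]:
        m = read_hypermap(path / entry["file"])
        if m.axis != axis:
            raise FormatError(f"{entry['file']}: map axis differs from cohort axis")
        if (m.map_id, m.condition) != (entry["map_id"], entry["condition"]):
            raise FormatError(f"{entry['file']}: metadata disagrees with manifest")
        maps.append(m)
        if "mask_file" in entry:
            mask = read_mask(path / entry["mask_file"])
            if mask.shape != (m.height, m.width):
                raise FormatError(f"{entry['mask_file']}: mask shape {mask.shape} != map grid")
            masks[m.map_id] = mask
    return maps, masks, manifest


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, conditions: dict[str, str] | None = None) -> CountMatrix:
    """Read a transcript count TSV (transcript_id + one integer column/sample).

    Rejects duplicate transcript ids and negative or non-numeric counts,
    reporting the 1-based data row of the first offender. Row order is
    preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no sample columns")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise FormatError(f"{path}: non-integer count in column {col!r}, data row {row}")
        neg = numeric < 0
        if neg.any():
            row = int(np.nonzero(neg.to_numpy())[0][0]) + 1
            raise FormatError(f"{path}: negative count in column {col!r}, data row {row}")
        df[col] = numeric.astype(np.int64)
    if df.index.duplicated().any():
        row = int(np.nonzero(df.index.duplicated())[0][0]) + 1
        raise FormatError(f"{path}: duplicate transcript id at data row {row}")
    return CountMatrix(counts=df, conditions=dict(conditions or {}))


def write_counts(cm: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    cm.counts.to_csv(path, sep="\t", index_label="transcript_id")
    return path
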