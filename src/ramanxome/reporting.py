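"""Run manifests and the assembled pipeline report.

Every pipeline stage writes plain TSV/JSON artifacts into a run directory
under conventional names; ``build_report`` assembles whatever is present
into a single static HTML document (QC table, per-PC tests, LOO confusion,
predicted-vs-cell score scatter, top VIP transcripts). The report body is
deterministic for identical inputs — timestamps live only in the manifest —
and report generation never mutates stage outputs.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

#: stage -> artifact files the report knows how to render
STAGE_ARTIFACTS = {
    "segment": ["qc_report.tsv", "assignment.tsv", "centroids.tsv"],
    "classify": ["scores.tsv", "pc_tests.tsv", "confusion.json", "ld_loading.tsv", "ld_model.json"],
    "crossmodal": ["predictions.tsv", "vip_top.tsv", "crossmodal_summary.json"],
}

REPORT_NAME = "report.html"


@dataclass
class RunManifest:
    """Record of a pipeline run: config hash, seeds, per-stage outputs."""

    config_hash: str = ""
    seeds: dict[str, int] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    stages: dict[str, list[str]] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def hash_config(config: dict) -> str:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def record_stage(self, stage: str, outputs: list[str]) -> None:
        self.stages[stage] = list(outputs)
        self.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def save(self, run_dir: str | Path) -> Path:
        path = Path(run_dir) / "run_manifest.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "config_hash": self.config_hash,
                    "seeds": self.seeds,
                    "inputs": self.inputs,
                    "stages": self.stages,
                    "timestamps": self.timestamps,
                },
                fh,
                sort_keys=False,
            )
        return path

    @classmethod
    def load(cls, run_dir: str | Path) -> "RunManifest":
        path = Path(run_dir) / "run_manifest.yaml"
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            config_hash=data.get("config_hash", ""),
            seeds=data.get("seeds", {}),
            inputs=data.get("inputs", {}),
            stages=data.get("stages", {}),
            timestamps=data.get("timestamps", {}),
        )

    def verify_outputs(self, run_dir: str | Path) -> list[str]:
        """Return the referenced output files that are missing on disk."""
        run_dir = Path(run_dir)
        return [
            f for outputs in self.stages.values() for f in outputs if not (run_dir / f).exists()
        ]


def _table(df: pd.DataFrame, max_rows: int = 30) -> str:
    shown = df.head(max_rows)
    note = f"<p>({len(df)} rows, first {max_rows} shown)</p>" if len(df) > max_rows else ""
    return shown.to_html(index=False, float_format=lambda v: f"{v:.4g}", border=0) + note


def _scatter_svg(run_dir: Path) -> str | None:
    """Predicted pseudo-replicate scores over the single-cell score cloud."""
    scores_p = run_dir / "scores.tsv"
    preds_p = run_dir / "predictions.tsv"
    if not (scores_p.exists() and preds_p.exists()):
        return None
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    # deterministic SVG: fixed hash salt and no embedded date
    plt.rcParams["svg.hashsalt"] = "ramanxome"

    scores = pd.read_csv(scores_p, sep="\t")
    preds = pd.read_csv(preds_p, sep="\t")
    if not {"PC1", "PC2"} <= set(scores.columns) & set(preds.columns):
        return None
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, marker in (("D0", "o"), ("D4", "s")):
        sub = scores[scores["condition"] == cond]
        ax.scatter(sub["PC1"], sub["PC2"], s=12, alpha=0.5, marker=marker, label=f"cells {cond}")
    for cond, color in (("D0", "tab:blue"), ("D4", "tab:red")):
        sub = preds[preds["condition"] == cond]
        ax.scatter(sub["PC1"], sub["PC2"], s=90, marker="*", color=color,
                   edgecolor="k", label=f"predicted {cond}")
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    ax.legend(fontsize=7)
    fig.tight_layout()
    buf = _io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def build_report(run_dir: str | Path, strict: bool = False) -> Path:
    """Assemble the run's artifacts into ``report.html``.

    Missing stage outputs yield a section marked absent; with
    ``strict=True`` they raise instead.
    """
    run_dir = Path(run_dir)
    parts: list[str] = ["<html><head><title>ramanxome run report</title></head><body>"]
    parts.append("<h1>ramanxome run report</h1>")

    any_stage = False

    def section(title: str, fname: str, render) -> None:
        nonlocal any_stage
        parts.append(f"<h2>{title}</h2>")
        path = run_dir / fname
        if path.exists():
            any_stage = True
            parts.append(render(path))
        elif strict:
            raise FileNotFoundError(f"missing stage output: {path}")
        else:
            parts.append(f"<p><em>absent</em> ({fname} not found)</p>")

    section("Segmentation QC", "qc_report.tsv",
            lambda p: _table(pd.read_csv(p, sep="\t")))
    section("Per-PC score tests", "pc_tests.tsv",
            lambda p: _table(pd.read_csv(p, sep="\t")))
    section("Leave-one-out confusion", "confusion.json",
            lambda p: "<pre>" + json.dumps(json.loads(p.read_text()), indent=2, sort_keys=True) + "</pre>")

    parts.append("<h2>Predicted vs single-cell scores</h2>")
    svg = _scatter_svg(run_dir)
    if svg is not None:
        any_stage = True
        parts.append(svg)
    elif strict:
        raise FileNotFoundError("missing scores.tsv/predictions.tsv for the scatter section")
    else:
        parts.append("<p><em>absent</em> (scores.tsv / predictions.tsv not found)</p>")

    section("Top VIP transcripts", "vip_top.tsv",
            lambda p: _table(pd.read_csv(p, sep="\t")))

    if not any_stage:
        raise FileNotFoundError(f"no stage outputs found in {run_dir}")
    parts.append("</body></html>")
    out = run_dir / REPORT_NAME
    out.write_text("\n".join(parts))
    return out
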