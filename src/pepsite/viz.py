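"""Fragment maps, waterfall plots and run summaries.

SVG is the default output (deterministic text, diffable); every rendered
data series is exported alongside the image as TSV so plotted values stay
machine-checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .core import PeptideMapping  # noqa: E402
from .grouped import PointRecord, ScoreTrack  # noqa: E402

plt.rcParams["svg.hashsalt"] = "pepsite"


@dataclass
class PlotSpec:
    """Options shared by the two protein-level plots."""

    protein: str
    length: int
    annotations: Sequence[tuple[int, int, str]] = field(default_factory=tuple)
    fmt: str = "svg"
    cmap: str = "coolwarm"

    def __post_init__(self) -> None:
        for start, end, _ in self.annotations:
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"annotation [{start},{end}] outside [1,{self.length}]"
                )


def _save(fig, path: Path) -> None:
    fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)


def _assign_lanes(spans: Sequence[tuple[int, int]]) -> list[int]:
    """Greedy non-overlapping lane assignment, deterministic order."""
    lanes_end: list[int] = []
    out = []
    for s, e in spans:
        for lane, end in enumerate(lanes_end):
            if s > end:
                lanes_end[lane] = e
                out.append(lane)
                break
        else:
            lanes_end.append(e)
            out.append(len(lanes_end) - 1)
    return out


def plot_fragment_map(
    peptides: Sequence[tuple[PeptideMapping, float]],
    spec: PlotSpec,
    out_path: str | Path,
) -> Path:
    """Differential peptides as stacked spans coloured by log2 fold change."""
    out_path = Path(out_path)
    ordered = sorted(peptides, key=lambda p: (p[0].start, p[0].end, p[0].peptide))
    spans = [(m.start, m.end) for m, _ in ordered]
    lanes = _assign_lanes(spans)
    log2fc = [float(np.sign(fc) * np.log2(max(abs(fc), 1.0))) for _, fc in ordered]

    fig, ax = plt.subplots(figsize=(10, 2 + 0.18 * (max(lanes) + 1 if lanes else 1)))
    if ordered:
        vmax = max(1.0, max(abs(v) for v in log2fc))
        cmap = plt.get_cmap(spec.cmap)
        for (m, _), lane, val in zip(ordered, lanes, log2fc):
            ax.plot(
                [m.start, m.end], [lane, lane],
                lw=3, solid_capstyle="butt",
                color=cmap(0.5 + val / (2 * vmax)),
            )
    ax.set_xlim(0, spec.length + 1)
    ax.set_ylim(-1, (max(lanes) + 1) if lanes else 1)
    ax.set_xlabel("aa position")
    ax.set_yticks([])
    ax.set_title(f"{spec.protein} differential fragments")
    _save(fig, out_path)

    series = pd.DataFrame(
        {
            "peptide": [m.peptide for m, _ in ordered],
            "start": [m.start for m, _ in ordered],
            "end": [m.end for m, _ in ordered],
            "signed_fc": [fc for _, fc in ordered],
            "log2_fc": log2fc,
            "lane": lanes,
        }
    )
    series.to_csv(out_path.with_suffix(".tsv"), sep="\t", index=False)
    return out_path


def plot_waterfall(
    track: ScoreTrack,
    points: Sequence[PointRecord],
    spec: PlotSpec,
    out_path: str | Path,
) -> Path:
    """Cumulative aa-score curve with transition points marked."""
    out_path = Path(out_path)
    bonds = np.arange(track.length + 1)
    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.step(bonds, track.scores, where="post", lw=1.2, color="0.2")
    ax.axhline(0, color="0.7", lw=0.6)
    marked = [rec for rec in points if rec.is_transition]
    for rec in marked:
        b = rec.label.terminal_bond
        ax.plot([b], [track.scores[b]], marker="v" if rec.step < 0 else "^",
                ms=5, color="firebrick" if rec.step > 0 else "steelblue")
    for start, end, label in spec.annotations:
        ax.axvspan(start - 1, end, ymin=0.0, ymax=0.04, color="goldenrod", alpha=0.6)
        ax.text((start + end) / 2, ax.get_ylim()[0], label, fontsize=6,
                ha="center", va="bottom")
    ax.set_xlabel("peptide bond position")
    ax.set_ylabel("grouped aa-score")
    ax.set_title(f"{spec.protein} waterfall ({track.comparison})")
    _save(fig, out_path)

    pd.DataFrame({"bond": bonds, "score": track.scores, "n": track.counts}).to_csv(
        out_path.with_suffix(".tsv"), sep="\t", index=False
    )
    return out_path


def report_summary(
    n_peptides_input: int,
    n_peptides_kept: int,
    results: Mapping[str, pd.DataFrame],
    catalog: pd.DataFrame,
    important: Sequence,
    candidates: Sequence[str] = (),
    out_path: str | Path | None = None,
) -> dict:
    """Counts at every stage, identical to the table outputs."""
    summary = {
        "peptides_input": int(n_peptides_input),
        "peptides_kept": int(n_peptides_kept),
        "differential": {
            comp: int((res["call"].isin(["up", "down"])).sum())
            for comp, res in sorted(results.items())
        },
        "points": {
            "total": int(len(catalog)),
            "stable": int((catalog["class"] == "stable").sum()) if len(catalog) else 0,
            "dynamic": int((catalog["class"] == "dynamic").sum()) if len(catalog) else 0,
            "transition": int(catalog["transition"].sum()) if len(catalog) else 0,
        },
        "important_positions": len(important),
        "candidates": sorted(candidates),
    }
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary
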