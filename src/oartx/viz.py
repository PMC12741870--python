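"""Longitudinal and distributional figures, each backed by a tabular series.

Every visual element is driven by a named table inside a
:class:`FigureSpec`; rendering is a pure function of the spec, so tests
assert on the exported series and regenerated images are bit-stable for
identical specs.  Images are written as PNG or SVG; a CSV of the plotted
series is written next to each image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dvh import ObjectiveSpec, band, objective_series, paired_differences, structure_dvh
from .errors import ConfigurationError, DomainError
from .plans import ADAPTIVE, SCHEDULED
from .structures import volume_trend

if TYPE_CHECKING:  # pragma: no cover
    from .plans import CourseRecord


@dataclass
class FigureSpec:
    """Renderable figure description: kind + the tables behind every element."""

    kind: str  # volume_trend | dvh_spread | objective_distribution
    series: dict[str, pd.DataFrame] = field(default_factory=dict)
    style: dict = field(default_factory=dict)

    def export_series(self, path_stem) -> list[Path]:
        """Write each series as ``<stem>.<name>.csv``; returns the paths."""
        out = []
        for name, df in self.series.items():
            p = Path(f"{path_stem}.{name}.csv")
            df.to_csv(p, index=False)
            out.append(p)
        return out


def plot_volume_trend(
    course: "CourseRecord", structure: str, mode: str = "relative"
) -> FigureSpec:
    """Per-fraction volume trajectory, color-coded adapted vs scheduled.

    ``mode="relative"`` plots the delta versus the reference volume (the
    baseline sits at 0% on fraction 0); ``"absolute"`` plots cm^3 with the
    baseline at the reference volume.
    """
    if mode not in ("relative", "absolute"):
        raise DomainError(f"unknown mode {mode!r}")
    df = volume_trend(course, structure)
    if df.empty:
        available = sorted(
            {s.name for d in course.documents.values() for s in d.structures}
        )
        raise ConfigurationError(
            f"no delivered-session data for structure {structure!r}; "
            f"available structures: {', '.join(available)}"
        )
    ref_entry = course.reference.structure(structure) if course.reference else None
    baseline = 0.0 if mode == "relative" else (ref_entry.volume_cm3 if ref_entry else np.nan)
    ycol = "delta_rel" if mode == "relative" else "volume_cm3"
    series = df[["fraction", ycol, "adapted"]].rename(columns={ycol: "value"})
    return FigureSpec(
        kind="volume_trend",
        series={
            "trend": series,
            "reference": pd.DataFrame({"fraction": [0], "value": [baseline]}),
        },
        style={"structure": structure, "mode": mode},
    )


def plot_dvh_spread(
    course: "CourseRecord",
    structures: Sequence[str],
    plan_filters: Sequence[str] = (ADAPTIVE, SCHEDULED),
    fractions: Sequence[int] | None = None,
    source: str = "tpms",
    grid_step: float = 0.5,
) -> FigureSpec:
    """DVH sliding box-and-whiskers: extrema, 20th-80th band, median, reference.

    One panel per plan filter (adaptive on the left, scheduled on the
    right), each overlaying the requested structures.  ``fractions``
    restricts the phase (e.g. primary vs boost fraction ranges); default is
    the whole course.
    """
    keep = None if fractions is None else set(fractions)
    if keep is not None and not keep:
        raise DomainError("empty phase selection")
    series: dict[str, pd.DataFrame] = {}
    for plan_filter in plan_filters:
        for structure in structures:
            curves = []
            for session in course.sessions:
                if keep is not None and session.fraction not in keep:
                    continue
                from .dvh import _session_plan

                ident = _session_plan(session, plan_filter)
                doc = course.document_for(ident) if ident is not None else None
                dvh = structure_dvh(doc, structure, source) if doc is not None else None
                if dvh is not None:
                    curves.append(dvh)
            if not curves:
                continue
            reference = (
                structure_dvh(course.reference, structure, source)
                if course.reference is not None
                else None
            )
            series[f"{plan_filter}:{structure}"] = band(
                curves, reference, grid_step=grid_step
            ).to_frame()
    if not series:
        raise ConfigurationError("no DVH curves matched the requested selection")
    return FigureSpec(
        kind="dvh_spread",
        series=series,
        style={"structures": list(structures), "plan_filters": list(plan_filters),
               "source": source},
    )


def plot_objective_distribution(
    courses: "Sequence[CourseRecord] | CourseRecord",
    spec: ObjectiveSpec,
    grouping: str = "overlay",
    comparison: str = "vs_reference",
    source: str = "tpms",
) -> FigureSpec:
    """Distribution of an objective across sessions of one or many courses.

    ``vs_reference`` plots per-session plan values minus the course's
    reference value, per plan type; ``adaptive_vs_scheduled`` plots paired
    per-fraction differences, as both percentage-point difference and
    ratio columns (the field uses either convention).
    """
    if grouping not in ("overlay", "side_by_side"):
        raise DomainError(f"unknown grouping {grouping!r}")
    if comparison not in ("vs_reference", "adaptive_vs_scheduled"):
        raise DomainError(f"unknown comparison {comparison!r}")
    course_list = [courses] if not isinstance(courses, (list, tuple)) else list(courses)

    series: dict[str, pd.DataFrame] = {}
    if comparison == "vs_reference":
        for plan_filter in (ADAPTIVE, SCHEDULED):
            frames = []
            for course in course_list:
                df = objective_series(course, spec, plan_filter, source)
                df = df[~df["missing"]].assign(patient=course.patient_id)
                frames.append(df[["patient", "fraction", "value", "relative"]])
            joined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            if len(joined):
                series[plan_filter] = joined
    else:
        frames = []
        for course in course_list:
            df = paired_differences(course, spec, source)
            df = df.dropna(subset=["difference"]).assign(patient=course.patient_id)
            df["ratio"] = df["adaptive"] / df["scheduled"]
            frames.append(df)
        joined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        if len(joined):
            series["paired"] = joined
    if not series:
        raise ConfigurationError(
            f"objective {spec.label} is not computable for any session "
            f"(structure missing everywhere?)"
        )
    return FigureSpec(
        kind="objective_distribution",
        series=series,
        style={"objective": spec.label, "grouping": grouping, "comparison": comparison},
    )


def _fd_bins(values: np.ndarray) -> int | np.ndarray:
    # Freedman-Diaconis, falling back when the IQR degenerates
    values = values[np.isfinite(values)]
    if values.size < 2 or np.ptp(values) == 0:
        return 1
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    if iqr <= 0:
        return 10
    width = 2 * iqr / values.size ** (1 / 3)
    return max(1, int(np.ceil(np.ptp(values) / width)))


def render(figspec: FigureSpec, path) -> Path:
    """Render a figure spec to an image file (format from the suffix)."""
    path = Path(path)
    if figspec.kind == "volume_trend":
        fig, ax = plt.subplots(figsize=(7, 4))
        df = figspec.series["trend"]
        for adapted, grp in df.groupby("adapted"):
            ax.scatter(
                grp["fraction"], grp["value"],
                label="adapted" if adapted else "scheduled",
                color="tab:orange" if adapted else "tab:blue",
            )
        ref = figspec.series["reference"]
        ax.scatter(ref["fraction"], ref["value"], marker="s", color="k", label="reference")
        ax.axhline(float(ref["value"].iloc[0]), color="k", lw=0.5, ls=":")
        mode = figspec.style.get("mode", "relative")
        ax.set_xlabel("fraction")
        ax.set_ylabel("volume change (fraction of reference)" if mode == "relative" else "volume (cm³)")
        ax.set_title(figspec.style.get("structure", ""))
        ax.legend()
    elif figspec.kind == "dvh_spread":
        panels = figspec.style.get("plan_filters", [ADAPTIVE, SCHEDULED])
        fig, axes = plt.subplots(1, len(panels), figsize=(6 * len(panels), 4), squeeze=False)
        cmap = plt.get_cmap("tab10")
        for j, plan_filter in enumerate(panels):
            ax = axes[0][j]
            i = 0
            for key, df in figspec.series.items():
                if not key.startswith(f"{plan_filter}:"):
                    continue
                color = cmap(i % 10)
                ax.fill_between(df["dose_gy"], df["lo"], df["hi"], alpha=0.15, color=color)
                ax.fill_between(df["dose_gy"], df["p20"], df["p80"], alpha=0.35, color=color)
                ax.plot(df["dose_gy"], df["median"], color=color, label=key.split(":", 1)[1])
                if "reference" in df:
                    ax.plot(df["dose_gy"], df["reference"], color=color, ls="--", lw=1)
                i += 1
            ax.set_xlabel("dose (Gy)")
            ax.set_ylabel("volume (%)")
            ax.set_title(plan_filter)
            ax.legend(fontsize=8)
    elif figspec.kind == "objective_distribution":
        names = list(figspec.series)
        side = figspec.style.get("grouping") == "side_by_side"
        ncols = len(names) if side else 1
        fig, axes = plt.subplots(1, ncols, figsize=(5 * ncols, 4), squeeze=False)
        for j, name in enumerate(names):
            ax = axes[0][j if side else 0]
            df = figspec.series[name]
            col = "relative" if "relative" in df.columns else "difference"
            vals = df[col].to_numpy(dtype=float)
            ax.hist(vals, bins=_fd_bins(vals), alpha=0.6, label=name)
            ax.set_xlabel(f"{figspec.style.get('objective', '')} {col}")
            ax.set_ylabel("sessions")
            ax.legend()
    else:
        raise DomainError(f"unknown figure kind {figspec.kind!r}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
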