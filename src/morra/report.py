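"""Descriptive 2x2 comparison of randomness profiles.

The study design crosses Expertise (expert vs beginner, between
participants) with Task (in-game Morra vs isolated RNGT, within
participants).  This module reproduces the descriptive layer of that
analysis on any set of labelled randomness profiles:

* per-cell means and standard deviations of the five indices,
* the overlap index OV - the integral of the pointwise minimum of two
  kernel density estimates - as a nonparametric effect size (1 identical
  distributions, 0 disjoint; below 0.20 corresponds to roughly d > 2),
* two-sided permutation tests on the mean difference for the four
  contrasts of interest (between groups within each task, between tasks
  within each group),
* pairwise correlations among the five indices across sequences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .metrics import INDEX_NAMES

__all__ = [
    "CellSummary",
    "ComparisonReport",
    "CONTRASTS",
    "summarize_cells",
    "overlap_index",
    "overlap_index_full",
    "permutation_contrast",
    "metric_correlations",
    "build_report",
]

#: The four contrasts of the 2x2 design: (name, fixed factor filter,
#: contrast factor, its two levels).
CONTRASTS: tuple[tuple[str, tuple[str, str], str, tuple[str, str]], ...] = (
    ("morra:beginner_vs_expert", ("task", "morra"), "group", ("beginner", "expert")),
    ("rngt:beginner_vs_expert", ("task", "rngt"), "group", ("beginner", "expert")),
    ("beginner:morra_vs_rngt", ("group", "beginner"), "task", ("morra", "rngt")),
    ("expert:morra_vs_rngt", ("group", "expert"), "task", ("morra", "rngt")),
)


@dataclass(frozen=True)
class CellSummary:
    group: str
    task: str
    n_sequences: int
    mean: dict[str, float]
    sd: dict[str, float]


class OverlapResult(NamedTuple):
    value: float
    method: str  # "kde" or "discrete" (zero-variance fallback)


class PermutationResult(NamedTuple):
    observed_diff: float
    p_value: float


@dataclass(frozen=True)
class ComparisonReport:
    cells: tuple[CellSummary, ...]
    missing_cells: tuple[tuple[str, str], ...]
    ov: dict[str, dict[str, float]]
    ov_method: dict[str, dict[str, str]]
    permutation_p: dict[str, dict[str, float]]
    observed_diff: dict[str, dict[str, float]]
    correlations: pd.DataFrame
    config_echo: dict = field(default_factory=dict)


def summarize_cells(profiles: pd.DataFrame):
    """Mean and sample SD of each index per (group, task) cell.

    Returns ``(cells, missing)`` where ``missing`` lists the design cells
    with no data; empty cells are reported, never fabricated.
    """
    cells: list[CellSummary] = []
    missing: list[tuple[str, str]] = []
    for group in ("beginner", "expert"):
        for task in ("morra", "rngt"):
            sub = profiles[(profiles["group"] == group) & (profiles["task"] == task)]
            if len(sub) == 0:
                missing.append((group, task))
                continue
            cells.append(
                CellSummary(
                    group=group,
                    task=task,
                    n_sequences=len(sub),
                    mean={k: float(sub[k].mean()) for k in INDEX_NAMES},
                    sd={k: float(sub[k].std(ddof=1)) for k in INDEX_NAMES},
                )
            )
    return tuple(cells), tuple(missing)


def _silverman_bw(x: np.ndarray) -> float:
    # Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)
    n = len(x)
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-1 / 5)


def overlap_index_full(
    sample_1: Sequence[float], sample_2: Sequence[float], grid_size: int = 512
) -> OverlapResult:
    """Overlap OV between two empirical distributions, with method flag.

    OV is the integral of the pointwise minimum of two Gaussian kernel
    density estimates (Silverman bandwidth) evaluated on a common grid
    spanning the pooled range plus three bandwidths each side, integrated
    with the trapezoidal rule.  Zero-variance samples fall back to
    discrete probability-mass overlap and are flagged as such.
    """
    x = np.asarray(sample_1, dtype=float)
    y = np.asarray(sample_2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        values = np.union1d(x, y)
        px = np.array([np.mean(x == v) for v in values])
        py = np.array([np.mean(y == v) for v in values])
        return OverlapResult(float(np.minimum(px, py).sum()), "discrete")
    bw_x, bw_y = _silverman_bw(x), _silverman_bw(y)
    pad = 3 * max(bw_x, bw_y)
    lo = min(x.min(), y.min()) - pad
    hi = max(x.max(), y.max()) + pad
    grid = np.linspace(lo, hi, max(grid_size, 512))

    def kde(data: np.ndarray, bw: float) -> np.ndarray:
        z = (grid[:, None] - data[None, :]) / bw
        return np.exp(-0.5 * z**2).sum(axis=1) / (len(data) * bw * np.sqrt(2 * np.pi))

    ov = float(np.trapezoid(np.minimum(kde(x, bw_x), kde(y, bw_y)), grid))
    return OverlapResult(min(ov, 1.0), "kde")


def overlap_index(sample_1, sample_2, grid_size: int = 512) -> float:
    """Overlap OV in [0, 1]; see :func:`overlap_index_full`."""
    result = overlap_index_full(sample_1, sample_2, grid_size)
    if result.method == "discrete":
        warnings.warn("zero-variance sample: OV fell back to discrete mass overlap")
    return result.value


def permutation_contrast(
    sample_1: Sequence[float],
    sample_2: Sequence[float],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test on the difference of means.

    p = (1 + #{permuted |diff| >= observed |diff|}) / (n_perm + 1), an
    exchangeability-valid (slightly conservative) Monte-Carlo p-value.
    """
    x = np.asarray(sample_1, dtype=float)
    y = np.asarray(sample_2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    observed = float(x.mean() - y.mean())
    n1 = len(x)
    perm = np.tile(pooled, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    diffs = perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1)
    extreme = int(np.sum(np.abs(diffs) >= abs(observed) - 1e-12))
    return PermutationResult(observed, (1 + extreme) / (n_perm + 1))


def metric_correlations(profiles: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlations among the five indices across sequences.

    Constant columns yield NaN for their pairs (flagged by being NaN, not
    imputed).  ``method`` may be 'pearson' (default) or 'spearman'.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles to correlate indices")
    sub = profiles[list(INDEX_NAMES)].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sub.corr(method=method)


def _contrast_samples(profiles: pd.DataFrame, contrast):
    name, (fix_col, fix_val), var_col, (lvl1, lvl2) = contrast
    base = profiles[profiles[fix_col] == fix_val]
    s1 = base[base[var_col] == lvl1]
    s2 = base[base[var_col] == lvl2]
    return s1, s2


def build_report(
    profiles: pd.DataFrame,
    out_dir=None,
    n_perm: int = 999,
    seed: int | None = None,
    config_echo: dict | None = None,
) -> ComparisonReport:
    """Assemble the full descriptive comparison; optionally write it out.

    Produces the four cell summaries, OV and permutation p for each of the
    four contrasts on each of the five indices, and the index correlation
    matrix.  When ``out_dir`` is given, writes a human-readable
    ``report.txt`` and a machine-readable ``report.json`` (deterministic
    bytes given the same inputs and seed).
    """
    cells, missing = summarize_cells(profiles)
    ov: dict[str, dict[str, float]] = {}
    ov_method: dict[str, dict[str, str]] = {}
    perm_p: dict[str, dict[str, float]] = {}
    obs: dict[str, dict[str, float]] = {}
    rng = np.random.default_rng(seed)
    for contrast in CONTRASTS:
        name = contrast[0]
        s1, s2 = _contrast_samples(profiles, contrast)
        ov[name], ov_method[name], perm_p[name], obs[name] = {}, {}, {}, {}
        for index in INDEX_NAMES:
            x = s1[index].dropna().to_numpy()
            y = s2[index].dropna().to_numpy()
            if len(x) < 2 or len(y) < 2:
                ov[name][index] = float("nan")
                ov_method[name][index] = "missing"
                perm_p[name][index] = float("nan")
                obs[name][index] = float("nan")
                continue
            result = overlap_index_full(x, y)
            ov[name][index] = result.value
            ov_method[name][index] = result.method
            pr = permutation_contrast(x, y, n_perm=n_perm, seed=int(rng.integers(2**31)))
            perm_p[name][index] = pr.p_value
            obs[name][index] = pr.observed_diff
    try:
        corr = metric_correlations(profiles)
    except ValueError:
        corr = pd.DataFrame(index=list(INDEX_NAMES), columns=list(INDEX_NAMES), dtype=float)
    report = ComparisonReport(
        cells=cells,
        missing_cells=missing,
        ov=ov,
        ov_method=ov_method,
        permutation_p=perm_p,
        observed_diff=obs,
        correlations=corr,
        config_echo=dict(config_echo or {}) | {"n_perm": n_perm, "seed": seed},
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _fmt(x: float) -> str:
    return "nan" if pd.isna(x) else f"{x:.4f}"


def _write_report(report: ComparisonReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["Cell summaries (mean (SD) per index)", ""]
    header = f"{'group':<10}{'task':<8}{'n':>4}  " + "".join(f"{k:>18}" for k in INDEX_NAMES)
    lines.append(header)
    for c in report.cells:
        row = f"{c.group:<10}{c.task:<8}{c.n_sequences:>4}  " + "".join(
            f"{_fmt(c.mean[k]) + ' (' + _fmt(c.sd[k]) + ')':>18}" for k in INDEX_NAMES
        )
        lines.append(row)
    for group, task in report.missing_cells:
        lines.append(f"{group:<10}{task:<8}  MISSING CELL")
    lines += ["", "Contrasts: overlap index OV and permutation p (two-sided)", ""]
    for name in report.ov:
        lines.append(name)
        for index in INDEX_NAMES:
            lines.append(
                f"  {index:<12} OV={_fmt(report.ov[name][index])}"
                f" ({report.ov_method[name][index]})"
                f"  diff={_fmt(report.observed_diff[name][index])}"
                f"  p={_fmt(report.permutation_p[name][index])}"
            )
    lines += ["", "Index correlations (pearson)", report.correlations.round(4).to_string(), ""]
    (out_dir / "report.txt").write_text("\n".join(lines))

    payload = {
        "cells": [
            {
                "group": c.group,
                "task": c.task,
                "n_sequences": c.n_sequences,
                "mean": c.mean,
                "sd": c.sd,
            }
            for c in report.cells
        ],
        "missing_cells": [list(m) for m in report.missing_cells],
        "ov": report.ov,
        "ov_method": report.ov_method,
        "permutation_p": report.permutation_p,
        "observed_diff": report.observed_diff,
        "correlations": {
            a: {b: (None if pd.isna(v) else v) for b, v in row.items()}
            for a, row in report.correlations.to_dict().items()
        },
        "config_echo": report.config_echo,
    }
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
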