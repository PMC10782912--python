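"""Per-sample window coverage, QC, bias correction, and cohort matrix assembly.

The processing order is: count -> bias-correct -> sample QC -> assemble ->
row-normalize -> prune.  Coverage values are summed base coverage per window
(depth x overlap bp), restricted to unmasked windows.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .windows import WindowSet, accumulate_track

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageProfile",
    "CoverageMatrix",
    "PruningReport",
    "BiasCorrectionConfig",
    "QCResult",
    "count_coverage",
    "sample_qc",
    "correct_bias",
    "assemble_matrix",
    "normalize_rows",
    "prune_windows",
]

STAGES = ("raw", "corrected", "normalized", "imputed")


@dataclass
class CoverageProfile:
    """One sample's per-window summed base coverage over unmasked windows."""

    sample_id: str
    values: np.ndarray
    window_indices: np.ndarray
    mean_depth: float
    n_unique_reads: int | None = None
    qc_pass: bool | None = None
    stage: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.window_indices = np.asarray(self.window_indices, dtype=np.int64)
        if len(self.values) != len(self.window_indices):
            raise ValueError("values and window_indices length mismatch")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")


@dataclass
class QCResult:
    passed: bool
    reasons: list[str]


@dataclass
class CoverageMatrix:
    """Samples x windows cohort matrix with labels and a processing stage flag."""

    sample_ids: list[str]
    window_indices: np.ndarray
    values: np.ndarray
    labels: np.ndarray
    stage: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.window_indices = np.asarray(self.window_indices, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length != row count")
        if len(self.window_indices) != m:
            raise ValueError("window_indices length != column count")
        if len(self.labels) != n:
            raise ValueError("labels length != row count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def advance(self, values: np.ndarray, stage: str, window_indices=None) -> "CoverageMatrix":
        """Return a copy at a later stage; stage transitions only move forward."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"stage cannot move backwards: {self.stage} -> {stage}")
        return CoverageMatrix(
            sample_ids=list(self.sample_ids),
            window_indices=self.window_indices if window_indices is None else window_indices,
            values=values,
            labels=self.labels.copy(),
            stage=stage,
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path, sidecar: str | None = None) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=[str(i) for i in self.window_indices])
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
        meta = {
            "stage": self.stage,
            "window_indices": [int(i) for i in self.window_indices],
            "labels": {s: int(l) for s, l in zip(self.sample_ids, self.labels)},
        }
        sidecar = sidecar or f"{path}.json"
        with open(sidecar, "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def from_tsv(cls, path, sidecar: str | None = None) -> "CoverageMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = sidecar or f"{path}.json"
        with open(sidecar) as fh:
            meta = json.load(fh)
        sample_ids = [str(s) for s in df.index]
        return cls(
            sample_ids=sample_ids,
            window_indices=np.array(meta["window_indices"]),
            values=df.to_numpy(dtype=float),
            labels=np.array([meta["labels"][s] for s in sample_ids]),
            stage=meta["stage"],
        )


@dataclass
class PruningReport:
    dropped: list[tuple[int, str]]
    n_initial: int
    n_retained: int

    def __post_init__(self):
        if self.n_initial != self.n_retained + len(self.dropped):
            raise ValueError("pruning report does not account for all windows")

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "n_retained": self.n_retained,
            "dropped": [[int(i), r] for i, r in self.dropped],
        }


def count_coverage(
    ws: WindowSet,
    depth_records: Iterable[tuple[str, int, int, float]],
    sample_id: str = "sample",
    n_unique_reads: int | None = None,
) -> CoverageProfile:
    """Sum base coverage into windows from sorted, non-overlapping depth records.

    The window value is sum(depth * overlap bp).  Masked windows are omitted
    from the profile.  Mean depth is total aligned bases over unmasked
    windows divided by the total unmasked genome length.
    """
    records = list(depth_records)
    for chrom, start, end, depth in records:
        if depth < 0:
            raise ValueError(f"negative depth {depth} at {chrom}:{start}-{end}")
        if chrom in ws.chrom_sizes and end > ws.chrom_sizes[chrom]:
            raise ValueError(
                f"record {chrom}:{start}-{end} extends beyond chromosome "
                f"length {ws.chrom_sizes[chrom]}"
            )
    wsum, _ = accumulate_track(ws, records)
    unmasked = ws.unmasked_indices
    values = wsum[unmasked]
    genome_len = int(ws.lengths[unmasked].sum())
    mean_depth = float(values.sum() / genome_len) if genome_len else 0.0
    return CoverageProfile(
        sample_id=sample_id,
        values=values,
        window_indices=unmasked,
        mean_depth=mean_depth,
        n_unique_reads=n_unique_reads,
    )


def sample_qc(
    p: CoverageProfile,
    min_mean_depth: float = 0.15,
    min_reads: int | None = 6_000_000,
) -> QCResult:
    """Sample-level QC: fail iff mean depth or unique read count falls strictly
    below its threshold.  Sets ``p.qc_pass``.  ``min_reads=None`` disables the
    read-count check."""
    reasons: list[str] = []
    if p.mean_depth < min_mean_depth:
        reasons.append("low_coverage")
    if min_reads is None:
        pass
    elif p.n_unique_reads is None:
        warnings.warn(f"{p.sample_id}: n_unique_reads missing, read-count check skipped")
    elif p.n_unique_reads < min_reads:
        reasons.append("low_reads")
    result = QCResult(passed=not reasons, reasons=reasons)
    p.qc_pass = result.passed
    return result


@dataclass
class BiasCorrectionConfig:
    """Two-stage trend-removal settings (GC stage then mappability stage)."""

    span: float = 0.3
    degree: int = 2
    trim_quantiles: tuple[float, float] = (0.001, 0.999)
    min_mappability: float = 0.9
    min_fit_windows: int = 50
    grid_points: int = 200


def _local_poly_trend(
    x: np.ndarray,
    y: np.ndarray,
    span: float,
    degree: int,
    grid_points: int,
    grid_range: tuple[float, float] | None = None,
):
    """Tricube-weighted local polynomial trend, evaluated via a dense grid.

    Returns a callable mapping new x values to trend values (linear
    interpolation between grid points, constant extrapolation at the ends).
    ``grid_range`` widens the evaluation grid beyond the fitted x (so points
    excluded from fitting are still predicted by the local fit rather than by
    constant extrapolation).  Degenerate x (near-constant) falls back to the
    mean of y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xmin, xmax = x.min(), x.max()
    if grid_range is not None:
        xmin = min(xmin, grid_range[0])
        xmax = max(xmax, grid_range[1])
    if xmax - xmin < 1e-12:
        mean = float(y.mean())
        return lambda xn: np.full(np.shape(xn), mean)
    k = max(degree + 1, int(np.ceil(span * len(x))))
    k = min(k, len(x))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    grid = np.linspace(xmin, xmax, grid_points)
    fitted = np.empty(grid_points)
    for i, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        h = np.partition(d, k - 1)[k - 1]
        h = max(h, 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        if not (w > 0).any():
            # all k nearest points sit exactly at distance h; weight them evenly
            w = (d <= h).astype(float)
        sel = w > 0
        # degenerate designs (few distinct x in bandwidth) get a reduced degree
        deg = min(degree, int(np.unique(xs[sel]).size) - 1)
        if deg == 0:
            fitted[i] = np.average(ys[sel], weights=w[sel])
        else:
            coeffs = np.polyfit(xs[sel] - x0, ys[sel], deg, w=np.sqrt(w[sel]))
            fitted[i] = coeffs[-1]  # polynomial evaluated at x0

    def trend(xn):
        return np.interp(np.asarray(xn, dtype=float), grid, fitted)

    return trend


def correct_bias(
    p: CoverageProfile,
    gc: np.ndarray,
    mappability: np.ndarray,
    cfg: BiasCorrectionConfig | None = None,
) -> CoverageProfile:
    """Remove GC then mappability trends from a coverage profile.

    Stage 1 fits a smooth trend of value vs GC on fitting-eligible windows
    (value inside the trim quantiles, mappability >= min_mappability) and
    divides it out; stage 2 fits corrected value vs mappability on trimmed
    windows and divides again.  The output is rescaled so the profile mean is
    preserved.  Windows excluded from fitting are still corrected by the
    fitted trends.
    """
    cfg = cfg or BiasCorrectionConfig()
    if p.stage != "raw":
        raise ValueError(f"correct_bias expects a raw profile, got stage {p.stage!r}")
    gc = np.asarray(gc, dtype=float)
    mappability = np.asarray(mappability, dtype=float)
    if len(gc) != len(p.values) or len(mappability) != len(p.values):
        raise ValueError("gc/mappability arrays not aligned to profile windows")
    values = p.values
    valid = np.isfinite(gc) & np.isfinite(mappability) & np.isfinite(values)

    lo, hi = np.quantile(values[valid], cfg.trim_quantiles)
    trimmed = valid & (values >= lo) & (values <= hi)
    eligible1 = trimmed & (mappability >= cfg.min_mappability)
    if eligible1.sum() < cfg.min_fit_windows:
        raise ValueError(
            f"bias correction refused: only {int(eligible1.sum())} fitting-eligible "
            f"windows (< {cfg.min_fit_windows})"
        )
    trend1 = _local_poly_trend(
        gc[eligible1], values[eligible1], cfg.span, cfg.degree, cfg.grid_points,
        grid_range=(gc[valid].min(), gc[valid].max()),
    )
    pred1 = np.clip(trend1(gc), 1e-12, None)
    corrected = values / pred1

    # stage 2: mappability trend over the full mappability range
    trend2 = _local_poly_trend(
        mappability[trimmed], corrected[trimmed], cfg.span, cfg.degree, cfg.grid_points,
        grid_range=(mappability[valid].min(), mappability[valid].max()),
    )
    pred2 = np.clip(trend2(mappability), 1e-12, None)
    final = corrected / pred2

    mean_out = final[valid].mean()
    if mean_out > 0:
        final = final * (values[valid].mean() / mean_out)
    return replace(p, values=final, stage="corrected")


def assemble_matrix(
    profiles: Sequence[CoverageProfile],
    labels: dict[str, int] | Sequence[int],
) -> CoverageMatrix:
    """Stack QC-passing profiles into a cohort matrix (input sample order)."""
    if not profiles:
        raise ValueError("no profiles")
    if not isinstance(labels, dict):
        if len(labels) != len(profiles):
            raise ValueError("labels length != number of profiles")
        labels = {p.sample_id: int(l) for p, l in zip(profiles, labels)}
    kept = []
    for p in profiles:
        if p.qc_pass is False:
            logger.info("excluding %s: failed QC", p.sample_id)
            continue
        if p.sample_id not in labels:
            raise ValueError(f"label missing for sample {p.sample_id!r}")
        kept.append(p)
    if not kept:
        raise ValueError("no QC-passing profiles")
    ref = kept[0]
    for p in kept[1:]:
        if p.stage != ref.stage:
            raise ValueError("profiles at mixed stages")
        if len(p.window_indices) != len(ref.window_indices) or not np.array_equal(
            p.window_indices, ref.window_indices
        ):
            raise ValueError(f"window-set mismatch for sample {p.sample_id!r}")
    return CoverageMatrix(
        sample_ids=[p.sample_id for p in kept],
        window_indices=ref.window_indices.copy(),
        values=np.vstack([p.values for p in kept]),
        labels=np.array([labels[p.sample_id] for p in kept]),
        stage=ref.stage,
    )


def normalize_rows(m: CoverageMatrix) -> CoverageMatrix:
    """Divide each row by its mean so every sample's mean coverage is 1."""
    if m.stage not in ("raw", "corrected"):
        raise ValueError(f"normalize_rows expects raw/corrected, got {m.stage!r}")
    row_means = m.values.mean(axis=1)
    zero = np.flatnonzero(row_means <= 0)
    if zero.size:
        raise ValueError(
            f"cannot normalize all-zero row(s): {[m.sample_ids[i] for i in zero]}"
        )
    return m.advance(m.values / row_means[:, None], "normalized")


def prune_windows(
    m: CoverageMatrix,
    dropout_frac: float = 0.8,
    dropout_value: float = 0.1,
    mean_diff: float = 0.01,
) -> tuple[CoverageMatrix, PruningReport]:
    """Drop uninformative windows from a normalized matrix.

    Rule 1 (dropout): the fraction of samples with value strictly below
    ``dropout_value`` is strictly above ``dropout_frac``.
    Rule 2 (mean difference): |mean over label-0 - mean over label-1| is
    strictly below ``mean_diff``.
    Rule 1 is checked first for reason attribution only; the retained set is
    the same under either precedence.
    """
    if m.stage != "normalized":
        raise ValueError(f"prune_windows expects a normalized matrix, got {m.stage!r}")
    if len(np.unique(m.labels)) < 2:
        raise ValueError("mean-difference rule requires both classes present")
    frac_low = (m.values < dropout_value).mean(axis=0)
    rule1 = frac_low > dropout_frac
    mean0 = m.values[m.labels == 0].mean(axis=0)
    mean1 = m.values[m.labels == 1].mean(axis=0)
    # round so a difference that equals the decimal threshold in real
    # arithmetic is not dropped by float summation error
    rule2 = np.round(np.abs(mean0 - mean1), 12) < mean_diff
    drop = rule1 | rule2
    dropped = [
        (int(m.window_indices[j]), "dropout_rule" if rule1[j] else "mean_diff_rule")
        for j in np.flatnonzero(drop)
    ]
    keep = ~drop
    report = PruningReport(
        dropped=dropped, n_initial=m.n_windows, n_retained=int(keep.sum())
    )
    pruned = m.advance(m.values[:, keep], m.stage, window_indices=m.window_indices[keep])
    logger.info("pruned %d of %d windows", len(dropped), m.n_windows)
    return pruned, report
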