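"""Synthetic low-coverage cohort generator with GC/mappability bias, dropout,
and group-specific copy-number segments, plus truth-recovery scoring.

The simulator is the test bed for every other module: it produces window
counts whose expected value is

    mu[s, w] = depth_s * window_len_w * bias(gc_w) * map_w * cn[s, w] / 2

where ``cn`` is 2 everywhere except inside signal segments of case samples
that express the effect, where it is ``2 * effect_size``.  Counts are drawn
Poisson or negative-binomial (or taken as ``mu`` exactly in noise-free mode),
then zeroed with the dropout probability.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import ChromSizes, WindowSet, make_windows

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort", "truth_recovery",
           "gc_bias_curve"]


@dataclass
class SimConfig:
    n_samples: int = 400
    case_fraction: float = 0.5
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 12_000_000),
        ("chr2", 8_000_000),
    )
    window_size: int = 10_000
    mean_depth_range: tuple[float, float] = (0.18, 0.25)
    gc_bias_strength: float = 0.0
    n_signal_segments: int = 5
    segment_length_windows: int = 20
    effect_size: float = 1.5
    penetrance: float = 1.0
    dropout_rate: float = 0.0
    noise: str = "poisson"            # poisson | negbin | none
    negbin_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("case_fraction", "penetrance", "dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.noise not in ("poisson", "negbin", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        n_case = round(self.n_samples * self.case_fraction)
        if self.case_fraction > 0 and n_case == 0:
            raise ValueError("case_fraction yields zero case samples")


@dataclass
class SyntheticCohort:
    window_set: WindowSet
    counts: np.ndarray               # samples x windows
    labels: np.ndarray               # 0/1
    sample_ids: list[str]
    truth_windows: np.ndarray        # indices of signal windows
    truth_direction: int             # +1 gain, -1 loss
    gc: np.ndarray
    mappability: np.ndarray
    depths: np.ndarray               # per-sample nominal mean depth
    config: SimConfig

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def depth_bedgraph(self, sample: int) -> list[tuple[str, int, int, float]]:
        """Per-window constant-depth records reproducing this sample's counts
        under ``count_coverage`` (depth = count / window length)."""
        ws = self.window_set
        lens = ws.lengths
        return [
            (str(ws.chroms[j]), int(ws.starts[j]), int(ws.ends[j]),
             float(self.counts[sample, j] / lens[j]))
            for j in range(len(ws))
        ]

    def write(self, outdir, depth_files: bool = False) -> None:
        os.makedirs(outdir, exist_ok=True)
        ws = self.window_set
        ws.to_tsv(os.path.join(outdir, "windows.tsv"))
        pd.DataFrame(
            {"sample_id": self.sample_ids, "label": self.labels}
        ).to_csv(os.path.join(outdir, "labels.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "truth.bed"), "w") as fh:
            for j in self.truth_windows:
                fh.write(
                    f"{ws.chroms[j]}\t{ws.starts[j]}\t{ws.ends[j]}\t{j}\t"
                    f"{self.truth_direction}\n"
                )
        counts = pd.DataFrame(
            self.counts, index=self.sample_ids,
            columns=[str(j) for j in range(len(ws))],
        )
        counts.index.name = "sample_id"
        counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
        if depth_files:
            ddir = os.path.join(outdir, "depth")
            os.makedirs(ddir, exist_ok=True)
            for i, sid in enumerate(self.sample_ids):
                with open(os.path.join(ddir, f"{sid}.bedgraph"), "w") as fh:
                    for chrom, start, end, depth in self.depth_bedgraph(i):
                        fh.write(f"{chrom}\t{start}\t{end}\t{depth:.8g}\n")


def gc_bias_curve(gc: np.ndarray, strength: float) -> np.ndarray:
    """Unimodal quadratic GC bias centered at 0.45 with amplitude ``strength``;
    clipped away from zero so expected counts stay positive."""
    gc = np.asarray(gc, dtype=float)
    return np.clip(1.0 + strength * 2.0 * (0.25 - (gc - 0.45) ** 2), 0.05, None)


def _place_segments(rng, ws: WindowSet, n_segments: int, seg_len: int) -> np.ndarray:
    """Pick non-overlapping runs of ``seg_len`` windows, each inside one
    chromosome."""
    chrom_ids = pd.factorize(ws.chroms)[0]
    taken = np.zeros(len(ws), dtype=bool)
    segments = []
    candidates = [
        j for j in range(len(ws) - seg_len + 1)
        if chrom_ids[j] == chrom_ids[j + seg_len - 1]
    ]
    if not candidates:
        raise ValueError(
            f"signal segments of {seg_len} windows do not fit the toy genome"
        )
    for _ in range(n_segments):
        free = [j for j in candidates if not taken[j:j + seg_len].any()]
        if not free:
            raise ValueError(
                f"cannot place {n_segments} non-overlapping segments of "
                f"{seg_len} windows"
            )
        j = free[rng.integers(len(free))]
        taken[j:j + seg_len] = True
        segments.append(np.arange(j, j + seg_len))
    return np.sort(np.concatenate(segments))


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Draw a fully reproducible synthetic cohort from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    chrom_sizes = ChromSizes(cfg.chrom_lengths)
    ws = make_windows(chrom_sizes, cfg.window_size)
    n_win = len(ws)
    lens = ws.lengths.astype(float)

    gc = rng.beta(5, 5, size=n_win)
    # mostly high-mappability windows with a low-mappability minority
    low = rng.random(n_win) < 0.2
    mappability = np.where(
        low, rng.uniform(0.5, 0.9, size=n_win), rng.uniform(0.9, 1.0, size=n_win)
    )
    ws.set_track("gc", gc, np.ones(n_win))
    ws.set_track("mappability", mappability, np.ones(n_win))

    n_case = round(cfg.n_samples * cfg.case_fraction)
    labels = np.zeros(cfg.n_samples, dtype=np.int64)
    labels[:n_case] = 1          # leading block are cases; sample ids encode labels
    sample_ids = [
        f"{'case' if l else 'ctrl'}_{i:04d}" for i, l in enumerate(labels)
    ]

    if cfg.n_signal_segments > 0 and cfg.effect_size != 1.0:
        truth = _place_segments(
            rng, ws, cfg.n_signal_segments, cfg.segment_length_windows
        )
    else:
        truth = np.array([], dtype=np.int64)
    direction = 1 if cfg.effect_size >= 1.0 else -1

    depths = rng.uniform(*cfg.mean_depth_range, size=cfg.n_samples)
    bias = gc_bias_curve(gc, cfg.gc_bias_strength)

    cn = np.full((cfg.n_samples, n_win), 2.0)
    if truth.size:
        seg_starts = truth.reshape(cfg.n_signal_segments, cfg.segment_length_windows)
        for s in range(cfg.n_samples):
            if labels[s] != 1:
                continue
            for seg in seg_starts:
                if rng.random() < cfg.penetrance:
                    cn[s, seg] = 2.0 * cfg.effect_size

    mu = depths[:, None] * lens[None, :] * bias[None, :] * mappability[None, :] * cn / 2.0
    if cfg.noise == "none":
        counts = mu.copy()
    elif cfg.noise == "poisson":
        counts = rng.poisson(mu).astype(float)
    else:
        r = cfg.negbin_dispersion
        counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    if cfg.dropout_rate > 0:
        counts[rng.random(counts.shape) < cfg.dropout_rate] = 0.0

    return SyntheticCohort(
        window_set=ws,
        counts=counts,
        labels=labels,
        sample_ids=sample_ids,
        truth_windows=truth,
        truth_direction=direction,
        gc=gc,
        mappability=mappability,
        depths=depths,
        config=cfg,
    )


def truth_recovery(
    ranked_indices: np.ndarray,
    truth: np.ndarray,
    k: int,
    n_windows: int,
) -> tuple[float, float]:
    """Precision@k of a ranking against the true signal windows, and its fold
    enrichment over the truth base rate ``|truth| / n_windows``."""
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ValueError("empty truth set")
    ranked_indices = np.asarray(ranked_indices)
    if k > len(ranked_indices):
        raise ValueError(f"k={k} exceeds ranking length {len(ranked_indices)}")
    topk = ranked_indices[:k]
    precision = len(np.intersect1d(topk, truth)) / k
    base_rate = truth.size / n_windows
    return float(precision), float(precision / base_rate)
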