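"""Attention-ranked region export, gene annotation, and over-representation
analysis (hypergeometric test with Benjamini-Hochberg correction)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .windows import WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "RankedRegions",
    "EnrichmentResult",
    "rank_windows",
    "annotate_genes",
    "ora_enrich",
    "bh_adjust",
    "read_gene_bed",
    "read_gmt",
]


@dataclass
class RankedRegions:
    """Windows ordered by descending attention weight (genome-order tie-break)."""

    window_index: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    weight: np.ndarray
    top_k: int

    def __len__(self) -> int:
        return len(self.window_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_index": self.window_index,
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "weight": self.weight,
            }
        )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(
                    f"{self.chrom[i]}\t{self.start[i]}\t{self.end[i]}\t"
                    f"{self.window_index[i]}\t{self.weight[i]:.6g}\n"
                )


def rank_windows(
    weights: np.ndarray,
    ws: WindowSet,
    top_k: int = 5000,
    window_indices: np.ndarray | None = None,
) -> RankedRegions:
    """Stable descending sort of windows by weight; keep the top ``top_k``.

    ``weights`` may cover all windows of ``ws`` or, if ``window_indices`` is
    given, just that subset (e.g. the retained columns after pruning).  Ties
    are broken by genome order.
    """
    weights = np.asarray(weights, dtype=float).ravel()
    if window_indices is None:
        if len(weights) != len(ws):
            raise ValueError(
                f"weights length {len(weights)} != {len(ws)} windows; "
                "pass window_indices for a subset"
            )
        window_indices = np.arange(len(ws))
    else:
        window_indices = np.asarray(window_indices, dtype=np.int64)
        if len(weights) != len(window_indices):
            raise ValueError("weights and window_indices length mismatch")
    if top_k > len(weights):
        warnings.warn(
            f"top_k={top_k} exceeds {len(weights)} windows; returning all"
        )
        top_k = len(weights)
    order = np.lexsort((window_indices, -weights))[:top_k]
    idx = window_indices[order]
    return RankedRegions(
        window_index=idx,
        chrom=ws.chroms[idx],
        start=ws.starts[idx],
        end=ws.ends[idx],
        weight=weights[order],
        top_k=top_k,
    )


def annotate_genes(
    rr: RankedRegions,
    genes: list[tuple[str, int, int, str]],
) -> list[str]:
    """Names of genes overlapping (>= 1 bp) any selected window.

    De-duplicated, in stable order of the first overlapping window (i.e. by
    descending window weight).  Gene intervals are 0-based half-open.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name in genes:
        if end <= start:
            warnings.warn(f"skipping malformed gene interval {name} {chrom}:{start}-{end}")
            continue
        by_chrom.setdefault(chrom, []).append((start, end, name))
    seen: set[str] = set()
    out: list[str] = []
    for i in range(len(rr)):
        c, s, e = rr.chrom[i], rr.start[i], rr.end[i]
        for gs, ge, name in by_chrom.get(c, ()):
            if gs < e and s < ge and name not in seen:
                seen.add(name)
                out.append(name)
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


@dataclass
class EnrichmentResult:
    """Per gene-set hypergeometric ORA results, ordered by adjusted p."""

    table: pd.DataFrame          # term_id, k, K, n, N, p_value, p_adjusted, genes
    dropped_genes: list[str]     # selected genes absent from the universe
    alpha: float = 0.05

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_adjusted"] < self.alpha]


def ora_enrich(
    selected: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``selected`` within each gene set.

    For a universe of N genes, a set of K, and n selected genes of which k
    fall in the set, p = P[X >= k] for X ~ Hypergeometric(N, K, n).  BH
    correction is applied across all tested sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel_all = list(dict.fromkeys(selected))
    if not sel_all:
        raise ValueError("empty selection")
    dropped = [g for g in sel_all if g not in uni]
    sel = [g for g in sel_all if g in uni]
    if not sel:
        raise ValueError("no selected genes remain after intersecting the universe")
    N = len(uni)
    n = len(sel)
    sel_set = set(sel)
    rows = []
    for term_id, members in gene_sets.items():
        members_in = set(members) & uni
        K = len(members_in)
        overlap = sorted(sel_set & members_in)
        k = len(overlap)
        # P[X >= k] with X ~ hypergeom(M=N, n=K, N=n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": term_id, "k": k, "K": K, "n": n, "N": N,
             "p_value": p, "genes": ",".join(overlap)}
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(
        ["p_adjusted", "p_value", "term_id"], kind="stable"
    ).reset_index(drop=True)
    table = table[["term_id", "k", "K", "n", "N", "p_value", "p_adjusted", "genes"]]
    if dropped:
        logger.info("dropped %d selected genes not in universe", len(dropped))
    return EnrichmentResult(table=table, dropped_genes=dropped, alpha=alpha)


def read_gene_bed(path) -> list[tuple[str, int, int, str]]:
    """Read gene intervals from BED4+ (name in column 4); malformed lines are
    reported and skipped."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if len(fields) < 4:
                    raise ValueError("expected >= 4 columns")
                out.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
            except ValueError as exc:
                warnings.warn(f"{path}:{lineno}: skipping malformed line ({exc})")
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (term, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
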