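"""Alignment quality: node correctness, confusion counts, ROC/AUC, sweeps.

Candidate pairs are the Cartesian product V x U.  A pair (v, u) in the
alignment is a true positive when u is v's ground-truth counterpart
(namesake) and a false positive otherwise; an unaligned true pair is a
false negative; everything else is a true negative.  Node correctness is
TP / |V|.  Robustness to perturbation is measured by aligning a network
against noisy versions of itself across a grid of noise levels, averaging
repeats, and summarizing the (FPR, TPR) points as a ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, align_networks
from .embedding import SGParams, WalkParams
from .generator import inject_noise
from .netio import TemporalNetwork

__all__ = [
    "ConfusionCounts",
    "ROCResult",
    "confusion_counts",
    "node_correctness",
    "roc_auc",
    "noise_sweep",
    "moving_average",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN over the Cartesian product of candidate node pairs."""

    TP: int
    FP: int
    TN: int
    FN: int
    n_source: int
    n_target: int

    def __post_init__(self) -> None:
        if self.TP + self.FP + self.TN + self.FN != self.n_source * self.n_target:
            raise ValueError("confusion counts must partition |V| x |U|")

    @property
    def nc(self) -> float:
        """Node correctness: fraction of source nodes correctly mapped."""
        return self.TP / self.n_source if self.n_source else 0.0

    @property
    def tpr(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else 0.0

    @property
    def fpr(self) -> float:
        d = self.FP + self.TN
        return self.FP / d if d else 0.0


@dataclass
class ROCResult:
    """(FPR, TPR) points sorted by FPR plus the trapezoidal AUC."""

    points: list[tuple[float, float]]
    auc: float


def confusion_counts(alignment: Alignment, truth: dict[str, str]) -> ConfusionCounts:
    """Score an alignment against the ground-truth injective mapping."""
    missing = [v for v in alignment.mapping if v not in truth]
    if missing:
        raise ValueError(
            f"aligned nodes missing from the ground truth: {sorted(missing)[:5]}"
        )
    n, m = len(alignment.g_nodes), len(alignment.h_nodes)
    tp = sum(1 for v, u in alignment.mapping.items() if truth[v] == u)
    fp = len(alignment.mapping) - tp
    # a true pair (v, truth[v]) is a false negative iff it was not aligned
    fn = sum(
        1
        for v in alignment.g_nodes
        if v in truth and alignment.mapping.get(v) != truth[v]
        and truth[v] in alignment.h_nodes
    )
    tn = n * m - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn, n, m)


def node_correctness(alignment: Alignment, truth: dict[str, str]) -> float:
    """NC = correctly mapped source nodes / |V|, in [0, 1]."""
    if not alignment.mapping:
        warnings.warn("empty alignment: node correctness is 0")
        return 0.0
    return confusion_counts(alignment, truth).nc


def roc_auc(points: list[tuple[float, float]]) -> ROCResult:
    """Assemble a ROC curve from (FPR, TPR) points and integrate it.

    Points are deduplicated, sorted by (FPR, TPR), anchored at (0, 0) and
    (1, 1) when absent, and integrated with the trapezoidal rule.
    """
    for x, y in points:
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise ValueError(f"ROC coordinate outside [0, 1]: ({x}, {y})")
    pts = sorted(set((float(x), float(y)) for x, y in points))
    if not pts or pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(ys, xs))
    return ROCResult(pts, auc)


def noise_sweep(
    base: TemporalNetwork,
    levels: list[float],
    mode: str = "edges",
    walk_params: WalkParams | None = None,
    sg_params: SGParams | None = None,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Align ``base`` against noisy copies of itself across noise levels.

    For each level and repeat a fresh noisy copy is drawn, the pair is
    aligned, and the result is scored against the identity ground truth.
    Returns one row per level with mean NC, TPR and FPR over repeats.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    for lv in levels:
        if not 0.0 <= lv <= 1.0:
            raise ValueError(f"noise level outside [0, 1]: {lv}")
    sg_params = sg_params or SGParams()
    truth = {n: n for n in base.nodes}
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(levels) * repeats))
    rows = []
    for level in levels:
        ncs, tprs, fprs = [], [], []
        for _ in range(repeats):
            child = next(children)
            s_noise, s_embed = (
                int(c.generate_state(1)[0] % 2**31) for c in child.spawn(2)
            )
            noisy = inject_noise(base, level, mode=mode, seed=s_noise)
            from dataclasses import replace

            aln = align_networks(
                base, noisy, walk_params, replace(sg_params, seed=s_embed)
            )
            cc = confusion_counts(aln, truth)
            ncs.append(cc.nc)
            tprs.append(cc.tpr)
            fprs.append(cc.fpr)
        rows.append(
            {
                "level": level,
                "mode": mode,
                "mean_nc": float(np.mean(ncs)),
                "mean_tpr": float(np.mean(tprs)),
                "mean_fpr": float(np.mean(fprs)),
                "n_repeats": repeats,
            }
        )
    return pd.DataFrame(rows)


def moving_average(series, window: int) -> list[float]:
    """Simple unweighted moving average; output length = len - window + 1."""
    series = list(series)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(series):
        raise ValueError(
            f"window {window} larger than series length {len(series)}"
        )
    kernel = np.ones(window) / window
    return np.convolve(np.asarray(series, dtype=float), kernel, "valid").tolist()
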