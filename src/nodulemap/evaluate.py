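"""Ground-truth labeling and confusion-matrix evaluation of detection maps.

A grid point is truth-tumor when it lies over the planar projection of any
inclusion (boundary inclusive) — depth is deliberately ignored, so a point
over a deep small nodule still counts as tumor even though palpation may
not feel it; that is exactly what produces stiffness false negatives.

Rates are class-conditional: TP% and FN% are fractions of the truth-tumor
points, TN% and FP% fractions of the truth-healthy points, so TP% + FN% =
100 and TN% + FP% = 100.  Accuracy and misclassification rate are fractions
of all points and sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ClassificationMap
from .phantom import Phantom
from .scan_sim import ScanDataset

__all__ = [
    "ConfusionSummary",
    "ground_truth_labels",
    "confusion",
    "summarize_methods",
    "pool_summaries",
    "category_codes",
    "CATEGORY_NAMES",
    "format_summary",
    "save_summary",
    "save_category_grid",
    "save_category_png",
]

#: Category encoding of per-point outcomes: index = 2*truth + pred.
CATEGORY_NAMES = ("TN", "FP", "FN", "TP")


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/TN/FP/FN counts with class-conditional percentage rates."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tp_rate_pct(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def fn_rate_pct(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.fn / pos if pos else float("nan")

    @property
    def tn_rate_pct(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")

    @property
    def fp_rate_pct(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.fp / neg if neg else float("nan")

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def misclassification_pct(self) -> float:
        return 100.0 * (self.fp + self.fn) / self.total if self.total else float("nan")

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "tp_rate_pct": self.tp_rate_pct,
            "tn_rate_pct": self.tn_rate_pct,
            "fp_rate_pct": self.fp_rate_pct,
            "fn_rate_pct": self.fn_rate_pct,
            "accuracy_pct": self.accuracy_pct,
            "misclassification_pct": self.misclassification_pct,
        }


def ground_truth_labels(phantom: Phantom, points) -> np.ndarray:
    """True where a grid point lies within any inclusion's projected circle."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = np.zeros(len(pts), dtype=bool)
    for inc in phantom.inclusions:
        cx, cy, _ = inc.center_mm
        d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
        labels |= d2 <= inc.radius_mm**2 + 1e-12
    return labels


def _pred_labels(pred) -> np.ndarray:
    if isinstance(pred, ClassificationMap):
        return pred.labels
    return np.asarray(pred, dtype=bool)


def confusion(pred, truth) -> ConfusionSummary:
    """Cross-tabulate predicted vs true labels into a confusion summary."""
    p = _pred_labels(pred)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("prediction and truth label arrays must align")
    return ConfusionSummary(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def category_codes(pred, truth) -> np.ndarray:
    """Per-point outcome codes (0=TN, 1=FP, 2=FN, 3=TP) for map rendering."""
    p = _pred_labels(pred).astype(int)
    t = np.asarray(truth, dtype=bool).astype(int)
    return 2 * t + p


def summarize_methods(
    dataset: ScanDataset,
    maps: dict[str, ClassificationMap],
    phantom: Phantom | None = None,
) -> tuple[dict[str, ConfusionSummary], dict[str, np.ndarray], np.ndarray]:
    """Evaluate every method's map against the phantom ground truth.

    Returns per-method confusion summaries, per-method category-code
    arrays (for TP/TN/FP/FN map rendering), and the truth labels.
    """
    phantom = phantom or dataset.phantom_truth
    if phantom is None:
        raise ValueError("no phantom ground truth available")
    truth = ground_truth_labels(phantom, dataset.grid)
    summaries: dict[str, ConfusionSummary] = {}
    categories: dict[str, np.ndarray] = {}
    for name, cmap in maps.items():
        if len(cmap.labels) != len(truth):
            raise ValueError(f"map '{name}' is not aligned with the dataset grid")
        summaries[name] = confusion(cmap, truth)
        categories[name] = category_codes(cmap, truth)
    return summaries, categories, truth


def pool_summaries(summaries: list[ConfusionSummary]) -> ConfusionSummary:
    """Pool counts over replicate phantoms (rates recomputed from pooled counts)."""
    if not summaries:
        raise ValueError("nothing to pool")
    out = summaries[0]
    for s in summaries[1:]:
        out = out + s
    return out


def format_summary(name: str, s: ConfusionSummary) -> str:
    return (
        f"{name:>10}: TP={s.tp:4d} TN={s.tn:4d} FP={s.fp:4d} FN={s.fn:4d} | "
        f"TP%={s.tp_rate_pct:6.2f} TN%={s.tn_rate_pct:6.2f} "
        f"FP%={s.fp_rate_pct:6.2f} FN%={s.fn_rate_pct:6.2f} | "
        f"acc={s.accuracy_pct:6.2f}%"
    )


def save_summary(summaries: dict[str, ConfusionSummary], path) -> None:
    """Write per-method summaries as delimited text."""
    cols = (
        "method\ttp\ttn\tfp\tfn\ttp_rate_pct\ttn_rate_pct\tfp_rate_pct"
        "\tfn_rate_pct\taccuracy_pct\tmisclassification_pct\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for name, s in summaries.items():
            d = s.as_dict()
            fh.write(
                f"{name}\t{d['tp']}\t{d['tn']}\t{d['fp']}\t{d['fn']}\t"
                f"{d['tp_rate_pct']!r}\t{d['tn_rate_pct']!r}\t{d['fp_rate_pct']!r}\t"
                f"{d['fn_rate_pct']!r}\t{d['accuracy_pct']!r}\t{d['misclassification_pct']!r}\n"
            )


def save_category_grid(points, codes, path) -> None:
    """Write a per-point TP/TN/FP/FN category grid as delimited text."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    with open(path, "w") as fh:
        fh.write("x_mm\ty_mm\tcategory\n")
        for (x, y), c in zip(pts, codes):
            fh.write(f"{float(x)!r}\t{float(y)!r}\t{CATEGORY_NAMES[int(c)]}\n")


def save_category_png(points, codes, path, title: str = "") -> None:
    """Render the TP/TN/FP/FN map as a PNG heat/scatter image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    cmap = ListedColormap(["#2c7bb6", "#fdae61", "#d7191c", "#1a9641"])
    fig, ax = plt.subplots(figsize=(7, 4.5))
    sc = ax.scatter(pts[:, 0], pts[:, 1], c=np.asarray(codes), cmap=cmap,
                    vmin=-0.5, vmax=3.5, s=18, marker="s")
    cbar = fig.colorbar(sc, ticks=[0, 1, 2, 3])
    cbar.ax.set_yticklabels(CATEGORY_NAMES)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
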