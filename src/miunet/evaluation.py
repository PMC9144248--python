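"""Dice-based evaluation and paired statistical model comparison.

Evaluation uses the *hard* Dice coefficient 2|A∩B| / (|A| + |B|) on
argmax masks (the soft squared-denominator form is a training loss
only). Model comparisons use paired two-tailed t-tests on per-slice
structure-mean Dice at a 5% significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DataError, DimensionError

__all__ = [
    "STRUCTURES",
    "dice_score",
    "predict_mask",
    "evaluate_model",
    "paired_ttest",
    "compare_models",
    "EvalReport",
    "TTestResult",
]

STRUCTURES = {1: "LVC", 2: "LVM", 3: "RV"}


def dice_score(pred_mask, ref_mask, label: int) -> float:
    """Hard Dice for one label; both-empty -> 1.0, one-empty -> 0.0."""
    pred_mask, ref_mask = np.asarray(pred_mask), np.asarray(ref_mask)
    if pred_mask.shape != ref_mask.shape:
        raise DimensionError(
            f"mask shapes differ: {pred_mask.shape} vs {ref_mask.shape}"
        )
    a, b = pred_mask == label, ref_mask == label
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def predict_mask(model, X) -> np.ndarray:
    """Per-pixel argmax over class probabilities (ties go to the lower
    label index, so uniform maps predict background)."""
    return model.predict(X)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero-variance nonzero-mean differences


def paired_ttest(scores_a, scores_b) -> TTestResult:
    """Two-tailed paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1.

    Degenerate cases: all-zero differences give (t=0, p=1); zero-variance
    nonzero-mean differences give p = 0 with the degeneracy flag set.
    """
    a, b = np.asarray(scores_a, dtype=float), np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired scores must be equal-length 1D sequences")
    n = len(a)
    if n < 2:
        raise DataError("paired t-test requires n >= 2")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(np.inf if md > 0 else -np.inf, df, 0.0, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


@dataclass
class EvalReport:
    """Per-slice per-structure Dice plus summary statistics."""

    per_slice: pd.DataFrame  # columns: slice, structure, dice
    summary: pd.DataFrame  # columns: structure, mean, sd, n

    def structure_mean_series(self) -> np.ndarray:
        """Per-slice mean Dice across structures (the t-test pairing unit)."""
        wide = self.per_slice.pivot(index="slice", columns="structure", values="dice")
        return wide.mean(axis=1).to_numpy()


def _report_from_masks(pred: np.ndarray, ref: np.ndarray) -> EvalReport:
    rows = [
        {"slice": i, "structure": name, "dice": dice_score(p, r, label)}
        for i, (p, r) in enumerate(zip(pred, ref))
        for label, name in STRUCTURES.items()
    ]
    per_slice = pd.DataFrame(rows)
    summaries = []
    for name in STRUCTURES.values():
        vals = per_slice.loc[per_slice.structure == name, "dice"].to_numpy()
        summaries.append(
            {
                "structure": name,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            }
        )
    wide = per_slice.pivot(index="slice", columns="structure", values="dice")
    slice_means = wide.mean(axis=1).to_numpy()
    summaries.append(
        {
            "structure": "Mean",
            "mean": float(slice_means.mean()),
            "sd": float(slice_means.std(ddof=1)) if len(slice_means) > 1 else 0.0,
            "n": len(slice_means),
        }
    )
    return EvalReport(per_slice, pd.DataFrame(summaries))


def evaluate_model(model, X, y, stream: int | None = None) -> EvalReport:
    """Evaluate a fitted segmenter on a labeled test set.

    For pair models (X of shape (n, 2, H, W)) `stream` selects the
    contrast: 0 = cine, 1 = LGE; None evaluates both and concatenates.
    """
    X, y = np.asarray(X), np.asarray(y)
    if len(X) == 0:
        raise DataError("empty test set")
    pred = model.predict(X)
    if pred.ndim == 4:  # pair model output (n, 2, H, W)
        if stream is None:
            pred = pred.reshape(-1, *pred.shape[2:])
            ref = y.reshape(-1, *y.shape[2:])
        else:
            pred, ref = pred[:, stream], y[:, stream]
    else:
        ref = y
    return _report_from_masks(pred, ref)


def compare_models(
    reports: dict[str, EvalReport], baseline: str
) -> pd.DataFrame:
    """Tabulate per-structure Dice (mean ± SD) for several models with
    paired t-tests of each model against the named baseline.

    All reports must cover the identical slice set.
    """
    if baseline not in reports:
        raise DataError(f"baseline {baseline!r} not among reports")
    base = reports[baseline]
    n_ref = len(base.per_slice)
    rows = []
    for name, report in reports.items():
        if len(report.per_slice) != n_ref:
            raise DataError("compared models were evaluated on different slice sets")
        for _, srow in report.summary.iterrows():
            entry = {
                "model": name,
                "structure": srow["structure"],
                "mean": srow["mean"],
                "sd": srow["sd"],
                "n": srow["n"],
            }
            if srow["structure"] == "Mean":
                own = report.structure_mean_series()
                ref = base.structure_mean_series()
            else:
                own = report.per_slice.loc[
                    report.per_slice.structure == srow["structure"], "dice"
                ].to_numpy()
                ref = base.per_slice.loc[
                    base.per_slice.structure == srow["structure"], "dice"
                ].to_numpy()
            tt = paired_ttest(own, ref)
            entry.update({"t_vs_baseline": tt.t, "p_vs_baseline": tt.p})
            rows.append(entry)
    return pd.DataFrame(rows)


def format_comparison(table: pd.DataFrame) -> str:
    """Human-readable grid: one line per (model, structure)."""
    lines = [f"{'model':<16} {'structure':<10} {'Dice':>14} {'p vs base':>10}"]
    for _, row in table.iterrows():
        lines.append(
            f"{row['model']:<16} {row['structure']:<10} "
            f"{row['mean']:.3f} ± {row['sd']:.3f} {row['p_vs_baseline']:>10.4f}"
        )
    return "\n".join(lines)
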