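"""Report rendering: per-task result tables, ensemble summary, figures."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec
from .ensemble import EnsembleEvaluation
from .model_selection import ParetoReport, ResultRecord

_CLF_DISPLAY = {
    "lda": "LDA", "svm_linear": "SVM-L", "svm_sigmoid": "SVM-S",
    "svm_rbf": "SVM-RBF", "rf": "RF", "xgb": "XGBoost",
}
_EFS_DISPLAY = {
    "ga": "GA", "sda": "SDA", "rfe": "RFE", "rf_importance": "RF",
    "xgb_importance": "XGBoost",
}


def records_frame(records: list[ResultRecord]) -> pd.DataFrame:
    """Result records as a table with the standard column layout:
    EFS, Estimator, # Features, Classifier, NDF, BACC, AUC, F1-S."""
    rows = []
    for r in records:
        sel = r.config.selection
        est = sel.estimator
        est_tag = (_CLF_DISPLAY.get(est.kind, est.kind)
                   if isinstance(est, ClassifierSpec) else "–")
        row = {
            "Task": r.config.task,
            "EFS": _EFS_DISPLAY.get(sel.method, sel.method),
            "Estimator": est_tag,
            "# Features": sel.p,
            "Classifier": _CLF_DISPLAY.get(r.config.classifier.kind,
                                           r.config.classifier.kind),
            "NDF": "NDF" if sel.ndf_only else "–",
        }
        if r.summary is not None:
            row.update(
                BACC=round(r.summary.mean["bacc"], 3),
                AUC=round(r.summary.mean["auc"], 3),
                **{"F1-S": round(r.summary.mean["f1"], 3)},
            )
        else:
            row.update({"BACC": np.nan, "AUC": np.nan, "F1-S": np.nan,
                        "error": r.error})
        rows.append(row)
    return pd.DataFrame(rows)


def render_pareto_table(report: ParetoReport) -> str:
    """Front table with the best overall row marked by '*'."""
    df = records_frame(report.front)
    best = report.best if report.front else None
    marks = []
    for r in report.front:
        marks.append("*" if r is best else "")
    df.insert(0, "Best", marks)
    return df.to_string(index=False)


def render_ensemble_summary(ev: EnsembleEvaluation) -> str:
    """Across-class Range / Mean / Std summary plus the confusion matrix."""
    lines = ["Metric  Range          Mean   Std."]
    for metric, name in (("f1", "F1-S"), ("bacc", "BACC"), ("auc", "AUC")):
        s = ev.summary[metric]
        lines.append(
            f"{name:<7} {s['min']:.3f}–{s['max']:.3f}    {s['mean']:.3f}  "
            f"{s['sd']:.3f}"
        )
    lines.append("")
    lines.append("Confusion matrix (rows true, columns predicted):")
    header = "            " + "  ".join(f"{c:>10}" for c in ev.classes)
    lines.append(header)
    for i, c in enumerate(ev.classes):
        lines.append(
            f"{c:>10}  " + "  ".join(f"{ev.confusion[i, j]:>10d}"
                                     for j in range(len(ev.classes)))
        )
    lines.append("")
    lines.append(f"Macro BACC (3-class): {ev.macro_bacc:.3f}")
    return "\n".join(lines)


def save_figures(ev: EnsembleEvaluation, out_dir: str | Path) -> list[Path]:
    """ROC curves and confusion heatmap as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, (fpr, tpr) in ev.roc_curves.items():
        ax.plot(fpr, tpr, label=f"{cls} (AUC {ev.per_class[cls]['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("One-vs-rest ROC per class")
    ax.legend(loc="lower right", fontsize=8)
    p = out_dir / "roc_ovr.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(ev.confusion, cmap="Blues")
    ax.set_xticks(range(len(ev.classes)), ev.classes, rotation=30)
    ax.set_yticks(range(len(ev.classes)), ev.classes)
    for i in range(len(ev.classes)):
        for j in range(len(ev.classes)):
            ax.text(j, i, str(ev.confusion[i, j]), ha="center", va="center")
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    fig.colorbar(im, shrink=0.8)
    p = out_dir / "confusion.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths


def render_report(
    records: list[ResultRecord] | None = None,
    pareto: ParetoReport | None = None,
    ensemble_eval: EnsembleEvaluation | None = None,
) -> str:
    """Human-readable run report combining whichever artifacts exist."""
    parts = []
    if records is not None:
        parts.append("All configurations\n" + records_frame(records).to_string(index=False))
    if pareto is not None:
        parts.append(
            f"Pareto front (floor {pareto.floor:.2f}; best marked '*')\n"
            + (render_pareto_table(pareto) if pareto.front else "  (empty)")
        )
    if ensemble_eval is not None:
        parts.append("OvR ensemble\n" + render_ensemble_summary(ensemble_eval))
    return "\n\n".join(parts) + "\n"
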