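"""Figures for audit reports: null-AUC box plots and ROC transfer grids."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .audit import AuditReport

#: conventional "looks predictive" reference level for the null box plot
AUC_REFERENCE = 0.7


def plot_null_boxplot(report: AuditReport, ax=None, reference: float = AUC_REFERENCE):
    """Box plot of per-cohort random-signature resubstitution AUCs.

    A dotted reference line marks an AUC that would usually be read as
    good performance; random gene sets clearing it is the point.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * len(report.cohort_names) + 1.5, 4))
    names = report.cohort_names
    ax.boxplot(
        [report.null_audits[n].auc_values for n in names],
        tick_labels=[
            f"{n}\n(k={report.null_audits[n].signature_size})" for n in names
        ],
        whis=1.5,
    )
    ax.axhline(reference, linestyle=":", color="0.3")
    ax.set_ylabel("resubstitution AUC")
    ax.set_ylim(0, 1.05)
    ax.set_title(
        f"Random gene sets, {report.n_draws} draws per cohort (training AUC)"
    )
    return ax


def plot_roc_grid(report: AuditReport, axes=None):
    """One panel per training cohort: resubstitution vs held-out ROC curves."""
    names = report.cohort_names
    if axes is None:
        _, axes = plt.subplots(
            1, len(names), figsize=(4 * len(names), 4), squeeze=False
        )
        axes = axes[0]
    for ax, name in zip(axes, names):
        cross = report.cross_audits[name]
        resub = cross.training_resubstitution
        ax.plot(
            resub.fpr,
            resub.tpr,
            color="0.4",
            linestyle="--",
            label=f"train (resub) {resub.auc:.2f}",
        )
        for test_name in sorted(cross.test_results):
            r = cross.test_results[test_name]
            ax.plot(r.fpr, r.tpr, label=f"{test_name} {r.auc:.2f}")
        ax.plot([0, 1], [0, 1], color="0.85", linewidth=0.8)
        ax.set_title(f"trained on {name}")
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
        ax.legend(fontsize=8, loc="lower right")
    return axes


def save_report_figures(report: AuditReport, out_dir: Path) -> dict[str, Path]:
    """Write the two standard figures as PNGs under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    ax = plot_null_boxplot(report)
    fig = ax.figure
    fig.tight_layout()
    paths["null_boxplot"] = out_dir / "random_signature_null.png"
    fig.savefig(paths["null_boxplot"], dpi=150)
    plt.close(fig)

    axes = plot_roc_grid(report)
    fig = axes[0].figure
    fig.tight_layout()
    paths["roc_grid"] = out_dir / "cross_cohort_roc.png"
    fig.savefig(paths["roc_grid"], dpi=150)
    plt.close(fig)
    return paths
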