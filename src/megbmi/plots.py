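"""Figure helpers: bar charts with 95% CIs for the crossover outcomes."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def _ci95(values: np.ndarray) -> float:
    values = np.asarray(values, float)
    if values.size < 2:
        return 0.0
    return 1.96 * values.std(ddof=1) / np.sqrt(values.size)


def crossover_accuracy_figure(report: dict, path=None):
    """Pre/post nested-CV accuracy per arm (mean bar + 95% CI)."""
    fig, ax = plt.subplots(figsize=(4, 3))
    xs, heights, errs, labels = [], [], [], []
    for k, kind in enumerate(("real", "sham")):
        vals = {"pre": [], "post": []}
        for rec in report["per_subject"]:
            if rec.get(kind):
                vals["pre"].append(rec[kind]["pre_accuracy_pct"])
                vals["post"].append(rec[kind]["post_accuracy_pct"])
        for j, phase in enumerate(("pre", "post")):
            xs.append(2.5 * k + j)
            heights.append(np.mean(vals[phase]))
            errs.append(_ci95(np.asarray(vals[phase])))
            labels.append(f"{kind}\n{phase}")
    ax.bar(xs, heights, yerr=errs, capsize=3,
           color=["C0", "C0", "C1", "C1"])
    ax.axhline(50, ls=":", color="k", lw=1)  # chance level
    ax.set_xticks(xs, labels)
    ax.set_ylabel("classification accuracy (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def correct_rate_improvement_figure(report: dict, path=None):
    """Last-minus-first-minute correct-rate improvement per arm."""
    fig, ax = plt.subplots(figsize=(3, 3))
    for k, kind in enumerate(("real", "sham")):
        imps = []
        for rec in report["per_subject"]:
            arm = rec.get(kind)
            if arm and arm["first_min_rate"] is not None \
                    and arm["last_min_rate"] is not None:
                imps.append(arm["last_min_rate"] - arm["first_min_rate"])
        if imps:
            ax.bar(k, np.mean(imps), yerr=_ci95(np.asarray(imps)), capsize=3,
                   color=f"C{k}")
    ax.set_xticks([0, 1], ["real", "sham"])
    ax.set_ylabel("correct-rate improvement")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
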