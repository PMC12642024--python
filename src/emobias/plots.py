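"""Optional figures (requires matplotlib): per-participant fit curves and
the group x moderator interaction plot."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from emobias.io import AnalysisReport
from emobias.psychometric import _model_prob


def plot_fit_curve(fit_row: dict, ax=None):
    """Fitted psychometric curve for one participant's fit row."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.linspace(-90, 90, 361)
    y = _model_prob(x, fit_row["mu"], fit_row["sigma"], fit_row["guess"],
                    fit_row["lapse"])
    ax.plot(x, 100 * y)
    ax.axhline(50, color="gray", lw=0.5)
    ax.axvline(fit_row["pse"], color="gray", ls="--", lw=0.8)
    ax.set_xlabel("morph level (% happy)")
    ax.set_ylabel("% judged happy")
    ax.set_title(f"{fit_row.get('participant_id', '')} "
                 f"PSE={fit_row['pse']:.2f}, slope={fit_row['slope_at_pse']:.3f}")
    return ax


def plot_interaction(moderation_result: dict, outcome: str, ax=None):
    """Model-implied outcome at group x (mean -/+ 1 SD moderator) cells."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    step = moderation_result["step2"]
    sd = moderation_result["na_sd"]
    for sa, label in ((0.0, "LSA"), (1.0, "HSA")):
        y = [step["coef"]["const"] + step["coef"]["sa"] * sa
             + step["coef"]["na_c"] * m + step["coef"]["sa_x_na_c"] * sa * m
             for m in (-sd, sd)]
        ax.plot([-1, 1], y, marker="o", label=label)
    ax.set_xticks([-1, 1], ["-1 SD", "+1 SD"])
    ax.set_xlabel("negative affect (centered)")
    ax.set_ylabel(outcome)
    ax.legend()
    return ax


def save_run_figures(report: AnalysisReport, outdir: str | Path) -> dict:
    """Write fit-curve and interaction figures for a finished run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: dict[str, str] = {}
    if report.fits:
        n = min(len(report.fits), 6)
        fig, axes = plt.subplots(2, 3, figsize=(12, 6), squeeze=False)
        for ax in axes.flat[n:]:
            ax.set_visible(False)
        for fit_row, ax in zip(report.fits[:n], axes.flat):
            plot_fit_curve(fit_row, ax=ax)
        fig.tight_layout()
        path = outdir / "fit_curves.svg"
        fig.savefig(path)
        plt.close(fig)
        written["fig_fit_curves"] = str(path)
    for outcome, result in sorted(report.moderation.items()):
        fig, ax = plt.subplots(figsize=(4, 3))
        plot_interaction(result, outcome, ax=ax)
        fig.tight_layout()
        path = outdir / f"interaction_{outcome}.svg"
        fig.savefig(path)
        plt.close(fig)
        written[f"fig_interaction_{outcome}"] = str(path)
    return written
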