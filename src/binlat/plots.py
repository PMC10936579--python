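"""Optional figure output mirroring the pipeline's summary views."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .longitudinal import ChangeRecord, metric_change_matrix
from .metrics import retain_trials
from .normative import DivergenceProfile
from .schema import ILD_SET, ITD_PHYSIOLOGICAL, LateralizationSession


def plot_session(
    session: LateralizationSession,
    path: str | Path,
    control_band: dict | None = None,
) -> None:
    """Per-stimulus response scatter with side-fit lines, one panel per family.

    ``control_band`` may map family -> (cues, mean, sd) arrays to draw the
    control mean +- 1.5 SD band behind the responses.
    """
    from .metrics import _SIDE_STIMULI, fit_side_line  # local: plotting only

    retained = retain_trials(session)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, family, cues in (
        (axes[0], "itd", ITD_PHYSIOLOGICAL),
        (axes[1], "ild", ILD_SET),
    ):
        if control_band and family in control_band:
            c, m, s = control_band[family]
            ax.fill_between(c, np.array(m) - 1.5 * np.array(s),
                            np.array(m) + 1.5 * np.array(s),
                            color="0.85", label="control band")
        xs, ys = [], []
        for t in retained.trials:
            if t.stimulus.cue_type == family:
                xs.append(t.stimulus.cue_value)
                ys.append(t.response_key)
            elif t.stimulus.cue_type == "diotic":
                xs.append(0.0)
                ys.append(t.response_key)
        ax.plot(xs, ys, "o", ms=4, alpha=0.5)
        for side, color in (("left", "tab:blue"), ("right", "tab:red")):
            side_cues = _SIDE_STIMULI[(family, side)]
            side_trials = [
                t
                for t in retained.trials
                if t.stimulus.cue_type == family and t.stimulus.cue_value in side_cues
            ]
            fit = fit_side_line(side_trials, side, family)
            grid = np.linspace(min(side_cues), max(side_cues), 10)
            ax.plot(grid, fit.intercept + fit.slope * grid, color=color)
        ax.set_xlabel("ITD (µs)" if family == "itd" else "ILD (dB)")
        ax.set_ylim(0.5, 9.5)
    axes[0].set_ylabel("response key")
    fig.suptitle(f"{session.participant_id} / {session.phase}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_divergence_pairs(
    profiles: dict[tuple[str, str], DivergenceProfile],
    pairs: list[tuple[str, str]],
    path: str | Path,
) -> None:
    """Phase-vs-phase scatter of divergence counts, one panel per pair."""
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 4))
    if len(pairs) == 1:
        axes = [axes]
    for ax, (earlier, later) in zip(axes, pairs):
        xs, ys = [], []
        for pid in sorted({p for p, _ in profiles}):
            if (pid, earlier) in profiles and (pid, later) in profiles:
                xs.append(profiles[(pid, earlier)].count)
                ys.append(profiles[(pid, later)].count)
        ax.plot([0, 31], [0, 31], "k--", lw=0.8)
        ax.plot(xs, ys, "o")
        ax.set_xlabel(f"divergences ({earlier})")
        ax.set_ylabel(f"divergences ({later})")
        ax.set_xlim(-1, 32)
        ax.set_ylim(-1, 32)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_change_heatmap(records: list[ChangeRecord], path: str | Path) -> None:
    """Per-metric signed-change heat map grouped into clusters A-F."""
    df = metric_change_matrix(records)
    fig, ax = plt.subplots(
        figsize=(0.32 * df.shape[1] + 2, 0.32 * df.shape[0] + 2)
    )
    vmax = np.nanmax(np.abs(df.values)) if df.size else 1.0
    im = ax.imshow(df.values, cmap="RdBu", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(df.shape[1]))
    ax.set_xticklabels([m for _, m in df.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(df.shape[0]))
    ax.set_yticklabels([f"{p} {pair}" for p, pair in df.index], fontsize=6)
    fig.colorbar(im, ax=ax, label="change (control-SD units, + = toward control)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
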