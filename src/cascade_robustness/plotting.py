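"""Optional matplotlib views of sweep results.

Plotting is best-effort: any failure is logged and swallowed so that the
numeric outputs of a pipeline run are never affected.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["plot_sweep", "plot_profiles"]


def _savefig(fig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")


def plot_sweep(result, out_dir, stem: str = "sweep"):
    """Duration, similarity and gain versus the swept parameter.

    Writes ``<stem>_duration.png``, ``<stem>_similarity.png`` and
    ``<stem>_gain.png`` under ``out_dir``; returns the written paths (or an
    empty list on failure).
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rec = result.records
        v = rec["param_value"].to_numpy()
        written = []

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.loglog(v, rec["duration"], "k.-")
        if result.crossover is not None:
            ax.axvline(result.crossover, color="magenta", ls=":", label="min-rate crossover")
        for iv in result.robust_intervals:
            ax.axvspan(iv.lower, iv.upper, color="tab:blue", alpha=0.15)
        ax.set_xlabel("swept parameter")
        ax.set_ylabel("half-life")
        p = Path(out_dir) / f"{stem}_duration.png"
        _savefig(fig, p)
        plt.close(fig)
        written.append(p)

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.semilogx(v, rec["similarity"], "k.-")
        ax.axhline(0.3, color="gray", ls="--")
        ax.set_xlabel("swept parameter")
        ax.set_ylabel("consecutive similarity")
        p = Path(out_dir) / f"{stem}_similarity.png"
        _savefig(fig, p)
        plt.close(fig)
        written.append(p)

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.semilogx(v, rec["gain"], "k.-")
        for y in (-0.3, 0.3):
            ax.axhline(y, color="gray", ls="--")
        ax.axhline(-1.0, color="tab:red", ls=":")
        ax.set_xlabel("swept parameter")
        ax.set_ylabel("log gain of half-life")
        p = Path(out_dir) / f"{stem}_gain.png"
        _savefig(fig, p)
        plt.close(fig)
        written.append(p)
        return written
    except Exception as exc:
        logger.warning("plotting failed (numeric results unaffected): %s", exc)
        return []


def plot_profiles(trajectories, out_path, labels=None):
    """Fan of output profiles against log10(t)."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        cmap = plt.get_cmap("viridis")
        n = max(len(trajectories) - 1, 1)
        for i, traj in enumerate(trajectories):
            label = labels[i] if labels else None
            ax.plot(traj.tau_grid, traj.output, color=cmap(i / n), lw=1, label=label)
        ax.set_xlabel(r"$\log_{10}(t)$")
        ax.set_ylabel("output")
        if labels:
            ax.legend(fontsize=7)
        _savefig(fig, Path(out_path))
        plt.close(fig)
        return [Path(out_path)]
    except Exception as exc:
        logger.warning("plotting failed (numeric results unaffected): %s", exc)
        return []
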