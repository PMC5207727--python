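"""Small matplotlib helpers for the standard figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_size_spectrum(histogram, peakset=None, path=None, ax=None):
    """Fragment-size density with local maxima marked by dashed lines."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 3.5))
    grid, dense = histogram.dense()
    ax.plot(grid, dense / max(histogram.n_total, 1), lw=0.8, color="tab:blue")
    if peakset is not None:
        for p in peakset.peak_positions:
            ax.axvline(p, ls="--", lw=0.5, color="grey")
    ax.set_xlabel("insert size (bp)")
    ax.set_ylabel("density")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_boundary_profile(profile, path=None, ax=None):
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 3.5))
    x = profile.window_centers
    ax.plot(x, profile.freq_5p, lw=0.8, label="5' boundaries")
    ax.plot(x, profile.freq_3p, lw=0.8, label="3' boundaries")
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel(f"position relative to {profile.anchor_class or 'anchor'} (bp)")
    ax.set_ylabel("boundaries per anchor per 5 bp")
    ax.legend(frameon=False)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_depth_profile(profile, path=None, ax=None):
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(profile.rel_pos, profile.norm_depth, lw=0.8, color="tab:orange")
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel(f"position relative to {profile.anchor_class or 'anchor'} (bp)")
    ax.set_ylabel("depth / regional mean")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_cnv(profile, segments=None, path=None, ax=None):
    """Per-window log2 ratio with segment means overlaid in red."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(8, 3))
    idx = np.arange(profile.log2_ratio.size)
    ax.plot(idx[profile.valid], profile.log2_ratio[profile.valid], ".",
            ms=2, color="tab:blue", alpha=0.5)
    ax.axhline(0.0, color="grey", lw=0.7)
    if segments is not None:
        for s in segments.segments:
            ax.plot([s.start_window, s.end_window - 1],
                    [s.mean_log2, s.mean_log2], color="red", lw=1.5)
    ax.set_xlabel("10 kb window index")
    ax.set_ylabel("log2 ratio")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
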