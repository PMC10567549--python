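"""Optional plots: overlap spectrum bars and phasing metaplot with
autocorrelation inset."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .signatures import OverlapSpectrum, PhasingProfile


def plot_spectrum(spectrum: OverlapSpectrum, z: float, p: float,
                  path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    offsets = np.arange(len(spectrum.counts))
    colors = ["#c0392b" if o == 10 else "#7f8c8d" for o in offsets]
    ax.bar(offsets, spectrum.counts, color=colors)
    ax.set_xlabel("5′–5′ overlap (nt)")
    ax.set_ylabel(f"{spectrum.weighting}-weighted pairs")
    ax.set_title(f"$Z_{{10}}$ = {z:.1f}, P = {p:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_metaplot(profile: PhasingProfile, autocorr: np.ndarray | None,
                  path: str | Path) -> None:
    ncols = 2 if autocorr is not None else 1
    fig, axes = plt.subplots(1, ncols, figsize=(4 * ncols, 3))
    ax = axes[0] if ncols == 2 else axes
    x = np.arange(len(profile.median))
    lo = profile.median - profile.iqr / 2
    hi = profile.median + profile.iqr / 2
    ax.fill_between(x, lo, hi, color="#bdc3c7", label="IQR")
    ax.plot(x, profile.median, color="black", lw=1, label="median")
    ax.set_xlabel("distance from pre-pre-piRNA 5′ end (nt)")
    ax.set_ylabel("piRNA 5′-end density")
    ax.legend(frameon=False, fontsize=8)
    if autocorr is not None:
        ax2 = axes[1]
        lags = np.arange(1, len(autocorr))
        ax2.plot(lags, autocorr[1:], color="#2c3e50")
        ax2.axhline(0, color="#95a5a6", lw=0.5)
        ax2.set_xlabel("lag (nt)")
        ax2.set_ylabel("autocorrelation r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
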