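"""Report figures: Bland-Altman, trend, per-site box plots, VOI histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .evaluate import BlandAltmanResult  # noqa: E402

__all__ = ["bland_altman_plot", "trend_plot", "diffmax_boxplot",
           "voi_suv_histogram"]


def bland_altman_plot(pairs, result: BlandAltmanResult, path) -> None:
    arr = np.asarray(pairs, dtype=float)
    mean_ab = arr.mean(axis=1)
    diff = arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean_ab, diff, s=18)
    for yv, style in ((result.mean_difference, "-"),
                      (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of SUV Error Ratios")
    ax.set_ylabel("difference (original - synthetic)")
    ax.set_title("Bland-Altman: SUV Error Ratio agreement")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def trend_plot(diameters, ler, slope: float, r2: float, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(diameters, ler, s=18)
    xs = np.linspace(min(diameters), max(diameters), 50)
    inter = float(np.mean(ler) - slope * np.mean(diameters))
    ax.plot(xs, slope * xs + inter, "k--", linewidth=1,
            label=f"slope={slope:.4f}, R$^2$={r2:.3f}")
    ax.axhline(1.0, color="grey", linewidth=0.8)
    ax.set_xlabel("lesion diameter (mm)")
    ax.set_ylabel("Lesion Error Ratio")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def diffmax_boxplot(site_to_values: dict[str, list[float]], path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 4))
    names = list(site_to_values)
    ax.boxplot([site_to_values[n] for n in names], tick_labels=names)
    ax.axhline(0.0, color="grey", linewidth=0.8)
    ax.set_ylabel("max SUV difference (%)")
    ax.set_title("diff%max per anatomical target")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def voi_suv_histogram(suv_ctac, suv_mrac, site_name: str, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    bins = np.histogram_bin_edges(np.concatenate([suv_ctac, suv_mrac]), 20)
    ax.hist(suv_ctac, bins=bins, alpha=0.6, label="SUV CTAC")
    ax.hist(suv_mrac, bins=bins, alpha=0.6, label="SUV MRAC")
    ax.set_xlabel("SUV")
    ax.set_ylabel("voxels")
    ax.set_title(site_name)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
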