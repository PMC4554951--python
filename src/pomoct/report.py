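"""Derived figures and aggregate summaries from pipeline CSV outputs.

Plots are presentation artifacts only; every number in ``summary.json`` is
read back from the CSVs the analysis commands wrote.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def make_report(results_dir, out_dir) -> dict:
    """Render figures for whatever result CSVs exist and aggregate them.

    Recognizes ``results.csv`` (morphometry rows), ``distribution.csv``
    (cumulative void-size curves), ``metrics.csv`` (network metrics),
    ``branch_radial.csv`` and ``density_radial.csv`` (radial profiles).
    """
    results_dir = Path(results_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    found = False

    res_files = sorted(results_dir.rglob("results.csv"))
    if res_files:
        found = True
        rows = pd.concat([_read_csv(p) for p in res_files], ignore_index=True)
        summary["morphometry_rows"] = len(rows)
        summary["porosity_pct"] = rows["porosity_pct"].tolist()
        fig, axes = plt.subplots(2, 4, figsize=(16, 7))
        for ax, col in zip(axes.ravel(), [c for c in rows.columns if c != "sample_volume_mm3"]):
            ax.plot(rows.index, rows[col], "o-")
            ax.set_xlabel("sample")
            ax.set_title(col, fontsize=9)
        fig.tight_layout()
        fig.savefig(out / "morphometry.png", dpi=110)
        plt.close(fig)

    dist_files = sorted(results_dir.rglob("distribution.csv"))
    if dist_files:
        found = True
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        n = 0
        for p in dist_files:
            d = _read_csv(p)
            n = max(n, len(d))
            axes[0].plot(d["equivalent_diameter_mm"], d["cumulative_volume_fraction"],
                         drawstyle="steps-post")
            axes[1].plot(d["equivalent_diameter_mm"], d["cumulative_frequency_fraction"],
                         drawstyle="steps-post")
        axes[0].set_ylabel("cumulative volume fraction")
        axes[1].set_ylabel("cumulative frequency fraction")
        for ax in axes:
            ax.set_xlabel("equivalent void diameter (mm)")
            ax.set_ylim(0, 1.02)
        fig.tight_layout()
        fig.savefig(out / "void_size_distribution.png", dpi=110)
        plt.close(fig)
        summary["n_voids_largest_distribution"] = int(n)

    met_files = sorted(results_dir.rglob("metrics.csv"))
    if met_files:
        found = True
        rows = pd.concat([_read_csv(p) for p in met_files], ignore_index=True)
        summary["network_total_length_m"] = rows["total_length_m"].tolist()
        summary["network_density_cm_per_cm3"] = rows["length_density_cm_per_cm3"].tolist()

    br_files = sorted(results_dir.rglob("branch_radial.csv"))
    if br_files:
        found = True
        fig, ax = plt.subplots(figsize=(5, 4))
        for p in br_files:
            d = _read_csv(p)
            centers = 0.5 * (d["shell_low_r_over_R"] + d["shell_high_r_over_R"])
            width = (d["shell_high_r_over_R"] - d["shell_low_r_over_R"]).iloc[0]
            ax.bar(centers, d["branch_point_count"], width=0.9 * width, alpha=0.6)
        ax.set_xlabel("relative radial position r/R")
        ax.set_ylabel("branch points per shell")
        fig.tight_layout()
        fig.savefig(out / "branch_radial.png", dpi=110)
        plt.close(fig)
        summary["branch_radial_bins"] = int(len(_read_csv(br_files[0])))

    de_files = sorted(results_dir.rglob("density_radial.csv"))
    if de_files:
        found = True
        fig, ax = plt.subplots(figsize=(5, 4))
        for p in de_files:
            d = _read_csv(p)
            centers = 0.5 * (d["shell_low_mm"] + d["shell_high_mm"])
            ax.plot(centers, d["vessel_density_cm_per_cm3"], "o-")
        ax.set_xlabel("radial distance (mm)")
        ax.set_ylabel("vessel density (cm per cm³)")
        fig.tight_layout()
        fig.savefig(out / "density_radial.png", dpi=110)
        plt.close(fig)

    if not found:
        raise FileNotFoundError(f"no recognized result CSVs under {results_dir}")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
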