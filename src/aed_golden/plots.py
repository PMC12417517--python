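"""Small plotting helpers for the pipeline artifacts (matplotlib, Agg)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coverage import CoverageProfile, TargetState
from .optimize import RadiusSearchResult


def plot_profile(profile: CoverageProfile, target: TargetState, path) -> None:
    """Benefit-profile curves: mean accessible devices and percent covered
    versus radius, with the target state marked."""
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(profile.radii, profile.avg_devices, "o-", color="tab:blue", label="avg devices")
    ax1.axhline(target.target_avg, color="tab:blue", ls=":", lw=1)
    ax1.set_xlabel("radius (m)")
    ax1.set_ylabel("mean accessible devices", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(profile.radii, profile.pct_covered, "s-", color="tab:red", label="% covered")
    ax2.axhline(target.target_pct, color="tab:red", ls=":", lw=1)
    ax2.set_ylabel("% of cases covered", color="tab:red")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_objective(result: RadiusSearchResult, path) -> None:
    """Objective curve with the best radius and its 5% band."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.curve["radius_m"], result.curve["J"], "o-")
    ax.axvline(result.best_radius, color="k", ls="--", lw=1,
               label=f"best {result.best_radius:.0f} m")
    ax.axvspan(*result.band, color="0.85", zorder=0)
    ax.set_xlabel("radius (m)")
    ax.set_ylabel("objective J")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_city(event_xy: np.ndarray, device_xy: np.ndarray, region, path) -> None:
    """Scatter map of events and devices over the region outline."""
    fig, ax = plt.subplots(figsize=(6, 6))
    x, y = region.exterior.xy
    ax.plot(x, y, "k-", lw=1)
    ax.scatter(device_xy[:, 0], device_xy[:, 1], s=6, c="tab:green", label="devices")
    ax.scatter(event_xy[:, 0], event_xy[:, 1], s=4, c="tab:red", alpha=0.5, label="events")
    ax.set_aspect("equal")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_placement(outcome, coverage_radius: float, region, path) -> None:
    """Before/after placement with coverage disks."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 5), sharex=True, sharey=True)
    for ax, pts, title, area in (
            (axes[0], outcome.baseline_points, "baseline", outcome.baseline_area_km2),
            (axes[1], outcome.simulated_points, "simulated", outcome.simulated_area_km2)):
        x, y = region.exterior.xy
        ax.plot(x, y, "k-", lw=1)
        for p in pts:
            ax.add_patch(plt.Circle(p, coverage_radius, alpha=0.2, color="tab:blue"))
        ax.scatter(pts[:, 0], pts[:, 1], s=8, c="k")
        ax.set_title(f"{title}: {area:.2f} km$^2$")
        ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
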