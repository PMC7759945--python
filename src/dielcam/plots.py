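"""Diel activity figures: density panels and rose diagrams.

Matplotlib is imported lazily so headless pipelines never touch a display
backend unless a figure is requested.
"""

from __future__ import annotations

import numpy as np

from ._util import TWO_PI, radians_to_hours
from .density import rose_bins, trig_sum_density, vm_kernel_density
from .events import EventSeries, SolarSchedule


def activity_panel(series: EventSeries, solar: SolarSchedule | None = None, ax=None):
    """Kernel (solid) and trigonometric-sum (dashed) densities over clock
    hours, with a rug of event times and twilight/sunrise/sunset guides."""
    import matplotlib.pyplot as plt

    solar = solar or SolarSchedule()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.2))
    kde = vm_kernel_density(series.times)
    trig = trig_sum_density(series.times)
    hours = radians_to_hours(kde.grid)
    order = np.argsort(hours)
    scale = TWO_PI / 24.0  # density per radian -> per hour
    ax.plot(hours[order], kde.values[order] * scale, "-", lw=1.5, label="kernel")
    ax.plot(hours[order], trig.values[order] * scale, "--", lw=1.2, label="trig sum")
    ax.plot(series.hours, np.zeros(series.n), "|", color="k", ms=6, alpha=0.5)
    for anchor in (solar.sunrise, solar.sunset):
        for x in (anchor - solar.twilight_halfwidth, anchor, anchor + solar.twilight_halfwidth):
            ax.axvline(x, color="grey", ls=":", lw=0.8)
    ax.set_xlim(0, 24)
    ax.set_xticks(range(0, 25, 6))
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel("density (h$^{-1}$)")
    ax.set_title(f"{series.species} (n = {series.n})")
    ax.legend(frameon=False, fontsize=8)
    return ax


def rose_diagram(series: EventSeries, n_bins: int = 24, ax=None):
    """Polar rose of relative frequencies per class interval, midnight at
    the top, clockwise."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(3.5, 3.5))
    freqs = rose_bins(series.times, n_bins)
    width = TWO_PI / n_bins
    centers = (np.arange(n_bins) + 0.5) * width
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.bar(centers, freqs, width=width, edgecolor="k", lw=0.4, alpha=0.7)
    ax.set_xticks(np.linspace(0, TWO_PI, 8, endpoint=False))
    ax.set_xticklabels([f"{int(h)}h" for h in np.linspace(0, 24, 8, endpoint=False)])
    ax.set_title(series.species, fontsize=9)
    return ax
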