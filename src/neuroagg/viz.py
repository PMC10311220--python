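"""Raster-plot rendering for spike trains with optional burst shading."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .bursts import Burst
from .ephys import SpikeTrain

__all__ = ["raster_plot"]


def raster_plot(
    trains: Sequence[SpikeTrain],
    bursts: Optional[Dict[str, List[Burst]]] = None,
    path=None,
):
    """Render one raster row per electrode; detected bursts are shaded.

    Returns the matplotlib figure; if ``path`` is given the figure is
    also saved (format from the extension, e.g. .png or .svg).
    """
    fig, ax = plt.subplots(figsize=(10, 0.4 * max(len(trains), 4) + 1.5))
    for row, train in enumerate(trains):
        ax.vlines(train.times, row + 0.6, row + 1.4, color="k", lw=0.5)
        for b in (bursts or {}).get(train.electrode_id, []):
            ax.axvspan(b.t_start, b.t_end, ymin=(row + 0.55) / (len(trains) + 1),
                       ymax=(row + 1.45) / (len(trains) + 1), color="tab:orange", alpha=0.3)
    ax.set_yticks([r + 1 for r in range(len(trains))])
    ax.set_yticklabels([t.electrode_id for t in trains])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("electrode")
    ax.set_ylim(0, len(trains) + 1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
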