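"""ISI-based burst detection and burst-structure metrics.

A burst is a run of at least ``min_spikes`` spikes opened by an
interspike interval at or below ``isi_init`` (default 100 ms) and
sustained while subsequent ISIs stay at or below ``isi_continue``
(default 250 ms) -- the max-interval convention used for in vitro
hippocampal cultures.  Burstiness is the fraction of all spikes that
fall inside detected bursts, so a fully bursting electrode scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .ephys import SpikeTrain

__all__ = ["BurstParams", "Burst", "BurstMetrics", "detect_bursts", "burst_metrics"]


@dataclass
class BurstParams:
    min_spikes: int = 5
    isi_init: float = 0.1
    isi_continue: float = 0.25

    def __post_init__(self) -> None:
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")
        if not 0 < self.isi_init <= self.isi_continue:
            raise ValueError("require 0 < isi_init <= isi_continue")


@dataclass
class Burst:
    """A detected run of spikes: indices into the parent train plus timing."""

    start_index: int
    end_index: int
    t_start: float
    t_end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class BurstMetrics:
    bursts_per_minute: float
    mean_spikes_per_burst: float
    mean_burst_duration: float
    mean_interburst_interval: float
    burstiness: float
    n_bursts: int


def detect_bursts(train: SpikeTrain, params: BurstParams | None = None) -> List[Burst]:
    """Scan a spike train's ISI sequence for bursts.

    A candidate opens at spike ``i`` when ISI(i -> i+1) <= isi_init,
    extends while following ISIs <= isi_continue, and closes at the
    first ISI above isi_continue (or at the train end).  Candidates with
    fewer than ``min_spikes`` spikes are discarded; scanning resumes
    after the closing gap, so no spike joins two bursts.
    """
    params = params or BurstParams()
    t = train.times
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    n = t.size
    isi = np.diff(t)
    bursts: List[Burst] = []
    i = 0
    while i < n - 1:
        if isi[i] <= params.isi_init:
            j = i + 1
            while j < n - 1 and isi[j] <= params.isi_continue:
                j += 1
            count = j - i + 1
            if count >= params.min_spikes:
                bursts.append(
                    Burst(
                        start_index=i,
                        end_index=j,
                        t_start=float(t[i]),
                        t_end=float(t[j]),
                        n_spikes=count,
                    )
                )
            i = j + 1
        else:
            i += 1
    return bursts


def burst_metrics(train: SpikeTrain, bursts: List[Burst]) -> BurstMetrics:
    """Summary statistics over the bursts detected in one train.

    The interburst interval is measured end-to-start (gap between
    consecutive bursts).  With zero bursts, burstiness is 0 and the
    per-burst means are NaN; an empty train is an error because
    burstiness is undefined on zero spikes.
    """
    n_total = train.n_spikes
    if n_total == 0:
        raise ValueError("burstiness is undefined for an empty spike train")
    if train.duration <= 0:
        raise ValueError("train duration must be positive")
    n_bursts = len(bursts)
    in_burst = sum(b.n_spikes for b in bursts)
    if in_burst > n_total:
        raise ValueError("bursts contain more spikes than the train")
    bpm = n_bursts / (train.duration / 60.0)
    if n_bursts:
        mean_spb = in_burst / n_bursts
        mean_dur = float(np.mean([b.duration for b in bursts]))
    else:
        mean_spb = float("nan")
        mean_dur = float("nan")
    if n_bursts >= 2:
        ibis = [bursts[k + 1].t_start - bursts[k].t_end for k in range(n_bursts - 1)]
        mean_ibi = float(np.mean(ibis))
    else:
        mean_ibi = float("nan")
    return BurstMetrics(
        bursts_per_minute=float(bpm),
        mean_spikes_per_burst=float(mean_spb),
        mean_burst_duration=mean_dur,
        mean_interburst_interval=mean_ibi,
        burstiness=in_burst / n_total,
        n_bursts=n_bursts,
    )
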