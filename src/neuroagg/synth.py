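"""Synthetic data with exact ground truth for every analysis stage.

Each generator is a pure function of its spec (including the seed) and
returns both the data object and a :class:`GroundTruth` record holding
the exact quantities the corresponding analysis stage should recover:
burst-structured spike trains, noisy voltage traces with embedded
biphasic spike waveforms, two-channel image pairs with constructively
exact pixel-overlap counts, and branching arbor trees with known branch
and junction counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .ephys import SpikeTrain, VoltageTrace
from .coloc import ImagePair
from .morpho import Arbor, MorphometricsResult, MorphometryParams

__all__ = [
    "SpikeTrainSpec",
    "VoltageSpec",
    "ImagePairSpec",
    "ArborSpec",
    "GroundTruth",
    "gen_spike_train",
    "gen_benchmark_spike_times",
    "gen_voltage_trace",
    "gen_image_pair",
    "gen_arbor",
    "gen_super_burst_train",
]

# noise spikes are kept at least this far from burst windows and from
# each other, so they can neither extend a burst (continuation ISI is
# 250 ms) nor chain into one of their own
_NOISE_GUARD = 0.3


@dataclass
class GroundTruth:
    """Exact expected outputs paired with a generated input."""

    true_spike_times: Optional[np.ndarray] = None
    true_burst_windows: Optional[List[Tuple[float, float]]] = None
    true_M1: Optional[float] = None
    true_M2: Optional[float] = None
    true_mask_a: Optional[np.ndarray] = None
    true_mask_b: Optional[np.ndarray] = None
    true_morphometrics: Optional[MorphometricsResult] = None


@dataclass
class SpikeTrainSpec:
    """Burst-structured spike train: n_bursts regular bursts plus noise spikes."""

    n_bursts: int = 10
    spikes_per_burst: int = 8
    intra_burst_isi: float = 0.03
    inter_burst_gap: float = 2.0
    n_noise_spikes: int = 0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bursts < 0 or self.n_noise_spikes < 0:
            raise ValueError("counts must be non-negative")
        if self.n_bursts and self.spikes_per_burst < 1:
            raise ValueError("spikes_per_burst must be >= 1")
        if self.intra_burst_isi <= 0:
            raise ValueError("intra_burst_isi must be positive")
        if self.inter_burst_gap <= self.intra_burst_isi:
            raise ValueError("inter_burst_gap must exceed intra_burst_isi")
        needed = (
            self.n_bursts * (self.spikes_per_burst - 1) * self.intra_burst_isi
            + self.n_bursts * self.inter_burst_gap
        )
        if self.duration < needed:
            raise ValueError(
                f"duration {self.duration}s cannot fit {self.n_bursts} bursts "
                f"(needs >= {needed}s)"
            )


def gen_spike_train(spec: SpikeTrainSpec) -> Tuple[SpikeTrain, GroundTruth]:
    """Deterministic bursts at regular ISI, plus seeded isolated noise spikes.

    Burst k starts at gap/2 + k*(burst span + gap); noise spikes are
    rejection-sampled at least 0.3 s away from every burst window and
    from each other, so they never merge with or form bursts under the
    default detection rules.
    """
    rng = np.random.default_rng(spec.seed)
    burst_span = (spec.spikes_per_burst - 1) * spec.intra_burst_isi
    windows: List[Tuple[float, float]] = []
    times: List[float] = []
    for k in range(spec.n_bursts):
        t0 = spec.inter_burst_gap / 2.0 + k * (burst_span + spec.inter_burst_gap)
        windows.append((t0, t0 + burst_span))
        times.extend(t0 + i * spec.intra_burst_isi for i in range(spec.spikes_per_burst))

    noise: List[float] = []
    tries = 0
    while len(noise) < spec.n_noise_spikes:
        tries += 1
        if tries > 10000 * max(spec.n_noise_spikes, 1):
            raise ValueError("could not place noise spikes clear of burst windows")
        t = float(rng.uniform(0.0, spec.duration))
        if any(w0 - _NOISE_GUARD <= t <= w1 + _NOISE_GUARD for w0, w1 in windows):
            continue
        if any(abs(t - u) < _NOISE_GUARD for u in noise):
            continue
        noise.append(t)

    all_times = np.sort(np.array(times + noise, dtype=float))
    train = SpikeTrain("synthetic", all_times, spec.duration)
    return train, GroundTruth(true_spike_times=all_times, true_burst_windows=windows)


def gen_super_burst_train(
    duration_short: float = 20.0,
    duration_dense: float = 20.0,
    short_isi: float = 0.2,
    dense_isi: float = 0.07,
    seed: int = 0,
) -> Tuple[SpikeTrain, float]:
    """Two-epoch train mimicking a 'super burst': short bursts at a slow
    within-burst rate (~5 Hz) followed by one long dense burst (~14 Hz).

    Returns the train and the epoch boundary time.  The spectrogram of
    the rectified rendered voltage shifts its dominant low-frequency
    band from 2-10 Hz to 10-20 Hz across the boundary.
    """
    times: List[float] = []
    t = 1.0
    while t + 4 * short_isi < duration_short - 1.0:
        times.extend(t + i * short_isi for i in range(5))
        t += 5 * short_isi + 0.6
    t = duration_short + 1.0
    while t < duration_short + duration_dense - 1.0:
        times.append(t)
        t += dense_isi
    total = duration_short + duration_dense
    return SpikeTrain("superburst", np.array(times), total), duration_short


def gen_benchmark_spike_times(
    n_spikes: int = 100,
    duration: float = 10.0,
    min_gap: float = 0.005,
    edge_margin: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Random spike times for the spike-detection benchmark.

    Uniform over the recording, at least ``min_gap`` apart (well above
    the detector's dead time) and clear of the trace edges where the
    zero-phase filter has transients.
    """
    if n_spikes * min_gap > duration - 2 * edge_margin:
        raise ValueError("cannot fit that many spikes at the requested spacing")
    rng = np.random.default_rng(seed)
    # sample gaps then rescale: n ordered times with guaranteed spacing
    slack = (duration - 2 * edge_margin) - (n_spikes - 1) * min_gap
    u = np.sort(rng.uniform(0.0, slack, n_spikes))
    return edge_margin + u + min_gap * np.arange(n_spikes)


@dataclass
class VoltageSpec:
    """Noisy extracellular trace with embedded biphasic spike waveforms."""

    sampling_rate: float = 12500.0
    duration: float = 600.0
    noise_sigma: float = 5.0
    spike_amplitude: float = -60.0
    spike_width: float = 0.0012
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.spike_width * self.sampling_rate < 4:
            raise ValueError("spike_width must span at least 4 samples")


def _biphasic_template(n_samples: int, amplitude: float) -> Tuple[np.ndarray, int]:
    """Biphasic waveform (leading lobe 2x the trailing, opposite sign).

    Returns (template, index of the extremum sample).  For a negative
    ``amplitude`` the leading lobe is negative with peak = amplitude.
    """
    tt = np.arange(n_samples) / n_samples
    shape = -np.sin(2 * np.pi * tt) * np.where(tt < 0.5, 1.0, 0.5)
    if amplitude < 0:
        tmpl = shape * (-amplitude)
    else:
        tmpl = -shape * amplitude
    return tmpl, int(np.argmax(np.abs(tmpl)))


def gen_voltage_trace(
    spike_times, spec: VoltageSpec
) -> Tuple[VoltageTrace, GroundTruth]:
    """Render spike times into a noisy voltage trace.

    Each spike becomes a biphasic template whose extremum sample sits at
    the spike time; i.i.d. Gaussian noise of sd ``noise_sigma`` is
    added.  Raises if spikes are requested at zero amplitude (the truth
    would be undetectable).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size and spec.spike_amplitude == 0:
        raise ValueError("spike_amplitude of 0 makes the ground truth undetectable")
    if spike_times.size and (
        np.any(spike_times < 0) or np.any(spike_times > spec.duration)
    ):
        raise ValueError("spike times must lie within [0, duration]")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    x = rng.normal(0.0, spec.noise_sigma, n) if spec.noise_sigma > 0 else np.zeros(n)
    nw = int(round(spec.spike_width * spec.sampling_rate))
    tmpl, peak = _biphasic_template(nw, spec.spike_amplitude)
    for t in spike_times:
        start = int(round(t * spec.sampling_rate)) - peak
        lo, hi = max(start, 0), min(start + nw, n)
        if hi > lo:
            x[lo:hi] += tmpl[lo - start : hi - start]
    trace = VoltageTrace(x, spec.sampling_rate, "synthetic")
    return trace, GroundTruth(true_spike_times=np.sort(spike_times))


@dataclass
class ImagePairSpec:
    """Two-channel image with an exact, integer pixel-overlap count."""

    shape: Tuple[int, int] = (128, 128)
    n_signal_a: int = 200
    n_signal_b: int = 200
    overlap_fraction: float = 0.5
    fg_intensity: float = 200.0
    bg_intensity: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_pix = self.shape[0] * self.shape[1]
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        n_ov = self.n_signal_a * self.overlap_fraction
        if abs(n_ov - round(n_ov)) > 1e-9:
            raise ValueError(
                "n_signal_a * overlap_fraction must be an integer for exact truth"
            )
        if self.fg_intensity <= self.bg_intensity:
            raise ValueError("fg_intensity must exceed bg_intensity")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        n_union = self.n_signal_a + self.n_signal_b - int(round(n_ov))
        if n_union > n_pix or self.n_signal_a > n_pix or self.n_signal_b > n_pix:
            raise ValueError("signal pixel counts exceed the image size")

    @property
    def n_overlap(self) -> int:
        return int(round(self.n_signal_a * self.overlap_fraction))


def gen_image_pair(spec: ImagePairSpec) -> Tuple[ImagePair, GroundTruth]:
    """Construct a channel pair with exact foreground/overlap pixel counts.

    Foreground pixels are sampled without replacement: the first
    ``n_overlap`` carry both channels, so true M1 = overlap/n_signal_a
    and true M2 = overlap/n_signal_b hold exactly.  Gaussian noise (if
    any) is added afterwards and clipped at zero.
    """
    n_ov = spec.n_overlap
    if n_ov > min(spec.n_signal_a, spec.n_signal_b):
        raise ValueError("required overlap exceeds the smaller channel's pixel count")
    rng = np.random.default_rng(spec.seed)
    n_pix = spec.shape[0] * spec.shape[1]
    n_union = spec.n_signal_a + spec.n_signal_b - n_ov
    chosen = rng.choice(n_pix, size=n_union, replace=False)
    both = chosen[:n_ov]
    only_a = chosen[n_ov : spec.n_signal_a]
    only_b = chosen[spec.n_signal_a :]

    mask_a = np.zeros(n_pix, dtype=bool)
    mask_b = np.zeros(n_pix, dtype=bool)
    mask_a[both] = mask_a[only_a] = True
    mask_b[both] = mask_b[only_b] = True

    def render(mask: np.ndarray) -> np.ndarray:
        img = np.full(n_pix, spec.bg_intensity)
        img[mask] = spec.fg_intensity
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, n_pix)
        return np.clip(img, 0.0, None).reshape(spec.shape)

    pair = ImagePair(render(mask_a), render(mask_b))
    truth = GroundTruth(
        true_M1=n_ov / spec.n_signal_a if spec.n_signal_a else float("nan"),
        true_M2=n_ov / spec.n_signal_b if spec.n_signal_b else float("nan"),
        true_mask_a=mask_a.reshape(spec.shape),
        true_mask_b=mask_b.reshape(spec.shape),
    )
    return pair, truth


@dataclass
class ArborSpec:
    """Radially arranged main branches with side branches at known junctions.

    Each main branch is a trunk of ``junctions_per_branch + 1`` segments
    of ``segment_length``; one side branch of ``side_branch_length``
    (default: segment_length) leaves each interior trunk node.  Angles
    are jittered within ``branch_angle_spread``; all lengths are exact,
    so the morphometric ground truth is computed constructively from the
    spec, not from the coordinates.
    """

    n_main_branches: int = 3
    junctions_per_branch: int = 2
    segment_length: float = 20.0
    branch_angle_spread: float = 20.0
    side_branch_length: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_main_branches < 0 or self.junctions_per_branch < 0:
            raise ValueError("counts must be non-negative")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.side_branch_length is not None and self.side_branch_length <= 0:
            raise ValueError("side_branch_length must be positive")
        if self.branch_angle_spread < 0:
            raise ValueError("branch_angle_spread must be non-negative")


def _arbor_truth(spec: ArborSpec, params: MorphometryParams) -> MorphometricsResult:
    """Morphometric ground truth derived from the spec's exact lengths."""
    L = spec.segment_length
    side = spec.side_branch_length if spec.side_branch_length is not None else L
    n_seg = spec.junctions_per_branch + 1
    trunk_len = n_seg * L

    # depth below trunk node i (i segments from the soma), walking back
    # from the terminal; a side branch longer than the remaining trunk
    # re-routes the longest path
    depth = 0.0
    junctions_per_trunk = 0
    for i in range(n_seg - 1, 0, -1):
        via_trunk = L + depth
        side_path = min(side, via_trunk)
        if side_path >= params.min_junction_branch:
            junctions_per_trunk += 1
        depth = max(via_trunk, side)
    branch_extent = L + depth  # max soma-to-terminal path per main branch

    include = junctions_per_trunk > 0 or branch_extent >= params.min_main_branch
    n_main = spec.n_main_branches if include else 0
    longest = branch_extent if include and spec.n_main_branches else 0.0
    total = spec.n_main_branches * (trunk_len + spec.junctions_per_branch * side)
    return MorphometricsResult(
        n_main_branches=n_main,
        longest_main_branch=float(longest),
        total_process_length=float(total),
        n_junctions=spec.n_main_branches * junctions_per_trunk,
    )


def gen_arbor(
    spec: ArborSpec, params: MorphometryParams | None = None
) -> Tuple[Arbor, GroundTruth]:
    """Generate a planar arbor tree (z = 0) with known morphometrics.

    The soma is node 1 at the origin; trunks radiate at evenly spaced
    base angles with seeded per-segment jitter.  Side-branch headings
    alternate +/-65 degrees off the trunk.  Same seed, same spec ->
    identical arbor (and byte-identical SWC output).
    """
    params = params or MorphometryParams()
    rng = np.random.default_rng(spec.seed)
    spread = math.radians(spec.branch_angle_spread)
    side_len = spec.side_branch_length if spec.side_branch_length is not None else spec.segment_length

    ids = [1]
    xyz = [(0.0, 0.0, 0.0)]
    parents = [-1]
    types = [1]  # soma
    radii = [5.0]
    next_id = 2

    def add_node(parent_id: int, pos: Tuple[float, float, float]) -> int:
        nonlocal next_id
        ids.append(next_id)
        xyz.append(pos)
        parents.append(parent_id)
        types.append(3)
        radii.append(1.0)
        next_id += 1
        return next_id - 1

    n_seg = spec.junctions_per_branch + 1
    for k in range(spec.n_main_branches):
        base = 2 * math.pi * k / max(spec.n_main_branches, 1)
        angle = base + rng.uniform(-spread / 2, spread / 2)
        pos = np.zeros(3)
        parent = 1
        side_sign = 1.0
        for i in range(n_seg):
            angle += rng.uniform(-spread / 2, spread / 2) if i else 0.0
            pos = pos + spec.segment_length * np.array(
                [math.cos(angle), math.sin(angle), 0.0]
            )
            parent = add_node(parent, tuple(pos))
            if i < n_seg - 1:  # interior trunk node: attach the side branch
                side_angle = angle + side_sign * math.radians(65.0)
                side_sign = -side_sign
                side_pos = pos + side_len * np.array(
                    [math.cos(side_angle), math.sin(side_angle), 0.0]
                )
                add_node(parent, tuple(side_pos))

    arbor = Arbor(
        ids=np.array(ids),
        xyz=np.array(xyz, dtype=float),
        parents=np.array(parents),
        types=np.array(types),
        radii=np.array(radii, dtype=float),
    )
    return arbor, GroundTruth(true_morphometrics=_arbor_truth(spec, params))
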