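"""Synthetic sensor arrays, labeled cortical meshes, and simulated task sessions.

Everything downstream of raw data acquisition is testable against ground truth
produced here: a helmet-like array of sensor loci (each carrying a gradiometer
doublet), a labeled cortical surface inside the helmet, and a simulated motor
task session — 1/f background noise on every channel plus, at chosen target
loci, a band-limited oscillatory burst locked (with trial-to-trial jitter) to
each visual cue onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "REGIONS",
    "CUE_DURATION",
    "SensorArray",
    "CorticalMesh",
    "SimConfig",
    "GroundTruth",
    "RawSession",
    "make_sensor_array",
    "make_cortical_mesh",
    "simulate_session",
    "pick_target_loci",
]

#: The ten cortical regions of interest: motor, frontal (anterior to motor),
#: parietal, temporal and occipital, for the left and right hemispheres.
REGIONS = (
    "Lmot", "Rmot", "Lfront", "Rfront", "Lpar",
    "Rpar", "Ltemp", "Rtemp", "Locc", "Rocc",
)

#: Anterior-to-posterior order of the five areas within each hemisphere.
_LOBE_ORDER = ("front", "mot", "par", "temp", "occ")

#: Duration of the visual cue in seconds (the white-sphere display period).
CUE_DURATION = 2.0

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SensorArray:
    """Helmet-shaped array of sensor loci, each with co-localized channels.

    Parameters
    ----------
    locus_positions : (L, 3) ndarray
        Locus coordinates in mm; right-handed frame, helmet apex on +z.
    channels_per_locus : int
        Number of co-localized channels per locus (2 = gradiometer doublet).
    """

    locus_positions: np.ndarray
    channels_per_locus: int = 2

    @property
    def n_loci(self) -> int:
        return self.locus_positions.shape[0]

    @property
    def n_channels(self) -> int:
        return self.n_loci * self.channels_per_locus

    @property
    def channel_locus(self) -> np.ndarray:
        """Locus index of every channel (channels are locus-major)."""
        return np.repeat(np.arange(self.n_loci), self.channels_per_locus)

    def channel_index(self, channel: int) -> tuple[int, int]:
        """Map a channel to its ``(locus, within-locus slot)`` pair."""
        return divmod(int(channel), self.channels_per_locus)

    @property
    def shell_radius(self) -> float:
        return float(np.linalg.norm(self.locus_positions, axis=1).mean())


@dataclass(frozen=True)
class CorticalMesh:
    """Triangulated cortical surface with a region label per vertex."""

    vertices: np.ndarray        # (V, 3) mm
    faces: np.ndarray           # (F, 3) vertex indices
    region_label: np.ndarray    # (V,) strings from REGIONS

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def region_vertices(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region_label == region)


@dataclass(frozen=True)
class RawSession:
    """Sampled multichannel recording with its channel-to-locus map."""

    data: np.ndarray            # (channels, samples)
    fs: float                   # Hz
    channel_locus: np.ndarray   # (channels,) locus index per channel
    locus_positions: np.ndarray  # (L, 3) mm

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated task session.

    Defaults mirror a ~10 min session of >100 trials: each trial shows a
    fixation cross for 2.25–4 s followed by a 2 s visual cue, and the
    simulated motor response occurs ``response_delay`` (plus Gaussian jitter)
    after cue onset.
    """

    fs: float = 1000.0                      # sampling rate, Hz
    duration: float = 600.0                 # session length, s
    n_trials: int = 110
    fixation_range: tuple[float, float] = (2.25, 4.0)   # s
    target_loci: tuple[int, ...] = (0,)
    target_band: float = 20.0               # burst carrier frequency, Hz
    response_delay: float = 0.4             # s after cue onset
    jitter_sd: float = 0.1                  # s, trial-to-trial latency jitter
    modulation_gain: float = 2.0            # burst envelope gain (x noise sd)
    noise_exponent: float = 1.0             # 1/f^a background slope
    line_freq: float | None = None          # power-line contamination, Hz
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.fixation_range
        if not (0 < lo <= hi < self.duration):
            raise ValueError("fixation_range must lie within (0, duration)")
        if not self.target_band < self.fs / 2:
            raise ValueError("target_band must be below the Nyquist frequency")
        if self.modulation_gain < 0:
            raise ValueError("modulation_gain must be >= 0")
        if self.n_trials * (lo + CUE_DURATION) > self.duration:
            raise ValueError(
                "trial schedule overflows the session: "
                f"{self.n_trials} trials x (min fixation + cue) "
                f"= {self.n_trials * (lo + CUE_DURATION):.1f} s "
                f"> duration {self.duration:.1f} s"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator planted: cue onsets, response times, and targets."""

    onset_times: np.ndarray      # visual cue onsets, s
    movement_times: np.ndarray   # onset + jittered response delay, s
    target_loci: tuple[int, ...]
    target_band: float
    response_delay: float


def make_sensor_array(
    n_loci: int, seed: int, radius: float = 100.0, channels_per_locus: int = 2
) -> SensorArray:
    """Quasi-uniform sensor loci on an upper hemisphere of given radius (mm).

    A Fibonacci lattice covers the hemisphere evenly; the seed rotates the
    lattice about the vertical axis so distinct seeds give distinct layouts.
    """
    if n_loci < 3:
        raise ValueError("n_loci must be >= 3 (IDW uses 3 nearest loci)")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(n_loci)
    z = (i + 0.5) / n_loci                       # (0, 1]: equator to apex
    rho = np.sqrt(1.0 - z**2)
    phi = i * _GOLDEN_ANGLE + phase
    pos = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return SensorArray(locus_positions=pos, channels_per_locus=channels_per_locus)


def make_cortical_mesh(
    n_vertices: int, sensor_array: SensorArray, seed: int
) -> CorticalMesh:
    """Random labeled cortical cap strictly inside the sensor shell.

    Vertices are drawn uniformly on an upper hemisphere of radius 0.8x the
    sensor shell radius and triangulated by planar Delaunay of their (x, y)
    projection. Labels form ten compact contiguous patches: an equal-count
    left/right split on x, then five equal-count anterior-to-posterior bands
    on y within each half (front, mot, par, temp, occ) — so every region is
    non-empty whenever V >= 10 and no two regions meet at the helmet apex.
    """
    if n_vertices < 10:
        raise ValueError("n_vertices must be >= 10 (one per region)")
    rng = np.random.default_rng(seed)
    radius = 0.8 * sensor_array.shell_radius
    z = rng.uniform(0.05, 1.0, n_vertices)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_vertices)
    rho = np.sqrt(1.0 - z**2)
    verts = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    faces = Delaunay(verts[:, :2]).simplices.astype(np.int64)

    labels = np.empty(n_vertices, dtype=object)
    by_x = np.argsort(verts[:, 0], kind="stable")
    halves = np.array_split(by_x, 2)             # -x half is "left"
    for side, half in zip("LR", halves):
        by_y = half[np.argsort(-verts[half, 1], kind="stable")]  # +y anterior
        for lobe, chunk in zip(_LOBE_ORDER, np.array_split(by_y, 5)):
            labels[chunk] = side + lobe
    return CorticalMesh(vertices=verts, faces=faces, region_label=labels.astype(str))


def pick_target_loci(
    array: SensorArray, mesh: CorticalMesh, region: str, n: int = 2
) -> tuple[int, ...]:
    """The ``n`` sensor loci that best overlie a mesh region.

    "Overlying" is judged through the analysis's own projection operator:
    activity planted at a candidate locus set spreads over the mesh by
    inverse distance weighting, and the chosen set maximizes the margin
    between the target region's mean received weight and the best
    non-target region's. This guarantees that, geometry permitting,
    activity planted at the returned loci projects most strongly into the
    requested region. Exhaustive over locus sets for n <= 2, greedy beyond.
    Convenience for planting simulated activity over a named region.
    """
    from itertools import combinations

    from .projection import _idw_weights

    inside = mesh.region_label == region
    if not inside.any():
        raise ValueError(f"region {region!r} has no vertices")
    W = _idw_weights(mesh.vertices, array, k=min(3, array.n_loci), power=1.0)
    region_names = np.unique(mesh.region_label)
    masks = [mesh.region_label == r for r in region_names]
    target_row = int(np.flatnonzero(region_names == region)[0])
    # region x locus: mean weight each region receives from each locus
    M = np.stack([W[mask].mean(axis=0) for mask in masks])

    def margin(loci: tuple[int, ...]) -> float:
        got = M[:, list(loci)].sum(axis=1)
        others = np.delete(got, target_row)
        return float(got[target_row] - others.max())

    if n <= 2:
        candidates = combinations(range(array.n_loci), n)
        return tuple(sorted(max(candidates, key=margin)))
    chosen: list[int] = []
    for _ in range(n):
        rest = [i for i in range(array.n_loci) if i not in chosen]
        chosen.append(max(rest, key=lambda i: margin((*chosen, i))))
    return tuple(sorted(chosen))


def _one_over_f_noise(rng: np.random.Generator, n_samples: int, fs: float,
                      exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n_samples)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    f[0] = f[1]                                  # keep DC finite
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n_samples)
    return x / x.std()


_BURST_WIDTH = 0.5  # s, full width of the Hann amplitude envelope


def simulate_session(cfg: SimConfig, array: SensorArray) -> tuple[RawSession, GroundTruth]:
    """Simulate a task session on the given sensor array.

    Trial k shows a fixation cross for Uniform(fixation_range) seconds, then
    the cue onset; onsets are therefore spaced by fixation + cue duration.
    Channels at ``target_loci`` receive, per trial, a Hann-windowed burst of a
    ``target_band`` Hz carrier, centered ``response_delay + N(0, jitter_sd)``
    after the onset, with amplitude ``modulation_gain`` relative to the unit
    noise floor. The carrier is phase-locked to the burst center, so a
    jitter-free session has a nonzero trial-averaged evoked response.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration * cfg.fs))

    fix = rng.uniform(*cfg.fixation_range, cfg.n_trials)
    onsets = np.cumsum(fix) + CUE_DURATION * np.arange(cfg.n_trials)
    if onsets[-1] + CUE_DURATION > cfg.duration:
        raise ValueError(
            f"trial schedule overflows the session: last cue ends at "
            f"{onsets[-1] + CUE_DURATION:.1f} s > duration {cfg.duration:.1f} s"
        )

    latency = cfg.response_delay + rng.normal(0.0, cfg.jitter_sd, cfg.n_trials)
    if np.any(latency < 0):
        warnings.warn(
            f"{int((latency < 0).sum())} trial(s) had jittered latency < 0; "
            "clipped at 0", stacklevel=2,
        )
        latency = np.clip(latency, 0.0, None)
    movements = onsets + latency

    data = np.empty((array.n_channels, n_samples))
    for ch in range(array.n_channels):
        data[ch] = _one_over_f_noise(rng, n_samples, cfg.fs, cfg.noise_exponent)

    if cfg.line_freq is not None:
        t = np.arange(n_samples) / cfg.fs
        for ch in range(array.n_channels):
            data[ch] += 0.5 * np.sin(2 * np.pi * cfg.line_freq * t + rng.uniform(0, 2 * np.pi))

    if cfg.modulation_gain > 0:
        half = _BURST_WIDTH / 2.0
        target_channels = np.flatnonzero(np.isin(array.channel_locus, cfg.target_loci))
        for center in movements:
            i0 = max(0, int(np.ceil((center - half) * cfg.fs)))
            i1 = min(n_samples, int(np.floor((center + half) * cfg.fs)) + 1)
            if i0 >= i1:
                continue
            trel = np.arange(i0, i1) / cfg.fs - center
            env = 0.5 * (1.0 + np.cos(np.pi * trel / half))
            burst = cfg.modulation_gain * env * np.cos(2 * np.pi * cfg.target_band * trel)
            data[target_channels, i0:i1] += burst

    session = RawSession(
        data=data, fs=cfg.fs,
        channel_locus=array.channel_locus,
        locus_positions=array.locus_positions,
    )
    truth = GroundTruth(
        onset_times=onsets, movement_times=movements,
        target_loci=tuple(cfg.target_loci),
        target_band=cfg.target_band, response_delay=cfg.response_delay,
    )
    return session, truth
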