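"""Synthetic thalamo-cortical scenes with known ground truth.

A scene is a set of dipolar Gaussian-source components (a strong, shallow
"cortical" generator and a weak, deep "thalamic" one by default), each with
a parametric stimulus-locked time course.  Scenes can be projected onto
realistic probe geometries with additive noise and missing channels; the
noiseless per-region potentials are returned alongside, forming the
recovery target for the estimation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ValidationError
from .forward import GaussianSource, unit_csd, unit_potential
from .geometry import ElectrodeGrid, EvokedPotential, Medium, Region

DEFAULT_DT = 0.2  # ms, i.e. 5 kHz
#: Default epoch: 50 ms pre-stimulus, 100 ms post.
DEFAULT_TIMES = np.arange(-50.0, 100.0 + 1e-9, DEFAULT_DT)


def alpha_waveform(
    t: np.ndarray, onset: float, peak: float, shape: float = 2.0
) -> np.ndarray:
    """Alpha-function-like unit waveform: 0 before onset, 1 at ``peak``.

    w(t) = ((t-onset)/tau)^shape * exp(shape * (1 - (t-onset)/tau)) with
    tau = peak - onset; larger ``shape`` gives a sharper rise and faster decay.
    """
    if not peak > onset:
        raise ValidationError("waveform requires onset < peak")
    t = np.asarray(t, dtype=float)
    tau = peak - onset
    u = np.clip((t - onset) / tau, 0.0, None)
    return u**shape * np.exp(shape * (1.0 - u))


def damped_sine_waveform(
    t: np.ndarray, onset: float, period: float, decay: float
) -> np.ndarray:
    """Damped oscillation: 0 before onset, first extremum normalized to 1.

    w(t) = exp(-(t-onset)/decay) * sin(2 pi (t-onset)/period) for t > onset,
    rescaled so the magnitude of the first extremum is 1.  The first
    extremum falls at atan(2 pi decay / period) * period / (2 pi) after
    onset.
    """
    t = np.asarray(t, dtype=float)
    omega = 2.0 * np.pi / period
    delta = np.clip(t - onset, 0.0, None)
    w = np.exp(-delta / decay) * np.sin(omega * delta)
    d_peak = np.arctan(omega * decay) / omega
    peak_val = np.exp(-d_peak / decay) * np.sin(omega * d_peak)
    return w / peak_val


@dataclass
class SceneComponent:
    """One generator: Gaussian source terms sharing a time course.

    ``name`` labels the anatomical region the component belongs to.  Two
    waveform kinds are supported: ``alpha`` (monophasic, optionally with an
    opposite-sign rebound alpha wave starting at the main peak) and
    ``damped_sine`` (oscillatory with linear onset, the biphasic shape
    typical of evoked potentials).
    """

    name: str
    sources: list  # of GaussianSource; amplitudes are peak currents, uA
    onset: float  # ms
    peak: float  # ms
    shape: float = 2.0
    rebound: float = 0.0  # fraction of main amplitude, opposite sign
    rebound_delay: float = 5.0  # ms from main peak to rebound peak
    kind: str = "alpha"
    decay: float | None = None  # damped_sine envelope time constant, ms

    def __post_init__(self) -> None:
        if not self.onset < self.peak:
            raise ValidationError("component requires onset < peak")
        if not self.sources:
            raise ValidationError("component needs at least one source")
        if self.kind not in ("alpha", "damped_sine"):
            raise ValidationError(f"unknown waveform kind {self.kind!r}")

    def _period(self) -> float:
        # choose the period so the first extremum of the damped sine falls
        # at the requested peak time: d* = atan(omega*decay)/omega
        from scipy.optimize import brentq

        decay = self.decay if self.decay is not None else 25.0
        target = self.peak - self.onset

        def f(period):
            omega = 2.0 * np.pi / period
            return np.arctan(omega * decay) / omega - target

        return float(brentq(f, 4.0 * target + 1e-6, 1000.0 * target))

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Unit time course; identically 0 for t < onset."""
        if self.kind == "damped_sine":
            return damped_sine_waveform(
                t,
                self.onset,
                self._period(),
                self.decay if self.decay is not None else 25.0,
            )
        w = alpha_waveform(t, self.onset, self.peak, self.shape)
        if self.rebound:
            w = w - self.rebound * alpha_waveform(
                t, self.peak, self.peak + self.rebound_delay, self.shape
            )
        return w

    def scaled(self, factor: float) -> "SceneComponent":
        return SceneComponent(
            name=self.name,
            sources=[
                GaussianSource(s.center, s.width, s.amplitude * factor)
                for s in self.sources
            ],
            onset=self.onset,
            peak=self.peak,
            shape=self.shape,
            rebound=self.rebound,
            rebound_delay=self.rebound_delay,
            kind=self.kind,
            decay=self.decay,
        )


@dataclass
class SyntheticScene:
    """Ground-truth generators plus the anatomical region boxes they live in."""

    components: list
    medium: Medium = field(default_factory=Medium)
    seed: int | None = None
    regions: dict = field(default_factory=dict)
    landmarks: dict = field(default_factory=dict)  # named reference points, mm

    def region_names(self) -> list:
        seen = []
        for c in self.components:
            if c.name not in seen:
                seen.append(c.name)
        return seen

    def _component_potential(
        self, comp: SceneComponent, points: np.ndarray, times: np.ndarray
    ) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        spatial = np.zeros(pts.shape[0])
        for src in comp.sources:
            r = np.linalg.norm(pts - np.asarray(src.center), axis=1)
            spatial += src.amplitude * unit_potential(
                r, src.width, self.medium.conductivity
            )
        return np.outer(spatial, comp.waveform(times))

    def potential(self, points, times, by_region: bool = False):
        """Noiseless potential (mV) at points x times; optionally per region."""
        times = np.asarray(times, dtype=float)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        per = {name: np.zeros((pts.shape[0], times.size)) for name in self.region_names()}
        for comp in self.components:
            per[comp.name] += self._component_potential(comp, pts, times)
        if by_region:
            return per
        return sum(per.values())

    def csd(self, points, times) -> np.ndarray:
        """Ground-truth CSD (uA/mm^3) at points x times."""
        times = np.asarray(times, dtype=float)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros((pts.shape[0], times.size))
        for comp in self.components:
            centers = np.array([s.center for s in comp.sources])
            amps = np.array([s.amplitude for s in comp.sources])
            widths = {s.width for s in comp.sources}
            w = comp.waveform(times)
            for width in widths:
                sel = np.array([s.width == width for s in comp.sources])
                prof = unit_csd(cdist(pts, centers[sel]), width) @ amps[sel]
                out += np.outer(prof, w)
        return out

    def total_current(self, times) -> np.ndarray:
        """Spatial integral of the scene CSD per instant (charge balance)."""
        times = np.asarray(times, dtype=float)
        total = np.zeros(times.size)
        for comp in self.components:
            amp_sum = sum(s.amplitude for s in comp.sources)
            total += amp_sum * comp.waveform(times)
        return total


# ---------------------------------------------------------------------------
# Probe geometries
# ---------------------------------------------------------------------------


def build_standard_grid(kind: str, **params) -> ElectrodeGrid:
    """Construct one of the standard probe geometries.

    ``np_long_column``
        384 sites in a zig-zag column (20 um vertical pitch, 16 um
        horizontal stagger) spanning 7.68 mm of tissue along an insertion
        axis tiltable by ``tilt_deg``.
    ``a8x8_combined``
        Combined cortical 8x11 and thalamic 8x18 grids at 0.2 mm pitch.
    ``linear16``
        16 collinear sites at ``pitch`` mm (0.1 or 0.15 typical).
    """
    if kind == "np_long_column":
        n = int(params.get("n_sites", 384))
        pitch = params.get("pitch", 0.020)
        stagger = params.get("stagger", 0.016)
        z_top = params.get("z_top", -0.1)
        tilt = np.deg2rad(params.get("tilt_deg", 0.0))
        axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        k = np.arange(n)
        along = z_top + k * pitch
        pos = np.outer(along, axis)
        pos[:, 0] += (k % 2) * stagger - stagger / 2.0
        ids = [f"np{i:03d}" for i in range(n)]
        broken = np.zeros(n, dtype=bool)
        return ElectrodeGrid(channel_ids=ids, positions=pos, broken=broken)

    if kind == "a8x8_combined":
        pitch = params.get("pitch", 0.2)
        n_shanks = int(params.get("n_shanks", 8))
        cortex_rows = int(params.get("cortex_rows", 11))
        thal_rows = int(params.get("thal_rows", 18))
        cortex_top = params.get("cortex_top", 0.2)
        thal_top = params.get("thal_top", 4.2)
        xs = (np.arange(n_shanks) - (n_shanks - 1) / 2.0) * pitch
        ids, pos = [], []
        for r in range(cortex_rows):
            for s, x in enumerate(xs):
                ids.append(f"ctx_r{r:02d}_s{s}")
                pos.append([x, 0.0, cortex_top + r * pitch])
        for r in range(thal_rows):
            for s, x in enumerate(xs):
                ids.append(f"th_r{r:02d}_s{s}")
                pos.append([x, 0.0, thal_top + r * pitch])
        pos = np.array(pos)
        return ElectrodeGrid(
            channel_ids=ids, positions=pos, broken=np.zeros(len(ids), dtype=bool)
        )

    if kind == "linear16":
        pitch = params.get("pitch", 0.1)
        n = int(params.get("n_sites", 16))
        z_top = params.get("z_top", 0.0)
        pos = np.column_stack(
            [np.zeros(n), np.zeros(n), z_top + pitch * np.arange(n)]
        )
        ids = [f"lin{i:02d}" for i in range(n)]
        return ElectrodeGrid(
            channel_ids=ids, positions=pos, broken=np.zeros(n, dtype=bool)
        )

    raise ValidationError(f"unknown grid kind {kind!r}")


# ---------------------------------------------------------------------------
# Default scene
# ---------------------------------------------------------------------------


def make_default_scene(
    seed: int | None = None,
    amplitude_ratio: float = 10.0,
    conductivity: float = 0.3,
    include_zona_incerta: bool = False,
) -> SyntheticScene:
    """Two-generator thalamo-cortical scene with a 10:1 amplitude disparity.

    The cortical component is a laterally extended dipole sheet (return
    source at 0.9 mm over the mid-layer sink at 1.4 mm depth; onset 5 ms,
    peak 10 ms).  The thalamic activity is a compact dipole centred 4 mm
    deeper carrying three stimulus-locked components: a fast early wave
    (onset 3 ms, peak ~4 ms), the main slow biphasic wave (peak ~8 ms) and
    a small fast ripple — together they give the thalamic trace temporal
    structure across the whole 0-25 ms analysis window.  The thalamic peak
    current is calibrated so the electrode-level cortex:thalamus amplitude
    ratio equals ``amplitude_ratio``.
    """
    medium = Medium(conductivity=conductivity)
    lateral = [-0.5, 0.0, 0.5]
    # Return current (source) above the mid-layer sink: the far field below
    # the pair then carries the sign of the deeper (sink) pole, giving the
    # single-polarity negative stripe observed at subcortical depths.
    ctx_sources = []
    for x in lateral:
        for y in lateral:
            ctx_sources.append(GaussianSource((x, y, 0.9), width=0.4, amplitude=+1.0))
            ctx_sources.append(GaussianSource((x, y, 1.4), width=0.4, amplitude=-1.0))
    cortical = SceneComponent(
        name="cortex", sources=ctx_sources, onset=5.0, peak=10.0, shape=4.0
    )

    def thal_dipole(amp: float, width: float) -> list:
        return [
            GaussianSource((0.0, 0.0, 4.95), width=width, amplitude=-amp),
            GaussianSource((0.0, 0.0, 5.35), width=width, amplitude=+amp),
        ]

    # main slow wave (N1_2-like), oscillatory with slow envelope decay
    thalamic_main = SceneComponent(
        name="thalamus",
        sources=thal_dipole(1.0, 0.3),
        onset=3.0,
        peak=8.0,
        kind="damped_sine",
        decay=70.0,
    )
    # fast early wave (N1_1-like), the sharpest and strongest deflection
    thalamic_early = SceneComponent(
        name="thalamus",
        sources=thal_dipole(1.35, 0.25),
        onset=3.0,
        peak=4.2,
        shape=2.0,
    )
    # fast ripple (~7 ms period) riding on the response
    thalamic_ripple = SceneComponent(
        name="thalamus",
        sources=thal_dipole(0.6, 0.3),
        onset=3.0,
        peak=4.75,
        kind="damped_sine",
        decay=70.0,
    )

    components = [cortical, thalamic_main, thalamic_early, thalamic_ripple]
    if include_zona_incerta:
        components.append(
            SceneComponent(
                name="thalamus",
                sources=[
                    GaussianSource((0.0, 0.0, 7.0), width=0.25, amplitude=-0.3),
                    GaussianSource((0.0, 0.0, 7.35), width=0.25, amplitude=+0.3),
                ],
                onset=3.5,
                peak=8.5,
                kind="damped_sine",
                decay=50.0,
            )
        )

    regions = {
        "cortex": Region("cortex", [[[-1.3, -0.7, 0.0], [1.3, 0.7, 2.4]]]),
        "thalamus": Region("thalamus", [[[-1.3, -0.7, 4.0], [1.3, 0.7, 7.8]]]),
    }

    scene = SyntheticScene(
        components=components,
        medium=medium,
        seed=seed,
        regions=regions,
        landmarks={
            "cortex_center": (0.0, 0.0, 1.15),
            "thalamus_center": (0.0, 0.0, 5.15),
        },
    )

    # calibrate thalamic peak current: electrode-level amplitude ratio along
    # a reference laminar track through each structure
    track_ctx = np.column_stack(
        [np.zeros(21), np.zeros(21), np.linspace(0.2, 2.2, 21)]
    )
    track_th = np.column_stack(
        [np.zeros(21), np.zeros(21), np.linspace(4.2, 7.6, 21)]
    )
    a_ctx = np.abs(scene.potential(track_ctx, DEFAULT_TIMES)).max()
    per = scene.potential(track_th, DEFAULT_TIMES, by_region=True)
    a_th = np.abs(per["thalamus"]).max()
    factor = (a_ctx / amplitude_ratio) / a_th
    scene.components = [
        c.scaled(factor) if c.name == "thalamus" else c for c in scene.components
    ]
    return scene


def make_thalamus_only_scene(seed: int | None = None, **kwargs) -> SyntheticScene:
    """Default scene with the cortical generator removed (silenced cortex)."""
    scene = make_default_scene(seed=seed, **kwargs)
    scene.components = [c for c in scene.components if c.name != "cortex"]
    return scene


# ---------------------------------------------------------------------------
# Projection onto a grid
# ---------------------------------------------------------------------------


def project_scene(
    scene: SyntheticScene,
    grid: ElectrodeGrid,
    noise_sd: float = 0.0,
    n_broken: int = 0,
    seed: int | None = None,
    times: np.ndarray | None = None,
    artifact_amp: float = 0.0,
):
    """Project a scene onto a grid: (EvokedPotential, per-region ground truth).

    ``noise_sd`` is the additive white Gaussian noise standard deviation as a
    fraction of the overall noiseless signal RMS.  ``n_broken`` channels are
    flagged broken at random.  Ground truth is returned noiseless, per
    region, at the resulting active channels.  Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if n_broken >= grid.n_channels:
        raise ValidationError("n_broken must be smaller than the channel count")
    if times is None:
        times = DEFAULT_TIMES.copy()
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)

    broken = grid.broken.copy()
    if n_broken > 0:
        candidates = np.flatnonzero(~broken)
        broken[rng.choice(candidates, size=n_broken, replace=False)] = True
    out_grid = ElectrodeGrid(
        channel_ids=list(grid.channel_ids),
        positions=grid.positions.copy(),
        broken=broken,
    )

    truth = scene.potential(out_grid.active_positions, times, by_region=True)
    total = sum(truth.values())
    values = total.copy()
    if artifact_amp:
        # bipolar stimulus artifact common to all channels, centred at t = 0
        wave = artifact_amp * times * np.exp(-0.5 * (times / 0.4) ** 2)
        values = values + wave[None, :]
    if noise_sd > 0:
        rms = np.sqrt(np.mean(total**2))
        values = values + noise_sd * rms * rng.standard_normal(values.shape)

    dt = times[1] - times[0]
    ep = EvokedPotential(
        grid=out_grid, times=times, values=values, sampling_rate=1000.0 / dt
    )
    return ep, truth
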