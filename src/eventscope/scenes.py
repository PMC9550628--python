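"""Ground-truth scene simulator standing in for the microscope.

Generates widefield timelapses for the three event classes the detection
pipelines target — fast multiplicative intensity spikes with exponential
decay (calcium / pHluorin), spots rising slowly over ~1 s (dynamin
recruitment), and diffusing point-like vesicles including scripted
approach-and-merge encounters — plus bead fields observed in two
distorted coordinate systems for transform calibration, and a toy
high-resolution renderer for triggered scan ROIs.

Every generator is a pure function of (spec, seed): the same seed gives a
bit-identical stack, and each emitted ground-truth record corresponds to
rendered photons. The camera model is sCMOS-like: expected counts pass
through a Poisson draw, then additive Gaussian read noise, then clamping
at zero and rounding to integers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .imaging_core import Frame, WidefieldTimelapse
from .transform import ControlPointSet, PolynomialTransform2D, _EXPONENTS

__all__ = [
    "generate_scene",
    "SCENE_KINDS",
    "SpikeEvent",
    "RampEvent",
    "MergeScript",
    "SceneSpec",
    "SceneGroundTruth",
    "generate_calcium_scene",
    "generate_dynamin_scene",
    "generate_vesicle_scene",
    "generate_bead_field",
    "random_polynomial_transform",
    "brownian_trajectories",
    "render_scan_roi",
]


@dataclass(frozen=True)
class SpikeEvent:
    """A transient local intensity spike: instantaneous rise, exponential decay.

    ``amplitude`` is the peak dF/F0 (the spot centre is multiplied by
    1 + amplitude at onset); ``tau_ms`` the decay time constant;
    ``sigma_spot`` the Gaussian spatial footprint in px.
    """

    onset_frame: int
    x: float
    y: float
    amplitude: float = 1.0
    tau_ms: float = 400.0
    sigma_spot: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.tau_ms <= 0 or self.sigma_spot <= 0:
            raise ValueError("spike amplitude, tau_ms and sigma_spot must be > 0")


@dataclass(frozen=True)
class RampEvent:
    """A spot rising from amplitude I0 to ratio*I0 over ramp_frames frames."""

    onset_frame: int
    x: float
    y: float
    i0: float = 100.0
    ratio: float = 2.6
    ramp_frames: int = 5
    sigma_spot: float = 2.0
    shape: str = "linear"  # or "sigmoid"

    def __post_init__(self) -> None:
        if self.i0 <= 0 or self.ratio < 1 or self.ramp_frames < 1:
            raise ValueError("invalid ramp parameters")
        if self.shape not in ("linear", "sigmoid"):
            raise ValueError("ramp shape must be 'linear' or 'sigmoid'")

    def amplitude_at(self, frame: int) -> float:
        if frame < self.onset_frame:
            return self.i0
        u = min(1.0, (frame - self.onset_frame) / max(1, self.ramp_frames - 1))
        if self.shape == "sigmoid":
            u = 0.5 * (1 - np.cos(np.pi * u))
        return self.i0 * (1.0 + (self.ratio - 1.0) * u)


@dataclass(frozen=True)
class MergeScript:
    """Scripted approach: vesicle ``mover`` walks onto ``target`` and merges.

    From ``start_frame`` the mover's path is a straight approach that
    reaches the target at ``merge_frame``; from the next frame on the two
    are unresolvable and only the target is rendered.
    """

    mover: int
    target: int
    start_frame: int
    merge_frame: int

    def __post_init__(self) -> None:
        if self.merge_frame <= self.start_frame:
            raise ValueError("merge_frame must be after start_frame")
        if self.mover == self.target:
            raise ValueError("mover and target must differ")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic widefield scene.

    Geometry mirrors a widefield surveillance recording (default 100 nm
    pixels, 50 ms frame period); ``background`` is the flat specimen
    baseline in counts inside the field, and structures (stationary spots,
    filament-like random-walk curves) sit on top of it.
    """

    shape: tuple[int, int] = (200, 200)
    pixel_size_nm: float = 100.0
    frame_period_ms: float = 50.0
    n_frames: int = 100
    background: float = 100.0
    poisson_noise: bool = True
    read_noise: float = 2.0
    n_filaments: int = 0
    filament_amplitude: float = 80.0
    n_spots: int = 0
    spot_amplitude: float = 150.0
    spot_sigma: float = 2.0
    spikes: tuple[SpikeEvent, ...] = ()
    ramps: tuple[RampEvent, ...] = ()
    n_vesicles: int = 0
    vesicle_amplitude: float = 300.0
    vesicle_sigma: float = 1.2
    diffusion_um2_s: float = 0.01
    vesicle_starts: tuple[tuple[float, float], ...] = ()
    merges: tuple[MergeScript, ...] = ()

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or min(self.shape) < 8:
            raise ValueError("scene shape must be 2-D, at least 8 px per side")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if min(self.pixel_size_nm, self.frame_period_ms) <= 0:
            raise ValueError("pixel_size_nm and frame_period_ms must be > 0")
        if self.background < 0 or self.read_noise < 0 or self.diffusion_um2_s < 0:
            raise ValueError("rates and levels must be >= 0")
        h, w = self.shape
        for ev in list(self.spikes) + list(self.ramps):
            if not (0 <= ev.x < w and 0 <= ev.y < h):
                raise ValueError(f"scheduled event at ({ev.x}, {ev.y}) outside field")
            if not 0 <= ev.onset_frame < self.n_frames:
                raise ValueError("scheduled event onset outside the timelapse")
        for m in self.merges:
            if not (0 <= m.mover < self.n_vesicles and 0 <= m.target < self.n_vesicles):
                raise ValueError("merge script references a missing vesicle")
            if m.merge_frame >= self.n_frames:
                raise ValueError("merge_frame outside the timelapse")
        if self.vesicle_starts and len(self.vesicle_starts) != self.n_vesicles:
            raise ValueError("vesicle_starts must list one (x, y) per vesicle")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["spikes"] = [asdict(s) for s in self.spikes]
        d["ramps"] = [asdict(r) for r in self.ramps]
        d["merges"] = [asdict(m) for m in self.merges]
        d["vesicle_starts"] = [list(p) for p in self.vesicle_starts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        d["shape"] = tuple(d.get("shape", (200, 200)))
        d["spikes"] = tuple(SpikeEvent(**s) for s in d.get("spikes", []))
        d["ramps"] = tuple(RampEvent(**r) for r in d.get("ramps", []))
        d["merges"] = tuple(MergeScript(**m) for m in d.get("merges", []))
        d["vesicle_starts"] = tuple(tuple(p) for p in d.get("vesicle_starts", []))
        return cls(**d)


@dataclass
class SceneGroundTruth:
    """Scripted truth emitted alongside a rendered scene.

    ``events`` lists every scheduled occurrence (type, frame, position,
    kinetics); ``trajectories`` is a (T, V, 2) array of vesicle (x, y)
    positions in px with NaN after a vesicle dies in a merge;
    ``static_emitters`` are (x, y, amplitude, sigma) tuples present in
    every frame; ``spec`` is the generating spec.
    """

    spec: SceneSpec
    events: list[dict] = field(default_factory=list)
    trajectories: np.ndarray | None = None  # (T, V, 2), px
    static_emitters: list[tuple[float, float, float, float]] = field(default_factory=list)
    true_transform: PolynomialTransform2D | None = None

    def emitters_at(self, frame_index: int) -> list[tuple[float, float, float, float]]:
        """All point emitters (x, y, amplitude, sigma_px) alive at a frame."""
        out = list(self.static_emitters)
        for ev in self.events:
            if ev["type"] == "spike":
                t = frame_index - ev["onset_frame"]
                if t >= 0:
                    dt_ms = self.spec.frame_period_ms
                    amp = (
                        self.spec.background
                        * ev["amplitude"]
                        * float(np.exp(-t * dt_ms / ev["tau_ms"]))
                    )
                    out.append((ev["x"], ev["y"], amp, ev["sigma_spot"]))
            elif ev["type"] == "ramp":
                ramp = RampEvent(
                    onset_frame=ev["onset_frame"], x=ev["x"], y=ev["y"],
                    i0=ev["i0"], ratio=ev["ratio"], ramp_frames=ev["ramp_frames"],
                    sigma_spot=ev["sigma_spot"],
                )
                out.append((ev["x"], ev["y"], ramp.amplitude_at(frame_index), ev["sigma_spot"]))
        if self.trajectories is not None:
            T = self.trajectories.shape[0]
            if 0 <= frame_index < T:
                for v in range(self.trajectories.shape[1]):
                    x, y = self.trajectories[frame_index, v]
                    if np.isfinite(x):
                        out.append(
                            (float(x), float(y), self.spec.vesicle_amplitude, self.spec.vesicle_sigma)
                        )
        return out

    def to_json(self, path: str | Path) -> None:
        doc = {
            "spec": self.spec.to_dict(),
            "events": self.events,
            "trajectories": None
            if self.trajectories is None
            else np.where(np.isfinite(self.trajectories), self.trajectories, None).tolist(),
            "static_emitters": [list(e) for e in self.static_emitters],
            "true_transform": None
            if self.true_transform is None
            else self.true_transform.to_dict(),
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneGroundTruth":
        doc = json.loads(Path(path).read_text())
        traj = doc.get("trajectories")
        if traj is not None:
            traj = np.array(
                [[[np.nan if c is None else c for c in p] for p in fr] for fr in traj],
                dtype=float,
            )
        tt = doc.get("true_transform")
        return cls(
            spec=SceneSpec.from_dict(doc["spec"]),
            events=doc.get("events", []),
            trajectories=traj,
            static_emitters=[tuple(e) for e in doc.get("static_emitters", [])],
            true_transform=None if tt is None else PolynomialTransform2D.from_dict(tt),
        )


# ---------------------------------------------------------------------------
# rendering helpers


def _add_gaussian_spot(image: np.ndarray, x: float, y: float, amplitude: float, sigma: float) -> None:
    """Add a peak-normalised Gaussian blob in place (windowed at 4 sigma)."""
    h, w = image.shape
    r = max(1, int(np.ceil(4 * sigma)))
    r0, r1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    c0, c1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
    )


def _base_image(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Stationary specimen: flat background plus filaments and fixed spots."""
    h, w = spec.shape
    base = np.full((h, w), float(spec.background))
    for _ in range(spec.n_filaments):
        # neurite-like curve: a smoothed 2-D random walk
        n_steps = 4 * max(h, w)
        pos = rng.uniform([0.1 * w, 0.1 * h], [0.9 * w, 0.9 * h])
        angle = rng.uniform(0, 2 * np.pi)
        canvas = np.zeros((h, w))
        for _ in range(n_steps):
            angle += rng.normal(0, 0.15)
            pos = pos + np.array([np.cos(angle), np.sin(angle)])
            c, r = int(pos[0]) % w, int(pos[1]) % h
            canvas[r, c] += 1.0
        from scipy.ndimage import gaussian_filter

        canvas = gaussian_filter(canvas, 1.0, mode="reflect")
        if canvas.max() > 0:
            base += spec.filament_amplitude * canvas / canvas.max()
    return base


def _static_spots(spec: SceneSpec, rng: np.random.Generator) -> list[tuple[float, float, float, float]]:
    h, w = spec.shape
    spots = []
    for _ in range(spec.n_spots):
        x = float(rng.uniform(0.1 * w, 0.9 * w))
        y = float(rng.uniform(0.1 * h, 0.9 * h))
        spots.append((x, y, float(spec.spot_amplitude), float(spec.spot_sigma)))
    return spots


def _apply_noise(expected: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    out = expected
    if spec.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if spec.read_noise > 0:
        out = out + rng.normal(0.0, spec.read_noise, size=out.shape)
    if spec.poisson_noise or spec.read_noise > 0:
        out = np.clip(np.round(out), 0, None)
    return out.astype(np.uint16) if (spec.poisson_noise or spec.read_noise > 0) else out


def _spike_factor(spec: SceneSpec, spike: SpikeEvent, frame: int, shape) -> np.ndarray | None:
    t = frame - spike.onset_frame
    if t < 0:
        return None
    decay = float(np.exp(-t * spec.frame_period_ms / spike.tau_ms))
    h, w = shape
    r = max(1, int(np.ceil(4 * spike.sigma_spot)))
    r0, r1 = max(0, int(spike.y) - r), min(h, int(spike.y) + r + 1)
    c0, c1 = max(0, int(spike.x) - r), min(w, int(spike.x) + r + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    foot = np.exp(-((xx - spike.x) ** 2 + (yy - spike.y) ** 2) / (2 * spike.sigma_spot**2))
    factor = np.ones((h, w))
    factor[r0:r1, c0:c1] += spike.amplitude * decay * foot
    return factor


# ---------------------------------------------------------------------------
# generators


def generate_calcium_scene(spec: SceneSpec, seed: int) -> tuple[WidefieldTimelapse, SceneGroundTruth]:
    """Render a scene of transient multiplicative spikes on static structure.

    Spikes multiply the local baseline by ``1 + A * exp(-(t - t_on)/tau)``
    over a Gaussian footprint, so the dF/F0 amplitude is independent of
    local brightness.
    """
    rng = np.random.default_rng(seed)
    base = _base_image(spec, rng)
    spots = _static_spots(spec, rng)
    for x, y, a, s in spots:
        _add_gaussian_spot(base, x, y, a, s)

    frames = np.empty((spec.n_frames, *spec.shape), dtype=np.uint16 if (spec.poisson_noise or spec.read_noise > 0) else float)
    for t in range(spec.n_frames):
        expected = base.copy()
        for spike in spec.spikes:
            factor = _spike_factor(spec, spike, t, spec.shape)
            if factor is not None:
                expected = expected * factor
        frames[t] = _apply_noise(expected, spec, rng)

    truth = SceneGroundTruth(
        spec=spec,
        events=[
            {
                "type": "spike",
                "onset_frame": s.onset_frame,
                "x": s.x,
                "y": s.y,
                "amplitude": s.amplitude,
                "tau_ms": s.tau_ms,
                "sigma_spot": s.sigma_spot,
            }
            for s in spec.spikes
        ],
        static_emitters=spots,
    )
    return (
        WidefieldTimelapse(frames, spec.pixel_size_nm, spec.frame_period_ms),
        truth,
    )


def generate_dynamin_scene(spec: SceneSpec, seed: int) -> tuple[WidefieldTimelapse, SceneGroundTruth]:
    """Render spots that ramp from I0 to ratio*I0 over a few frames."""
    rng = np.random.default_rng(seed)
    base = _base_image(spec, rng)
    spots = _static_spots(spec, rng)
    for x, y, a, s in spots:
        _add_gaussian_spot(base, x, y, a, s)

    frames = np.empty((spec.n_frames, *spec.shape), dtype=np.uint16 if (spec.poisson_noise or spec.read_noise > 0) else float)
    for t in range(spec.n_frames):
        expected = base.copy()
        for ramp in spec.ramps:
            _add_gaussian_spot(expected, ramp.x, ramp.y, ramp.amplitude_at(t), ramp.sigma_spot)
        frames[t] = _apply_noise(expected, spec, rng)

    truth = SceneGroundTruth(
        spec=spec,
        events=[
            {
                "type": "ramp",
                "onset_frame": r.onset_frame,
                "x": r.x,
                "y": r.y,
                "i0": r.i0,
                "ratio": r.ratio,
                "ramp_frames": r.ramp_frames,
                "sigma_spot": r.sigma_spot,
                # the frame at which the ramp completes is the detection target
                "target_frame": r.onset_frame + r.ramp_frames - 1,
            }
            for r in spec.ramps
        ],
        static_emitters=spots,
    )
    return (
        WidefieldTimelapse(frames, spec.pixel_size_nm, spec.frame_period_ms),
        truth,
    )


def brownian_trajectories(
    n_tracks: int,
    n_steps: int,
    diffusion_um2_s: float,
    dt_s: float,
    seed: int,
    origin_box_um: tuple[float, float] = (20.0, 20.0),
) -> np.ndarray:
    """Pure 2-D Brownian trajectories in µm, shape (n_steps, n_tracks, 2).

    Per-axis step standard deviation is sqrt(2 D dt), the standard
    Einstein relation, so the ensemble MSD at lag dt is 4 D dt.
    """
    rng = np.random.default_rng(seed)
    origins = rng.uniform([0, 0], origin_box_um, size=(n_tracks, 2))
    sigma = float(np.sqrt(2 * diffusion_um2_s * dt_s))
    steps = rng.normal(0.0, sigma, size=(n_steps - 1, n_tracks, 2))
    return np.concatenate([origins[None], origins[None] + np.cumsum(steps, axis=0)])


def generate_vesicle_scene(spec: SceneSpec, seed: int) -> tuple[WidefieldTimelapse, SceneGroundTruth]:
    """Render diffusing point vesicles, with optional scripted merges.

    Unscripted vesicles take Brownian steps (per-axis std sqrt(2 D dt) in
    px). A :class:`MergeScript` overrides the mover's path from its
    position at ``start_frame`` to the target's position at
    ``merge_frame`` with a straight approach; after the merge the mover is
    no longer rendered (the pair is unresolvable) and its trajectory truth
    is NaN.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    T, V = spec.n_frames, spec.n_vesicles

    px_per_um = 1000.0 / spec.pixel_size_nm
    dt_s = spec.frame_period_ms / 1000.0
    sigma_px = float(np.sqrt(2 * spec.diffusion_um2_s * dt_s)) * px_per_um

    margin = 0.15 * min(h, w)
    traj = np.empty((T, V, 2))
    if spec.vesicle_starts:
        traj[0] = np.asarray(spec.vesicle_starts, dtype=float)
    else:
        traj[0] = rng.uniform([margin, margin], [w - margin, h - margin], size=(V, 2))
    steps = rng.normal(0.0, sigma_px, size=(max(T - 1, 0), V, 2)) if sigma_px > 0 else np.zeros((max(T - 1, 0), V, 2))
    for t in range(1, T):
        traj[t] = np.clip(traj[t - 1] + steps[t - 1], [2, 2], [w - 3, h - 3])

    merge_events = []
    for m in spec.merges:
        start_pos = traj[m.start_frame, m.mover].copy()
        for t in range(m.start_frame, m.merge_frame + 1):
            u = (t - m.start_frame) / (m.merge_frame - m.start_frame)
            traj[t, m.mover] = start_pos + u * (traj[m.merge_frame, m.target] - start_pos)
        traj[m.merge_frame + 1 :, m.mover] = np.nan
        merge_events.append(
            {
                "type": "merge",
                "frame_index": m.merge_frame,
                "x": float(traj[m.merge_frame, m.target, 0]),
                "y": float(traj[m.merge_frame, m.target, 1]),
                "mover": m.mover,
                "target": m.target,
            }
        )

    base = _base_image(spec, rng)
    frames = np.empty((T, h, w), dtype=np.uint16 if (spec.poisson_noise or spec.read_noise > 0) else float)
    for t in range(T):
        expected = base.copy()
        for v in range(V):
            x, y = traj[t, v]
            if np.isfinite(x):
                _add_gaussian_spot(expected, float(x), float(y), spec.vesicle_amplitude, spec.vesicle_sigma)
        frames[t] = _apply_noise(expected, spec, rng)

    truth = SceneGroundTruth(spec=spec, events=merge_events, trajectories=traj)
    return (
        WidefieldTimelapse(frames, spec.pixel_size_nm, spec.frame_period_ms),
        truth,
    )


SCENE_KINDS = {
    "calcium": generate_calcium_scene,
    "dynamin": generate_dynamin_scene,
    "vesicle": generate_vesicle_scene,
}


def generate_scene(kind: str, spec: SceneSpec, seed: int) -> tuple[WidefieldTimelapse, SceneGroundTruth]:
    """Dispatch to the generator for one of the three scene kinds."""
    try:
        gen = SCENE_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown scene kind {kind!r}; choose from {sorted(SCENE_KINDS)}") from None
    return gen(spec, seed)


# ---------------------------------------------------------------------------
# calibration fixtures


def random_polynomial_transform(
    field_shape: tuple[int, int],
    seed: int,
    distortion_px: float = 2.0,
) -> PolynomialTransform2D:
    """A ground-truth cubic transform: identity plus a smooth distortion.

    The distortion coefficients are drawn on the normalised domain so the
    warp is a few px (``distortion_px``) across the field, mimicking mild
    optical aberration between camera and scan space.
    """
    rng = np.random.default_rng(seed)
    h, w = field_shape
    offset = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    scale = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    coeffs = np.zeros((2, 10))
    coeffs[0, _EXPONENTS.index((1, 0))] = scale[0]
    coeffs[0, _EXPONENTS.index((0, 0))] = offset[0]
    coeffs[1, _EXPONENTS.index((0, 1))] = scale[1]
    coeffs[1, _EXPONENTS.index((0, 0))] = offset[1]
    coeffs += rng.normal(0.0, distortion_px / 3.0, size=(2, 10))
    return PolynomialTransform2D(coeffs=coeffs, offset=offset, scale=scale)


def generate_bead_field(
    true_transform: PolynomialTransform2D,
    n: int,
    detection_noise_px: float,
    seed: int,
    field_shape: tuple[int, int] = (800, 800),
) -> ControlPointSet:
    """Matched bead detections in the two coordinate systems.

    Widefield points are scattered uniformly; scan points are the true
    transform of those plus isotropic Gaussian detection noise.
    """
    if n < 10:
        raise ValueError("need at least 10 beads for a usable calibration field")
    rng = np.random.default_rng(seed)
    h, w = field_shape
    src = rng.uniform([0, 0], [w - 1, h - 1], size=(n, 2))
    dst = true_transform(src)
    if detection_noise_px > 0:
        dst = dst + rng.normal(0.0, detection_noise_px, size=dst.shape)
    return ControlPointSet(src=src, dst=dst)


# ---------------------------------------------------------------------------
# scan rendering


def render_scan_roi(
    truth: SceneGroundTruth,
    center: tuple[float, float],
    size_um: float,
    pixel_nm: float,
    frames: int,
    psf_fwhm_nm: float = 40.0,
    frame_index: int = 0,
    seed: int = 0,
    background: float = 2.0,
) -> np.ndarray:
    """Toy high-resolution render of a small ROI around a scan centre.

    The same ground-truth emitters are sampled at scan resolution
    (``pixel_nm``, typically 25-30 nm) and convolved with a narrow
    Gaussian PSF (default FWHM 40 nm). ``center`` is in widefield px of
    the truth's coordinate frame. Returns a (frames, n, n) uint16 stack
    with n = round(size_um * 1000 / pixel_nm).
    """
    spec = truth.spec
    h, w = spec.shape
    n = int(round(size_um * 1000.0 / pixel_nm))
    if n < 1 or frames < 1:
        raise ValueError("scan ROI must have at least one pixel and one frame")
    half_px_wf = (size_um * 1000.0 / spec.pixel_size_nm) / 2.0
    cx, cy = center
    if not (half_px_wf <= cx <= w - 1 - half_px_wf and half_px_wf <= cy <= h - 1 - half_px_wf):
        raise ValueError(
            f"scan ROI of {size_um} um at ({cx:.1f}, {cy:.1f}) exceeds the field"
        )

    emitters = truth.emitters_at(frame_index)
    sigma_scan_px = (psf_fwhm_nm / 2.3548) / pixel_nm
    scale = spec.pixel_size_nm / pixel_nm  # scan px per widefield px

    expected = np.full((n, n), float(background))
    for ex, ey, amp, _sig in emitters:
        sx = (ex - cx) * scale + (n - 1) / 2.0
        sy = (ey - cy) * scale + (n - 1) / 2.0
        if -4 * sigma_scan_px <= sx <= n - 1 + 4 * sigma_scan_px and -4 * sigma_scan_px <= sy <= n - 1 + 4 * sigma_scan_px:
            _add_gaussian_spot(expected, sx, sy, amp, sigma_scan_px)

    rng = np.random.default_rng(seed)
    stack = np.empty((frames, n, n), dtype=np.uint16)
    for f in range(frames):
        noisy = expected
        if spec.poisson_noise:
            noisy = rng.poisson(np.clip(noisy, 0, None)).astype(float)
        if spec.read_noise > 0:
            noisy = noisy + rng.normal(0.0, spec.read_noise, size=expected.shape)
        stack[f] = np.clip(np.round(noisy), 0, None).astype(np.uint16)
    return stack
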