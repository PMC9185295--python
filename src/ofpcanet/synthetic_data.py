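"""Synthetic clip datasets with subject structure and class-dependent motion.

Real micro-expression corpora are license-restricted, so this module
fabricates the statistical structure the pipeline assumes: short grayscale
clips of a textured, otherwise static scene in which a small localized region
drifts by a sub-pixel-to-few-pixel amount per frame.  Subject identity
determines the base texture (standing in for facial appearance); the class
label determines *where* and *in which direction* the localized motion
occurs, mimicking sparse facial action units.  Ground-truth displacement
fields are saved as Middlebury .flo files so the flow solver can be scored
against a known answer.

Everything is driven by a single integer seed through one
``numpy.random.Generator``; a given spec always produces byte-identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .clip_io import Clip, DatasetIndex, ManifestEntry, write_flo, write_manifest
from .exceptions import ConfigError, InputError

#: Built-in motion archetypes: (bump center as (row, col) fractions,
#: unit direction as (dv, du)) — or "dilate" for a radial pattern.
#: Loosely: an upper-region upward drift (brow raise), a lower-region
#: downward drift (mouth depress), and a central radial spread.
ARCHETYPES: dict[str, tuple[tuple[float, float], tuple[float, float] | str]] = {
    "raise": ((0.30, 0.45), (-1.0, 0.0)),
    "depress": ((0.72, 0.55), (1.0, 0.0)),
    "spread": ((0.52, 0.50), "dilate"),
    "shift": ((0.40, 0.70), (0.0, 1.0)),
}


@dataclass
class SynthSpec:
    """Recipe for one synthetic dataset.

    ``motion_amplitude`` is the peak displacement per frame in pixels and
    must stay within the small-motion regime (<= 3 px/frame);
    ``noise_sigma`` is the standard deviation of i.i.d. intensity noise added
    after warping (intensity units on [0, 1] frames), which mildly violates
    brightness constancy the way sensor noise does.
    """

    n_subjects: int = 6
    clips_per_subject: int = 3
    classes: tuple[str, ...] = ("raise", "depress", "spread")
    frame_size: tuple[int, int] = (64, 64)
    clip_length: int = 12
    motion_amplitude: float = 2.0
    noise_sigma: float = 0.01
    texture: str = "filtered-noise"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motion_amplitude < 0 or self.motion_amplitude > 3:
            raise ConfigError(
                "motion_amplitude must be in [0, 3] px/frame (small-motion regime)"
            )
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.clip_length < 2:
            raise ConfigError("clip_length must be >= 2")
        if self.texture not in ("gaussian-blobs", "filtered-noise"):
            raise ConfigError(f"unknown texture model {self.texture!r}")
        unknown = [c for c in self.classes if c not in ARCHETYPES]
        if unknown:
            raise ConfigError(
                f"unknown motion class(es) {unknown}; available: {sorted(ARCHETYPES)}"
            )
        self.classes = tuple(self.classes)
        self.frame_size = tuple(self.frame_size)  # type: ignore[assignment]


def _make_texture(rng: np.random.Generator, shape: tuple[int, int], kind: str) -> np.ndarray:
    """Per-subject base image: rich texture so flow is well constrained."""
    if kind == "filtered-noise":
        img = gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    else:  # gaussian-blobs
        img = np.zeros(shape)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        for _ in range(30):
            cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
            s = rng.uniform(1.5, 5.0)
            a = rng.uniform(-1.0, 1.0)
            img += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    lo, hi = img.min(), img.max()
    return 0.1 + 0.8 * (img - lo) / (hi - lo)


def class_displacement_field(
    class_name: str,
    shape: tuple[int, int],
    amplitude: float,
    *,
    center_jitter: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (du, dv) displacement field of one motion archetype.

    A smooth Gaussian bump of support ~15% of the frame at the archetype's
    location, moving in its direction with peak ``amplitude`` px/frame.
    """
    if class_name not in ARCHETYPES:
        raise ConfigError(f"unknown motion class {class_name!r}")
    (fy, fx), direction = ARCHETYPES[class_name]
    h, w = shape
    cy = fy * h + center_jitter[0]
    cx = fx * w + center_jitter[1]
    sigma = 0.15 * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    if direction == "dilate":
        ry, rx = yy - cy, xx - cx
        norm = np.maximum(np.hypot(ry, rx), 1e-9)
        dv = amplitude * bump * ry / norm
        du = amplitude * bump * rx / norm
    else:
        dv = amplitude * bump * direction[0]
        du = amplitude * bump * direction[1]
    return du, dv


def warp_sequence(
    base: np.ndarray, displacement: tuple[np.ndarray, np.ndarray], n_frames: int
) -> np.ndarray:
    """Generate frames by warping ``base`` with a linearly growing field.

    Frame t (0-based) is the bilinear backward warp of ``base`` by
    ``t * displacement``: content at reference position p appears at
    p + t*d, so the ground-truth flow from frame 0 to frame t is ``t * d``.
    Frame 0 is the base itself.  Returns an (N, M, n_frames) stack.
    """
    du, dv = np.asarray(displacement[0]), np.asarray(displacement[1])
    base = np.asarray(base, dtype=np.float64)
    if du.shape != base.shape or dv.shape != base.shape:
        raise InputError("displacement fields must match the base image shape")
    h, w = base.shape
    if np.max(np.abs(du)) * (n_frames - 1) >= w or np.max(np.abs(dv)) * (n_frames - 1) >= h:
        raise InputError("cumulative displacement exceeds the image extent")
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    frames = np.empty((h, w, n_frames))
    frames[:, :, 0] = base
    for t in range(1, n_frames):
        frames[:, :, t] = map_coordinates(
            base, [yy - t * dv, xx - t * du], order=1, mode="nearest"
        )
    return frames


def make_synthetic_clips(spec: SynthSpec) -> list[tuple[Clip, np.ndarray, np.ndarray]]:
    """Generate the dataset in memory.

    Returns one (clip, du, dv) triple per clip, where (du, dv) is the
    per-frame ground-truth displacement field (flow to frame t is t*(du, dv)).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size
    out = []
    for si in range(spec.n_subjects):
        texture = _make_texture(rng, (h, w), spec.texture)
        for ci in range(spec.clips_per_subject):
            cls = spec.classes[ci % len(spec.classes)]
            jitter = tuple(rng.uniform(-0.03, 0.03) * min(h, w) for _ in range(2))
            du, dv = class_displacement_field(
                cls, (h, w), spec.motion_amplitude, center_jitter=jitter
            )
            frames = warp_sequence(texture, (du, dv), spec.clip_length)
            if spec.noise_sigma > 0:
                frames = frames + rng.normal(0, spec.noise_sigma, frames.shape)
            frames = np.clip(frames, 0.0, 1.0)
            clip = Clip(
                frames=frames,
                subject_id=f"s{si:02d}",
                label=cls,
                clip_id=f"s{si:02d}_c{ci:02d}_{cls}",
            )
            out.append((clip, du, dv))
    return out


def make_synthetic_dataset(spec: SynthSpec, out_dir: str | Path) -> DatasetIndex:
    """Write a synthetic dataset to disk and return its index.

    Layout: one directory of zero-padded PNG frames per clip, a
    ``manifest.csv`` (clip_id, path, subject, label), a ``spec.json`` echo of
    the generation parameters, and ground-truth flow fields under ``gt/`` as
    ``<clip_id>_<t>.flo`` for t = 1..L-1 (the flow from frame 1 to frame
    t+1).  Identical specs produce byte-identical trees.
    """
    import json

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "gt").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    entries = []
    for clip, du, dv in make_synthetic_clips(spec):
        clip_dir = out_dir / clip.clip_id
        clip_dir.mkdir(exist_ok=True)
        for t in range(clip.n_frames):
            frame8 = np.round(clip.frames[:, :, t] * 255).astype(np.uint8)
            iio.imwrite(clip_dir / f"frame_{t:04d}.png", frame8)
        for t in range(1, clip.n_frames):
            write_flo((t * du, t * dv), out_dir / "gt" / f"{clip.clip_id}_{t}.flo")
        entries.append(
            ManifestEntry(
                clip_id=clip.clip_id,
                path=clip.clip_id,
                subject=clip.subject_id,
                label=clip.label,
            )
        )
    index = DatasetIndex(entries=entries)
    write_manifest(index, out_dir / "manifest.csv")
    (out_dir / "spec.json").write_text(json.dumps(asdict(spec), indent=2))
    # re-anchor manifest paths relative to out_dir for the returned index
    return DatasetIndex(
        entries=[
            ManifestEntry(e.clip_id, str(out_dir / e.path), e.subject, e.label)
            for e in entries
        ]
    )
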