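"""Clip and dataset I/O: frame stacks, manifests, and Middlebury .flo caching.

A *clip* is a short grayscale video of a pre-cropped face, stored on disk as a
directory of numbered image frames (PNG/JPEG) or a video container the imageio
backend can decode.  In memory it is an ``N x M x L`` float array with
intensities in [0, 1]; the first frame serves as the reference frame for all
downstream optical-flow computation.

Coordinate convention used throughout the package: row-major arrays with the
origin at the top-left, 0-based indices; ``u`` is the horizontal (column)
displacement and ``v`` the vertical (row) displacement, both in pixels.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from .exceptions import FormatError, InputError

logger = logging.getLogger(__name__)

#: Rec. 709 luma weights, matching skimage.color.rgb2gray.
LUMA_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])

#: Magic number of the Middlebury .flo format (decodes to the bytes "PIEH").
FLO_MAGIC = 202021.25

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class Clip:
    """A grayscale frame stack with subject identity and class label.

    ``frames`` has shape (N, M, L): height, width, number of frames, with
    intensities scaled to [0, 1].  ``subject_id`` groups clips for the
    leave-one-subject-out protocol; ``label`` is the motion class.
    """

    frames: np.ndarray
    subject_id: str
    label: str
    clip_id: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise InputError(
                f"clip {self.clip_id!r}: frames must be 3-D (N, M, L), "
                f"got shape {self.frames.shape}"
            )
        if self.frames.shape[2] < 2:
            raise InputError(
                f"clip {self.clip_id!r}: at least 2 frames required, "
                f"got {self.frames.shape[2]}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise InputError(f"clip {self.clip_id!r}: non-finite intensities")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise InputError(
                f"clip {self.clip_id!r}: intensities outside [0, 1] "
                f"(range [{self.frames.min():.3g}, {self.frames.max():.3g}])"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def frame_size(self) -> tuple[int, int]:
        return self.frames.shape[0], self.frames.shape[1]


@dataclass(frozen=True)
class ManifestEntry:
    clip_id: str
    path: str
    subject: str
    label: str


@dataclass
class DatasetIndex:
    """Ordered clip manifest with first-appearance class ordering."""

    entries: list[ManifestEntry]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.clip_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate clip_id(s) in manifest: {dupes}")
        if not self.class_names:
            seen: list[str] = []
            for e in self.entries:
                if e.label not in seen:
                    seen.append(e.label)
            self.class_names = seen
        missing = {e.label for e in self.entries} - set(self.class_names)
        if missing:
            raise InputError(f"labels missing from class_names: {sorted(missing)}")

    @property
    def subjects(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        seen: list[str] = []
        for e in self.entries:
            if e.subject not in seen:
                seen.append(e.subject)
        return seen

    def __len__(self) -> int:
        return len(self.entries)


def _to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an imageio frame to float64 grayscale in [0, 1]."""
    arr = np.asarray(img)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ LUMA_WEIGHTS
        else:
            arr = arr[:, :, 0]
    return np.clip(arr, 0.0, 1.0)


def load_clip(
    path: str | Path,
    target_size: tuple[int, int] = (170, 139),
    *,
    subject_id: str = "",
    label: str = "",
    clip_id: str | None = None,
) -> Clip:
    """Load a clip from a frame directory or video file.

    Frames are gray-converted with Rec. 709 luma weights, resized to
    ``target_size`` (height, width) with bilinear interpolation and scaled to
    [0, 1].  Frame order is the lexicographic order of the file names (use
    zero-padded frame numbers).

    Parameters
    ----------
    path
        Directory of image frames, or a video file readable by imageio.
    target_size
        Output (height, width) of every frame.

    Raises
    ------
    InputError
        Empty directory, unreadable file, or fewer than 2 frames.
    """
    path = Path(path)
    if path.is_dir():
        frame_files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not frame_files:
            raise InputError(f"no image frames found in directory {path}")
        raw = [iio.imread(p) for p in frame_files]
    elif path.is_file():
        try:
            raw = list(iio.imiter(path))
        except Exception as exc:  # pragma: no cover - backend dependent
            raise InputError(f"cannot decode video file {path}: {exc}") from exc
        if not raw:
            raise InputError(f"no frames decoded from {path}")
    else:
        raise InputError(f"clip path does not exist: {path}")

    shapes = {np.asarray(f).shape[:2] for f in raw}
    if len(shapes) > 1:
        logger.warning(
            "clip %s: frames have inconsistent sizes %s; resizing each independently",
            path,
            sorted(shapes),
        )

    frames = []
    for f in raw:
        g = _to_gray(f)
        if g.shape != tuple(target_size):
            g = resize(
                g, target_size, order=1, mode="edge",
                anti_aliasing=False, preserve_range=True,
            )
        frames.append(np.clip(g, 0.0, 1.0))

    stack = np.stack(frames, axis=2)
    if stack.shape[2] < 2:
        raise InputError(f"clip {path} has {stack.shape[2]} frame(s); need >= 2")
    return Clip(
        frames=stack,
        subject_id=subject_id,
        label=label,
        clip_id=clip_id if clip_id is not None else path.name,
    )


def read_manifest(path: str | Path) -> DatasetIndex:
    """Read a dataset manifest CSV with columns clip_id, path, subject, label.

    ``path`` column entries are interpreted relative to the manifest's own
    directory when they are not absolute.  Class names are recorded in
    first-appearance order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"manifest {path} is empty") from exc
    required = ["clip_id", "path", "subject", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"manifest {path} missing column(s): {missing}")
    if len(df) == 0:
        raise InputError(f"manifest {path} has no rows")
    for col in required:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise InputError(
                f"manifest {path}: missing {col!r} in row(s) {list(bad + 2)} "
                "(1-based line numbers incl. header)"
            )
    base = path.parent
    entries = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        entries.append(
            ManifestEntry(
                clip_id=row["clip_id"], path=str(p),
                subject=row["subject"], label=row["label"],
            )
        )
    return DatasetIndex(entries=entries)


def write_manifest(index: DatasetIndex, path: str | Path) -> None:
    """Write a DatasetIndex back to manifest CSV."""
    df = pd.DataFrame(
        [(e.clip_id, e.path, e.subject, e.label) for e in index.entries],
        columns=["clip_id", "path", "subject", "label"],
    )
    df.to_csv(path, index=False)


def write_flo(flow: tuple[np.ndarray, np.ndarray], path: str | Path) -> None:
    """Write one (u, v) flow field in Middlebury .flo layout.

    Layout: float32 magic 202021.25, int32 width, int32 height, then
    row-major interleaved (u, v) float32 pairs.  The round trip through
    :func:`read_flo` is bit-exact at 32-bit precision.
    """
    u, v = np.asarray(flow[0]), np.asarray(flow[1])
    if u.shape != v.shape or u.ndim != 2:
        raise InputError(f"u and v must be equal-shape 2-D fields, got {u.shape} / {v.shape}")
    h, w = u.shape
    data = np.empty((h, w, 2), dtype=np.float32)
    data[:, :, 0] = u
    data[:, :, 1] = v
    with open(path, "wb") as fh:
        fh.write(struct.pack("<fii", FLO_MAGIC, w, h))
        fh.write(data.tobytes())


def read_flo(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a Middlebury .flo file; returns (u, v) float32 arrays."""
    with open(path, "rb") as fh:
        header = fh.read(12)
        if len(header) < 12:
            raise FormatError(f"{path}: truncated .flo header")
        magic, w, h = struct.unpack("<fii", header)
        if magic != FLO_MAGIC:
            raise FormatError(f"{path}: bad .flo magic number {magic!r}")
        if w <= 0 or h <= 0:
            raise FormatError(f"{path}: invalid dimensions {w}x{h}")
        data = np.frombuffer(fh.read(w * h * 8), dtype=np.float32)
        if data.size != w * h * 2:
            raise FormatError(f"{path}: truncated .flo payload")
    data = data.reshape(h, w, 2)
    return data[:, :, 0].copy(), data[:, :, 1].copy()
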