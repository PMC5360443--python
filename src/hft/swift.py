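"""Cyclic local-contour scrambling in the wavelet domain.

Each detail location carries a 3-vector of (horizontal, vertical,
diagonal) coefficients describing the local contour.  Scrambling rotates
every such vector along a randomly oriented circle that lies on the
sphere of the vector's own norm, so local contrast energy is conserved
while contour orientation — and hence image semantics — is destroyed and
restored once per cycle.  The lowpass (approximation) band is never
touched, which pins global luminance.

The circle through the original vector and two random same-norm vectors
necessarily lies on the common sphere, so every point of the path has
the original norm; phase 0 of the path is the original vector itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meyer import WaveletDecomposition, wavedec2, waverec2

__all__ = [
    "ScramblePath",
    "SwiftCycle",
    "decompose",
    "generate_cycle",
    "load_image",
    "make_scramble_path",
    "point_at",
    "scramble_distance",
]

#: vectors shorter than this are held fixed (nothing to scramble)
DEGENERATE_NORM = 1e-12

DEFAULT_LEVELS = 6
DEFAULT_FRAMES_PER_CYCLE = 92


def decompose(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> WaveletDecomposition:
    """Six-level (default) Meyer decomposition of a square grayscale image."""
    return wavedec2(image, levels)


@dataclass
class ScramblePath:
    """Circular path on the norm sphere of one contour vector.

    ``point(phase) = center + radius * (cos(2 pi phase) * e1
    + sin(2 pi phase) * e2)`` with ``point(0)`` equal to the original
    vector exactly (``phase0 = 0`` by construction).
    """

    center: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    radius: float
    phase0: float = 0.0

    def point_at(self, phase: float) -> np.ndarray:
        ang = 2.0 * np.pi * ((phase + self.phase0) % 1.0)
        return self.center + self.radius * (np.cos(ang) * self.e1 + np.sin(ang) * self.e2)


def point_at(path: ScramblePath, phase: float) -> np.ndarray:
    """Vector at ``phase`` (taken modulo 1) along ``path``."""
    return path.point_at(phase)


def _circumcircle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Vectorised circumcircle of point triples, shape (..., 3).

    Returns (center, e1, e2, radius, ok) where ``ok`` is False for
    (near-)collinear triples.
    """
    t2 = p2 - p1
    t3 = p3 - p1
    n = np.cross(t2, t3)
    nn = np.sum(n * n, axis=-1)
    scale = np.sum(t2 * t2, axis=-1) * np.sum(t3 * t3, axis=-1)
    ok = nn > 1e-12 * np.maximum(scale, DEGENERATE_NORM)
    nn_safe = np.where(ok, nn, 1.0)
    l2 = np.sum(t2 * t2, axis=-1, keepdims=True)
    l3 = np.sum(t3 * t3, axis=-1, keepdims=True)
    # circumcenter: c = p1 + (|t2|^2 (t3 x n) + |t3|^2 (n x t2)) / (2 |n|^2)
    offset = (l2 * np.cross(t3, n) + l3 * np.cross(n, t2)) / (2.0 * nn_safe[..., None])
    center = p1 + offset
    rad_vec = p1 - center
    radius = np.linalg.norm(rad_vec, axis=-1)
    r_safe = np.where(radius > 0, radius, 1.0)
    e1 = rad_vec / r_safe[..., None]
    n_hat = n / np.sqrt(nn_safe)[..., None]
    e2 = np.cross(n_hat, e1)
    return center, e1, e2, radius, ok


def _random_on_sphere(rng: np.random.Generator, norms: np.ndarray) -> np.ndarray:
    v = rng.standard_normal(norms.shape + (3,))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    return v * norms[..., None]


def _make_paths(vecs: np.ndarray, rng: np.random.Generator):
    """Circular scramble paths for an (m, 3) stack of contour vectors.

    Degenerate (near-zero) vectors get a zero-radius path fixed at the
    vector itself; collinear random triples are resampled.
    """
    vecs = np.asarray(vecs, dtype=float)
    norms = np.linalg.norm(vecs, axis=-1)
    live = norms > DEGENERATE_NORM

    center = vecs.copy()
    e1 = np.zeros_like(vecs)
    e2 = np.zeros_like(vecs)
    radius = np.zeros(vecs.shape[:-1])

    pending = live.copy()
    for _ in range(64):
        if not np.any(pending):
            break
        idx = np.nonzero(pending)[0]
        p1 = vecs[idx]
        p2 = _random_on_sphere(rng, norms[idx])
        p3 = _random_on_sphere(rng, norms[idx])
        c, b1, b2, r, ok = _circumcircle(p1, p2, p3)
        good = idx[ok]
        center[good] = c[ok]
        e1[good] = b1[ok]
        e2[good] = b2[ok]
        radius[good] = r[ok]
        pending[good] = False
    if np.any(pending):  # pragma: no cover - probability ~0
        raise RuntimeError("failed to draw non-collinear path points")
    return center, e1, e2, radius, live


def make_scramble_path(v: np.ndarray, rng: np.random.Generator) -> ScramblePath:
    """Random norm-preserving circular path through contour vector ``v``."""
    v = np.asarray(v, dtype=float).reshape(3)
    center, e1, e2, radius, live = _make_paths(v[None, :], rng)
    if not live[0]:
        return ScramblePath(center=v.copy(), e1=np.zeros(3), e2=np.zeros(3), radius=0.0)
    return ScramblePath(center=center[0], e1=e1[0], e2=e2[0], radius=float(radius[0]))


@dataclass
class SwiftCycle:
    """One scrambling cycle: an ordered, periodic frame stack.

    ``frames[peak_index]`` reconstructs the (unscrambled) source image;
    all other frames are rotated-coefficient versions with identical
    per-location coefficient norms.
    """

    frames: np.ndarray  # (frames_per_cycle, n, n)
    peak_index: int
    source_image_id: str = ""
    levels: int = DEFAULT_LEVELS

    @property
    def frames_per_cycle(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def phase_of(self, k: int) -> float:
        return ((k - self.peak_index) / self.frames_per_cycle) % 1.0


def _stack_details(dec: WaveletDecomposition) -> list[np.ndarray]:
    """Per level, an (m, 3) array of contour vectors (H, V, D per location)."""
    out = []
    for h, v, d in dec.details:
        out.append(np.stack([h.ravel(), v.ravel(), d.ravel()], axis=-1))
    return out


def generate_cycle(
    image: np.ndarray,
    frames_per_cycle: int = DEFAULT_FRAMES_PER_CYCLE,
    rng: np.random.Generator | None = None,
    *,
    levels: int = DEFAULT_LEVELS,
    peak_index: int | None = None,
    source_image_id: str = "",
) -> SwiftCycle:
    """Generate one scrambling cycle from a square grayscale image.

    One random circular path is drawn per (level, location); frame ``k``
    is reconstructed with every vector at common phase
    ``(k - peak_index) / frames_per_cycle``, so all locations peak
    together and frame ``peak_index`` is the unscrambled image.
    """
    if frames_per_cycle < 2:
        raise ValueError("frames_per_cycle must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    if peak_index is None:
        peak_index = frames_per_cycle // 2
    peak_index = int(peak_index) % frames_per_cycle

    image = np.asarray(image, dtype=float)
    dec = decompose(image, levels)
    stacks = _stack_details(dec)
    paths = [_make_paths(s, rng) for s in stacks]

    n = image.shape[0]
    frames = np.empty((frames_per_cycle, n, n), dtype=float)
    work = dec.copy()
    for k in range(frames_per_cycle):
        phase = ((k - peak_index) / frames_per_cycle) % 1.0
        ang = 2.0 * np.pi * phase
        cos_a, sin_a = np.cos(ang), np.sin(ang)
        for lvl, (stack, (center, e1, e2, radius, live)) in enumerate(zip(stacks, paths)):
            pts = center + radius[:, None] * (cos_a * e1 + sin_a * e2)
            pts = np.where(live[:, None], pts, stack)
            side = dec.details[lvl][0].shape[0]
            work.details[lvl] = (
                pts[:, 0].reshape(side, side),
                pts[:, 1].reshape(side, side),
                pts[:, 2].reshape(side, side),
            )
        frames[k] = waverec2(work)
    return SwiftCycle(
        frames=frames,
        peak_index=peak_index,
        source_image_id=source_image_id,
        levels=levels,
    )


def scramble_distance(frame: np.ndarray, original: np.ndarray) -> float:
    """Euclidean pixel-space distance between two frames.

    The metric used to pick the "most scrambled" frame of a cycle; zero
    iff identical, symmetric by construction.
    """
    frame = np.asarray(frame, dtype=float)
    original = np.asarray(original, dtype=float)
    if frame.shape != original.shape:
        raise ValueError(f"shape mismatch: {frame.shape} vs {original.shape}")
    return float(np.linalg.norm(frame - original))


def load_image(path: str, size: int = 256) -> np.ndarray:
    """Read an image file as [0, 1] grayscale, center-cropped/resized to square.

    PNG/TIFF (anything imageio reads); color inputs are converted by the
    Rec. 601 luma weights.
    """
    import imageio.v3 as iio
    from scipy.ndimage import zoom

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    if arr.max() > 1.0:
        arr = arr / 255.0
    h, w = arr.shape
    side = min(h, w)
    top, left = (h - side) // 2, (w - side) // 2
    arr = arr[top : top + side, left : left + side]
    if side != size:
        arr = zoom(arr, size / side, order=1)
        arr = arr[:size, :size]
    return np.clip(arr, 0.0, 1.0)
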