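"""Synthetic projection datasets.

Builds 3D density volumes of distinct geometric shape families, projects
them at uniform random orientations to centred 2D images, and applies a
micrograph-like noise model (Gaussian noise parameterised by the image's
own pixel mean/variance, plus salt-and-pepper corruption of a fixed pixel
fraction).  These stand in for projection stacks derived from deposited
macromolecular structures: same geometry of the task (several particle
classes, a handful of views each, shared 100x100 canvas), without any
external data dependency.

Projection is exact mass-preserving voxel splatting: voxel centre
coordinates are rotated and each voxel's density is distributed bilinearly
over the 2D pixel grid, so ``sum(image) == sum(volume)`` to machine
precision for every orientation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from skimage.transform import resize

__all__ = [
    "SHAPE_FAMILIES",
    "SyntheticVolume",
    "ProjectionSet",
    "make_volume",
    "project_volume",
    "make_dataset",
    "add_noise",
]

SHAPE_FAMILIES = ("sphere", "dumbbell", "cube", "torus", "rod", "L-shape")

#: variants per base shape reachable through seeded perturbation
MAX_VARIANTS = 16


@dataclass
class SyntheticVolume:
    """Cubic nonnegative density grid from one shape family."""

    grid: np.ndarray
    shape_id: str
    seed: int

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 3 or len(set(g.shape)) != 1:
            raise ValueError("volume grid must be cubic")
        if g.min() < 0 or g.sum() <= 0:
            raise ValueError("volume must be nonnegative with positive mass")
        self.grid = g


@dataclass
class ProjectionSet:
    """A stack of same-sized grayscale projection images.

    ``labels`` (optional) give the ground-truth particle class of each
    image; ``pixel_size`` is in arbitrary length units per pixel.
    """

    images: np.ndarray
    labels: np.ndarray | None = None
    pixel_size: float = 1.0
    source: str = ""

    def __post_init__(self):
        imgs = np.asarray(self.images, dtype=float)
        if imgs.ndim != 3 or imgs.shape[0] < 1:
            raise ValueError("images must be an n x H x W array with n >= 1")
        self.images = imgs
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(imgs):
                raise ValueError("labels length must equal number of images")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "ProjectionSet":
        idx = np.asarray(idx)
        return dataclasses.replace(
            self,
            images=self.images[idx],
            labels=None if self.labels is None else self.labels[idx],
        )


def _coords(n: int) -> np.ndarray:
    """Normalised grid coordinates in [-1, 1] with centre (n-1)/2."""
    c = (np.arange(n) - (n - 1) / 2) / ((n - 1) / 2)
    return c


def _smooth_ind(d: np.ndarray, width: float) -> np.ndarray:
    # soft indicator: 1 inside (d<0), 0 outside, linear ramp of `width`
    return np.clip(0.5 - d / width, 0.0, 1.0)


def make_volume(
    shape_id: str, grid_size: int, seed: int = 0, perturb: float = 0.0
) -> SyntheticVolume:
    """Build a density volume of one shape family on a cubic grid.

    Deterministic in ``(shape_id, grid_size, seed, perturb)``.  With
    ``perturb > 0`` the shape is given a seeded anisotropic rescaling and
    additive Gaussian lobes, producing distinct class variants from one
    family (a stand-in for distinct macromolecules, not an emulation of
    any deposited structure).
    """
    if shape_id not in SHAPE_FAMILIES:
        raise ValueError(
            f"unknown shape_id {shape_id!r}; choose from {SHAPE_FAMILIES}"
        )
    if grid_size < 16:
        raise ValueError("grid_size must be >= 16")
    rng = np.random.default_rng(seed)
    c = _coords(grid_size)
    z, y, x = np.meshgrid(c, c, c, indexing="ij")
    if perturb > 0:
        sx, sy, sz = 1.0 + perturb * rng.uniform(-1, 1, 3)
        x, y, z = x * sx, y * sy, z * sz
    w = 2.0 / grid_size  # ~1 voxel soft edge

    r = np.sqrt(x**2 + y**2 + z**2)
    if shape_id == "sphere":
        g = _smooth_ind(r - 0.55, w)
    elif shape_id == "dumbbell":
        r1 = np.sqrt(x**2 + y**2 + (z - 0.38) ** 2)
        r2 = np.sqrt(x**2 + y**2 + (z + 0.38) ** 2)
        bar = np.maximum(np.sqrt(x**2 + y**2) - 0.12, np.abs(z) - 0.38)
        g = np.maximum.reduce(
            [
                _smooth_ind(r1 - 0.3, w),
                _smooth_ind(r2 - 0.3, w),
                _smooth_ind(bar, w),
            ]
        )
    elif shape_id == "cube":
        box = np.maximum.reduce([np.abs(x), np.abs(y), np.abs(z)]) - 0.4
        g = _smooth_ind(box, w)
    elif shape_id == "torus":
        g = _smooth_ind(
            np.sqrt((np.sqrt(x**2 + y**2) - 0.5) ** 2 + z**2) - 0.18, w
        )
    elif shape_id == "rod":
        g = _smooth_ind(
            np.maximum(np.sqrt(x**2 + y**2) - 0.16, np.abs(z) - 0.65), w
        )
    else:  # L-shape
        arm1 = np.maximum.reduce(
            [np.abs(x + 0.2) - 0.45, np.abs(y) - 0.16, np.abs(z + 0.3) - 0.16]
        )
        arm2 = np.maximum.reduce(
            [np.abs(x + 0.49) - 0.16, np.abs(y) - 0.16, np.abs(z) - 0.46]
        )
        g = np.maximum(_smooth_ind(arm1, w), _smooth_ind(arm2, w))
    if perturb > 0:
        # a few soft additive lobes on the support surface
        for _ in range(rng.integers(2, 5)):
            p = rng.uniform(-0.5, 0.5, 3)
            s = rng.uniform(0.08, 0.2)
            lobe = np.exp(
                -((x - p[0]) ** 2 + (y - p[1]) ** 2 + (z - p[2]) ** 2)
                / (2 * s**2)
            )
            g = np.maximum(g, perturb * 2 * np.clip(lobe, 0, 1))
    return SyntheticVolume(grid=g, shape_id=shape_id, seed=seed)


def _projection_canvas(n: int) -> int:
    # pad so any rotation of the cube's support fits; keep parity of n
    pad = int(np.ceil(n * (np.sqrt(3) - 1) / 2)) + 1
    return n + 2 * pad


def project_volume(
    vol: SyntheticVolume, orientation: tuple[float, float, float] | Rotation
) -> np.ndarray:
    """Line-integral projection of the rotated volume along the viewing axis.

    ``orientation`` is either a ``scipy`` Rotation or ZYZ Euler angles in
    degrees.  Voxel centres are rotated about the grid centre (N-1)/2 and
    splatted bilinearly onto the image plane, so total intensity equals
    total volume mass exactly.
    """
    if isinstance(orientation, Rotation):
        rot = orientation
    else:
        rot = Rotation.from_euler("zyz", orientation, degrees=True)
    n = vol.grid.shape[0]
    c = (n - 1) / 2
    idx = np.arange(n) - c
    zz, yy, xx = np.meshgrid(idx, idx, idx, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    rp = rot.apply(pts)
    vals = vol.grid.ravel()
    P = _projection_canvas(n)
    cc = (P - 1) / 2
    u = rp[:, 0] + cc  # image column
    v = rp[:, 1] + cc  # image row
    img = np.zeros((P, P))
    i0 = np.floor(v).astype(int)
    j0 = np.floor(u).astype(int)
    fv = v - i0
    fu = u - j0
    for di, wi in ((0, 1 - fv), (1, fv)):
        for dj, wj in ((0, 1 - fu), (1, fu)):
            np.add.at(img, (i0 + di, j0 + dj), vals * wi * wj)
    return img


def add_noise(
    image: np.ndarray,
    sp_fraction: float = 0.01,
    seed: int = 0,
    zero_mean: bool = False,
) -> np.ndarray:
    """Micrograph-like noise: image-parameterised Gaussian + salt and pepper.

    Gaussian noise is drawn with mean and variance equal to the input
    image's pixel mean and variance (``zero_mean=True`` keeps the variance
    but centres the noise at zero).  Then ``round(sp_fraction * H * W)``
    pixels are set to the input image's minimum (pepper) or maximum
    (salt), half each.  Deterministic under ``seed``.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image is empty")
    if not 0 <= sp_fraction < 1:
        raise ValueError("sp_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mu = 0.0 if zero_mean else image.mean()
    sd = image.std()
    out = image + rng.normal(mu, sd, size=image.shape)
    n_sp = int(round(sp_fraction * image.size))
    if n_sp:
        flat = out.reshape(-1)
        pick = rng.choice(image.size, size=n_sp, replace=False)
        n_salt = n_sp // 2
        flat[pick[:n_salt]] = image.max()
        flat[pick[n_salt:]] = image.min()
    return out


def make_dataset(
    n_classes: int,
    projections_per_class: tuple[int, int] = (2, 12),
    image_size: int = 100,
    noisy: bool = False,
    seed: int = 0,
    grid_size: int = 40,
    sp_fraction: float = 0.01,
    zero_mean_noise: bool = False,
) -> ProjectionSet:
    """Generate a labelled multi-class projection dataset.

    Per-class projection counts are drawn uniformly from the inclusive
    range ``projections_per_class``; orientations are uniform on SO(3);
    images are rendered on a common padded canvas and rescaled to
    ``image_size`` squared.  Classes beyond the six base shape families
    are seeded perturbed variants of the families.
    """
    lo, hi = projections_per_class
    if lo > hi or lo < 1:
        raise ValueError("projections_per_class range is empty")
    if n_classes > len(SHAPE_FAMILIES) * MAX_VARIANTS:
        raise ValueError(
            f"at most {len(SHAPE_FAMILIES) * MAX_VARIANTS} classes available"
        )
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cls in range(n_classes):
        family = SHAPE_FAMILIES[cls % len(SHAPE_FAMILIES)]
        variant = cls // len(SHAPE_FAMILIES)
        perturb = 0.0 if variant == 0 else 0.35
        vol = make_volume(
            family, grid_size, seed=int(rng.integers(2**31)), perturb=perturb
        )
        count = int(rng.integers(lo, hi + 1))
        for _ in range(count):
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat))
            img = project_volume(vol, rot)
            img = resize(
                img, (image_size, image_size), order=1, anti_aliasing=True,
                preserve_range=True,
            )
            if noisy:
                img = add_noise(
                    img, sp_fraction, seed=int(rng.integers(2**31)),
                    zero_mean=zero_mean_noise,
                )
            images.append(img)
            labels.append(cls)
    return ProjectionSet(
        images=np.stack(images),
        labels=np.array(labels),
        source=f"cryoclust.simulate(n_classes={n_classes}, "
        f"range={projections_per_class}, noisy={noisy}, seed={seed})",
    )
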