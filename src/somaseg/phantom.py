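"""Synthetic 3D phantoms of touching neuronal somata.

Real Nissl/GFP stacks show compact, bright, irregular cell bodies, many of
them clustered so tightly that the intensity interface between neighbors is
blurred away and simple thresholding merges them into one component.  The
generator emulates exactly that structure: randomly oriented ellipsoids with
a low-frequency radial deformation, placed either isolated or in touching
clusters of 2-3 whose center distance is the sum of the two directional radii
minus 1-2 voxels, each with its own jittered brightness, Gaussian-blurred
(which erases the interface between similar-brightness neighbors) and
corrupted with additive Gaussian noise.

All randomness flows from the single integer seed in :class:`PhantomConfig`;
no global random state is touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class PlacementError(RuntimeError):
    """Rejection sampling could not place a soma in the volume."""


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one phantom volume.

    Intensities are in arbitrary units; radii and blur in voxels.  Defaults
    describe a 64^3 desk-scale stack with somata of mean radius 7 voxels,
    bright foreground on dark background, per-soma brightness jitter, a
    1-voxel interface blur and moderate sensor noise.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_somata: int = 8
    radius_range: tuple[float, float] = (5.0, 9.0)
    touching_fraction: float = 0.3
    ellipticity_range: tuple[float, float] = (0.75, 1.3)
    foreground_mean: float = 200.0
    background_mean: float = 60.0
    intensity_jitter: float = 30.0
    noise_sd: float = 10.0
    boundary_blur_sigma: float = 1.0
    deform_amplitude: float = 0.15  # fraction of radius, <= 0.2
    interface_dip: float = 0.25  # partial-volume seam attenuation at contacts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_somata < 0:
            raise ValueError("n_somata must be >= 0")
        if self.radius_range[0] < 3:
            raise ValueError("minimum radius must be >= 3 voxels")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (min, max)")
        if not self.foreground_mean > self.background_mean:
            raise ValueError("foreground_mean must exceed background_mean")
        if not 0.0 <= self.touching_fraction <= 1.0:
            raise ValueError("touching_fraction must lie in [0, 1]")
        if not 0.0 <= self.deform_amplitude <= 0.2:
            raise ValueError("deform_amplitude must lie in [0, 0.2]")
        if not 0.0 <= self.interface_dip < 1.0:
            raise ValueError("interface_dip must lie in [0, 1)")
        rmax = self.radius_range[1] * max(self.ellipticity_range[1], 1.0)
        for dim in self.shape:
            if dim < 2 * rmax + 2:
                raise ValueError(
                    f"volume dim {dim} too small for max radius {rmax:.1f}"
                )


@dataclass(frozen=True, eq=False)
class _Soma:
    center: np.ndarray          # (3,) float, voxel coords (z, y, x)
    semiaxes: np.ndarray        # (3,) float
    rotation: np.ndarray        # (3, 3) orthonormal
    deform_w: np.ndarray        # (3, 3) wave vectors for radial deformation
    deform_phase: np.ndarray    # (3,)
    deform_amp: float

    @property
    def max_extent(self) -> float:
        return float(self.semiaxes.max()) * (1.0 + self.deform_amp)

    def norm_matrix(self) -> np.ndarray:
        """Maps offsets to the unit-ball frame: inside iff ||A v|| <= 1+def."""
        return np.diag(1.0 / self.semiaxes) @ self.rotation

    def directional_radius(self, direction: np.ndarray) -> float:
        """Distance from center to the *deformed* surface along a unit
        direction: the surface lies at ||A v|| = 1 + deformation(u)."""
        base = 1.0 / float(np.linalg.norm(self.norm_matrix() @ direction))
        bump = float(self.deformation(direction[None, :])[0])
        return base * (1.0 + bump)

    def normalized_distance(self, offsets: np.ndarray) -> np.ndarray:
        """||A v|| for an (..., 3) array of offsets from the center."""
        return np.linalg.norm(offsets @ self.norm_matrix().T, axis=-1)

    def deformation(self, offsets: np.ndarray) -> np.ndarray:
        """Low-frequency radial perturbation in (-amp, amp), per offset."""
        r = np.linalg.norm(offsets, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(r[..., None] > 0, offsets / np.maximum(r, 1e-9)[..., None], 0.0)
        waves = np.cos(u @ self.deform_w.T + self.deform_phase)
        return self.deform_amp * waves.mean(axis=-1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sample_soma(rng: np.random.Generator, config: PhantomConfig,
                 center: np.ndarray) -> _Soma:
    r = rng.uniform(*config.radius_range)
    ratios = rng.uniform(*config.ellipticity_range, size=3)
    ratios /= np.cbrt(np.prod(ratios))  # keep volume ~ (4/3)pi r^3
    return _Soma(
        center=center,
        semiaxes=r * ratios,
        rotation=_random_rotation(rng),
        deform_w=rng.uniform(1.0, 3.0, size=(3, 3)) * rng.choice([-1, 1], size=(3, 3)),
        deform_phase=rng.uniform(0, 2 * np.pi, size=3),
        deform_amp=config.deform_amplitude,
    )


def _sample_center(rng: np.random.Generator, shape, margin: float) -> np.ndarray:
    return np.array(
        [rng.uniform(margin, dim - 1 - margin) for dim in shape]
    )


def _too_close(candidate: _Soma, placed: list[_Soma], clearance: float = 2.0) -> bool:
    """Surface-to-surface check along the center line (directional radii
    inflated by the deformation amplitude)."""
    for other in placed:
        offset = other.center - candidate.center
        d = float(np.linalg.norm(offset))
        if d == 0.0:
            return True
        u = offset / d
        r_cand = candidate.directional_radius(u)
        r_other = other.directional_radius(-u)
        if d < r_cand + r_other + clearance:
            return True
    return False


def _plan_clusters(config: PhantomConfig, rng: np.random.Generator) -> list[int]:
    """Partition n_somata into cluster sizes (1 = isolated, 2-3 = touching)."""
    n_touching = int(round(config.touching_fraction * config.n_somata))
    if n_touching == 1:
        n_touching = 2 if config.n_somata >= 2 else 0
    sizes = []
    remaining = n_touching
    while remaining >= 2:
        k = int(rng.integers(2, 4)) if remaining >= 3 else 2
        k = min(k, remaining)
        sizes.append(k)
        remaining -= k
    sizes.extend([1] * (config.n_somata - sum(sizes)))
    return sizes


def generate_phantom(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (intensity, instance-label) phantom pair.

    Returns
    -------
    intensity : float32 array of ``config.shape``
    labels : uint16 array of ``config.shape``; 0 = background, 1..n = somata.

    Raises
    ------
    PlacementError
        If rejection sampling cannot place some soma (volume too crowded);
        the error names the failing instance index.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    labels = np.zeros(shape, dtype=np.uint16)
    intensity = np.full(shape, config.background_mean, dtype=np.float32)

    if config.n_somata == 0:
        intensity += rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
        return intensity, labels

    somata: list[_Soma] = []
    max_attempts = 2000
    for cluster_size in _plan_clusters(config, rng):
        cluster: list[_Soma] = []
        for member in range(cluster_size):
            placed = False
            for _ in range(max_attempts):
                if member == 0:
                    cand = _sample_soma(rng, config, np.zeros(3))
                    margin = cand.max_extent + 1
                    center = _sample_center(rng, shape, margin)
                    cand = dataclasses.replace(cand, center=center)
                    if not _too_close(cand, somata):
                        placed = True
                else:
                    anchor = cluster[int(rng.integers(0, len(cluster)))]
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    cand = _sample_soma(rng, config, anchor.center.copy())
                    gap = rng.uniform(1.0, 2.0)
                    dist = (
                        anchor.directional_radius(direction)
                        + cand.directional_radius(-direction)
                        - gap
                    )
                    center = anchor.center + dist * direction
                    cand = dataclasses.replace(cand, center=center)
                    inside = all(
                        cand.max_extent + 1 <= c <= dim - 2 - cand.max_extent
                        for c, dim in zip(center, shape)
                    )
                    cluster_ids = {id(s) for s in cluster}
                    others = [s for s in somata if id(s) not in cluster_ids]
                    if inside and not _too_close(cand, others):
                        placed = True
                if placed:
                    cluster.append(cand)
                    somata.append(cand)
                    break
            if not placed:
                raise PlacementError(
                    f"cannot place {config.n_somata} somata: instance "
                    f"{len(somata) + 1} failed after {max_attempts} attempts"
                )

    # Rasterize: overlap voxels go to the instance with the smaller
    # normalized ellipsoid distance; ties to the lower label.
    best = np.full(shape, np.inf, dtype=np.float32)
    fg_values = config.foreground_mean + rng.uniform(
        -1.0, 1.0, size=len(somata)
    ) * config.intensity_jitter
    for k, soma in enumerate(somata, start=1):
        lo = np.maximum(np.floor(soma.center - soma.max_extent - 1), 0).astype(int)
        hi = np.minimum(
            np.ceil(soma.center + soma.max_extent + 2), shape
        ).astype(int)
        grid = np.stack(
            np.meshgrid(
                *[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"
            ),
            axis=-1,
        ).astype(np.float64)
        offsets = grid - soma.center
        d = soma.normalized_distance(offsets)
        inside = d <= 1.0 + soma.deformation(offsets)
        box = tuple(slice(lo[a], hi[a]) for a in range(3))
        claim = inside & (d < best[box])
        labels[box][claim] = k
        best[box][claim] = d[claim]
        intensity[box][claim] = fg_values[k - 1]

    _enforce_connectivity(labels, somata)

    if config.interface_dip > 0:
        # partial-volume seam: the unstained gap between abutting cell
        # bodies attenuates intensity at instance-instance interfaces
        seam = np.zeros(shape, dtype=bool)
        fg = labels > 0
        for axis in range(3):
            for shift in (1, -1):
                rolled = np.roll(labels, shift, axis=axis)
                seam |= fg & (rolled > 0) & (rolled != labels)
        intensity[seam] *= 1.0 - config.interface_dip

    if config.boundary_blur_sigma > 0:
        intensity = ndimage.gaussian_filter(
            intensity, sigma=config.boundary_blur_sigma
        )
    intensity += rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
    return intensity.astype(np.float32), labels


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _enforce_connectivity(labels: np.ndarray, somata: list[_Soma]) -> None:
    """Drop stray satellite voxels so each instance is one 26-connected blob.

    Overlap stealing between two ellipsoid metrics can, rarely, sever a few
    voxels from their instance; those specks are handed to the competing
    instance whose support contains them, or to background.
    """
    for k in range(1, len(somata) + 1):
        mask = labels == k
        comp, n = ndimage.label(mask, structure=_STRUCT26)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        stray = mask & (comp != keep)
        coords = np.argwhere(stray)
        for zyx in coords:
            owner = 0
            best_d = np.inf
            for j, soma in enumerate(somata, start=1):
                if j == k:
                    continue
                off = zyx.astype(np.float64) - soma.center
                d = float(soma.normalized_distance(off))
                if d <= 1.0 + float(soma.deformation(off[None, :])[0]) and d < best_d:
                    owner, best_d = j, d
            labels[tuple(zyx)] = owner
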