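"""Bilateral parcel atlas for the language network.

The language network is constrained by five left-hemisphere parcels — three
frontal (LIFG, LIFGorb, LMFG) and two temporal (LAntTemp, LPostTemp) — plus
their right-hemisphere homotopes obtained by reflecting each parcel across the
mid-sagittal plane. Labels 1–5 are LH parcels, 6–10 the corresponding RH
mirrors, 0 is background. The grid's first axis is the left–right axis and must
have even length so that the mirror plane falls between voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LH_PARCEL_NAMES = {1: "LIFG", 2: "LIFGorb", 3: "LMFG", 4: "LAntTemp", 5: "LPostTemp"}
FRONTAL = ("IFG", "IFGorb", "MFG")
TEMPORAL = ("AntTemp", "PostTemp")
N_LH_PARCELS = 5


class AtlasSizingError(ValueError):
    """Grid too small to host the requested disjoint parcels."""


@dataclass
class ParcelAtlas:
    """Integer-labelled 3-D grid of bilateral language parcels.

    Attributes
    ----------
    labels : ndarray of int, shape (X, Y, Z)
        0 background, 1–5 LH parcels, 6–10 RH mirror parcels.
    names : dict of int to str
        Label to parcel name (e.g. 1 -> "LIFG", 6 -> "RIFG").
    affine : ndarray, shape (4, 4)
        Voxel-to-world (RAS+) affine.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D integer grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def parcel_voxels(self, label: int) -> np.ndarray:
        """Flat (C-order) voxel indices of one parcel, ascending."""
        return np.flatnonzero(self.labels.ravel() == label)

    def parcel_size(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    @property
    def lh_labels(self) -> tuple[int, ...]:
        return tuple(range(1, N_LH_PARCELS + 1))

    @property
    def rh_labels(self) -> tuple[int, ...]:
        return tuple(range(N_LH_PARCELS + 1, 2 * N_LH_PARCELS + 1))

    def hemisphere_of(self, label: int) -> str:
        return "LH" if label <= N_LH_PARCELS else "RH"

    def homotope(self, label: int) -> int:
        """Mirror-image label in the opposite hemisphere."""
        return label + N_LH_PARCELS if label <= N_LH_PARCELS else label - N_LH_PARCELS

    def component_labels(self, component: str, hemisphere: str = "LH") -> tuple[int, ...]:
        """Labels of the frontal or temporal network component."""
        stems = FRONTAL if component == "frontal" else TEMPORAL
        out = [
            lab
            for lab, name in self.names.items()
            if self.hemisphere_of(lab) == hemisphere and any(name.endswith(s) for s in stems)
        ]
        return tuple(sorted(out))


def _validate_grid(grid_shape) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"grid_shape must be 3 positive integers, got {grid_shape}")
    if shape[0] % 2 != 0:
        raise ValueError("first grid axis must be even so the mid-sagittal plane lies between voxels")
    return shape


def mirror_index(i: int | np.ndarray, nx: int):
    """Reflect a first-axis voxel index across the mid-sagittal plane."""
    return nx - 1 - i


def mirror_parcels(labels: np.ndarray) -> np.ndarray:
    """Project LH parcels (labels 1–5) onto the right hemisphere.

    Returns a new label grid where parcel ``k + 5`` is the exact reflection of
    parcel ``k`` across the mid-sagittal plane (x index i -> X-1-i). Any
    existing RH labels are recomputed.
    """
    labels = np.asarray(labels)
    nx = labels.shape[0]
    if nx % 2 != 0:
        raise ValueError("cannot mirror parcels on a grid with odd first-axis length")
    out = np.where(labels <= N_LH_PARCELS, labels, 0).copy()
    lh = out[::-1, :, :]
    rh_region = lh > 0
    if np.any((out > 0) & rh_region):
        raise ValueError("LH parcels overlap their own mirror image; keep them in one half-grid")
    out[rh_region] = lh[rh_region] + N_LH_PARCELS
    return out


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    d2 = dx**2 + dy**2 + dz**2
    keep = d2 <= radius**2 + 1e-9
    offs = np.stack([dx[keep], dy[keep], dz[keep]], axis=1)
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], d2[keep]))
    return offs[order]


def _radius_for_count(n: int) -> float:
    for r2 in range(1, 10000):
        radius = float(np.sqrt(r2))
        if len(_ball_offsets(radius)) >= n:
            return radius
    raise AtlasSizingError(f"cannot find sphere radius for {n} voxels")


def build_atlas(
    grid_shape,
    voxels_per_parcel: int = 100,
    seed: int = 0,
    affine: np.ndarray | None = None,
) -> ParcelAtlas:
    """Construct a synthetic bilateral parcel atlas.

    Five disjoint spherical LH parcels of exactly ``voxels_per_parcel`` voxels
    are placed in the left half-grid on a collision-free lattice (site choice
    randomized by ``seed``), then mirrored into the right half.

    Raises
    ------
    AtlasSizingError
        If the half-grid cannot host five disjoint parcels of the requested size.
    """
    shape = _validate_grid(grid_shape)
    if voxels_per_parcel < 50:
        raise ValueError("voxels_per_parcel must be >= 50")
    radius = _radius_for_count(voxels_per_parcel)
    offs = _ball_offsets(radius)[:voxels_per_parcel]
    r = int(np.ceil(radius))
    half_x = shape[0] // 2
    # candidate centres keep the whole sphere inside the LH half-grid
    spacing = 2 * r + 1
    xs = list(range(r, half_x - r))
    ys = list(range(r, shape[1] - r, spacing))
    zs = list(range(r, shape[2] - r, spacing))
    # thin x candidates to the collision-free lattice as well
    xs = xs[::spacing] if xs else xs
    sites = [(x, y, z) for x in xs for y in ys for z in zs]
    if len(sites) < N_LH_PARCELS:
        raise AtlasSizingError(
            f"grid {shape} too small for {N_LH_PARCELS} disjoint LH parcels of "
            f"{voxels_per_parcel} voxels (radius {radius:.2f}); found {len(sites)} slots"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(sites), size=N_LH_PARCELS, replace=False)
    labels = np.zeros(shape, dtype=np.int32)
    for k, site_idx in enumerate(sorted(chosen), start=1):
        cx, cy, cz = sites[site_idx]
        vox = offs + np.array([cx, cy, cz])
        labels[vox[:, 0], vox[:, 1], vox[:, 2]] = k
    labels = mirror_parcels(labels)
    names = dict(LH_PARCEL_NAMES)
    names.update({k + N_LH_PARCELS: "R" + v[1:] for k, v in LH_PARCEL_NAMES.items()})
    return ParcelAtlas(labels=labels, names=names, affine=affine if affine is not None else np.eye(4))
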