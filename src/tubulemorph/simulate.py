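"""Ground-truthed synthetic data generators.

Two generators back every stage of the analysis:

* :func:`make_tubule_field` emulates a dSTORM experiment on cortical
  microtubules: fluorophore-carrying antibodies ("emitters") are scattered
  along tubule centerlines of known outer diameter, each emitter is detected
  a Poisson number of times, and every detection carries an isotropic
  Gaussian localization error.  Single microtubules are ~25 nm across;
  bundles are modelled as a single tubule of larger outer diameter, since
  the downstream readout is width only.

* :func:`make_confocal_stack` emulates a two-channel immunofluorescence
  z-stack of a cylindrical cell decorated with short filament structures, a
  controllable fraction of which appear in both channels.  This is the test
  bed for the Manders colocalization and ROI volume quantifications.

Both generators are deterministic given their spec's ``seed``.  Every random
draw comes from a single :class:`numpy.random.Generator` in a documented,
fixed order (see the docstrings), so determinism survives refactoring.

Coordinates are nanometres, origin at the field corner, x right / y down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TubuleSpec",
    "FieldSpec",
    "TubuleTruth",
    "GroundTruth",
    "ConfocalSpec",
    "ConfocalGroundTruth",
    "straight_tubule",
    "make_tubule_field",
    "make_confocal_stack",
]

# Localization-table column order shared with :mod:`tubulemorph.reconstruction`.
LOC_COLUMNS = ("frame", "x", "y", "intensity", "uncertainty")

#: Nominal photon count written into the intensity column.  The morphometry
#: readout is localization *counts*, so per-localization photon numbers are
#: carried only for format fidelity.
NOMINAL_PHOTONS = 1000.0


class SpecValidationError(ValueError):
    """A simulation spec violates one of its invariants; names the field."""


@dataclass(frozen=True)
class TubuleSpec:
    """A single tubule (microtubule or bundle) as a tube around a polyline.

    Parameters
    ----------
    centerline
        ``(n, 2)`` array of (x, y) points in nm, ``n >= 2``, consecutive
        points distinct.
    outer_diameter
        Outer diameter of the tube in nm (a single MT is ~25 nm; bundles
        are represented by a larger diameter).
    label
        Identifier used in the ground-truth assignment table.
    """

    centerline: np.ndarray
    outer_diameter: float
    label: int = 0

    def __post_init__(self) -> None:
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[1] != 2 or cl.shape[0] < 2:
            raise SpecValidationError(
                "centerline: expected an (n>=2, 2) array of points"
            )
        steps = np.linalg.norm(np.diff(cl, axis=0), axis=1)
        if np.any(steps == 0):
            raise SpecValidationError("centerline: consecutive points must be distinct")
        if not np.all(np.isfinite(cl)):
            raise SpecValidationError("centerline: coordinates must be finite")
        if not self.outer_diameter > 0:
            raise SpecValidationError("outer_diameter: must be > 0")
        object.__setattr__(self, "centerline", cl)

    @property
    def arc_length(self) -> float:
        """Total centerline length in nm."""
        return float(
            np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum()
        )


def straight_tubule(
    start: tuple[float, float],
    angle: float,
    length: float,
    outer_diameter: float,
    label: int = 0,
) -> TubuleSpec:
    """Convenience constructor for a straight tubule.

    ``angle`` is in radians, measured from the +x axis towards +y
    (image convention, y down).
    """
    sx, sy = start
    end = (sx + length * math.cos(angle), sy + length * math.sin(angle))
    return TubuleSpec(
        centerline=np.array([[sx, sy], list(end)]),
        outer_diameter=outer_diameter,
        label=label,
    )


@dataclass(frozen=True)
class FieldSpec:
    """Specification of one simulated dSTORM field of view.

    labeling_density is in emitters per nm of centerline;
    background_density in localizations per nm^2; loc_precision_sigma is the
    standard deviation (nm) of the isotropic Gaussian localization error.
    """

    field_size: tuple[float, float]  # (width, height) nm
    tubules: tuple[TubuleSpec, ...] = ()
    labeling_density: float = 0.5
    locs_per_emitter_mean: float = 4.0
    loc_precision_sigma: float = 2.0
    background_density: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.field_size
        if not (w > 0 and h > 0):
            raise SpecValidationError("field_size: both extents must be > 0")
        for name in ("labeling_density", "locs_per_emitter_mean", "background_density"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name}: must be >= 0")
        if self.loc_precision_sigma < 0:
            raise SpecValidationError("loc_precision_sigma: must be >= 0")
        object.__setattr__(self, "tubules", tuple(self.tubules))


@dataclass(frozen=True)
class TubuleTruth:
    """Per-tubule ground truth: true diameter, arc length, emitter count."""

    diameter: float
    length: float
    n_emitters: int


@dataclass(frozen=True)
class GroundTruth:
    """Simulator truth for one field.

    ``assignment`` has one entry per localization-table row: the tubule
    label, or -1 for background.
    """

    assignment: np.ndarray
    tubules: dict[int, TubuleTruth]
    n_background: int

    def locs_of(self, label: int) -> np.ndarray:
        """Row indices of localizations assigned to ``label``."""
        return np.flatnonzero(self.assignment == label)


def _points_on_polyline(cl: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Points and unit normals at arc positions ``s`` along polyline ``cl``."""
    seg = np.diff(cl, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.clip(s, 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    pts = cl[idx] + frac[:, None] * seg[idx]
    tang = seg[idx] / seg_len[idx][:, None]
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return pts, normals


def make_tubule_field(spec: FieldSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one dSTORM localization table with ground truth.

    For each tubule (in list order) the generator draws, in this fixed
    order from a single RNG seeded with ``spec.seed``:

    1. emitter count ~ Poisson(labeling_density * arc_length);
    2. emitter arc positions ~ Uniform(0, arc_length);
    3. transverse offsets ~ Uniform(-d/2, +d/2) along the local normal
       (a filled projected cylinder -- antibody geometry is not modelled);
    4. per-emitter localization counts ~ Poisson(locs_per_emitter_mean);
    5. localization errors ~ Normal(0, loc_precision_sigma), isotropic.

    After all tubules, the background count ~ Poisson(background_density *
    field area) and background positions ~ Uniform over the field.

    Returns
    -------
    (table, truth)
        ``table`` is a localization table (columns ``frame, x, y,
        intensity, uncertainty``; nm units).  ``truth`` records the
        per-localization tubule assignment and per-tubule diameter,
        length and emitter count.
    """
    rng = np.random.default_rng(spec.seed)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    assign: list[np.ndarray] = []
    tubule_truth: dict[int, TubuleTruth] = {}

    for tub in spec.tubules:
        L = tub.arc_length
        n_emitters = int(rng.poisson(spec.labeling_density * L))
        s = rng.uniform(0.0, L, size=n_emitters)
        offsets = rng.uniform(
            -tub.outer_diameter / 2.0, tub.outer_diameter / 2.0, size=n_emitters
        )
        counts = rng.poisson(spec.locs_per_emitter_mean, size=n_emitters)
        n_locs = int(counts.sum())
        noise = rng.normal(0.0, spec.loc_precision_sigma, size=(n_locs, 2))

        if tub.label in tubule_truth:
            raise SpecValidationError("tubules: duplicate tubule label")
        tubule_truth[tub.label] = TubuleTruth(
            diameter=tub.outer_diameter, length=L, n_emitters=n_emitters
        )
        if n_locs == 0:
            continue
        pts, normals = _points_on_polyline(tub.centerline, s)
        emitters = pts + offsets[:, None] * normals
        locs = np.repeat(emitters, counts, axis=0) + noise
        xs.append(locs[:, 0])
        ys.append(locs[:, 1])
        assign.append(np.full(n_locs, tub.label, dtype=np.int64))

    w, h = spec.field_size
    n_bg = int(rng.poisson(spec.background_density * w * h))
    if n_bg:
        bg = rng.uniform([0.0, 0.0], [w, h], size=(n_bg, 2))
        xs.append(bg[:, 0])
        ys.append(bg[:, 1])
        assign.append(np.full(n_bg, -1, dtype=np.int64))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        assignment = np.concatenate(assign)
    else:
        x = np.empty(0)
        y = np.empty(0)
        assignment = np.empty(0, dtype=np.int64)

    table = pd.DataFrame(
        {
            "frame": np.arange(len(x), dtype=np.int64),
            "x": x,
            "y": y,
            "intensity": np.full(len(x), NOMINAL_PHOTONS),
            "uncertainty": np.full(len(x), float(spec.loc_precision_sigma)),
        }
    )
    return table, GroundTruth(
        assignment=assignment, tubules=tubule_truth, n_background=n_bg
    )


# ---------------------------------------------------------------------------
# Confocal stacks


@dataclass(frozen=True)
class ConfocalSpec:
    """Specification of a synthetic two-channel confocal stack.

    The cell is a cylinder with its long axis along x.  Channel-A
    structures are short filament segments of radius ``structure_radius``;
    a deterministic fraction of them (``round(fraction_colocalized *
    n_structures_a)``, chosen by the seeded RNG) also appear in channel B,
    together with ``n_structures_b_only`` B-only segments.  Each channel is
    the binary structure mask times ``amplitude`` plus ``baseline``,
    blurred by a Gaussian PSF of per-axis sigma ``psf_sigma`` (nm), with
    additive Gaussian read noise of sd ``noise_sd``.
    """

    shape: tuple[int, int, int]  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (200.0, 100.0, 100.0)  # nm (z, y, x)
    n_structures_a: int = 10
    n_structures_b_only: int = 0
    structure_radius: float = 250.0  # nm
    segment_length: tuple[float, float] = (1000.0, 3000.0)  # nm
    fraction_colocalized: float = 0.5
    psf_sigma: tuple[float, float, float] = (0.0, 0.0, 0.0)  # nm (z, y, x)
    amplitude: float = 100.0
    baseline: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise SpecValidationError("shape: all extents must be > 0")
        if not 0.0 <= self.fraction_colocalized <= 1.0:
            raise SpecValidationError("fraction_colocalized: must be in [0, 1]")
        if any(v <= 0 for v in self.voxel_size):
            raise SpecValidationError("voxel_size: must be > 0")
        if self.structure_radius <= 0:
            raise SpecValidationError("structure_radius: must be > 0")


@dataclass(frozen=True)
class ConfocalGroundTruth:
    """Truth for a synthetic stack: per-structure voxel masks and sharing.

    ``coloc_fraction_a`` is the fraction of channel-A structure voxels that
    belong to at least one shared (both-channel) structure -- with zero PSF
    and zero noise this is exactly what Manders M1 should recover.
    """

    structure_voxels: dict[int, np.ndarray]  # id -> (n, 3) voxel indices (z, y, x)
    a_ids: tuple[int, ...]
    shared_ids: tuple[int, ...]
    b_only_ids: tuple[int, ...]
    coloc_fraction_a: float


def _rasterize_segment(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    p0: np.ndarray,
    p1: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Voxel indices within ``radius`` nm of segment p0-p1 (nm coords, z,y,x)."""
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    vox = np.asarray(voxel)
    i0 = np.maximum(np.floor(lo / vox).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / vox).astype(int) + 1, np.asarray(shape))
    if np.any(i0 >= i1):
        return np.empty((0, 3), dtype=np.int64)
    grids = np.meshgrid(
        *[(np.arange(a, b) + 0.5) * v for a, b, v in zip(i0, i1, vox)],
        indexing="ij",
    )
    pts = np.stack([g.ravel() for g in grids], axis=1)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        dist = np.linalg.norm(pts - p0, axis=1)
    else:
        t = np.clip((pts - p0) @ d / denom, 0.0, 1.0)
        proj = p0 + t[:, None] * d
        dist = np.linalg.norm(pts - proj, axis=1)
    keep = dist <= radius
    idx = np.stack(
        np.unravel_index(np.flatnonzero(keep), tuple(i1 - i0)), axis=1
    ) + i0
    return idx.astype(np.int64)


def make_confocal_stack(
    spec: ConfocalSpec,
) -> tuple[np.ndarray, ConfocalGroundTruth]:
    """Simulate a two-channel 3D stack with known colocalized fraction.

    Draw order from the single seeded RNG: (1) channel-A structure centres,
    directions and lengths; (2) the permutation selecting which A structures
    are shared with channel B (the first ``round(fraction * n)`` of the
    permutation -- so on matched seeds larger fractions give nested shared
    sets); (3) B-only structures; (4) channel-A noise; (5) channel-B noise.

    Returns
    -------
    (stack, truth)
        ``stack`` has shape ``(2, z, y, x)`` (channel A first);
        ``truth`` records per-structure voxel sets and the shared ids.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    vz, vy, vx = spec.voxel_size
    extent = np.array([nz * vz, ny * vy, nx * vx])  # nm (z, y, x)
    cyl_radius = 0.4 * min(extent[0], extent[1])

    def draw_segment() -> tuple[np.ndarray, np.ndarray]:
        # centre inside the cylinder (axis along x, centred in z/y)
        while True:
            c = rng.uniform(0.0, 1.0, size=3) * extent
            dz = c[0] - extent[0] / 2
            dy = c[1] - extent[1] / 2
            if dz * dz + dy * dy <= cyl_radius * cyl_radius:
                break
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        length = rng.uniform(*spec.segment_length)
        return c - u * length / 2, c + u * length / 2

    structures: dict[int, np.ndarray] = {}
    a_ids = tuple(range(spec.n_structures_a))
    for sid in a_ids:
        p0, p1 = draw_segment()
        structures[sid] = _rasterize_segment(
            spec.shape, spec.voxel_size, p0, p1, spec.structure_radius
        )

    n_shared = int(math.floor(spec.fraction_colocalized * spec.n_structures_a + 0.5))
    perm = rng.permutation(spec.n_structures_a)
    shared_ids = tuple(int(i) for i in perm[:n_shared])

    b_only_ids = tuple(
        range(spec.n_structures_a, spec.n_structures_a + spec.n_structures_b_only)
    )
    for sid in b_only_ids:
        p0, p1 = draw_segment()
        structures[sid] = _rasterize_segment(
            spec.shape, spec.voxel_size, p0, p1, spec.structure_radius
        )

    def union_mask(ids) -> np.ndarray:
        m = np.zeros(spec.shape, dtype=bool)
        for sid in ids:
            idx = structures[sid]
            if len(idx):
                m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return m

    mask_a = union_mask(a_ids)
    mask_shared = union_mask(shared_ids)
    mask_b = union_mask(shared_ids + b_only_ids)

    n_a = int(mask_a.sum())
    coloc_fraction = float((mask_a & mask_shared).sum() / n_a) if n_a else float("nan")

    sigma_vox = tuple(s / v for s, v in zip(spec.psf_sigma, spec.voxel_size))

    def render(mask: np.ndarray, noise: np.ndarray | None) -> np.ndarray:
        img = spec.baseline + spec.amplitude * mask.astype(float)
        if any(s > 0 for s in sigma_vox):
            img = gaussian_filter(img, sigma_vox, mode="constant")
        if noise is not None:
            img = img + noise
        return img

    noise_a = rng.normal(0.0, spec.noise_sd, size=spec.shape) if spec.noise_sd else None
    noise_b = rng.normal(0.0, spec.noise_sd, size=spec.shape) if spec.noise_sd else None
    stack = np.stack([render(mask_a, noise_a), render(mask_b, noise_b)])

    truth = ConfocalGroundTruth(
        structure_voxels=structures,
        a_ids=a_ids,
        shared_ids=shared_ids,
        b_only_ids=b_only_ids,
        coloc_fraction_a=coloc_fraction,
    )
    return stack, truth
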