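"""3D colocalization (Manders M1/M2) and ROI volume/intensity quantification.

Operates on two-channel confocal stacks of pollen tubes.  Manders
coefficients measure the fraction of one channel's integrated intensity
that lies in voxels where the other channel is above threshold -- the
standard readout for "how much of protein X is on structure Y".  The ROI
quantifications reproduce the "full object" convention: the tube volume is
everything above a permissive low threshold, microtubules are everything
above a structure-specific threshold, and percent volume is their ratio.
Mean ROI intensity is evaluated on a small set of medial z-planes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfocalStack",
    "ROIBox",
    "MandersResult",
    "manders_coefficients",
    "percent_volume",
    "mean_roi_intensity",
    "roi_from_micron",
    "write_stack",
    "read_stack",
]


@dataclass(frozen=True)
class ConfocalStack:
    """Two-channel 3D intensity data with voxel size.

    ``data`` has shape (2, z, y, x); ``voxel_size`` is nm per axis
    (z, y, x).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4 or d.shape[0] != 2:
            raise ValueError("data must have shape (2, z, y, x)")
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, idx: int) -> np.ndarray:
        return self.data[idx]


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned half-open voxel box, labelled by tube zone."""

    z: tuple[int, int]
    y: tuple[int, int]
    x: tuple[int, int]
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("z", "y", "x"):
            a, b = getattr(self, name)
            if not (0 <= a < b):
                raise ValueError(f"{name}: ROI range must be non-empty and >= 0")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.z), slice(*self.y), slice(*self.x))

    def check_bounds(self, shape: tuple[int, int, int]) -> None:
        for (a, b), n, name in zip((self.z, self.y, self.x), shape, "zyx"):
            if b > n:
                raise ValueError(f"ROI {name} range {(a, b)} exceeds stack extent {n}")


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def roi_from_micron(
    stack: ConfocalStack,
    x_um: tuple[float, float],
    label: str = "",
) -> ROIBox:
    """Build a full-cross-section ROI spanning ``x_um`` along the tube axis.

    Micron positions convert to voxel indices via the x voxel size,
    rounding half up; z and y span the whole stack.
    """
    nz, ny, nx = stack.shape
    vx = stack.voxel_size[2]
    a = _round_half_up(x_um[0] * 1000.0 / vx)
    b = _round_half_up(x_um[1] * 1000.0 / vx)
    a = max(0, min(a, nx - 1))
    b = max(a + 1, min(b, nx))
    return ROIBox(z=(0, nz), y=(0, ny), x=(a, b), label=label)


@dataclass(frozen=True)
class MandersResult:
    """Manders coefficients; NaN with ``defined=False`` when a channel sum is 0."""

    m1: float
    m2: float
    m1_defined: bool = True
    m2_defined: bool = True


def manders_coefficients(
    cha: np.ndarray,
    chb: np.ndarray,
    thresh_a: float = 0.0,
    thresh_b: float = 0.0,
    roi: ROIBox | None = None,
) -> MandersResult:
    """Manders colocalization coefficients M1 and M2.

    M1 is the fraction of channel-A intensity (over voxels with A >
    thresh_a) that lies in voxels where B > thresh_b; M2 is symmetric
    with the channel roles swapped.  Both lie in [0, 1].  Sums are
    restricted to ``roi`` when given.  A zero denominator yields NaN with
    the corresponding ``defined`` flag cleared, never a silent 0.
    """
    a = np.asarray(cha, dtype=float)
    b = np.asarray(chb, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must be congruent in shape")
    if thresh_a < 0 or thresh_b < 0:
        raise ValueError("thresholds must be >= 0")
    if roi is not None:
        roi.check_bounds(a.shape)
        a = a[roi.slices]
        b = b[roi.slices]
    above_a = a > thresh_a
    above_b = b > thresh_b

    denom1 = float(a[above_a].sum())
    denom2 = float(b[above_b].sum())
    num1 = float(a[above_a & above_b].sum())
    num2 = float(b[above_a & above_b].sum())
    m1 = num1 / denom1 if denom1 > 0 else float("nan")
    m2 = num2 / denom2 if denom2 > 0 else float("nan")
    return MandersResult(
        m1=m1, m2=m2, m1_defined=denom1 > 0, m2_defined=denom2 > 0
    )


def percent_volume(
    stack: ConfocalStack,
    channel: int,
    roi: ROIBox,
    low_threshold: float,
    mt_threshold: float,
) -> float:
    """Percent of the "full object" volume occupied by thresholded signal.

    The full object is every ROI voxel above ``low_threshold`` (a
    permissive threshold capturing the whole tube); the structure volume
    is every ROI voxel above ``mt_threshold``.  Returns
    ``100 * structure / full``; NaN when the full object is empty.
    """
    if mt_threshold < low_threshold:
        raise ValueError("mt_threshold must be >= low_threshold")
    ch = stack.channel(channel)
    roi.check_bounds(ch.shape)
    sub = ch[roi.slices]
    full = int((sub > low_threshold).sum())
    if full == 0:
        return float("nan")
    mt = int((sub > mt_threshold).sum())
    return 100.0 * mt / full


def mean_roi_intensity(
    stack: ConfocalStack,
    channel: int,
    roi: ROIBox,
    planes: list[int] | None = None,
) -> float:
    """Mean voxel intensity over selected z-planes within the ROI.

    ``planes`` defaults to the five central planes: the window of 5
    centred on plane ``ceil(n_z / 2)`` (1-based), clipped to the stack.
    """
    ch = stack.channel(channel)
    roi.check_bounds(ch.shape)
    nz = ch.shape[0]
    if planes is None:
        center = math.ceil(nz / 2) - 1  # 0-based index of the medial plane
        planes = [p for p in range(center - 2, center + 3) if 0 <= p < nz]
    planes = sorted(set(int(p) for p in planes))
    if not planes:
        raise ValueError("planes must be non-empty")
    if planes[0] < 0 or planes[-1] >= nz:
        raise ValueError(f"planes {planes} outside stack z-extent {nz}")
    zsel = [p for p in planes if roi.z[0] <= p < roi.z[1]]
    if not zsel:
        raise ValueError("no selected plane intersects the ROI z-range")
    sub = ch[zsel][:, roi.slices[1], roi.slices[2]]
    return float(sub.mean())


def write_stack(
    stack: ConfocalStack, path: str | Path, extra_metadata: dict | None = None
) -> None:
    """Write a stack as multi-page TIFF (CZYX pages) with a JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        photometric="minisblack",
        planarconfig="separate",
    )
    meta = {"voxel_size_nm": list(stack.voxel_size), "axes": "CZYX"}
    if extra_metadata:
        meta.update(extra_metadata)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_stack(
    path: str | Path, voxel_size: tuple[float, float, float] | None = None
) -> ConfocalStack:
    """Read a stack written by :func:`write_stack`.

    Voxel size comes from the JSON sidecar unless given explicitly.
    """
    import tifffile

    path = Path(path)
    data = tifffile.imread(path)
    if voxel_size is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no voxel size given and no sidecar at {sidecar}"
            )
        meta = json.loads(sidecar.read_text())
        voxel_size = tuple(meta["voxel_size_nm"])
    return ConfocalStack(data=np.asarray(data), voxel_size=tuple(voxel_size))
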