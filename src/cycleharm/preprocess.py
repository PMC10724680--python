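"""In-scope preprocessing: median normalization, pad/crop, brain histograms.

Upstream steps (skull-stripping, bias-field correction, affine registration)
are external: this module consumes volumes that are already masked and
registered.  What remains before harmonization is

* **median-500 normalization** — a pure rescaling that sets the median of the
  brain voxels to a target intensity (default 500), which is less sensitive
  to outliers than max normalization;
* **pad/crop to a cube** (default 192 per axis, tests use smaller grids) that
  never removes a brain voxel;
* **brain-intensity histograms** — 100 consecutive bins from 0 to 900 by
  default — and their per-site averages, the raw material for histogram
  distances and the multisite heterogeneity index.

Intensities above the histogram ceiling are ignored (not clipped into the
last bin); the ignored count is reported so counts always reconcile with the
brain-voxel total.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import DegenerateInputError, Volume

__all__ = ["HistogramSummary", "normalize_median", "pad_crop",
           "brain_histogram", "average_histograms"]


@dataclasses.dataclass
class HistogramSummary:
    """Bin counts (or mean counts) with shared edges; ``ignored`` is the
    number of brain voxels outside the histogram range."""

    counts: np.ndarray
    edges: np.ndarray
    ignored: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.float64)
        if len(self.edges) != len(self.counts) + 1:
            raise ValueError("edges must have length len(counts) + 1")
        if (self.counts < 0).any():
            raise ValueError("negative bin count")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"lo": self.edges[:-1], "hi": self.edges[1:],
                             "count": self.counts})


def normalize_median(vol: Volume, target: float = 500.0) -> Volume:
    """Rescale so the median brain intensity equals ``target``.

    Pure rescaling (output = input * target / median); the background stays
    zero.  The median uses the midpoint-of-two convention for even counts.
    Idempotent up to floating tolerance.
    """
    brain = vol.brain_values()
    med = float(np.median(brain))
    if med <= 0:
        raise DegenerateInputError("median brain intensity is not positive")
    return vol.copy_with(vol.data * (target / med))


def pad_crop(vol: Volume, target: int = 192) -> Volume:
    """Pad and crop to ``target`` voxels per axis without removing any brain
    voxel.

    Centering rule: the brain bounding-box center maps to the grid center,
    ties broken toward the lower index.  Refuses (rather than silently
    cropping brain) if the brain extent exceeds the target on any axis.
    """
    if not vol.mask.any():
        raise DegenerateInputError("brain mask is empty")
    nz = np.nonzero(vol.mask)
    out_data = np.zeros((target,) * 3, dtype=vol.data.dtype)
    out_mask = np.zeros((target,) * 3, dtype=bool)
    src_slices, dst_slices = [], []
    for axis in range(3):
        lo, hi = int(nz[axis].min()), int(nz[axis].max())
        extent = hi - lo + 1
        if extent > target:
            raise ValueError(
                f"brain extent {extent} exceeds target {target} on axis {axis}; "
                "refusing to crop brain voxels")
        bbox_center = (lo + hi) / 2.0
        out_center = (target - 1) / 2.0
        # round half toward the lower index
        shift = int(np.ceil(out_center - bbox_center - 0.5))
        n_in = vol.data.shape[axis]
        src_lo = max(0, -shift)
        src_hi = min(n_in, target - shift)
        dst_lo = src_lo + shift
        dst_hi = src_hi + shift
        src_slices.append(slice(src_lo, src_hi))
        dst_slices.append(slice(dst_lo, dst_hi))
    out_data[tuple(dst_slices)] = vol.data[tuple(src_slices)]
    out_mask[tuple(dst_slices)] = vol.mask[tuple(src_slices)]
    if out_mask.sum() != vol.mask.sum():
        raise ValueError("internal error: pad_crop lost brain voxels")
    return Volume(out_data, out_mask, vol.spacing, vol.affine)


def brain_histogram(vol: Volume, n_bins: int = 100, lo: float = 0.0,
                    hi: float = 900.0) -> HistogramSummary:
    """Histogram of brain-voxel intensities over ``n_bins`` consecutive bins
    from ``lo`` to ``hi``.

    Bins are half-open [e_i, e_{i+1}) with the last bin closed at ``hi``;
    voxels outside [lo, hi] are ignored and counted in ``ignored``.
    """
    brain = vol.brain_values()
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(brain, bins=edges)
    ignored = int(((brain < lo) | (brain > hi)).sum())
    return HistogramSummary(counts=counts.astype(float), edges=edges,
                            ignored=ignored)


def average_histograms(hists: list[HistogramSummary]) -> HistogramSummary:
    """Elementwise arithmetic mean of histograms sharing the same edges."""
    if not hists:
        raise ValueError("need at least one histogram")
    edges = hists[0].edges
    for h in hists[1:]:
        if not np.array_equal(h.edges, edges):
            raise ValueError("histograms have mismatched edges")
    counts = np.mean([h.counts for h in hists], axis=0)
    ignored = int(round(float(np.mean([h.ignored for h in hists]))))
    return HistogramSummary(counts=counts, edges=edges.copy(), ignored=ignored)
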