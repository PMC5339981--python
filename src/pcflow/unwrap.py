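"""Salvage of velocity-aliased maps by phase unwrapping.

Decoded velocities live on a circle of circumference 2*venc; a true velocity
just above venc appears as a large negative value.  Because the aortic jet is
temporally transient (it rises from and returns to near-zero flow), a
temporal pass can re-anchor each pixel on its low-flow frame and undo wraps
by adding multiples of 2*venc wherever consecutive frames jump by more than
venc.  A spatial pass region-grows from a low-velocity seed for maps aliased
in some frames everywhere in time.  ``hybrid`` applies temporal then one
spatial pass.

Unwrapping is attempted only for directions the wrap detector flags; if a
direction still shows wrap signatures afterwards (e.g. velocity aliased in
every frame with no anchor), the salvage is declared failed and the maps are
returned unchanged — the pipeline then excludes that subject, mirroring
clinical practice of discarding unrecoverable acquisitions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .encoding import DIRECTIONS, VelocityMaps, detect_aliasing, _lumen_estimate

__all__ = ["UnwrapReport", "unwrap_velocity"]

_METHODS = ("temporal", "spatial", "hybrid")


@dataclass
class UnwrapReport:
    """Accounting of a salvage attempt."""

    attempted: list[str] = field(default_factory=list)
    corrections: dict[str, int] = field(default_factory=dict)
    corrections_per_frame: dict[str, np.ndarray] = field(default_factory=dict)
    unanchored_pixels: dict[str, int] = field(default_factory=dict)
    salvage_failed: dict[str, bool] = field(default_factory=dict)

    @property
    def total_corrections(self) -> int:
        return int(sum(self.corrections.values()))

    @property
    def failed(self) -> bool:
        return any(self.salvage_failed.values())


def _temporal_unwrap(v: np.ndarray, pixels: np.ndarray, venc: float,
                     anchor_frac: float) -> tuple[np.ndarray, int]:
    """Per-pixel temporal unwrap anchored on the lowest-|v| frame."""
    out = v.copy()
    unanchored = 0
    ys, xs = np.nonzero(pixels)
    period = 2.0 * venc
    for y, x in zip(ys, xs):
        seq = v[:, y, x]
        i0 = int(np.argmin(np.abs(seq)))
        if abs(seq[i0]) > anchor_frac * venc:
            unanchored += 1
            continue
        new = seq.copy()
        new[i0:] = np.unwrap(seq[i0:], period=period)
        new[: i0 + 1] = np.unwrap(seq[i0::-1], period=period)[::-1]
        out[:, y, x] = new
    return out, unanchored


def _spatial_unwrap_frame(v2d: np.ndarray, mask: np.ndarray, venc: float) -> np.ndarray:
    """Region-grow from the lowest-|v| masked pixel, shifting by 2*venc steps."""
    out = v2d.copy()
    if not mask.any():
        return out
    period = 2.0 * venc
    flat = np.where(mask, np.abs(out), np.inf)
    seed = np.unravel_index(int(np.argmin(flat)), out.shape)
    visited = np.zeros_like(mask)
    visited[seed] = True
    q: deque[tuple[int, int]] = deque([seed])
    ny, nx = out.shape
    while q:
        y, x = q.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] and not visited[yy, xx]:
                k = round((out[yy, xx] - out[y, x]) / period)
                if k:
                    out[yy, xx] -= period * k
                visited[yy, xx] = True
                q.append((yy, xx))
    return out


def unwrap_velocity(
    maps: VelocityMaps,
    method: str = "temporal",
    *,
    lumen_mask: np.ndarray | None = None,
    anchor_frac: float = 0.9,
    detect_kwargs: dict | None = None,
) -> tuple[VelocityMaps, UnwrapReport]:
    """Unwrap flagged directions; return (possibly new) maps and a report.

    When nothing is flagged the input is returned untouched with zero
    corrections.  When any flagged direction cannot be salvaged, the original
    maps are returned and ``report.salvage_failed`` marks the direction.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    detect_kwargs = detect_kwargs or {}
    mask = _lumen_estimate(maps) if lumen_mask is None else lumen_mask

    before = detect_aliasing(maps, lumen_mask=mask, **detect_kwargs)
    report = UnwrapReport()
    flagged = [d for d in DIRECTIONS if before.direction_flags[d]]
    if not flagged:
        return maps, report

    new = maps.copy()
    for d in flagged:
        report.attempted.append(d)
        v = new.component(d)
        orig = v.copy()
        unanchored = 0
        if method in ("temporal", "hybrid"):
            # Restrict the per-pixel pass to the flagged neighbourhood.
            region = ndimage.binary_dilation(before.pixel_maps[d], iterations=1) & mask
            v, unanchored = _temporal_unwrap(v, region, maps.venc, anchor_frac)
        if method in ("spatial", "hybrid"):
            for f in range(v.shape[0]):
                v[f] = _spatial_unwrap_frame(v[f], mask, maps.venc)
        changed = v != orig
        report.corrections[d] = int(changed.sum())
        report.corrections_per_frame[d] = changed.sum(axis=(1, 2))
        report.unanchored_pixels[d] = unanchored
        if d == "x":
            new.vx = v
        elif d == "y":
            new.vy = v
        else:
            new.vz = v

    after = detect_aliasing(new, lumen_mask=mask, **detect_kwargs)
    for d in flagged:
        report.salvage_failed[d] = after.direction_flags[d]
    if report.failed:
        return maps, report
    new.aliased_flag = after.direction_flags
    return new, report
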