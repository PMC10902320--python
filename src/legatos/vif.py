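"""Vascular input function extraction and segment concatenation.

The plasma input Cp(t) is measured in the superior sagittal sinus (SSS): a
vessel mask is drawn manually, and voxels whose first-pass enhancement peak
is largest are selected automatically and averaged.  Because the interleaved
protocol splits the high-temporal (HT) series into an initial arterial block
plus later segments between the high-spatial frames, the HT samples must be
concatenated by acquisition time into a single curve before extraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import VascularInputFunction

__all__ = [
    "Segment",
    "SegmentedSeries",
    "concatenate_segments",
    "extract_vif",
    "write_vif",
    "read_vif",
]


@dataclass(frozen=True)
class Segment:
    """One acquisition segment: absolute frame times and their values.

    ``values`` has time on the last axis (1-D for a single voxel curve,
    4-D ``(x, y, z, t)`` for a volume segment).
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape[-1] != t.size:
            raise ValueError("segment values must have time on the last axis")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("within-segment times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def start(self) -> float:
        return float(self.times[0])

    @property
    def end(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class SegmentedSeries:
    """A list of non-overlapping acquisition segments sharing one resolution."""

    segments: tuple[Segment, ...]
    resolution: str = "HT"  # HT | HS

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("series must contain at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))


def concatenate_segments(series: SegmentedSeries) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate all segments by acquisition time.

    Returns a single strictly increasing time axis and the values in
    acquisition order; every input sample appears exactly once.  Overlapping
    segment windows raise an error naming the offending pair.
    """
    order = np.argsort([s.start for s in series.segments], kind="stable")
    segs = [series.segments[i] for i in order]
    for a, b in zip(segs[:-1], segs[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"segments overlap in time: [{a.start:g}, {a.end:g}] s and "
                f"[{b.start:g}, {b.end:g}] s"
            )
    times = np.concatenate([s.times for s in segs])
    values = np.concatenate([s.values for s in segs], axis=-1)
    return times, values


def extract_vif(
    conc_4d: np.ndarray,
    times: np.ndarray,
    vessel_mask: np.ndarray,
    n_select: int = 10,
    first_pass_window_s: float = 60.0,
) -> VascularInputFunction:
    """Extract the plasma input from a vessel mask of a concentration series.

    Mask voxels are ranked by their peak concentration within the first-pass
    window (default first 60 s); the top ``n_select`` voxel curves are
    averaged to form Cp(t).

    Parameters
    ----------
    conc_4d : (x, y, z, t) concentration volume in mM.
    times : frame times in seconds.
    vessel_mask : boolean 3-D mask of the vessel.
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    if not mask.any():
        raise ValueError("vessel mask is empty")
    curves = np.asarray(conc_4d, dtype=float)[mask]  # (n_voxels, t)
    n_vox = curves.shape[0]
    if n_select > n_vox:
        raise ValueError(f"n_select={n_select} exceeds mask size {n_vox}")
    times = np.asarray(times, dtype=float)
    window = times <= times[0] + first_pass_window_s
    peaks = curves[:, window].max(axis=1)
    if np.allclose(peaks, peaks[0]):
        warnings.warn("all vessel-mask curves are flat; VIF may be unreliable")
    top = np.argsort(peaks, kind="stable")[::-1][:n_select]
    cp = curves[top].mean(axis=0)
    return VascularInputFunction(times=times, cp=cp, provenance="measured")


def write_vif(vif: VascularInputFunction, path, metadata: dict | None = None) -> None:
    """Write a VIF as two-column TSV (time_s, Cp_mM) plus a JSON sidecar."""
    path = Path(path)
    header = "time_s\tCp_mM"
    np.savetxt(path, np.column_stack([vif.times, vif.cp]),
               delimiter="\t", header=header, comments="")
    side = {"provenance": vif.provenance, "n_samples": int(vif.times.size)}
    side.update(metadata or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=2))


def read_vif(path) -> VascularInputFunction:
    """Read a VIF written by :func:`write_vif`."""
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    provenance = "measured"
    side = Path(path).with_suffix(Path(path).suffix + ".json")
    if side.exists():
        provenance = json.loads(side.read_text()).get("provenance", provenance)
    return VascularInputFunction(times=arr[:, 0], cp=arr[:, 1], provenance=provenance)
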