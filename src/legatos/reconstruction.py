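"""Dual-temporal-resolution (DTR) curve merging, calibration and mapping.

A merged voxel curve carries a high-temporal (HT) low-spatial 'arterial'
phase followed by a low-temporal high-spatial (HS) 'parenchymal' phase.  The
observed level difference between the two phases in a voxel reflects their
differing native spatial resolution, so the arterial phase is rescaled by a
per-voxel calibration ratio

    ratio_calib = mean(first 5 HS frames after the concatenation point)
                / mean(last 4 HT frames before it)

to obtain a smooth concatenation before kinetic fitting.  Voxelwise fitting
runs on the HS grid: HT voxel curves are resampled to the HS grid
(nearest-neighbour block mapping by default), both series are converted to
concentration, merged, calibrated, and fitted with the extended Tofts model
against the vascular input function.  Per-voxel failures are flagged in the
output maps and never abort the volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import (FitConfig, FitResult, KineticParams, TissueCurve,
                       VascularInputFunction, fit_etm)
from .signal_model import (AcquisitionParams, ContrastAgentSpec,
                           RelaxationState, si_to_concentration)

__all__ = [
    "MergedCurve",
    "ParameterMaps",
    "ReconConfig",
    "merge_dtr",
    "calibration_ratio",
    "rescale_arterial",
    "fit_voxelwise",
]

#: Frame counts entering the calibration ratio, on either side of the
#: concatenation point.
N_HS_CALIB = 5
N_HT_CALIB = 4


@dataclass(frozen=True)
class MergedCurve:
    """Concatenated HT-arterial + HS-parenchymal concentration curve."""

    times: np.ndarray
    conc: np.ndarray
    concat_index: int
    ratio_calib: float | None = None
    ratio_flagged: bool = False
    source: str = "LEGATOS_LDHS"  # LEGATOS_LDHS | LEGATOS_DICE

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and conc must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("merged times must be strictly increasing")
        if self.ratio_calib is not None and not self.ratio_calib > 0:
            raise ValueError("calibration ratio must be positive when defined")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)

    def as_tissue_curve(self) -> TissueCurve:
        return TissueCurve(times=self.times, ct=self.conc)


@dataclass
class ParameterMaps:
    """Voxelwise kinetic maps on the HS grid; NaN marks out-of-mask/failed."""

    ktrans: np.ndarray
    vp: np.ndarray
    ve: np.ndarray
    bat: np.ndarray
    sfe: np.ndarray
    affine: np.ndarray
    source: str = "LEGATOS_LDHS"

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.ktrans, self.vp, self.ve, self.bat, self.sfe)}
        if len(shapes) != 1:
            raise ValueError("all parameter maps must share one shape")

    @property
    def shape(self):
        return self.ktrans.shape

    def items(self):
        return {"ktrans": self.ktrans, "vp": self.vp, "ve": self.ve,
                "bat": self.bat, "sfe": self.sfe}.items()


@dataclass(frozen=True)
class ReconConfig:
    """Knobs of the DTR reconstruction pipeline."""

    concat_time_s: float = 73.0          # end of the 50-frame HT arterial phase
    n_baseline_ht: int = 6
    n_baseline_hs: int = 2
    sfe_threshold: float = 0.5
    centile: float = 99.0
    ht_to_hs_interp: str = "nearest"     # nearest | linear
    source: str = "LEGATOS_LDHS"


def merge_dtr(ht_curve: TissueCurve, hs_curve: TissueCurve,
              concat_time_s: float) -> MergedCurve:
    """Concatenate an HT arterial curve with an HS parenchymal curve.

    HT frames must lie at or before ``concat_time_s`` and HS frames strictly
    after it (earlier HS frames, e.g. pre-injection baselines, are dropped).
    Neither phase is resampled.  Requires >= 4 HT frames before and >= 5 HS
    frames after the concatenation point so the calibration ratio is defined.
    """
    ht_keep = ht_curve.times <= concat_time_s + 1e-9
    hs_keep = hs_curve.times > concat_time_s + 1e-9
    n_ht, n_hs = int(ht_keep.sum()), int(hs_keep.sum())
    if n_ht < N_HT_CALIB:
        raise ValueError(
            f"need >= {N_HT_CALIB} HT frames before the concatenation point, got {n_ht}")
    if n_hs < N_HS_CALIB:
        raise ValueError(
            f"need >= {N_HS_CALIB} HS frames after the concatenation point, got {n_hs}")
    if ht_keep.sum() != ht_curve.times.size:
        raise ValueError("HT curve extends past the concatenation point; "
                         "the HT phase must precede the HS phase")
    times = np.concatenate([ht_curve.times[ht_keep], hs_curve.times[hs_keep]])
    conc = np.concatenate([ht_curve.ct[ht_keep], hs_curve.ct[hs_keep]])
    return MergedCurve(times=times, conc=conc, concat_index=n_ht)


def calibration_ratio(curve: MergedCurve) -> tuple[float, bool]:
    """Per-voxel calibration ratio of the merged curve.

    ratio = mean(first 5 HS frames) / mean(last 4 HT frames).  A
    non-positive HT mean leaves the ratio undefined; such voxels fall back
    to ratio 1 with the flag set, so maps stay dense.
    """
    i = curve.concat_index
    ht_mean = float(np.mean(curve.conc[i - N_HT_CALIB:i]))
    hs_mean = float(np.mean(curve.conc[i:i + N_HS_CALIB]))
    if ht_mean <= 0:
        return 1.0, True
    return hs_mean / ht_mean, False


def rescale_arterial(curve: MergedCurve, ratio: float | None = None,
                     flagged: bool = False) -> MergedCurve:
    """Rescale the HT arterial phase by the calibration ratio.

    Every pre-concatenation sample is multiplied by the ratio; parenchymal
    samples are untouched.  With ``ratio=None`` the ratio is computed from
    the curve itself, making rescaled means on the two sides of the junction
    equal by construction.
    """
    if ratio is None:
        ratio, flagged = calibration_ratio(curve)
    conc = curve.conc.copy()
    conc[: curve.concat_index] *= ratio
    return replace(curve, conc=conc, ratio_calib=ratio, ratio_flagged=flagged)


def _hs_to_ht_index_map(hs_shape, hs_affine, ht_shape, ht_affine):
    """Nearest-neighbour HT voxel index for every HS voxel (block mapping)."""
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in hs_shape], indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    world = hs_affine @ vox
    ht_idx = np.linalg.inv(ht_affine) @ world
    ht_idx = np.rint(ht_idx[:3]).astype(int)
    for ax, n in enumerate(ht_shape[:3]):
        np.clip(ht_idx[ax], 0, n - 1, out=ht_idx[ax])
    return tuple(ht_idx.reshape(3, *hs_shape))


def _as_array_affine(img):
    """Accept a nibabel image or an (array, affine) pair."""
    if hasattr(img, "get_fdata"):
        return np.asarray(img.get_fdata(), dtype=float), img.affine
    arr, aff = img
    return np.asarray(arr, dtype=float), np.asarray(aff, dtype=float)


def fit_voxelwise(
    ht_img,
    hs_img,
    ht_times,
    hs_times,
    vif: VascularInputFunction,
    r1_map,
    mask_img,
    agent: ContrastAgentSpec,
    acq_ht: AcquisitionParams,
    acq_hs: AcquisitionParams,
    fit_config: FitConfig | None = None,
    recon_config: ReconConfig | None = None,
) -> tuple[ParameterMaps, dict]:
    """Voxelwise DTR kinetic mapping on the HS grid.

    Parameters
    ----------
    ht_img, hs_img : 4-D SI series (nibabel image or (array, affine)).
    ht_times, hs_times : frame times in seconds.
    r1_map : 3-D R1_0 map (1/s) on the HS grid, used for both series'
        concentration conversion (native R1 is resolution-independent).
    mask_img : 3-D boolean mask on the HS grid.

    Returns
    -------
    (maps, qc) : parameter maps (NaN outside the mask / on failure) and a QC
    summary with flagged-ratio, non-converged and high-SFE fractions.
    """
    cfg = recon_config or ReconConfig()
    fcfg = fit_config or FitConfig()
    ht_4d, ht_aff = _as_array_affine(ht_img)
    hs_4d, hs_aff = _as_array_affine(hs_img)
    r1_arr, _ = _as_array_affine(r1_map) if not isinstance(r1_map, np.ndarray) else (r1_map, None)
    mask, _ = _as_array_affine(mask_img) if not isinstance(mask_img, np.ndarray) else (mask_img, None)
    mask = mask.astype(bool)
    ht_times = np.asarray(ht_times, dtype=float)
    hs_times = np.asarray(hs_times, dtype=float)

    hs_shape = hs_4d.shape[:3]
    maps = {k: np.full(hs_shape, np.nan) for k in ("ktrans", "vp", "ve", "bat", "sfe")}
    idx_map = _hs_to_ht_index_map(hs_shape, hs_aff, ht_4d.shape, ht_aff)

    arterial = ht_times <= cfg.concat_time_s + 1e-9
    n_flagged = n_failed = n_fitted = 0

    for (i, j, k) in zip(*np.nonzero(mask)):
        r1_0 = float(r1_arr[i, j, k])
        if not np.isfinite(r1_0) or r1_0 <= 0:
            n_failed += 1
            continue
        state = RelaxationState(r1_0=r1_0, m0=1.0)  # M0 re-estimated from baselines
        hi, hj, hk = idx_map[0][i, j, k], idx_map[1][i, j, k], idx_map[2][i, j, k]
        ht_si = ht_4d[hi, hj, hk]
        hs_si = hs_4d[i, j, k]
        ht_conc, _ = si_to_concentration(ht_si, cfg.n_baseline_ht, state, agent, acq_ht)
        hs_conc, _ = si_to_concentration(hs_si, cfg.n_baseline_hs, state, agent, acq_hs)
        try:
            merged = merge_dtr(
                TissueCurve(times=ht_times[arterial], ct=ht_conc[arterial]),
                TissueCurve(times=hs_times, ct=hs_conc),
                cfg.concat_time_s,
            )
            merged = rescale_arterial(merged)
            if merged.ratio_flagged:
                n_flagged += 1
            fit = fit_etm(merged.as_tissue_curve(), vif, fcfg)
        except Exception:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        maps["ktrans"][i, j, k] = fit.params.ktrans
        maps["vp"][i, j, k] = fit.params.vp
        maps["ve"][i, j, k] = fit.params.ve
        maps["bat"][i, j, k] = fit.bat
        maps["sfe"][i, j, k] = fit.sfe
        n_fitted += 1

    n_mask = int(mask.sum())
    sfe_vals = maps["sfe"][mask]
    n_high_sfe = int(np.sum(sfe_vals > cfg.sfe_threshold))
    qc = {
        "n_mask_voxels": n_mask,
        "n_fitted": n_fitted,
        "n_failed": n_failed,
        "n_ratio_flagged": n_flagged,
        "frac_ratio_flagged": n_flagged / n_mask if n_mask else 0.0,
        "n_sfe_above_threshold": n_high_sfe,
        "frac_sfe_above_threshold": n_high_sfe / n_mask if n_mask else 0.0,
        "sfe_threshold": cfg.sfe_threshold,
        "source": cfg.source,
    }
    pm = ParameterMaps(affine=hs_aff, source=cfg.source, **maps)
    return pm, qc
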