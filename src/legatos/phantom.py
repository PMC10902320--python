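"""Seeded synthetic 4D phantom matching the interleaved DTR acquisition.

Emits registered high-temporal (HT) and high-spatial (HS) dynamic SPGR
series, an optional higher-dose HS series (for the dual-injection variant),
variable-flip-angle volumes for R1_0 mapping, tumour and vessel masks, and
ground-truth kinetic parameter maps — all as NIfTI-1 with shared world
space, plus a JSON manifest carrying the seed and configuration.

The phantom is geometric, not anatomical: an ellipsoidal tumour with
uniform extended Tofts kinetics and a cylindrical vessel carrying the
population plasma input sit in a non-enhancing background.  Grids default
to a 0.25-scale version of the full acquisition matrices (HT 96x96x28 at
2.5x2.5x5 mm; HS 240x240x56 at 1x1x2.5 mm) so end-to-end tests run in
minutes; scale 1.0 reproduces the full geometry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .kinetics import KineticParams, etm_forward
from .signal_model import RelaxationState, ContrastAgentSpec, spgr_signal, m0_for_baseline
from .simulation import (ACQ_HS, ACQ_HT, NL_HS_DEFAULT, NL_HT_DEFAULT,
                         NoiseSpec, PopulationVIFModel, SamplingScheme,
                         add_rician_noise)

__all__ = ["PhantomConfig", "build_phantom", "generate_phantom"]

FULL_HT_SHAPE = (96, 96, 28)
FULL_HS_SHAPE = (240, 240, 56)
HT_VOXEL_MM = (2.5, 2.5, 5.0)
HS_VOXEL_MM = (1.0, 1.0, 2.5)
VFA_ANGLES_DEG = (2.0, 6.0, 12.0, 16.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, kinetics and noise of the synthetic phantom.

    Tumour and vessel are defined in world millimetres as fractions of the
    field of view, so they stay inside the grid at any ``scale``.  Noise
    levels default to the protocol's HT/HS values; set them to zero for a
    noiseless phantom.
    """

    scale: float = 0.25
    seed: int = 0
    tumour_params: KineticParams = KineticParams(ktrans=0.26, vp=0.07, ve=0.5)
    tumour_center_frac: tuple[float, float, float] = (0.5, 0.5, 0.5)
    tumour_radii_frac: tuple[float, float, float] = (0.12, 0.12, 0.15)
    vessel_center_frac: tuple[float, float] = (0.2, 0.2)
    vessel_radius_frac: float = 0.06
    r1_0_background: float = 1.0
    r1_0_tumour: float = 1.0
    r1_0_vessel: float = 0.7
    baseline_ht: float = 371.1
    baseline_hs: float = 84.4
    noise_ht: NoiseSpec = NL_HT_DEFAULT
    noise_hs: NoiseSpec = NL_HS_DEFAULT
    scheme: SamplingScheme = SamplingScheme()
    vif_model: PopulationVIFModel = PopulationVIFModel()
    agent: ContrastAgentSpec = ContrastAgentSpec()
    write_fdhs: bool = False
    fdhs_dose_ratio: float = 4.0  # e.g. 0.080 vs 0.020 mmol/kg

    def __post_init__(self) -> None:
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        for f in (*self.tumour_center_frac, *self.tumour_radii_frac,
                  *self.vessel_center_frac, self.vessel_radius_frac):
            if not 0 < f < 1:
                raise ValueError("geometry fractions must be in (0, 1)")

    def grid(self, which: str) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
        full = FULL_HT_SHAPE if which == "HT" else FULL_HS_SHAPE
        vox = HT_VOXEL_MM if which == "HT" else HS_VOXEL_MM
        shape = tuple(max(4, int(round(n * self.scale))) for n in full)
        return shape, vox

    @property
    def fov_mm(self) -> np.ndarray:
        shape, vox = self.grid("HS")
        return np.array(shape) * np.array(vox)


def _affine(voxel_mm) -> np.ndarray:
    aff = np.diag([*voxel_mm, 1.0])
    aff[:3, 3] = np.asarray(voxel_mm) / 2.0  # voxel i centered at (i + 1/2) * vs
    return aff


def _voxel_centers(shape, affine):
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    return (
        affine[0, 0] * ii + affine[0, 3],
        affine[1, 1] * jj + affine[1, 3],
        affine[2, 2] * kk + affine[2, 3],
    )


def _region_masks(cfg: PhantomConfig, shape, affine):
    """(tumour, vessel) boolean masks on the given grid."""
    fov = cfg.fov_mm
    x, y, z = _voxel_centers(shape, affine)
    c = np.array(cfg.tumour_center_frac) * fov
    r = np.array(cfg.tumour_radii_frac) * fov
    tumour = (((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2
              + ((z - c[2]) / r[2]) ** 2) <= 1.0
    vc = np.array(cfg.vessel_center_frac) * fov[:2]
    vr = cfg.vessel_radius_frac * min(fov[:2])
    vessel = ((x - vc[0]) ** 2 + (y - vc[1]) ** 2) <= vr ** 2  # full-length cylinder
    vessel &= ~tumour
    if not tumour.any() or not vessel.any():
        raise ValueError("phantom regions are empty on this grid; increase scale")
    if (tumour & vessel).any():
        raise ValueError("tumour and vessel masks overlap")
    return tumour, vessel


def _region_curves(cfg: PhantomConfig, times: np.ndarray, dose_ratio: float):
    """(tumour Ct, vessel Cb) concentration curves at the given frame times."""
    grid_dt = cfg.scheme.ht_dt
    t_grid = np.arange(min(times.min(), 0.0), times.max() + grid_dt, grid_dt)
    vif_model = dataclasses.replace(
        cfg.vif_model,
        amplitude=cfg.vif_model.amplitude * dose_ratio,
        washout_amp=cfg.vif_model.washout_amp * dose_ratio,
    )
    vif = vif_model.as_vif(t_grid)
    ct_tumour = etm_forward(cfg.tumour_params, vif, times, grid_dt_s=grid_dt).ct
    cb_vessel = np.interp(times, vif.times, vif.cp, left=0.0)
    return ct_tumour, cb_vessel


def _region_fractions(cfg: PhantomConfig, which: str):
    """Per-voxel (tumour, vessel) volume fractions on the requested grid.

    Regions are painted binary on the HS grid (the reference resolution);
    the HT grid sees them through partial-volume block averaging of the HS
    voxels each HT voxel contains — the situation the per-voxel calibration
    ratio is designed to correct.
    """
    hs_shape, hs_vox = cfg.grid("HS")
    hs_aff = _affine(hs_vox)
    tumour_hs, vessel_hs = _region_masks(cfg, hs_shape, hs_aff)
    if which == "HS":
        return tumour_hs.astype(float), vessel_hs.astype(float), hs_aff, hs_shape
    ht_shape, ht_vox = cfg.grid("HT")
    ht_aff = _affine(ht_vox)
    x, y, z = _voxel_centers(hs_shape, hs_aff)
    idx = []
    for coord, step, off, n in zip((x, y, z), np.diag(ht_aff)[:3],
                                   ht_aff[:3, 3], ht_shape):
        idx.append(np.clip(np.floor((coord - off + step / 2) / step).astype(int),
                           0, n - 1))
    flat = np.ravel_multi_index(tuple(i.ravel() for i in idx), ht_shape)
    counts = np.bincount(flat, minlength=int(np.prod(ht_shape))).astype(float)
    counts[counts == 0] = 1.0
    f_t = (np.bincount(flat, weights=tumour_hs.ravel().astype(float),
                       minlength=int(np.prod(ht_shape))) / counts).reshape(ht_shape)
    f_v = (np.bincount(flat, weights=vessel_hs.ravel().astype(float),
                       minlength=int(np.prod(ht_shape))) / counts).reshape(ht_shape)
    return f_t, f_v, ht_aff, ht_shape


def _series(cfg: PhantomConfig, which: str, times: np.ndarray,
            dose_ratio: float = 1.0) -> dict:
    """Noiseless SI series and per-region metadata on one grid."""
    f_t, f_v, aff, shape = _region_fractions(cfg, which)
    acq = ACQ_HT if which == "HT" else ACQ_HS
    baseline = cfg.baseline_ht if which == "HT" else cfg.baseline_hs
    ct_tumour, cb_vessel = _region_curves(cfg, times, dose_ratio)

    m0 = m0_for_baseline(baseline, cfg.r1_0_background, acq)
    f_bg = 1.0 - f_t - f_v
    r1_map = (f_bg * cfg.r1_0_background + f_t * cfg.r1_0_tumour
              + f_v * cfg.r1_0_vessel)
    conc = f_t[..., None] * ct_tumour + f_v[..., None] * cb_vessel
    si = spgr_signal(r1_map[..., None] + cfg.agent.r1 * conc, m0, acq)
    return {"si": si.astype(np.float32), "affine": aff, "times": times,
            "tumour": f_t > 0.5, "vessel": f_v > 0.5,
            "tumour_frac": f_t, "vessel_frac": f_v,
            "r1_map": r1_map, "m0": m0, "acq": acq}


def _vfa_stack(r1_map: np.ndarray, m0: float, tr_ms: float) -> np.ndarray:
    vols = []
    for ang in VFA_ANGLES_DEG:
        acq = dataclasses.replace(ACQ_HS, tr_ms=tr_ms, flip_deg=ang)
        vols.append(spgr_signal(r1_map, m0, acq).astype(np.float32))
    return np.stack(vols, axis=-1)


def build_phantom(cfg: PhantomConfig | None = None) -> dict:
    """Construct the phantom in memory.

    Returns a dict with entries ``ht``, ``hs`` (and ``fdhs`` when enabled),
    each ``{"si", "affine", "times", ...}`` with Rician noise applied, the
    VFA stacks, masks, ground-truth maps and the manifest.  Identical seeds
    give bit-identical arrays; the noise stream of each series is a
    distinct child of the one seed.
    """
    cfg = cfg or PhantomConfig()
    scheme = cfg.scheme
    ht = _series(cfg, "HT", scheme.ht_times)
    hs = _series(cfg, "HS", scheme.hs_times)

    rng_children = np.random.SeedSequence(cfg.seed).spawn(3)
    for series, spec, child in ((ht, cfg.noise_ht, rng_children[0]),
                                (hs, cfg.noise_hs, rng_children[1])):
        if spec.nl > 0:
            rng = np.random.default_rng(child)
            series["si"] = add_rician_noise(series["si"], spec, rng).astype(np.float32)

    out = {"ht": ht, "hs": hs}
    if cfg.write_fdhs:
        fd = _series(cfg, "HS", scheme.hs_times, dose_ratio=cfg.fdhs_dose_ratio)
        if cfg.noise_hs.nl > 0:
            rng = np.random.default_rng(rng_children[2])
            fd["si"] = add_rician_noise(fd["si"], cfg.noise_hs, rng).astype(np.float32)
        out["fdhs"] = fd

    out["vfa_ht"] = {"si": _vfa_stack(ht["r1_map"], ht["m0"], ACQ_HT.tr_ms),
                     "affine": ht["affine"], "angles_deg": VFA_ANGLES_DEG,
                     "tr_ms": ACQ_HT.tr_ms}
    out["vfa_hs"] = {"si": _vfa_stack(hs["r1_map"], hs["m0"], ACQ_HS.tr_ms),
                     "affine": hs["affine"], "angles_deg": VFA_ANGLES_DEG,
                     "tr_ms": ACQ_HS.tr_ms}

    truth = {name: np.where(hs["tumour"], val, np.nan).astype(np.float32)
             for name, val in zip(("ktrans", "vp", "ve"),
                                  cfg.tumour_params.as_array())}
    out["truth_maps"] = truth
    out["manifest"] = {
        "seed": cfg.seed,
        "config": _config_to_jsonable(cfg),
        "ht_shape": list(ht["si"].shape),
        "hs_shape": list(hs["si"].shape),
        "ht_times_s": [float(t) for t in scheme.ht_times],
        "hs_times_s": [float(t) for t in scheme.hs_times],
        "concat_time_s": scheme.concat_time_s,
        "vfa_angles_deg": list(VFA_ANGLES_DEG),
    }
    return out


def _config_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _config_to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_config_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _save(path: Path, arr: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)


def generate_phantom(cfg: PhantomConfig | None = None, out_dir="phantom") -> dict:
    """Write the phantom file set and return the manifest.

    Files: ``ht.nii.gz``, ``hs.nii.gz`` (optionally ``fdhs.nii.gz``),
    ``vfa_ht.nii.gz``/``vfa_hs.nii.gz`` (flip angle on the 4th axis),
    ``tumour_mask.nii.gz`` + ``vessel_mask_hs.nii.gz`` on the HS grid,
    ``vessel_mask_ht.nii.gz`` on the HT grid, ground-truth
    ``truth_<param>.nii.gz`` maps, and ``manifest.json``.
    """
    cfg = cfg or PhantomConfig()
    data = build_phantom(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _save(out / "ht.nii.gz", data["ht"]["si"], data["ht"]["affine"])
    _save(out / "hs.nii.gz", data["hs"]["si"], data["hs"]["affine"])
    if "fdhs" in data:
        _save(out / "fdhs.nii.gz", data["fdhs"]["si"], data["fdhs"]["affine"])
    _save(out / "vfa_ht.nii.gz", data["vfa_ht"]["si"], data["vfa_ht"]["affine"])
    _save(out / "vfa_hs.nii.gz", data["vfa_hs"]["si"], data["vfa_hs"]["affine"])
    _save(out / "tumour_mask.nii.gz", data["hs"]["tumour"].astype(np.float32),
          data["hs"]["affine"])
    _save(out / "vessel_mask_hs.nii.gz", data["hs"]["vessel"].astype(np.float32),
          data["hs"]["affine"])
    _save(out / "vessel_mask_ht.nii.gz", data["ht"]["vessel"].astype(np.float32),
          data["ht"]["affine"])
    for name, arr in data["truth_maps"].items():
        _save(out / f"truth_{name}.nii.gz", arr, data["hs"]["affine"])
    (out / "manifest.json").write_text(json.dumps(data["manifest"], indent=2))
    return data["manifest"]
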