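"""Region summaries, QC statistics and run manifests."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .reconstruction import ParameterMaps

__all__ = ["summarize_maps", "write_manifest"]


def summarize_maps(maps: ParameterMaps, mask, sfe_threshold: float | None = 0.5,
                   centile: float | None = 99.0) -> dict:
    """Per-region summary of fitted parameter maps after QC exclusions.

    Voxels with SFE above ``sfe_threshold`` are excluded, then values above
    the ``centile`` percentile of each parameter are trimmed (pass ``None``
    to disable either step).  Returns a dict with a pandas DataFrame
    (``table``: mean/SD/n per parameter), the fraction of in-mask voxels
    with SFE above threshold, and an ``empty`` flag set when the exclusions
    remove everything.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != maps.shape:
        raise ValueError("mask shape does not match the parameter maps")
    sfe = maps.sfe[mask]
    fitted = np.isfinite(sfe)
    frac_high_sfe = (float(np.sum(sfe[fitted] > (sfe_threshold if sfe_threshold is not None else np.inf)) / fitted.sum())
                     if fitted.any() else float("nan"))
    keep = fitted.copy()
    if sfe_threshold is not None:
        keep &= ~(sfe > sfe_threshold)
    rows = []
    for name, arr in maps.items():
        if name == "sfe":
            continue
        vals = arr[mask][keep]
        vals = vals[np.isfinite(vals)]
        if centile is not None and vals.size:
            vals = vals[vals <= np.percentile(vals, centile)]
        rows.append({
            "parameter": name,
            "mean": float(np.mean(vals)) if vals.size else float("nan"),
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
            "n_voxels": int(vals.size),
        })
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "frac_sfe_above_threshold": frac_high_sfe,
        "n_mask_voxels": int(mask.sum()),
        "empty": bool(table["n_voxels"].max() == 0),
    }


def write_manifest(out_dir, *, command: str, seed: int | None, config_hash: str,
                   inputs: dict | None = None, extra: dict | None = None) -> Path:
    """Write a run manifest (command, seed, config hash, versions) as JSON."""
    import legatos

    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash,
        "inputs": inputs or {},
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "versions": {
            "legatos": legatos.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    manifest.update(extra or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
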