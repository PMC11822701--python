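"""Result and configuration I/O: CSV tables, JSON summaries, run manifests.

Column orders are fixed and documented here so downstream tooling can rely
on them:

* element dump            — id, x, y, z, nx, ny, nz, area_m2
* field results           — element_id, area_m2, fluence_mJ_cm2, dose_mJ_cm2
* rate matrices (wide)    — element_id, then one column per timestamp ``t<i>_s``
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import uvfield


def read_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def write_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def elements_to_dataframe(elements) -> pd.DataFrame:
    from .geometry import SurfaceElements
    els = SurfaceElements.from_sequence(elements)
    return pd.DataFrame({
        "id": els.ids,
        "x": els.positions[:, 0], "y": els.positions[:, 1], "z": els.positions[:, 2],
        "nx": els.normals[:, 0], "ny": els.normals[:, 1], "nz": els.normals[:, 2],
        "area_m2": els.areas,
    })


def write_elements_csv(elements, path) -> None:
    elements_to_dataframe(elements).to_csv(path, index=False)


def write_field_csv(fld, path) -> None:
    pd.DataFrame({
        "element_id": fld.element_ids,
        "area_m2": fld.areas,
        "fluence_mJ_cm2": fld.fluence,
        "dose_mJ_cm2": fld.dose,
    }).to_csv(path, index=False)


def write_rate_matrix_csv(fld, which: str, path) -> None:
    """Wide per-timestamp matrix; ``which`` is 'fluence_rate' or 'irradiance'."""
    matrix = getattr(fld, which)
    df = pd.DataFrame(matrix, columns=[f"t{i}_s" for i in range(matrix.shape[1])])
    df.insert(0, "element_id", fld.element_ids)
    df.to_csv(path, index=False)


def write_summary_json(summary, settings: dict, path) -> None:
    payload = {"summary": summary.as_dict(), "settings": settings}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def write_manifest(path, settings: dict, seed=None) -> None:
    """Reproducibility manifest: settings echo, RNG seed, library versions."""
    manifest = {
        "uvfield_version": uvfield.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "settings": settings,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
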