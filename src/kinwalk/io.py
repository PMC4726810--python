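"""Result persistence: versioned JSON metadata + CSV tables.

All physical columns carry units in their headers (nm, ms, pN, nm/s); every
output records the parameter hash and the seed that produced it.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Dict, Optional

import pandas as pd

from .params import ModelParams
from .config import params_to_dict

FORMAT_VERSION = 1


def parameter_hash(params: ModelParams) -> str:
    blob = json.dumps(params_to_dict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_result(outdir, name: str, params: ModelParams,
                 tables: Optional[Dict[str, pd.DataFrame]] = None,
                 meta: Optional[Dict[str, Any]] = None,
                 seed: Optional[int] = None) -> Path:
    """Write a result bundle: <name>.json plus one CSV per table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "format_version": FORMAT_VERSION,
        "name": name,
        "parameter_hash": parameter_hash(params),
        "seed": seed,
        "parameters": params_to_dict(params),
        "tables": [],
    }
    if meta:
        record.update(meta)
    for tname, df in (tables or {}).items():
        csv_path = outdir / f"{name}_{tname}.csv"
        df.to_csv(csv_path, index=False, float_format="%.10g")
        record["tables"].append(csv_path.name)
    json_path = outdir / f"{name}.json"
    json_path.write_text(json.dumps(record, indent=2, default=float))
    return json_path


def binding_table(bp) -> pd.DataFrame:
    rows = [{"site_id": i, "P_b": v} for i, v in sorted(bp.p_b.items())]
    rows.append({"site_id": "residual", "P_b": bp.residual})
    return pd.DataFrame(rows)


def flux_table(solution) -> pd.DataFrame:
    """Per-site outflow rate series of a transient solve (t_ms, site_id, flux_per_ms)."""
    recs = []
    for site, series in solution.absorbed_flux.items():
        for t, f in zip(solution.times, series):
            recs.append({"t_ms": t, "site_id": site, "flux_per_ms": f})
    return pd.DataFrame(recs)


def trajectory_table(traj) -> pd.DataFrame:
    return pd.DataFrame({
        "t_ms": traj.times,
        "protofilament": [s[0] for s in traj.sites],
        "axial_index": [s[1] for s in traj.sites],
        "x_nm": [ (s[1]-traj.sites[0][1]) * traj.axial_spacing for s in traj.sites],
    })
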