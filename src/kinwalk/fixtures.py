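"""Deterministic fixture bundles for tests and demos (no external data)."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict

import numpy as np

from .params import ModelParams, KineticsParams
from .lattice import build_lattice
from .obstacles import deposit_at_density
from . import neck
from . import io as kio


def generate_fixtures(seed: int, outdir) -> Dict[str, str]:
    """Emit a small lattice, a coarse force-field table, a mini obstacle set
    and a 20-walker trajectory bundle; returns {name: filename} plus a stable
    bundle hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = ModelParams()
    out: Dict[str, str] = {}

    lat = build_lattice(13, 26.5, 60, True)
    (outdir / "lattice.json").write_text(lat.to_json())
    lat.site_table().to_csv(outdir / "lattice_sites.csv", index=False)
    out["lattice"] = "lattice.json"
    out["lattice_sites"] = "lattice_sites.csv"

    ff = neck.tabulate_force_field((-12, 12, -10, 10), 1.0, (0.0, 0.0), params)
    ff.to_dataframe().to_csv(outdir / "force_field.csv", index=False,
                             float_format="%.8g")
    out["force_field"] = "force_field.csv"

    obs = deposit_at_density(build_lattice(13, 26.5, 120, True), 3, 0.03,
                             seed=seed)
    obs.to_dataframe().to_csv(outdir / "obstacles.csv", index=False)
    out["obstacles"] = "obstacles.csv"

    from .stepper import StepTable, simulate_walk
    table = StepTable(params=params)
    table.ensure({})
    kin = KineticsParams(max_steps=200)
    rng = np.random.default_rng(seed)
    recs = []
    for w in range(20):
        traj = simulate_walk(build_lattice(13, 26.5, 400, True), None, table,
                             kin, seed=int(rng.integers(2**31 - 1)))
        df = kio.trajectory_table(traj)
        df.insert(0, "walker", w)
        recs.append(df)
    import pandas as pd
    pd.concat(recs).to_csv(outdir / "walks.csv", index=False,
                           float_format="%.6g")
    out["walks"] = "walks.csv"

    h = hashlib.sha256()
    for name in sorted(out.values()):
        h.update((outdir / name).read_bytes())
    out["bundle_hash"] = h.hexdigest()[:16]
    (outdir / "manifest.json").write_text(json.dumps(
        {"seed": seed, **out}, indent=2))
    return out
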