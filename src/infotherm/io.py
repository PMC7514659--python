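"""Round-trippable series files, density files, and the fixture generator.

Series are 3-column TSV (``t``, ``x``, ``y``) with ``#``-prefixed header
lines carrying JSON metadata (model, params, dt_sample, seed), so a file
re-read reproduces the original :class:`TimeSeries` bit for bit and a run
can be reconstructed from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .containers import GridDensity, TimeSeries
from .errors import ParseError

_MAGIC = "# infotherm-series v1"


def write_series(ts: TimeSeries, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "model": ts.model,
        "params": ts.params,
        "dt_sample": ts.dt_sample,
        "seed": ts.seed,
    }
    with path.open("w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"# meta={json.dumps(meta)}\n")
        fh.write("# t\tx\ty\n")
        for i in range(len(ts)):
            fh.write(
                f"{float(i * ts.dt_sample)!r}\t{float(ts.x[i])!r}\t{float(ts.y[i])!r}\n"
            )


def read_series(path: str | Path) -> TimeSeries:
    path = Path(path)
    meta: dict = {}
    t_vals: list[float] = []
    x_vals: list[float] = []
    y_vals: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("meta="):
                    try:
                        meta = json.loads(body[len("meta="):])
                    except json.JSONDecodeError as exc:
                        raise ParseError(f"line {lineno}: bad metadata JSON: {exc}") from exc
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            try:
                t, x, y = (float(p) for p in parts)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric cell ({exc})") from exc
            t_vals.append(t)
            x_vals.append(x)
            y_vals.append(y)
    if len(t_vals) < 2:
        raise ParseError("series needs at least 2 rows")
    t_arr = np.asarray(t_vals)
    steps = np.diff(t_arr)
    dt = steps[0]
    bad = np.nonzero(np.abs(steps - dt) > 1e-9 * max(dt, 1.0))[0]
    if bad.size:
        i = int(bad[0])
        raise ParseError(
            f"non-uniform time grid: interval {float(steps[i])!r} between data rows "
            f"{i + 1} and {i + 2} differs from dt={float(dt)!r}"
        )
    return TimeSeries(
        dt_sample=float(meta.get("dt_sample", dt)),
        x=np.asarray(x_vals),
        y=np.asarray(y_vals),
        model=meta.get("model", "unknown"),
        seed=meta.get("seed"),
        params=meta.get("params", {}),
    )


def write_density(gd: GridDensity, path: str | Path) -> None:
    """TSV matrix with axis headers; rows follow x_axis, columns y_axis."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# infotherm-density v1\n")
        fh.write("# x_axis\t" + "\t".join(repr(float(v)) for v in gd.x_axis) + "\n")
        fh.write("# y_axis\t" + "\t".join(repr(float(v)) for v in gd.y_axis) + "\n")
        for row in gd.psi:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the three canonical small test inputs and a checksum manifest.

    (a) a linear-model series at the reference parameters (beta=0.2,
    trel=10); (b) a receptor-ligand series at kon=5, koff=1, h=2; (c) an
    i.i.d. white-noise series as the reversible control.  Re-running with
    the same seed regenerates byte-identical files.
    """
    from .blrm import BLRMParams
    from .simulate import (
        RLParams,
        SimConfig,
        simulate_blrm,
        simulate_receptor_ligand,
        white_noise_series,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    blrm = simulate_blrm(
        BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2),
        SimConfig(dt=0.05, n_steps=40_000, burn_in=100.0, seed=seeds[0], store_every=0.5),
    )
    rl = simulate_receptor_ligand(
        RLParams(kon=5.0, koff=1.0, h=2.0),
        SimConfig(dt=1e-3, n_steps=200_000, burn_in=10.0, seed=seeds[1], store_every=0.05),
    )
    wn = white_noise_series(4000, dt_sample=1.0, seed=seeds[2])

    manifest: dict = {"seed": seed, "fixtures": []}
    for name, ts in (("blrm_ref.tsv", blrm), ("receptor_ligand_ref.tsv", rl),
                     ("white_noise.tsv", wn)):
        path = out / name
        write_series(ts, path)
        manifest["fixtures"].append(
            {
                "file": name,
                "model": ts.model,
                "seed": ts.seed,
                "n": len(ts),
                "dt_sample": ts.dt_sample,
                "sha256": _sha256(path),
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
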