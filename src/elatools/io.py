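"""File formats, manifests, and the end-to-end pipeline.

Series files are delimited text (comma by default, tab autodetected): one
row per ROI, first column the ROI label, remaining columns the time points;
an optional header row is autodetected.  A cohort lives in a directory of
such files plus a YAML manifest mapping (participant_id, session_id) to
filenames.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mem
from .preprocess import binarize, zscore_global
from .reliability import SessionTable, permutation_test
from .series import BinaryTimeSeries, ContinuousTimeSeries

__all__ = [
    "read_series",
    "write_series",
    "write_cohort",
    "read_cohort",
    "params_to_json",
    "params_from_json",
    "run_pipeline",
]

MANIFEST_VERSION = "1"


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if first.count("\t") > first.count(",") else ","


def read_series(path: str | Path) -> ContinuousTimeSeries | BinaryTimeSeries:
    """Read a delimited ROI × time series file.

    Returns a :class:`BinaryTimeSeries` when all entries are ±1, otherwise a
    :class:`ContinuousTimeSeries`.  Malformed files raise a parse error
    naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty series file")
    sep = _sniff_delimiter(path)
    # header detection: a header's non-label cells are not all numeric
    first_cells = text.splitlines()[0].split(sep)[1:]
    header: int | None = 0
    try:
        [float(c) for c in first_cells]
        header = None
    except ValueError:
        header = 0
    try:
        df = pd.read_csv(path, sep=sep, header=header, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited file: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna().to_numpy()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        bad_rows = np.flatnonzero((numeric.isna()).any(axis=1).to_numpy())
        row = int(bad_rows[0]) + (2 if header == 0 else 1)
        raise ValueError(f"{path}: non-numeric or missing cell on line {row}")
    values = numeric.to_numpy().astype(float)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"{path}: series must have at least one ROI and one time point")
    labels = [str(x) for x in df.index]
    if np.all(np.isin(values, (-1.0, 1.0))):
        return BinaryTimeSeries(values=values.astype(np.int8), roi_labels=labels)
    return ContinuousTimeSeries(values=values, roi_labels=labels)


def write_series(
    series: ContinuousTimeSeries | BinaryTimeSeries, path: str | Path, sep: str = ","
) -> None:
    """Write a series as delimited text (rows = ROIs, first column = label)."""
    path = Path(path)
    df = pd.DataFrame(series.values, index=series.roi_labels)
    df.to_csv(path, sep=sep, header=False)


def write_cohort(table: SessionTable, outdir: str | Path, sep: str = ",") -> Path:
    """Write every cell of a session table plus a YAML manifest.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in table.participants:
        for s in table.sessions:
            cell = table.grid[(p, s)]
            fname = f"{p}_{s}.csv"
            write_series(cell, outdir / fname, sep=sep)
            entries.append(
                {
                    "participant_id": p,
                    "session_id": s,
                    "path": fname,
                    "n_rois": int(cell.n),
                    "t_max": int(cell.t_max),
                }
            )
    manifest = {
        "format_version": MANIFEST_VERSION,
        "participants": list(table.participants),
        "sessions": list(table.sessions),
        "entries": entries,
    }
    mpath = outdir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath


def read_cohort(manifest_path: str | Path) -> SessionTable:
    """Load a session table from a manifest, validating shapes and coverage."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    grid = {}
    seen = set()
    for e in manifest["entries"]:
        key = (str(e["participant_id"]), str(e["session_id"]))
        if key in seen:
            raise ValueError(f"duplicate manifest entry for cell {key}")
        seen.add(key)
        series = read_series(base / e["path"])
        if series.n != e["n_rois"] or series.t_max != e["t_max"]:
            raise ValueError(
                f"{e['path']}: shape ({series.n}, {series.t_max}) does not match "
                f"manifest ({e['n_rois']}, {e['t_max']})"
            )
        series.meta.update(participant_id=key[0], session_id=key[1])
        grid[key] = series
    participants = [str(p) for p in manifest.get("participants", sorted({k[0] for k in grid}))]
    sessions = [str(s) for s in manifest.get("sessions", sorted({k[1] for k in grid}))]
    return SessionTable(grid=grid, participants=participants, sessions=sessions)


# ---------------------------------------------------------------------------
# parameter serialization


def params_to_json(params: mem.MEMParams, roi_labels: list[str] | None = None) -> str:
    iu = np.triu_indices(params.n, k=1)
    payload = {
        "n": params.n,
        "roi_labels": roi_labels or [f"roi{i}" for i in range(params.n)],
        "h": [float(x) for x in params.h],
        "J_upper": {f"{i},{j}": float(params.J[i, j]) for i, j in zip(*iu)},
    }
    return json.dumps(payload, indent=2)


def params_from_json(text: str) -> mem.MEMParams:
    payload = json.loads(text)
    n = payload["n"]
    J = np.zeros((n, n))
    for key, val in payload["J_upper"].items():
        i, j = (int(x) for x in key.split(","))
        J[i, j] = J[j, i] = val
    return mem.MEMParams(h=np.asarray(payload["h"], dtype=float), J=J)


# ---------------------------------------------------------------------------
# pipeline


def _preprocess_table(table: SessionTable) -> SessionTable:
    """Z-score + binarize any continuous cells; binary cells pass through."""
    grid = {}
    for key, cell in table.grid.items():
        if isinstance(cell, BinaryTimeSeries):
            grid[key] = cell
        else:
            grid[key] = binarize(zscore_global(cell))
            grid[key].meta.update(cell.meta)
    return SessionTable(grid=grid, participants=table.participants, sessions=table.sessions)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run manifest → preprocessing → permutation test(s) end to end.

    ``config`` keys: ``manifest`` (path), ``design``, ``estimator``,
    ``measures`` (list or "all"), ``permutations``, ``shuffle``, ``seed`` and
    optional estimation settings (``m``, ``reps_within``, ``reps_between``,
    ``null_reps``).  Results (one JSON per measure plus a bundle echoing the
    config) are written under ``outdir``; the run is deterministic for a
    fixed config.
    """
    required = {"manifest", "design", "estimator", "measures", "permutations", "seed"}
    missing = required - set(config)
    if missing:
        raise ValueError(f"config is missing required keys: {sorted(missing)}")
    measures = config["measures"]
    if measures == "all":
        measures = ["dJ", "dH", "dbasin", "dL"]
    if isinstance(measures, str):
        measures = [measures]

    table = _preprocess_table(read_cohort(config["manifest"]))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    extra = {
        k: config[k]
        for k in ("m", "reps_within", "reps_between", "null_reps")
        if k in config
    }
    results = {}
    for measure in measures:
        res = permutation_test(
            table,
            design=config["design"],
            measure=measure,
            estimator=config["estimator"],
            c=int(config["permutations"]),
            shuffle=config.get("shuffle", "global"),
            seed=int(config["seed"]),
            **extra,
        )
        results[measure] = res.to_dict()
        (outdir / f"permutation_{measure}.json").write_text(
            json.dumps(results[measure], indent=2)
        )
    bundle = {"config": {k: str(v) if isinstance(v, Path) else v for k, v in config.items()},
              "results": results}
    text = json.dumps(bundle, indent=2, sort_keys=True)
    bundle["sha256"] = hashlib.sha256(text.encode()).hexdigest()
    (outdir / "results.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle
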