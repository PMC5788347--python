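"""Delimited-table IO with versioned headers and an explicit UNDETECTED sentinel.

Every table written by the pipeline starts with a comment header line

    # scqpcr-table v1 kind=<kind> config=<hash>

carrying the format version and a hash of the generating configuration, so
that downstream stages can verify provenance and reruns with identical
configuration produce identical files.  Chambers that never crossed
threshold are encoded with the sentinel string ``UNDETECTED`` — never an
empty cell — so round-trips are unambiguous.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import UNDETECTED, ChipConfig
from .simulate import ChipRun

FORMAT_VERSION = "v1"

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "traces_to_frame",
    "truth_to_frame",
    "write_config",
    "read_config",
]


def config_hash(params: dict) -> str:
    blob = yaml.safe_dump(params, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_line(kind: str, chash: str) -> str:
    return (
        f"# scqpcr-table {FORMAT_VERSION} kind={kind} config={chash} "
        f"pkg={__version__}\n"
    )


def write_table(df: pd.DataFrame, path, kind: str, params: dict | None = None) -> None:
    """Write a comma-delimited table with a versioned header line.

    The ``ct`` column, if present, has NaN entries replaced by the
    UNDETECTED sentinel.
    """
    df = df.copy()
    if "ct" in df.columns:
        df["ct"] = df["ct"].map(
            lambda v: UNDETECTED if pd.isna(v) else repr(float(v))
        )
    chash = config_hash(params or {})
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_line(kind, chash))
        df.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`; returns (df, header meta)."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("# scqpcr-table"):
            parts = first.strip().split()
            meta["format_version"] = parts[2]
            meta.update(dict(kv.split("=", 1) for kv in parts[3:] if "=" in kv))
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body))
    if "ct" in df.columns:
        df["ct"] = pd.to_numeric(df["ct"].replace(UNDETECTED, np.nan))
    return df, meta


def traces_to_frame(run: ChipRun, run_id: str = "run") -> pd.DataFrame:
    """Long trace table: run_id, subarray, unit, chamber, assay, cycle, fluorescence."""
    cfg = run.config
    n_units, n_chambers, n_cycles = run.traces.shape
    addr = run.addresses
    return pd.DataFrame({
        "run_id": run_id,
        "subarray": np.repeat(addr[:, 0], n_chambers * n_cycles),
        "unit": np.repeat(addr[:, 1], n_chambers * n_cycles),
        "chamber": np.tile(np.repeat(np.arange(1, n_chambers + 1), n_cycles), n_units),
        "assay": np.tile(np.repeat(np.array(run.chamber_assays, dtype=object), n_cycles), n_units),
        "cycle": np.tile(np.arange(1, n_cycles + 1), n_units * n_chambers),
        "fluorescence": run.traces.ravel(),
    })


def frame_to_traces(df: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Reassemble a trace array from the long table.

    Returns (traces[n_units, chambers, cycles], unit address frame, assays).
    """
    required = {"subarray", "unit", "chamber", "cycle", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table is missing columns: {sorted(missing)}")
    df = df.sort_values(["subarray", "unit", "chamber", "cycle"], kind="stable")
    units = df[["subarray", "unit"]].drop_duplicates().reset_index(drop=True)
    chambers = np.sort(df["chamber"].unique())
    cycles = np.sort(df["cycle"].unique())
    traces = df["fluorescence"].to_numpy().reshape(
        len(units), len(chambers), len(cycles)
    )
    if "assay" in df.columns:
        assays = (
            df.drop_duplicates("chamber").sort_values("chamber")["assay"]
            .astype(str).tolist()
        )
    else:
        assays = [str(c) for c in chambers]
    return traces, units, assays


def truth_to_frame(run: ChipRun) -> pd.DataFrame:
    """Long ground-truth table: subarray, unit, occupancy, population, gene, true_count."""
    t = run.truth
    addr = run.addresses
    g = t.n_genes
    return pd.DataFrame({
        "subarray": np.repeat(addr[:, 0], g),
        "unit": np.repeat(addr[:, 1], g),
        "occupancy": np.repeat(t.occupancy, g),
        "population": np.repeat(t.population, g),
        "gene": np.tile(np.array(t.gene_names, dtype=object), t.n_units),
        "true_count": t.counts.ravel(),
    })


def write_config(params: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(params, sort_keys=True))


def read_config(path) -> dict:
    loaded = yaml.safe_load(Path(path).read_text())
    if not isinstance(loaded, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return loaded
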