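"""JSON/manifest glue shared by the CLI and pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .traces import KineticTrace, write_trace_csv

__all__ = ["dump_json", "write_trace_set", "read_manifest"]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder, sort_keys=True)
        fh.write("\n")


def write_trace_set(traces: list[KineticTrace], out_dir, prefix: str) -> Path:
    """Write traces as CSVs plus a manifest indexing them; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, tr in enumerate(traces):
        name = f"{prefix}_{i:02d}_{tr.kind}.csv"
        write_trace_csv(tr, out_dir / name)
        entries.append({"file": name, **tr.metadata})
    manifest = out_dir / f"{prefix}_manifest.json"
    dump_json({"traces": entries}, manifest)
    return manifest


def read_manifest(manifest_path) -> list[KineticTrace]:
    from .traces import read_trace_csv

    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    traces = []
    for entry in manifest["traces"]:
        tr = read_trace_csv(manifest_path.parent / entry["file"])
        tr.metadata.update({k: v for k, v in entry.items() if k != "file"})
        traces.append(tr)
    return traces
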