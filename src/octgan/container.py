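"""Zip-style multi-array container with a JSON metadata record.

Every artifact the package writes (paired B-scans, checkpoints) goes through
this format: a zip archive holding one ``.npy`` entry per named array plus a
``meta.json`` record carrying the schema version, seeds and provenance.
Round-trips are bit-identical for every dtype used in the package, including
complex128.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path

import numpy as np

SCHEMA_VERSION = 1

__all__ = ["ContainerError", "write_container", "read_container", "SCHEMA_VERSION"]


class ContainerError(RuntimeError):
    """Raised for schema-version mismatches or missing required arrays."""


def write_container(path, arrays: dict, meta: dict | None = None) -> Path:
    """Write named arrays plus metadata to ``path``.

    The metadata record always embeds ``schema_version`` so readers can
    refuse containers written by an incompatible layout.
    """
    path = Path(path)
    record = dict(meta or {})
    record["schema_version"] = SCHEMA_VERSION
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr), allow_pickle=False)
            zf.writestr(f"{name}.npy", buf.getvalue())
        zf.writestr("meta.json", json.dumps(record, indent=1, sort_keys=True))
    return path


def read_container(path, required: tuple = ()) -> tuple[dict, dict]:
    """Read a container back as ``(arrays, meta)``.

    Parameters
    ----------
    required:
        Array names that must be present; a missing one raises
        :class:`ContainerError` naming it.
    """
    path = Path(path)
    arrays: dict = {}
    with zipfile.ZipFile(path, "r") as zf:
        names = zf.namelist()
        if "meta.json" not in names:
            raise ContainerError(f"{path}: no meta.json record")
        meta = json.loads(zf.read("meta.json"))
        version = meta.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ContainerError(
                f"{path}: schema version {version!r}, expected {SCHEMA_VERSION}"
            )
        for entry in names:
            if entry.endswith(".npy"):
                arrays[entry[:-4]] = np.lib.format.read_array(
                    io.BytesIO(zf.read(entry)), allow_pickle=False
                )
    for name in required:
        if name not in arrays:
            raise ContainerError(f"{path}: required array {name!r} missing")
    return arrays, meta
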