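"""Container I/O, run configuration, and the optional Bruker raw-data reader.

The native container is a single HDF5 file holding named complex arrays and
one JSON-encoded metadata attribute, versioned so incompatible files are
rejected explicitly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import h5py
import numpy as np
import yaml

from .recon import ProcessingConfig, Spectrum2D
from .sequence import SequenceParams, derive_geometry
from .simulate import JitterSpec, NoiseSpec, RawUF

__all__ = [
    "CONTAINER_FORMAT",
    "CONTAINER_VERSION",
    "ContainerError",
    "save_container",
    "load_container",
    "save_raw",
    "load_raw",
    "save_spectrum",
    "load_spectrum",
    "export_spectrum_csv",
    "RunConfig",
    "read_bruker2d",
]

CONTAINER_FORMAT = "ufcosy-container"
CONTAINER_VERSION = 1


class ContainerError(RuntimeError):
    """Raised for unreadable, foreign or version-mismatched containers."""


def save_container(path, arrays: Dict[str, np.ndarray], metadata: dict) -> None:
    """Write named arrays plus JSON metadata to a versioned HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = CONTAINER_FORMAT
        f.attrs["version"] = CONTAINER_VERSION
        f.attrs["metadata"] = json.dumps(metadata)
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr))


def load_container(path) -> Tuple[Dict[str, np.ndarray], dict]:
    """Read back a container; raises :class:`ContainerError` on bad files."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerError(f"not a readable container: {path}") from exc
    with f:
        if f.attrs.get("format") != CONTAINER_FORMAT:
            raise ContainerError(f"{path} is not a {CONTAINER_FORMAT} file")
        version = int(f.attrs.get("version", -1))
        if version != CONTAINER_VERSION:
            raise ContainerError(
                f"container version {version} unsupported "
                f"(expected {CONTAINER_VERSION})"
            )
        arrays = {name: f[name][...] for name in f.keys()}
        metadata = json.loads(f.attrs["metadata"])
    return arrays, metadata


def save_raw(path, raw: RawUF) -> None:
    metadata = {
        "kind": "raw",
        "params": raw.params.to_dict(),
        "derived": raw.derived.to_dict(),
        "provenance": raw.provenance,
    }
    save_container(path, {"data": raw.data}, metadata)


def load_raw(path) -> RawUF:
    arrays, metadata = load_container(path)
    if metadata.get("kind") != "raw":
        raise ContainerError(f"{path} does not hold raw data")
    params = SequenceParams.from_dict(metadata["params"])
    return RawUF(
        data=arrays["data"],
        params=params,
        derived=derive_geometry(params),
        provenance=metadata.get("provenance", {}),
    )


def save_spectrum(path, spec: Spectrum2D) -> None:
    metadata = {"kind": "spectrum", "provenance": spec.provenance}
    save_container(
        path,
        {"matrix": spec.matrix, "f1_axis": spec.f1_axis, "f2_axis": spec.f2_axis},
        metadata,
    )


def load_spectrum(path) -> Spectrum2D:
    arrays, metadata = load_container(path)
    if metadata.get("kind") != "spectrum":
        raise ContainerError(f"{path} does not hold a spectrum")
    return Spectrum2D(
        matrix=arrays["matrix"],
        f1_axis=arrays["f1_axis"],
        f2_axis=arrays["f2_axis"],
        provenance=metadata.get("provenance", {}),
    )


def export_spectrum_csv(path, spec: Spectrum2D) -> None:
    """Plain-text export: first row f2 axis, first column f1 axis."""
    out = np.empty((spec.matrix.shape[0] + 1, spec.matrix.shape[1] + 1))
    out[0, 0] = np.nan
    out[0, 1:] = spec.f2_axis
    out[1:, 0] = spec.f1_axis
    out[1:, 1:] = spec.matrix
    np.savetxt(path, out, delimiter=",", fmt="%.8g")


@dataclass
class RunConfig:
    """Everything needed to rerun a simulation/reconstruction end to end."""

    sequence: SequenceParams = field(default_factory=SequenceParams)
    suppression: str = "msup"
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    jitter: JitterSpec = field(default_factory=JitterSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence.to_dict(),
            "suppression": self.suppression,
            "processing": self.processing.to_dict(),
            "jitter": self.jitter.to_dict(),
            "noise": self.noise.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            sequence=SequenceParams.from_dict(d.get("sequence", {})),
            suppression=d.get("suppression", "msup"),
            processing=ProcessingConfig.from_dict(d.get("processing", {})),
            jitter=JitterSpec(**d.get("jitter", {})),
            noise=NoiseSpec(**d.get("noise", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Optional vendor-format reader (benchmark input only)

_PARAM_RE = re.compile(r"^##\$(\w+)=\s*(.*)$")


def _read_jcamp_params(path: Path) -> dict:
    """Minimal JCAMP-DX key/value parser for acqus-style parameter files."""
    params: dict = {}
    for line in path.read_text(errors="replace").splitlines():
        m = _PARAM_RE.match(line)
        if not m:
            continue
        key, value = m.group(1), m.group(2).strip()
        if value.startswith("("):  # array header; values follow, skip
            continue
        if value.startswith("<") and value.endswith(">"):
            params[key] = value[1:-1]
            continue
        try:
            params[key] = int(value)
        except ValueError:
            try:
                params[key] = float(value)
            except ValueError:
                params[key] = value
    return params


def read_bruker2d(path) -> Tuple[np.ndarray, dict]:
    """Read a 2D vendor raw directory (``ser`` + ``acqus``/``acqu2s``).

    Returns a complex matrix of shape (TD2, TD1//2) and the merged parameter
    dictionary (direct-dimension keys verbatim, indirect prefixed ``2_``),
    with a best-effort ``sequence`` sub-dict mapping named parameters onto
    :class:`SequenceParams` fields.
    """
    path = Path(path)
    ser = path / "ser"
    acqus = path / "acqus"
    acqu2s = path / "acqu2s"
    for required in (ser, acqus, acqu2s):
        if not required.exists():
            raise FileNotFoundError(f"missing vendor file: {required}")
    p1 = _read_jcamp_params(acqus)
    p2 = _read_jcamp_params(acqu2s)
    td1 = int(p1.get("TD", 0))
    td2 = int(p2.get("TD", 0))
    if td1 <= 0 or td2 <= 0:
        raise ValueError("TD missing or non-positive in parameter files")
    byteorder = ">" if int(p1.get("BYTORDA", 0)) == 1 else "<"
    dtype = np.dtype(f"{byteorder}i4")
    values = np.fromfile(ser, dtype=dtype)
    if values.size != td1 * td2:
        raise ValueError(
            f"ser size {values.size} does not match TD1*TD2 = {td1 * td2}"
        )
    values = values.reshape(td2, td1).astype(np.float64)
    matrix = values[:, 0::2] + 1j * values[:, 1::2]
    params = {**{f"2_{k}": v for k, v in p2.items()}, **p1}
    sequence_map = {}
    if "SFO1" in p1:
        sequence_map["larmor"] = float(p1["SFO1"])
    if "D1" in p1:
        sequence_map["recovery"] = float(p1["D1"])
    params["sequence"] = sequence_map
    return matrix, params
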