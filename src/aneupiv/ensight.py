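"""Minimal EnSight Gold case reader/writer for gridded vector time series.

Covers the structured *block* subset used for planar PIV exports: one part,
uniform node ordering (i fastest), one vector-per-node variable with a
wildcarded per-timestep file series.  ASCII files are written; both ASCII
and C-binary files are read (the dialect is auto-detected from the first
record of the geometry file).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["EnSightCase", "read_ensight", "write_ensight"]


@dataclass(frozen=True)
class EnSightCase:
    """Gridded time-dependent vector dataset."""

    x_mm: np.ndarray              # 1-D block axes
    y_mm: np.ndarray
    z_mm: np.ndarray
    values: np.ndarray            # (n_times, ny, nx, 3) for a planar block
    times: np.ndarray
    variable: str


# --------------------------------------------------------------------------
# writing (ASCII)
# --------------------------------------------------------------------------

def write_ensight(prefix, x_mm: np.ndarray, y_mm: np.ndarray,
                  vectors: np.ndarray, times: np.ndarray,
                  variable: str = "velocity") -> Path:
    """Write a one-part block case; returns the .case path.

    ``vectors`` has shape (n_times, ny, nx, 3); NaNs (masked points) are
    stored as zeros with the mask implied by the flow itself.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vectors = np.asarray(vectors, dtype=float)
    times = np.asarray(times, dtype=float)
    if vectors.ndim != 4 or vectors.shape[-1] != 3 or len(times) != vectors.shape[0]:
        raise ValueError("vectors must be (n_times, ny, nx, 3) matching times")
    nx, ny = len(x_mm), len(y_mm)
    if vectors.shape[1:3] != (ny, nx):
        raise ValueError("vector grid does not match the axes")

    geo = prefix.with_suffix(".geo")
    with open(geo, "w") as fh:
        fh.write("EnSight Gold geometry\nwritten by aneupiv\n")
        fh.write("node id off\nelement id off\n")
        fh.write("part\n%10d\nmeasurement plane\nblock\n" % 1)
        fh.write("%10d%10d%10d\n" % (nx, ny, 1))
        for axis in (np.tile(x_mm, ny), np.repeat(y_mm, nx), np.zeros(nx * ny)):
            for val in axis:
                fh.write("%14.7e\n" % val)

    width = max(4, len(str(len(times) - 1)))
    for i, frame in enumerate(vectors):
        path = prefix.parent / f"{prefix.name}.{i:0{width}d}.vec"
        with open(path, "w") as fh:
            fh.write(f"{variable}\npart\n%10d\nblock\n" % 1)
            comp = np.nan_to_num(frame)
            for c in range(3):
                for val in comp[..., c].ravel():   # i fastest, matches block order
                    fh.write("%14.7e\n" % val)

    case = prefix.with_suffix(".case")
    with open(case, "w") as fh:
        fh.write("FORMAT\ntype: ensight gold\n\nGEOMETRY\n")
        fh.write(f"model: {geo.name}\n\nVARIABLE\n")
        fh.write(f"vector per node: 1 {variable} {prefix.name}.{'*' * width}.vec\n\n")
        fh.write("TIME\ntime set: 1\n")
        fh.write(f"number of steps: {len(times)}\n")
        fh.write("filename start number: 0\nfilename increment: 1\n")
        fh.write("time values:\n")
        for t in times:
            fh.write("%12.5e\n" % t)
    return case


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------

def _is_binary(path: Path) -> bool:
    head = path.open("rb").read(80)
    return (b"C Binary" in head or b"Fortran Binary" in head
            or b"\x00" in head)   # variable files: padded 80-char records


def _read_ascii_tokens(path: Path) -> list[str]:
    return path.read_text().split("\n")


def _parse_geo_ascii(path: Path):
    lines = [ln.strip() for ln in _read_ascii_tokens(path)]
    try:
        i = next(k for k, ln in enumerate(lines) if ln == "block")
    except StopIteration:
        raise ValueError(f"unsupported EnSight geometry (no block part): {path}")
    nx, ny, nz = (int(v) for v in lines[i + 1].split())
    n = nx * ny * nz
    vals = np.array([float(v) for v in lines[i + 2:i + 2 + 3 * n]])
    coords = vals.reshape(3, n)
    x = coords[0, :nx]
    y = coords[1, :nx * ny:nx]
    z = coords[2, ::nx * ny]
    return x, y, z, (nx, ny, nz)


def _parse_var_ascii(path: Path, shape):
    nx, ny, nz = shape
    n = nx * ny * nz
    lines = [ln.strip() for ln in _read_ascii_tokens(path)]
    try:
        i = next(k for k, ln in enumerate(lines) if ln == "block")
    except StopIteration:
        raise ValueError(f"unsupported EnSight variable layout: {path}")
    vals = np.array([float(v) for v in lines[i + 1:i + 1 + 3 * n]])
    return vals.reshape(3, nz, ny, nx)


def _parse_geo_binary(path: Path):
    buf = path.read_bytes()
    pos = 0

    def string():
        nonlocal pos
        s = buf[pos:pos + 80].split(b"\x00")[0].decode("latin1").strip()
        pos += 80
        return s

    def ints(n):
        nonlocal pos
        out = np.frombuffer(buf, dtype="<i4", count=n, offset=pos)
        pos += 4 * n
        return out

    def floats(n):
        nonlocal pos
        out = np.frombuffer(buf, dtype="<f4", count=n, offset=pos)
        pos += 4 * n
        return out.astype(float)

    first = string()
    if "C Binary" not in first:
        raise ValueError(f"unsupported EnSight binary dialect in {path}")
    string(); string()                    # description lines
    tok = string()                        # node id ...
    if not tok.startswith("node id"):
        raise ValueError(f"unexpected geometry record {tok!r}")
    string()                              # element id ...
    tok = string()
    if tok.startswith("extents"):
        floats(6)
        tok = string()
    if tok != "part":
        raise ValueError(f"unsupported EnSight geometry (no part): {path}")
    ints(1)
    string()                              # part description
    tok = string()
    if not tok.startswith("block"):
        raise ValueError(f"unsupported EnSight geometry (no block part): {path}")
    nx, ny, nz = (int(v) for v in ints(3))
    n = nx * ny * nz
    coords = floats(3 * n).reshape(3, n)
    return coords[0, :nx], coords[1, :nx * ny:nx], coords[2, ::nx * ny], (nx, ny, nz)


def _parse_var_binary(path: Path, shape):
    nx, ny, nz = shape
    n = nx * ny * nz
    buf = path.read_bytes()
    pos = 0

    def string():
        nonlocal pos
        s = buf[pos:pos + 80].split(b"\x00")[0].decode("latin1").strip()
        pos += 80
        return s

    string()                              # description
    string()                              # part
    pos += 4                              # part number
    tok = string()
    if not tok.startswith("block"):
        raise ValueError(f"unsupported EnSight variable layout: {path}")
    vals = np.frombuffer(buf, dtype="<f4", count=3 * n, offset=pos).astype(float)
    return vals.reshape(3, nz, ny, nx)


_CASE_RE = {
    "model": re.compile(r"^model:\s*(?:\d+\s+)?(\S+)"),
    "vector": re.compile(r"^vector per node:\s*(?:\d+\s+)?(\S+)\s+(\S+)"),
    "steps": re.compile(r"^number of steps:\s*(\d+)"),
    "start": re.compile(r"^filename start number:\s*(\d+)"),
    "inc": re.compile(r"^filename increment:\s*(\d+)"),
}


def read_ensight(case_path) -> EnSightCase:
    """Read a block-structured EnSight Gold case with one vector variable.

    Missing referenced files raise FileNotFoundError naming the file;
    unsupported layouts raise ValueError.
    """
    case_path = Path(case_path)
    if not case_path.exists():
        raise FileNotFoundError(str(case_path))
    text = case_path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]

    model = varname = pattern = None
    steps, start, inc = 1, 0, 1
    times: list[float] = []
    in_times = False
    for ln in lines:
        if m := _CASE_RE["model"].match(ln):
            model = m.group(1)
        elif m := _CASE_RE["vector"].match(ln):
            varname, pattern = m.group(1), m.group(2)
        elif m := _CASE_RE["steps"].match(ln):
            steps = int(m.group(1))
        elif m := _CASE_RE["start"].match(ln):
            start = int(m.group(1))
        elif m := _CASE_RE["inc"].match(ln):
            inc = int(m.group(1))
        elif ln.startswith("time values"):
            in_times = True
            tail = ln.split(":", 1)[1].strip()
            if tail:
                times.extend(float(v) for v in tail.split())
        elif in_times and ln and not ln[0].isalpha():
            times.extend(float(v) for v in ln.split())
        elif in_times and ln and ln[0].isalpha():
            in_times = False
    if model is None or pattern is None:
        raise ValueError(f"case file lacks a model/vector variable: {case_path}")

    root = case_path.parent
    geo_path = root / model
    if not geo_path.exists():
        raise FileNotFoundError(f"geometry file referenced by case not found: {geo_path}")
    binary = _is_binary(geo_path)
    x, y, z, shape = (_parse_geo_binary if binary else _parse_geo_ascii)(geo_path)

    nwild = pattern.count("*")
    frames = []
    for step in range(steps):
        num = start + step * inc
        name = pattern.replace("*" * nwild, f"{num:0{nwild}d}") if nwild else pattern
        vpath = root / name
        if not vpath.exists():
            raise FileNotFoundError(f"variable file referenced by case not found: {vpath}")
        comp = (_parse_var_binary if _is_binary(vpath) else _parse_var_ascii)(vpath, shape)
        frames.append(np.moveaxis(comp[:, 0], 0, -1))   # planar: take k = 0 slab
    values = np.stack(frames)

    if not times:
        times = list(range(steps))
    return EnSightCase(x_mm=np.asarray(x), y_mm=np.asarray(y), z_mm=np.asarray(z),
                       values=values, times=np.asarray(times, dtype=float),
                       variable=varname or "velocity")
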