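"""Tables with metadata headers, run manifests, seed handling."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = ["write_table", "read_table", "RunManifest", "spawn_seeds", "TableParseError"]


class TableParseError(ValueError):
    def __init__(self, msg, line_no=None):
        super().__init__(msg if line_no is None else f"line {line_no}: {msg}")
        self.line_no = line_no


def write_table(path: str | Path, columns: dict[str, np.ndarray],
                metadata: dict | None = None) -> None:
    """Write a TSV with '#'-prefixed ``key=value`` metadata header lines.

    Floats are written with 17 significant digits so that a read-back is
    bit-exact.  An empty table writes the header only and round-trips.
    """
    path = Path(path)
    names = list(columns)
    arrays = [np.asarray(columns[c]) for c in names]
    lens = {len(a) for a in arrays} or {0}
    if len(lens) > 1:
        raise ValueError("columns must have equal lengths")
    nrow = lens.pop() if arrays else 0
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={json.dumps(v) if not isinstance(v, str) else v}\n")
        fh.write("\t".join(names) + "\n")
        for i in range(nrow):
            cells = []
            for a in arrays:
                x = a[i]
                if isinstance(x, (float, np.floating)):
                    cells.append(repr(float(x)))
                else:
                    cells.append(str(x))
            fh.write("\t".join(cells) + "\n")
    os.replace(tmp, path)


def read_table(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read a TSV written by :func:`write_table`; extra columns are preserved."""
    path = Path(path)
    metadata: dict = {}
    names = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise TableParseError("malformed metadata header "
                                          f"(expected key=value): {body!r}", ln)
                k, v = body.split("=", 1)
                try:
                    metadata[k.strip()] = json.loads(v)
                except json.JSONDecodeError:
                    metadata[k.strip()] = v
                continue
            if names is None:
                names = line.split("\t")
                continue
            cells = line.split("\t")
            if len(cells) != len(names):
                raise TableParseError(
                    f"expected {len(names)} cells, got {len(cells)}", ln)
            rows.append(cells)
    if names is None:
        raise TableParseError("missing column header line")
    out = {}
    for j, name in enumerate(names):
        col = [r[j] for r in rows]
        try:
            out[name] = np.array([float(x) for x in col])
        except ValueError:
            out[name] = np.array(col)
    return out, metadata


@dataclass
class RunManifest:
    """Provenance record written atomically alongside every experiment output."""

    experiment: str
    seed: int | None
    config: dict = field(default_factory=dict)
    solver_settings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)     # path -> sha256
    wall_clock_s: float = 0.0
    tool_version: str = ""

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        h = hashlib.sha256(p.read_bytes()).hexdigest()
        self.outputs[p.name] = h

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")
        os.replace(tmp, path)


class Stopwatch:
    def __enter__(self):
        self.t0 = time.time()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.time() - self.t0
        return False


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]
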