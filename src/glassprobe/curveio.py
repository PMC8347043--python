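"""Self-describing curve files: two/three-column CSV with a YAML header.

Every synthetic or measured curve is written as ``x,y[,sigma]`` rows
preceded by a ``#``-commented YAML block carrying units, temperature,
seed and (for synthetic data) the ground-truth parameters, so a fixture
file is interpretable on its own.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

__all__ = ["write_curve", "read_curve"]


def write_curve(path, x, y, sigma=None, metadata: Optional[dict[str, Any]] = None,
                columns: tuple[str, ...] = ("x", "y", "sigma")) -> None:
    meta = dict(metadata or {})
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cols = [x, y]
    names = list(columns[:2])
    if sigma is not None:
        cols.append(np.asarray(sigma, float))
        names.append(columns[2] if len(columns) > 2 else "sigma")
    buf = io.StringIO()
    header = yaml.safe_dump(meta, sort_keys=True).rstrip("\n")
    for line in header.splitlines():
        buf.write(f"# {line}\n")
    buf.write("# ---\n")
    buf.write(",".join(names) + "\n")
    for row in zip(*cols):
        buf.write(",".join(repr(float(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_curve(path):
    """Returns (metadata dict, column dict of float arrays)."""
    text = Path(path).read_text().splitlines()
    meta_lines, data_lines = [], []
    for line in text:
        if line.startswith("#"):
            # strip only the comment prefix; YAML indentation is significant
            stripped = line[2:] if line.startswith("# ") else line[1:]
            if stripped.strip() != "---":
                meta_lines.append(stripped)
        elif line.strip():
            data_lines.append(line)
    meta = yaml.safe_load("\n".join(meta_lines)) if meta_lines else {}
    names = data_lines[0].split(",")
    rows = np.array([[float(v) for v in ln.split(",")] for ln in data_lines[1:]])
    return meta or {}, {n: rows[:, i] for i, n in enumerate(names)}
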