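"""Plain-text ``key = value`` configuration files.

The device and cohort configurations are flat key-value files: one
``key = value`` pair per line, ``#`` starts a comment, blank lines ignored.
"""

from __future__ import annotations

import os
from typing import Mapping


def read_kv(path: str | os.PathLike) -> dict[str, str]:
    """Read a flat key=value file into a string dict.

    Raises ``ValueError`` on malformed lines or duplicate keys.
    """
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not key:
                raise ValueError(f"{path}:{lineno}: empty key")
            if key in out:
                raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
            out[key] = value
    return out


def write_kv(path: str | os.PathLike, mapping: Mapping[str, object]) -> None:
    """Write a mapping as a flat key=value file (insertion order preserved)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in mapping.items():
            fh.write(f"{key} = {value}\n")
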