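"""CSV/YAML plumbing shared by the pipeline stages and the CLI.

All tabular interchange is plain CSV.  Files written by the pipeline
carry ``# key=value`` comment headers (config hash, seed, stage) so any
output can be traced to the run that produced it; readers skip comment
lines transparently.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_csv", "read_csv"]


def write_csv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_meta(path: str | Path) -> dict:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
            meta[key] = value
    return meta
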