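"""Delimited-text table I/O with provenance headers.

Every table the pipeline writes carries a small comment header (lines
starting with ``#``) recording the producing stage, the seed and a hash of
the configuration, so a run directory is self-describing.  Dates are
ISO-8601, decimal separator is always the point.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

SEP = "\t"


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, *, stage: str = "",
                seed: int | None = None, config: dict | None = None) -> Path:
    """Write ``df`` as TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# stage: {stage}" if stage else "# stage: unknown"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    header = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep=SEP, index=False)
    return path


def read_table(path: str | Path, parse_dates: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment lines skipped)."""
    df = pd.read_csv(path, sep=SEP, comment="#")
    for col in parse_dates or []:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df
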