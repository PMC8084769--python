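"""CSV interchange with versioned schema headers.

All tabular artifacts are plain CSV with a single leading comment line
naming the schema and version (e.g. ``# hapticmem-trials v1``); readers
reject unknown schemas loudly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "TRIALS_SCHEMA",
    "JND_SCHEMA",
    "CONTRASTS_SCHEMA",
    "write_table",
    "read_table",
]

TRIALS_SCHEMA = "hapticmem-trials v1"
JND_SCHEMA = "hapticmem-jnd-table v1"
CONTRASTS_SCHEMA = "hapticmem-contrasts v1"

TRIALS_COLUMNS = [
    "participant",
    "session",
    "block",
    "condition",
    "n1",
    "masked",
    "standard_period_mm",
    "comparison_period_mm",
    "side",
    "response",
]


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# {schema}\n")
        df.to_csv(fh, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise ValueError(
                f"{path}: missing schema header line; expected '# {schema}'"
            )
        found = first.lstrip("# ").strip()
        if found != schema:
            raise ValueError(f"{path}: unknown schema '{found}'; expected '{schema}'")
        return pd.read_csv(fh)
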