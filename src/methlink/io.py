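"""Plain-text readers and writers for the pipeline's tabular formats.

Matrices travel as TSV with the sample id in the first column and probe ids
in the header; gene sets use the standard GMT format (set name, description,
then member genes, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x probes matrix TSV (first column = sample id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a phenotype/manifest-style TSV with a leading id column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into ``{set_name: [genes]}``.

    The description field (second column) is discarded; duplicate genes
    within a set are kept once, preserving first-seen order.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, genes = parts[0], parts[2:]
            seen: list[str] = []
            for g in genes:
                if g and g not in seen:
                    seen.append(g)
            sets[name] = seen
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_truth(truth: dict, path: str | Path) -> None:
    """Write the generator's planted-truth sidecar as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=_jsonable)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if hasattr(obj, "tolist"):
        return obj.tolist()  # numpy arrays and scalars
    raise TypeError(f"not JSON-serializable: {type(obj)}")
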