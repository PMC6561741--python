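"""File formats: BED, bedGraph, chrom.sizes, provenance-stamped TSV, JSON.

TSV outputs carry ``#``-prefixed provenance header lines (tool version,
config hash, seed) so every table records how it was produced; readers skip
comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__


def config_hash(config: Mapping) -> str:
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def provenance_header(seed=None, config: Mapping | None = None,
                      **extra) -> str:
    fields = {"tool": f"spikecal {__version__}"}
    if seed is not None:
        fields["seed"] = seed
    if config is not None:
        fields["config_hash"] = config_hash(config)
    fields.update(extra)
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def write_tsv(df: pd.DataFrame, path, seed=None, config=None,
              index: bool = False, **extra) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config, **extra))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_chrom_sizes(path) -> dict:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path) -> pd.DataFrame:
    """BED3/BED6 (tab-separated, no header, 0-based half-open)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
            if c in df.columns]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(df: pd.DataFrame, value_column: str, path,
                   track_name: str | None = None) -> None:
    """bedGraph of one value column over chrom/start/end rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        df[["chrom", "start", "end", value_column]].to_csv(
            fh, sep="\t", header=False, index=False)


def write_json(obj, path, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_provenance": {"tool": f"spikecal {__version__}",
                               "seed": seed}}
    payload.update(obj if isinstance(obj, dict) else {"value": obj})
    path.write_text(json.dumps(payload, indent=1, sort_keys=True,
                               default=str))


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV with the genome-split totals per library."""
    required = ["sample_id", "assay", "condition", "replicate", "n_target",
                "n_spike", "control_n_target", "control_n_spike",
                "control_kind"]
    df = read_tsv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {missing}")
    for i, row in df.iterrows():
        for col in ("n_target", "n_spike", "control_n_target",
                    "control_n_spike"):
            if row[col] < 0 or pd.isna(row[col]):
                raise ValueError(
                    f"sample sheet row {i} (sample {row['sample_id']!r}): "
                    f"invalid {col}={row[col]}")
    return df
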