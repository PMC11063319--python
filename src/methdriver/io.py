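"""Readers and writers for the plain-text interchange formats.

Everything is tab-separated with a header row and the feature ID in the
first column.  Gene-set collections use the Broad GMT dialect
(``set_name<TAB>description<TAB>gene1<TAB>gene2...``).  Run configuration
is a flat YAML mapping.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .datatypes import SampleSheet
from .errors import ValidationError


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index_label=index_label)
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> Path:
    path = Path(path)
    sheet.data.to_csv(path, sep="\t", index_label="sample_id")
    return path


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleSheet(df)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    ann.to_csv(path, sep="\t", index_label="probe_id")
    return path


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_probe_gene_map(mapping: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    mapping.rename("gene").to_csv(path, sep="\t", index_label="probe_id")
    return path


def read_probe_gene_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "gene" not in df.columns:
        raise ValidationError(f"{path}: expected a 'gene' column")
    return df["gene"]


def read_blacklist(path: str | Path) -> list[str]:
    """One probe ID per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_blacklist(probes: list[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(probes) + ("\n" if probes else ""))
    return path


def read_gmt(path: str | Path) -> dict[str, tuple[str, tuple[str, ...]]]:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, desc = parts[0], parts[1]
        genes = tuple(dict.fromkeys(g for g in parts[2:] if g))
        if not genes:
            raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets[name] = (desc, genes)
    return sets


def write_gmt(sets: Mapping[str, tuple[str, tuple[str, ...]]], path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for name, (desc, genes) in sets.items():
        lines.append("\t".join([name, desc, *genes]))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a flat key: value mapping")
    return cfg


def write_config(cfg: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
    return path
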