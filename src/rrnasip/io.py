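"""Readers and writers for gradient tables, measurement series and FASTA."""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from rrnasip.simulate import GradientTable

__all__ = [
    "gradient_filename",
    "write_gradient_tsv",
    "read_gradient_tsv",
    "write_measurements_csv",
    "read_measurements_csv",
    "read_fasta",
    "write_fasta",
]

# Column header: fraction number + bin midpoint density, e.g. "F03_d1.82625"
_FRACTION_COL = re.compile(r"^F(\d+)_d([0-9.]+)$")


def gradient_filename(table: GradientTable) -> str:
    return f"{table.substrate}_{table.isotope}_{table.timepoint}.tsv"


def write_gradient_tsv(table: GradientTable, path: str | Path) -> Path:
    """Write taxon x fraction counts as TSV; header carries fraction densities."""
    path = Path(path)
    cols = [
        f"F{int(f):02d}_d{rho:.5f}"
        for f, rho in zip(table.counts.columns, table.densities)
    ]
    df = table.counts.copy()
    df.columns = cols
    df.index.name = "taxon"
    df.to_csv(path, sep="\t")
    return path


def read_gradient_tsv(
    path: str | Path,
    substrate: str | None = None,
    isotope: str | None = None,
    timepoint: str | None = None,
) -> GradientTable:
    """Read a gradient TSV; gradient identity defaults to the filename fields."""
    path = Path(path)
    if substrate is None or isotope is None or timepoint is None:
        parts = path.stem.split("_")
        if len(parts) != 3:
            raise ValueError(
                f"cannot infer gradient identity from filename {path.name!r}; "
                "pass substrate, isotope and timepoint explicitly"
            )
        substrate = substrate or parts[0]
        isotope = isotope or parts[1]
        timepoint = timepoint or parts[2]
    df = pd.read_csv(path, sep="\t", index_col=0)
    fractions, densities = [], []
    for col in df.columns:
        m = _FRACTION_COL.match(col)
        if not m:
            raise ValueError(f"{path}: unrecognized fraction column {col!r}")
        fractions.append(int(m.group(1)))
        densities.append(float(m.group(2)))
    df.columns = fractions
    return GradientTable(
        counts=df,
        densities=np.array(densities),
        substrate=substrate,
        isotope=isotope,
        timepoint=timepoint,
    )


def write_measurements_csv(measurements: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["pool", "treatment", "timepoint", "replicate", "delta13C"]
    measurements[cols].to_csv(path, index=False)
    return path


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"pool", "treatment", "timepoint", "replicate", "delta13C"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    items = sequences.items() if isinstance(sequences, dict) else sequences
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
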