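"""File formats and configuration.

FASTQ (Phred+33, plain or gzip) streaming via Biopython's fast iterator;
TSV count tables and barcode-library files with ``#``-prefixed provenance
headers; JSON QC reports; YAML pipeline configuration. All table writers
emit a provenance header recording the tool version and the parameters and
seeds that produced the file, so outputs are self-describing and reruns are
byte-comparable.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__
from .extract import CountTable, ReadRecord
from .simdata import BarcodeLibrary

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_count_table",
    "write_count_table",
    "read_library",
    "write_library",
    "read_metadata",
    "write_qc_report",
    "PipelineConfig",
    "load_config",
]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ file (plain or gzip), constant memory.

    Malformed records (truncation, sequence/quality length mismatch) raise a
    ValueError identifying the offending record.
    """
    n = 0
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                if len(seq) != len(qual):
                    raise ValueError(
                        f"{path}: record {n} ({title.split()[0]}): sequence length "
                        f"{len(seq)} != quality length {len(qual)}"
                    )
                if not qual:
                    raise ValueError(f"{path}: record {n} has an empty quality string")
                yield ReadRecord(title.split()[0], seq, qual)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ near record {n + 1}: {exc}") from exc


def write_fastq(records, path: str | Path) -> None:
    """Write ReadRecords as 4-line FASTQ."""
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.qualities}\n")


def _provenance_lines(kind: str, params: dict | None) -> list[str]:
    lines = [f"#clonetrace={__version__}", f"#content={kind}"]
    for key, value in (params or {}).items():
        lines.append(f"#{key}={value}")
    return lines


def write_count_table(table: CountTable | pd.DataFrame, path: str | Path,
                      params: dict | None = None) -> None:
    """Write a barcode x sample count table as TSV with a provenance header."""
    df = table.df if isinstance(table, CountTable) else table
    with open(path, "wt") as fh:
        for line in _provenance_lines("count_table", params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index_label="barcode")


def read_count_table(path: str | Path) -> CountTable:
    """Read a count-table TSV back; rejects negative or non-integer counts."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="barcode", dtype=str)
    if df.empty and df.columns.size == 0:
        return CountTable(pd.DataFrame(index=pd.Index([], name="barcode")))
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: counts must be integers") from exc
    if (df.values < 0).any():
        raise ValueError(f"{path}: counts must be non-negative")
    df.index = df.index.astype(str)
    return CountTable(df)


def write_library(library: BarcodeLibrary, path: str | Path,
                  params: dict | None = None) -> None:
    """Write a barcode library as TSV: header '#linker=..', columns side/index/sequence."""
    with open(path, "wt") as fh:
        for line in _provenance_lines("barcode_library", params):
            fh.write(line + "\n")
        fh.write(f"#linker={library.linker}\n")
        fh.write("side\tindex\tsequence\n")
        for i, seq in enumerate(library.left_modules, start=1):
            fh.write(f"L\t{i}\t{seq}\n")
        for i, seq in enumerate(library.right_modules, start=1):
            fh.write(f"R\t{i}\t{seq}\n")


def read_library(path: str | Path) -> BarcodeLibrary:
    """Read a library TSV written by :func:`write_library`."""
    linker = None
    rows: list[tuple[str, int, str]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("#linker="):
                    linker = line.split("=", 1)[1]
                continue
            if line.startswith("side\t") or not line:
                continue
            side, index, seq = line.split("\t")
            rows.append((side, int(index), seq))
    if linker is None:
        raise ValueError(f"{path}: missing '#linker=' header line")
    left = [seq for side, i, seq in sorted(rows) if side == "L"]
    right = [seq for side, i, seq in sorted(rows) if side == "R"]
    for side, seqs in (("L", left), ("R", right)):
        indices = [i for s, i, _ in sorted(rows) if s == side]
        if indices != list(range(1, len(seqs) + 1)):
            raise ValueError(f"{path}: {side} module indices must be 1..n without gaps")
    return BarcodeLibrary(tuple(left), tuple(right), linker)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, stage, [group], [replicate])."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    from .cohort import validate_metadata

    return validate_metadata(meta)


def write_qc_report(table: CountTable, path: str | Path, params: dict | None = None) -> None:
    """JSON QC report: per-sample totals and discard-reason tallies."""
    payload = {
        "clonetrace": __version__,
        "params": params or {},
        "samples": table.qc,
    }
    with open(path, "wt") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulate -> extract -> diversity)."""

    out_dir: str
    seed: int = 0
    n_left: int = 150
    n_right: int = 150
    min_pairwise_distance: int = 5
    n_clones: int = 2000
    cells_per_clone: int = 500
    evenness: float = 0.97
    n_replicates: int = 3
    n_reads: int = 50_000
    substitution_rate: float = 0.005
    fraction_low_quality: float = 0.02
    min_mean_phred: float = 30.0
    max_mismatches: int = 2
    min_count: int = 1
    rarefy_depths: tuple = ()
    rarefy_replicates: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.min_mean_phred <= 41:
            raise ValueError("min_mean_phred outside the Phred+33 range")
        if not 0 <= self.max_mismatches <= 18:
            raise ValueError("max_mismatches must lie in [0, 18]")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat YAML config file into a PipelineConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "out_dir" not in raw:
        raise ValueError(f"{path}: config must set 'out_dir'")
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "rarefy_depths" in raw and raw["rarefy_depths"] is not None:
        raw["rarefy_depths"] = tuple(int(d) for d in raw["rarefy_depths"])
    return PipelineConfig(**raw)
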