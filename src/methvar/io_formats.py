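"""On-disk formats for the methylation-variability pipeline.

Every interval in the package is 0-based half-open; BED is the only
interchange dialect.  Three text formats are defined here:

* **Read-haplotype TSV** — one line per distinct read haplotype:
  ``chrom  <pos,pos,...>  <states over {M,U}>  <multiplicity>  <sample_id>``.
  Positions are 0-based CpG site coordinates, strictly increasing; the state
  string gives the methylation call (M = methylated, U = unmethylated) at
  each position; multiplicity collapses identical reads.
* **BED3/BED4** — annotations, mappable segments, called blocks.
* **Labelled matrix TSV** — first column row labels, header row column
  labels, ``NA`` as the sole missingness token (β matrices, genotype
  dosages, phenotypes).

All readers validate eagerly and report the offending line number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NA_TOKEN = "NA"

__all__ = [
    "ReadHaplotype",
    "GenomicInterval",
    "read_haplotype_file",
    "write_haplotype_file",
    "read_bed",
    "write_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_config",
    "write_config",
]


@dataclass(frozen=True)
class ReadHaplotype:
    """One sequencing read's binary methylation states over consecutive CpGs.

    ``states`` is a string over {M, U} aligned with ``cpg_positions``;
    ``multiplicity`` counts identical reads collapsed into this record.
    """

    chrom: str
    cpg_positions: tuple[int, ...]
    states: str
    sample_id: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        bad = set(self.states) - {"M", "U"}
        if bad:
            raise ValueError(f"invalid state characters {sorted(bad)!r}; only M/U allowed")
        if len(self.states) != len(self.cpg_positions):
            raise ValueError(
                f"state string length {len(self.states)} != "
                f"{len(self.cpg_positions)} positions"
            )
        if any(b <= a for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ValueError("cpg_positions must be strictly increasing")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


# ---------------------------------------------------------------------------
# read-haplotype TSV


def read_haplotype_file(path: str | Path) -> list[ReadHaplotype]:
    """Parse a read-haplotype TSV; malformed lines raise with line number."""
    records: list[ReadHaplotype] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_str, states, count_str, sample_id = fields
            try:
                positions = tuple(int(p) for p in pos_str.split(","))
                multiplicity = int(count_str)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            try:
                records.append(
                    ReadHaplotype(chrom, positions, states, sample_id, multiplicity)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def write_haplotype_file(records: Iterable[ReadHaplotype], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                "\t".join(
                    (
                        rec.chrom,
                        ",".join(str(p) for p in rec.cpg_positions),
                        rec.states,
                        str(rec.multiplicity),
                        rec.sample_id,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 (extra columns ignored); intervals returned sorted."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 else None
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    intervals.sort()
    return intervals


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED3/BED4(+score), sorted by (chrom, start)."""
    items = list(intervals)
    if scores is not None and len(list(scores)) != len(items):
        raise ValueError("scores length must match intervals")
    order = sorted(range(len(items)), key=lambda i: items[i])
    with open(path, "w") as fh:
        for i in order:
            iv = items[i]
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            if scores is not None:
                if iv.name is None:
                    cols.append(".")
                cols.append(f"{scores[i]:.6g}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# labelled matrices


def read_matrix_tsv(path: str | Path, na_token: str = NA_TOKEN) -> pd.DataFrame:
    """Read a labelled numeric matrix; ``na_token`` cells become NaN.

    Raises on ragged rows and on duplicate row or column labels.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=[na_token],
        keep_default_na=False,
        on_bad_lines="error",
    )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row labels {dupes}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate column labels")
    # pandas silently NaN-pads short rows only when malformed; enforce numeric
    df = df.apply(pd.to_numeric)
    return df


def write_matrix_tsv(
    df: pd.DataFrame, path: str | Path, na_token: str = NA_TOKEN
) -> None:
    df.to_csv(path, sep="\t", na_rep=na_token, index_label=df.index.name or "id")


# ---------------------------------------------------------------------------
# plain-text key:value config


def _parse_scalar(text: str):
    text = text.strip()
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def read_config(path: str | Path) -> dict:
    """Parse ``key: value`` lines; '#' starts a comment.

    Values are coerced to int/float/bool where possible; comma-separated
    values become tuples.
    """
    out: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key: value'")
            key, _, val = line.partition(":")
            val = val.strip()
            if "," in val:
                out[key.strip()] = tuple(_parse_scalar(v) for v in val.split(","))
            else:
                out[key.strip()] = _parse_scalar(val)
    return out


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, val in cfg.items():
            if isinstance(val, (tuple, list)):
                val = ",".join(str(v) for v in val)
            fh.write(f"{key}: {val}\n")
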