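"""Readers and writers for pooled-screen data and genomics side products.

Tabular containers are plain pandas DataFrames with a validated schema:

* count table — TSV, first column ``guide_id`` (unique), remaining columns
  one sample each, non-negative integer read counts;
* sample sheet — CSV with columns ``sample, condition, replicate,
  generation`` ((condition, replicate, generation) unique, every
  condition/replicate pair anchored by a generation-0 sample);
* guide library — TSV with columns ``guide_id, target_id`` plus optional
  ``sequence, chrom, start, end, strand`` (coordinates 0-based half-open;
  control guides carry the control target label, default ``ctrl``).

Also provided: exact-match guide counting from FASTQ and bedGraph export
of per-guide fitness as a genome-browser coverage track.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_LABEL",
    "read_count_table",
    "write_count_table",
    "read_sample_sheet",
    "validate_sample_sheet",
    "read_library",
    "write_library",
    "validate_library",
    "read_guide_bed",
    "read_guide_gff3",
    "count_guides_from_fastq",
    "coverage_intervals",
    "export_coverage_track",
]

CONTROL_LABEL = "ctrl"

LIBRARY_OPTIONAL = ("sequence", "chrom", "start", "end", "strand")


class ScreenIOError(ValueError):
    """Malformed screen input file."""


# ---------------------------------------------------------------- counts


def read_count_table(path) -> pd.DataFrame:
    """Read a guide-by-sample count table (TSV, first column guide_id)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "guide_id":
        raise ScreenIOError(
            f"{path}: first column must be 'guide_id', got '{df.columns[0]}'"
        )
    dup = df["guide_id"][df["guide_id"].duplicated()]
    if len(dup):
        raise ScreenIOError(f"{path}: duplicated guide id '{dup.iloc[0]}'")
    df = df.set_index("guide_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise ScreenIOError(
                f"{path}: non-integer or negative count in column '{col}', "
                f"line {line}"
            )
        df[col] = vals.astype(np.int64)
    return df


def write_count_table(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="guide_id")


# ---------------------------------------------------------- sample sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "condition", "replicate", "generation"}
    missing = required - set(sheet.columns)
    if missing:
        raise ScreenIOError(f"sample sheet missing columns: {sorted(missing)}")
    key = sheet[["condition", "replicate", "generation"]]
    if key.duplicated().any():
        row = key[key.duplicated()].iloc[0]
        raise ScreenIOError(
            "duplicate (condition, replicate, generation): "
            f"({row.condition}, {row.replicate}, {row.generation})"
        )
    if sheet["sample"].duplicated().any():
        raise ScreenIOError("duplicate sample ids in sample sheet")
    for (cond, rep), grp in sheet.groupby(["condition", "replicate"]):
        if 0 not in set(grp["generation"]):
            raise ScreenIOError(
                f"condition {cond} replicate {rep} lacks a generation-0 sample"
            )
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    sheet["generation"] = pd.to_numeric(sheet["generation"])
    sheet["replicate"] = pd.to_numeric(sheet["replicate"], downcast="integer")
    return validate_sample_sheet(sheet)


# -------------------------------------------------------------- library


def validate_library(lib: pd.DataFrame) -> pd.DataFrame:
    if "guide_id" not in lib.columns or "target_id" not in lib.columns:
        raise ScreenIOError("library needs 'guide_id' and 'target_id' columns")
    dup = lib["guide_id"][lib["guide_id"].duplicated()]
    if len(dup):
        raise ScreenIOError(f"duplicated guide id '{dup.iloc[0]}' in library")
    if {"start", "end"} <= set(lib.columns):
        coords = lib.dropna(subset=["start", "end"])
        bad = coords[coords["start"] >= coords["end"]]
        if len(bad):
            raise ScreenIOError(
                f"guide '{bad['guide_id'].iloc[0]}' has start >= end"
            )
    return lib


def read_library(path) -> pd.DataFrame:
    lib = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "target_id": str})
    return validate_library(lib)


def write_library(lib: pd.DataFrame, path) -> None:
    lib.to_csv(path, sep="\t", index=False)


def read_guide_bed(path) -> pd.DataFrame:
    """Guide coordinates from BED (0-based half-open; name = guide_id)."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "guide_id", "score", "strand"],
        usecols=range(6),
    )
    return bed[["guide_id", "chrom", "start", "end", "strand"]]


def read_guide_gff3(path) -> pd.DataFrame:
    """Guide coordinates from GFF3 (1-based closed, converted to 0-based
    half-open). The guide id is taken from the ``ID=`` attribute."""
    gff = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "chrom", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
    )
    guide_id = gff["attributes"].str.extract(r"ID=([^;]+)")[0]
    out = pd.DataFrame(
        {
            "guide_id": guide_id,
            "chrom": gff["chrom"],
            "start": gff["start"].astype(int) - 1,
            "end": gff["end"].astype(int),
            "strand": gff["strand"],
        }
    )
    return out


# ------------------------------------------------------- FASTQ counting


def count_guides_from_fastq(
    reads, library: pd.DataFrame, flank5: str, flank3: str
) -> tuple[pd.Series, int]:
    """Count reads per guide by exact spacer matching.

    A read contributes one count to guide g iff the subsequence between
    the first occurrence of ``flank5`` and the following ``flank3``
    exactly equals g's spacer sequence. Everything else (missing flanks,
    mismatched spacer) is tallied as unmatched. Returns
    ``(counts indexed by guide_id, n_unmatched)`` with
    ``counts.sum() + n_unmatched`` equal to the number of reads.
    """
    from Bio import SeqIO

    if "sequence" not in library.columns or library["sequence"].isna().all():
        raise ScreenIOError("library provides no guide sequences")
    spacer_to_guide = {
        str(seq).upper(): gid
        for gid, seq in zip(library["guide_id"], library["sequence"])
        if isinstance(seq, str) and seq
    }
    counts = pd.Series(0, index=library["guide_id"], dtype=np.int64)
    flank5, flank3 = flank5.upper(), flank3.upper()
    unmatched = 0
    for record in SeqIO.parse(reads, "fastq"):
        seq = str(record.seq).upper()
        i = seq.find(flank5)
        if i < 0:
            unmatched += 1
            continue
        j = seq.find(flank3, i + len(flank5))
        if j < 0:
            unmatched += 1
            continue
        spacer = seq[i + len(flank5) : j]
        gid = spacer_to_guide.get(spacer)
        if gid is None:
            unmatched += 1
        else:
            counts[gid] += 1
    return counts, unmatched


# ------------------------------------------------------ coverage tracks


def coverage_intervals(
    guides: Iterable[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Collapse overlapping guide intervals to a max-|fitness| coverage track.

    ``guides`` is an iterable of (start, end, fitness) with 0-based
    half-open coordinates. For every covered position the emitted value
    is the fitness of the covering guide with maximal absolute fitness;
    ties on |fitness| resolve toward the positive value, then toward the
    earlier-starting guide. Adjacent runs with equal value are merged;
    the returned intervals are sorted, non-overlapping, half-open.
    """
    guides = [(int(s), int(e), float(f)) for s, e, f in guides]
    if not guides:
        return []
    breaks = sorted({p for s, e, _ in guides for p in (s, e)})
    out: list[tuple[int, int, float]] = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        covering = [(s, e, f) for s, e, f in guides if s <= lo and e >= hi]
        if not covering:
            continue
        # max |f|, ties -> positive f, then earlier start
        _, _, value = max(covering, key=lambda g: (abs(g[2]), g[2], -g[0]))
        if out and out[-1][1] == lo and out[-1][2] == value:
            out[-1] = (out[-1][0], hi, value)
        else:
            out.append((lo, hi, value))
    return out


def export_coverage_track(
    fitness: pd.Series,
    library: pd.DataFrame,
    path,
    track_name: str = "fitness",
) -> pd.DataFrame:
    """Write per-guide fitness as a bedGraph coverage track.

    ``fitness`` is indexed by guide_id; coordinates come from the library
    annotation (``chrom, start, end``). Guides without coordinates are
    skipped with a warning. Returns the interval table that was written
    (columns chrom, start, end, value).
    """
    needed = {"chrom", "start", "end"}
    if not needed <= set(library.columns):
        raise ScreenIOError("library lacks chrom/start/end coordinates")
    lib = library.set_index("guide_id")
    rows = []
    for gid, value in fitness.items():
        if gid not in lib.index or pd.isna(lib.at[gid, "start"]):
            warnings.warn(f"guide {gid} has no coordinates; skipped", stacklevel=2)
            continue
        rows.append(
            (lib.at[gid, "chrom"], int(lib.at[gid, "start"]),
             int(lib.at[gid, "end"]), float(value))
        )
    records = []
    by_chrom: dict[str, list] = {}
    for chrom, s, e, f in rows:
        by_chrom.setdefault(chrom, []).append((s, e, f))
    for chrom in sorted(by_chrom):
        for s, e, v in coverage_intervals(by_chrom[chrom]):
            records.append((chrom, s, e, v))
    table = pd.DataFrame(records, columns=["chrom", "start", "end", "value"])
    buf = io.StringIO()
    buf.write(f'track type=bedGraph name="{track_name}"\n')
    table.to_csv(buf, sep="\t", header=False, index=False)
    Path(path).write_text(buf.getvalue())
    return table
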