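"""Convenience I/O: metadata tables and a `samtools depth` averaging helper.

Matrix/catalog/feature/call formats live next to their owning types; this
module only holds the odds and ends that do not belong to a single stage.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from stsdel.catalog import STSCatalog
from stsdel.errors import FormatError


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Cohort metadata TSV with columns sample_id, group."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in frame.columns:
            raise FormatError(f"metadata {path}: missing column {col!r}")
    return frame


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Sample x marker genotype TSV, indexed by sample id."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    return frame


def mean_depth_from_basewise(
    path: str | Path, catalog: STSCatalog
) -> dict[str, float]:
    """Average a `samtools depth`-style per-base TSV (chrom, pos, depth; pos
    1-based) over the catalog's intervals.

    Returns sts_id -> mean per-base depth, counting uncovered bases as zero.
    Upstream alignment and depth extraction are out of scope; this is
    convenience plumbing for one sample's row of the depth matrix.
    """
    sums = {r.sts_id: 0.0 for r in catalog}
    by_chrom: dict[str, list] = {}
    for r in catalog:
        by_chrom.setdefault(r.chrom, []).append(r)
    with Path(path).open(newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            try:
                chrom, pos, depth = row[0], int(row[1]), float(row[2])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"bad per-base depth line: {row!r}") from exc
            pos0 = pos - 1
            for rec in by_chrom.get(chrom, ()):
                if rec.start <= pos0 < rec.end:
                    sums[rec.sts_id] += depth
    return {r.sts_id: sums[r.sts_id] / r.length for r in catalog}
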