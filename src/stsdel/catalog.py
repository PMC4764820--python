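"""STS catalog: coordinates, copy-class and annotation for every tracked site.

The catalog is the coordinate backbone of the pipeline: depth columns, calls
and merged intervals are all keyed by ``sts_id`` and ordered by the catalog's
(chrom, start) sort. Coordinates are 0-based half-open (BED convention)
throughout, and the distance between two STSs is the gap
``start(downstream) - end(upstream)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from stsdel.errors import FormatError, LookupError_, ValidationError

COPY_CLASSES = ("single", "multi")
REGIONS = ("AZFa", "AZFb", "AZFc", "Yp", "other")
ANNOTATIONS = ("coding", "UTR", "intron", "intergenic")

#: column order of the catalog TSV
CATALOG_COLUMNS = (
    "chrom",
    "start",
    "end",
    "sts_id",
    "copy_class",
    "region",
    "annotation",
    "gene",
)


@dataclass(frozen=True)
class STSRecord:
    """One catalog entry.

    ``start``/``end`` are 0-based half-open base-pair coordinates.
    ``copy_class`` is ``single`` for uniquely mapping STSs and ``multi`` for
    STSs with several alignment positions; ``annotation`` is a single
    exclusive category with precedence coding > UTR > intron > intergenic.
    """

    sts_id: str
    chrom: str
    start: int
    end: int
    copy_class: str
    region: str = "other"
    annotation: str = "intergenic"
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"STS {self.sts_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.start < 0:
            raise ValidationError(f"STS {self.sts_id!r}: negative start {self.start}")
        if self.copy_class not in COPY_CLASSES:
            raise ValidationError(
                f"STS {self.sts_id!r}: copy_class {self.copy_class!r} not in {COPY_CLASSES}"
            )
        if self.region not in REGIONS:
            raise ValidationError(
                f"STS {self.sts_id!r}: region {self.region!r} not in {REGIONS}"
            )
        if self.annotation not in ANNOTATIONS:
            raise ValidationError(
                f"STS {self.sts_id!r}: annotation {self.annotation!r} not in {ANNOTATIONS}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def is_multi_copy(self) -> bool:
        return self.copy_class == "multi"


@dataclass
class STSCatalog:
    """Ordered collection of :class:`STSRecord`, sorted by (chrom, start)."""

    records: list[STSRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.start, r.end))
        self._index: dict[str, STSRecord] = {}
        for rec in self.records:
            if rec.sts_id in self._index:
                raise ValidationError(f"duplicate sts_id {rec.sts_id!r} in catalog")
            self._index[rec.sts_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[STSRecord]:
        return iter(self.records)

    def __contains__(self, sts_id: str) -> bool:
        return sts_id in self._index

    def __getitem__(self, sts_id: str) -> STSRecord:
        try:
            return self._index[sts_id]
        except KeyError:
            raise LookupError_(f"unknown sts_id {sts_id!r}") from None

    @property
    def sts_ids(self) -> list[str]:
        return [r.sts_id for r in self.records]

    def position(self, sts_id: str) -> int:
        """Rank of an STS in the catalog's coordinate sort."""
        rec = self[sts_id]
        return self.records.index(rec)

    def gap(self, upstream: str, downstream: str) -> int:
        """Gap distance start(downstream) - end(upstream) in bp."""
        a, b = self[upstream], self[downstream]
        if a.chrom != b.chrom:
            raise ValidationError(
                f"{upstream!r} and {downstream!r} are on different chromosomes"
            )
        return b.start - a.end

    def neighbors_between(self, a: str, b: str) -> list[STSRecord]:
        """All records strictly between ``a``'s end and ``b``'s start.

        ``a`` must lie upstream of ``b`` on the same chromosome. Adjacent
        records yield an empty list.
        """
        ra, rb = self[a], self[b]
        if ra.chrom != rb.chrom:
            raise ValidationError(f"{a!r} and {b!r} are on different chromosomes")
        if ra.start > rb.start:
            raise ValidationError(f"{a!r} is not upstream of {b!r}")
        return [
            r
            for r in self.records
            if r.chrom == ra.chrom and r.start >= ra.end and r.end <= rb.start
        ]

    def subset(self, sts_ids: Sequence[str]) -> "STSCatalog":
        wanted = set(sts_ids)
        return STSCatalog([r for r in self.records if r.sts_id in wanted])


def load_catalog(path: str | Path) -> STSCatalog:
    """Read a catalog TSV (header: chrom start end sts_id copy_class region annotation gene)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in CATALOG_COLUMNS[:-1]:  # gene is optional
            if col not in header:
                raise FormatError(f"catalog {path}: missing required column {col!r}")
        records = []
        for row in reader:
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise FormatError(
                    f"catalog {path}: non-integer coordinate in row {row!r}"
                ) from exc
            gene = (row.get("gene") or "").strip() or None
            if gene == ".":
                gene = None
            records.append(
                STSRecord(
                    sts_id=row["sts_id"],
                    chrom=row["chrom"],
                    start=start,
                    end=end,
                    copy_class=row["copy_class"],
                    region=row["region"],
                    annotation=row["annotation"],
                    gene=gene,
                )
            )
    return STSCatalog(records)


def write_catalog(catalog: STSCatalog, path: str | Path) -> None:
    """Write the catalog back as a TSV; round-trips with :func:`load_catalog`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CATALOG_COLUMNS)
        for r in catalog:
            writer.writerow(
                [r.chrom, r.start, r.end, r.sts_id, r.copy_class, r.region, r.annotation, r.gene or "."]
            )


def to_bed(catalog: STSCatalog) -> str:
    """Export catalog intervals as 6-column BED text."""
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.sts_id}\t0\t." for r in catalog
    ]
    return "\n".join(lines) + ("\n" if lines else "")
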