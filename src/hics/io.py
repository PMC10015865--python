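"""Reading contact records and peak intervals; writing boundary/domain BED.

Text inputs are accepted as 1-based bp coordinates (``pairs`` dialect) or as
0-based bin triples (``triples`` dialect); all internal coordinates are
0-based half-open bins, and BED outputs follow the 0-based half-open BED
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .contact_map import BinnedContactMap

logger = logging.getLogger(__name__)

DIALECTS = ("pairs", "triples")


class ContactParseError(ValueError):
    """A contact line that cannot be interpreted under the declared dialect."""


@dataclass(frozen=True)
class ContactRecord:
    """One contact between two genomic positions of a chromosome.

    ``pos1``/``pos2`` are 1-based bp for the ``pairs`` dialect.  Records read
    from the ``triples`` dialect carry 0-based bin indices instead and an
    empty ``chrom``; they are consumed by :func:`triples_to_map`, not
    :func:`bin_contacts`.
    """

    chrom: str
    pos1: int
    pos2: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED semantics)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval needs start < end, got [{self.start}, {self.end})")


def read_contacts(path: str | Path, dialect: str = "pairs") -> list[ContactRecord]:
    """Parse a whitespace-separated contact file.

    ``pairs`` lines are ``chrom pos1 pos2 [count]`` with 1-based bp
    positions, or the two-chromosome form ``chrom1 pos1 chrom2 pos2
    [count]`` — inter-chromosomal pairs of the latter are dropped with a
    logged count (domain calling is per-chromosome).  ``triples`` lines are
    ``bin_i bin_j count`` with 0-based bin indices.  Lines starting with
    ``#`` are comments.  A malformed line raises
    :class:`ContactParseError` naming the line number — bad input is never
    silently dropped.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    records: list[ContactRecord] = []
    n_inter = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "pairs":
                    if len(fields) not in (3, 4, 5):
                        raise ValueError("expected 3 to 5 columns")
                    two_chrom = len(fields) >= 4 and not _is_int(fields[2])
                    if two_chrom:
                        chrom, chrom2 = fields[0], fields[2]
                        pos1, pos2 = int(fields[1]), int(fields[3])
                        count = int(fields[4]) if len(fields) == 5 else 1
                        if chrom != chrom2:
                            n_inter += 1
                            continue
                    else:
                        if len(fields) == 5:
                            raise ValueError("expected 3 or 4 columns")
                        chrom = fields[0]
                        pos1, pos2 = int(fields[1]), int(fields[2])
                        count = int(fields[3]) if len(fields) == 4 else 1
                    if pos1 < 1 or pos2 < 1:
                        raise ValueError("positions are 1-based and must be >= 1")
                    rec = ContactRecord(chrom, pos1, pos2, count)
                else:
                    if len(fields) not in (2, 3):
                        raise ValueError("expected 2 or 3 columns")
                    i, j = int(fields[0]), int(fields[1])
                    count = int(fields[2]) if len(fields) == 3 else 1
                    if i < 0 or j < 0:
                        raise ValueError("bin indices must be >= 0")
                    rec = ContactRecord("", i, j, count)
            except ValueError as exc:
                raise ContactParseError(
                    f"{path}:{lineno}: cannot parse {line!r} as {dialect}: {exc}"
                ) from exc
            records.append(rec)
    if n_inter:
        logger.info("dropped %d inter-chromosomal contact(s) from %s", n_inter, path)
    return records


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True


def partition_by_chrom(
    records: Iterable[ContactRecord],
) -> dict[str, list[ContactRecord]]:
    """Split a multi-chromosome record list into per-chromosome lists.

    Contacts are intra-chromosomal by construction here (each record names a
    single chromosome); callers that merge two-chromosome formats should drop
    inter-chromosomal pairs before this point.
    """
    out: dict[str, list[ContactRecord]] = {}
    for rec in records:
        out.setdefault(rec.chrom, []).append(rec)
    return out


def bin_contacts(
    records: Sequence[ContactRecord],
    bin_size: int,
    chrom_length: int,
    chrom: str | None = None,
) -> BinnedContactMap:
    """Aggregate 1-based bp contact records into a symmetric binned map.

    Bin index of a position is ``floor((pos - 1) / bin_size)``; the map has
    ``ceil(chrom_length / bin_size)`` bins.  A record beyond ``chrom_length``
    is an error (it would silently truncate coverage otherwise).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    n_bins = -(-chrom_length // bin_size)
    mat = np.zeros((n_bins, n_bins), dtype=float)
    name = chrom
    for rec in records:
        if name is None:
            name = rec.chrom
        elif rec.chrom and rec.chrom != name:
            raise ValueError(
                f"records span multiple chromosomes ({name!r} vs {rec.chrom!r}); "
                "partition them first"
            )
        if rec.pos1 > chrom_length or rec.pos2 > chrom_length:
            raise ValueError(
                f"record {rec} lies beyond chrom_length={chrom_length}"
            )
        i = (rec.pos1 - 1) // bin_size
        j = (rec.pos2 - 1) // bin_size
        mat[i, j] += rec.count
        if i != j:
            mat[j, i] += rec.count
    return BinnedContactMap(mat, bin_size=bin_size, chrom=name or "chr1", stage="raw")


def triples_to_map(
    records: Sequence[ContactRecord],
    bin_size: int,
    n_bins: int | None = None,
    chrom: str = "chr1",
) -> BinnedContactMap:
    """Build a raw map from pre-binned (bin_i, bin_j, count) records."""
    if n_bins is None:
        n_bins = max((max(r.pos1, r.pos2) for r in records), default=-1) + 1
    if n_bins < 1:
        raise ValueError("cannot infer n_bins from an empty record list")
    mat = np.zeros((n_bins, n_bins), dtype=float)
    for rec in records:
        if rec.pos1 >= n_bins or rec.pos2 >= n_bins:
            raise ValueError(f"bin index in {rec} exceeds n_bins={n_bins}")
        mat[rec.pos1, rec.pos2] += rec.count
        if rec.pos1 != rec.pos2:
            mat[rec.pos2, rec.pos1] += rec.count
    return BinnedContactMap(mat, bin_size=bin_size, chrom=chrom, stage="raw")


def map_to_records(cmap: BinnedContactMap) -> list[ContactRecord]:
    """Synthesize 1-based bp records (at bin-start positions) from a raw map.

    Inverse of :func:`bin_contacts` up to within-bin position: re-binning the
    returned records reproduces the matrix exactly.
    """
    if cmap.stage != "raw":
        raise ValueError("records can only be synthesized from a raw map")
    recs: list[ContactRecord] = []
    iu, ju = np.nonzero(np.triu(cmap.matrix))
    for i, j in zip(iu.tolist(), ju.tolist()):
        recs.append(
            ContactRecord(
                cmap.chrom,
                i * cmap.bin_size + 1,
                j * cmap.bin_size + 1,
                int(cmap.matrix[i, j]),
            )
        )
    return recs


def write_contacts(records: Sequence[ContactRecord], path: str | Path) -> None:
    """Write records in the ``pairs`` dialect (chrom pos1 pos2 count)."""
    with Path(path).open("w") as fh:
        fh.write("# chrom\tpos1\tpos2\tcount\n")
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.pos1}\t{rec.pos2}\t{rec.count}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into genomic intervals (extra columns -> name, score)."""
    out: list[GenomicInterval] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 else None
            out.append(GenomicInterval(fields[0], start, end, name, score))
    return out


def write_boundaries_bed(bset, bin_size: int, path: str | Path) -> None:
    """One BED line per boundary bin: start = i*bin_size, end = (i+1)*bin_size.

    Column 4 carries the eta score of the bin, column 5 the alpha level.
    """
    with Path(path).open("w") as fh:
        for bin_idx, eta in zip(bset.bins, bset.eta):
            start = int(bin_idx) * bin_size
            fh.write(
                f"{bset.chrom}\t{start}\t{start + bin_size}\t"
                f"eta={eta:.6g}\t{bset.alpha:g}\n"
            )


def write_domains_bed(hierarchy, bin_size: int, path: str | Path) -> None:
    """Domain intervals of every hierarchy level, sorted by level then start.

    Column 4 carries the alpha of the level the domain belongs to.
    """
    with Path(path).open("w") as fh:
        for level in hierarchy.levels:
            for start_bin, end_bin in level.domains:
                fh.write(
                    f"{hierarchy.chrom}\t{start_bin * bin_size}\t"
                    f"{end_bin * bin_size}\t{level.alpha:g}\n"
                )
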