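"""Genomic interval sets with a declared coordinate convention.

All intervals are stored half-open 0-based internally regardless of the
input dialect; BED input is consumed as-is (already 0-based half-open),
1-based inclusive input is converted on construction. Chromosome names are
normalized through a small alias map ("chrX" -> "X", "23" -> "X") so mixed
inputs compose.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = ["GenomicIntervalSet", "normalize_chrom", "PAR_HG19"]

# hg19/GRCh37 pseudoautosomal regions on X, 1-based inclusive as published.
PAR_HG19 = (("X", 60_001, 2_699_520), ("X", 154_931_044, 155_260_560))

_ALIASES = {"chrx": "X", "x": "X", "23": "X", "chr23": "X"}


def normalize_chrom(chrom: str) -> str:
    """Map chromosome aliases onto the internal name ("chrX" -> "X")."""
    c = chrom.strip()
    c = _ALIASES.get(c.lower(), c)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclasses.dataclass
class GenomicIntervalSet:
    """Named intervals on one or more chromosomes, 0-based half-open.

    ``role`` tags the set's purpose: ``coding``, ``PAR``, ``escape_genes``,
    ``editing_sites`` or ``gene_map``. Gene maps carry a name per interval.
    """

    role: str
    _trees: dict[str, IntervalTree] = dataclasses.field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, name: str | None = None) -> None:
        if start >= end:
            raise ValueError(f"interval start must be < end: {chrom}:{start}-{end}")
        self._trees.setdefault(normalize_chrom(chrom), IntervalTree()).addi(
            start, end, name
        )

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple],
        role: str,
        one_based: bool = False,
    ) -> "GenomicIntervalSet":
        """Build from (chrom, start, end[, name]) tuples.

        With ``one_based=True`` the input is 1-based inclusive and is
        converted to 0-based half-open.
        """
        out = cls(role=role)
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            name = iv[3] if len(iv) > 3 else None
            if one_based:
                start -= 1
            out.add(chrom, start, end, name)
        return out

    @classmethod
    def from_bed(cls, path: str | Path, role: str) -> "GenomicIntervalSet":
        """Read BED3/BED6 (0-based half-open; column 4 is the name)."""
        out = cls(role=role)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
                start, end = int(fields[1]), int(fields[2])
                if start >= end:
                    raise ValueError(
                        f"{path}:{lineno}: BED start {start} >= end {end}"
                    )
                name = fields[3] if len(fields) > 3 else None
                out.add(fields[0], start, end, name)
        return out

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self._trees.get(normalize_chrom(chrom))
        return bool(tree and tree.overlaps(pos - 1))

    def names_at(self, chrom: str, pos: int) -> list[str]:
        """Names of intervals containing the 1-based position, sorted by
        (start, end, name) for deterministic overlap resolution."""
        tree = self._trees.get(normalize_chrom(chrom))
        if not tree:
            return []
        hits = sorted(tree[pos - 1], key=lambda iv: (iv.begin, iv.end, iv.data or ""))
        return [iv.data for iv in hits if iv.data is not None]

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __iter__(self) -> Iterator[tuple[str, int, int, str | None]]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield chrom, iv.begin, iv.end, iv.data

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, name in self:
                if name is None:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
                else:
                    fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def default_par_intervals() -> GenomicIntervalSet:
    """hg19 PAR1 + PAR2 on X as a ready-made exclusion set."""
    return GenomicIntervalSet.from_intervals(PAR_HG19, role="PAR", one_based=True)
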