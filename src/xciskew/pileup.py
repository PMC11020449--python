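"""samtools-mpileup text parsing and per-site allele counting.

The pileup base string is tokenized read by read: ``.``/``,`` are reference
matches, letters are mismatches, ``^X`` marks a read start (the following
character is the mapping quality, not a base), ``$`` a read end, ``+N<seq>``
and ``-N<seq>`` insertions/deletions attached to the preceding base, ``*``
(or ``#``) a deletion placeholder and ``>``/``<`` reference skips. Exactly
one base-quality character accompanies each counted column symbol.

Mapping-quality filtering is the pileup producer's job (``samtools mpileup
-q 20``); this parser enforces only the base-quality floor.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator

from .intervals import normalize_chrom
from .sites import CvacRecord, HetSite

__all__ = ["PileupParseError", "parse_pileup_bases", "count_alleles_from_mpileup",
           "count_alleles_for_sites"]

_COLUMN_CHARS = set(".,ACGTNacgtn*#><")


class PileupParseError(ValueError):
    """Malformed pileup base/quality string."""


@dataclasses.dataclass(frozen=True)
class _BaseCall:
    symbol: str  # the column character as written ('.', ',', 'T', 't', '*', ...)
    qual: int  # phred base quality
    indel: tuple[str, str] | None = None  # ('+'|'-', uppercased sequence)


def parse_pileup_bases(bases: str, quals: str, line_no: int = 0) -> list[_BaseCall]:
    """Tokenize one pileup base string against its quality string."""
    calls: list[_BaseCall] = []
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(f"line {line_no}: dangling '^'")
            i += 2  # skip mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"line {line_no}: '{c}' without length")
            length = int(bases[i + 1 : j])
            seq = bases[j : j + length]
            if len(seq) < length:
                raise PileupParseError(f"line {line_no}: truncated indel sequence")
            if not calls:
                raise PileupParseError(f"line {line_no}: indel with no preceding base")
            prev = calls[-1]
            calls[-1] = _BaseCall(prev.symbol, prev.qual, (c, seq.upper()))
            i = j + length
            continue
        if c in _COLUMN_CHARS:
            if qi >= len(quals):
                raise PileupParseError(
                    f"line {line_no}: base string longer than quality string"
                )
            calls.append(_BaseCall(c, ord(quals[qi]) - 33))
            qi += 1
            i += 1
            continue
        raise PileupParseError(f"line {line_no}: unexpected pileup character {c!r}")
    if qi != len(quals):
        raise PileupParseError(
            f"line {line_no}: {len(quals) - qi} unconsumed quality characters"
        )
    return calls


def _is_ref_match(call: _BaseCall, ref_base: str) -> bool:
    return call.symbol in ".," or call.symbol.upper() == ref_base.upper()


def count_alleles_from_mpileup(
    mpileup_line: str,
    site: HetSite,
    min_baseq: int = 30,
    sample_id: str = "sample",
    line_no: int = 0,
) -> CvacRecord:
    """Count reference and alternate RNA reads for one site from one
    mpileup line (6-column text format).

    SNV alleles are counted from column symbols; 1-bp indel alleles are
    counted from ``+1X``/``-1X`` tokens attached to a reference-matching
    base (the anchor), whose quality gates the call. ``N``, deletion
    placeholders and reference skips count toward neither allele.
    """
    fields = mpileup_line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise PileupParseError(f"line {line_no}: expected 6 mpileup columns")
    chrom, pos_s, ref_base, _depth, bases, quals = fields[:6]
    if normalize_chrom(chrom) != normalize_chrom(site.chrom) or int(pos_s) != site.pos:
        raise ValueError(
            f"mpileup line {chrom}:{pos_s} does not match site "
            f"{site.chrom}:{site.pos}"
        )
    calls = parse_pileup_bases(bases, quals, line_no=line_no)

    ref, alt = site.ref_allele, site.alt_allele
    ref_count = 0
    alt_count = 0
    if len(ref) == 1 and len(alt) == 1:  # SNV
        for call in calls:
            if call.qual < min_baseq:
                continue
            if _is_ref_match(call, ref):
                ref_count += 1
            elif call.symbol.upper() == alt.upper():
                alt_count += 1
    else:  # 1-bp indel: ref C / alt CA (insertion) or ref CA / alt C (deletion)
        if len(alt) > len(ref):
            want = ("+", alt[1:].upper())
        else:
            want = ("-", ref[1:].upper())
        for call in calls:
            if call.qual < min_baseq or not _is_ref_match(call, ref[0]):
                continue
            if call.indel == want:
                alt_count += 1
            elif call.indel is None:
                ref_count += 1
    return CvacRecord(
        sample_id=sample_id,
        chrom=normalize_chrom(chrom),
        pos=site.pos,
        ref_allele=ref,
        alt_allele=alt,
        ref_count=ref_count,
        alt_count=alt_count,
    )


def count_alleles_for_sites(
    mpileup_lines: Iterable[str],
    sites: list[HetSite],
    min_baseq: int = 30,
    sample_id: str = "sample",
) -> Iterator[CvacRecord]:
    """Stream a whole mpileup file against a site list (matched on
    chrom:pos); sites with no pileup line yield zero counts."""
    by_pos = {(normalize_chrom(s.chrom), s.pos): s for s in sites}
    seen: set[tuple[str, int]] = set()
    for line_no, line in enumerate(mpileup_lines, 1):
        if not line.strip():
            continue
        fields = line.split("\t", 2)
        key = (normalize_chrom(fields[0]), int(fields[1]))
        site = by_pos.get(key)
        if site is None:
            continue
        seen.add(key)
        yield count_alleles_from_mpileup(
            line, site, min_baseq=min_baseq, sample_id=sample_id, line_no=line_no
        )
    for key, site in by_pos.items():
        if key not in seen:
            yield CvacRecord(
                sample_id=sample_id,
                chrom=site.chrom,
                pos=site.pos,
                ref_allele=site.ref_allele,
                alt_allele=site.alt_allele,
                ref_count=0,
                alt_count=0,
            )
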