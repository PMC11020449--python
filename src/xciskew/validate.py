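"""Pre-flight validation of input files (format well-formedness, coordinate
dialects, chromosome-name consistency)."""

from __future__ import annotations

from pathlib import Path

from .intervals import normalize_chrom

__all__ = ["validate_inputs", "ValidationReport"]


class ValidationReport:
    def __init__(self) -> None:
        self.errors: list[str] = []
        self.warnings: list[str] = []

    @property
    def ok(self) -> bool:
        return not self.errors


def _check_bed(path: Path, report: ValidationReport) -> None:
    chroms: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                report.errors.append(f"{path}:{lineno}: BED line has <3 columns")
                continue
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                report.errors.append(f"{path}:{lineno}: non-integer BED coordinates")
                continue
            if start >= end:
                report.errors.append(f"{path}:{lineno}: start {start} >= end {end}")
            chroms.add(f[0])
    if len({normalize_chrom(c) for c in chroms}) < len(chroms):
        report.warnings.append(
            f"{path}: mixed chromosome naming ({sorted(chroms)}); normalized to 'X'"
        )


def _check_cvac(path: Path, report: ValidationReport) -> None:
    from .sites import CVAC_COLUMNS

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CVAC_COLUMNS:
            report.errors.append(f"{path}: bad CVAC header {header}")
            return
        for lineno, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(CVAC_COLUMNS):
                report.errors.append(f"{path}:{lineno}: wrong column count")
                continue
            try:
                rc, ac = int(f[5]), int(f[6])
            except ValueError:
                report.errors.append(f"{path}:{lineno}: non-integer counts")
                continue
            if rc < 0 or ac < 0:
                report.errors.append(f"{path}:{lineno}: negative allele count")


def _check_vcf(path: Path, report: ValidationReport) -> None:
    import pysam

    try:
        with pysam.VariantFile(str(path)) as vf:
            for i, _rec in enumerate(vf):
                if i >= 100:
                    break
    except (OSError, ValueError) as exc:
        report.errors.append(f"{path}: unreadable VCF ({exc})")


def _check_mpileup(path: Path, report: ValidationReport) -> None:
    from .pileup import PileupParseError, parse_pileup_bases

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                report.errors.append(f"{path}:{lineno}: <6 mpileup columns")
                continue
            try:
                parse_pileup_bases(f[4], f[5], line_no=lineno)
            except PileupParseError as exc:
                report.errors.append(str(exc))


_CHECKERS = {
    "bed": _check_bed,
    "cvac": _check_cvac,
    "vcf": _check_vcf,
    "mpileup": _check_mpileup,
}


def validate_inputs(paths: dict[str, str | Path]) -> ValidationReport:
    """Validate a mapping of declared format -> path.

    Keys are ``vcf``, ``bed``, ``cvac``, ``mpileup`` (optionally suffixed,
    e.g. ``bed:par``). Unknown formats are reported as errors.
    """
    report = ValidationReport()
    for declared, path in paths.items():
        fmt = declared.split(":", 1)[0]
        checker = _CHECKERS.get(fmt)
        p = Path(path)
        if checker is None:
            report.errors.append(f"unknown declared format {declared!r}")
            continue
        if not p.exists():
            report.errors.append(f"{p}: file not found")
            continue
        checker(p, report)
    return report
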