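"""Readers and writers for the pipeline's file formats.

Three formats are handled, each with its native coordinate convention:

* VCF v4.x — variant sites, 1-based positions.  Genotypes come from the
  ``GT`` FORMAT subfield; a per-variant quality score and an externally
  computed Mendelian-error count are read from configurable INFO keys
  (defaults ``SVM`` and ``MIE``), since INFO layouts are caller-specific.
* PED — 6-column pedigree; ``0`` marks an unknown (founder) parent.
* BED-like repeat track — 0-based half-open intervals with optional
  repeat class / name columns (RepeatMasker-style annotation).

Conversion between the 1-based VCF world and the 0-based BED world
happens only inside overlap queries, never at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from ._utils import open_text

Genotype = tuple[int, int]  # pair of allele indices, 0 = REF

MISSING = None  # sentinel for a missing genotype
FOUNDER_MARKER = "0"


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One VCF site with the annotations the QC pipeline consumes."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: list[str]
    filter_status: set[str]
    svm_score: float | None
    info_mie: int | None
    genotypes: list[Genotype | None]
    vcf_id: str = "."
    qual: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if not self.alt_alleles:
            raise FormatError("ALT must list at least one allele")
        if self.info_mie is not None and self.info_mie < 0:
            raise FormatError(f"MIE count must be >= 0, got {self.info_mie}")
        n_alt = len(self.alt_alleles)
        for gt in self.genotypes:
            if gt is not None and max(gt) > n_alt:
                raise FormatError(
                    f"allele index {max(gt)} exceeds ALT count {n_alt} at "
                    f"{self.chrom}:{self.pos}"
                )

    @property
    def is_binary(self) -> bool:
        """True for biallelic sites (exactly one alternative allele)."""
        return len(self.alt_alleles) == 1

    @property
    def passes_filters(self) -> bool:
        return self.filter_status == {"PASS"}

    def alt_dosage(self, sample_index: int) -> int | None:
        """Alt-allele count in {0,1,2} for biallelic sites, None if missing."""
        gt = self.genotypes[sample_index]
        if gt is None:
            return None
        return gt[0] + gt[1]


def _parse_genotype(token: str, line_number: int) -> Genotype | None:
    # Only the GT subfield matters; phase ("|") is discarded.  Half-missing
    # calls such as "0/." are treated as fully missing — partial transmission
    # evidence is not fabricated.
    gt_field = token.split(":", 1)[0]
    if gt_field in (".", "./.", ".|."):
        return None
    sep = "|" if "|" in gt_field else "/"
    parts = gt_field.split(sep)
    if len(parts) != 2:
        raise FormatError(f"malformed genotype field {token!r}", line_number)
    if "." in parts:
        return None
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError:
        raise FormatError(f"malformed genotype field {token!r}", line_number)
    if a < 0 or b < 0:
        raise FormatError(f"negative allele index in {token!r}", line_number)
    return (a, b)


def _parse_info(info: str) -> dict[str, str | bool]:
    out: dict[str, str | bool] = {}
    if info == ".":
        return out
    for item in info.split(";"):
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            out[key] = value
        else:
            out[item] = True
    return out


def read_vcf(
    path: str | Path,
    required_info_keys: Sequence[str] = (),
    svm_key: str = "SVM",
    mie_key: str = "MIE",
    sort: bool = False,
) -> tuple[list[VariantRecord], list[str]]:
    """Read a multi-sample VCF into :class:`VariantRecord` objects.

    Parameters
    ----------
    path : file path, plain or ``.gz``.
    required_info_keys : INFO keys that must be present on every record;
        a record missing one raises :class:`FormatError` with its line number.
    svm_key, mie_key : INFO keys holding the per-variant quality score and
        the externally computed Mendelian-error count.
    sort : if True, records are sorted by (chrom, pos); if False, unsorted
        input is a fatal error.

    Returns
    -------
    (records, samples) : the variant records in positional order and the
        sample names from the ``#CHROM`` header line.
    """
    samples: list[str] | None = None
    records: list[VariantRecord] = []
    with open_text(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                samples = cols[9:] if len(cols) > 9 else []
                continue
            if samples is None:
                raise FormatError("data line before #CHROM header", line_number)
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"expected >= 8 columns, found {len(fields)}", line_number
                )
            chrom, pos_s, vcf_id, ref, alt, qual, filt, info = fields[:8]
            gt_tokens = fields[9:] if len(fields) > 9 else []
            if len(gt_tokens) != len(samples):
                raise FormatError(
                    f"{len(samples)} samples declared but {len(gt_tokens)} "
                    "genotype columns found",
                    line_number,
                )
            info_map = _parse_info(info)
            for key in required_info_keys:
                if key not in info_map:
                    raise FormatError(
                        f"required INFO key {key!r} absent", line_number
                    )
            svm = info_map.get(svm_key)
            mie = info_map.get(mie_key)
            filter_status = (
                {"PASS"} if filt in ("PASS", ".") else set(filt.split(";"))
            )
            try:
                record = VariantRecord(
                    chrom=chrom,
                    pos=int(pos_s),
                    ref_allele=ref,
                    alt_alleles=alt.split(","),
                    filter_status=filter_status,
                    svm_score=float(svm) if svm is not None else None,
                    info_mie=int(mie) if mie is not None else None,
                    genotypes=[
                        _parse_genotype(tok, line_number) for tok in gt_tokens
                    ],
                    vcf_id=vcf_id,
                    qual=qual,
                )
            except FormatError as exc:
                if exc.line_number is None:
                    raise FormatError(str(exc), line_number) from None
                raise
            records.append(record)
    if samples is None:
        raise FormatError("no #CHROM header line found")
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        if sort:
            records.sort(key=lambda r: (r.chrom, r.pos))
        else:
            raise FormatError(
                "records are not sorted by (chrom, pos); pass sort=True"
            )
    return records, samples


def write_vcf(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    svm_key: str = "SVM",
    mie_key: str = "MIE",
) -> None:
    """Write records back out as VCF v4.2 (round-trips with :func:`read_vcf`)."""
    filters_seen: set[str] = set()
    records = list(records)
    for r in records:
        filters_seen |= r.filter_status - {"PASS"}
    with open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID={svm_key},Number=1,Type=Float,'
            'Description="Variant quality score (higher = more confident)">\n'
        )
        fh.write(
            f'##INFO=<ID={mie_key},Number=1,Type=Integer,'
            'Description="Externally computed Mendelian inheritance error count">\n'
        )
        for name in sorted(filters_seen):
            fh.write(f'##FILTER=<ID={name},Description="{name} filter">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            header.append("FORMAT")
            header.extend(samples)
        fh.write("\t".join(header) + "\n")
        for r in records:
            info_parts = []
            if r.svm_score is not None:
                info_parts.append(f"{svm_key}={r.svm_score:g}")
            if r.info_mie is not None:
                info_parts.append(f"{mie_key}={r.info_mie}")
            info = ";".join(info_parts) if info_parts else "."
            filt = (
                "PASS"
                if r.filter_status == {"PASS"}
                else ";".join(sorted(r.filter_status))
            )
            row = [
                r.chrom,
                str(r.pos),
                r.vcf_id,
                r.ref_allele,
                ",".join(r.alt_alleles),
                r.qual,
                filt,
                info,
            ]
            if samples:
                row.append("GT")
                row.extend(
                    "./." if gt is None else f"{gt[0]}/{gt[1]}"
                    for gt in r.genotypes
                )
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

@dataclass
class PedigreeIndividual:
    family_id: str
    individual_id: str
    father_id: str | None  # None = founder (PED "0")
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    sample_column: int | None = None  # index into VCF sample order

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


_SEX_CODES = {"1": "male", "2": "female"}


def read_ped(path: str | Path) -> list[PedigreeIndividual]:
    """Read a 6+-column whitespace-delimited PED file.

    Individuals absent from any VCF are retained (``sample_column`` stays
    None); they still contribute pedigree structure.  Duplicated ids,
    references to never-defined parents, and ancestry cycles are fatal.
    """
    individuals: list[PedigreeIndividual] = []
    seen: set[tuple[str, str]] = set()
    with open_text(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise FormatError(
                    f"expected >= 6 columns, found {len(cols)}", line_number
                )
            fam, iid, fid, mid, sex = cols[:5]
            key = (fam, iid)
            if key in seen:
                raise FormatError(
                    f"duplicate individual {iid!r} in family {fam!r}",
                    line_number,
                )
            seen.add(key)
            individuals.append(
                PedigreeIndividual(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if fid == FOUNDER_MARKER else fid,
                    mother_id=None if mid == FOUNDER_MARKER else mid,
                    sex=_SEX_CODES.get(sex, "unknown"),
                )
            )
    _validate_pedigree(individuals)
    return individuals


def _validate_pedigree(individuals: list[PedigreeIndividual]) -> None:
    by_key = {(p.family_id, p.individual_id): p for p in individuals}
    for p in individuals:
        for parent_id in (p.father_id, p.mother_id):
            if parent_id is not None and (p.family_id, parent_id) not in by_key:
                raise FormatError(
                    f"parent {parent_id!r} of {p.individual_id!r} "
                    f"(family {p.family_id!r}) is never defined"
                )
    # cycle check via iterative DFS over the child -> parent graph
    WHITE, GREY, BLACK = 0, 1, 2
    color = {k: WHITE for k in by_key}
    for start in by_key:
        if color[start] != WHITE:
            continue
        stack: list[tuple[tuple[str, str], bool]] = [(start, False)]
        while stack:
            node, done = stack.pop()
            if done:
                color[node] = BLACK
                continue
            if color[node] == GREY:
                raise FormatError(
                    f"pedigree cycle involving {node[1]!r} in family {node[0]!r}"
                )
            if color[node] == BLACK:
                continue
            color[node] = GREY
            stack.append((node, True))
            p = by_key[node]
            for parent_id in (p.father_id, p.mother_id):
                if parent_id is not None:
                    parent_key = (p.family_id, parent_id)
                    if color[parent_key] == GREY:
                        raise FormatError(
                            f"pedigree cycle involving {parent_id!r} "
                            f"in family {p.family_id!r}"
                        )
                    if color[parent_key] == WHITE:
                        stack.append((parent_key, False))
    for p in individuals:
        if p.father_id == p.individual_id or p.mother_id == p.individual_id:
            raise FormatError(
                f"{p.individual_id!r} listed as its own parent"
            )


def assign_sample_columns(
    individuals: list[PedigreeIndividual], samples: Sequence[str]
) -> list[PedigreeIndividual]:
    """Attach VCF sample-column indices in place by matching individual ids."""
    index = {name: i for i, name in enumerate(samples)}
    for p in individuals:
        p.sample_column = index.get(p.individual_id)
    return individuals


def write_ped(individuals: Iterable[PedigreeIndividual], path: str | Path) -> None:
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    with open_text(path, "wt") as fh:
        for p in individuals:
            fh.write(
                "\t".join(
                    [
                        p.family_id,
                        p.individual_id,
                        p.father_id or FOUNDER_MARKER,
                        p.mother_id or FOUNDER_MARKER,
                        sex_out[p.sex],
                        "0",  # phenotype unused by the QC pipeline
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Repeat track (BED-like)
# ---------------------------------------------------------------------------

def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so '3' and 'chr3' compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class RepeatTrack:
    """Interval annotation of repetitive elements (0-based half-open)."""

    intervals: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, start, end, _cls, _name in self.intervals:
            if start >= end:
                raise FormatError(
                    f"interval start {start} >= end {end} on {chrom}"
                )
        self._trees = {}
        for chrom, start, end, _cls, _name in self.intervals:
            self._trees.setdefault(normalize_chrom(chrom), IntervalTree()).addi(
                start, end
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Does any interval cover the 1-based position ``pos``?

        A variant at 1-based pos p overlaps [s, e) iff s <= p-1 < e.
        """
        tree = self._trees.get(normalize_chrom(chrom))
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def merged_intervals(
        self, chrom: str | None = None
    ) -> list[tuple[str, int, int]]:
        """Union of intervals (overlaps and abutments merged), sorted."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, start, end, _cls, _name in self.intervals:
            c = normalize_chrom(c)
            if chrom is not None and c != normalize_chrom(chrom):
                continue
            by_chrom.setdefault(c, []).append((start, end))
        merged: list[tuple[str, int, int]] = []
        for c in sorted(by_chrom):
            merged.extend((c, s, e) for s, e in merge_intervals(by_chrom[c]))
        return merged

    def total_covered_bases(self, chrom: str | None = None) -> int:
        return sum(e - s for _c, s, e in self.merged_intervals(chrom))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting half-open intervals."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_repeat_track(path: str | Path) -> RepeatTrack:
    """Read a BED3+ repeat track; columns 4/5 are repeat class and name."""
    intervals: list[tuple[str, int, int, str, str]] = []
    with open_text(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"expected >= 3 columns, found {len(cols)}", line_number
                )
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise FormatError("non-integer coordinates", line_number)
            if start >= end:
                raise FormatError(
                    f"start {start} >= end {end}", line_number
                )
            repeat_class = cols[3] if len(cols) > 3 and cols[3] else "other"
            repeat_name = cols[4] if len(cols) > 4 and cols[4] else "."
            intervals.append((chrom, start, end, repeat_class, repeat_name))
    return RepeatTrack(intervals=intervals)


def write_repeat_track(track: RepeatTrack, path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        for chrom, start, end, cls, name in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{cls}\t{name}\n")
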