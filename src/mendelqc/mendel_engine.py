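"""Single-locus Mendelian inheritance error (MIE) detection.

An arbitrary multi-generation pedigree is dissected into nuclear families
(one parent-pair, or single known parent, plus their shared children) and
each child's genotype is checked against its parents' genotypes one locus
at a time, ignoring haplotypes and recombination — the classic fast
approach to pedigree genotype QC.  The engine is defined for biallelic
autosomal variants only; multi-allelic sites must be excluded upstream.

An externally computed MIE count (e.g. from an extended-pedigree,
haplotype-aware caller, carried in VCF INFO) is never recomputed here; it
is copied through as an alternative detection source so downstream
statistics can be run against either column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import PedigreeIndividual, VariantRecord

TrioVerdict = Literal["consistent", "error", "unchecked"]

# Genotypes are alt-allele dosages {0, 1, 2}; 3 encodes "missing" in the
# vectorized lookup table.
_MISSING_CODE = 3


@dataclass
class NuclearFamily:
    """One parent-pair (or single known parent) with their shared children.

    ``father``/``mother`` and each child are VCF sample-column indices;
    a parent may be None (unknown) or have index None (known individual
    but not genotyped), both of which check as a missing genotype.
    """

    family_id: str
    father: int | None
    mother: int | None
    children: list[int]
    father_id: str | None = None
    mother_id: str | None = None
    child_ids: list[str] = field(default_factory=list)


def extract_nuclear_families(
    pedigree: Sequence[PedigreeIndividual],
) -> list[NuclearFamily]:
    """Dissect a pedigree into nuclear families.

    Children sharing the same (father, mother) pair — including pairs with
    one unknown parent — form one nuclear family.  An individual may be a
    child in one family and a parent in another.  Families in which no
    member is genotyped (no VCF sample column) are dropped, as are children
    whose known parents are all ungenotyped *and* who are ungenotyped
    themselves only when nobody in the family carries genotypes.
    """
    by_key = {(p.family_id, p.individual_id): p for p in pedigree}
    groups: dict[tuple[str, str | None, str | None], list[PedigreeIndividual]] = {}
    for p in pedigree:
        if p.is_founder:
            continue
        groups.setdefault((p.family_id, p.father_id, p.mother_id), []).append(p)

    families: list[NuclearFamily] = []
    for (fam, father_id, mother_id), children in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1] or "", kv[0][2] or "")
    ):
        father = by_key.get((fam, father_id)) if father_id else None
        mother = by_key.get((fam, mother_id)) if mother_id else None
        columns = [
            p.sample_column
            for p in ((father, mother) + tuple(children))
            if p is not None and p.sample_column is not None
        ]
        if not columns:
            continue
        families.append(
            NuclearFamily(
                family_id=fam,
                father=father.sample_column if father else None,
                mother=mother.sample_column if mother else None,
                children=[c.sample_column for c in children],
                father_id=father_id,
                mother_id=mother_id,
                child_ids=[c.individual_id for c in children],
            )
        )
    return families


def check_trio(
    father_gt: int | None,
    mother_gt: int | None,
    child_gt: int | None,
    duo_checking: bool = True,
) -> TrioVerdict:
    """Classify one (father, mother, child) genotype triple at a biallelic site.

    Genotypes are alt-allele dosages in {0, 1, 2} or None (missing).

    * both parents known  — "error" iff the child cannot receive one gamete
      from each parent (e.g. parents 0/0 but child carries an alt allele);
    * one parent known    — with ``duo_checking``, "error" iff parent and
      child are opposite homozygotes (the child is homozygous for the allele
      the known parent entirely lacks); otherwise "unchecked";
    * child missing, or both parents missing — "unchecked".
    """
    for g in (father_gt, mother_gt, child_gt):
        if g is not None and g not in (0, 1, 2):
            raise ValueError(
                f"genotype dosage must be in {{0,1,2}} or None, got {g!r}"
            )
    if child_gt is None:
        return "unchecked"
    if father_gt is None and mother_gt is None:
        return "unchecked"
    if father_gt is None or mother_gt is None:
        if not duo_checking:
            return "unchecked"
        parent = father_gt if father_gt is not None else mother_gt
        if (parent, child_gt) in ((0, 2), (2, 0)):
            return "error"
        return "consistent"
    # both parents present: child dosage must be the sum of one gamete per
    # parent; gametes from dosage g are {0} (g=0), {0,1} (g=1), {1} (g=2)
    gametes = ({0}, {0, 1}, {1})
    possible = {
        a + b for a in gametes[father_gt] for b in gametes[mother_gt]
    }
    return "consistent" if child_gt in possible else "error"


def _verdict_table(duo_checking: bool) -> np.ndarray:
    """4x4x4 lookup of check_trio verdicts; axis order (father, mother, child).

    Encodes 0/1/2 dosage and 3 = missing; values 0=consistent, 1=error,
    2=unchecked.
    """
    codes = {"consistent": 0, "error": 1, "unchecked": 2}
    table = np.empty((4, 4, 4), dtype=np.int8)
    dec = [0, 1, 2, None]
    for fi, f in enumerate(dec):
        for mi, m in enumerate(dec):
            for ci, c in enumerate(dec):
                table[fi, mi, ci] = codes[check_trio(f, m, c, duo_checking)]
    return table


@dataclass
class MieTable:
    """Per-variant Mendelian-error counts by detection source.

    ``native_mie`` counts (family, child) pairs this engine flags;
    ``external_mie`` is the count carried in VCF INFO (NaN when absent).
    ``details`` (optional) lists every flagged (variant, family, child).
    """

    variant_index: np.ndarray  # indices into the variant list checked
    native_mie: np.ndarray  # int, per variant
    external_mie: np.ndarray  # float with NaN for absent
    n_checked: np.ndarray  # (family, child) pairs with a definite verdict
    details: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.variant_index)

    def counts(self, source: str) -> np.ndarray:
        """Per-variant counts for ``source`` in {"native", "external"}.

        Absent external counts are treated as zero errors.
        """
        if source == "native":
            return self.native_mie.astype(np.int64)
        if source == "external":
            ext = self.external_mie.copy()
            ext[np.isnan(ext)] = 0
            return ext.astype(np.int64)
        raise ValueError(f"unknown MIE source {source!r}")

    def to_frame(self, variants: Sequence[VariantRecord]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [variants[i].chrom for i in self.variant_index],
                "pos": [variants[i].pos for i in self.variant_index],
                "native_mie": self.native_mie,
                "external_mie": self.external_mie,
                "n_checked": self.n_checked,
            }
        )

    def write_tsv(self, variants: Sequence[VariantRecord], path: str | Path) -> None:
        self.to_frame(variants).to_csv(path, sep="\t", index=False)


def count_mies(
    variants: Sequence[VariantRecord],
    families: Iterable[NuclearFamily],
    duo_checking: bool = True,
    per_family_cap: bool = False,
    keep_details: bool = False,
) -> MieTable:
    """Count single-locus Mendelian errors at every biallelic variant.

    The counting unit is the (family, child) pair: each inconsistent child
    adds one error, so a variant's count can exceed the number of families.
    ``per_family_cap`` caps each family's contribution at one error per
    variant (stricter semantics some tools use).

    Raises ``ValueError`` on multi-allelic input — the engine is defined for
    binary variants only.
    """
    variants = list(variants)
    families = list(families)
    for v in variants:
        if not v.is_binary:
            raise ValueError(
                f"multi-allelic variant at {v.chrom}:{v.pos}; the Mendel "
                "engine handles biallelic sites only (filter first)"
            )
    n_var = len(variants)
    n_samples = len(variants[0].genotypes) if variants else 0

    # dosage matrix (variants x samples), 3 = missing
    dosage = np.full((n_var, n_samples), _MISSING_CODE, dtype=np.int8)
    for i, v in enumerate(variants):
        for j, gt in enumerate(v.genotypes):
            if gt is not None:
                dosage[i, j] = gt[0] + gt[1]

    table = _verdict_table(duo_checking)
    native = np.zeros(n_var, dtype=np.int64)
    checked = np.zeros(n_var, dtype=np.int64)
    detail_rows: list[tuple[int, str, str]] = []

    missing_col = np.full(n_var, _MISSING_CODE, dtype=np.int8)
    for fam in families:
        f_dos = dosage[:, fam.father] if fam.father is not None else missing_col
        m_dos = dosage[:, fam.mother] if fam.mother is not None else missing_col
        fam_err = np.zeros(n_var, dtype=bool)
        for child_idx, child in enumerate(fam.children):
            c_dos = dosage[:, child] if child is not None else missing_col
            verdict = table[f_dos, m_dos, c_dos]
            err = verdict == 1
            checked += verdict != 2
            if per_family_cap:
                fam_err |= err
            else:
                native += err
            if keep_details and err.any():
                child_id = (
                    fam.child_ids[child_idx]
                    if fam.child_ids
                    else str(child)
                )
                detail_rows.extend(
                    (int(i), fam.family_id, child_id) for i in np.nonzero(err)[0]
                )
        if per_family_cap:
            native += fam_err

    external = np.array(
        [np.nan if v.info_mie is None else float(v.info_mie) for v in variants]
    )
    details = None
    if keep_details:
        details = pd.DataFrame(
            detail_rows, columns=["variant_index", "family_id", "child_id"]
        )
    return MieTable(
        variant_index=np.arange(n_var),
        native_mie=native,
        external_mie=external,
        n_checked=checked,
        details=details,
    )
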