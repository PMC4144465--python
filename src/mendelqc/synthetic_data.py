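"""Pedigree-structured genotype simulator with injected genotyping errors.

The generator emulates the data regime the QC pipeline expects from a
family-based WGS call set, without any external download:

* nuclear families (trio / quartet / three-generation shapes);
* biallelic SNVs at Hardy-Weinberg founder frequencies drawn from a Beta
  distribution, children receiving one uniformly random allele per parent;
* a small fraction of multi-allelic sites with a grossly elevated error
  rate (multi-allelic calls are error-prone in real callers);
* genotyping errors injected as uniform flips to a random different
  genotype, at a base rate everywhere, an elevated rate inside repeat
  intervals, and a strongly elevated rate inside a few planted "peak"
  regions (which are themselves repeat-dense) — giving the pipeline
  spatial clustering and repeat enrichment to recover;
* a per-variant SVM-like quality score anticorrelated with error status,
  plus caller-style FILTER flags (negative score -> SVM; a small random
  subset -> INDEL5) and an external MIE count in INFO emulating an
  extended-pedigree error caller that sees more errors than single-locus
  trio checking.

A truth table records every injected error and, per variant, whether the
injected errors create a single-locus Mendelian inconsistency (the
"obligate" indicator, computed here by direct gamete enumeration so it is
independent of the detection engine under test).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    PedigreeIndividual,
    RepeatTrack,
    VariantRecord,
    write_ped,
    write_repeat_track,
    write_vcf,
)

FamilyShape = Literal["trio", "quartet", "three_generation"]


@dataclass
class SimulationConfig:
    """Parameters of one simulated family-based call set.

    Defaults describe the standard scenario used throughout the test
    suite: 30 trios, 100,000 variants (100 bins of 1000) on a 30 Mb
    chromosome, a background error rate giving ~0.04 detected errors per
    variant, a 10x elevated rate inside repeats, three planted
    high-error peak regions each spanning about one bin, and a quality
    score separated by ~2.7 SD between errored and clean variants.
    """

    seed: int = 0
    n_families: int = 30
    family_shape: FamilyShape = "trio"
    n_variants: int = 100_000
    chrom: str = "3"
    chrom_length: int = 30_000_000
    # alt-allele frequency ~ Beta(a, b); skewed toward rare alternates
    allele_freq_alpha: float = 0.8
    allele_freq_beta: float = 2.0
    base_error_rate: float = 0.001  # per-genotype flip probability outside repeats
    repeat_error_rate: float = 0.01  # inside repeat intervals
    peak_error_rate: float = 0.08  # inside planted peak regions
    repeat_fraction: float = 0.30  # target genome fraction covered by repeats
    n_repeat_intervals: int = 600
    # repeat density varies regionally (as in real genomes): interval
    # placement is weighted by per-block Dirichlet weights; a smaller
    # concentration gives stronger regional clumping
    repeat_density_blocks: int = 20
    repeat_density_concentration: float = 1.0
    n_peak_regions: int = 3
    peak_width: int = 300_000  # bp; about one 1000-variant bin by default
    peak_repeat_boost: float = 0.7  # repeat coverage inside peak regions
    # SVM-like score: clean variants ~ N(mu_clean, sd), errored ~ N(mu_err, sd)
    svm_mu_clean: float = 5.0
    svm_mu_err: float = 1.0
    svm_sd: float = 1.5
    multiallelic_fraction: float = 0.002
    indel5_fraction: float = 0.01
    # external (extended-pedigree style) caller: per injected error,
    # probability it is flagged in the INFO MIE count
    external_detection_rate: float = 0.9

    def __post_init__(self) -> None:
        if self.n_variants <= 0 or self.n_families <= 0:
            raise ValueError("n_variants and n_families must be positive")
        if not 0 <= self.base_error_rate <= self.repeat_error_rate <= 1:
            raise ValueError(
                "need 0 <= base_error_rate <= repeat_error_rate <= 1"
            )
        if self.n_peak_regions * self.peak_width > self.chrom_length:
            raise ValueError("peak regions exceed chromosome length")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimulationResult:
    variants: list[VariantRecord]
    samples: list[str]
    pedigree: list[PedigreeIndividual]
    repeat_track: RepeatTrack
    truth: pd.DataFrame  # per-variant ground truth
    peak_regions: list[tuple[int, int]]  # 0-based half-open, bp
    config: SimulationConfig

    def write(self, out_prefix: str | Path) -> dict[str, Path]:
        """Write VCF / PED / BED / truth TSV next to ``out_prefix``."""
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": prefix.with_suffix(".vcf"),
            "ped": prefix.with_suffix(".ped"),
            "repeats": prefix.with_suffix(".repeats.bed"),
            "truth": prefix.with_suffix(".truth.tsv"),
        }
        write_vcf(self.variants, self.samples, paths["vcf"])
        write_ped(self.pedigree, paths["ped"])
        write_repeat_track(self.repeat_track, paths["repeats"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# pedigree construction
# ---------------------------------------------------------------------------

def _build_pedigree(config: SimulationConfig) -> list[PedigreeIndividual]:
    people: list[PedigreeIndividual] = []

    def add(fam, iid, fid, mid, sex):
        people.append(
            PedigreeIndividual(
                family_id=fam,
                individual_id=iid,
                father_id=fid,
                mother_id=mid,
                sex=sex,
            )
        )

    for f in range(1, config.n_families + 1):
        fam = f"F{f}"
        if config.family_shape == "trio":
            add(fam, f"{fam}_P1", None, None, "male")
            add(fam, f"{fam}_P2", None, None, "female")
            add(fam, f"{fam}_C1", f"{fam}_P1", f"{fam}_P2", "male")
        elif config.family_shape == "quartet":
            add(fam, f"{fam}_P1", None, None, "male")
            add(fam, f"{fam}_P2", None, None, "female")
            add(fam, f"{fam}_C1", f"{fam}_P1", f"{fam}_P2", "male")
            add(fam, f"{fam}_C2", f"{fam}_P1", f"{fam}_P2", "female")
        elif config.family_shape == "three_generation":
            # grandparents -> parent (their child) x married-in spouse -> child
            add(fam, f"{fam}_G1", None, None, "male")
            add(fam, f"{fam}_G2", None, None, "female")
            add(fam, f"{fam}_P1", f"{fam}_G1", f"{fam}_G2", "male")
            add(fam, f"{fam}_P2", None, None, "female")
            add(fam, f"{fam}_C1", f"{fam}_P1", f"{fam}_P2", "male")
        else:
            raise ValueError(f"unknown family shape {config.family_shape!r}")
    return people


# ---------------------------------------------------------------------------
# single-locus consistency oracle (local to the simulator, by enumeration)
# ---------------------------------------------------------------------------

def _gametes(dosage: int) -> tuple[int, ...]:
    return ((0,), (0, 1), (1,))[dosage]


def _trio_consistent(f: int | None, m: int | None, c: int | None) -> bool:
    """Gamete-enumeration consistency check; missing = any gamete.

    Used for the truth table's obligate-error indicator, independent of
    the detection engine.
    """
    if c is None:
        return True
    fg = (0, 1) if f is None else _gametes(f)
    mg = (0, 1) if m is None else _gametes(m)
    return any(a + b == c for a in fg for b in mg)


def _consistency_lookup() -> np.ndarray:
    """4x4x4 boolean table of _trio_consistent; code 3 = missing."""
    table = np.ones((4, 4, 4), dtype=bool)
    dec = [0, 1, 2, None]
    for fi, f in enumerate(dec):
        for mi, m in enumerate(dec):
            for ci, c in enumerate(dec):
                table[fi, mi, ci] = _trio_consistent(f, m, c)
    return table


def _any_inconsistency(
    dosages: np.ndarray, trios: list[tuple[int | None, int | None, int]]
) -> np.ndarray:
    """Per-variant flag: does any (father, mother, child) trio conflict?"""
    lookup = _consistency_lookup()
    flags = np.zeros(dosages.shape[0], dtype=bool)
    missing = np.full(dosages.shape[0], 3, dtype=np.int8)
    for fi, mi, ci in trios:
        f = dosages[:, fi] if fi is not None else missing
        m = dosages[:, mi] if mi is not None else missing
        flags |= ~lookup[f, m, dosages[:, ci]]
    return flags


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def _sample_regions(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[list[tuple[int, int]], list[tuple[str, int, int, str, str]]]:
    """Place peak regions and repeat intervals on the chromosome."""
    L = config.chrom_length
    # evenly spaced peak anchors with random jitter keep peaks well separated
    peaks: list[tuple[int, int]] = []
    if config.n_peak_regions:
        slots = np.linspace(0, L - config.peak_width, config.n_peak_regions + 2)[
            1:-1
        ]
        for anchor in slots:
            jitter = rng.integers(-config.peak_width, config.peak_width)
            start = int(np.clip(anchor + jitter, 0, L - config.peak_width))
            peaks.append((start, start + config.peak_width))

    classes = ["SINE", "LINE", "LTR", "DNA", "Simple_repeat"]
    class_p = np.array([0.315, 0.29, 0.138, 0.10, 0.157])
    class_p = class_p / class_p.sum()
    names = {
        "SINE": "AluY",
        "LINE": "L1",
        "LTR": "ERVL",
        "DNA": "hAT",
        "Simple_repeat": "(TA)n",
    }
    intervals: list[tuple[str, int, int, str, str]] = []
    mean_len = max(1, int(config.repeat_fraction * L / config.n_repeat_intervals))
    # regional repeat density: blocks weighted by a Dirichlet draw
    n_blocks = max(1, config.repeat_density_blocks)
    block_w = rng.dirichlet(
        np.full(n_blocks, config.repeat_density_concentration)
    )
    block_len = L / n_blocks
    for _ in range(config.n_repeat_intervals):
        length = max(50, int(rng.exponential(mean_len)))
        block = int(rng.choice(n_blocks, p=block_w))
        lo = int(block * block_len)
        hi = int(min((block + 1) * block_len, max(lo + 1, L - length)))
        start = int(rng.integers(lo, max(lo + 1, hi)))
        cls = str(rng.choice(classes, p=class_p))
        intervals.append(
            (config.chrom, start, min(start + length, L), cls, names[cls])
        )
    # densify repeats inside each peak region up to the boost fraction
    for p_start, p_end in peaks:
        covered = 0
        target = int(config.peak_repeat_boost * (p_end - p_start))
        while covered < target:
            length = max(200, int(rng.exponential(mean_len)))
            start = int(rng.integers(p_start, max(p_start + 1, p_end - length)))
            cls = str(rng.choice(classes, p=class_p))
            intervals.append(
                (config.chrom, start, min(start + length, p_end), cls, names[cls])
            )
            covered += length
    intervals.sort(key=lambda iv: (iv[1], iv[2]))
    return peaks, intervals


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate one pedigree-structured call set with ground truth.

    Identical configs (same seed) produce identical output, suitable for
    byte-identical file writes.
    """
    rng = np.random.default_rng(config.seed)
    pedigree = _build_pedigree(config)
    samples = [p.individual_id for p in pedigree]
    col = {p.individual_id: i for i, p in enumerate(pedigree)}
    for p in pedigree:
        p.sample_column = col[p.individual_id]
    n_samples = len(samples)

    peaks, repeat_intervals = _sample_regions(rng, config)
    track = RepeatTrack(intervals=repeat_intervals)

    # variant positions: uniform, unique, sorted (rejection-sample the
    # rare collisions rather than materializing the whole coordinate range)
    positions = np.unique(
        rng.integers(1, config.chrom_length + 1, size=config.n_variants)
    )
    while len(positions) < config.n_variants:
        extra = rng.integers(
            1, config.chrom_length + 1,
            size=config.n_variants - len(positions),
        )
        positions = np.unique(np.concatenate([positions, extra]))
    n_var = config.n_variants
    freqs = rng.beta(config.allele_freq_alpha, config.allele_freq_beta, size=n_var)
    is_multi = rng.random(n_var) < config.multiallelic_fraction

    # per-variant per-genotype error rate from spatial context
    in_peak = np.zeros(n_var, dtype=bool)
    for s, e in peaks:
        in_peak |= (positions - 1 >= s) & (positions - 1 < e)
    in_repeat = np.array(
        [track.contains(config.chrom, int(p)) for p in positions]
    )
    rate = np.full(n_var, config.base_error_rate)
    rate[in_repeat] = config.repeat_error_rate
    rate[in_peak] = config.peak_error_rate
    rate[is_multi] = np.minimum(100.0 * config.base_error_rate, 0.5)

    # true genotypes: founders HWE, children one gamete per parent.
    # dosage coding 0/1/2, 3 = missing (never produced here).
    true_dosage = np.empty((n_var, n_samples), dtype=np.int8)
    for p in pedigree:
        j = p.sample_column
        if p.is_founder:
            u = rng.random((n_var, 2))
            true_dosage[:, j] = (u[:, 0] < freqs).astype(np.int8) + (
                u[:, 1] < freqs
            ).astype(np.int8)
    # children in pedigree order (parents precede children by construction)
    for p in pedigree:
        if p.is_founder:
            continue
        j = p.sample_column
        fj = col.get(p.father_id) if p.father_id else None
        mj = col.get(p.mother_id) if p.mother_id else None
        f_dos = true_dosage[:, fj] if fj is not None else None
        m_dos = true_dosage[:, mj] if mj is not None else None

        def transmit(dos):
            if dos is None:  # unknown parent: population gamete
                return (rng.random(n_var) < freqs).astype(np.int8)
            u = rng.random(n_var)
            gamete = np.where(dos == 1, (u < 0.5).astype(np.int8), 0)
            return np.where(dos == 2, 1, gamete).astype(np.int8)

        true_dosage[:, j] = transmit(f_dos) + transmit(m_dos)

    # inject errors: flip to a uniformly random *different* dosage
    err_mask = rng.random((n_var, n_samples)) < rate[:, None]
    observed = true_dosage.copy()
    if err_mask.any():
        vi, si = np.nonzero(err_mask)
        shift = rng.integers(1, 3, size=len(vi)).astype(np.int8)  # +1 or +2 mod 3
        observed[vi, si] = (observed[vi, si] + shift) % 3

    n_errors = err_mask.sum(axis=1)

    # obligate indicator: observed genotypes create a single-locus conflict
    trios: list[tuple[int | None, int | None, int]] = []
    for p in pedigree:
        if p.is_founder:
            continue
        trios.append(
            (
                col.get(p.father_id) if p.father_id else None,
                col.get(p.mother_id) if p.mother_id else None,
                col[p.individual_id],
            )
        )
    errored_variants = np.nonzero(n_errors > 0)[0]
    obligate = np.zeros(n_var, dtype=bool)
    if len(errored_variants):
        obligate[errored_variants] = _any_inconsistency(
            observed[errored_variants], trios
        )

    # external caller: each injected error independently detected
    external_mie = rng.binomial(n_errors.astype(np.int64),
                                config.external_detection_rate)

    # SVM-like score and FILTER column
    has_err = n_errors > 0
    svm = np.where(
        has_err,
        rng.normal(config.svm_mu_err, config.svm_sd, n_var),
        rng.normal(config.svm_mu_clean, config.svm_sd, n_var),
    )
    indel5 = rng.random(n_var) < config.indel5_fraction

    alleles = ["A", "C", "G", "T"]
    ref_idx = rng.integers(0, 4, size=n_var)
    variants: list[VariantRecord] = []
    for v in range(n_var):
        ref = alleles[ref_idx[v]]
        others = [a for a in alleles if a != ref]
        if is_multi[v]:
            alts = others[:2]
        else:
            alts = [others[int(rng.integers(0, 3))]]
        filt: set[str] = set()
        if svm[v] < 0:
            filt.add("SVM")
        if indel5[v]:
            filt.add("INDEL5")
        if not filt:
            filt = {"PASS"}
        genotypes = []
        for j in range(n_samples):
            d = int(observed[v, j])
            if is_multi[v] and d > 0:
                # spread alt copies over the two alt alleles deterministically
                genotypes.append((0, 1) if d == 1 else (1, 2))
            else:
                genotypes.append(((0, 0), (0, 1), (1, 1))[d])
        variants.append(
            VariantRecord(
                chrom=config.chrom,
                pos=int(positions[v]),
                ref_allele=ref,
                alt_alleles=alts,
                filter_status=filt,
                svm_score=float(np.round(svm[v], 3)),
                info_mie=int(external_mie[v]),
                genotypes=genotypes,
            )
        )

    truth = pd.DataFrame(
        {
            "pos": positions,
            "alt_freq": np.round(freqs, 6),
            "is_multiallelic": is_multi,
            "in_repeat": in_repeat,
            "in_peak": in_peak,
            "n_errors_injected": n_errors,
            "obligate_error": obligate,
            "external_mie": external_mie,
            "svm_score": np.round(svm, 3),
        }
    )
    return SimulationResult(
        variants=variants,
        samples=samples,
        pedigree=pedigree,
        repeat_track=track,
        truth=truth,
        peak_regions=peaks,
        config=config,
    )


# ---------------------------------------------------------------------------
# detectability helpers
# ---------------------------------------------------------------------------

def detectable_fraction_at_freq(freq: float) -> float:
    """Exact P(a single uniform genotype flip in a trio creates a conflict).

    Enumerates all HWE parent pairs, transmission outcomes, flip targets
    (each of the three trio members, flipped to each of the two other
    dosages with equal probability) and checks single-locus consistency.
    """
    p = freq
    hwe = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p * p}
    trans = {
        (f, m): {
            c: sum(
                1
                for a in _gametes(f)
                for b in _gametes(m)
                if a + b == c
            )
            / (len(_gametes(f)) * len(_gametes(m)))
            for c in (0, 1, 2)
        }
        for f in (0, 1, 2)
        for m in (0, 1, 2)
    }
    total = 0.0
    detected = 0.0
    for f in (0, 1, 2):
        for m in (0, 1, 2):
            for c in (0, 1, 2):
                prob = hwe[f] * hwe[m] * trans[(f, m)][c]
                if prob == 0:
                    continue
                for member in range(3):
                    for shift in (1, 2):
                        w = prob * (1 / 3) * (1 / 2)
                        g = [f, m, c]
                        g[member] = (g[member] + shift) % 3
                        total += w
                        if not _trio_consistent(*g):
                            detected += w
    return detected / total if total else 0.0


def expected_detectable_fraction(
    config: SimulationConfig, n_draws: int = 2000, seed: int | None = None
) -> float:
    """Monte-Carlo mean of :func:`detectable_fraction_at_freq` under the
    configured allele-frequency distribution (trio families).

    Not every injected error is detectable as a Mendelian conflict, which
    is why flagged MIE counts undercount true genotyping errors.
    """
    if config.family_shape != "trio":
        raise ValueError("detectability helper is defined for trio families")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    freqs = rng.beta(config.allele_freq_alpha, config.allele_freq_beta, n_draws)
    return float(np.mean([detectable_fraction_at_freq(f) for f in freqs]))
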