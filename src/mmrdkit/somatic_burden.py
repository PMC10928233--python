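"""Consensus somatic variant merging, tumor mutation burden, hypermutator call.

Somatic callers disagree; the burden estimate therefore uses the consensus of
variants reported by at least two callers, SNVs and indels kept separate.
TMB is somatic SNVs per callable megabase (default ~50 Mb, the typical
callable exome footprint), and a sample is a hypermutator when TMB strictly
exceeds 10 mutations/Mb.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

DEFAULT_CALLABLE_MB = 50.0
HYPERMUTANT_THRESHOLD = 10.0

SNV = "SNV"
INDEL = "indel"

VariantKey = tuple[str, int, str, str]  # contig, 1-based pos, ref, alt


@dataclass(frozen=True)
class SomaticVariant:
    """One normalized somatic variant and the callers that reported it."""

    contig: str
    position: int  # 1-based, VCF convention
    ref: str
    alt: str
    callers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("empty allele")

    @property
    def variant_class(self) -> str:
        return SNV if len(self.ref) == 1 and len(self.alt) == 1 else INDEL

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.position, self.ref, self.alt)


def normalize_alleles(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix bases, keeping >= 1 base each.

    Reference-free normalization so that caller dialects of the same indel
    (e.g. padded representations) share an identity key.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


@dataclass
class TMBResult:
    """SNV count, callable span, mutations per megabase, hypermutator flag."""

    snv_count: int
    callable_mb: float
    tmb: float
    hypermutant: bool
    indel_count: int | None = None
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: Union[str, Path] | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def read_caller_vcf(
    path: Union[str, Path], caller: str, include_filtered: bool = False
) -> list[SomaticVariant]:
    """Read one caller's VCF; split multi-allelic records; normalize alleles.

    Records with a non-PASS FILTER are dropped unless ``include_filtered``.
    """
    from cyvcf2 import VCF

    out: list[SomaticVariant] = []
    vcf = VCF(str(path))
    for rec in vcf:
        if rec.FILTER is not None and not include_filtered:
            continue  # cyvcf2 reports PASS / '.' as None
        for alt in rec.ALT:
            if alt in (None, "", "*") or set(alt) - set("ACGTN"):
                continue  # symbolic / breakend alleles are out of scope
            pos, ref, a = normalize_alleles(rec.POS, rec.REF, alt)
            out.append(
                SomaticVariant(rec.CHROM, pos, ref, a, callers=frozenset({caller}))
            )
    vcf.close()
    return out


def merge_consensus(
    caller_sets: Mapping[str, Sequence[SomaticVariant]],
    min_callers: int = 2,
) -> tuple[list[SomaticVariant], list[SomaticVariant]]:
    """Variants reported by >= ``min_callers`` callers, as (snvs, indels).

    Identity is (contig, position, ref, alt) after normalization; each
    consensus record carries the union of its supporting callers. Duplicate
    reports of one variant by the same caller are collapsed first.
    """
    if min_callers > len(caller_sets):
        raise ValueError(
            f"min_callers {min_callers} exceeds caller count {len(caller_sets)}"
        )
    support: dict[VariantKey, set[str]] = {}
    for caller, variants in caller_sets.items():
        for v in variants:
            support.setdefault(v.key, set()).add(caller)

    contigs_per_caller = {
        c: {v.contig for v in vs} for c, vs in caller_sets.items() if vs
    }
    if contigs_per_caller:
        all_contigs = set.union(*contigs_per_caller.values())
        chr_styles = {c.startswith("chr") for c in all_contigs}
        if len(chr_styles) > 1:
            raise ValueError(
                "inconsistent contig naming across callers (mixed chr-prefixed "
                f"and bare names): {sorted(all_contigs)}"
            )

    snvs, indels = [], []
    for key in sorted(support):
        callers = support[key]
        if len(callers) < min_callers:
            continue
        v = SomaticVariant(*key, callers=frozenset(callers))
        (snvs if v.variant_class == SNV else indels).append(v)
    return snvs, indels


def compute_tmb(
    consensus_snvs: Sequence[SomaticVariant],
    callable_mb: float = DEFAULT_CALLABLE_MB,
    consensus_indels: Sequence[SomaticVariant] | None = None,
    hypermutant_threshold: float = HYPERMUTANT_THRESHOLD,
) -> TMBResult:
    """TMB = distinct consensus SNVs / callable megabases.

    Indels never enter the TMB numerator or the hypermutator call; when
    provided they are reported separately.
    """
    if callable_mb <= 0:
        raise ValueError(f"callable_mb must be positive, got {callable_mb}")
    distinct = {v.key for v in consensus_snvs if v.variant_class == SNV}
    tmb = len(distinct) / callable_mb
    return TMBResult(
        snv_count=len(distinct),
        callable_mb=callable_mb,
        tmb=tmb,
        hypermutant=classify_hypermutant(tmb, hypermutant_threshold),
        indel_count=(
            len({v.key for v in consensus_indels}) if consensus_indels is not None else None
        ),
        provenance={"hypermutant_threshold": hypermutant_threshold},
    )


def classify_hypermutant(
    tmb: Union[TMBResult, float], threshold: float = HYPERMUTANT_THRESHOLD
) -> bool:
    """Hypermutator iff TMB strictly exceeds the threshold (>10 mut/Mb)."""
    value = tmb.tmb if isinstance(tmb, TMBResult) else tmb
    return value > threshold


def callable_mb_from_bed(path: Union[str, Path]) -> float:
    """Total span of a BED file in megabases (alternative to the scalar default)."""
    total = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        total += int(parts[2]) - int(parts[1])
    return total / 1e6


def write_consensus_vcf(
    path: Union[str, Path],
    variants: Iterable[SomaticVariant],
    contig_lengths: Mapping[str, int],
) -> None:
    """Write consensus variants as uncompressed VCF with supporting callers in INFO."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers">')
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: x.key):
            rec = out.new_record(
                contig=v.contig,
                start=v.position - 1,
                alleles=(v.ref, v.alt),
            )
            rec.info["CALLERS"] = tuple(sorted(v.callers))
            out.write(rec)
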