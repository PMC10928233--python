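"""Synthetic data with known ground truth for every pipeline stage.

Patient sequencing data behind mismatch-repair studies is rarely shareable,
so every input the pipeline consumes can be simulated here: a reference with
embedded mononucleotide microsatellites, ~1x coverage reads carrying
slippage deletions, multi-caller somatic variant sets with partial overlap,
trinucleotide mutation catalogs drawn from signature mixtures, and five-locus
fragment-analysis peak profiles with configurable allele shifts. Each
generator returns machine-readable truth alongside the data, and every output
is a pure function of (config, seed).

The defaults mirror a low-pass whole-genome MSI experiment: mean 1 read per
locus, loci of 10-15 bp, slippage producing 1-bp deletions at an
MMR-proficient (~1%) or MMR-deficient (~20%) per-read rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .ms_catalog import LocusCatalog, MicrosatelliteLocus
from .panel_msi import PANEL_LOCI, PanelProfile
from .signature_refit import CHANNELS_96, MutationCatalog, SignatureMatrix
from .somatic_burden import SomaticVariant

#: Baseline (normal) representative allele length per panel locus, bp.
PANEL_BASELINE_BP = {
    "BAT-25": 125,
    "BAT-26": 120,
    "NR-21": 103,
    "NR-24": 132,
    "MONO-27": 142,
}

#: Stutter peak heights relative to the main peak, at +/-1 and +/-2 bp.
STUTTER_FRACTIONS = (0.5, 0.25)


def _default_locus_counts() -> dict[int, int]:
    return {L: 100 for L in range(10, 16)}


def _default_mixture() -> dict[str, float]:
    return {"SBS6": 0.8, "SBS1": 0.2}


def _default_shifts() -> dict[str, int]:
    return {name: 0 for name in PANEL_LOCI}


@dataclass
class SimConfig:
    """Shared knobs for all simulators; see module docstring for rationale."""

    seed: int = 0
    genome_length: int = 100_000
    locus_count_per_length: dict[int, int] = field(default_factory=_default_locus_counts)
    slippage_del_rate: float = 0.01
    coverage: float = 1.0
    n_mutations: int = 1000
    mixture: dict[str, float] = field(default_factory=_default_mixture)
    caller_count: int = 4
    caller_overlap: float = 0.8
    fp_rate: float = 0.0  # expected caller-private false positives per true variant
    indel_fraction: float = 0.15  # of simulated caller variants
    panel_shifts: dict[str, int] = field(default_factory=_default_shifts)
    contig: str = "sim1"

    def __post_init__(self) -> None:
        for name in ("slippage_del_rate", "caller_overlap"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")
        if self.mixture:
            w = np.array(list(self.mixture.values()), dtype=float)
            if (w < 0).any():
                raise ValueError("mixture weights must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must sum to 1, got {w.sum()}")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


# ---------------------------------------------------------------------------
# reference with embedded microsatellites


def _random_flank(rng: np.random.Generator, n: int, forbid_first: str | None = None,
                  tail: str = "") -> str:
    """Random sequence with no homopolymer run longer than 3, continuing
    ``tail`` (the last bases already emitted) and never starting with
    ``forbid_first``."""
    out: list[str] = []
    recent = tail
    for i in range(n):
        choices = [b for b in "ACGT"]
        if len(recent) >= 3 and recent[-1] == recent[-2] == recent[-3]:
            choices.remove(recent[-1])
        if i == 0 and forbid_first and forbid_first in choices:
            choices.remove(forbid_first)
        b = choices[int(rng.integers(len(choices)))]
        out.append(b)
        recent = (recent + b)[-3:]
    return "".join(out)


def simulate_reference(config: SimConfig) -> tuple[dict[str, str], LocusCatalog]:
    """Build one contig containing the configured microsatellites.

    Loci are placed left to right separated by random non-repeat spacers of
    at least 5 bp whose own runs never exceed 3 bp, so each embedded run is
    maximal and the only runs of length >= 10 are the intended ones. Returns
    the reference as ``{contig: sequence}`` plus the exact truth catalog.
    """
    rng = config.rng(salt=1)
    lengths: list[int] = []
    for L, n in sorted(config.locus_count_per_length.items()):
        lengths.extend([L] * n)
    order = rng.permutation(len(lengths))
    lengths = [lengths[i] for i in order]

    min_spacer = 5
    needed = sum(lengths) + (len(lengths) + 1) * min_spacer
    if needed > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too small: need >= {needed} bp "
            f"for {len(lengths)} loci with {min_spacer}-bp flanks"
        )
    slack = config.genome_length - needed
    # distribute the slack over the spacers
    extra = rng.multinomial(slack, np.full(len(lengths) + 1, 1.0 / (len(lengths) + 1)))

    parts: list[str] = []
    loci: list[MicrosatelliteLocus] = []
    pos = 0
    tail = ""
    for i, L in enumerate(lengths):
        spacer = _random_flank(rng, min_spacer + int(extra[i]), tail=tail)
        parts.append(spacer)
        pos += len(spacer)
        base = "ACGT"[int(rng.integers(4))]
        while spacer and spacer[-1] == base:
            base = "ACGT"[int(rng.integers(4))]
        parts.append(base * L)
        loci.append(MicrosatelliteLocus(config.contig, pos, pos + L, base))
        pos += L
        tail = base * 3  # forbid extending the run into the next spacer
    final = _random_flank(rng, min_spacer + int(extra[-1]), tail=tail)
    parts.append(final)
    seq = "".join(parts)
    assert len(seq) == config.genome_length
    return {config.contig: seq}, LocusCatalog(loci=loci)


# ---------------------------------------------------------------------------
# slippage reads


def simulate_locus_reads(
    truth: LocusCatalog,
    config: SimConfig,
    reference: Mapping[str, str],
) -> list[pysam.AlignedSegment]:
    """Poisson(coverage) aligned reads per locus, each independently carrying
    a 1-bp deletion of the run with probability ``slippage_del_rate``.

    Reads span the locus with 6-15 bp of flank on each side (clipped at
    contig ends); a deleted read encodes the event as a 1-base D in its CIGAR
    at a uniform position inside the run. Reads come back coordinate-sorted,
    ready to write as SAM via :func:`write_sam`.
    """
    rng = config.rng(salt=2)
    header = sam_header(reference)
    reads: list[tuple[int, pysam.AlignedSegment]] = []
    serial = 0
    for loc in truth:
        seq = reference[loc.contig]
        n_reads = int(rng.poisson(config.coverage))
        for _ in range(n_reads):
            lf = int(rng.integers(6, 16))
            rf = int(rng.integers(6, 16))
            rstart = max(0, loc.start - lf)
            rend = min(len(seq), loc.end + rf)
            deleted = bool(rng.random() < config.slippage_del_rate)
            a = pysam.AlignedSegment(header)
            a.query_name = f"read{serial}"
            serial += 1
            a.reference_id = header.get_tid(loc.contig)
            a.reference_start = rstart
            a.mapping_quality = 60
            a.flag = 0
            if deleted:
                dpos = int(rng.integers(loc.start, loc.end))
                a.cigarstring = f"{dpos - rstart}M1D{rend - dpos - 1}M"
                a.query_sequence = seq[rstart:dpos] + seq[dpos + 1 : rend]
            else:
                a.cigarstring = f"{rend - rstart}M"
                a.query_sequence = seq[rstart:rend]
            reads.append((rstart, a))
    reads.sort(key=lambda t: t[0])
    return [a for _, a in reads]


def sam_header(reference: Mapping[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in reference.items()],
        }
    )


def write_sam(reads: Sequence[pysam.AlignedSegment], path: Union[str, Path]) -> None:
    if not reads:
        raise ValueError("no reads to write")
    with pysam.AlignmentFile(str(path), "w", header=reads[0].header) as out:
        for read in reads:
            out.write(read)


def write_fasta(reference: Mapping[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for contig, seq in reference.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# multi-caller somatic variant sets


def simulate_caller_vcfs(
    config: SimConfig,
    reference: Mapping[str, str] | None = None,
) -> tuple[dict[str, list[SomaticVariant]], list[SomaticVariant]]:
    """Per-caller variant sets with partial overlap, plus the truth list.

    ``n_mutations`` true variants (SNVs and, per ``indel_fraction``, 1-bp
    indels) are placed at distinct positions; each caller reports each truth
    independently with probability ``caller_overlap`` and adds
    Poisson(fp_rate * n_mutations) private false positives.
    """
    if config.caller_count < 2:
        raise ValueError("caller_count must be >= 2")
    rng = config.rng(salt=3)
    if reference is None:
        seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=config.genome_length)])
        reference = {config.contig: seq}
    contig = config.contig
    seq = reference[contig]

    n = config.n_mutations
    n_fp_total = config.caller_count  # reserve position space for FPs
    all_pos = rng.choice(
        np.arange(2, len(seq) - 2), size=min(len(seq) - 4, n * 3 + 10), replace=False
    )
    truth: list[SomaticVariant] = []
    used = 0
    while len(truth) < n and used < len(all_pos):
        pos = int(all_pos[used]) + 1  # 1-based
        used += 1
        ref_base = seq[pos - 1]
        if rng.random() < config.indel_fraction:
            if rng.random() < 0.5:  # 1-bp deletion, anchored VCF style
                v = SomaticVariant(contig, pos, seq[pos - 1 : pos + 1], ref_base)
            else:  # 1-bp insertion
                ins = "ACGT"[int(rng.integers(4))]
                v = SomaticVariant(contig, pos, ref_base, ref_base + ins)
        else:
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            v = SomaticVariant(contig, pos, ref_base, str(alt))
        truth.append(v)
    if len(truth) < n:
        raise ValueError("genome too small to place the requested variants")

    callers: dict[str, list[SomaticVariant]] = {}
    for ci in range(config.caller_count):
        name = f"caller{ci + 1}"
        emitted = [v for v in truth if rng.random() < config.caller_overlap]
        n_fp = int(rng.poisson(config.fp_rate * n))
        for _ in range(n_fp):
            pos = int(all_pos[used % len(all_pos)]) + 1
            used += 1
            ref_base = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            emitted.append(SomaticVariant(contig, pos, ref_base, str(alt)))
        callers[name] = [
            SomaticVariant(v.contig, v.position, v.ref, v.alt, frozenset({name}))
            for v in sorted(emitted, key=lambda v: v.key)
        ]
    return callers, truth


def write_caller_vcfs(
    callers: Mapping[str, Sequence[SomaticVariant]],
    reference: Mapping[str, str],
    directory: Union[str, Path],
) -> dict[str, Path]:
    """One uncompressed VCF per caller; returns {caller: path}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for caller, variants in callers.items():
        header = pysam.VariantHeader()
        for contig, seq in reference.items():
            header.add_line(f"##contig=<ID={contig},length={len(seq)}>")
        path = directory / f"{caller}.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for v in sorted(variants, key=lambda x: x.key):
                rec = out.new_record(
                    contig=v.contig, start=v.position - 1, alleles=(v.ref, v.alt)
                )
                out.write(rec)
        paths[caller] = path
    return paths


# ---------------------------------------------------------------------------
# signature-mixture catalogs


def simulate_catalog(
    signatures: SignatureMatrix, config: SimConfig
) -> tuple[MutationCatalog, dict[str, float]]:
    """Multinomial catalog drawn from the mixture-weighted channel distribution."""
    unknown = set(config.mixture) - set(signatures.signature_ids)
    if unknown:
        raise ValueError(f"mixture references unknown signature(s): {sorted(unknown)}")
    rng = config.rng(salt=4)
    p = np.zeros(96)
    for sig, w in config.mixture.items():
        p += w * signatures.matrix[sig].values
    p = p / p.sum() if p.sum() > 0 else np.full(96, 1 / 96)
    counts = rng.multinomial(config.n_mutations, p)
    catalog = MutationCatalog(pd.Series(counts, index=list(CHANNELS_96)))
    return catalog, dict(config.mixture)


def synthetic_signature_matrix(
    signature_ids: Sequence[str] = ("SBS1", "SBS5", "SBS6", "SBS18"),
    seed: int = 96,
    concentration: float = 0.05,
) -> SignatureMatrix:
    """Deterministic sparse synthetic signature matrix (96 x k).

    Columns are Dirichlet draws with a small concentration, giving each
    synthetic signature a few dominant channels — well separated, so mixture
    recovery is identifiable. Synthetic stand-in for a COSMIC download; not
    the real COSMIC profiles.
    """
    rng = np.random.default_rng(seed)
    cols = {
        sig: rng.dirichlet(np.full(96, concentration)) for sig in signature_ids
    }
    return SignatureMatrix(pd.DataFrame(cols, index=list(CHANNELS_96)))


def simulate_context_snvs(
    reference: Mapping[str, str],
    signatures: SignatureMatrix,
    config: SimConfig,
) -> tuple[list[SomaticVariant], MutationCatalog]:
    """SNVs whose trinucleotide contexts realize a mixture-drawn catalog.

    Draws channel counts multinomially from the mixture, then places each
    mutation at a reference position whose forward- or reverse-strand context
    matches the channel. Channels with no matching position in the reference
    are dropped (counted in the returned catalog only if placed). Returns the
    variant list and the catalog actually realized.
    """
    from .signature_refit import revcomp

    rng = config.rng(salt=5)
    catalog, _ = simulate_catalog(signatures, config)

    # index reference positions by pyrimidine-normalized context
    by_context: dict[str, list[tuple[str, int, bool]]] = {}
    for contig, seq in reference.items():
        seq = seq.upper()
        for i in range(1, len(seq) - 1):
            ctx = seq[i - 1 : i + 2]
            if set(ctx) - set("ACGT"):
                continue
            if ctx[1] in "CT":
                by_context.setdefault(ctx, []).append((contig, i + 1, False))
            else:
                by_context.setdefault(revcomp(ctx), []).append((contig, i + 1, True))

    variants: list[SomaticVariant] = []
    realized = np.zeros(96, dtype=int)
    for idx, ch in enumerate(CHANNELS_96):
        k = int(catalog.counts.iloc[idx])
        if k == 0:
            continue
        ctx = ch[0] + ch[2] + ch[6]  # e.g. A[C>T]G -> ACG
        alt = ch[4]
        pool = by_context.get(ctx, [])
        if not pool:
            continue
        picks = rng.integers(len(pool), size=k)
        for j in picks:
            contig, pos, flipped = pool[int(j)]
            ref_base = reference[contig][pos - 1].upper()
            alt_base = revcomp(alt) if flipped else alt
            variants.append(SomaticVariant(contig, pos, ref_base, alt_base))
            realized[idx] += 1
    return variants, MutationCatalog(pd.Series(realized, index=list(CHANNELS_96)))


# ---------------------------------------------------------------------------
# panel peak profiles


def simulate_panel_profile(config: SimConfig) -> tuple[PanelProfile, PanelProfile]:
    """Matched (normal, test) fragment-analysis profiles.

    The normal profile puts its main peak at each locus baseline with stutter
    side-peaks at 50% / 25% of the main height at +/-1 / +/-2 bp. The test
    profile's main peak is moved by ``panel_shifts[locus]`` bp (negative =
    shorter allele); stutter stays relative to the moved peak.
    """
    unknown = set(config.panel_shifts) - set(PANEL_BASELINE_BP)
    if unknown:
        raise ValueError(f"panel_shifts for unknown locus: {sorted(unknown)}")
    rng = config.rng(salt=6)

    def profile(shifts: Mapping[str, int]) -> PanelProfile:
        peaks: dict[str, list[tuple[int, float]]] = {}
        for locus in PANEL_LOCI:
            main = PANEL_BASELINE_BP[locus] + int(shifts.get(locus, 0))
            height = float(rng.uniform(800, 1200))
            plist = [(main, height)]
            for off, frac in zip((1, 2), STUTTER_FRACTIONS):
                plist.append((main - off, height * frac * float(rng.uniform(0.9, 1.0))))
                plist.append((main + off, height * frac * float(rng.uniform(0.9, 1.0))))
            peaks[locus] = sorted(plist)
        return PanelProfile(peaks=peaks)

    normal = profile({l: 0 for l in PANEL_LOCI})
    test = profile(config.panel_shifts)
    return normal, test
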