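"""Genome-wide microsatellite-instability (MMRDness) scoring from low-pass
whole-genome alignments.

The read-out targets polymerase-slippage deletions left uncorrected when DNA
mismatch repair is lost. For every mononucleotide locus of 10-15 bp, spanning
reads are inspected for a 1-bp deletion inside the run. The per-length
deleted-locus fractions are averaged, log-transformed and offset by +1.1 so
that 0 separates MMR-deficient (score > 0) from MMR-proficient (score <= 0)
samples:

    score = log10( mean_L  n_del[L] / n_loci[L] ) + 1.1

At ~1x coverage most loci carry a single read, so a locus is called deleted
when at least ``min_support`` spanning reads (default 1) show a 1-bp deletion.
"""

from __future__ import annotations

import json
import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import pysam

from .ms_catalog import LocusCatalog, MicrosatelliteLocus

DEFAULT_OFFSET = 1.1
DEFAULT_LOG_BASE = 10.0

MMRD = "MMRD"
MMR_PROFICIENT = "MMR-proficient"


@dataclass(frozen=True)
class LocusObservation:
    """Read support at one locus: spanning reads and 1-bp-deletion reads."""

    locus: MicrosatelliteLocus
    reads_total: int
    reads_del1: int
    deleted: bool

    def __post_init__(self) -> None:
        if not 0 <= self.reads_del1 <= self.reads_total:
            raise ValueError(
                f"reads_del1 {self.reads_del1} outside [0, {self.reads_total}]"
            )


@dataclass
class LocusLengthTable:
    """Per-length counts of observed loci and of loci carrying a 1-bp deletion."""

    n_loci: dict[int, int] = field(default_factory=dict)
    n_del: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for L in self.n_loci:
            nd = self.n_del.get(L, 0)
            if not 0 <= nd <= self.n_loci[L]:
                raise ValueError(f"n_del[{L}]={nd} outside [0, {self.n_loci[L]}]")

    @property
    def lengths(self) -> list[int]:
        return sorted(self.n_loci)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length": self.lengths,
                "n_loci": [self.n_loci[L] for L in self.lengths],
                "n_del": [self.n_del.get(L, 0) for L in self.lengths],
            }
        )

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class MMRDnessResult:
    """Normalized MMRDness score and the MMRD/proficient call.

    ``raw_score`` is the log of the mean deleted-locus fraction; ``score`` is
    ``raw_score + offset``; ``call`` follows the sign of ``score`` with the
    boundary (exactly 0) assigned to MMR-proficient.
    """

    fraction: dict[int, float]
    mean_fraction: float
    raw_score: float
    score: float
    call: str
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: Union[str, Path] | None = None) -> str:
        payload = {
            "fraction": {str(k): v for k, v in self.fraction.items()},
            "mean_fraction": self.mean_fraction,
            "raw_score": self.raw_score,
            "score": self.score,
            "call": self.call,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _read_deletion_events(read: pysam.AlignedSegment) -> tuple[list, list]:
    """Return ([(ref_pos, del_len)], [ref_pos of insertions]) for one alignment."""
    dels, ins = [], []
    pos = read.reference_start
    for op, length in read.cigartuples or ():
        if op == 2:  # D
            dels.append((pos, length))
            pos += length
        elif op in (0, 7, 8):  # M, =, X
            pos += length
        elif op == 1:  # I
            ins.append(pos)
        elif op == 3:  # N
            pos += length
        # S/H/P consume no reference
    return dels, ins


def observe_loci(
    alignments: Union[str, Path, pysam.AlignmentFile],
    catalog: LocusCatalog,
    min_support: int = 1,
    min_flank: int = 1,
) -> list[LocusObservation]:
    """Tabulate spanning reads and 1-bp deletions at every catalog locus.

    The alignment file (SAM or BAM) is streamed once; reads are assigned to
    loci by binary search, so no coordinate sort or index is required. A read
    spans a locus when its aligned reference interval covers the run plus
    ``min_flank`` bases on each side. A spanning read counts toward
    ``reads_del1`` iff the only indel its alignment places inside the run is a
    single deletion of exactly 1 base. Loci with zero spanning reads are
    omitted (they carry no information at low coverage).
    """
    if isinstance(alignments, (str, Path)):
        af = pysam.AlignmentFile(str(alignments), check_sq=False)
        close = True
    else:
        af, close = alignments, False

    by_contig: dict[str, list[MicrosatelliteLocus]] = {}
    for loc in catalog:
        by_contig.setdefault(loc.contig, []).append(loc)
    starts = {c: [l.start for l in ll] for c, ll in by_contig.items()}

    total: dict[MicrosatelliteLocus, int] = {}
    del1: dict[MicrosatelliteLocus, int] = {}
    seen_contigs: set[str] = set()
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name not in by_contig:
                continue
            contig = read.reference_name
            seen_contigs.add(contig)
            rstart, rend = read.reference_start, read.reference_end
            if rend is None:
                continue
            loci = by_contig[contig]
            # candidate loci: start >= rstart + min_flank, scanned left to right
            i = bisect_right(starts[contig], rstart + min_flank - 1)
            events = None
            while i < len(loci) and loci[i].end + min_flank <= rend:
                loc = loci[i]
                i += 1
                total[loc] = total.get(loc, 0) + 1
                if events is None:
                    events = _read_deletion_events(read)
                dels, ins = events
                in_run_dels = [
                    (p, l) for p, l in dels if p >= loc.start and p + l <= loc.end
                ]
                ins_in_run = any(loc.start < p < loc.end for p in ins)
                if (
                    len(in_run_dels) == 1
                    and in_run_dels[0][1] == 1
                    and not ins_in_run
                ):
                    del1[loc] = del1.get(loc, 0) + 1
    finally:
        if close:
            af.close()

    missing = set(by_contig) - seen_contigs
    if missing:
        warnings.warn(
            f"catalog contigs absent from alignments, loci skipped: {sorted(missing)}"
        )

    obs = [
        LocusObservation(
            locus=loc,
            reads_total=total[loc],
            reads_del1=del1.get(loc, 0),
            deleted=del1.get(loc, 0) >= min_support,
        )
        for loc in sorted(total, key=lambda l: (l.contig, l.start))
    ]
    return obs


def build_length_table(observations: Iterable[LocusObservation]) -> LocusLengthTable:
    """Group observations by run length into (observed, deleted) locus counts."""
    n_loci: dict[int, int] = {}
    n_del: dict[int, int] = {}
    for ob in observations:
        L = ob.locus.length
        n_loci[L] = n_loci.get(L, 0) + 1
        if ob.deleted:
            n_del[L] = n_del.get(L, 0) + 1
    return LocusLengthTable(n_loci=n_loci, n_del=n_del)


def mmrdness_score(
    table: LocusLengthTable,
    pseudocount: float = 0.0,
    offset: float = DEFAULT_OFFSET,
    log_base: float = DEFAULT_LOG_BASE,
) -> MMRDnessResult:
    """Average the per-length deleted fractions, log-transform, add the offset.

    Length bins with no observed loci are excluded from the mean and listed in
    the result provenance. With ``pseudocount`` 0 and no deletions anywhere the
    raw score is -inf (sentinel; the call is then MMR-proficient).
    """
    present = [L for L in table.lengths if table.n_loci[L] > 0]
    if not present:
        raise ValueError("no length bin has observed loci; cannot score")
    empty = [L for L in table.lengths if table.n_loci[L] == 0]

    fraction = {
        L: (table.n_del.get(L, 0) + pseudocount) / (table.n_loci[L] + pseudocount)
        for L in present
    }
    mean_fraction = sum(fraction.values()) / len(fraction)
    if mean_fraction > 0:
        raw = math.log(mean_fraction, log_base)
    else:
        raw = -math.inf
    score = raw + offset
    result = MMRDnessResult(
        fraction=fraction,
        mean_fraction=mean_fraction,
        raw_score=raw,
        score=score,
        call="",
        provenance={
            "offset": offset,
            "log_base": log_base,
            "pseudocount": pseudocount,
            "excluded_empty_bins": empty,
            "zero_mean_fraction": mean_fraction == 0,
        },
    )
    result.call = classify_mmrd(result)
    return result


def classify_mmrd(result: Union[MMRDnessResult, float]) -> str:
    """Positive normalized score -> MMRD; zero or negative -> MMR-proficient."""
    score = result.score if isinstance(result, MMRDnessResult) else result
    return MMRD if score > 0 else MMR_PROFICIENT


def observations_to_dataframe(observations: Sequence[LocusObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                ob.locus.contig,
                ob.locus.start,
                ob.locus.end,
                ob.locus.base,
                ob.locus.length,
                ob.reads_total,
                ob.reads_del1,
                ob.deleted,
            )
            for ob in observations
        ],
        columns=[
            "contig",
            "start",
            "end",
            "base",
            "length",
            "reads_total",
            "reads_del1",
            "deleted",
        ],
    )
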