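"""Detection and filtering of mononucleotide microsatellite loci.

A microsatellite locus here is a *maximal* homopolymer run in the reference
sequence: the bases immediately before and after the run differ from the run
base (or fall off the end of the contig). The genome-wide MMRDness score is
computed over the catalog of such runs with lengths inside a configurable
window, 10-15 bp by default.

Coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

VALID_BASES = frozenset("ACGTN")

DEFAULT_MIN_LEN = 10
DEFAULT_MAX_LEN = 15

# maximal runs of a single non-N base, length >= 2
_RUN_RE = re.compile(r"A{2,}|C{2,}|G{2,}|T{2,}")


@dataclass(frozen=True, order=True)
class MicrosatelliteLocus:
    """A maximal mononucleotide run in the reference."""

    contig: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    base: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty locus interval [{self.start}, {self.end})")
        if self.base not in "ACGT":
            raise ValueError(f"locus base must be one of A/C/G/T, got {self.base!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LocusCatalog:
    """Ordered, non-overlapping set of microsatellite loci.

    ``length_filter`` records the inclusive length window applied (None for an
    unfiltered catalog fresh from :func:`scan_reference`).
    """

    loci: list[MicrosatelliteLocus] = field(default_factory=list)
    length_filter: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.contig, l.start))
        prev = None
        for loc in self.loci:
            if prev is not None and prev.contig == loc.contig and loc.start < prev.end:
                raise ValueError(f"overlapping loci at {loc.contig}:{loc.start}")
            prev = loc

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def filter_by_length(
        self, min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN
    ) -> "LocusCatalog":
        return filter_by_length(self, min_len, max_len)

    def tabulate_by_length(self) -> dict[int, int]:
        return tabulate_by_length(self)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l.contig, l.start, l.end, l.base, l.length) for l in self.loci],
            columns=["contig", "start", "end", "base", "length"],
        )

    def write_tsv(self, path: Union[str, Path]) -> None:
        """BED-like TSV: contig, start, end, base, length."""
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "LocusCatalog":
        df = pd.read_csv(path, sep="\t")
        loci = [
            MicrosatelliteLocus(str(r.contig), int(r.start), int(r.end), str(r.base))
            for r in df.itertuples()
        ]
        return cls(loci=loci)


def _iter_contigs(source) -> Iterable[tuple[str, str]]:
    """Yield (contig, sequence) pairs from a string, mapping, FASTA path or
    pyfaidx.Fasta-like object."""
    if isinstance(source, (str, Path)):
        if isinstance(source, str) and not Path(source).exists():
            yield "seq", source.upper()  # raw sequence string
            return
        import pyfaidx

        fasta = pyfaidx.Fasta(str(source))
        for name in fasta.keys():
            yield name, str(fasta[name][:]).upper()
        return
    if isinstance(source, Mapping):
        for name, seq in source.items():
            yield str(name), str(seq).upper()
        return
    # pyfaidx.Fasta or similar
    for name in source.keys():
        yield str(name), str(source[name][:]).upper()


def scan_reference(source) -> LocusCatalog:
    """Scan a reference for every maximal homopolymer run of length >= 2.

    ``source`` may be a raw sequence string, a ``{contig: sequence}`` mapping,
    a FASTA path, or an open ``pyfaidx.Fasta``. Runs of N are skipped; any
    other non-nucleotide symbol raises ``ValueError``.
    """
    loci: list[MicrosatelliteLocus] = []
    for contig, seq in _iter_contigs(source):
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {contig!r} contains non-nucleotide symbols: {sorted(bad)}"
            )
        for m in _RUN_RE.finditer(seq):
            loci.append(
                MicrosatelliteLocus(contig, m.start(), m.end(), seq[m.start()])
            )
    return LocusCatalog(loci=loci)


def filter_by_length(
    catalog: LocusCatalog,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> LocusCatalog:
    """Retain loci with ``min_len <= length <= max_len`` (both ends inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [l for l in catalog.loci if min_len <= l.length <= max_len]
    return LocusCatalog(loci=kept, length_filter=(min_len, max_len))


def tabulate_by_length(catalog: LocusCatalog) -> dict[int, int]:
    """Number of loci at each run length, as ``{length: count}``."""
    counts = Counter(l.length for l in catalog.loci)
    return dict(sorted(counts.items()))
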