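"""MSI classification from five-locus mononucleotide fragment-analysis profiles.

Capillary-electrophoresis genotyping of the pentaplex mononucleotide panel
(BAT-25, BAT-26, NR-21, NR-24, MONO-27) yields, per locus, a set of peaks at
discrete allele lengths. PCR stutter produces minor peaks adjacent to the true
allele, so the representative allele is the highest peak flanked by lower
peaks. A locus is unstable when the test sample's representative allele is
shifted >= 3 bp from the matched normal; the sample is MSI-High with >= 2
unstable loci, MSI-Low with exactly 1, MS-Stable with 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

PANEL_LOCI = ("BAT-25", "BAT-26", "NR-21", "NR-24", "MONO-27")

SHIFT_THRESHOLD_BP = 3
MSI_HIGH_MIN_UNSTABLE = 2

MSI_HIGH = "MSI-High"
MSI_LOW = "MSI-Low"
MS_STABLE = "MS-Stable"

Peak = tuple[int, float]  # (allele_length_bp, peak_height)


@dataclass
class PanelProfile:
    """Per-locus peak tables: {locus: [(allele_length_bp, peak_height), ...]}."""

    peaks: dict[str, list[Peak]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, plist in self.peaks.items():
            lengths = [p[0] for p in plist]
            if len(set(lengths)) != len(lengths):
                raise ValueError(f"duplicate allele lengths at locus {locus}")
            if any(h < 0 for _, h in plist):
                raise ValueError(f"negative peak height at locus {locus}")
            if not plist:
                raise ValueError(f"locus {locus} has no peaks")

    @property
    def loci(self) -> list[str]:
        return list(self.peaks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (locus, length, height)
            for locus, plist in self.peaks.items()
            for length, height in plist
        ]
        return pd.DataFrame(rows, columns=["locus", "allele_length_bp", "peak_height"])

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "PanelProfile":
        df = pd.read_csv(path, sep="\t")
        peaks: dict[str, list[Peak]] = {}
        for r in df.itertuples():
            peaks.setdefault(str(r.locus), []).append(
                (int(r.allele_length_bp), float(r.peak_height))
            )
        return cls(peaks=peaks)


@dataclass
class PanelResult:
    """Per-locus shifts and the derived sample-level MSI category."""

    representative_normal: dict[str, int]
    representative_test: dict[str, int]
    shift: dict[str, int]
    unstable: dict[str, bool]
    unstable_count: int
    assayed_count: int
    sample_call: str
    flags: list[str] = field(default_factory=list)

    def to_json(self, path: Union[str, Path] | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def representative_allele(peaks: Sequence[Peak]) -> int:
    """Allele length of the highest peak flanked by strictly lower peaks.

    Flanking is judged against the immediate neighbours in allele-length
    order; a boundary peak has no higher-side neighbour and cannot satisfy
    the rule. If no interior peak does (monotone or degenerate profiles),
    fall back to the global maximum. Height ties break toward the shorter
    allele, the direction slippage deletions move alleles.
    """
    if not peaks:
        raise ValueError("empty peak list")
    ordered = sorted(peaks)
    flanked = [
        ordered[i]
        for i in range(1, len(ordered) - 1)
        if ordered[i - 1][1] < ordered[i][1] and ordered[i + 1][1] < ordered[i][1]
    ]
    pool = flanked if flanked else ordered
    # max height, ties toward shorter allele
    best = max(pool, key=lambda p: (p[1], -p[0]))
    return best[0]


def locus_shift(
    test: int, normal: int, shift_threshold: int = SHIFT_THRESHOLD_BP
) -> tuple[int, bool]:
    """Absolute allele-length shift in bp and whether it marks instability."""
    shift = abs(int(test) - int(normal))
    return shift, shift >= shift_threshold


def classify_sample(
    unstable_flags: Sequence[bool], msi_high_min: int = MSI_HIGH_MIN_UNSTABLE
) -> str:
    """MSI-High with >= 2 unstable loci, MSI-Low with 1, MS-Stable with 0."""
    if len(unstable_flags) == 0:
        raise ValueError("no loci assayed")
    n = sum(bool(f) for f in unstable_flags)
    if n >= msi_high_min:
        return MSI_HIGH
    if n == 1:
        return MSI_LOW
    return MS_STABLE


def classify_panel(
    normal: PanelProfile,
    test: PanelProfile,
    shift_threshold: int = SHIFT_THRESHOLD_BP,
    msi_high_min: int = MSI_HIGH_MIN_UNSTABLE,
    expected_loci: Sequence[str] = PANEL_LOCI,
) -> PanelResult:
    """Compare a test profile against its matched normal, locus by locus.

    Loci missing from either profile reduce the assayed denominator and are
    flagged; the MSI-High rule still requires >= ``msi_high_min`` unstable
    among the assayed loci.
    """
    assayed = [l for l in expected_loci if l in normal.peaks and l in test.peaks]
    flags = [
        f"locus {l} missing from {'normal' if l not in normal.peaks else 'test'} profile"
        for l in expected_loci
        if l not in assayed
    ]
    extra = [l for l in test.peaks if l not in expected_loci]
    if extra:
        flags.append(f"unexpected loci ignored: {extra}")
    if not assayed:
        raise ValueError("no panel locus present in both profiles")

    rep_n, rep_t, shifts, unstable = {}, {}, {}, {}
    for locus in assayed:
        rep_n[locus] = representative_allele(normal.peaks[locus])
        rep_t[locus] = representative_allele(test.peaks[locus])
        shifts[locus], unstable[locus] = locus_shift(
            rep_t[locus], rep_n[locus], shift_threshold
        )
    call = classify_sample(list(unstable.values()), msi_high_min)
    return PanelResult(
        representative_normal=rep_n,
        representative_test=rep_t,
        shift=shifts,
        unstable=unstable,
        unstable_count=sum(unstable.values()),
        assayed_count=len(assayed),
        sample_call=call,
        flags=flags,
    )
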