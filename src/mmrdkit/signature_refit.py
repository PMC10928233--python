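"""96-channel trinucleotide mutation catalogs and signature refitting.

SNVs are classified by pyrimidine-normalized substitution (C>A, C>G, C>T,
T>A, T>C, T>G) and immediate 5'/3' flanking bases — 96 channels in the COSMIC
convention. A catalog is refit against a fixed reference signature matrix S
(96 x k, column-stochastic) by non-negative least squares:

    e* = argmin_{e >= 0} || c - S e ||_2

Exposures are reported both as mutation counts and as percentage
contributions; the fraction attributed to mismatch-repair-deficiency
signatures (Signature 6 in COSMIC v2; SBS6/15/21/26/44 in v3) is the
MMRD read-out.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: 96 channels in COSMIC order: substitution blocks, then 5' and 3' context.
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Default MMRD-hallmark signature ids per reference-matrix generation.
MMRD_SIGNATURES_V2 = frozenset({"Signature.6"})
MMRD_SIGNATURES_V3 = frozenset({"SBS6", "SBS15", "SBS21", "SBS26", "SBS44"})


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_for(context: str, alt: str) -> str:
    """COSMIC channel for a substitution given its 3-base reference context.

    ``context`` is the 5' base, the mutated reference base, and the 3' base on
    the forward strand; purine-reference substitutions are mapped to the
    reverse-complement strand.
    """
    context = context.upper()
    alt = alt.upper()
    if len(context) != 3:
        raise ValueError(f"context must be 3 bases, got {context!r}")
    if context[1] in "AG":
        context = revcomp(context)
        alt = revcomp(alt)
    ch = f"{context[0]}[{context[1]}>{alt}]{context[2]}"
    if ch not in _CHANNEL_INDEX:
        raise ValueError(f"invalid channel {ch!r} (ref==alt or non-ACGT base?)")
    return ch


_CHANNEL_INDEX = {ch: i for i, ch in enumerate(CHANNELS_96)}


@dataclass
class MutationCatalog:
    """Counts over the 96 trinucleotide channels."""

    counts: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(list(CHANNELS_96), fill_value=0).astype(int)
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def zeros(cls) -> "MutationCatalog":
        return cls(pd.Series(0, index=list(CHANNELS_96)))

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.counts.rename_axis("channel").rename("count").to_frame().to_csv(
            path, sep="\t"
        )

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.iloc[:, 0])


@dataclass
class SignatureMatrix:
    """96 x k column-stochastic reference signatures (COSMIC-style)."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        self.matrix = self.matrix.reindex(list(CHANNELS_96))
        if self.matrix.isna().any().any():
            raise ValueError("signature matrix is missing channels")
        if (self.matrix.values < 0).any():
            raise ValueError("negative signature entry")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-6)]
            raise ValueError(f"signature columns must sum to 1: {dict(bad)}")

    @property
    def signature_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "SignatureMatrix":
        """COSMIC download format: channel row id + one column per signature."""
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.matrix.rename_axis("channel").to_csv(path, sep="\t")


@dataclass
class RefitResult:
    """Non-negative exposures, their percentage breakdown, and fit quality."""

    exposures: pd.Series
    contribution_pct: pd.Series
    reconstruction: np.ndarray
    cosine: float
    residual_norm: float
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: Union[str, Path] | None = None) -> str:
        payload = {
            "exposures": {k: float(v) for k, v in self.exposures.items()},
            "contribution_pct": {k: float(v) for k, v in self.contribution_pct.items()},
            "cosine": self.cosine,
            "residual_norm": self.residual_norm,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _fetch_context(reference, contig: str, position: int) -> str | None:
    """3-base forward-strand context around a 1-based position, None at edges."""
    if isinstance(reference, Mapping):
        seq = reference[contig]
        if position < 2 or position > len(seq) - 1:
            return None
        return str(seq[position - 2 : position + 1]).upper()
    # pyfaidx.Fasta or similar random-access object
    rec = reference[contig]
    if position < 2 or position > len(rec) - 1:
        return None
    return str(rec[position - 2 : position + 1]).upper()


def build_catalog(snvs: Iterable, reference) -> MutationCatalog:
    """Channelize consensus SNVs against their reference context.

    ``snvs`` yields objects with contig / position (1-based) / ref / alt
    attributes; ``reference`` is a {contig: sequence} mapping, an open
    ``pyfaidx.Fasta``, or a FASTA path. A mismatch between a variant's ref
    allele and the reference base is an error; variants at contig edges
    (no flanking base) are skipped with a warning.
    """
    if isinstance(reference, (str, Path)):
        import pyfaidx

        reference = pyfaidx.Fasta(str(reference))
    counts = np.zeros(96, dtype=int)
    mismatches, skipped = [], 0
    for v in snvs:
        if len(v.ref) != 1 or len(v.alt) != 1:
            continue  # indels have no SBS channel
        ctx = _fetch_context(reference, v.contig, v.position)
        if ctx is None:
            skipped += 1
            continue
        if ctx[1] != v.ref.upper():
            mismatches.append(f"{v.contig}:{v.position} ref={v.ref} fasta={ctx[1]}")
            continue
        counts[_CHANNEL_INDEX[channel_for(ctx, v.alt)]] += 1
    if mismatches:
        raise ValueError(
            "ref allele mismatches with reference sequence: " + "; ".join(mismatches[:10])
        )
    if skipped:
        warnings.warn(f"{skipped} SNV(s) at contig edges lacked context; skipped")
    return MutationCatalog(pd.Series(counts, index=list(CHANNELS_96)))


def refit(catalog: MutationCatalog, signatures: SignatureMatrix) -> RefitResult:
    """Non-negative least-squares decomposition of a catalog onto signatures."""
    if catalog.total == 0:
        raise ValueError("cannot refit an empty catalog")
    S = signatures.matrix.values.astype(float)
    c = catalog.counts.values.astype(float)
    exposures, _ = nnls(S, c)
    recon = S @ exposures
    resid = float(np.linalg.norm(c - recon))
    denom = np.linalg.norm(c) * np.linalg.norm(recon)
    cosine = float(c @ recon / denom) if denom > 0 else 0.0
    total = exposures.sum()
    pct = 100.0 * exposures / total if total > 0 else np.zeros_like(exposures)
    rank = np.linalg.matrix_rank(S)
    return RefitResult(
        exposures=pd.Series(exposures, index=signatures.signature_ids),
        contribution_pct=pd.Series(pct, index=signatures.signature_ids),
        reconstruction=recon,
        cosine=cosine,
        residual_norm=resid,
        provenance={
            "method": "nnls",
            "rank_deficient": bool(rank < S.shape[1]),
        },
    )


def mmrd_signature_fraction(
    result: RefitResult, mmrd_ids: Sequence[str] | frozenset[str] = MMRD_SIGNATURES_V2
) -> float:
    """Summed percentage contribution of the MMRD-hallmark signatures."""
    unknown = set(mmrd_ids) - set(result.contribution_pct.index)
    if unknown:
        raise ValueError(f"unknown signature id(s): {sorted(unknown)}")
    return float(result.contribution_pct[list(mmrd_ids)].sum())
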