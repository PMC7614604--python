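"""Mutational-signature attribution of driver SNVs.

Single-base-substitution (SBS) signatures are probability distributions
over 96 trinucleotide substitution channels (pyrimidine-reference
convention: 6 substitution classes C>A, C>G, C>T, T>A, T>C, T>G, each in
16 flanking contexts).  Given a patient's signature exposures (activities)
and the 96-channel profiles of the active signatures, each observed clonal
driver SNV is assigned the posterior probability of having been generated
by each signature,

    P(signature s | channel c)  ∝  exposure_s * profile_s[c],

normalized to sum to one.  Per-patient aggregation and the tobacco-carrier
classification (a driver is smoking-attributable when the combined SBS4 +
SBS92 probability reaches 0.5) follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import UnattributableMutationError

__all__ = [
    "SBS96_CHANNELS",
    "SMOKING_SIGNATURES",
    "sbs96_channels",
    "channel_index",
    "SignatureProfile",
    "ExposureVector",
    "DriverSNV",
    "AttributionResult",
    "mutation_attribution",
    "aggregate_attribution",
    "smoking_probability",
    "classify_tobacco_carrier",
    "read_signature_catalog",
]

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Signatures attributed to tobacco smoking.
SMOKING_SIGNATURES = frozenset({"SBS4", "SBS92"})


def sbs96_channels() -> tuple[str, ...]:
    """The 96 channels in canonical order: substitution class major
    (C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank, then 3' flank,
    each alphabetical.  Channel 0 is ``A[C>A]A``, channel 95 ``T[T>G]T``."""
    return tuple(
        f"{five}[{sub}]{three}"
        for sub in _SUBSTITUTIONS
        for five in _BASES
        for three in _BASES
    )


SBS96_CHANNELS: tuple[str, ...] = sbs96_channels()
_CHANNEL_TO_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_index(trinucleotide: str, alt: str) -> int:
    """Map a reference trinucleotide and alternate base to a channel index.

    The middle base of ``trinucleotide`` is the reference allele.  Purine
    references are folded onto the reverse-complement strand so that every
    channel is pyrimidine-referenced (C or T), the COSMIC convention.

    >>> channel_index("ACA", "A")
    0
    >>> channel_index("TGT", "T")  # reverse complement of the above
    0
    """
    trinucleotide = trinucleotide.upper()
    alt = alt.upper()
    if len(trinucleotide) != 3 or any(b not in _COMPLEMENT for b in trinucleotide):
        raise ValueError(f"invalid trinucleotide {trinucleotide!r}")
    if alt not in _COMPLEMENT:
        raise ValueError(f"invalid alternate base {alt!r}")
    ref = trinucleotide[1]
    if alt == ref:
        raise ValueError("alternate base equals the reference base")
    if ref in ("A", "G"):  # fold purines onto the pyrimidine strand
        trinucleotide = _revcomp(trinucleotide)
        ref = trinucleotide[1]
        alt = _COMPLEMENT[alt]
    key = f"{trinucleotide[0]}[{ref}>{alt}]{trinucleotide[2]}"
    return _CHANNEL_TO_INDEX[key]


@dataclass(frozen=True)
class SignatureProfile:
    """A signature's probability distribution over the 96 channels."""

    signature_id: str
    channel_probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.channel_probs, dtype=float)
        object.__setattr__(self, "channel_probs", probs)
        if probs.shape != (96,):
            raise ValueError("channel_probs must have shape (96,)")
        if np.any(probs < 0):
            raise ValueError("channel probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("channel probabilities must sum to 1 within 1e-8")


@dataclass(frozen=True)
class ExposureVector:
    """Per-patient signature activities (non-negative, not all zero)."""

    patient_id: str
    exposures: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.exposures.values()):
            raise ValueError("exposures must be non-negative")
        if not any(v > 0 for v in self.exposures.values()):
            raise ValueError("at least one exposure must be positive")

    def active(self) -> dict[str, float]:
        """Signatures with strictly positive exposure."""
        return {s: v for s, v in self.exposures.items() if v > 0}


@dataclass(frozen=True)
class DriverSNV:
    """An observed clonal driver SNV with its trinucleotide channel."""

    patient_id: str
    gene: str
    channel: int

    def __post_init__(self) -> None:
        if not 0 <= self.channel < 96:
            raise ValueError("channel must lie in 0..95")

    @classmethod
    def from_context(
        cls, patient_id: str, gene: str, trinucleotide: str, alt: str
    ) -> "DriverSNV":
        return cls(patient_id, gene, channel_index(trinucleotide, alt))


@dataclass(frozen=True)
class AttributionResult:
    """Per-signature causal probabilities for one driver SNV."""

    per_signature_prob: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.per_signature_prob.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError("attribution probabilities must sum to 1 within 1e-8")
        if any(p < 0 for p in self.per_signature_prob.values()):
            raise ValueError("attribution probabilities must be non-negative")

    @property
    def smoking_prob(self) -> float:
        return smoking_probability(self)


def mutation_attribution(
    snv: DriverSNV,
    exposures: ExposureVector,
    catalog: Mapping[str, SignatureProfile] | Iterable[SignatureProfile],
) -> AttributionResult:
    """Attribute one driver SNV to the patient's active signatures.

    The unnormalized weight of signature ``s`` is
    ``exposure_s * channel_probs_s[snv.channel]``; weights are normalized
    to sum to one.  Signatures with zero exposure are dropped first.

    Raises
    ------
    UnattributableMutationError
        If every active signature has zero probability on the channel.
    """
    if not isinstance(catalog, Mapping):
        catalog = {p.signature_id: p for p in catalog}
    active = exposures.active()
    missing = set(active) - set(catalog)
    if missing:
        raise KeyError(f"active signatures missing from catalog: {sorted(missing)}")
    weights = {
        s: exposure * catalog[s].channel_probs[snv.channel]
        for s, exposure in active.items()
    }
    total = sum(weights.values())
    if total == 0:
        raise UnattributableMutationError(
            f"no active signature emits channel {snv.channel} "
            f"({SBS96_CHANNELS[snv.channel]}) for patient {snv.patient_id!r}"
        )
    return AttributionResult({s: w / total for s, w in weights.items()})


def aggregate_attribution(
    results: Sequence[AttributionResult], normalize: bool = False
) -> dict[str, float]:
    """Aggregate per-SNV attributions into per-signature totals.

    The total for signature ``s`` is the sum of its probabilities over all
    driver SNVs — the signature's overall contribution to driver
    mutations, in units of mutations.  With ``normalize=True`` the totals
    are divided by the number of SNVs, giving fractions that sum to one.
    """
    if not results:
        raise ValueError("cannot aggregate an empty list of attributions")
    totals: dict[str, float] = {}
    for res in results:
        for s, p in res.per_signature_prob.items():
            totals[s] = totals.get(s, 0.0) + p
    if normalize:
        n = len(results)
        totals = {s: v / n for s, v in totals.items()}
    return totals


def smoking_probability(
    result: AttributionResult,
    smoking_signatures: frozenset[str] | set[str] = SMOKING_SIGNATURES,
) -> float:
    """Probability mass the attribution places on smoking signatures."""
    return sum(
        p for s, p in result.per_signature_prob.items() if s in smoking_signatures
    )


def classify_tobacco_carrier(
    patient_snvs: Sequence[AttributionResult],
    smoking_signatures: frozenset[str] | set[str] = SMOKING_SIGNATURES,
    threshold: float = 0.5,
) -> str:
    """Classify a patient by tobacco-related driver carriage.

    ``"non-carrier"`` iff every driver SNV's smoking probability is
    strictly below ``threshold`` (0.5); ``"carrier"`` if any reaches it;
    ``"no-driver"`` for patients without driver SNVs.
    """
    if not patient_snvs:
        return "no-driver"
    if any(
        smoking_probability(r, smoking_signatures) >= threshold for r in patient_snvs
    ):
        return "carrier"
    return "non-carrier"


def read_signature_catalog(path) -> dict[str, SignatureProfile]:
    """Read a 96-row signature catalogue TSV (COSMIC text dialect).

    The file must have a channel column (named ``Type``, ``channel``,
    ``MutationType`` or similar, values like ``A[C>A]A``) and one column
    per signature.  Rows may be in any order; they are reindexed to the
    canonical channel order.
    """
    df = pd.read_csv(path, sep="\t")
    channel_col = None
    for cand in df.columns:
        if str(df[cand].iloc[0]) in _CHANNEL_TO_INDEX:
            channel_col = cand
            break
    if channel_col is None:
        raise ValueError("no channel column recognized in catalogue")
    df = df.set_index(channel_col)
    if set(df.index) != set(SBS96_CHANNELS):
        raise ValueError("catalogue must contain exactly the 96 SBS channels")
    df = df.loc[list(SBS96_CHANNELS)]
    return {
        str(col): SignatureProfile(str(col), df[col].to_numpy(dtype=float))
        for col in df.columns
    }
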