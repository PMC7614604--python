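"""Poisson-statistics quantification of droplet digital PCR (ddPCR) assays.

In ddPCR a reaction is partitioned into ~20,000 droplets and the target
concentration is recovered from the fraction of droplets that light up.
Because template molecules distribute over droplets approximately as a
Poisson process, the mean number of copies per droplet is ``-ln(1 - P/T)``
where ``P`` of ``T`` droplets are positive.  This module implements the
resulting estimators: target concentration in the input sample, variant
allele frequency (VAF), pooling of replicate wells, the minimum-droplet
positivity call, genome-equivalent accounting and the Poisson limit of
detection of a rare-mutation screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import optimize, stats

from .exceptions import SaturationError, UndefinedVAFError

__all__ = [
    "WellCount",
    "AssayConstants",
    "TargetQuant",
    "target_concentration",
    "compute_vaf",
    "merge_wells",
    "call_positive",
    "genome_equivalents",
    "limit_of_detection",
    "round_sig",
    "quantify_samples",
]


@dataclass(frozen=True)
class WellCount:
    """Droplet counts for one reaction well (or a pool of wells).

    Parameters
    ----------
    positives : int
        Number of positive droplets, ``P``.
    total : int
        Number of droplets analysed, ``T``.
    """

    positives: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total droplet count must be positive")
        if not 0 <= self.positives <= self.total:
            raise ValueError("positives must satisfy 0 <= P <= T")

    @property
    def fraction_positive(self) -> float:
        return self.positives / self.total


@dataclass(frozen=True)
class AssayConstants:
    """Volumetric constants of a ddPCR reaction, all in microlitres.

    Defaults follow the Bio-Rad QX200 geometry: droplet volume
    ``V_d = 0.85e-3`` ul and reaction volume ``V_r = 20`` ul.  The input
    volume ``V_i`` is the volume of input DNA sample loaded per reaction
    and has no universal default.
    """

    input_volume: float
    droplet_volume: float = 0.85e-3
    reaction_volume: float = 20.0

    def __post_init__(self) -> None:
        if min(self.input_volume, self.droplet_volume, self.reaction_volume) <= 0:
            raise ValueError("all volumes must be strictly positive")
        if self.input_volume > self.reaction_volume:
            raise ValueError("input volume cannot exceed reaction volume")


@dataclass(frozen=True)
class TargetQuant:
    """Quantification result for one sample-assay: concentrations in
    copies per ul of input sample and the VAF in percent."""

    variant_conc: float
    wildtype_conc: float
    vaf: float

    def __post_init__(self) -> None:
        if self.variant_conc < 0 or self.wildtype_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0 <= self.vaf <= 100:
            raise ValueError("VAF must lie in [0, 100] percent")


def target_concentration(well: WellCount, constants: AssayConstants) -> float:
    """Concentration of the target in the input sample, copies per ul.

    Implements ``C = -ln(1 - P/T) / V_d * V_r / V_i``: the Poisson mean
    per droplet, converted to copies per ul of reaction, and scaled back
    to the input sample volume.

    Raises
    ------
    SaturationError
        If every droplet is positive (``P == T``); the estimate diverges.
    """
    if well.positives == well.total:
        raise SaturationError(
            f"all {well.total} droplets positive; concentration not estimable"
        )
    lam = -math.log1p(-well.fraction_positive)
    return lam / constants.droplet_volume * constants.reaction_volume / constants.input_volume


def compute_vaf(variant_conc: float, wildtype_conc: float) -> float:
    """Variant allele frequency in percent: ``Cv / (Cv + Cw) * 100``."""
    if variant_conc < 0 or wildtype_conc < 0:
        raise ValueError("concentrations must be non-negative")
    denom = variant_conc + wildtype_conc
    if denom == 0:
        raise UndefinedVAFError("variant and wild-type concentrations both zero")
    return variant_conc / denom * 100.0


def merge_wells(wells: Iterable[WellCount]) -> WellCount:
    """Pool replicate wells by summing positives and totals.

    The study design runs each sample-assay across 4 reaction wells and
    reports a single pooled result; pooling precedes quantification and
    the positivity call.
    """
    wells = list(wells)
    if not wells:
        raise ValueError("cannot merge an empty list of wells")
    return WellCount(
        positives=sum(w.positives for w in wells),
        total=sum(w.total for w in wells),
    )


def call_positive(merged_variant: WellCount, min_droplets: int = 3) -> bool:
    """Positivity rule: at least ``min_droplets`` positive droplets
    (default 3) are required to call a sample positive."""
    return merged_variant.positives >= min_droplets


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures with half-even ties."""
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if x == 0 or not math.isfinite(x):
        return float(x)
    # float formatting rounds half-to-even, the convention used throughout
    return float(f"{x:.{sig_figs - 1}e}")


def genome_equivalents(mass_ng: float, haploid_mass_pg: float = 3.3) -> float:
    """Haploid genome copies in ``mass_ng`` nanograms of DNA.

    With the standard 3.3 pg human haploid genome mass, 500 ng corresponds
    to ~151,515 copies (150,000 to 2 significant figures; see
    :func:`round_sig`).
    """
    if haploid_mass_pg <= 0:
        raise ValueError("haploid genome mass must be positive")
    if mass_ng < 0:
        raise ValueError("DNA mass must be non-negative")
    return mass_ng * 1000.0 / haploid_mass_pg


def limit_of_detection(
    copies_screened: float,
    min_droplets: int = 3,
    detect_prob: float = 0.95,
) -> float:
    """Limit of detection of a rare-mutation screen, in percent VAF.

    Defined as the VAF whose expected mutant-copy load ``lambda*`` gives
    probability ``detect_prob`` of observing at least ``min_droplets``
    positive droplets under Poisson counting:
    ``P(Poisson(lambda*) >= min_droplets) = detect_prob``, solved
    numerically, then ``LOD = lambda* / copies_screened * 100``.

    At 150,000 genome equivalents and the >=3-droplet rule this gives
    ~0.0042%, i.e. 0.004% to one significant figure.
    """
    if copies_screened <= 0:
        raise ValueError("copies_screened must be positive")
    if not 0 < detect_prob < 1:
        raise ValueError("detect_prob must lie in (0, 1)")
    if min_droplets < 0:
        raise ValueError("min_droplets must be non-negative")
    if min_droplets == 0:
        return 0.0

    def tail(lam: float) -> float:
        return stats.poisson.sf(min_droplets - 1, lam) - detect_prob

    # tail is monotone increasing in lam; bracket then solve
    hi = float(min_droplets)
    while tail(hi) < 0:
        hi *= 2.0
    lam_star = optimize.brentq(tail, 1e-12, hi, xtol=1e-12, rtol=1e-12)
    return lam_star / copies_screened * 100.0


def quantify_samples(
    wells: pd.DataFrame,
    constants: AssayConstants | None = None,
    min_droplets: int = 3,
) -> pd.DataFrame:
    """Quantify a long-format well table into per-sample-assay results.

    Parameters
    ----------
    wells : DataFrame
        Columns ``sample_id, assay_id, well_id, target, positives, total``
        and optionally ``input_volume_ul``; ``target`` is ``variant`` or
        ``wildtype``.  Replicate wells are pooled per sample-assay-target
        before quantification.
    constants : AssayConstants, optional
        Volumetric constants; if omitted, ``input_volume_ul`` must be a
        column (constant within each sample-assay).
    min_droplets : int
        Positivity threshold applied to the pooled variant counts.

    Returns
    -------
    DataFrame with one row per (sample_id, assay_id) and columns
    ``variant_positives, wildtype_positives, total_droplets,
    variant_conc, wildtype_conc, vaf_pct, positive_call``.
    """
    required = {"sample_id", "assay_id", "well_id", "target", "positives", "total"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    bad = set(wells["target"]) - {"variant", "wildtype"}
    if bad:
        raise ValueError(f"unknown target labels: {sorted(bad)}")

    rows = []
    for (sample, assay), grp in wells.groupby(["sample_id", "assay_id"], sort=True):
        if constants is not None:
            consts = constants
        else:
            vols = grp["input_volume_ul"].unique()
            if len(vols) != 1:
                raise ValueError(
                    f"input_volume_ul not constant within sample {sample!r} assay {assay!r}"
                )
            consts = AssayConstants(input_volume=float(vols[0]))
        merged = {
            target: merge_wells(
                WellCount(int(r.positives), int(r.total))
                for r in sub.itertuples()
            )
            for target, sub in grp.groupby("target")
        }
        var = merged.get("variant", None)
        wt = merged.get("wildtype", None)
        var_conc = target_concentration(var, consts) if var else 0.0
        wt_conc = target_concentration(wt, consts) if wt else 0.0
        try:
            vaf = compute_vaf(var_conc, wt_conc)
        except UndefinedVAFError:
            vaf = float("nan")
        rows.append(
            {
                "sample_id": sample,
                "assay_id": assay,
                "variant_positives": var.positives if var else 0,
                "wildtype_positives": wt.positives if wt else 0,
                "total_droplets": (var.total if var else 0) + (wt.total if wt else 0),
                "variant_conc": var_conc,
                "wildtype_conc": wt_conc,
                "vaf_pct": vaf,
                "positive_call": call_positive(var, min_droplets) if var else False,
            }
        )
    return pd.DataFrame(rows)
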