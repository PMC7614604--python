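"""Seeded generators for every input the analysis modules consume.

Each generator emulates the statistical structure of one real data
source — Poisson droplet occupancy at a known concentration, per-cell
mutation events with a copy-threshold detection rule, mixture sampling of
trinucleotide channels from signature profiles, clustered spatial point
patterns with background noise, planted tumour-shared contamination in
variant tables, and linear PM2.5-incidence relations with heteroscedastic
test counts — and emits the ground truth alongside, so every downstream
module has a parameter-recovery test that needs no external download.

All randomness flows through a single ``numpy.random.Generator`` passed
explicitly (an integer seed is also accepted); a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ddpcr import AssayConstants, WellCount
from .prevalence import ScreenDesign, ScreenObservation
from .signatures import DriverSNV, ExposureVector, SignatureProfile

__all__ = [
    "gen_droplets",
    "gen_cohort_screen",
    "gen_signature_mutations",
    "gen_cell_field",
    "gen_normal_cohort",
    "gen_region_table",
]


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_droplets(
    true_conc: float,
    constants: AssayConstants,
    n_wells: int = 4,
    droplets_per_well: int = 20_000,
    seed: int | np.random.Generator | None = None,
) -> list[WellCount]:
    """Simulate droplet counts at a known input-sample concentration.

    Each droplet is positive with ``p = 1 - exp(-C * V_i / V_r * V_d)``
    (the Poisson occupancy of a droplet given ``C`` copies/ul of input
    sample diluted into the reaction), so well counts are
    Binomial(droplets_per_well, p).
    """
    if true_conc < 0:
        raise ValueError("true concentration must be non-negative")
    if n_wells < 1 or droplets_per_well < 1:
        raise ValueError("well and droplet counts must be >= 1")
    rng = _as_rng(seed)
    lam = (
        true_conc
        * constants.input_volume
        / constants.reaction_volume
        * constants.droplet_volume
    )
    p = -np.expm1(-lam)
    positives = rng.binomial(droplets_per_well, p, size=n_wells)
    return [WellCount(int(k), droplets_per_well) for k in positives]


def gen_cohort_screen(
    rate: float,
    design: ScreenDesign = ScreenDesign(),
    seed: int | np.random.Generator | None = None,
) -> tuple[ScreenObservation, pd.DataFrame]:
    """Simulate a cohort screen and return the per-test truth table.

    The truth table has one row per sample-assay test with the latent
    mutant-copy count and the resulting positivity call; the observation
    is the total positive-test count, exactly as
    :func:`clonoprev.prevalence.simulate_screen` would report it.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = _as_rng(seed)
    lam = rate * design.copies_per_assay
    copies = rng.poisson(lam, size=design.n_tests)
    positive = copies >= design.positivity_threshold
    truth = pd.DataFrame(
        {
            "sample_index": np.repeat(
                np.arange(design.n_samples), design.assays_per_sample
            ),
            "assay_index": np.tile(
                np.arange(design.assays_per_sample), design.n_samples
            ),
            "mutant_copies": copies,
            "positive": positive,
        }
    )
    return ScreenObservation(int(positive.sum())), truth


def gen_signature_mutations(
    catalog: Mapping[str, SignatureProfile],
    exposures: ExposureVector,
    n: int,
    seed: int | np.random.Generator | None = None,
    gene: str = "SYNTH",
) -> tuple[list[DriverSNV], np.ndarray]:
    """Sample driver SNVs from the generative mixture of signatures.

    The latent causal signature is drawn proportional to the (normalized)
    exposures; the channel is then drawn from that signature's 96-channel
    profile.  Returns the SNVs and the latent causal signature labels.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = _as_rng(seed)
    active = exposures.active()
    missing = set(active) - set(catalog)
    if missing:
        raise KeyError(f"active signatures missing from catalog: {sorted(missing)}")
    sig_ids = sorted(active)
    weights = np.array([active[s] for s in sig_ids], dtype=float)
    weights = weights / weights.sum()
    causal_idx = rng.choice(len(sig_ids), size=n, p=weights)
    snvs = []
    causal = np.array([sig_ids[i] for i in causal_idx], dtype=object)
    for i in causal_idx:
        channel = int(rng.choice(96, p=catalog[sig_ids[i]].channel_probs))
        snvs.append(DriverSNV(exposures.patient_id, gene, channel))
    return snvs, causal


def gen_cell_field(
    n_clusters: int,
    sizes: Sequence[int] | int,
    spread: float,
    extent: tuple[float, float] = (2000.0, 2000.0),
    background_rate: float = 0.0,
    min_separation: float = 140.0,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Plant Gaussian cell clusters on a rectangular field.

    Cluster centres are drawn uniformly on ``extent`` with rejection until
    all pairwise separations exceed ``min_separation``; members scatter
    isotropically with standard deviation ``spread`` around their centre;
    background cells arrive as a homogeneous Poisson process with
    intensity ``background_rate`` per unit area.

    Returns ``(points, labels)`` where ``labels[i]`` is the planted
    cluster index of point ``i`` (-1 for background).  For exact recovery
    by DBSCAN at radius ``eps`` use ``spread <= eps/4`` and
    ``min_separation >= 4 * eps``.
    """
    if isinstance(sizes, int):
        sizes = [sizes] * n_clusters
    sizes = list(sizes)
    if len(sizes) != n_clusters:
        raise ValueError("one size per cluster is required")
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be >= 1")
    if spread < 0 or background_rate < 0:
        raise ValueError("spread and background_rate must be non-negative")
    rng = _as_rng(seed)
    width, height = extent

    centres: list[np.ndarray] = []
    attempts = 0
    while len(centres) < n_clusters:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_clusters} centres at separation "
                f"{min_separation} within {max_attempts} attempts"
            )
        cand = rng.uniform((0, 0), (width, height))
        attempts += 1
        if all(np.linalg.norm(cand - c) > min_separation for c in centres):
            centres.append(cand)

    points, labels = [], []
    for idx, (centre, size) in enumerate(zip(centres, sizes)):
        points.append(centre + rng.normal(0.0, spread, size=(size, 2)))
        labels.extend([idx] * size)
    n_background = rng.poisson(background_rate * width * height)
    if n_background:
        points.append(rng.uniform((0, 0), (width, height), size=(n_background, 2)))
        labels.extend([-1] * n_background)
    if not points:
        return np.empty((0, 2)), np.empty(0, dtype=int)
    return np.vstack(points), np.asarray(labels, dtype=int)


def gen_normal_cohort(
    n_patients: int = 195,
    prevalence: float = 0.19,
    contamination_prob: float = 0.1,
    mean_vaf: float = 0.05,
    seed: int | np.random.Generator | None = None,
    variants: Sequence[tuple[str, str]] = (
        ("EGFR", "L858R"),
        ("EGFR", "ex19del"),
        ("EGFR", "L861Q"),
        ("EGFR", "G719S"),
        ("EGFR", "S768I"),
    ),
) -> dict[str, pd.DataFrame]:
    """Plant a matched normal/tumour variant-call cohort.

    Each patient carries a true normal-tissue driver with probability
    ``prevalence`` (variant drawn uniformly from ``variants``; VAF
    exponential with mean ``mean_vaf`` percent, the rare-clone regime).
    Independently, with probability ``contamination_prob`` a patient's
    normal tissue additionally shows a variant that is also present in
    the matched tumour — the planted contamination the filter must
    remove.  Defaults mirror the primary screening cohort (195 patients,
    ~19% prevalence).

    Returns a dict with ``normal_calls``, ``tumour_calls``, ``roster``
    and a ``truth`` sidecar labelling each normal call as planted-real or
    planted-contamination.
    """
    if not 0 <= prevalence <= 1 or not 0 <= contamination_prob <= 1:
        raise ValueError("prevalence and contamination_prob must lie in [0, 1]")
    rng = _as_rng(seed)
    variants = list(variants)
    normal_rows, tumour_rows, truth_rows, roster_rows = [], [], [], []
    for i in range(n_patients):
        patient = f"P{i:04d}"
        sample = f"{patient}_N1"
        roster_rows.append(
            {
                "sample_id": sample,
                "patient_id": patient,
                "cohort": "synthetic",
                "smoking_status": "smoker" if rng.random() < 0.5 else "never",
            }
        )
        carried: set[tuple[str, str]] = set()
        if rng.random() < prevalence:
            gene, key = variants[rng.integers(len(variants))]
            carried.add((gene, key))
            normal_rows.append(
                {
                    "patient_id": patient,
                    "sample_id": sample,
                    "tissue": "normal",
                    "gene": gene,
                    "variant_key": key,
                    "vaf": float(rng.exponential(mean_vaf)),
                    "assay": "ddpcr",
                }
            )
            truth_rows.append(
                {"patient_id": patient, "gene": gene, "variant_key": key,
                 "planted": "real"}
            )
        if rng.random() < contamination_prob:
            remaining = [v for v in variants if v not in carried] or variants
            gene, key = remaining[rng.integers(len(remaining))]
            normal_rows.append(
                {
                    "patient_id": patient,
                    "sample_id": sample,
                    "tissue": "normal",
                    "gene": gene,
                    "variant_key": key,
                    "vaf": float(rng.exponential(mean_vaf)),
                    "assay": "ddpcr",
                }
            )
            tumour_rows.append(
                {
                    "patient_id": patient,
                    "sample_id": f"{patient}_T1",
                    "tissue": "tumour",
                    "region": f"R{rng.integers(1, 4)}",
                    "gene": gene,
                    "variant_key": key,
                    "vaf": float(rng.uniform(5, 50)),
                    "assay": "miseq",
                }
            )
            truth_rows.append(
                {"patient_id": patient, "gene": gene, "variant_key": key,
                 "planted": "contamination"}
            )
    columns = dict(
        normal_calls=["patient_id", "sample_id", "tissue", "gene", "variant_key",
                      "vaf", "assay"],
        tumour_calls=["patient_id", "sample_id", "tissue", "region", "gene",
                      "variant_key", "vaf", "assay"],
        roster=["sample_id", "patient_id", "cohort", "smoking_status"],
        truth=["patient_id", "gene", "variant_key", "planted"],
    )
    frames = dict(
        normal_calls=pd.DataFrame(normal_rows, columns=columns["normal_calls"]),
        tumour_calls=pd.DataFrame(tumour_rows, columns=columns["tumour_calls"]),
        roster=pd.DataFrame(roster_rows, columns=columns["roster"]),
        truth=pd.DataFrame(truth_rows, columns=columns["truth"]),
    )
    return frames


def gen_region_table(
    n_regions: int = 20,
    intercept: float = 2.0,
    slope: float = 0.6,
    noise_sd: float = 0.5,
    pm_range: tuple[float, float] = (5.0, 15.0),
    mean_tests: float = 1000.0,
    incidence: float = 60.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Regions with a linear PM2.5 -> EGFR-mutant-incidence relation.

    PM2.5 is uniform on ``pm_range``; the EGFR-mutant incidence per
    100,000 is ``intercept + slope * pm + Normal(0, noise_sd)`` (floored
    at a small positive value); per-region EGFR test totals are Poisson
    with mean ``mean_tests`` (the heteroscedastic weights of the weighted
    correlation) and abnormal counts are Binomial with the implied
    mutation rate ``egfrm_incidence / incidence``.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    rng = _as_rng(seed)
    pm = rng.uniform(pm_range[0], pm_range[1], size=n_regions)
    egfrm = intercept + slope * pm + rng.normal(0.0, noise_sd, size=n_regions)
    egfrm = np.maximum(egfrm, 1e-3)
    mutation_rate = np.clip(egfrm / incidence, 0.0, 1.0)
    tests = np.maximum(rng.poisson(mean_tests, size=n_regions), 1)
    abnormal = rng.binomial(tests, mutation_rate)
    return pd.DataFrame(
        {
            "region_id": [f"region_{i:02d}" for i in range(n_regions)],
            "pm25": pm,
            "incidence": incidence,
            "egfrm_incidence_true": egfrm,
            "egfr_abnormal": abnormal,
            "egfr_normal": tests - abnormal,
        }
    )
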