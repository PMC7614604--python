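"""Per-cell oncogenic-mutation prevalence by approximate Bayesian computation.

A cohort-wide rare-mutation screen tests ``n_samples`` tissue samples with
``assays_per_sample`` mutation-specific ddPCR assays, each interrogating
``copies_per_assay`` genome equivalents and calling a test positive when at
least ``positivity_threshold`` mutant copies are present.  If every cell
carries a given mutation independently with per-cell rate ``mu``, the
mutant-copy count of one test is Poisson(``mu * copies_per_assay``) and the
number of positive tests in the cohort is Binomial with the corresponding
Poisson tail probability.

:class:`MutationPrevalenceModel` inverts this generative model with
rejection ABC: per-cell rates are proposed from a log-uniform prior,
cohorts are simulated, and proposals whose simulated positive-test count
falls within ``tolerance`` of the observed count are retained as posterior
draws.  :class:`MutationPrevalenceResults` summarizes the accepted draws
(median point estimate, equal-tailed credible interval, "1 in N" per-cell
frequencies).

The module-level functions :func:`simulate_screen`, :func:`abc_infer`,
:func:`posterior_summary` and :func:`per_cell_frequency` expose the same
machinery functionally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyPosteriorError

__all__ = [
    "ScreenDesign",
    "ScreenObservation",
    "RatePrior",
    "MutationPrevalenceModel",
    "MutationPrevalenceResults",
    "simulate_screen",
    "abc_infer",
    "posterior_summary",
    "per_cell_frequency",
]


@dataclass(frozen=True)
class ScreenDesign:
    """Geometry of a cohort screen.

    Defaults are the study design: 253 samples, 5 mutation-specific
    assays per sample, ~150,000 genome equivalents per sample-assay, and
    the >=3-copy positivity rule.
    """

    n_samples: int = 253
    assays_per_sample: int = 5
    copies_per_assay: float = 150_000.0
    positivity_threshold: int = 3

    def __post_init__(self) -> None:
        if min(self.n_samples, self.assays_per_sample) < 1:
            raise ValueError("sample and assay counts must be >= 1")
        if self.copies_per_assay < 1:
            raise ValueError("copies_per_assay must be >= 1")
        if self.positivity_threshold < 0:
            raise ValueError("positivity_threshold must be >= 0")

    @property
    def n_tests(self) -> int:
        return self.n_samples * self.assays_per_sample

    def positive_probability(self, rate: float) -> float:
        """P(one test is positive) = P(Poisson(rate * copies) >= threshold)."""
        lam = rate * self.copies_per_assay
        return float(stats.poisson.sf(self.positivity_threshold - 1, lam))


@dataclass(frozen=True)
class ScreenObservation:
    """Observed summary of a cohort screen: total positive tests."""

    positive_tests: int

    def __post_init__(self) -> None:
        if self.positive_tests < 0:
            raise ValueError("positive_tests must be >= 0")


@dataclass(frozen=True)
class RatePrior:
    """Log-uniform prior on the per-cell per-mutation-type rate."""

    low: float = 1e-9
    high: float = 1e-5

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("prior must satisfy 0 < low < high")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        log_lo, log_hi = np.log(self.low), np.log(self.high)
        return np.exp(rng.uniform(log_lo, log_hi, size=n))

    @property
    def median(self) -> float:
        return float(np.sqrt(self.low * self.high))


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_screen(
    rate: float,
    design: ScreenDesign = ScreenDesign(),
    seed: int | np.random.Generator | None = None,
) -> ScreenObservation:
    """Simulate one cohort screen at per-cell rate ``rate``.

    Each of the ``design.n_tests`` sample-assay tests draws a mutant-copy
    count from Poisson(``rate * copies_per_assay``) and is positive iff
    the count reaches ``positivity_threshold``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = _as_rng(seed)
    lam = rate * design.copies_per_assay
    copies = rng.poisson(lam, size=design.n_tests)
    return ScreenObservation(int(np.sum(copies >= design.positivity_threshold)))


def _simulate_positive_counts(
    rates: np.ndarray, design: ScreenDesign, rng: np.random.Generator
) -> np.ndarray:
    """Positive-test totals for a batch of proposed rates.

    Uses the exact marginal: the positive-test total of n_tests
    independent Poisson-threshold tests is Binomial(n_tests, p(rate)).
    """
    p = stats.poisson.sf(
        design.positivity_threshold - 1, rates * design.copies_per_assay
    )
    return rng.binomial(design.n_tests, p)


def per_cell_frequency(rate: float, k_mutation_types: int = 5) -> dict[str, float]:
    """Report a per-cell rate as "1 in N" frequencies.

    Returns the raw probabilities and their reciprocals, both for a single
    mutation type (``per_mutation``) and for carrying any of
    ``k_mutation_types`` independent mutation types
    (``any_mutation = 1 - (1 - rate)**k``).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if k_mutation_types < 1:
        raise ValueError("k_mutation_types must be >= 1")
    if rate == 0:
        warnings.warn("rate is zero; per-cell frequencies are infinite", stacklevel=2)
        return {
            "per_mutation_prob": 0.0,
            "per_mutation_one_in": float("inf"),
            "any_mutation_prob": 0.0,
            "any_mutation_one_in": float("inf"),
        }
    any_prob = -np.expm1(k_mutation_types * np.log1p(-rate))
    return {
        "per_mutation_prob": rate,
        "per_mutation_one_in": 1.0 / rate,
        "any_mutation_prob": float(any_prob),
        "any_mutation_one_in": float(1.0 / any_prob),
    }


class MutationPrevalenceModel:
    """Rejection-ABC model for the per-cell oncogenic-mutation rate.

    Parameters
    ----------
    observed : ScreenObservation or int
        Observed number of positive sample-assay tests.
    design : ScreenDesign
        Screening geometry simulated under each proposed rate.
    prior : RatePrior
        Log-uniform prior on the per-cell per-mutation-type rate.

    Examples
    --------
    >>> model = MutationPrevalenceModel(42)
    >>> res = model.fit(n_sims=50_000, seed=7)
    >>> 1e-6 < res.rate < 1e-5
    True
    """

    def __init__(
        self,
        observed: ScreenObservation | int,
        design: ScreenDesign = ScreenDesign(),
        prior: RatePrior = RatePrior(),
    ) -> None:
        if isinstance(observed, int):
            observed = ScreenObservation(observed)
        if observed.positive_tests > design.n_tests:
            raise ValueError("observed positives exceed the number of tests")
        self.observed = observed
        self.design = design
        self.prior = prior

    def simulate(
        self, rate: float, seed: int | np.random.Generator | None = None
    ) -> ScreenObservation:
        """Forward-simulate the screen under this model's design."""
        return simulate_screen(rate, self.design, seed)

    def fit(
        self,
        n_sims: int = 100_000,
        tolerance: int = 0,
        seed: int | np.random.Generator | None = None,
    ) -> "MutationPrevalenceResults":
        """Run rejection ABC and return the posterior results object.

        A proposed rate is accepted iff its simulated positive-test total
        differs from the observed total by at most ``tolerance`` tests
        (default 0: exact-count rejection).
        """
        if n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        rng = _as_rng(seed)
        rates = self.prior.sample(n_sims, rng)
        sim = _simulate_positive_counts(rates, self.design, rng)
        accepted = rates[np.abs(sim - self.observed.positive_tests) <= tolerance]
        if accepted.size == 0:
            raise EmptyPosteriorError(
                f"0 of {n_sims} proposals accepted at tolerance {tolerance}; "
                "increase tolerance or n_sims"
            )
        return MutationPrevalenceResults(
            model=self,
            accepted_rates=np.sort(accepted),
            n_proposed=n_sims,
            tolerance=tolerance,
        )


@dataclass
class MutationPrevalenceResults:
    """Posterior over the per-cell mutation rate from rejection ABC."""

    model: MutationPrevalenceModel
    accepted_rates: np.ndarray
    n_proposed: int
    tolerance: int
    _level: float = field(default=0.95, repr=False)

    @property
    def n_accepted(self) -> int:
        return int(self.accepted_rates.size)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed

    @property
    def rate(self) -> float:
        """Posterior median per-cell per-mutation-type rate."""
        return float(np.median(self.accepted_rates))

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed credible interval (linear-interpolation quantiles)."""
        if not 0 < level < 1:
            raise ValueError("level must lie in (0, 1)")
        alpha = 1.0 - level
        lo, hi = np.quantile(self.accepted_rates, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)

    # alias used in the Bayesian literature
    credible_interval = conf_int

    def per_cell_frequency(self, k_mutation_types: int = 5) -> dict[str, float]:
        """Per-cell "1 in N" frequencies at the posterior median rate."""
        return per_cell_frequency(self.rate, k_mutation_types)

    def to_frame(self) -> pd.DataFrame:
        """Accepted posterior draws, one per row."""
        return pd.DataFrame({"rate": self.accepted_rates})

    def summary(self, level: float = 0.95, k_mutation_types: int = 5) -> str:
        """Plain-text summary table of the fit."""
        lo, hi = self.conf_int(level)
        freq = self.per_cell_frequency(k_mutation_types)
        d = self.model.design
        per_mut = "1 in {:,.0f}".format(freq["per_mutation_one_in"])
        any_mut = "1 in {:,.0f}".format(freq["any_mutation_one_in"])
        rows = [
            ("Observed positive tests", str(self.model.observed.positive_tests)),
            ("Tests (samples x assays)", f"{d.n_samples} x {d.assays_per_sample}"),
            ("Copies per assay", f"{d.copies_per_assay:,.0f}"),
            ("Positivity threshold (copies)", str(d.positivity_threshold)),
            ("Proposals / accepted", f"{self.n_proposed} / {self.n_accepted}"),
            ("Tolerance (tests)", str(self.tolerance)),
            ("---", ""),
            ("Posterior median rate", f"{self.rate:.3e}"),
            (f"{level:.0%} credible interval", f"[{lo:.3e}, {hi:.3e}]"),
            ("Per-mutation frequency", per_mut),
            (f"Any-of-{k_mutation_types} frequency", any_mut),
        ]
        width = 56
        lines = ["Mutation prevalence (rejection ABC)", "=" * width]
        for name, value in rows:
            if name == "---":
                lines.append("-" * width)
            else:
                lines.append(f"{name:<30}{value:>{width - 30}}")
        lines.append("=" * width)
        return "\n".join(lines)

    def plot_posterior(self, ax=None, bins: int = 40):
        """Histogram of accepted rates on a log axis, with the median and
        credible-interval bounds marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        edges = np.geomspace(
            self.accepted_rates.min(), self.accepted_rates.max(), bins + 1
        )
        ax.hist(self.accepted_rates, bins=edges, color="steelblue", alpha=0.8)
        lo, hi = self.conf_int()
        ax.axvline(self.rate, color="k", lw=1.5, label="posterior median")
        for v in (lo, hi):
            ax.axvline(v, color="k", lw=1.0, ls="--")
        ax.set_xscale("log")
        ax.set_xlabel("per-cell mutation rate")
        ax.set_ylabel("accepted draws")
        ax.legend()
        return ax


def abc_infer(
    observed: ScreenObservation | int,
    design: ScreenDesign = ScreenDesign(),
    prior: RatePrior = RatePrior(),
    n_sims: int = 100_000,
    tolerance: int = 0,
    seed: int | np.random.Generator | None = None,
) -> MutationPrevalenceResults:
    """Functional wrapper: build the model and fit in one call."""
    return MutationPrevalenceModel(observed, design, prior).fit(
        n_sims=n_sims, tolerance=tolerance, seed=seed
    )


def posterior_summary(
    posterior: MutationPrevalenceResults, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Point estimate (median) and equal-tailed interval of a posterior."""
    if posterior.n_accepted == 0:
        raise EmptyPosteriorError("posterior has no accepted draws")
    return posterior.rate, posterior.conf_int(level)
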