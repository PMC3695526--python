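"""Experiment-design calculators for saturation-mutagenesis screens.

Two questions dominate the design of a random-mutagenesis sort-seq screen:

* how many transformants are needed so that every possible substitution of an
  L-nt target is sampled at least k times (a coupon-collector problem over
  the 3L single or 9*C(L,2) double substitutions), and
* how long a read can be before per-base call errors make whole-read accuracy
  collapse: with per-base accuracy 1 - 10**(-q/10), the chance that an L-nt
  read is entirely correct is (1 - 10**(-q/10))**L.

Both closed forms and seeded Monte-Carlo simulators are provided; the
simulators draw transformants i.i.d. uniformly over the mutation space
(an optional weight vector admits non-uniform mutational spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def error_free_fraction(q: float, L: int) -> float:
    """Probability that every base of an L-nt read is called correctly.

    ``(1 - 10**(-q/10))**L`` for phred score q; equals 1 at L = 0.
    """
    if L < 0:
        raise ValueError(f"length must be non-negative, got {L}")
    if q < 0:
        raise ValueError(f"phred score must be non-negative, got {q}")
    per_base = 1.0 - 10.0 ** (-q / 10.0)
    return float(per_base**L)


def mutation_space_size(L: int, order: str = "single") -> int:
    """Number of distinct mutants: 3L singles, or 9*C(L,2) doubles.

    A double mutant carries substitutions at two *distinct* positions (a
    position holds one base), hence 9*C(L,2) rather than C(3L,2).
    """
    if order == "single":
        return 3 * L
    if order == "double":
        return 9 * (L * (L - 1) // 2)
    raise ValueError(f"order must be 'single' or 'double', got {order!r}")


def expected_coverage_fraction(L: int, n: int, k: int, order: str = "single") -> float:
    """Expected fraction of the mutation space drawn >= k times in n draws.

    Under i.i.d. uniform draws each mutant is hit Binomial(n, 1/M) times, so
    the per-mutant marginal (= the expected fraction by linearity) is
    ``1 - BinomCDF(k-1; n, 1/M)``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if k < 1:
        raise ValueError("k must be >= 1")
    M = mutation_space_size(L, order)
    if M == 0:
        raise ValueError(f"empty mutation space for L={L}, order={order}")
    return float(stats.binom.sf(k - 1, n, 1.0 / M))


@dataclass
class CoverageSimResult:
    """Per-run coverage fractions from :func:`simulate_coverage`."""

    L: int
    n_transformants: int
    order: str
    k: int
    per_run_fractions: np.ndarray
    seed: int | None

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_run_fractions))

    def summary(self) -> dict:
        """Boxplot-style statistics of the per-run coverage fractions."""
        q1, med, q3 = np.percentile(self.per_run_fractions, [25, 50, 75])
        return {
            "L": self.L,
            "n_transformants": self.n_transformants,
            "order": self.order,
            "k": self.k,
            "n_runs": int(len(self.per_run_fractions)),
            "mean": self.mean,
            "min": float(np.min(self.per_run_fractions)),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(np.max(self.per_run_fractions)),
            "analytic_mean": expected_coverage_fraction(
                self.L, self.n_transformants, self.k, self.order
            ),
        }


def _draw_counts(rng: np.random.Generator, M: int, n: int, weights) -> np.ndarray:
    if weights is None:
        draws = rng.integers(0, M, size=n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (M,):
            raise ValueError(f"weights must have length {M}")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative and sum to > 0")
        draws = rng.choice(M, size=n, p=w / w.sum())
    return np.bincount(draws, minlength=M)


def simulate_coverage(
    L: int,
    n_transformants: int,
    n_runs: int,
    k: int = 1,
    order: str = "single",
    seed: int | np.random.Generator = None,
    weights=None,
) -> CoverageSimResult:
    """Monte-Carlo coverage of the mutation space by random transformants.

    Each run draws ``n_transformants`` mutants i.i.d. from the space of
    ``mutation_space_size(L, order)`` mutants (uniform unless ``weights`` is
    given) and records the fraction of the space covered at least ``k``
    times.  The seed is mandatory; the same seed reproduces every run
    bit-for-bit.
    """
    if seed is None:
        raise ValueError("a seed (or Generator) is required for reproducibility")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = mutation_space_size(L, order)
    if M == 0:
        raise ValueError(f"empty mutation space for L={L}, order={order}")
    fractions = np.empty(n_runs, dtype=float)
    for r in range(n_runs):
        counts = _draw_counts(rng, M, n_transformants, weights)
        fractions[r] = float(np.mean(counts >= k))
    return CoverageSimResult(
        L=L,
        n_transformants=n_transformants,
        order=order,
        k=k,
        per_run_fractions=fractions,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def prob_full_coverage(
    L: int,
    n: int,
    n_runs: int,
    seed: int | np.random.Generator = None,
    order: str = "single",
) -> float:
    """Monte-Carlo probability that all mutants are seen at least once.

    Estimated as the fraction of runs in which every one of the
    ``mutation_space_size(L, order)`` mutants occurs among the n uniform
    draws.  Zero whenever n < M (pigeonhole).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seed is None:
        raise ValueError("a seed (or Generator) is required for reproducibility")
    M = mutation_space_size(L, order)
    if n < M:
        return 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        counts = _draw_counts(rng, M, n, None)
        hits += bool((counts >= 1).all())
    return hits / n_runs


def exact_full_coverage_probability(M: int, n: int) -> float:
    """Exact coupon-collector probability that n uniform draws cover all M classes.

    Inclusion-exclusion: sum_j (-1)^j C(M,j) (1 - j/M)^n.  Intended as an
    analytic cross-check for the Monte-Carlo estimator at small M.
    """
    if n < M:
        return 0.0
    j = np.arange(M + 1)
    from scipy.special import comb

    terms = (-1.0) ** j * comb(M, j) * (1.0 - j / M) ** n
    return float(max(0.0, min(1.0, terms.sum())))
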