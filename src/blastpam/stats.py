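"""Paired response statistics: Wilcoxon signed-rank, paired t, effect sizes.

The behavioural-response comparisons are all paired: a baseline window is
matched with a post-detonation window for each training event.  Normally
distributed differences get a paired t-test with Cohen's d = t / sqrt(n);
everything else gets a Wilcoxon signed-rank test reported as a Z statistic
with effect size r = Z / sqrt(N).  Two r conventions exist in the
behavioural literature and both appear here, explicitly labelled:
``r_sqrt_pairs`` divides by the number of pairs, ``r_sqrt_obs`` by the
total number of observations (2 x pairs, used by the 30-s whistle-count
comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TestResult",
    "wilcoxon_signed_rank",
    "paired_t",
    "effect_size_r",
    "cohens_d",
    "choose_test",
    "whistles_30s_comparison",
]

MIN_PAIRS = 5  # minimum pairs for inferential output


@dataclass(frozen=True)
class PairedSample:
    """Matched values under two conditions, e.g. (day_before, day_of)."""

    a: np.ndarray
    b: np.ndarray
    labels: tuple[str, str] = ("a", "b")

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired sample requires two equal-length 1-d arrays")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.b - self.a

    @property
    def n_pairs(self) -> int:
        return len(self.a)


@dataclass
class TestResult:
    test: str                      # "wilcoxon" | "paired_t"
    statistic: float               # Z or t
    p_value: float
    n: int                         # pairs entering the test
    df: int | None = None
    effect_size: float | None = None
    convention: str | None = None  # "r_sqrt_pairs" | "r_sqrt_obs" | "d_t_over_sqrt_n"
    flags: list[str] = field(default_factory=list)


def effect_size_r(z: float, n_pairs: int, convention: str = "r_sqrt_pairs") -> float:
    """Effect size r for a Wilcoxon Z under either denominator convention."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if convention == "r_sqrt_pairs":
        denom = np.sqrt(n_pairs)
    elif convention == "r_sqrt_obs":
        denom = np.sqrt(2 * n_pairs)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(abs(z) / denom)


def cohens_d(t: float, n: int) -> float:
    """Paired-sample Cohen's d magnitude, d = |t| / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(abs(t) / np.sqrt(n))


def wilcoxon_signed_rank(
    sample: PairedSample | np.ndarray, convention: str = "r_sqrt_pairs"
) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (the classical treatment).
    The reported Z is the tie-corrected normal-approximation statistic
    (uncorrected for continuity, the convention effect sizes are built on).
    The two-sided p-value comes from the exact null distribution when
    n <= 15 with no tied |differences|, otherwise from the normal
    approximation with continuity correction.
    """
    d = sample.differences if isinstance(sample, PairedSample) else np.asarray(sample, float)
    n_orig = len(d)
    d = d[d != 0]
    n = len(d)
    flags: list[str] = []
    if n == 0:
        return TestResult(
            test="wilcoxon", statistic=0.0, p_value=1.0, n=n_orig,
            effect_size=0.0, convention=convention, flags=["degenerate_all_zero"],
        )
    if n < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} nonzero pairs, got {n}")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie correction to the null variance
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return TestResult(
            test="wilcoxon", statistic=0.0, p_value=1.0, n=n,
            effect_size=0.0, convention=convention, flags=["degenerate_variance"],
        )
    z = (w_plus - mu) / np.sqrt(sigma2)

    has_ties = np.any(counts > 1)
    if n <= 15 and not has_ties:
        p = float(sps.wilcoxon(d, method="exact", alternative="two-sided").pvalue)
        flags.append("exact_p")
    else:
        z_cc = max(abs(w_plus - mu) - 0.5, 0.0) / np.sqrt(sigma2)
        p = float(2 * sps.norm.sf(z_cc))
    return TestResult(
        test="wilcoxon",
        statistic=float(z),
        p_value=min(p, 1.0),
        n=n,
        effect_size=effect_size_r(z, n, convention),
        convention=convention,
        flags=flags,
    )


def paired_t(sample: PairedSample | np.ndarray) -> TestResult:
    """Paired t-test with Cohen's d = t / sqrt(n)."""
    d = sample.differences if isinstance(sample, PairedSample) else np.asarray(sample, float)
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    flags: list[str] = []
    if sd == 0:
        if mean == 0:
            return TestResult(
                test="paired_t", statistic=0.0, p_value=1.0, n=n, df=n - 1,
                effect_size=0.0, convention="d_t_over_sqrt_n", flags=["degenerate_all_zero"],
            )
        return TestResult(
            test="paired_t", statistic=float("inf"), p_value=0.0, n=n, df=n - 1,
            effect_size=float("inf"), convention="d_t_over_sqrt_n", flags=["zero_variance"],
        )
    t = mean / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), df=n - 1))
    return TestResult(
        test="paired_t", statistic=float(t), p_value=p, n=n, df=n - 1,
        effect_size=cohens_d(t, n), convention="d_t_over_sqrt_n", flags=flags,
    )


def choose_test(differences: np.ndarray, alpha: float = 0.05) -> str:
    """Pick the paired test from a Shapiro-Wilk normality gate on the differences."""
    d = np.asarray(differences, dtype=float)
    if len(d) < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} pairs for inferential output")
    if np.ptp(d) == 0:
        return "wilcoxon"  # constant differences: Shapiro undefined, degenerate branch
    p = float(sps.shapiro(d).pvalue)
    return "paired_t" if p >= alpha else "wilcoxon"


def compare_paired(sample: PairedSample, convention: str = "r_sqrt_pairs") -> TestResult:
    """Run the normality-gated paired comparison (t-test or Wilcoxon)."""
    which = choose_test(sample.differences)
    if which == "paired_t":
        return paired_t(sample)
    return wilcoxon_signed_rank(sample, convention=convention)


def whistles_30s_comparison(before: np.ndarray, after: np.ndarray) -> TestResult:
    """Whistle counts in the 30 s before vs after each detonation.

    A Wilcoxon signed-rank test on the per-detonation pairs, reported with
    the total-observations effect-size convention r = Z / sqrt(2n).
    """
    sample = PairedSample(np.asarray(before, float), np.asarray(after, float),
                          labels=("before_30s", "after_30s"))
    return wilcoxon_signed_rank(sample, convention="r_sqrt_obs")
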