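"""Bootstrap randomization tests, grand means with bootstrap CIs, Bonferroni.

The randomization tests use studentized statistics: a paired test on
differences x,

    T = |x_bar| / (s_x / sqrt(n)),

and an unpaired two-sample test on groups z (size n) and y (size m),

    T = |z_bar - y_bar| / sqrt(s_z^2/n + s_y^2/m),

with s computed with the n-1 denominator.  The null distribution is sampled
with replacement B times: random sign flips of the differences for the paired
test, random reassignment of group labels (preserving n and m) for the
two-sample test.  Two-tailedness is carried by the absolute value in T.  The
p-value is max(#{T* >= T}, 1)/B, so the smallest returnable p is exactly 1/B;
ties count toward the numerator, making the test conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RandomizationResult",
    "paired_randomization_test",
    "two_sample_randomization_test",
    "grand_mean_ci",
    "bonferroni",
]

# resamples are drawn in chunks so B = 1e7 stays within memory
_CHUNK = 200_000


@dataclass(frozen=True)
class RandomizationResult:
    """Outcome of a randomization test."""

    T_observed: float
    B: int
    count_ge: int
    p: float
    seed: int
    scheme: str

    def as_dict(self) -> dict:
        return {
            "T": self.T_observed,
            "p": self.p,
            "B": self.B,
            "seed": self.seed,
            "scheme": self.scheme,
        }


def _paired_T(x: np.ndarray) -> float:
    n = x.shape[-1]
    return abs(x.mean()) / (x.std(ddof=1) / np.sqrt(n))


def paired_randomization_test(
    x, B: int = 10_000_000, seed: int = 0
) -> RandomizationResult:
    """Paired two-tailed randomization test on differences ``x``.

    Null resamples flip the sign of each difference independently and
    recompute the studentized statistic.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("paired test needs at least 2 differences")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite differences")
    if x.std(ddof=1) == 0:
        raise ValueError("degenerate statistic: zero-variance differences")
    T_obs = _paired_T(x)

    rng = np.random.default_rng(seed)
    count_ge = 0
    done = 0
    sqrt_n = np.sqrt(n)
    while done < B:
        b = min(_CHUNK, B - done)
        signs = rng.integers(0, 2, size=(b, n)) * 2 - 1
        xs = signs * x
        means = xs.mean(axis=1)
        sds = xs.std(axis=1, ddof=1)
        T_null = np.abs(means) / (sds / sqrt_n)
        count_ge += int(np.count_nonzero(T_null >= T_obs))
        done += b
    p = max(count_ge, 1) / B
    return RandomizationResult(float(T_obs), B, count_ge, p, seed, "sign-flip")


def _two_sample_T(z_mean, z_var, y_mean, y_var, n, m):
    return np.abs(z_mean - y_mean) / np.sqrt(z_var / n + y_var / m)


def two_sample_randomization_test(
    z, y, B: int = 10_000_000, seed: int = 0
) -> RandomizationResult:
    """Unpaired two-tailed randomization test comparing groups ``z`` and ``y``.

    Null resamples shuffle the pooled observations into groups of the original
    sizes and recompute the studentized statistic.
    """
    z = np.asarray(z, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = z.size, y.size
    if n < 2 or m < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([z, y])
    if not np.all(np.isfinite(pooled)):
        raise ValueError("non-finite observations")
    denom = z.var(ddof=1) / n + y.var(ddof=1) / m
    if denom == 0:
        raise ValueError("degenerate statistic: zero pooled variance")
    T_obs = float(_two_sample_T(z.mean(), z.var(ddof=1), y.mean(), y.var(ddof=1), n, m))

    rng = np.random.default_rng(seed)
    count_ge = 0
    done = 0
    N = n + m
    while done < B:
        b = min(_CHUNK // 4, B - done)
        # vectorized label shuffles: argsort of uniforms gives b permutations
        perm = np.argsort(rng.random((b, N)), axis=1)
        res = pooled[perm]
        zs, ys = res[:, :n], res[:, n:]
        T_null = _two_sample_T(
            zs.mean(axis=1), zs.var(axis=1, ddof=1),
            ys.mean(axis=1), ys.var(axis=1, ddof=1), n, m,
        )
        count_ge += int(np.count_nonzero(T_null >= T_obs))
        done += b
    p = max(count_ge, 1) / B
    return RandomizationResult(T_obs, B, count_ge, p, seed, "label-permutation")


def grand_mean_ci(animal_means, n_boot: int = 5000, seed: int = 0):
    """Grand mean (mean of animal means) with a bootstrap percentile 95% CI.

    Returns ``(grand_mean, (lo, hi))``.  With a single animal the interval
    degenerates to the point estimate.
    """
    x = np.asarray(animal_means, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no animal means")
    gm = float(x.mean())
    if x.size == 1:
        return gm, (gm, gm)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boots = x[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return gm, (float(lo), float(hi))


def bonferroni(p_values, m_comparisons: int):
    """Bonferroni adjustment: min(1, p * m)."""
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.minimum(1.0, p * m_comparisons)
    return float(adj) if adj.ndim == 0 else adj
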