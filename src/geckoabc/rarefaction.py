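"""Monte-Carlo haplotype rarefaction.

Estimates the probability of observing a given number of distinct haplotypes
in a random subsample drawn from an empirical pool of sequences, as used to
compare marker panels of different sampling depth (e.g. a 17-sequence 16S
panel against a 123-sequence COI pool). Sampling is with replacement by
default; classical without-replacement rarefaction is available too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta

from .hapnet import HaplotypeTable


@dataclass
class RarefactionResult:
    probability: float
    reps: int
    ci_low: float
    ci_high: float
    n: int
    k: int
    mode: str
    successes: int

    def __post_init__(self) -> None:
        assert self.ci_low <= self.probability <= self.ci_high


def _count_distinct_per_row(draws: np.ndarray) -> np.ndarray:
    srt = np.sort(draws, axis=1)
    return 1 + (srt[:, 1:] != srt[:, :-1]).sum(axis=1)


def haplotype_subsample_probability(
    ht: HaplotypeTable,
    n: int,
    k: int,
    reps: int = 10000,
    seed: int | None = None,
    mode: str = "exactly",
    replace: bool = True,
) -> RarefactionResult:
    """P(number of distinct haplotypes in a size-n subsample satisfies mode/k).

    Each replicate draws ``n`` sequences (with replacement by default) from
    the pool of sequences behind ``ht``, counts the distinct haplotypes and
    compares against ``k`` under ``mode`` in {exactly, at_most, at_least}.
    The 95% CI is Clopper-Pearson on the success count. ``k > n`` cannot be
    reached, giving probability 0 without simulation.
    """
    if n < 1 or reps < 1:
        raise ValueError("n and reps must be >= 1")
    if mode not in ("exactly", "at_most", "at_least"):
        raise ValueError(f"unknown mode {mode!r}")
    pool = np.array([ht.member_of[sid] for sid in ht.member_of])
    codes = np.unique(pool, return_inverse=True)[1]
    if mode in ("exactly", "at_least") and k > n:
        return RarefactionResult(0.0, reps, 0.0, 0.0, n, k, mode, 0)
    if not replace and n > len(codes):
        raise ValueError("subsample larger than pool for without-replacement sampling")
    rng = np.random.default_rng(seed)
    if replace:
        draws = codes[rng.integers(0, len(codes), size=(reps, n))]
    else:
        draws = np.stack([rng.choice(codes, size=n, replace=False) for _ in range(reps)])
    counts = _count_distinct_per_row(draws)
    if mode == "exactly":
        succ = int((counts == k).sum())
    elif mode == "at_most":
        succ = int((counts <= k).sum())
    else:
        succ = int((counts >= k).sum())
    p = succ / reps
    # Clopper-Pearson exact interval
    lo = 0.0 if succ == 0 else float(beta.ppf(0.025, succ, reps - succ + 1))
    hi = 1.0 if succ == reps else float(beta.ppf(0.975, succ + 1, reps - succ))
    return RarefactionResult(p, reps, lo, hi, n, k, mode, succ)
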