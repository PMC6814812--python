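"""Rényi-entropy diversity profiles as effective numbers of species.

The Hill number of order q,

    D_q = (Σ_i p_i^q)^(1/(1−q)),        D_1 = exp(−Σ_i p_i ln p_i),

is the "effective number of species": the number of equally common
clonotypes that would give the same diversity.  The order q tunes the
weighting — q < 1 emphasises rare clones, q > 1 abundant ones; q = 0 is
richness, q = 1 the exponential of Shannon entropy, q = ∞ the inverse of
the largest frequency.  A diversity profile is D_q over a grid of orders,
the standard way to compare repertoires without committing to one index.

An optional coverage adjustment accounts for unseen species: Good–Turing
sample coverage Ĉ = 1 − f1/n rescales the observed frequencies, the
residual mass 1 − Ĉ is attributed to unseen clonotypes whose number is
imputed from the Chao1 richness estimate.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repcore import RepertoireSample, frequencies

DEFAULT_Q_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, math.inf)


@dataclass
class DiversityProfile:
    """ENS values over a grid of Rényi orders for one repertoire."""

    sample_id: str
    q_grid: list[float]
    renyi_entropy_nats: list[float]
    ens: list[float]
    coverage_adjusted: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "q": self.q_grid,
                "renyi_entropy_nats": self.renyi_entropy_nats,
                "ens": self.ens,
                "coverage_adjusted": self.coverage_adjusted,
            }
        )


def ens_from_frequencies(p: np.ndarray, q: float) -> float:
    """Hill number D_q of a frequency vector (zeros ignored)."""
    if q < 0:
        raise ValueError("Renyi order q must be non-negative")
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if math.isinf(q):
        return float(1.0 / p.max())
    if math.isclose(q, 1.0, rel_tol=0, abs_tol=1e-9):
        return float(np.exp(-(p * np.log(p)).sum()))
    if q == 0:
        return float(p.size)
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def renyi_ens(sample: RepertoireSample, q: float) -> float:
    """Effective number of species of order q for one repertoire sample."""
    if not sample.counts:
        raise ValueError(f"sample {sample.sample_id!r} is empty")
    p = np.array(list(frequencies(sample).values()))
    return ens_from_frequencies(p, q)


def coverage_adjust(
    sample: RepertoireSample,
) -> tuple[np.ndarray, float]:
    """Unseen-species adjustment of a repertoire's frequency vector.

    Good–Turing coverage Ĉ = 1 − f1/n (f1 singleton clonotypes, n reads)
    estimates the probability mass of the observed clonotypes.  Observed
    frequencies are rescaled to p̃_i = Ĉ·p_i and the residual mass 1 − Ĉ is
    split uniformly over f0 = Chao1 − S imputed unseen clonotypes, where
    Chao1 = S + f1(f1−1)/(2(f2+1)).  The returned vector is a proper
    distribution whose support size is the Chao1 estimate (rounded up), so
    D_0 of the adjusted vector reports Chao1-style richness.

    Returns ``(adjusted_frequencies, coverage)``.  An all-singleton sample
    (Ĉ = 0) triggers a warning and falls back to the plug-in frequencies.
    """
    n = sample.total_reads
    if n < 2:
        raise ValueError("coverage adjustment requires at least 2 reads")
    counts = np.array(list(sample.counts.values()))
    abundance = Counter(counts.tolist())
    f1 = abundance.get(1, 0)
    f2 = abundance.get(2, 0)
    s_obs = counts.size
    coverage = 1.0 - f1 / n
    p = counts / n
    if coverage <= 0.0:
        warnings.warn(
            f"sample {sample.sample_id!r} is all singletons (coverage 0); "
            "falling back to plug-in frequencies",
            stacklevel=2,
        )
        return p, 0.0
    if f1 == 0:
        return p, 1.0
    chao1 = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    f0 = max(int(math.ceil(chao1 - s_obs)), 1)
    adjusted = np.concatenate([coverage * p, np.full(f0, (1.0 - coverage) / f0)])
    return adjusted, coverage


def chao1_richness(sample: RepertoireSample) -> float:
    """Chao1 lower-bound richness estimate S + f1(f1−1)/(2(f2+1))."""
    counts = Counter(sample.counts.values())
    f1, f2 = counts.get(1, 0), counts.get(2, 0)
    return len(sample.counts) + f1 * (f1 - 1) / (2 * (f2 + 1))


def diversity_profile(
    sample: RepertoireSample,
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID,
    coverage_adjusted: bool = False,
) -> DiversityProfile:
    """ENS profile of one repertoire over an ascending grid of orders q."""
    grid = list(q_grid)
    if grid != sorted(grid):
        raise ValueError("q_grid must be sorted ascending")
    if not sample.counts:
        raise ValueError(f"sample {sample.sample_id!r} is empty")
    if coverage_adjusted:
        p, _ = coverage_adjust(sample)
    else:
        p = np.array(list(frequencies(sample).values()))
    ens = [ens_from_frequencies(p, q) for q in grid]
    entropy = [math.log(d) for d in ens]
    return DiversityProfile(
        sample_id=sample.sample_id,
        q_grid=grid,
        renyi_entropy_nats=entropy,
        ens=ens,
        coverage_adjusted=coverage_adjusted,
    )


def profiles_to_frame(profiles: list[DiversityProfile]) -> pd.DataFrame:
    """Stack profiles into one long table (sample_id, q, H_q, D_q, adjusted)."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)


def plot_profiles(profiles: list[DiversityProfile], ax=None, log_scale: bool = True):
    """Line plot of D_q over q, one line per sample (∞ drawn at the right edge)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for prof in profiles:
        qs = [q if not math.isinf(q) else max(
            x for x in prof.q_grid if not math.isinf(x)) * 2 for q in prof.q_grid]
        ax.plot(qs, prof.ens, marker="o", label=prof.sample_id)
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("Renyi order q")
    ax.set_ylabel("effective number of species $D_q$")
    ax.legend(fontsize="small")
    return ax
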