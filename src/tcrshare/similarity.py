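"""Mutual Information Index (MII) between repertoires.

The MII quantifies the overlap of two clonotype abundance patterns.  Pool
the two repertoires with mixture weights (w_a, w_b) and consider the joint
distribution of (clonotype, population label): the mutual information I
between clonotype identity and population label is 0 when the two
frequency vectors are identical (knowing the clonotype says nothing about
which repertoire it came from) and maximal — equal to the label entropy
H_L = −(w_a ln w_a + w_b ln w_b) — when the repertoires are disjoint.  The
index

    MII = 1 − I / H_L

is therefore 1 for completely overlapping repertoires with identical
abundance patterns and 0 for entirely non-overlapping ones.  With equal
weights, I is the Jensen–Shannon divergence and MII = 1 − JSD(p, q)/ln 2.

All entropies are computed in nats internally; the index itself is
base-invariant because the logarithm base cancels in I/H_L.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .repcore import IdentityKey, RepertoireSample, frequencies

Estimator = Literal["plugin", "miller_madow"]


@dataclass
class MIIResult:
    """One MII computation: the index plus its audit trail."""

    value: float
    mutual_information_nats: float
    label_entropy_nats: float
    weights: tuple[float, float]
    n_union_clonotypes: int

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "mutual_information_nats": self.mutual_information_nats,
            "label_entropy_nats": self.label_entropy_nats,
            "weights": list(self.weights),
            "n_union_clonotypes": self.n_union_clonotypes,
        }


def _freq_vectors(
    a: RepertoireSample, b: RepertoireSample, level: IdentityKey
) -> tuple[np.ndarray, np.ndarray]:
    fa: dict[tuple, float] = {}
    for clone, f in frequencies(a).items():
        k = clone.key(level)
        fa[k] = fa.get(k, 0.0) + f
    fb: dict[tuple, float] = {}
    for clone, f in frequencies(b).items():
        k = clone.key(level)
        fb[k] = fb.get(k, 0.0) + f
    union = sorted(set(fa) | set(fb))
    p = np.array([fa.get(k, 0.0) for k in union])
    q = np.array([fb.get(k, 0.0) for k in union])
    return p, q


def _plugin_entropy(dist: np.ndarray) -> float:
    nz = dist[dist > 0]
    return float(-(nz * np.log(nz)).sum())


def mii_from_frequencies(
    p: np.ndarray,
    q: np.ndarray,
    weights: tuple[float, float] = (0.5, 0.5),
) -> MIIResult:
    """MII of two aligned frequency vectors over the clonotype union.

    This is the exact (distribution-level) form used both by the estimator on
    observed frequencies and by the synthetic generator to record ground
    truth.  Zero-frequency entries contribute nothing (0·ln 0 := 0).
    """
    wa, wb = weights
    if not (wa > 0 and wb > 0):
        raise ValueError("mixture weights must be strictly positive")
    if not math.isclose(wa + wb, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"weights must sum to 1, got {wa + wb}")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("frequency vectors must be aligned on the same union")

    m = wa * p + wb * q
    with np.errstate(divide="ignore", invalid="ignore"):
        term_a = np.where(p > 0, wa * p * np.log(np.where(p > 0, p, 1) / m), 0.0)
        term_b = np.where(q > 0, wb * q * np.log(np.where(q > 0, q, 1) / m), 0.0)
    mi = float(term_a.sum() + term_b.sum())
    h_label = -(wa * math.log(wa) + wb * math.log(wb))
    value = 1.0 - mi / h_label
    # clip numerical spill just outside [0, 1]
    if -1e-15 < value < 0.0:
        value = 0.0
    if 1.0 < value < 1.0 + 1e-15:
        value = 1.0
    return MIIResult(
        value=value,
        mutual_information_nats=max(mi, 0.0),
        label_entropy_nats=h_label,
        weights=(wa, wb),
        n_union_clonotypes=int(np.count_nonzero((p > 0) | (q > 0))),
    )


def mii(
    a: RepertoireSample,
    b: RepertoireSample,
    weights: tuple[float, float] = (0.5, 0.5),
    estimator: Estimator = "plugin",
    level: IdentityKey = "nt",
) -> MIIResult:
    """Mutual Information Index between two repertoire samples.

    With the default plug-in estimator the observed frequencies stand in for
    the true clonotype distributions.  ``estimator="miller_madow"`` applies
    the (K−1)/(2n) entropy bias correction to each of the three plug-in
    entropies in the decomposition I = H(mix) − w_a·H(p) − w_b·H(q), using
    each distribution's own support size K and read count n.

    Symmetric under (a, b) swap when the weights are equal.
    """
    if not a.counts or not b.counts:
        raise ValueError("MII requires two non-empty repertoires")
    p, q = _freq_vectors(a, b, level)
    result = mii_from_frequencies(p, q, weights)
    if estimator == "plugin":
        return result
    if estimator != "miller_madow":
        raise ValueError(f"unknown estimator: {estimator!r}")

    wa, wb = result.weights
    m = wa * p + wb * q
    n_a, n_b = a.total_reads, b.total_reads
    h_p = _plugin_entropy(p) + (np.count_nonzero(p) - 1) / (2 * n_a)
    h_q = _plugin_entropy(q) + (np.count_nonzero(q) - 1) / (2 * n_b)
    h_m = _plugin_entropy(m) + (np.count_nonzero(m) - 1) / (2 * (n_a + n_b))
    mi = max(h_m - wa * h_p - wb * h_q, 0.0)
    value = min(max(1.0 - mi / result.label_entropy_nats, 0.0), 1.0)
    return MIIResult(
        value=value,
        mutual_information_nats=mi,
        label_entropy_nats=result.label_entropy_nats,
        weights=result.weights,
        n_union_clonotypes=result.n_union_clonotypes,
    )


def mii_matrix(
    samples: list[RepertoireSample],
    weights: tuple[float, float] = (0.5, 0.5),
    estimator: Estimator = "plugin",
    level: IdentityKey = "nt",
) -> pd.DataFrame:
    """All-pairs MII matrix: symmetric, unit diagonal, sample ids as labels."""
    if len(samples) < 2:
        raise ValueError("mii_matrix needs at least 2 samples")
    ids = [s.sample_id for s in samples]
    mat = np.eye(len(samples))
    for i, j in itertools.combinations(range(len(samples)), 2):
        v = mii(samples[i], samples[j], weights=weights, estimator=estimator,
                level=level).value
        mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=ids, columns=ids)


def strain_summary(matrix: pd.DataFrame, strains: dict[str, str]) -> pd.DataFrame:
    """Within- and cross-strain mean ± SD of off-diagonal MII values.

    ``strains`` maps sample id -> strain label.  Returns one row per
    (strain_a, strain_b) pair with columns n_pairs, mean, sd.
    """
    rows = []
    labels = sorted(set(strains.values()))
    for ia, sa in enumerate(labels):
        for sb in labels[ia:]:
            vals = []
            for i, j in itertools.combinations(range(len(matrix)), 2):
                si = strains[matrix.index[i]]
                sj = strains[matrix.index[j]]
                if {si, sj} == {sa, sb} or (sa == sb and si == sj == sa):
                    vals.append(matrix.iloc[i, j])
            if vals:
                rows.append(
                    {
                        "strain_a": sa,
                        "strain_b": sb,
                        "comparison": "within" if sa == sb else "cross",
                        "n_pairs": len(vals),
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )
    return pd.DataFrame(rows)
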