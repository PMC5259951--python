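"""Probe-target mismatch counting and the binomial mismatch model.

Cross-species hybridization turns each of the 25 probe positions into a
Bernoulli trial (match vs mismatch against the heterologous target), so
the per-probe mismatch count K is Binomial(n=25, p) with p the average
per-base divergence between the species (default 0.06).  This module
counts observed mismatches, evaluates the model pmf, and tests observed
mismatch histograms against the model with a pooled chi-square.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    MismatchModel,
    MismatchTable,
    ProbeSet,
    ValidationError,
    VALID_BASES,
)

DEFAULT_BINS: tuple[tuple[int, int], ...] = ((0, 0), (1, 1), (2, 2), (3, 3), (4, 25))


def count_mismatches(probe: str, target: str) -> int:
    """Hamming distance between a probe and its aligned target 25-mer."""
    if len(probe) != len(target):
        raise ValidationError(
            f"sequence length mismatch: {len(probe)} vs {len(target)}"
        )
    bad = (set(probe) | set(target)) - VALID_BASES
    if bad:
        raise ValidationError(
            f"ambiguity codes not allowed, found {sorted(bad)}; resolve or mask"
        )
    return sum(a != b for a, b in zip(probe, target))


def binomial_pmf(model: MismatchModel, k: int) -> float:
    """P(K = k) under Binomial(model.n, model.p)."""
    if not 0 <= k <= model.n:
        raise ValidationError(f"k must lie in [0, {model.n}], got {k}")
    return float(model.pmf(k))


def tail_probability(model: MismatchModel, k: int | None = None) -> float:
    """P(K > k); k defaults to the model's truncation kmax."""
    if k is None:
        k = model.kmax
    if not 0 <= k <= model.n:
        raise ValidationError(f"k must lie in [0, {model.n}], got {k}")
    return model.tail_above(k)


def mismatch_table(
    probesets: Sequence[ProbeSet],
    targets: Mapping[tuple[str, int], str],
    species: str = "",
) -> MismatchTable:
    """Count mismatches for every probe with an aligned target sequence.

    Probes without a target are omitted (they carry no divergence
    information for scaling); the caller sees the retained universe via
    the returned table's index.
    """
    index = []
    counts = []
    for ps in probesets:
        for idx, seq in ps.probes:
            key = (ps.probeset_id, idx)
            if key in targets:
                index.append(key)
                counts.append(count_mismatches(seq, targets[key]))
    k = pd.Series(
        counts,
        index=pd.MultiIndex.from_tuples(index, names=["probeset_id", "probe_index"]),
        dtype=int,
    )
    return MismatchTable(k, species)


def compare_to_expected(
    observed: np.ndarray | Sequence[int],
    model: MismatchModel,
    bins: Sequence[tuple[int, int]] = DEFAULT_BINS,
) -> tuple[float, int, float]:
    """Pearson chi-square of an observed k-histogram against the model.

    ``observed`` holds counts for k = 0..len(observed)-1; ``bins`` are
    inclusive (lo, hi) ranges pooling the upper tail so every expected
    count stays positive.  Returns (chi2, df, p) with df = #bins - 1 and
    p from the chi-square upper tail.
    """
    obs = np.asarray(observed, dtype=float)
    if (obs < 0).any():
        raise ValidationError("observed counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValidationError("observed histogram is empty")
    lo_all = min(lo for lo, _ in bins)
    hi_all = max(hi for _, hi in bins)
    if lo_all != 0 or hi_all < model.n:
        raise ValidationError(f"bins must cover 0..{model.n}")

    obs_binned = np.array(
        [obs[lo : min(hi, len(obs) - 1) + 1].sum() for lo, hi in bins]
    )
    ks = np.arange(model.n + 1)
    pk = model.pmf(ks)
    exp_binned = np.array(
        [total * pk[lo : hi + 1].sum() for lo, hi in bins]
    )
    if (exp_binned <= 0).any():
        raise ValidationError(
            "a bin has expected count 0 under the model; pool bins more coarsely"
        )
    chi2 = float(((obs_binned - exp_binned) ** 2 / exp_binned).sum())
    df = len(bins) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
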