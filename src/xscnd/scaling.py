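"""Mismatch-aware global signal scaling for cross-species hybridizations.

Probes whose heterologous target carries k mismatches lose signal by a
roughly k-dependent factor.  On a curated reference set of single-copy
genes with known target sequence, the incremental correction factor

    S_k = (1/N_k) * sum_i  H_ik / I_ik

is the arithmetic mean, over the N_k reference probes with exactly k
mismatches, of the ratio of home-species intensity H to heterologous
intensity I.  The species-specific global scaling factor weights these
by the binomial mismatch model truncated at kmax = 4:

    S = sum_{k=0..4}  S_k * P_n(k)

and every heterologous intensity is multiplied by S to make the two
species' hybridizations comparable.  Taken literally the truncated
weights do not sum to one (sum P_n(k), k<=4 ~ 0.985 at p = 0.06); a
``renormalize`` flag rescales them when a unit-sum convention is wanted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import (
    IntensityMatrix,
    MismatchModel,
    MismatchTable,
    ScalingFactors,
    ValidationError,
)

logger = logging.getLogger(__name__)


def incremental_correction_factors(
    home: IntensityMatrix,
    het: IntensityMatrix,
    mm: MismatchTable,
    kmax: int = 4,
    min_probes: int = 2,
) -> ScalingFactors:
    """Estimate S_k for k = 0..kmax from reference probes.

    Replicates are averaged per probe before the ratio is formed
    (ratio of replicate means).  Mismatch classes with fewer than
    ``min_probes`` probes are linearly interpolated from neighbouring
    classes with a logged warning.
    """
    if home.log_scale or het.log_scale:
        raise ValidationError("scaling factors are estimated on linear-scale intensities")
    home_species = home.species_list
    het_species = het.species_list
    if len(home_species) != 1 or len(het_species) != 1:
        raise ValidationError("home and het matrices must each hold one species")

    h = home.replicate_means(home_species[0])
    i = het.replicate_means(het_species[0])
    common = h.index.intersection(i.index).intersection(mm.k.index)
    if common.empty:
        raise ValidationError("no unmasked reference probes shared by both matrices")
    h, i, k = h.loc[common], i.loc[common], mm.k.loc[common]
    if (i <= 0).any():
        raise ValidationError("non-positive heterologous intensity; floor upstream")
    ratios = h / i

    rows = {}
    for kk in range(kmax + 1):
        sel = ratios[k == kk]
        if len(sel) >= min_probes:
            rows[kk] = (float(sel.mean()), int(len(sel)))
    observed = pd.DataFrame.from_dict(rows, orient="index", columns=["S_k", "N_k"])

    missing = [kk for kk in range(kmax + 1) if kk not in rows]
    interpolated: list[int] = []
    if missing:
        if observed.empty:
            raise ValidationError("no mismatch class has enough probes for S_k")
        full = observed.reindex(range(kmax + 1))
        full["S_k"] = full["S_k"].interpolate(limit_direction="both")
        full["N_k"] = full["N_k"].fillna(0).astype(int)
        for kk in missing:
            logger.warning(
                "S_%d based on <%d probes; linearly interpolated from neighbours",
                kk,
                min_probes,
            )
            interpolated.append(kk)
        observed = full

    sk = observed["S_k"].to_numpy()
    if np.any(np.diff(sk) < 0):
        logger.warning(
            "fitted S_k sequence is not non-decreasing in k: %s "
            "(plateauing attenuation can cause this)",
            np.round(sk, 3).tolist(),
        )
    return ScalingFactors(observed, interpolated=tuple(interpolated))


def global_scaling_factor(
    factors: ScalingFactors,
    model: MismatchModel,
    renormalize: bool = False,
) -> ScalingFactors:
    """Weight S_k by the binomial pmf truncated at kmax to obtain S."""
    needed = range(model.kmax + 1)
    missing = [k for k in needed if k not in factors.per_k.index]
    if missing:
        raise ValidationError(f"S_k missing for mismatch classes {missing}")
    ks = np.arange(model.kmax + 1)
    weights = model.pmf(ks)
    if renormalize:
        weights = weights / weights.sum()
    S = float((factors.per_k.loc[ks, "S_k"].to_numpy() * weights).sum())
    return ScalingFactors(
        factors.per_k.copy(),
        S=S,
        renormalized=renormalize,
        interpolated=factors.interpolated,
    )


def apply_scaling(het: IntensityMatrix, S: float) -> IntensityMatrix:
    """Multiply every unmasked heterologous intensity by S.

    On a glog/log2-scale matrix the equivalent additive shift log2(S)
    is applied instead.
    """
    if S <= 0:
        raise ValidationError(f"scaling factor must be positive, got {S}")
    out = het.copy()
    unmasked = ~out.mask
    if out.log_scale:
        out.values.loc[unmasked] = out.values.loc[unmasked] + np.log2(S)
    else:
        out.values.loc[unmasked] = out.values.loc[unmasked] * S
    return out


class GlobalScaler(BaseEstimator):
    """Estimator interface to the mismatch-aware global scaling step.

    ``fit`` estimates per-mismatch-class correction factors S_k
    (arithmetic means of home/heterologous intensity ratios on a
    reference probe set) and the binomial-weighted global factor S;
    ``transform`` multiplies a heterologous matrix by the fitted S.

    Parameters
    ----------
    n, p, kmax
        Binomial mismatch model: probe length, per-base mismatch
        probability, truncation of the weighted sum.
    min_probes
        Minimum probes per mismatch class before interpolation kicks in.
    renormalize
        Rescale the truncated binomial weights to sum to one.

    Attributes
    ----------
    factors_ : ScalingFactors
        Fitted per-k table plus the global factor.
    S_ : float
        The fitted global scaling factor.
    """

    def __init__(
        self,
        n: int = 25,
        p: float = 0.06,
        kmax: int = 4,
        min_probes: int = 2,
        renormalize: bool = False,
    ) -> None:
        self.n = n
        self.p = p
        self.kmax = kmax
        self.min_probes = min_probes
        self.renormalize = renormalize

    def fit(
        self,
        home: IntensityMatrix,
        het: IntensityMatrix,
        mismatches: MismatchTable,
    ) -> "GlobalScaler":
        model = MismatchModel(n=self.n, p=self.p, kmax=self.kmax)
        per_k = incremental_correction_factors(
            home, het, mismatches, kmax=self.kmax, min_probes=self.min_probes
        )
        self.factors_ = global_scaling_factor(per_k, model, renormalize=self.renormalize)
        self.S_ = self.factors_.S
        return self

    def transform(self, het: IntensityMatrix) -> IntensityMatrix:
        if not hasattr(self, "S_"):
            raise ValidationError("GlobalScaler is not fitted")
        return apply_scaling(het, self.S_)

    def fit_transform(
        self,
        home: IntensityMatrix,
        het: IntensityMatrix,
        mismatches: MismatchTable,
    ) -> IntensityMatrix:
        return self.fit(home, het, mismatches).transform(het)
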