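"""Background correction, probe masking and within-species normalization.

Raw genomic-DNA hybridization intensities carry an additive optical /
non-specific background and multiplicative array-to-array effects.
The stages here:

1. ``background_correct`` — subtract a per-sample low-quantile floor
   (a chip-geometry-free stand-in for zone-based background) and clamp
   to a small positive value so log-family transforms stay defined.
2. ``mask_probes`` — flag organellar / control / known multi-copy
   probesets for exclusion from every downstream statistic.
3. ``normalize_within_species`` — put each species' replicate arrays on
   a common generalized-log (glog2) scale via a robust two-parameter
   affine calibration per sample.  Calibration is *within species only*:
   the cross-species signal deficit caused by probe-target mismatches is
   deliberately preserved, because the global scaling factor downstream
   is what corrects it.

The calibration anchors each species to its lowest-numbered replicate
(a=0, b=1): for any other replicate the scale b is the ratio of median
absolute deviations and the offset a matches medians, so an array that
is a doubled copy of its partner gets b = 1/2 and identical medians.
glog2(y) = log2(y + sqrt(y^2 + 1)) behaves like log2(2y) for large y
and stays finite near zero, stabilizing replicate variance across the
intensity range.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import IntensityMatrix, ValidationError

logger = logging.getLogger(__name__)

#: positive floor applied after background subtraction
EPSILON = 1e-3


@dataclass
class NormalizationParams:
    """Fitted per-sample affine parameters of the glog2 calibration."""

    per_sample: dict[str, tuple[float, float]]  # sample_id -> (a, b)
    method: str = "glog-affine"
    background: str = ""
    q: float = 0.02

    def __post_init__(self) -> None:
        for sid, (a, b) in self.per_sample.items():
            if b <= 0:
                raise ValidationError(f"scale b must be positive for sample {sid}")


def glog2(y: np.ndarray | float) -> np.ndarray | float:
    """Generalized log2: log2(y + sqrt(y^2 + 1)); ~log2(2y) for large y."""
    y = np.asarray(y, dtype=float)
    out = np.log2(y + np.sqrt(y * y + 1.0))
    return out if out.ndim else float(out)


def iglog2(h: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`glog2` (a scaled sinh)."""
    h = np.asarray(h, dtype=float)
    out = (np.exp2(h) - np.exp2(-h)) / 2.0
    return out if out.ndim else float(out)


def background_correct(
    m: IntensityMatrix,
    method: str = "quantile_floor",
    q: float = 0.02,
    eps: float = EPSILON,
    floor_fraction: float = 0.125,
) -> IntensityMatrix:
    """Subtract a per-sample background floor from linear intensities.

    The background estimate is the q-quantile of the sample's unmasked
    probe intensities.  Corrected values are clamped at
    ``max(eps, floor_fraction * background)`` per sample: like zone-based
    chip background correctors, probes at or below background keep a
    small positive signal proportional to the background level rather
    than collapsing to ~0, which would make downstream intensity ratios
    meaningless.  ``method='none'`` returns the input unchanged.
    """
    if m.log_scale:
        raise ValidationError("background correction expects linear-scale input")
    if method == "none":
        return m.copy()
    if method != "quantile_floor":
        raise ValidationError(f"unknown background method {method!r}")
    if not 0 < q < 0.5:
        raise ValidationError(f"background quantile must lie in (0, 0.5), got {q}")
    unmasked = ~m.mask
    if not unmasked.any():
        raise ValidationError("all probes are masked; cannot estimate background")
    out = m.copy()
    floors = out.values.loc[unmasked].quantile(q, axis=0)
    corrected = out.values - floors
    clamp = np.maximum(eps, floor_fraction * floors.to_numpy())
    out.values = pd.DataFrame(
        np.maximum(corrected.to_numpy(), clamp[None, :]),
        index=corrected.index,
        columns=corrected.columns,
    )
    return out


def mask_probes(m: IntensityMatrix, exclude: list[str]) -> IntensityMatrix:
    """Flag probesets matching any glob pattern as masked.

    Dimensions are unchanged; an empty match is legal and merely logged.
    """
    out = m.copy()
    if not exclude:
        return out
    probeset_ids = out.values.index.get_level_values("probeset_id")
    unique_ids = pd.unique(probeset_ids)
    hit: set[str] = set()
    for pattern in exclude:
        matched = fnmatch.filter(list(unique_ids), pattern)
        if not matched:
            logger.info("mask pattern %r matched no probesets", pattern)
        hit.update(matched)
    out.mask = out.mask | pd.Series(probeset_ids.isin(hit), index=out.values.index)
    return out


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def normalize_within_species(
    m: IntensityMatrix, species: str
) -> tuple[IntensityMatrix, NormalizationParams]:
    """Calibrate a species' replicates onto a common glog2 scale.

    Returns a matrix restricted to that species' samples with values
    glog2(a_s + b_s * x), plus the fitted per-sample (a_s, b_s).  The
    lowest-numbered replicate anchors the calibration with (0, 1).
    """
    sub = m.select_species(species)
    if sub.log_scale:
        raise ValidationError("matrix already normalized")
    if len(sub.sample_ids) < 2:
        raise ValidationError(
            f"need >=2 replicates of species {species!r} for normalization"
        )
    if (sub.values.to_numpy() < 0).any():
        raise ValidationError("negative input; run background correction first")

    order = sub.samples.sort_values("replicate").index
    ref = order[0]
    unmasked = ~sub.mask
    xref = sub.values.loc[unmasked, ref].to_numpy()
    ref_med, ref_mad = float(np.median(xref)), _mad(xref)
    if ref_mad == 0:
        ref_mad = 1.0  # degenerate constant reference array

    per_sample: dict[str, tuple[float, float]] = {}
    out_values = sub.values.copy()
    for sid in sub.sample_ids:
        if sid == ref:
            a, b = 0.0, 1.0
        else:
            xs = sub.values.loc[unmasked, sid].to_numpy()
            mad_s = _mad(xs)
            b = ref_mad / mad_s if mad_s > 0 else 1.0
            a = ref_med - b * float(np.median(xs))
        per_sample[sid] = (a, b)
        out_values[sid] = glog2(a + b * sub.values[sid].to_numpy())
    params = NormalizationParams(per_sample)
    logger.debug("normalization params for %s: %s", species, per_sample)
    return (
        IntensityMatrix(out_values, sub.samples, sub.mask, log_scale=True),
        params,
    )


def normalize(m: IntensityMatrix) -> tuple[IntensityMatrix, dict[str, NormalizationParams]]:
    """Apply within-species normalization to every species in the matrix."""
    parts = []
    params: dict[str, NormalizationParams] = {}
    for sp in m.species_list:
        sub, p = normalize_within_species(m, sp)
        parts.append(sub)
        params[sp] = p
    values = pd.concat([p.values for p in parts], axis=1)[m.sample_ids]
    return IntensityMatrix(values, m.samples.copy(), m.mask.copy(), log_scale=True), params


def to_linear(m: IntensityMatrix) -> IntensityMatrix:
    """Back-transform a glog2 matrix to the calibrated linear scale.

    The result is the affine-calibrated linear intensity a_s + b_s * x,
    comparable across a species' replicates; ratios for scaling-factor
    estimation are formed on this scale.  Values are clamped positive.
    """
    if not m.log_scale:
        raise ValidationError("matrix is already linear")
    values = pd.DataFrame(
        np.clip(iglog2(m.values.to_numpy()), EPSILON, None),
        index=m.values.index,
        columns=m.values.columns,
    )
    return IntensityMatrix(values, m.samples.copy(), m.mask.copy(), log_scale=False)
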