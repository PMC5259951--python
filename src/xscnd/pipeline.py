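"""End-to-end orchestration of the cross-species copy-number pipeline.

The canonical flow, given one intensity matrix holding both species:

1. mask control / organellar / multi-copy probesets,
2. background-correct the linear intensities,
3. within-species glog normalization of each species' replicates,
4. back-transform to the calibrated linear scale,
5. estimate per-mismatch-class correction factors S_k on a reference
   probe subset of known heterologous sequence, combine them into the
   binomial-weighted global scaling factor S, scale the heterologous
   matrix,
6. form replicate-paired probe log2 ratios and run the moderated
   probe-level test, BH correction and CNE/CNR classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .calling import CNDCaller, probe_log2_ratios
from .datamodel import IntensityMatrix, MismatchTable, ScalingFactors
from .preprocess import background_correct, mask_probes, normalize, to_linear
from .scaling import GlobalScaler


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    factors: ScalingFactors
    scaler: GlobalScaler
    caller: CNDCaller
    home_linear: IntensityMatrix
    het_scaled: IntensityMatrix


def run_pipeline(
    intensities: IntensityMatrix,
    mismatches: MismatchTable,
    reference_probesets: Sequence[str],
    species_home: str,
    species_het: str,
    mask_patterns: Sequence[str] = (),
    gene_map: Mapping[str, str] | None = None,
    background_q: float = 0.02,
    model_n: int = 25,
    model_p: float = 0.06,
    model_kmax: int = 4,
    renormalize: bool = False,
    up: float = 1.0,
    down: float = -1.0,
    alpha: float = 0.1,
    min_probes: int = 3,
) -> PipelineResult:
    """Run the full mismatch-aware calling pipeline on one dataset."""
    m = mask_probes(intensities, list(mask_patterns))
    m = background_correct(m, method="quantile_floor", q=background_q)
    normalized, _ = normalize(m)
    home_lin = to_linear(normalized.select_species(species_home))
    het_lin = to_linear(normalized.select_species(species_het))

    ref_mm = MismatchTable(
        mismatches.k.loc[
            mismatches.k.index.get_level_values("probeset_id").isin(set(reference_probesets))
        ],
        mismatches.species,
    )
    scaler = GlobalScaler(
        n=model_n, p=model_p, kmax=model_kmax, renormalize=renormalize
    )
    het_scaled = scaler.fit_transform(home_lin, het_lin, ref_mm)

    ratios = probe_log2_ratios(home_lin, het_scaled)
    caller = CNDCaller(up=up, down=down, alpha=alpha, min_probes=min_probes)
    caller.fit(ratios, gene_map=gene_map)
    return PipelineResult(
        caller.results_, scaler.factors_, scaler, caller, home_lin, het_scaled
    )
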