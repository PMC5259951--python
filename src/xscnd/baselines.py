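"""Re-implementations of two earlier cross-species array-CGH callers.

Both serve as comparison baselines for the mismatch-aware global
scaling pipeline:

* ``baseline_conserved_loess`` — loess normalization anchored on a set
  of conserved single-copy genes, Avdiff probeset summarization, and a
  sign test of the corrected log ratio (expanded when ratio > 0 at
  adjusted p <= 0.1); the workflow of spotted-cDNA-array callers
  adapted to 25-mer probesets.
* ``baseline_affinity_scaled`` — per-probe adjustment of log intensity
  on the duplex free energy dG37 (SantaLucia unified nearest-neighbor
  model), control-probe median scaling, probeset-mean log ratios and
  fixed +/-0.25 thresholds; the workflow of tiling-array callers.

Neither baseline models probe-target mismatches explicitly, which is
exactly the deficiency the global scaling method addresses.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .calling import bh_adjust, probe_log2_ratios, test_probesets
from .datamodel import (
    CNE,
    CNR,
    NEUTRAL,
    CALL_COLUMNS,
    IntensityMatrix,
    ProbeSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

# Unified nearest-neighbor free energies dG37 (kcal/mol, 1 M NaCl).
# Keyed by the top-strand dinucleotide read 5'->3'; the table is
# symmetric under reverse complement (AC == GT etc.).
NN_DG37: dict[str, float] = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}

#: duplex initiation penalties per terminal base pair
INIT_GC = 0.98
INIT_AT = 1.03


def delta_g37(seq: str) -> float:
    """Nearest-neighbor duplex free energy at 37 C, in kcal/mol.

    Sum of the 16 published dinucleotide stack parameters plus one
    initiation term per duplex end; no salt correction.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise ValidationError("dG37 is defined for sequences of length >= 2")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValidationError(f"ambiguity codes not supported: {sorted(bad)}")
    dg = sum(NN_DG37[seq[i : i + 2]] for i in range(len(seq) - 1))
    for terminal in (seq[0], seq[-1]):
        dg += INIT_GC if terminal in "GC" else INIT_AT
    return float(dg)


def avdiff(values: Sequence[float], n_sd: float = 3.0) -> float:
    """Average-difference probeset summary with one-pass outlier trim.

    Mean and SD are taken over the values with the single largest and
    smallest observation removed; values within ``n_sd`` SDs of that
    mean are averaged.  With two or fewer values, the plain mean.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValidationError("avdiff needs at least one value")
    if len(x) <= 2:
        return float(x.mean())
    order = np.argsort(x)
    core = x[order[1:-1]]
    mu, sd = float(core.mean()), float(core.std(ddof=1)) if len(core) > 1 else 0.0
    keep = np.abs(x - mu) <= n_sd * sd
    if not keep.any():
        return float(x.mean())
    return float(x[keep].mean())


def _classify_sign(fc: np.ndarray, p_adj: np.ndarray, alpha: float) -> np.ndarray:
    cls = np.full(len(fc), NEUTRAL, dtype=object)
    cls[(fc > 0) & (p_adj <= alpha)] = CNE
    cls[(fc < 0) & (p_adj <= alpha)] = CNR
    return cls


def baseline_conserved_loess(
    home: IntensityMatrix,
    het: IntensityMatrix,
    conserved: Iterable[str],
    n_select: int = 1000,
    seed: int = 0,
    alpha: float = 0.1,
    span: float = 0.5,
) -> pd.DataFrame:
    """Conserved-gene loess baseline caller.

    A loess curve of the mean log ratio against mean log intensity is
    fitted on probes of ``n_select`` randomly chosen conserved
    single-copy probesets and subtracted from every probe's ratios.
    Probesets are summarized by :func:`avdiff`; significance comes from
    the same moderated probe-level test as the main pipeline, with
    expansion called at ratio > 0 and adjusted p <= ``alpha``.
    """
    conserved = list(dict.fromkeys(conserved))
    if not conserved:
        raise ValidationError("conserved probeset list is empty")
    rng = np.random.default_rng(seed)
    if len(conserved) < n_select:
        logger.warning(
            "conserved set smaller than n_select (%d < %d); using all",
            len(conserved),
            n_select,
        )
        chosen = set(conserved)
    else:
        chosen = set(rng.choice(conserved, size=n_select, replace=False))

    ratios = probe_log2_ratios(home, het)
    hbar = home.replicate_means(home.species_list[0])
    ibar = het.replicate_means(het.species_list[0])
    a_val = 0.5 * (np.log2(hbar) + np.log2(ibar))
    m_val = np.log2(ibar) - np.log2(hbar)

    in_conserved = a_val.index.get_level_values("probeset_id").isin(chosen)
    x = a_val.to_numpy()[in_conserved]
    y = m_val.to_numpy()[in_conserved]
    if len(np.unique(x)) < 2 or np.allclose(y, y[0]):
        correction = pd.Series(float(y.mean()) if len(y) else 0.0, index=a_val.index)
    else:
        fit = lowess(y, x, frac=span, return_sorted=True)
        xs, ys = fit[:, 0], fit[:, 1]
        xs, idx = np.unique(xs, return_index=True)
        correction = pd.Series(np.interp(a_val.to_numpy(), xs, ys[idx]), index=a_val.index)

    key = pd.MultiIndex.from_frame(ratios[["probeset_id", "probe_index"]])
    ratios = ratios.assign(
        log2_ratio=ratios["log2_ratio"].to_numpy() - correction.reindex(key).to_numpy()
    )

    tested = test_probesets(ratios, min_probes=3, moderate=True)
    corrected_probe_mean = (
        ratios.groupby(["probeset_id", "probe_index"], sort=False)["log2_ratio"].mean()
    )
    fc = (
        corrected_probe_mean.groupby(level="probeset_id", sort=False)
        .apply(lambda v: avdiff(v.to_numpy()))
        .rename("log2_fc")
    )
    out = tested.drop(columns=["log2_fc"]).merge(
        fc.reset_index(), on="probeset_id", how="left"
    )
    callable_mask = out["p_raw"].notna().to_numpy()
    p_adj = np.full(len(out), np.nan)
    p_adj[callable_mask] = bh_adjust(out.loc[callable_mask, "p_raw"])
    out["p_adj"] = p_adj
    cls = _classify_sign(
        out["log2_fc"].to_numpy(), np.nan_to_num(out["p_adj"].to_numpy(), nan=1.0), alpha
    )
    cls[~callable_mask] = None
    out["cnd_class"] = cls
    out["gene_id"] = ""
    return out[[c for c in CALL_COLUMNS if c in out.columns]]


def baseline_affinity_scaled(
    home: IntensityMatrix,
    het: IntensityMatrix,
    probesets: Sequence[ProbeSet],
    control_probesets: Iterable[str],
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Duplex-affinity-adjusted, control-probe-scaled baseline caller.

    Per species, log2 probe intensity (replicate mean) is regressed on
    dG37 over the control probes; the fitted affinity component is
    removed and the control-probe median subtracted (median scaling).
    Gene-level fold changes are probeset means of the adjusted ratio,
    thresholded at ``+/-threshold`` with no significance test.
    """
    controls = set(control_probesets)
    if not controls:
        raise ValidationError("control probeset set is empty")
    dg = {}
    for ps in probesets:
        for idx, seq in ps.probes:
            dg[(ps.probeset_id, idx)] = delta_g37(seq)
    dg_series = pd.Series(dg)
    dg_series.index.names = ["probeset_id", "probe_index"]

    def _adjust(m: IntensityMatrix) -> pd.Series:
        bar = m.replicate_means(m.species_list[0])
        common = bar.index.intersection(dg_series.index)
        logi = np.log2(bar.loc[common])
        x = dg_series.loc[common]
        is_ctrl = common.get_level_values("probeset_id").isin(controls)
        if not is_ctrl.any():
            raise ValidationError("no unmasked control probes in matrix")
        design = sm.add_constant(x.to_numpy()[is_ctrl])
        fit = sm.OLS(logi.to_numpy()[is_ctrl], design).fit()
        predicted = fit.params[0] + fit.params[1] * x.to_numpy()
        resid = logi.to_numpy() - predicted
        resid = resid - np.median(resid[is_ctrl])
        return pd.Series(resid, index=common)

    adj_home = _adjust(home)
    adj_het = _adjust(het)
    common = adj_home.index.intersection(adj_het.index)
    ratio = (adj_het.loc[common] - adj_home.loc[common]).rename("log2_ratio")
    fc = ratio.groupby(level="probeset_id", sort=False).mean()

    out = pd.DataFrame(
        {
            "probeset_id": fc.index,
            "gene_id": "",
            "log2_fc": fc.to_numpy(),
            "p_raw": np.nan,
            "p_adj": np.nan,
        }
    )
    cls = np.full(len(out), NEUTRAL, dtype=object)
    cls[out["log2_fc"].to_numpy() >= threshold] = CNE
    cls[out["log2_fc"].to_numpy() <= -threshold] = CNR
    out["cnd_class"] = cls
    return out.reset_index(drop=True)
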