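"""Per-gene differential testing of scaled cross-species signals.

After within-species normalization and global scaling, each probe yields
one log2(heterologous/home) ratio per replicate pairing.  Per probeset
the gene-level effect is the mean ratio over probes and replicates, and
its significance comes from a probe-blocked linear model with an
empirical-Bayes moderated variance:

    s2_mod = (d0 * s0^2 + d * s^2) / (d0 + d)

where s^2 is the probeset's within-probe (between-replicate) residual
variance on d degrees of freedom and the prior (d0, s0^2) is fitted by
matching the first two moments of log s^2 across all probesets against
a scaled inverse-chi-square model.  The moderated t statistic is
referred to a t distribution on d + d0 degrees of freedom.

Genes are then classified: CNE (copy number expanded) when the fold
change reaches ``up`` (+1 by default, i.e. a doubling) at
Benjamini-Hochberg adjusted p <= alpha (0.1); CNR when it falls below
``down`` (-1); otherwise neutral.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    CNE,
    CNR,
    NEUTRAL,
    CALL_COLUMNS,
    IntensityMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: effective "infinite" prior degrees of freedom
_D0_CAP = 1e7

RATIO_COLUMNS = ("probeset_id", "probe_index", "replicate", "log2_ratio")


def probe_log2_ratios(
    home: IntensityMatrix, het_scaled: IntensityMatrix
) -> pd.DataFrame:
    """Replicate-paired per-probe log2(het/home) ratios.

    Both matrices must be linear-scale, hold a single species each and
    share the probe universe; replicate 1 pairs with replicate 1, etc.
    Masked probes (in either matrix) are dropped.
    """
    if home.log_scale or het_scaled.log_scale:
        raise ValidationError("ratios are formed on linear-scale intensities")
    if not home.values.index.equals(het_scaled.values.index):
        only = home.values.index.symmetric_difference(het_scaled.values.index)
        raise ValidationError(
            f"probe universes differ between matrices ({len(only)} probes unshared)"
        )
    sp_h = home.species_list
    sp_i = het_scaled.species_list
    if len(sp_h) != 1 or len(sp_i) != 1:
        raise ValidationError("each matrix must hold exactly one species")

    rep_h = {int(r): s for s, r in home.samples["replicate"].items()}
    rep_i = {int(r): s for s, r in het_scaled.samples["replicate"].items()}
    common = sorted(set(rep_h) & set(rep_i))
    if not common:
        raise ValidationError("no shared replicate numbers between species")

    keep = ~(home.mask | het_scaled.mask)
    frames = []
    for r in common:
        h = home.values.loc[keep, rep_h[r]].to_numpy()
        i = het_scaled.values.loc[keep, rep_i[r]].to_numpy()
        if (h <= 0).any() or (i <= 0).any():
            raise ValidationError("non-positive intensity in ratio formation")
        sub = pd.DataFrame(
            {
                "probeset_id": home.values.index.get_level_values("probeset_id")[keep],
                "probe_index": home.values.index.get_level_values("probe_index")[keep],
                "replicate": r,
                "log2_ratio": np.log2(i / h),
            }
        )
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment fit of the scaled inverse-chi-square variance prior.

    Matches mean and variance of log(s^2) across probesets, using the
    known moments of log chi-square.  Returns (d0, s0_sq); d0 is capped
    at a large finite value when the observed spread of variances is no
    wider than pure sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2 or d <= 0:
        return _D0_CAP, float(np.mean(s2)) if len(s2) else 0.0
    z = np.log(s2)
    evar = float(np.var(z, ddof=1)) - float(polygamma(1, d / 2.0))
    bias_d = float(digamma(d / 2.0) - np.log(d / 2.0))
    if evar <= 0:
        d0 = _D0_CAP
        s0_sq = float(np.exp(np.mean(z) - bias_d))
    else:
        d0 = min(2.0 * trigamma_inverse(evar), _D0_CAP)
        bias_d0 = float(digamma(d0 / 2.0) - np.log(d0 / 2.0))
        s0_sq = float(np.exp(np.mean(z) - bias_d + bias_d0))
    return d0, s0_sq


def _probeset_stats(ratios: pd.DataFrame, min_probes: int) -> pd.DataFrame:
    """Per-probeset fold change and residual variance of the probe-blocked fit."""
    for col in ("probeset_id", "probe_index", "log2_ratio"):
        if col not in ratios.columns:
            raise ValidationError(f"ratio table lacks column {col!r}")
    if ratios.empty:
        raise ValidationError("empty ratio table")
    r = ratios["log2_ratio"].to_numpy(dtype=float)
    probe_mean = ratios.groupby(["probeset_id", "probe_index"], sort=False)[
        "log2_ratio"
    ].transform("mean")
    resid_sq = (r - probe_mean.to_numpy()) ** 2

    grp = ratios.groupby("probeset_id", sort=False)
    stats_df = pd.DataFrame(
        {
            "log2_fc": grp["log2_ratio"].mean(),
            "m": grp.size(),
            "n_probes": grp["probe_index"].nunique(),
            "rss": pd.Series(resid_sq, index=ratios.index)
            .groupby(ratios["probeset_id"], sort=False)
            .sum(),
        }
    )
    stats_df["d"] = stats_df["m"] - stats_df["n_probes"]
    stats_df["s2"] = np.where(
        stats_df["d"] > 0, stats_df["rss"] / stats_df["d"].clip(lower=1), np.nan
    )
    stats_df["callable"] = stats_df["n_probes"] >= min_probes
    return stats_df


def test_probesets(
    ratios: pd.DataFrame,
    min_probes: int = 3,
    moderate: bool = True,
) -> pd.DataFrame:
    """Moderated (or plain) probe-blocked test of mean log2 ratio = 0.

    Returns one row per probeset: log2_fc, p_raw, plus the variance
    bookkeeping.  Probesets with fewer than ``min_probes`` probes get
    p_raw = NaN and are excluded from downstream calling.
    """
    st = _probeset_stats(ratios, min_probes)
    d_typ = float(st.loc[st["callable"] & (st["d"] > 0), "d"].median())
    if moderate and np.isfinite(d_typ) and d_typ > 0:
        d0, s0_sq = fit_variance_prior(
            st.loc[st["callable"], "s2"].to_numpy(), d_typ
        )
    else:
        d0, s0_sq = 0.0, 0.0

    d = st["d"].to_numpy(dtype=float)
    s2 = np.nan_to_num(st["s2"].to_numpy(dtype=float), nan=0.0)
    s2_mod = np.where(
        d + d0 > 0, (d0 * s0_sq + d * s2) / np.maximum(d + d0, 1e-300), s2
    )
    se = np.sqrt(s2_mod / st["m"].to_numpy(dtype=float))
    fc = st["log2_fc"].to_numpy(dtype=float)
    t = np.zeros_like(fc)
    pos = se > 0
    t[pos] = fc[pos] / se[pos]
    degenerate = ~pos & (fc != 0.0)
    t[degenerate] = np.sign(fc[degenerate]) * np.inf
    df_t = d + d0
    p = np.where(df_t > 0, 2.0 * stats.t.sf(np.abs(t), np.maximum(df_t, 1e-9)), np.nan)
    out = st.copy()
    out["t"] = t
    out["p_raw"] = np.where(out["callable"], p, np.nan)
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out.reset_index().rename(columns={"index": "probeset_id"})


def bh_adjust(p: np.ndarray | Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(list(p), dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify(
    log2_fc: float, p_adj: float, up: float = 1.0, down: float = -1.0, alpha: float = 0.1
) -> str:
    """Classify one gene as CNE / CNR / neutral."""
    if np.isnan(p_adj):
        return NEUTRAL
    if log2_fc >= up and p_adj <= alpha:
        return CNE
    if log2_fc <= down and p_adj <= alpha:
        return CNR
    return NEUTRAL


def call_cnd(
    tested: pd.DataFrame,
    up: float = 1.0,
    down: float = -1.0,
    alpha: float = 0.1,
    gene_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """BH-adjust raw p-values and classify every callable probeset.

    ``tested`` needs columns probeset_id, log2_fc, p_raw.  Probesets
    with missing p_raw are reported with NaN p_adj and a neutral-free
    NaN class (excluded from calling).
    """
    if tested.empty:
        raise ValidationError("no tested probesets to call")
    if up <= down:
        raise ValidationError("up threshold must exceed down threshold")
    out = tested.copy()
    callable_mask = out["p_raw"].notna()
    p_adj = np.full(len(out), np.nan)
    p_adj[callable_mask.to_numpy()] = bh_adjust(out.loc[callable_mask, "p_raw"])
    out["p_adj"] = p_adj

    fc = out["log2_fc"].to_numpy(dtype=float)
    cls = np.where(
        callable_mask & (fc >= up) & (out["p_adj"] <= alpha),
        CNE,
        np.where(
            callable_mask & (fc <= down) & (out["p_adj"] <= alpha), CNR, NEUTRAL
        ),
    ).astype(object)
    cls[~callable_mask.to_numpy()] = None
    out["cnd_class"] = cls
    if gene_map is not None:
        out["gene_id"] = out["probeset_id"].map(lambda x: gene_map.get(x, ""))
    elif "gene_id" not in out.columns:
        out["gene_id"] = ""
    cols = [c for c in CALL_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra]


def intersect_species(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> tuple[set[str], set[str]]:
    """Probesets called CNE (resp. CNR) in both species."""
    def _sets(calls: pd.DataFrame) -> tuple[set[str], set[str]]:
        cne = set(calls.loc[calls["cnd_class"] == CNE, "probeset_id"])
        cnr = set(calls.loc[calls["cnd_class"] == CNR, "probeset_id"])
        return cne, cnr

    cne_a, cnr_a = _sets(calls_a)
    cne_b, cnr_b = _sets(calls_b)
    return cne_a & cne_b, cnr_a & cnr_b


class CNDCaller(BaseEstimator):
    """Estimator interface to probe-level differential calling.

    ``fit`` consumes the replicate-paired probe ratio table, fits the
    variance prior across probesets, computes moderated tests and the
    BH-adjusted classification.  Fitted state lives in ``results_``
    (one row per probeset with log2_fc, p_raw, p_adj, cnd_class) and
    the prior parameters ``d0_`` / ``s0_sq_``.

    Parameters
    ----------
    up, down : float
        log2 fold-change thresholds for CNE / CNR (defaults +1 / -1).
    alpha : float
        BH-adjusted significance cut-off (default 0.1).
    min_probes : int
        Minimum unmasked probes per probeset (default 3).
    moderate : bool
        Apply empirical-Bayes variance moderation (default True).
    """

    def __init__(
        self,
        up: float = 1.0,
        down: float = -1.0,
        alpha: float = 0.1,
        min_probes: int = 3,
        moderate: bool = True,
    ) -> None:
        self.up = up
        self.down = down
        self.alpha = alpha
        self.min_probes = min_probes
        self.moderate = moderate

    def fit(
        self,
        ratios: pd.DataFrame,
        gene_map: Mapping[str, str] | None = None,
    ) -> "CNDCaller":
        tested = test_probesets(
            ratios, min_probes=self.min_probes, moderate=self.moderate
        )
        self.d0_ = tested.attrs["d0"]
        self.s0_sq_ = tested.attrs["s0_sq"]
        self.results_ = call_cnd(
            tested, up=self.up, down=self.down, alpha=self.alpha, gene_map=gene_map
        )
        return self

    def predict(self, probeset_ids: Iterable[str] | None = None) -> pd.Series:
        """Fitted class per probeset (optionally for a subset)."""
        if not hasattr(self, "results_"):
            raise ValidationError("CNDCaller is not fitted")
        cls = self.results_.set_index("probeset_id")["cnd_class"]
        if probeset_ids is None:
            return cls
        return cls.reindex(list(probeset_ids))

    def fit_predict(
        self,
        ratios: pd.DataFrame,
        gene_map: Mapping[str, str] | None = None,
    ) -> pd.Series:
        return self.fit(ratios, gene_map).predict()
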