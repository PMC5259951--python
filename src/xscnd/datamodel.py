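"""Core data containers for cross-species array-CGH copy-number analysis.

The method compares genomic-DNA hybridization signal measured on a
short-oligonucleotide expression array designed for a reference species
("home" species) against hybridizations of genomic DNA from heterologous
relatives.  Sequence divergence between a relative's genome and the
25-mer probes attenuates the heterologous signal; the containers below
carry the objects every stage of the pipeline exchanges:

* :class:`ProbeSet` — the group of 25-mer probes interrogating one gene.
* :class:`IntensityMatrix` — probe × sample intensities with species /
  replicate metadata and a probe exclusion mask.
* :class:`MismatchModel` — Binomial(n, p) model of per-probe mismatch
  counts, the basis of the global scaling correction.
* :class:`MismatchTable` — observed probe→mismatch-count map for one
  heterologous species.
* :class:`ScalingFactors` — per-mismatch-count correction factors S_k
  and the binomial-weighted global factor S.
* :class:`CNDCall` — a per-gene copy-number divergence call
  (CNE = copy number expanded, CNR = copy number reduced).

All tabular state is held in pandas objects so that downstream numerics
stay vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class XscndError(Exception):
    """Base class for package errors."""


class ParseError(XscndError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(XscndError):
    """An object violates one of its invariants."""


PROBE_LENGTH = 25
VALID_BASES = frozenset("ACGT")

#: Copy-number divergence classes.
CNE = "CNE"
CNR = "CNR"
NEUTRAL = "neutral"
CND_CLASSES = (CNE, CNR, NEUTRAL)

#: Reference-truth statuses.
EXPANDED = "expanded"
SINGLE_COPY = "single_copy"
REDUCED = "reduced"
TRUTH_STATUSES = (EXPANDED, SINGLE_COPY, REDUCED)

#: Column layout of a calls table (one row per probeset).
CALL_COLUMNS = ("probeset_id", "gene_id", "log2_fc", "p_raw", "p_adj", "cnd_class")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValidationError(f"negative interval start: {self.start}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def validate_probe_sequence(seq: str) -> str:
    """Check a probe sequence is a 25-mer over {A, C, G, T}."""
    if len(seq) != PROBE_LENGTH:
        raise ValidationError(
            f"probe sequence must be {PROBE_LENGTH} nt, got {len(seq)}: {seq!r}"
        )
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValidationError(f"invalid bases {sorted(bad)} in probe sequence {seq!r}")
    return seq


@dataclass
class ProbeSet:
    """The probes interrogating one gene.

    Parameters
    ----------
    probeset_id
        Array identifier of the probeset (the unit of gene-level calling).
    probes
        Ordered ``(probe_index, sequence)`` pairs; sequences are 25-mers.
    gene_id
        Genome identifier of the interrogated gene ('' when unknown).
    coords
        Optional genomic location of the gene body.
    """

    probeset_id: str
    probes: list[tuple[int, str]]
    gene_id: str = ""
    coords: GenomicInterval | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for idx, seq in self.probes:
            if idx in seen:
                raise ValidationError(
                    f"duplicate probe_index {idx} in probeset {self.probeset_id}"
                )
            seen.add(idx)
            validate_probe_sequence(seq)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def sequences(self) -> dict[int, str]:
        return dict(self.probes)


@dataclass
class IntensityMatrix:
    """Probe × sample intensity matrix with sample metadata and a mask.

    ``values`` is indexed by a ``(probeset_id, probe_index)`` MultiIndex
    with one column per sample, in the order the samples were declared.
    ``samples`` is indexed by sample id with ``species`` and ``replicate``
    columns.  ``mask`` flags probes excluded from every downstream
    statistic (organellar, control and known multi-copy genes).

    ``log_scale`` records whether values are on the generalized-log
    (glog2) scale produced by within-species normalization; raw and
    background-corrected matrices are linear and must be non-negative.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    mask: pd.Series | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError(
                "intensity columns must match sample metadata ids in order"
            )
        for col in ("species", "replicate"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample metadata lacks column {col!r}")
        if self.samples["species"].isna().any() or (self.samples["species"] == "").any():
            raise ValidationError("every sample needs a species label")
        if not self.log_scale and (self.values.to_numpy() < 0).any():
            raise ValidationError("negative intensities on a linear-scale matrix")
        if self.values.index.nlevels != 2:
            raise ValidationError("values index must be (probeset_id, probe_index)")
        if self.mask is None:
            self.mask = pd.Series(False, index=self.values.index)
        else:
            self.mask = self.mask.reindex(self.values.index, fill_value=False).astype(bool)

    # -- convenience -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def species_list(self) -> list[str]:
        seen: list[str] = []
        for sp in self.samples["species"]:
            if sp not in seen:
                seen.append(sp)
        return seen

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.samples.copy(), self.mask.copy(), self.log_scale
        )

    def samples_of(self, species: str) -> list[str]:
        sel = self.samples.index[self.samples["species"] == species]
        return list(sel)

    def select_species(self, species: str) -> "IntensityMatrix":
        """Sub-matrix holding only the given species' samples."""
        ids = self.samples_of(species)
        if not ids:
            raise ValidationError(f"no samples for species {species!r}")
        return IntensityMatrix(
            self.values[ids].copy(),
            self.samples.loc[ids].copy(),
            self.mask.copy(),
            self.log_scale,
        )

    def unmasked(self) -> pd.DataFrame:
        """Values restricted to unmasked probes."""
        return self.values.loc[~self.mask]

    def replicate_means(self, species: str) -> pd.Series:
        """Per-probe mean over the species' replicate samples (unmasked only)."""
        ids = self.samples_of(species)
        if not ids:
            raise ValidationError(f"no samples for species {species!r}")
        return self.unmasked()[ids].mean(axis=1)


@dataclass(frozen=True)
class MismatchModel:
    """Binomial(n, p) model of mismatch counts in an n-mer probe.

    Each probe position either matches the heterologous target or not,
    so the number of mismatches per probe is Binomial(n, p), with p the
    per-base divergence (default 0.06, i.e. 94% identity).  ``kmax``
    truncates the mismatch classes entering the global scaling factor.
    """

    n: int = PROBE_LENGTH
    p: float = 0.06
    kmax: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p must lie in [0, 1], got {self.p}")
        if not 0 <= self.kmax <= self.n:
            raise ValidationError(f"kmax must lie in [0, n={self.n}], got {self.kmax}")
        if self.n < 1:
            raise ValidationError(f"probe length must be positive, got {self.n}")

    def pmf(self, k: int | np.ndarray) -> float | np.ndarray:
        return stats.binom.pmf(k, self.n, self.p)

    def tail_above(self, k: int) -> float:
        """P(K > k)."""
        return float(stats.binom.sf(k, self.n, self.p))


@dataclass
class MismatchTable:
    """Observed mismatch count per probe for one heterologous species."""

    k: pd.Series  # MultiIndex (probeset_id, probe_index) -> int
    species: str = ""

    def __post_init__(self) -> None:
        kv = self.k.to_numpy()
        if len(kv) and ((kv < 0).any() or (kv > PROBE_LENGTH).any()):
            raise ValidationError("mismatch counts must lie in [0, 25]")
        self.k = self.k.astype(int)

    def histogram(self, n: int = PROBE_LENGTH) -> np.ndarray:
        """Counts of probes with k = 0..n mismatches."""
        return np.bincount(self.k.to_numpy(), minlength=n + 1)


@dataclass
class ScalingFactors:
    """Incremental (per-k) and global signal correction factors.

    ``per_k`` is indexed by mismatch count k and holds ``S_k`` (mean
    home/heterologous intensity ratio among probes with k mismatches)
    and ``N_k`` (number of probes behind the estimate).  ``S`` is the
    binomial-weighted global factor; ``renormalized`` records whether
    the truncated binomial weights were rescaled to sum to one.
    """

    per_k: pd.DataFrame
    S: float | None = None
    renormalized: bool = False
    interpolated: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for col in ("S_k", "N_k"):
            if col not in self.per_k.columns:
                raise ValidationError(f"per_k table lacks column {col!r}")
        if (self.per_k["S_k"] <= 0).any():
            raise ValidationError("S_k factors must be positive")
        observed = self.per_k.index.difference(pd.Index(self.interpolated))
        if (self.per_k.loc[observed, "N_k"] < 1).any():
            raise ValidationError("each observed S_k needs N_k >= 1")
        if self.S is not None and self.S <= 0:
            raise ValidationError("global scaling factor S must be positive")

    def factor(self, k: int) -> float:
        return float(self.per_k.loc[k, "S_k"])


@dataclass(frozen=True)
class CNDCall:
    """A per-gene copy-number divergence call."""

    probeset_id: str
    gene_id: str
    log2_fc: float
    p_raw: float
    p_adj: float
    cnd_class: str

    def __post_init__(self) -> None:
        if self.cnd_class not in CND_CLASSES:
            raise ValidationError(f"unknown call class {self.cnd_class!r}")


def calls_to_frame(calls: Iterable[CNDCall]) -> pd.DataFrame:
    rows = [
        (c.probeset_id, c.gene_id, c.log2_fc, c.p_raw, c.p_adj, c.cnd_class)
        for c in calls
    ]
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))


def validate_truth(truth: pd.Series) -> pd.Series:
    """Validate a gene_id -> status truth series."""
    bad = set(truth.unique()) - set(TRUTH_STATUSES)
    if bad:
        raise ValidationError(f"unknown truth statuses {sorted(bad)}")
    if truth.index.duplicated().any():
        raise ValidationError("duplicate gene ids in truth set")
    return truth
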