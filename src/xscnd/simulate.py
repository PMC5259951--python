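"""Synthetic cross-species hybridization datasets with known truth.

The generator emulates the data-generating process the pipeline assumes:
uniform 25-mer probes; heterologous targets derived by independent
per-base substitution with probability ``p_divergence`` (so per-probe
mismatch counts are exactly Binomial(25, p)); per-probe home-species
intensity drawn log-normal; heterologous intensity equal to the home
intensity times the gene's copy ratio, a k-dependent attenuation factor
(large first-mismatch drop, small further decrements, plateauing), and
multiplicative replicate noise; an additive per-sample background.

Planted truth covers copy states (default 5% expanded at 2x, 5% reduced
at 0.5x), a functionally enriched category among the expanded genes, a
set of fully conserved control probesets, and a deterministic genome
layout (optionally with clustered expansion blocks) for the segment
scanner.  Every draw flows from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    EXPANDED,
    REDUCED,
    SINGLE_COPY,
    GenomicInterval,
    IntensityMatrix,
    MismatchTable,
    ProbeSet,
    ValidationError,
)
from .mismatch import count_mismatches

_BASES = np.array(list("ACGT"))

#: default k -> signal multiplier; ~37% drop for the first mismatch,
#: small further decrements, plateau beyond k = 4
DEFAULT_ATTENUATION: dict[int, float] = {1: 0.63, 2: 0.58, 3: 0.54, 4: 0.51}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark."""

    seed: int
    n_genes: int = 2000
    probes_per_gene: int = 11
    replicates: int = 2
    p_divergence: float = 0.06
    attenuation: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION)
    )
    cne_fraction: float = 0.05
    cnr_fraction: float = 0.05
    cne_copy_ratio: float = 2.0
    cnr_copy_ratio: float = 0.5
    noise_sd: float = 0.25  # log2 scale, per probe per replicate
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.2
    background_offset: float = 50.0
    n_control_genes: int = 40
    n_categories: int = 25
    planted_category: str = "BIN01"
    planted_category_rate: float = 0.35
    background_category_rate: float = 0.08
    n_chromosomes: int = 2
    gene_length: int = 3000
    gene_spacing: int = 1000
    n_segment_blocks: int = 0
    block_genes: int = 6
    species_home: str = "home"
    species_het: str = "het"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        for name in ("p_divergence", "cne_fraction", "cnr_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.cne_fraction + self.cnr_fraction > 0.8:
            raise ValidationError("planted fractions leave too few neutral genes")
        att = [self.attenuation.get(k) for k in sorted(self.attenuation)]
        if any(a is None or not 0 < a <= 1 for a in att):
            raise ValidationError("attenuation multipliers must lie in (0, 1]")
        if att != sorted(att, reverse=True):
            raise ValidationError("attenuation must be non-increasing in k")

    def attenuation_for(self, k: int) -> float:
        if k == 0 or not self.attenuation:
            return 1.0
        kmax = max(self.attenuation)
        return self.attenuation[min(k, kmax)]


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    probesets: list[ProbeSet]
    intensities: IntensityMatrix  # both species, raw linear scale
    mismatches: MismatchTable
    targets: dict[tuple[str, int], str]
    truth: pd.Series  # gene_id -> status
    categories: pd.DataFrame  # probeset_id, category, name
    coords: pd.DataFrame  # chrom, start, end, strand, gene_id, probeset_id
    control_probesets: tuple[str, ...]
    chrom_lengths: dict[str, int]

    @property
    def gene_map(self) -> dict[str, str]:
        return {ps.probeset_id: ps.gene_id for ps in self.probesets}

    def single_copy_probesets(self, include_controls: bool = False) -> list[str]:
        status = self.truth
        ids = [
            ps.probeset_id
            for ps in self.probesets
            if status[ps.gene_id] == SINGLE_COPY
        ]
        if not include_controls:
            ctrl = set(self.control_probesets)
            ids = [i for i in ids if i not in ctrl]
        return ids


def _mutate(seq: np.ndarray, rng: np.random.Generator, p: float) -> np.ndarray:
    """Per-base substitution to a uniformly chosen different base."""
    hit = rng.random(len(seq)) < p
    if not hit.any():
        return seq.copy()
    out = seq.copy()
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = (seq[hit] + shifts) % 4
    return out


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw a full synthetic two-species hybridization experiment."""
    rng = np.random.default_rng(cfg.seed)
    n, ppg = cfg.n_genes, cfg.probes_per_gene

    # --- planted copy states -------------------------------------------
    n_cne = int(round(cfg.cne_fraction * n))
    n_cnr = int(round(cfg.cnr_fraction * n))
    n_ctrl = min(cfg.n_control_genes, n - n_cne - n_cnr)

    order = rng.permutation(n)
    cne_idx: list[int] = []
    used: set[int] = set()
    if cfg.n_segment_blocks > 0:
        # carve contiguous gene runs out of the genome for segment tests
        starts = rng.choice(
            np.arange(0, n - cfg.block_genes, cfg.block_genes * 4),
            size=cfg.n_segment_blocks,
            replace=False,
        )
        for s in starts:
            block = list(range(int(s), int(s) + cfg.block_genes))
            cne_idx.extend(block)
            used.update(block)
    for g in order:
        if len(cne_idx) >= n_cne:
            break
        if g not in used:
            cne_idx.append(int(g))
            used.add(int(g))
    cnr_idx = [int(g) for g in order if g not in used][:n_cnr]
    used.update(cnr_idx)
    ctrl_idx = [int(g) for g in order if g not in used][:n_ctrl]

    status = np.full(n, SINGLE_COPY, dtype=object)
    status[cne_idx] = EXPANDED
    status[cnr_idx] = REDUCED
    copy_ratio = np.ones(n)
    copy_ratio[cne_idx] = cfg.cne_copy_ratio
    copy_ratio[cnr_idx] = cfg.cnr_copy_ratio

    gene_ids = np.array([f"g{i:05d}" for i in range(n)])
    probeset_ids = np.array([f"ps{i:05d}" for i in range(n)])
    ctrl_set = set(probeset_ids[ctrl_idx])

    # --- probes, targets, mismatches -----------------------------------
    probesets: list[ProbeSet] = []
    targets: dict[tuple[str, int], str] = {}
    k_index, k_values = [], []
    coords_rows = []
    genes_per_chrom = int(np.ceil(n / cfg.n_chromosomes))
    pitch = cfg.gene_length + cfg.gene_spacing
    chrom_lengths = {}
    for c in range(cfg.n_chromosomes):
        n_on = min(genes_per_chrom, n - c * genes_per_chrom)
        chrom_lengths[f"chr{c + 1}"] = n_on * pitch + cfg.gene_spacing

    probe_codes = rng.integers(0, 4, size=(n, ppg, 25))
    for i in range(n):
        pid, gid = probeset_ids[i], gene_ids[i]
        is_ctrl = pid in ctrl_set
        probes = []
        for j in range(ppg):
            code = probe_codes[i, j]
            seq = "".join(_BASES[code])
            probes.append((j + 1, seq))
            tgt_code = code if is_ctrl else _mutate(code, rng, cfg.p_divergence)
            tgt = "".join(_BASES[tgt_code])
            targets[(pid, j + 1)] = tgt
            k_index.append((pid, j + 1))
            k_values.append(count_mismatches(seq, tgt))
        chrom = f"chr{i // genes_per_chrom + 1}"
        start = (i % genes_per_chrom) * pitch + cfg.gene_spacing
        coords = GenomicInterval(chrom, start, start + cfg.gene_length)
        probesets.append(ProbeSet(pid, probes, gid, coords))
        coords_rows.append(
            (chrom, start, start + cfg.gene_length, "+", gid, pid)
        )

    k_series = pd.Series(
        k_values,
        index=pd.MultiIndex.from_tuples(k_index, names=["probeset_id", "probe_index"]),
        dtype=int,
    )
    mismatches = MismatchTable(k_series, cfg.species_het)

    # --- intensities ----------------------------------------------------
    affinity = np.exp2(
        rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=(n, ppg))
    )
    att = np.vectorize(cfg.attenuation_for)(k_series.to_numpy().reshape(n, ppg))
    het_mean = affinity * copy_ratio[:, None] * att

    samples = []
    columns = {}
    for r in range(1, cfg.replicates + 1):
        for species, mean in ((cfg.species_home, affinity), (cfg.species_het, het_mean)):
            sid = f"{species}_r{r}"
            noise = np.exp2(rng.normal(0.0, cfg.noise_sd, size=(n, ppg)))
            offset = cfg.background_offset * rng.uniform(0.8, 1.2)
            columns[sid] = (mean * noise + offset).ravel()
            samples.append((sid, species, r))
    sample_df = pd.DataFrame(samples, columns=["sample_id", "species", "replicate"]).set_index(
        "sample_id"
    )
    # home samples first, then het, ordered by replicate
    col_order = [f"{sp}_r{r}" for sp in (cfg.species_home, cfg.species_het) for r in range(1, cfg.replicates + 1)]
    values = pd.DataFrame(columns, index=k_series.index)[col_order]
    intensities = IntensityMatrix(values, sample_df.loc[col_order])

    # --- truth, categories, coordinates --------------------------------
    truth = pd.Series(status, index=gene_ids, name="status")
    cat_labels = [f"BIN{j + 1:02d}" for j in range(cfg.n_categories)]
    other = [c for c in cat_labels if c != cfg.planted_category]
    cat_rows = []
    for i in range(n):
        in_planted_cat = rng.random() < (
            cfg.planted_category_rate if status[i] == EXPANDED else cfg.background_category_rate
        )
        if in_planted_cat:
            cat_rows.append((probeset_ids[i], cfg.planted_category, "planted"))
        else:
            cat_rows.append((probeset_ids[i], other[rng.integers(len(other))], ""))
        if rng.random() < 0.2:  # MapMan-style multi-assignment
            cat_rows.append((probeset_ids[i], other[rng.integers(len(other))], ""))
    categories = pd.DataFrame(cat_rows, columns=["probeset_id", "category", "name"]).drop_duplicates(
        ["probeset_id", "category"]
    )

    coords = pd.DataFrame(
        coords_rows, columns=["chrom", "start", "end", "strand", "gene_id", "probeset_id"]
    )
    return SimulatedDataset(
        cfg,
        probesets,
        intensities,
        mismatches,
        targets,
        truth,
        categories,
        coords,
        tuple(sorted(ctrl_set)),
        chrom_lengths,
    )


def simulate_scaling_benchmark(
    seed: int,
    n_probes_per_k: int = 250,
    kmax: int = 4,
    attenuation: dict[int, float] | None = None,
    noise_sd: float = 0.25,
    replicates: int = 2,
    baseline_log2_mean: float = 9.0,
    baseline_log2_sd: float = 1.2,
    species_home: str = "home",
    species_het: str = "het",
) -> tuple[IntensityMatrix, IntensityMatrix, MismatchTable]:
    """Clean benchmark for correction-factor recovery.

    Heterologous intensity is exactly home intensity times the planted
    k-dependent attenuation times multiplicative replicate noise, with
    ``n_probes_per_k`` probes forced into every mismatch class and no
    additive background — the direct test bed for the S_k estimator.
    """
    rng = np.random.default_rng(seed)
    att_map = dict(DEFAULT_ATTENUATION) if attenuation is None else dict(attenuation)
    att_map.setdefault(0, 1.0)

    ks = np.repeat(np.arange(kmax + 1), n_probes_per_k)
    n = len(ks)
    index = pd.MultiIndex.from_arrays(
        [[f"ref{i:05d}" for i in range(n)], np.ones(n, dtype=int)],
        names=["probeset_id", "probe_index"],
    )
    affinity = np.exp2(rng.normal(baseline_log2_mean, baseline_log2_sd, size=n))
    att = np.array([att_map[min(k, max(att_map))] if k else 1.0 for k in ks])

    def _matrix(mean: np.ndarray, species: str) -> IntensityMatrix:
        cols = {}
        meta = []
        for r in range(1, replicates + 1):
            sid = f"{species}_r{r}"
            cols[sid] = mean * np.exp2(rng.normal(0.0, noise_sd, size=n))
            meta.append((sid, species, r))
        samples = pd.DataFrame(meta, columns=["sample_id", "species", "replicate"]).set_index("sample_id")
        return IntensityMatrix(pd.DataFrame(cols, index=index), samples)

    home = _matrix(affinity, species_home)
    het = _matrix(affinity * att, species_het)
    mm = MismatchTable(pd.Series(ks, index=index, dtype=int), species_het)
    return home, het, mm


@dataclass(frozen=True)
class ReferenceSubset:
    """Reference probesets (with mismatch counts) for scaling estimation."""

    probeset_ids: tuple[str, ...]
    mismatches: MismatchTable


def make_reference_subset(
    dataset: SimulatedDataset, n_genes: int = 40, seed: int | None = None
) -> ReferenceSubset:
    """Random single-copy reference subset, excluding planted CNDs.

    Mirrors the curated reference datasets of known sequence used to
    estimate the incremental correction factors: single-copy genes only,
    with planted expansions/reductions (and control probesets) removed.
    """
    pool = dataset.single_copy_probesets(include_controls=False)
    if len(pool) < n_genes:
        raise ValidationError(
            f"only {len(pool)} single-copy genes available, need {n_genes}"
        )
    rng = np.random.default_rng(dataset.config.seed + 1 if seed is None else seed)
    chosen = tuple(sorted(rng.choice(pool, size=n_genes, replace=False)))
    sub = dataset.mismatches.k.loc[list(chosen)]
    return ReferenceSubset(chosen, MismatchTable(sub, dataset.mismatches.species))
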