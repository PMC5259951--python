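"""Readers and writers for the tabular formats the pipeline exchanges.

Everything is plain TSV/CSV, FASTA, BED or YAML; probe intensities are
tabulated rather than read from binary chip formats.  All readers
validate on the way in and raise :class:`~xscnd.datamodel.ParseError`
with a line number where possible; writers round-trip exactly with the
corresponding reader.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .datamodel import (
    GenomicInterval,
    IntensityMatrix,
    MismatchTable,
    ParseError,
    ProbeSet,
    ScalingFactors,
    ValidationError,
    validate_truth,
)

_ANNOT_COLUMNS = ("probeset_id", "probe_index", "sequence")


# ---------------------------------------------------------------------------
# probe annotation

def read_probe_annotation(path: str | Path, sep: str = "\t") -> list[ProbeSet]:
    """Read a probe annotation table into ProbeSets.

    Required columns: probeset_id, probe_index, sequence.  Optional:
    gene_id, chrom, start, end, strand (0-based half-open coordinates).
    """
    df = pd.read_csv(path, sep=sep, dtype={"probeset_id": str})
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["probeset_id", "probe_index"])
    if dup.any():
        line = int(dup.idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}:{line}: duplicate (probeset_id, probe_index)")

    probesets: list[ProbeSet] = []
    has_coords = {"chrom", "start", "end"}.issubset(df.columns)
    for pid, grp in df.groupby("probeset_id", sort=False):
        probes = []
        for row in grp.itertuples():
            try:
                probes.append((int(row.probe_index), str(row.sequence)))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{row.Index + 2}: bad probe_index") from exc
        gene_id = str(grp["gene_id"].iloc[0]) if "gene_id" in grp.columns else ""
        coords = None
        if has_coords and not pd.isna(grp["chrom"].iloc[0]):
            coords = GenomicInterval(
                str(grp["chrom"].iloc[0]),
                int(grp["start"].iloc[0]),
                int(grp["end"].iloc[0]),
                str(grp["strand"].iloc[0]) if "strand" in grp.columns else "+",
            )
        try:
            probesets.append(ProbeSet(str(pid), probes, gene_id, coords))
        except ValidationError as exc:
            first = int(grp.index[0]) + 2
            raise ParseError(f"{path}:{first}: {exc}") from exc
    return probesets


def write_probe_annotation(probesets: Sequence[ProbeSet], path: str | Path) -> None:
    rows = []
    for ps in probesets:
        for idx, seq in ps.probes:
            row = {
                "probeset_id": ps.probeset_id,
                "probe_index": idx,
                "sequence": seq,
                "gene_id": ps.gene_id,
            }
            if ps.coords is not None:
                row.update(
                    chrom=ps.coords.chrom,
                    start=ps.coords.start,
                    end=ps.coords.end,
                    strand=ps.coords.strand,
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intensity matrices

def read_intensities(path: str | Path, sep: str = "\t") -> IntensityMatrix:
    """Read a probe-intensity matrix, wide or long layout.

    Wide layout: ``#sample <id> <species> <replicate>`` comment lines,
    then a table ``probeset_id  probe_index  <sample columns...>``.
    Long layout: columns probeset_id, probe_index, sample_id, species,
    replicate, intensity (no comment header needed).
    """
    path = Path(path)
    meta_rows: list[tuple[str, str, int]] = []
    body_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#sample\t"):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    raise ParseError(f"{path}:{lineno}: malformed #sample line")
                try:
                    meta_rows.append((parts[1], parts[2], int(parts[3])))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad replicate number") from exc
            elif line.startswith("#"):
                continue
            else:
                body_lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(body_lines)), sep=sep, dtype={"probeset_id": str})

    if "intensity" in df.columns:  # long layout
        required = {"probeset_id", "probe_index", "sample_id", "species", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: long layout missing columns {sorted(missing)}")
        if df["species"].isna().any():
            raise ParseError(f"{path}: sample with missing species label")
        samples = (
            df[["sample_id", "species", "replicate"]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")
        )
        wide = df.pivot_table(
            index=["probeset_id", "probe_index"],
            columns="sample_id",
            values="intensity",
            sort=False,
        )[list(samples.index)]
        wide.columns.name = None
        values = wide
    else:  # wide layout
        if not meta_rows:
            raise ParseError(f"{path}: wide layout requires #sample metadata lines")
        samples = pd.DataFrame(
            meta_rows, columns=["sample_id", "species", "replicate"]
        ).set_index("sample_id")
        if (samples["species"] == "").any():
            raise ParseError(f"{path}: sample with missing species label")
        for col in ("probeset_id", "probe_index"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing column {col!r}")
        missing_cols = [s for s in samples.index if s not in df.columns]
        if missing_cols:
            raise ParseError(f"{path}: intensity columns missing for {missing_cols}")
        values = df.set_index(["probeset_id", "probe_index"])[list(samples.index)]

    if values.isna().any().any():
        raise ParseError(f"{path}: missing intensity values")
    if (values.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative intensity value")
    return IntensityMatrix(values.astype(float), samples)


def write_intensities(
    m: IntensityMatrix, path: str | Path, layout: str = "wide"
) -> None:
    path = Path(path)
    if layout == "wide":
        with open(path, "w") as fh:
            for sid, row in m.samples.iterrows():
                fh.write(f"#sample\t{sid}\t{row['species']}\t{int(row['replicate'])}\n")
            m.values.reset_index().to_csv(fh, sep="\t", index=False)
    elif layout == "long":
        long = (
            m.values.stack()
            .rename("intensity")
            .reset_index()
            .rename(columns={"level_2": "sample_id"})
        )
        long = long.merge(m.samples.reset_index(), on="sample_id")
        long[
            ["probeset_id", "probe_index", "sample_id", "species", "replicate", "intensity"]
        ].to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# mismatch tables and target sequences

def read_mismatch_table(path: str | Path) -> MismatchTable:
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str})
    for col in ("probeset_id", "probe_index", "k"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    species = str(df["species"].iloc[0]) if "species" in df.columns and len(df) else ""
    k = df.set_index(["probeset_id", "probe_index"])["k"]
    return MismatchTable(k, species)


def write_mismatch_table(mm: MismatchTable, path: str | Path) -> None:
    df = mm.k.rename("k").reset_index()
    df["species"] = mm.species
    df.to_csv(path, sep="\t", index=False)


def read_target_fasta(path: str | Path) -> dict[tuple[str, int], str]:
    """Read aligned heterologous target 25-mers keyed ``probeset|index``."""
    targets: dict[tuple[str, int], str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            pid, idx = rec.id.rsplit("|", 1)
            key = (pid, int(idx))
        except ValueError as exc:
            raise ParseError(
                f"{path}: target id {rec.id!r} not of the form probeset|index"
            ) from exc
        targets[key] = str(rec.seq).upper()
    return targets


def write_target_fasta(targets: Mapping[tuple[str, int], str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for (pid, idx), seq in targets.items():
            fh.write(f">{pid}|{idx}\n{seq}\n")


# ---------------------------------------------------------------------------
# scaling factors

def write_scaling_factors(sf: ScalingFactors, path: str | Path) -> None:
    doc = {
        "global_S": None if sf.S is None else float(sf.S),
        "renormalized": bool(sf.renormalized),
        "interpolated_k": [int(k) for k in sf.interpolated],
        "per_k": [
            {"k": int(k), "S_k": float(r["S_k"]), "N_k": int(r["N_k"])}
            for k, r in sf.per_k.iterrows()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_scaling_factors(path: str | Path) -> ScalingFactors:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    per_k = pd.DataFrame(doc["per_k"]).set_index("k")[["S_k", "N_k"]]
    return ScalingFactors(
        per_k,
        S=doc.get("global_S"),
        renormalized=bool(doc.get("renormalized", False)),
        interpolated=tuple(doc.get("interpolated_k", ())),
    )


# ---------------------------------------------------------------------------
# truth sets, category maps, calls

def read_truth_set(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "status"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return validate_truth(df.set_index("gene_id")["status"])


def write_truth_set(truth: pd.Series, path: str | Path) -> None:
    truth.rename("status").rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_category_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV: probeset_id, category (path 'CODE:name' or bare code).

    Returns a tidy frame with columns probeset_id, category, name.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probeset_id", "category"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    split = df["category"].str.split(":", n=1, expand=True)
    out = pd.DataFrame(
        {
            "probeset_id": df["probeset_id"],
            "category": split[0],
            "name": split[1].fillna("") if split.shape[1] > 1 else "",
        }
    )
    return out


def write_category_map(categories: pd.DataFrame, path: str | Path) -> None:
    df = categories.copy()
    if "name" in df.columns:
        named = df["name"].fillna("") != ""
        df.loc[named, "category"] = df.loc[named, "category"] + ":" + df.loc[named, "name"]
    df[["probeset_id", "category"]].to_csv(path, sep="\t", index=False)


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probeset_id": str, "gene_id": str})


# ---------------------------------------------------------------------------
# genomic intervals (BED / GFF)

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into chrom/start/end(/name/score/strand) columns."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        raise ParseError(f"{path}: BED interval with end <= start")
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gff_genes(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Extract gene intervals from a GFF3 file (1-based -> 0-based half-open).

    The ``name`` column is taken from the ID= attribute.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"],
        dtype={"chrom": str},
    )
    df = df[df["feature"] == feature].copy()
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    df["name"] = df["attrs"].str.extract(r"ID=([^;]+)")[0]
    return df[["chrom", "start", "end", "name", "strand"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "model": {"n": 25, "p": 0.06, "kmax": 4},
    "thresholds": {"up": 1.0, "down": -1.0, "alpha": 0.1},
    "background": {"method": "quantile_floor", "q": 0.02},
    "scaling": {"renormalize": False, "min_probes": 2},
    "enrichment": {"alpha": 0.05, "alternative": "greater"},
    "segments": {"window": 20000, "step": 10000, "min_cov": 5000, "min_consecutive": 3},
    "seed": 0,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, filling unset keys with defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg
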