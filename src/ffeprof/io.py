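"""Readers and writers for the pipeline's tabular artifacts.

All files are TSV, UTF-8, with ``#`` comment lines permitted before the
header. Readers validate schema and content invariants and raise
:class:`~ffeprof.errors.SchemaError` / :class:`~ffeprof.errors.IntegrityError`
with offending line numbers where applicable; writers produce files that
read back to an equal object.

Quantification matrices exist at two levels: *fraction* (raw run, samples
1..96) and *pooled* (adjacent fractions combined, samples 1..48). The level
is auto-detected from the sample-axis range where unambiguous (max sample
> 48 implies fraction level); otherwise an explicit ``level`` is required.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

#: Controlled vocabulary of compartment labels, anodic to cathodic.
COMPARTMENTS = ("TP", "ER", "GA", "TGN", "Chl-envelope", "TLK", "MT", "PM")

#: The four transmembrane-prediction programs consumed as count columns:
#: two alpha-helix topology predictors and two beta-barrel predictors.
TM_PROGRAMS = ("hmmtop", "tmhmm", "mcmbb", "tmbetadisc_rbf")

_AGI_RE = re.compile(r"^At[1-5CM]g\d{5}$")

N_FRACTIONS = 96


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class QuantMatrix:
    """Long-form protein quantification table.

    ``data`` has columns ``protein_id`` (str), ``sample`` (int),
    ``replicate`` (int), ``peak_area`` (float >= 0); the (protein, sample,
    replicate) key is unique and the sample axis is contiguous.
    """

    data: pd.DataFrame
    level: str  # "fraction" | "pooled"

    def __post_init__(self) -> None:
        if self.level not in ("fraction", "pooled"):
            raise ValueError(f"unknown level {self.level!r}")
        _validate_quant_frame(self.data)

    @property
    def samples(self) -> np.ndarray:
        return np.sort(self.data["sample"].unique())

    @property
    def replicates(self) -> np.ndarray:
        return np.sort(self.data["replicate"].unique())

    @property
    def proteins(self) -> np.ndarray:
        return self.data["protein_id"].unique()

    def pivot(self) -> pd.DataFrame:
        """(protein_id, replicate) x sample wide matrix, missing cells 0."""
        wide = self.data.pivot_table(
            index=["protein_id", "replicate"],
            columns="sample",
            values="peak_area",
            aggfunc="sum",
            fill_value=0.0,
        )
        return wide.reindex(columns=self.samples, fill_value=0.0)

    def totals(self) -> pd.Series:
        """Total signal per (protein, replicate), conserved by pooling."""
        return self.data.groupby(["protein_id", "replicate"])["peak_area"].sum()


@dataclass
class FractionationRun:
    """Per-fraction OD280 trace of a 96-fraction run."""

    od280: pd.Series  # index: fraction 1..96

    def __post_init__(self) -> None:
        idx = np.asarray(self.od280.index)
        if len(idx) != N_FRACTIONS or not np.array_equal(
            np.sort(idx), np.arange(1, N_FRACTIONS + 1)
        ):
            raise IntegrityError(
                f"OD280 trace must cover fractions 1..{N_FRACTIONS} exactly once"
            )
        self.od280 = self.od280.sort_index().astype(float)
        self.od280.index.name = "fraction"
        self.od280.name = "od280"


@dataclass
class MarkerSet:
    """Curated marker proteins: one compartment per protein."""

    data: pd.DataFrame  # columns protein_id, compartment, source

    def __post_init__(self) -> None:
        df = self.data
        dup = df["protein_id"][df["protein_id"].duplicated()]
        if len(dup):
            raise IntegrityError(
                "marker listed under more than one entry: "
                + ", ".join(sorted(set(dup)))
            )
        bad = sorted(set(df["compartment"]) - set(COMPARTMENTS))
        if bad:
            raise IntegrityError(f"unknown compartment labels: {bad}")

    def by_compartment(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for comp, grp in self.data.groupby("compartment"):
            out[str(comp)] = list(grp["protein_id"])
        return out

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class AnnotationMap:
    """Prior localization per protein: AGI accession, high-confidence-marker
    (HCM) compartment, and consensus-predictor compartment(s).

    Multiple consensus locations are semicolon-separated. Empty strings mean
    "no annotation".
    """

    data: pd.DataFrame  # columns protein_id, agi, hcm, consensus

    def __post_init__(self) -> None:
        df = self.data
        dup = df["protein_id"][df["protein_id"].duplicated()]
        if len(dup):
            raise IntegrityError(
                "duplicate annotation rows for: " + ", ".join(sorted(set(dup)))
            )
        for agi in df["agi"]:
            if agi and not _AGI_RE.match(agi):
                raise IntegrityError(f"malformed AGI accession {agi!r}")
        self._by_id = df.set_index("protein_id")

    def compartments_of(self, protein_id: str) -> list[str]:
        """Annotated compartment(s); HCM preferred over consensus."""
        if protein_id not in self._by_id.index:
            return []
        row = self._by_id.loc[protein_id]
        if row["hcm"]:
            return [row["hcm"]]
        if row["consensus"]:
            return [c for c in str(row["consensus"]).split(";") if c]
        return []

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id.index


@dataclass
class TMTable:
    """Predicted transmembrane-domain counts, one column per program."""

    data: pd.DataFrame  # columns protein_id + TM_PROGRAMS

    def __post_init__(self) -> None:
        df = self.data
        dup = df["protein_id"][df["protein_id"].duplicated()]
        if len(dup):
            raise IntegrityError(
                "duplicate TM rows for: " + ", ".join(sorted(set(dup)))
            )
        counts = df[list(TM_PROGRAMS)]
        if (counts.to_numpy() < 0).any():
            raise IntegrityError("negative TMD counts are not allowed")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _validate_quant_frame(df: pd.DataFrame) -> None:
    required = ["protein_id", "sample", "replicate", "peak_area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"quant matrix missing columns: {missing}")
    if (df["peak_area"].to_numpy() < 0).any():
        raise IntegrityError("negative peak_area values are not allowed")
    if df.duplicated(["protein_id", "sample", "replicate"]).any():
        raise IntegrityError("duplicate (protein, sample, replicate) keys")
    samples = np.sort(df["sample"].unique())
    if len(samples) and not np.array_equal(
        samples, np.arange(samples[0], samples[-1] + 1)
    ):
        raise IntegrityError("sample axis is not contiguous")


def _read_tsv(path: str | Path, required: Sequence[str],
              numeric: Sequence[str] = ()) -> pd.DataFrame:
    """Read a '#'-commented TSV, check columns, and reject malformed
    numerics with their line numbers."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected a header") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    # recover 1-based file line numbers (header + preceding comment lines)
    with open(path, encoding="utf-8") as fh:
        offset = 1
        for line in fh:
            offset += 1
            if not line.startswith("#"):
                break
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & (df[col] != "")]
        if len(bad):
            lines = [int(i) + offset for i in bad[:5]]
            raise SchemaError(
                f"{path}: malformed numeric in column {col!r} "
                f"at line(s) {lines}"
            )
        df[col] = converted
    df.attrs["line_offset"] = offset
    return df


def _write_tsv(df: pd.DataFrame, path: str | Path,
               comments: Iterable[str] = ()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_quant_matrix(path: str | Path, level: str | None = None) -> QuantMatrix:
    """Read a long-form quantification TSV.

    ``level`` may be "fraction" or "pooled"; when omitted it is auto-detected
    from the sample range (max > 48 means fraction level, a complete 1..48
    axis means pooled). Ambiguous ranges require the explicit flag.

    Absent (protein, sample, replicate) cells are materialized as 0 on the
    full protein x sample x replicate grid, with a count logged (SWATH
    exports report non-detections as absent rows).
    """
    df = _read_tsv(path, ["protein_id", "sample", "replicate", "peak_area"],
                   numeric=["sample", "replicate", "peak_area"])
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    df["sample"] = df["sample"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    df["peak_area"] = df["peak_area"].astype(float)
    neg = df.index[df["peak_area"] < 0]
    if len(neg):
        line = int(neg[0]) + df.attrs["line_offset"]
        raise IntegrityError(f"{path}: negative peak_area at line {line}")
    dup = df.index[df.duplicated(["protein_id", "sample", "replicate"])]
    if len(dup):
        line = int(dup[0]) + df.attrs["line_offset"]
        raise IntegrityError(
            f"{path}: duplicate (protein, sample, replicate) key at "
            f"line {line}")

    smax = int(df["sample"].max())
    if level is None:
        if smax > 48:
            level = "fraction"
        elif smax == 48:
            level = "pooled"
        else:
            raise SchemaError(
                f"{path}: sample range 1..{smax} is ambiguous; "
                "pass level='fraction' or level='pooled'"
            )
    logger.info("read %s as %s-level matrix", path, level)

    # densify: absent cells become explicit zeros
    proteins = df["protein_id"].unique()
    samples = np.arange(int(df["sample"].min()), smax + 1)
    replicates = np.sort(df["replicate"].unique())
    full = pd.MultiIndex.from_product(
        [proteins, samples, replicates],
        names=["protein_id", "sample", "replicate"],
    )
    dense = (
        df.set_index(["protein_id", "sample", "replicate"])["peak_area"]
        .reindex(full, fill_value=0.0)
        .reset_index()
    )
    n_filled = len(dense) - len(df)
    if n_filled:
        logger.info("materialized %d absent cells as 0", n_filled)
    return QuantMatrix(dense, level=level)


def read_od280(path: str | Path) -> FractionationRun:
    """Read a per-fraction OD280 trace (columns fraction, od280)."""
    df = _read_tsv(path, ["fraction", "od280"], numeric=["fraction", "od280"])
    ser = pd.Series(
        df["od280"].astype(float).to_numpy(),
        index=df["fraction"].astype(int).to_numpy(),
    )
    if ser.index.duplicated().any():
        raise IntegrityError(f"{path}: duplicate fraction indices")
    return FractionationRun(ser)


def read_marker_table(path: str | Path) -> MarkerSet:
    """Read a marker table (columns protein_id, compartment, source)."""
    df = _read_tsv(path, ["protein_id", "compartment"])
    if "source" not in df.columns:
        df["source"] = ""
    return MarkerSet(df[["protein_id", "compartment", "source"]])


def read_annotation_table(path: str | Path) -> AnnotationMap:
    """Read prior-annotation table (protein_id, agi, hcm, consensus)."""
    df = _read_tsv(path, ["protein_id"])
    for col in ("agi", "hcm", "consensus"):
        if col not in df.columns:
            df[col] = ""
    return AnnotationMap(df[["protein_id", "agi", "hcm", "consensus"]])


def read_tm_table(path: str | Path) -> TMTable:
    """Read per-program TMD counts; missing program values are 0."""
    header = pd.read_csv(path, sep="\t", comment="#", nrows=0).columns
    df = _read_tsv(path, ["protein_id"],
                   numeric=[p for p in TM_PROGRAMS if p in header])
    for prog in TM_PROGRAMS:
        if prog not in df.columns:
            df[prog] = 0
        df[prog] = (
            pd.to_numeric(df[prog], errors="coerce").fillna(0).astype(int)
        )
    return TMTable(df[["protein_id", *TM_PROGRAMS]])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_quant_matrix(matrix: QuantMatrix, path: str | Path,
                       comments: Iterable[str] = ()) -> None:
    _write_tsv(matrix.data, path,
               comments=[f"level: {matrix.level}", *comments])


def write_od280(run: FractionationRun, path: str | Path,
                comments: Iterable[str] = ()) -> None:
    _write_tsv(run.od280.reset_index(), path, comments=comments)


def write_marker_table(markers: MarkerSet, path: str | Path) -> None:
    _write_tsv(markers.data, path)


def write_annotation_table(annotation: AnnotationMap, path: str | Path) -> None:
    _write_tsv(annotation.data, path)


def write_tm_table(tm: TMTable, path: str | Path) -> None:
    _write_tsv(tm.data, path)


def write_localization_report(calls, path: str | Path) -> pd.DataFrame:
    """Write one row per protein: per-compartment scores, assignment,
    population count and peak positions, dual and discordance flags.
    Column order is deterministic.
    """
    rows = []
    for call in calls:
        row: dict[str, object] = {"protein_id": call.protein_id}
        for comp in COMPARTMENTS:
            if comp in call.scores:
                score = call.scores[comp]
                row[f"score_{comp}"] = "" if score is None else round(score, 6)
        row["assigned"] = call.assigned
        row["margin"] = "" if call.margin is None else round(call.margin, 6)
        row["n_populations"] = len(call.populations)
        row["peak_samples"] = ";".join(
            str(p.peak_sample) for p in call.populations
        )
        row["population_masses"] = ";".join(
            f"{p.mass:.4f}" for p in call.populations
        )
        row["population_compartments"] = ";".join(
            p.compartment or "none" for p in call.populations
        )
        row["dual_flag"] = int(call.dual_flag)
        row["discordance_flag"] = int(call.discordance_flag)
        rows.append(row)
    df = pd.DataFrame(rows)
    _write_tsv(df, path)
    return df


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("ffeprof").joinpath("data", name)))


def load_default_markers() -> MarkerSet:
    """Marker fixture transcribed from the curated marker tables."""
    return read_marker_table(_data_path("markers_tables.tsv"))


def load_unexpected_pm() -> AnnotationMap:
    """PM-annotated proteins whose FFE profiles overlap the tonoplast
    window (the study's discordant set)."""
    df = _read_tsv(_data_path("unexpected_pm.tsv"),
                   ["protein_id", "agi", "annotated_compartment"])
    df = df.rename(columns={"annotated_compartment": "hcm"})
    df["consensus"] = df["hcm"]
    return AnnotationMap(df[["protein_id", "agi", "hcm", "consensus"]])
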