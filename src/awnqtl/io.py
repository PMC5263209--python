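"""Tabular formats, domain containers and run configuration.

All exchange formats are plain delimited text (TSV by default, comma
accepted on read).  Marker *names* are the currency between modules; cM
positions are real-valued and chromosome labels are free strings (``1H`` ..
``7H`` for barley).  Genotypes are coded as alternate-allele dosage 0/1/2
with ``NA`` for missing.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("awnqtl")

MISSING = -1  # internal integer code for a missing genotype call


class FormatError(ValueError):
    """Raised when an input file violates its documented schema."""


# ---------------------------------------------------------------------------
# Genetic map


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: name, chromosome label, position in cM.

    Markers are sorted by (chromosome, position); names are unique.
    ``chrom_lengths`` gives the simulated length of each chromosome; it
    defaults to the last marker position.
    """

    table: pd.DataFrame  # columns: marker, chromosome, position
    chrom_lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        dup = t["marker"][t["marker"].duplicated()].tolist()
        if dup:
            raise FormatError(f"duplicate marker name(s): {sorted(set(dup))}")
        if (t["position"] < 0).any():
            bad = t.loc[t["position"] < 0, "marker"].iloc[0]
            raise FormatError(f"negative cM position at marker {bad!r}")
        t = t.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "table", t)
        lengths = dict(self.chrom_lengths)
        for chrom, sub in t.groupby("chromosome", sort=False):
            lengths.setdefault(str(chrom), float(sub["position"].max()))
        object.__setattr__(self, "chrom_lengths", lengths)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chromosome"] == chrom, "position"].to_numpy(float)

    def markers_on(self, chrom: str) -> list[str]:
        return self.table.loc[self.table["chromosome"] == chrom, "marker"].tolist()

    def locate(self, marker: str) -> tuple[str, float]:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not on map")
        return str(row["chromosome"].iloc[0]), float(row["position"].iloc[0])

    def index_of(self, marker: str) -> int:
        idx = self.table.index[self.table["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"marker {marker!r} not on map")
        return int(idx[0])


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a map table with header columns marker, chromosome, position."""
    df = _read_table(path)
    required = {"marker", "chromosome", "position"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: map file needs columns {sorted(required)}")
    pos = pd.to_numeric(df["position"], errors="coerce")
    if pos.isna().any():
        line = int(pos.index[pos.isna()][0]) + 2  # header + 1-based
        raise FormatError(f"{path}: non-numeric position on line {line}")
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": df["marker"].astype(str),
                "chromosome": df["chromosome"].astype(str),
                "position": pos.astype(float),
            }
        )
    )


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Founder panel


@dataclass(frozen=True)
class FounderPanel:
    """Founder allele matrix (entries 0/1, MISSING) aligned to a map.

    The first founder is the recurrent (recipient) parent by convention;
    ``recipient_index`` makes the designation explicit.
    """

    founder_names: list[str]
    alleles: np.ndarray  # founders x markers, int8, entries {0,1,MISSING}
    recipient_index: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles, dtype=np.int8)
        ok = np.isin(a, (0, 1, MISSING))
        if not ok.all():
            raise FormatError("founder alleles must be 0, 1 or missing")
        if not 0 <= self.recipient_index < len(self.founder_names):
            raise FormatError("recipient index out of range")
        if len(set(self.founder_names)) != len(self.founder_names):
            raise FormatError("founder names must be unique")
        object.__setattr__(self, "alleles", a)

    @property
    def n_founders(self) -> int:
        return len(self.founder_names)

    @property
    def recipient(self) -> str:
        return self.founder_names[self.recipient_index]

    @property
    def donors(self) -> list[str]:
        return [f for i, f in enumerate(self.founder_names) if i != self.recipient_index]

    def founder_index(self, name: str) -> int:
        return self.founder_names.index(name)


def read_founder_panel(path: str | Path, gmap: GeneticMap) -> FounderPanel:
    """Read founders x markers alleles; first row is the recipient."""
    df = _read_table(path)
    if "founder" not in df.columns:
        raise FormatError(f"{path}: founder panel needs a 'founder' column")
    names = df["founder"].astype(str).tolist()
    mat = _genotype_matrix(df, gmap, path, allowed=(0, 1))
    return FounderPanel(names, mat, recipient_index=0)


def write_founder_panel(panel: FounderPanel, gmap: GeneticMap, path: str | Path) -> None:
    df = pd.DataFrame(panel.alleles, columns=gmap.markers)
    df = df.mask(df == MISSING).astype("Int64")
    df.insert(0, "founder", panel.founder_names)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Genotype table


@dataclass(frozen=True)
class MarkerGenotypeTable:
    """Lines x markers dosage matrix with a cross label per line."""

    line_ids: list[str]
    cross_ids: list[str]
    genotypes: np.ndarray  # lines x markers, int8, entries {0,1,2,MISSING}

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if not np.isin(g, (0, 1, 2, MISSING)).all():
            raise FormatError("genotype entries must be 0, 1, 2 or missing")
        if len(self.line_ids) != len(self.cross_ids) or len(self.line_ids) != g.shape[0]:
            raise FormatError("line/cross/genotype dimensions disagree")
        object.__setattr__(self, "genotypes", g)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


def read_genotypes(path: str | Path, gmap: GeneticMap) -> MarkerGenotypeTable:
    df = _read_table(path)
    for col in ("line_id", "cross_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: genotype file needs a {col!r} column")
    mat = _genotype_matrix(df, gmap, path, allowed=(0, 1, 2))
    return MarkerGenotypeTable(
        df["line_id"].astype(str).tolist(), df["cross_id"].astype(str).tolist(), mat
    )


def write_genotypes(table: MarkerGenotypeTable, gmap: GeneticMap, path: str | Path) -> None:
    df = pd.DataFrame(table.genotypes, columns=gmap.markers)
    df = df.mask(df == MISSING).astype("Int64")
    df.insert(0, "cross_id", table.cross_ids)
    df.insert(0, "line_id", table.line_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _genotype_matrix(df: pd.DataFrame, gmap: GeneticMap, path, allowed) -> np.ndarray:
    meta_cols = {"line_id", "cross_id", "founder"}
    value_cols = [c for c in df.columns if c not in meta_cols]
    unknown = set(value_cols) - set(gmap.markers)
    if unknown:
        raise FormatError(f"{path}: marker column(s) not on map: {sorted(unknown)}")
    missing = set(gmap.markers) - set(value_cols)
    if missing:
        raise FormatError(f"{path}: map marker(s) absent from table: {sorted(missing)}")
    sub = df[gmap.markers]
    mat = np.full(sub.shape, MISSING, dtype=np.int8)
    for j, m in enumerate(gmap.markers):
        col = pd.to_numeric(sub[m], errors="coerce")
        raw = sub[m]
        na = col.isna()
        bad_token = na & raw.notna() & (raw.astype(str).str.upper() != "NA")
        if bad_token.any():
            i = int(bad_token.index[bad_token][0])
            raise FormatError(f"{path}: unparseable genotype {raw.iloc[i]!r} at row {i}, marker {m}")
        vals = col.to_numpy()
        bad = ~na.to_numpy() & ~np.isin(vals, allowed)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: genotype {vals[i]:g} outside {sorted(allowed)} at row {i}, marker {m}"
            )
        mat[~na.to_numpy(), j] = vals[~na.to_numpy()].astype(np.int8)
    return mat


# ---------------------------------------------------------------------------
# Phenotypes


@dataclass(frozen=True)
class PhenotypeTable:
    """Replicate-level phenotype records (line, cross, replicate, value)."""

    records: pd.DataFrame  # columns: line_id, cross_id, replicate_id, value
    units: str = "mm"

    def __post_init__(self) -> None:
        needed = {"line_id", "cross_id", "replicate_id", "value"}
        if not needed.issubset(self.records.columns):
            raise FormatError(f"phenotype records need columns {sorted(needed)}")
        if not np.isfinite(self.records["value"].to_numpy(float)).all():
            raise FormatError("phenotype values must be finite")

    def line_means(self) -> pd.Series:
        """Per-line replicate mean, the response used for QTL mapping."""
        return self.records.groupby("line_id", sort=False)["value"].mean()

    def cross_of(self) -> pd.Series:
        return self.records.groupby("line_id", sort=False)["cross_id"].first()


def read_phenotypes(path: str | Path, units: str = "mm") -> PhenotypeTable:
    df = _read_table(path)
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    return PhenotypeTable(df, units=units)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; defaults mirror the mapping analysis conventions.

    ``significance_threshold`` is in −log10(p) units; ``cofactor_exclusion_window``
    is the cM radius within which background-QTL cofactors are dropped when
    testing a locus.
    """

    significance_threshold: float = 3.2
    cofactor_exclusion_window: float = 10.0
    scan_step: float = 0.0  # 0 = scan at marker positions only
    rng_seed: int = 1
    genotyping_error: float = 0.0
    max_scan_iterations: int = 20

    def __post_init__(self) -> None:
        if self.significance_threshold <= 0:
            raise FormatError("significance_threshold must be > 0")
        if self.cofactor_exclusion_window < 0:
            raise FormatError("cofactor_exclusion_window must be >= 0")
        if not 0 <= self.genotyping_error <= 1:
            raise FormatError("genotyping_error must be in [0, 1]")

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, rng_seed=int(seed))


_CONFIG_FIELDS = {
    "significance_threshold": float,
    "cofactor_exclusion_window": float,
    "scan_step": float,
    "rng_seed": int,
    "genotyping_error": float,
    "max_scan_iterations": int,
}


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file; '#' starts a comment."""
    values = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_FIELDS:
            raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _CONFIG_FIELDS[key](val.strip())
    cfg = RunConfig(**values)
    for k in _CONFIG_FIELDS:
        logger.info("config %s = %s", k, getattr(cfg, k))
    return cfg


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.read_text().splitlines()[0].count("\t") else ","
    return pd.read_csv(path, sep=sep, dtype=str).rename(columns=str.strip).apply(
        lambda c: c.str.strip() if c.dtype == object else c
    )


def spawn_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit sub-seed, logged for provenance."""
    tag = zlib.crc32(stage.encode()) % (2**31)
    child = np.random.SeedSequence([int(seed), tag]).generate_state(1)[0]
    sub = int(child % (2**31))
    logger.info("stage %s sub-seed %d", stage, sub)
    return sub
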