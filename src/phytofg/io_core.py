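"""Data model and I/O for phytoplankton monitoring tables.

Three tables drive the pipeline:

* an abundance table — long-format rows of (site, date, taxon, cells/L)
  plus per-taxon metadata (phylum, mean cell volume, optional
  functional-group code);
* an environment table — per-sample physicochemical measurements
  (WT, pH, DO, SD, TN, TP, NH3-N, CODMn);
* the functional-group catalog (see :mod:`phytofg.functional_groups`).

Long format is canonical on disk; wide sample-by-taxon matrices exist
in memory only. Dates are stored to day precision; monthly grouping
downstream uses calendar (year, month) keys. Missing environmental
cells are retained as NaN, never imputed — downstream statistics drop
incomplete samples and log how many.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("phytofg")

PHYLA = (
    "Chlorophyta",
    "Bacillariophyta",
    "Cyanophyta",
    "Dinophyta",
    "Euglenophyta",
    "Cryptophyta",
    "Chrysophyta",
)

#: Environmental variables, in canonical column order.
ENV_VARS = ("WT", "pH", "DO", "SD", "TN", "TP", "NH3N", "CODMn")

ABUNDANCE_COLUMNS = ("site", "date", "taxon_id", "abundance_cells_per_L")
TAXON_META_COLUMNS = ("taxon_id", "name", "phylum", "cell_volume_um3", "fg_code")


class SchemaError(ValueError):
    """A file is missing required columns or has an unusable layout."""


class ValidationError(ValueError):
    """Values violate a domain invariant (negative counts, pH out of range...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonRecord:
    """One taxon with the metadata needed for biomass conversion.

    Parameters
    ----------
    taxon_id : str
        Stable identifier used to join counts with metadata.
    name : str
        Binomial or genus-level name, e.g. ``"Cyclotella sp."``.
    phylum : str
        One of the seven phyla in :data:`PHYLA`.
    cell_volume : float
        Mean cell volume in µm³ per cell; must be positive.
    fg_code : str or None
        Reynolds functional-group code; ``None`` until classified.
    """

    taxon_id: str
    name: str
    phylum: str
    cell_volume: float
    fg_code: str | None = None

    def __post_init__(self) -> None:
        if self.phylum not in PHYLA:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: unknown phylum {self.phylum!r}; "
                f"expected one of {PHYLA}"
            )
        if not (self.cell_volume > 0):
            raise ValidationError(
                f"taxon {self.taxon_id!r}: cell_volume must be > 0, "
                f"got {self.cell_volume}"
            )


SampleKey = tuple[str, _dt.date]


@dataclass
class AbundanceTable:
    """Sample-by-taxon abundance matrix (cells/L) with taxon metadata.

    ``samples`` is an ordered list of unique (site_id, date) keys;
    ``abundance`` has one row per sample and one column per taxon.
    """

    samples: list[SampleKey]
    taxa: list[TaxonRecord]
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.abundance.shape != (len(self.samples), len(self.taxa)):
            raise ValidationError(
                f"abundance matrix shape {self.abundance.shape} does not match "
                f"{len(self.samples)} samples x {len(self.taxa)} taxa"
            )
        if np.any(self.abundance < 0):
            bad = int(np.sum(self.abundance < 0))
            raise ValidationError(f"{bad} negative abundance value(s)")
        if len(self.samples) and np.any(self.abundance.sum(axis=1) <= 0):
            empty = [self.samples[i] for i in
                     np.flatnonzero(self.abundance.sum(axis=1) <= 0)]
            logger.warning("samples with no positive abundance: %s", empty)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate (site, date) sample keys")

    # -- convenience accessors -------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def sites(self) -> list[str]:
        return sorted({s for s, _ in self.samples})

    def sample_frame(self) -> pd.DataFrame:
        """Samples as a DataFrame with ``site`` and ``date`` columns."""
        return pd.DataFrame(self.samples, columns=["site", "date"])

    def subset_samples(self, indices: np.ndarray | list[int]) -> "AbundanceTable":
        idx = np.asarray(indices, dtype=int)
        return AbundanceTable(
            samples=[self.samples[i] for i in idx],
            taxa=list(self.taxa),
            abundance=self.abundance[idx],
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame with the canonical on-disk columns."""
        rows = []
        for i, (site, date) in enumerate(self.samples):
            for j, t in enumerate(self.taxa):
                rows.append((site, date.isoformat(), t.taxon_id,
                             self.abundance[i, j]))
        return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


@dataclass
class EnvTable:
    """Per-sample physicochemical measurements.

    ``data`` holds one row per sample with the columns in
    :data:`ENV_VARS`. Missing cells are NaN and stay NaN.
    """

    samples: list[SampleKey]
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [v for v in ENV_VARS if v not in self.data.columns]
        if missing:
            raise SchemaError(f"environment table missing column(s): {missing}")
        self.data = self.data.loc[:, list(ENV_VARS)].reset_index(drop=True)
        if len(self.data) != len(self.samples):
            raise ValidationError(
                f"{len(self.data)} data rows for {len(self.samples)} samples"
            )
        self.validate()

    def validate(self) -> None:
        ph = self.data["pH"].to_numpy(float)
        bad_ph = (ph <= 0) | (ph >= 14)
        if np.any(bad_ph[~np.isnan(ph)] if np.isnan(ph).any() else bad_ph):
            with np.errstate(invalid="ignore"):
                offenders = np.flatnonzero((~np.isnan(ph)) & ((ph <= 0) | (ph >= 14)))
            if offenders.size:
                raise ValidationError(
                    f"pH outside (0, 14) at rows {offenders.tolist()}"
                )
        for var in ENV_VARS:
            if var == "pH":
                continue
            vals = self.data[var].to_numpy(float)
            with np.errstate(invalid="ignore"):
                neg = np.flatnonzero((~np.isnan(vals)) & (vals < 0))
            if neg.size:
                raise ValidationError(f"{var} negative at rows {neg.tolist()}")
        n_missing = int(self.data.isna().sum().sum())
        if n_missing:
            logger.warning("environment table has %d missing cell(s)", n_missing)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, indices: np.ndarray | list[int]) -> "EnvTable":
        idx = np.asarray(indices, dtype=int)
        return EnvTable(
            samples=[self.samples[i] for i in idx],
            data=self.data.iloc[idx].reset_index(drop=True),
        )

    def complete_cases(self) -> "EnvTable":
        """Drop samples with any missing variable, logging the count."""
        mask = ~self.data.isna().any(axis=1)
        dropped = int((~mask).sum())
        if dropped:
            logger.info("dropping %d incomplete environment sample(s)", dropped)
        return self.subset_samples(np.flatnonzero(mask.to_numpy()))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_dates(raw: pd.Series, context: str) -> list[_dt.date]:
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValidationError(
            f"{context}: unparseable date {raw.iloc[row]!r} at data row {row}"
        )
    return [d.date() for d in parsed]


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def load_taxon_metadata(path) -> dict[str, TaxonRecord]:
    """Read per-taxon metadata CSV into a taxon_id -> record mapping."""
    meta = _read_table(path)
    missing = [c for c in TAXON_META_COLUMNS[:4] if c not in meta.columns]
    if missing:
        raise SchemaError(f"taxon metadata missing column(s): {missing}")
    if meta["taxon_id"].duplicated().any():
        dups = meta.loc[meta["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise ValidationError(f"duplicate taxon metadata rows for: {dups}")
    records = {}
    for _, row in meta.iterrows():
        code = row.get("fg_code")
        if pd.isna(code) or code == "":
            code = None
        records[str(row["taxon_id"])] = TaxonRecord(
            taxon_id=str(row["taxon_id"]),
            name=str(row["name"]),
            phylum=str(row["phylum"]),
            cell_volume=float(row["cell_volume_um3"]),
            fg_code=code,
        )
    return records


def load_abundance(path, taxon_meta_path) -> AbundanceTable:
    """Load a long-format abundance file plus taxon metadata.

    Duplicate (site, date, taxon) rows are summed with a logged warning;
    taxa present in the counts but absent from the metadata are an error.
    """
    df = _read_table(path)
    missing = [c for c in ABUNDANCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"abundance file missing column(s): {missing}")
    if (df["abundance_cells_per_L"] < 0).any():
        rows = np.flatnonzero((df["abundance_cells_per_L"] < 0).to_numpy())
        raise ValidationError(
            f"negative abundance at data row(s) {rows.tolist()}"
        )
    dates = _parse_dates(df["date"], str(path))
    df = df.assign(date=dates, site=df["site"].astype(str),
                   taxon_id=df["taxon_id"].astype(str))

    dup_mask = df.duplicated(subset=["site", "date", "taxon_id"], keep=False)
    if dup_mask.any():
        logger.warning(
            "summing %d duplicate (site, date, taxon) row(s)", int(dup_mask.sum())
        )
    df = (df.groupby(["site", "date", "taxon_id"], sort=False, as_index=False)
            ["abundance_cells_per_L"].sum())

    records = load_taxon_metadata(taxon_meta_path)
    unknown = sorted(set(df["taxon_id"]) - set(records))
    if unknown:
        raise ValidationError(
            f"taxa present in counts but absent from metadata: {unknown}"
        )

    wide = df.pivot_table(index=["site", "date"], columns="taxon_id",
                          values="abundance_cells_per_L", fill_value=0.0,
                          sort=False)
    samples = [(s, d) for s, d in wide.index]
    taxa = [records[t] for t in wide.columns]
    return AbundanceTable(samples=samples, taxa=taxa,
                          abundance=wide.to_numpy(float))


def write_abundance(table: AbundanceTable, path, taxon_meta_path=None) -> None:
    """Write the canonical long-format CSV (and optionally the metadata CSV)."""
    table.to_long().to_csv(path, index=False)
    if taxon_meta_path is not None:
        meta = pd.DataFrame(
            [(t.taxon_id, t.name, t.phylum, t.cell_volume, t.fg_code or "")
             for t in table.taxa],
            columns=TAXON_META_COLUMNS,
        )
        meta.to_csv(taxon_meta_path, index=False)


def load_env(path) -> EnvTable:
    """Load an environment table (wide, or long with a ``variable`` column)."""
    df = _read_table(path)
    for col in ("site", "date"):
        if col not in df.columns:
            raise SchemaError(f"environment file missing column(s): ['{col}']")
    if "variable" in df.columns and "value" in df.columns:
        df = df.pivot_table(index=["site", "date"], columns="variable",
                            values="value", sort=False).reset_index()
    missing = [v for v in ENV_VARS if v not in df.columns]
    if missing:
        raise SchemaError(f"environment table missing column(s): {missing}")
    dates = _parse_dates(df["date"], str(path))
    samples = list(zip(df["site"].astype(str), dates))
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate (site, date) rows in environment table")
    return EnvTable(samples=samples, data=df.loc[:, list(ENV_VARS)])


def write_env(env: EnvTable, path) -> None:
    out = pd.DataFrame(env.samples, columns=["site", "date"])
    out["date"] = [d.isoformat() for d in out["date"]]
    out = pd.concat([out, env.data.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


def align_samples(a: AbundanceTable, e: EnvTable) -> tuple[AbundanceTable, EnvTable]:
    """Restrict both tables to their common (site, date) keys, same order.

    The order of the abundance table's keys is preserved. Idempotent;
    raises on an empty intersection.
    """
    keys_e = {k: i for i, k in enumerate(e.samples)}
    shared = [(i, keys_e[k]) for i, k in enumerate(a.samples) if k in keys_e]
    if not shared:
        raise ValidationError("no shared (site, date) keys between tables")
    dropped_a = len(a.samples) - len(shared)
    dropped_e = len(e.samples) - len(shared)
    if dropped_a or dropped_e:
        logger.info("align_samples dropped %d abundance and %d environment sample(s)",
                    dropped_a, dropped_e)
    ia, ie = zip(*shared)
    return a.subset_samples(list(ia)), e.subset_samples(list(ie))
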