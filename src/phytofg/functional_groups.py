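"""Reynolds functional-group classification, biomass and dominance.

The Reynolds coda scheme assigns phytoplankton taxa with similar
morphology, physiology and habitat template to alphanumeric groups
(A, B, ..., Z). The packaged catalog covers the 27 groups observed in
the reservoir study this package models, with habitat characteristics,
representative taxa, tolerances and susceptibilities, and flags the
eight groups that were dominant there (B, D, L_O, P, S1, W1, W2, Y).

Counts become biomass through the unit-density biovolume conversion

    biomass [mg/L] = density(=1) x cell_volume [µm³] x abundance [cells/L] x 1e-9

(1 µm³ of unit-density matter is 1e-9 mg, so the density of 1 g/cm³
acts as a dimensionless factor).

Species dominance uses the McNaughton index Y = (Ni/N) * fi, where Ni/N
is the taxon's share of total abundance over the evaluation scope and
fi its occurrence frequency (fraction of scope samples where present).
Y >= 0.02 marks a dominant species, Y > 0.1 an absolute dominant.
Functional groups with a relative biomass exceeding 5% of the
stratum-aggregated total are the dominant functional groups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import numpy as np
import pandas as pd

from .io_core import AbundanceTable, PHYLA, ValidationError

logger = logging.getLogger("phytofg")

UNASSIGNED = "UNASSIGNED"

#: The 27 functional-group codes of the packaged catalog.
CATALOG_CODES = (
    "A", "B", "C", "D", "E", "F", "G", "H1", "J", "K", "L_M", "L_O", "MP",
    "N", "P", "S1", "S2", "S_N", "T", "TC", "W1", "W2", "X1", "X2", "X3",
    "Y", "Z",
)

#: Groups dominant in the source study (relative biomass > 5%).
STUDY_DOMINANT_CODES = ("B", "D", "L_O", "P", "S1", "W1", "W2", "Y")


@dataclass(frozen=True)
class CatalogEntry:
    code: str
    habitat: str
    representative_taxa: tuple[str, ...]
    tolerance: str
    susceptibility: str
    is_dominant_in_study: bool


@dataclass
class FunctionalGroupCatalog:
    """Trait table for the functional groups plus a species->code map.

    ``species_map`` maps lowercase full names and genus tokens of the
    representative taxa to codes. Where a genus appears under several
    codes, catalog order wins (first listing); an explicit ``fg_code``
    in the taxon metadata always overrides pattern matching.
    """

    entries: list[CatalogEntry]
    species_map: dict[str, str]

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    @property
    def dominant_codes(self) -> list[str]:
        return [e.code for e in self.entries if e.is_dominant_in_study]

    def __getitem__(self, code: str) -> CatalogEntry:
        for e in self.entries:
            if e.code == code:
                return e
        raise KeyError(f"unknown functional-group code {code!r}")

    def match(self, name: str) -> str | None:
        """Match a taxon name to a code: full name first, then genus."""
        key = _normalize(name)
        if key in self.species_map:
            return self.species_map[key]
        genus = key.split()[0] if key else ""
        return self.species_map.get(genus)


def _normalize(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip().lower())


def load_catalog(path=None) -> FunctionalGroupCatalog:
    """Load the functional-group catalog (packaged default, or a CSV path)."""
    if path is None:
        ref = resources.files("phytofg").joinpath(
            "data/functional_groups_catalog.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, keep_default_na=False)
    else:
        df = pd.read_csv(path, keep_default_na=False)
    entries: list[CatalogEntry] = []
    species_map: dict[str, str] = {}
    for _, row in df.iterrows():
        taxa = tuple(t.strip() for t in str(row["representative_taxa"]).split(";")
                     if t.strip())
        entry = CatalogEntry(
            code=str(row["code"]),
            habitat=str(row["habitat"]),
            representative_taxa=taxa,
            tolerance=str(row["tolerance"]),
            susceptibility=str(row["susceptibility"]),
            is_dominant_in_study=bool(int(row["dominant_in_study"])),
        )
        entries.append(entry)
        for t in taxa:
            full = _normalize(t.replace("sp.", "").strip())
            for key in {_normalize(t), full, full.split()[0]}:
                species_map.setdefault(key, entry.code)
    codes = [e.code for e in entries]
    if len(set(codes)) != len(codes):
        raise ValidationError("duplicate functional-group codes in catalog")
    return FunctionalGroupCatalog(entries=entries, species_map=species_map)


def classify_taxa(table: AbundanceTable,
                  catalog: FunctionalGroupCatalog) -> AbundanceTable:
    """Assign every taxon a functional-group code.

    Priority: (1) an explicit ``fg_code`` already on the record,
    (2) case-insensitive name match against the catalog (full name,
    then leading genus token). Unmatched taxa get the sentinel
    ``UNASSIGNED`` and are reported in a logged summary.
    """
    new_taxa = []
    unassigned = []
    for t in table.taxa:
        if t.fg_code:
            new_taxa.append(t)
            continue
        code = catalog.match(t.name)
        if code is None:
            code = UNASSIGNED
            unassigned.append(t.name)
        new_taxa.append(replace(t, fg_code=code))
    if unassigned:
        logger.warning("%d taxa could not be classified: %s",
                       len(unassigned), unassigned)
    else:
        logger.info("all %d taxa classified", len(new_taxa))
    return AbundanceTable(samples=list(table.samples), taxa=new_taxa,
                          abundance=table.abundance.copy())


# ---------------------------------------------------------------------------
# biomass
# ---------------------------------------------------------------------------

@dataclass
class BiomassMatrix:
    """Sample-by-functional-group biomass (mg/L) and relative biomass.

    ``relative`` rows sum to 1 where the sample's total biomass is
    positive and are NaN (flagged in ``zero_samples``) where it is zero.
    """

    samples: list
    groups: list[str]
    biomass: np.ndarray
    relative: np.ndarray
    zero_samples: list = None

    def __post_init__(self) -> None:
        if self.zero_samples is None:
            self.zero_samples = []
        if np.any(self.biomass < 0):
            raise ValidationError("negative biomass")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.samples, names=["site", "date"])
        return pd.DataFrame(self.biomass, index=idx, columns=self.groups)

    def site_mask(self, site_id: str) -> np.ndarray:
        return np.array([s == site_id for s, _ in self.samples])

    def year_mask(self, year: int) -> np.ndarray:
        return np.array([d.year == year for _, d in self.samples])


def compute_biomass(table: AbundanceTable, density: float = 1.0) -> BiomassMatrix:
    """Convert counts to functional-group biomass (mg/L).

    Per-taxon biomass is ``density * cell_volume * abundance * 1e-9``
    with density 1 g/cm³ treated as a dimensionless 1; taxa are then
    summed within functional groups and rows normalized to relative
    biomass.
    """
    missing = [t.taxon_id for t in table.taxa if not t.fg_code]
    if missing:
        raise ValidationError(f"taxa without fg_code (classify first): {missing}")
    volumes = np.array([t.cell_volume for t in table.taxa])
    taxon_biomass = density * table.abundance * volumes[None, :] * 1e-9

    groups = sorted({t.fg_code for t in table.taxa})
    biomass = np.zeros((table.n_samples, len(groups)))
    col = {g: j for j, g in enumerate(groups)}
    for j_t, t in enumerate(table.taxa):
        biomass[:, col[t.fg_code]] += taxon_biomass[:, j_t]

    totals = biomass.sum(axis=1)
    relative = np.full_like(biomass, np.nan)
    pos = totals > 0
    relative[pos] = biomass[pos] / totals[pos, None]
    zero_samples = [table.samples[i] for i in np.flatnonzero(~pos)]
    if zero_samples:
        logger.warning("%d sample(s) with zero total biomass; relative "
                       "biomass undefined there", len(zero_samples))
    return BiomassMatrix(samples=list(table.samples), groups=groups,
                         biomass=biomass, relative=relative,
                         zero_samples=zero_samples)


# ---------------------------------------------------------------------------
# dominance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DominanceResult:
    """McNaughton dominance of one taxon over an evaluation scope."""

    taxon_id: str
    name: str
    ni_total: float
    share: float
    fi: float
    y: float
    status: str  # none | dominant | absolute_dominant


def _status(y: float) -> str:
    if y > 0.1:
        return "absolute_dominant"
    if y >= 0.02:
        return "dominant"
    return "none"


def dominance(table: AbundanceTable,
              scope: np.ndarray | list[int] | None = None) -> list[DominanceResult]:
    """McNaughton dominance index Y = (Ni/N) * fi per taxon.

    ``scope`` selects the samples to evaluate over (indices or boolean
    mask; default all). Ni sums the taxon over the scope, N sums all
    taxa, fi is the fraction of scope samples where the taxon's
    abundance is strictly positive.
    """
    X = table.abundance
    if scope is not None:
        scope = np.asarray(scope)
        X = X[scope] if scope.dtype != bool else X[np.flatnonzero(scope)]
    if X.shape[0] == 0:
        raise ValidationError("empty dominance scope")
    total = X.sum()
    if total <= 0:
        raise ValidationError("zero total abundance over scope")
    ni = X.sum(axis=0)
    share = ni / total
    fi = (X > 0).mean(axis=0)
    y = share * fi
    return [
        DominanceResult(taxon_id=t.taxon_id, name=t.name, ni_total=float(ni[j]),
                        share=float(share[j]), fi=float(fi[j]), y=float(y[j]),
                        status=_status(float(y[j])))
        for j, t in enumerate(table.taxa)
    ]


@dataclass(frozen=True)
class DominantGroups:
    """Dominant functional groups of a stratum plus the pooled remainder."""

    groups: list[tuple[str, float]]
    others: float


def dominant_groups(bm: BiomassMatrix,
                    stratum: np.ndarray | None = None,
                    threshold: float = 0.05) -> DominantGroups:
    """Groups whose stratum-aggregated relative biomass exceeds ``threshold``.

    Shares are computed on biomass summed over the stratum (not averaged
    per-sample shares), sorted descending; everything else pools into
    ``others``. The shares plus ``others`` sum to 1.
    """
    B = bm.biomass
    if stratum is not None:
        stratum = np.asarray(stratum)
        B = B[stratum] if stratum.dtype != bool else B[np.flatnonzero(stratum)]
    group_tot = B.sum(axis=0)
    total = group_tot.sum()
    if total <= 0:
        raise ValidationError("zero total biomass over stratum")
    shares = group_tot / total
    order = np.argsort(-shares, kind="stable")
    picked = [(bm.groups[j], float(shares[j])) for j in order
              if shares[j] > threshold]
    others = 1.0 - sum(s for _, s in picked)
    return DominantGroups(groups=picked, others=float(others))


def habitat_indication(codes: list[str],
                       catalog: FunctionalGroupCatalog) -> pd.DataFrame:
    """Habitat/tolerance/susceptibility text for the given codes.

    Interpretive reporting only — no automated trophic-state verdict.
    Unknown codes raise ``KeyError``.
    """
    rows = []
    for code in codes:
        e = catalog[code]
        rows.append((e.code, e.habitat, e.tolerance, e.susceptibility))
    return pd.DataFrame(rows, columns=["code", "habitat", "tolerance",
                                       "susceptibility"])


# ---------------------------------------------------------------------------
# composition summary
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (5 rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def composition_percentages(counts: dict[str, int]) -> pd.DataFrame:
    """Per-phylum species counts and percentages (2 decimals, half-up)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValidationError("no species counted")
    rows = [(ph, n, round_half_up(100.0 * n / total))
            for ph, n in counts.items()]
    return pd.DataFrame(rows, columns=["phylum", "n_species", "percent"])


def composition_summary(table: AbundanceTable) -> pd.DataFrame:
    """Species richness per phylum over the table's scope.

    A taxon counts toward its phylum if its abundance is positive in at
    least one sample. Percentages use 2-decimal half-up rounding.
    """
    present = table.abundance.sum(axis=0) > 0
    counts: dict[str, int] = {}
    for j, t in enumerate(table.taxa):
        if present[j]:
            counts[t.phylum] = counts.get(t.phylum, 0) + 1
    ordered = {ph: counts[ph] for ph in PHYLA if ph in counts}
    return composition_percentages(ordered)
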