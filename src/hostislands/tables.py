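"""Apparency table and utilization matrix ingestion, plus the island-geometry
summaries built from them: utilizer ratios, "mainland" family selection, and
minimum phylogenetic distance to the mainland (PD_min).

Apparency conventions: a family's apparency (PA) is its species count, genus
count, or distribution area in km².  Families with unresolved taxonomy carry
0.5 species / 0.5 genera; families without a mapped range carry a 1,000 km²
placeholder area — both fills are counted in the load report.
"""

from __future__ import annotations

import logging
import math
import unicodedata
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .phylo import DistanceMatrix

logger = logging.getLogger(__name__)

APPARENCY_MEASURES = ("species", "genera", "area")

#: Fill values for unresolved or unmapped families.
SPECIES_FILL = 0.5
GENUS_FILL = 0.5
AREA_FILL_KM2 = 1000.0


def normalize_name(name: str) -> str:
    """Canonical family-name form: Unicode NFC + stripped whitespace."""
    return unicodedata.normalize("NFC", str(name)).strip()


@dataclass
class FamilyRecord:
    """Per-family apparency: species count, genus count, area (km²)."""

    family: str
    n_species: float
    n_genera: float
    area_km2: float

    def apparency(self, measure: str) -> float:
        if measure == "species":
            return self.n_species
        if measure == "genera":
            return self.n_genera
        if measure == "area":
            return self.area_km2
        raise ValidationError(f"unknown apparency measure: {measure!r}")


@dataclass
class FamilyTableLoad:
    """Validated apparency records plus the fill-count load report."""

    records: list
    report: dict = field(default_factory=dict)

    def apparency_series(self, measure: str) -> pd.Series:
        return pd.Series(
            {r.family: r.apparency(measure) for r in self.records}, name=measure
        )


def read_family_table(path: str) -> FamilyTableLoad:
    """Read the per-family apparency CSV (family, n_species, n_genera, area_km2).

    Missing or zero species/genus counts become 0.5; missing areas become
    1,000 km².  Each replacement is counted in ``load.report``.  Duplicate
    family rows and negative numbers are hard errors.
    """
    df = pd.read_csv(path)
    required = {"family", "n_species", "n_genera", "area_km2"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"family table must have columns {sorted(required)}; "
            f"got {list(df.columns)}")
    df["family"] = df["family"].map(normalize_name)
    dups = df["family"][df["family"].duplicated()].unique().tolist()
    if dups:
        raise ValidationError(f"duplicate: {', '.join(dups)}")

    report = {"n_rows": len(df), "filled_species": 0, "filled_genera": 0,
              "filled_area": 0}
    records = []
    for row in df.itertuples(index=False):
        vals = {}
        for col, fill, key in (
            ("n_species", SPECIES_FILL, "filled_species"),
            ("n_genera", GENUS_FILL, "filled_genera"),
            ("area_km2", AREA_FILL_KM2, "filled_area"),
        ):
            raw = getattr(row, col)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                vals[col] = fill
                report[key] += 1
            else:
                x = float(raw)
                if x < 0:
                    raise ValidationError(
                        f"negative {col} for family {row.family}")
                if x == 0 and col != "area_km2":
                    vals[col] = fill
                    report[key] += 1
                elif col == "area_km2" and x < AREA_FILL_KM2:
                    # ranges below the placeholder resolution are floored
                    vals[col] = AREA_FILL_KM2
                    report[key] += 1
                else:
                    vals[col] = x
        records.append(FamilyRecord(row.family, vals["n_species"],
                                    vals["n_genera"], vals["area_km2"]))
    return FamilyTableLoad(records, report)


@dataclass
class FamilySummary:
    """Per-family island summary: utilizer ratio, PD_min, chosen apparency."""

    family: str
    UR: float
    PD_min: float
    apparency: float


@dataclass
class UtilizationMatrix:
    """Binary groups × families presence–absence matrix.

    ``data`` is indexed by family (rows) with one 0/1 column per retained
    utilization group.
    """

    data: pd.DataFrame
    dropped_groups: list = field(default_factory=list)

    @property
    def groups(self) -> list:
        return list(self.data.columns)

    @property
    def families(self) -> list:
        return list(self.data.index)

    @property
    def n_groups(self) -> int:
        return self.data.shape[1]

    def host_breadth(self) -> pd.Series:
        """HF: number of host families per group (column sums)."""
        return self.data.sum(axis=0)

    def presence(self, group: str) -> pd.Series:
        return self.data[group]


def read_utilization_matrix(path: str,
                            min_host_families: int = 10) -> UtilizationMatrix:
    """Read the families × groups 0/1 CSV (first column = family names).

    Groups utilizing fewer than *min_host_families* families are dropped with
    a warning — too few presences bias both the GLM fits and the phylogenetic
    signal.  Any non-binary cell is a hard error naming its coordinates.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = [normalize_name(x) for x in df.index]
    if pd.Index(df.index).duplicated().any():
        dup = pd.Index(df.index)[pd.Index(df.index).duplicated()].tolist()
        raise ValidationError(f"duplicate family rows: {dup}")
    if pd.Index(df.columns).duplicated().any():
        raise ValidationError("duplicate group columns")
    for col in df.columns:
        bad = df.index[~df[col].isin([0, 1])]
        if len(bad):
            raise ValidationError(
                f"non-binary cell at family {bad[0]!r}, group {col!r}: "
                f"{df.loc[bad[0], col]!r}")
    df = df.astype(np.int8)
    sums = df.sum(axis=0)
    dropped = [g for g in df.columns if sums[g] < min_host_families]
    if dropped:
        logger.warning("dropping %d group(s) with < %d host families: %s",
                       len(dropped), min_host_families, dropped)
    return UtilizationMatrix(df.drop(columns=dropped), dropped_groups=dropped)


def build_matrix(families, groups: dict,
                 min_host_families: int = 10) -> UtilizationMatrix:
    """Assemble a matrix from {group: 0/1 vector over *families*} in memory."""
    df = pd.DataFrame(groups, index=list(families)).astype(np.int8)
    sums = df.sum(axis=0)
    dropped = [g for g in df.columns if sums[g] < min_host_families]
    return UtilizationMatrix(df.drop(columns=dropped), dropped_groups=dropped)


def utilizer_ratio(matrix: UtilizationMatrix) -> pd.Series:
    """UR per family: share of retained groups that utilize it.

    The denominator is the number of groups actually present in the matrix
    (after any host-breadth filtering), never a hard-coded constant.
    """
    return matrix.data.sum(axis=1) / matrix.n_groups


def select_mainland(records, measure: str = "species",
                    fraction: float = 0.10) -> set:
    """Top-decile families by the chosen apparency measure (the "mainland").

    Takes the top ``k = ceil(fraction × N)`` families ranked descending, and
    additionally every family tied with the k-th value, so the boundary is
    deterministic and order-independent.
    """
    if not records:
        raise ValidationError("empty family table")
    vals = sorted(((r.apparency(measure), r.family) for r in records),
                  reverse=True)
    k = math.ceil(fraction * len(vals))
    cutoff = vals[k - 1][0]
    return {fam for val, fam in vals if val >= cutoff}


def pd_min(dm: DistanceMatrix, mainland: set,
           exclude_self: bool = False) -> pd.Series:
    """Minimum patristic distance (Myr) from each family to the mainland set.

    By default a mainland family's own zero self-distance is included, so
    mainland members get PD_min = 0; with ``exclude_self`` each mainland
    family instead reports its distance to the nearest *other* mainland
    member.
    """
    if not mainland:
        raise ValidationError("mainland set is empty")
    missing = set(mainland) - set(dm.labels)
    if missing:
        raise ValidationError(f"mainland families not in tree: {sorted(missing)[:5]}")
    mainland = sorted(mainland)
    out = {}
    for fam in dm.labels:
        targets = [m for m in mainland if m != fam] if exclude_self else mainland
        if not targets:
            raise ValidationError(
                "exclude_self with a single mainland family leaves no target")
        out[fam] = dm.submatrix_min(fam, targets)
    return pd.Series(out, name="PD_min")
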