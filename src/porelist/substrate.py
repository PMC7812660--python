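"""Species x substrate-category tables and the regular/specialist
substrate-association classification.

A species is classified *regular* on a substrate category if any of
three clauses holds:

  (a) it has at least 40 records in total and at least 5% of them are
      on the category;
  (b) it has fewer than 40 records in total and more than one of them
      is on the category;
  (c) its records make up at least 5% of all records in the category.

*Specialists* are the subset of regular species with more than two
records on the category which are either at least 90% of the species'
records, or all of them when the species has 3-9 records in total.

The host axis additionally feeds a presence/absence matrix of regular
host-species pairs into UPGMA clustering of host-tree assemblages.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from porelist.community import Dendrogram, DissimilarityMatrix, bray_curtis, upgma
from porelist.records import OccurrenceRecord, recode_decay

__all__ = [
    "AssociationTable", "ClassificationResult", "RegularRule",
    "build_association_table", "classify_regular", "classify_specialist",
    "classify_table", "host_range_summary", "host_similarity_input",
    "cluster_hosts",
]

AXIS_FIELDS = ("host_taxon", "substrate_fraction", "decay_class")


class RegularRule(str, enum.Enum):
    a_share5_total40 = "a_share5_total40"
    b_gt1_total_lt40 = "b_gt1_total_lt40"
    c_cat_share5 = "c_cat_share5"
    none = "none"


@dataclass
class ClassificationResult:
    species_id: str
    category: str
    n_cat: int
    n_species_total: int
    regular: bool
    regular_rule: RegularRule
    specialist: bool


@dataclass
class AssociationTable:
    """Species x substrate-category record counts.

    ``counts`` includes only records annotated on the axis;
    ``species_totals`` are the species' full record counts (so row sums
    can be below the totals when some records lack the annotation), and
    ``missing_axis`` reports that shortfall per species.
    """

    axis: tuple[str, ...]
    counts: pd.DataFrame
    species_totals: pd.Series
    missing_axis: pd.Series

    @property
    def category_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def coverage_report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "total_records": self.species_totals,
            "with_axis": self.counts.sum(axis=1),
            "missing_axis": self.missing_axis,
        })


def _axis_value(record: OccurrenceRecord, axis_field: str) -> Optional[str]:
    if axis_field == "host_taxon":
        return record.host_taxon
    if axis_field == "substrate_fraction":
        return record.substrate_fraction.value if record.substrate_fraction else None
    if axis_field == "decay_class":
        cls = recode_decay(record.decay_raw)
        return cls.value if cls else None
    raise ValueError(f"unknown axis field {axis_field!r}; expected one of {AXIS_FIELDS}")


def build_association_table(records: Iterable[OccurrenceRecord],
                            axis: Union[str, Sequence[str]]) -> AssociationTable:
    """Tabulate per-species record counts over a substrate axis
    (host taxon, woody fraction, decay class, or a cross of them).

    Records lacking the axis annotation are excluded from the counts
    (and reported in the coverage columns) but still contribute to
    ``species_totals``; categories are ordered lexicographically.
    """
    axis_fields = (axis,) if isinstance(axis, str) else tuple(axis)
    for f in axis_fields:
        if f not in AXIS_FIELDS:
            raise ValueError(f"unknown axis field {f!r}; expected one of {AXIS_FIELDS}")

    totals: dict[str, int] = {}
    cells: dict[tuple[str, str], int] = {}
    for rec in records:
        totals[rec.species_id] = totals.get(rec.species_id, 0) + 1
        values = [_axis_value(rec, f) for f in axis_fields]
        if any(v is None for v in values):
            continue
        cat = "|".join(values)
        cells[(rec.species_id, cat)] = cells.get((rec.species_id, cat), 0) + 1
    if not cells:
        raise ValueError(f"axis {axis_fields} absent from all records")

    species = sorted(totals)
    categories = sorted({c for _, c in cells})
    counts = pd.DataFrame(0, index=species, columns=categories, dtype=int)
    for (s, c), n in cells.items():
        counts.loc[s, c] = n
    species_totals = pd.Series(totals).reindex(species)
    missing = species_totals - counts.sum(axis=1)
    return AssociationTable(axis=axis_fields, counts=counts,
                            species_totals=species_totals, missing_axis=missing)


def classify_regular(n_cat: int, n_species_total: int,
                     n_cat_total: int) -> tuple[bool, RegularRule]:
    """Regular-association test for one species x category cell.

    Returns the boolean and the first matching clause in order a, b, c
    (precedence is for reporting only; the decision is the OR of the
    three clauses).  A zero category total simply skips clause (c).
    """
    if n_cat < 0 or n_cat > n_species_total or n_cat > max(n_cat_total, n_cat):
        raise ValueError("inconsistent counts")
    a = n_species_total >= 40 and n_cat >= 0.05 * n_species_total
    b = n_species_total < 40 and n_cat > 1
    c = n_cat_total > 0 and n_cat >= 0.05 * n_cat_total
    if a:
        return True, RegularRule.a_share5_total40
    if b:
        return True, RegularRule.b_gt1_total_lt40
    if c:
        return True, RegularRule.c_cat_share5
    return False, RegularRule.none


def classify_specialist(n_cat: int, n_species_total: int, regular: bool) -> bool:
    """Specialist test: a regular species with more than two records on
    the category, forming >= 90% of its records, or all of its records
    when the species total is 3-9."""
    if n_cat < 0 or n_cat > n_species_total:
        raise ValueError("inconsistent counts")
    if not regular or n_cat <= 2:
        return False
    if n_species_total > 0 and n_cat >= 0.90 * n_species_total:
        return True
    return 3 <= n_species_total <= 9 and n_cat == n_species_total


def classify_table(table: AssociationTable) -> list[ClassificationResult]:
    """Apply the regular/specialist classification to every
    species x category cell with at least one record."""
    results = []
    cat_totals = table.category_totals
    for species in table.counts.index:
        total = int(table.species_totals[species])
        for cat in table.counts.columns:
            n = int(table.counts.loc[species, cat])
            if n == 0:
                continue
            regular, rule = classify_regular(n, total, int(cat_totals[cat]))
            results.append(ClassificationResult(
                species_id=species, category=cat, n_cat=n,
                n_species_total=total, regular=regular, regular_rule=rule,
                specialist=classify_specialist(n, total, regular)))
    return results


def classification_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "species_id": r.species_id, "category": r.category,
        "n_cat": r.n_cat, "n_species_total": r.n_species_total,
        "regular": r.regular, "rule": r.regular_rule.value,
        "specialist": r.specialist,
    } for r in results])


_HOST_CLASSES = ("1-2", "3-7", ">=8")


def host_range_summary(table: AssociationTable,
                       min_records: int = 10) -> pd.DataFrame:
    """Host counts per species, classed as 1-2 / 3-7 / >=8 host taxa.

    Only species recorded strictly more than *min_records* times are
    classified (rarely-recorded species give unreliable host ranges).
    """
    rows = []
    for species in table.counts.index:
        total = int(table.species_totals[species])
        if total <= min_records:
            continue
        n_hosts = int((table.counts.loc[species] > 0).sum())
        if n_hosts == 0:
            continue
        cls = _HOST_CLASSES[0] if n_hosts <= 2 else \
            _HOST_CLASSES[1] if n_hosts <= 7 else _HOST_CLASSES[2]
        rows.append({"species_id": species, "total_records": total,
                     "n_hosts": n_hosts, "host_range_class": cls})
    return pd.DataFrame(rows)


def host_similarity_input(table: AssociationTable) -> pd.DataFrame:
    """Presence/absence matrix restricted to regular host-species pairs.

    Cell (s, h) is 1 iff the records of species s on host h reach 5% of
    the species' total records or 5% of the host's records; raw
    presence would over-emphasise atypical substrates.
    """
    counts = table.counts
    host_totals = table.category_totals
    pa = pd.DataFrame(0, index=counts.index, columns=counts.columns, dtype=int)
    for s in counts.index:
        total_s = table.species_totals[s]
        for h in counts.columns:
            n = counts.loc[s, h]
            if n == 0:
                continue
            if (total_s > 0 and n >= 0.05 * total_s) or \
               (host_totals[h] > 0 and n >= 0.05 * host_totals[h]):
                pa.loc[s, h] = 1
    return pa


def cluster_hosts(pa_matrix: pd.DataFrame) -> Dendrogram:
    """UPGMA dendrogram of host taxa from Bray-Curtis dissimilarities of
    their presence/absence polypore assemblages.

    Hosts without any present species are excluded with a warning.
    """
    occupied = pa_matrix.columns[(pa_matrix > 0).any(axis=0)]
    dropped = [h for h in pa_matrix.columns if h not in set(occupied)]
    if dropped:
        warnings.warn(f"excluding host(s) with no species: {', '.join(dropped)}")
    if len(occupied) < 3:
        raise ValueError("need at least three hosts with species present")
    hosts = pa_matrix[occupied].T  # hosts as samples
    dm: DissimilarityMatrix = bray_curtis(hosts)
    return upgma(dm)
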