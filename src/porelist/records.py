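"""Occurrence-record data model, CSV ingestion, and recoding rules.

One record corresponds to basidiomes of one species on one substrate unit
(e.g. a single fallen trunk), annotated with its provenance (data source,
year, plot), the stand it was found in (site-type group, tree-composition
class, stand-age class), and the substrate (host taxon, woody fraction,
decay stage).

Recoding rules implemented here:

* five-class wood decay stages (I-V, Renvall system) -> early / medium / late;
* woody-fraction classification with the fine-woody-debris (FWD) threshold
  at 10 cm diameter (items strictly below 10 cm are FWD);
* habitat keys combining site-type group x tree class x age class, with
  pooled special habitats (parks, wooded meadows, bog/heath forests);
* banded ("> 100") record counts for report export.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union


class DatasetId(str, enum.Enum):
    """Data-source codes: historical (I), systematic surveys (IIa-IId),
    casual/targeted collections (IIIa, IIIb)."""

    I = "I"
    IIa = "IIa"
    IIb = "IIb"
    IIc = "IIc"
    IId = "IId"
    IIIa = "IIIa"
    IIIb = "IIIb"

    @property
    def source_group(self) -> str:
        """Top-level source group: 'I' historical, 'II' systematic, 'III' casual."""
        if self.value == "I":
            return "I"
        return "III" if self.value.startswith("III") else "II"

    @property
    def systematic(self) -> bool:
        return self.source_group == "II"


class TreeClass(str, enum.Enum):
    """Stand tree-composition class."""

    picea = "picea"
    pinus = "pinus"
    deciduous = "deciduous"


class AgeClass(str, enum.Enum):
    """Stand-age class; 'old' means dominant tree layer older than 100 years.
    Early-successional (post clear-cut) stands are flagged separately so the
    assemblage analysis of stands > 20 years old can exclude them."""

    old = "old"
    other = "other"
    early_successional = "early_successional"


class SubstrateFraction(str, enum.Enum):
    coarse_fallen = "coarse_fallen"
    snag_stump = "snag_stump"
    fwd = "fwd"
    live_tree = "live_tree"


class DecayStage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"


class DecayClass(str, enum.Enum):
    early = "early"
    medium = "medium"
    late = "late"


class SpecialHabitat(str, enum.Enum):
    """Pooled habitat lists that are not described by a stand triple."""

    park = "park"
    wooded_meadow = "wooded_meadow"
    bog_forest = "bog_forest"
    heath_forest = "heath_forest"


#: Default controlled vocabulary of forest site-type groups: nine natural
#: groups plus two anthropogenic ones (drained peatlands, reclaimed areas).
DEFAULT_SITE_TYPE_GROUPS: tuple[str, ...] = (
    "dry_boreal",
    "fresh_boreal",
    "meso_eutrophic",
    "eutrophic_boreo_nemoral",
    "eutrophic_paludifying",
    "oligotrophic_paludifying",
    "minerotrophic_mire",
    "ombrotrophic_bog",
    "floodplain",
    "drained_peatland",
    "reclaimed",
)


class RecordValidationError(ValueError):
    """Raised for a structurally invalid occurrence record."""


@dataclass(frozen=True)
class HabitatKey:
    """Hashable habitat identifier: either the stand triple
    (site-type group, tree class, age class) or a pooled special habitat.

    Exactly one of the two representations is populated.
    """

    site_type_group: Optional[str] = None
    tree_class: Optional[TreeClass] = None
    age_class: Optional[AgeClass] = None
    special_habitat: Optional[SpecialHabitat] = None

    def __post_init__(self) -> None:
        triple = self.site_type_group is not None
        if triple == (self.special_habitat is not None):
            raise RecordValidationError(
                "habitat key needs exactly one of stand triple or special habitat"
            )
        if triple and (self.tree_class is None or self.age_class is None):
            raise RecordValidationError(
                "stand habitat key requires site_type_group, tree_class and age_class"
            )

    @property
    def early_successional(self) -> bool:
        return self.age_class is AgeClass.early_successional

    def __str__(self) -> str:
        if self.special_habitat is not None:
            return self.special_habitat.value
        return f"{self.site_type_group}|{self.tree_class.value}|{self.age_class.value}"


@dataclass(frozen=True)
class BandedCount:
    """A record count censored above a reporting threshold (default 100),
    matching checklist-table convention where large counts print as '>100'."""

    value: int
    band_threshold: int = 100
    censored: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("count must be non-negative")
        if not self.censored and self.value > self.band_threshold:
            raise ValueError("uncensored value exceeds the band threshold")

    def __str__(self) -> str:
        return f">{self.band_threshold}" if self.censored else str(self.value)


def band_count(n: int, threshold: int = 100) -> BandedCount:
    """Band a record count for export: counts strictly above *threshold*
    are censored and print as ``>threshold``; a count equal to the
    threshold is reported exactly.
    """
    if n < 0:
        raise ValueError("count must be non-negative")
    if n > threshold:
        return BandedCount(value=threshold, band_threshold=threshold, censored=True)
    return BandedCount(value=n, band_threshold=threshold)


@dataclass
class OccurrenceRecord:
    """One basidiome record on one substrate unit."""

    species_id: str
    dataset_id: DatasetId
    year: int
    plot_id: Optional[str] = None
    site_type_group: Optional[str] = None
    tree_class: Optional[TreeClass] = None
    age_class: Optional[AgeClass] = None
    host_taxon: Optional[str] = None
    substrate_fraction: Optional[SubstrateFraction] = None
    decay_raw: Optional[DecayStage] = None
    special_habitat: Optional[SpecialHabitat] = None
    stand_scale: bool = False  # occurrence refers to a whole forest stand

    def validate(self, current_year: int = 2019,
                 site_type_groups: Sequence[str] = DEFAULT_SITE_TYPE_GROUPS) -> None:
        if not self.species_id:
            raise RecordValidationError("empty species_id")
        if not (1800 <= self.year <= current_year):
            raise RecordValidationError(
                f"year {self.year} outside [1800, {current_year}]"
            )
        if (self.substrate_fraction is SubstrateFraction.live_tree
                and self.decay_raw is not None):
            raise RecordValidationError("live tree cannot carry a decay stage")
        if (self.site_type_group is not None
                and self.site_type_group not in site_type_groups):
            raise RecordValidationError(
                f"unknown site-type group {self.site_type_group!r}"
            )


def recode_decay(decay_raw: Optional[Union[DecayStage, str]],
                 extremely_decayed: bool = False) -> Optional[DecayClass]:
    """Collapse the five decay stages to three classes:
    I-II -> early, III -> medium, IV-V -> late.

    Free-text annotations describing the wood as extremely decayed map to
    'late' even without a numeric stage.  Missing decay stays missing.
    """
    if decay_raw is None:
        return DecayClass.late if extremely_decayed else None
    stage = DecayStage(decay_raw)
    if stage in (DecayStage.I, DecayStage.II):
        return DecayClass.early
    if stage is DecayStage.III:
        return DecayClass.medium
    return DecayClass.late


#: Diameter below which a dead woody item counts as fine woody debris.
FWD_DIAMETER_CM = 10.0


def classify_substrate_fraction(diameter_cm: float, *, is_standing: bool,
                                is_live: bool, is_stump: bool = False
                                ) -> SubstrateFraction:
    """Assign the woody-fraction class from field measurements.

    Live trees are their own class.  Dead items strictly below 10 cm
    diameter (at the basidiome location) are fine woody debris regardless
    of posture; at or above 10 cm, standing dead wood and stumps are
    snags/stumps and fallen wood is coarse fallen dead wood.
    """
    if diameter_cm < 0:
        raise ValueError("negative diameter")
    if is_live:
        if is_stump:
            raise ValueError("a live tree cannot be a stump")
        return SubstrateFraction.live_tree
    if diameter_cm < FWD_DIAMETER_CM:
        return SubstrateFraction.fwd
    if is_stump or is_standing:
        return SubstrateFraction.snag_stump
    return SubstrateFraction.coarse_fallen


def habitat_key(record: OccurrenceRecord) -> HabitatKey:
    """Build the habitat key for a record: the stand triple, or the
    pooled special habitat.  Having both, or an incomplete triple, is an
    error; early-successional stands carry a flag so they can be excluded
    from the >20-year assemblage analysis.
    """
    has_triple = record.site_type_group is not None
    if has_triple and record.special_habitat is not None:
        raise RecordValidationError(
            f"record for {record.species_id}: both stand triple and special habitat set"
        )
    if record.special_habitat is not None:
        return HabitatKey(special_habitat=record.special_habitat)
    if not has_triple or record.tree_class is None or record.age_class is None:
        raise RecordValidationError(
            f"record for {record.species_id}: incomplete stand triple"
        )
    return HabitatKey(site_type_group=record.site_type_group,
                      tree_class=record.tree_class,
                      age_class=record.age_class)


# ---------------------------------------------------------------------------
# CSV ingestion

#: Default CSV column names; override via a schema config mapping.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "species_id": "species_id",
    "dataset_id": "dataset_id",
    "year": "year",
    "plot_id": "plot_id",
    "site_type_group": "site_type_group",
    "tree_class": "tree_class",
    "age_class": "age_class",
    "host_taxon": "host_taxon",
    "substrate_fraction": "substrate_fraction",
    "decay_raw": "decay_raw",
    "special_habitat": "special_habitat",
    "stand_scale": "stand_scale",
}

REQUIRED_FIELDS = ("species_id", "dataset_id", "year")


@dataclass
class Rejection:
    row: int  # 1-based data-row number
    reason: str


@dataclass
class ReadReport:
    accepted: int = 0
    rejected: int = 0
    rejections: list[Rejection] = field(default_factory=list)

    def log_text(self) -> str:
        lines = [f"accepted={self.accepted} rejected={self.rejected}"]
        lines += [f"row {r.row}: {r.reason}" for r in self.rejections]
        return "\n".join(lines) + "\n"


def _parse_optional(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    value = value.strip()
    return value or None


def read_records(source: Union[TextIO, str], *,
                 columns: Optional[Mapping[str, str]] = None,
                 current_year: int = 2019,
                 site_type_groups: Sequence[str] = DEFAULT_SITE_TYPE_GROUPS,
                 host_vocabulary: Optional[Sequence[str]] = None,
                 ) -> tuple[list[OccurrenceRecord], ReadReport]:
    """Read occurrence records from a CSV stream (or CSV text).

    Every row becomes a validated :class:`OccurrenceRecord` or a logged
    rejection carrying the 1-based data-row number and reason.  A missing
    required column is a hard failure; an unknown enum token rejects the
    row rather than silently coercing it.  *host_vocabulary*, when given,
    is the controlled list of host taxa (rows with hosts outside it are
    rejected).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise ValueError("CSV stream has no header row")
    for field_name in REQUIRED_FIELDS:
        if colmap[field_name] not in reader.fieldnames:
            raise ValueError(f"missing required column {colmap[field_name]!r}")

    records: list[OccurrenceRecord] = []
    report = ReadReport()

    def get(row: Mapping[str, str], field_name: str) -> Optional[str]:
        return _parse_optional(row.get(colmap[field_name]))

    for i, row in enumerate(reader, start=1):
        try:
            raw_year = get(row, "year")
            if raw_year is None:
                raise RecordValidationError("missing year")
            try:
                year = int(raw_year)
            except ValueError:
                raise RecordValidationError(f"unparseable year {raw_year!r}")
            raw_ds = get(row, "dataset_id")
            if raw_ds is None:
                raise RecordValidationError("missing dataset_id")
            try:
                dataset_id = DatasetId(raw_ds)
            except ValueError:
                raise RecordValidationError(f"unknown dataset id {raw_ds!r}")
            species = get(row, "species_id")
            if species is None:
                raise RecordValidationError("missing species_id")

            def parse_enum(field_name: str, enum_cls, label: str):
                token = get(row, field_name)
                if token is None:
                    return None
                try:
                    return enum_cls(token)
                except ValueError:
                    raise RecordValidationError(f"unknown {label} {token!r}")

            host = get(row, "host_taxon")
            if (host is not None and host_vocabulary is not None
                    and host not in host_vocabulary):
                raise RecordValidationError(f"unknown host taxon {host!r}")

            rec = OccurrenceRecord(
                species_id=species,
                dataset_id=dataset_id,
                year=year,
                plot_id=get(row, "plot_id"),
                site_type_group=get(row, "site_type_group"),
                tree_class=parse_enum("tree_class", TreeClass, "tree class"),
                age_class=parse_enum("age_class", AgeClass, "age class"),
                host_taxon=host,
                substrate_fraction=parse_enum(
                    "substrate_fraction", SubstrateFraction, "substrate fraction"),
                decay_raw=parse_enum("decay_raw", DecayStage, "decay stage"),
                special_habitat=parse_enum(
                    "special_habitat", SpecialHabitat, "special habitat"),
                stand_scale=(get(row, "stand_scale") or "").lower()
                in ("1", "true", "yes"),
            )
            rec.validate(current_year=current_year,
                         site_type_groups=site_type_groups)
        except RecordValidationError as exc:
            report.rejected += 1
            report.rejections.append(Rejection(row=i, reason=str(exc)))
            continue
        records.append(rec)
        report.accepted += 1
    return records, report


def write_records(records: Iterable[OccurrenceRecord], dest: TextIO) -> int:
    """Write records as normalized CSV (the inverse of :func:`read_records`).

    Returns the number of rows written.
    """
    writer = csv.DictWriter(dest, fieldnames=list(DEFAULT_COLUMNS.values()),
                            lineterminator="\n")
    writer.writeheader()
    n = 0
    for rec in records:
        writer.writerow({
            "species_id": rec.species_id,
            "dataset_id": rec.dataset_id.value,
            "year": rec.year,
            "plot_id": rec.plot_id or "",
            "site_type_group": rec.site_type_group or "",
            "tree_class": rec.tree_class.value if rec.tree_class else "",
            "age_class": rec.age_class.value if rec.age_class else "",
            "host_taxon": rec.host_taxon or "",
            "substrate_fraction":
                rec.substrate_fraction.value if rec.substrate_fraction else "",
            "decay_raw": rec.decay_raw.value if rec.decay_raw else "",
            "special_habitat":
                rec.special_habitat.value if rec.special_habitat else "",
            "stand_scale": "true" if rec.stand_scale else "",
        })
        n += 1
    return n
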