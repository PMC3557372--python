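"""Occurrence-record parsing, validation, filtering, harmonization and tabulation.

Records arrive as UTF-8 comma-separated text with one header row.  Mandatory
columns are ``species``, ``lon``, ``lat`` and ``locality_quality``; the
remaining documented columns (``year``, ``day_of_year``, ``host_name``,
``stage``, ``collection_method``, ``source_id``, ``region_tag``) are optional
and may be empty.  Coordinates are decimal degrees WGS84 with a decimal
point.

Curation follows the inclusion rules used for western-Palearctic tick
surveillance compilations: a record is retained only if it carries a
species-level name on the accepted-names list (or a defined species-group
label) and an unambiguous locality — either coordinates or an unambiguous
place name — inside the study window.  Records referred only to a genus, to a
large administrative division, or to an ambiguous locality are rejected and
tallied per rule.  Temporal fields never gate inclusion: most historical
records lack a collection year and are kept.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("tickniche")

# ---------------------------------------------------------------------------
# Controlled vocabularies and default taxonomy tables
# ---------------------------------------------------------------------------

STAGES = frozenset({"larva", "nymph", "adult", "unknown"})
COLLECTION_METHODS = frozenset({"host", "dragging", "unknown"})
LOCALITY_QUALITIES = frozenset(
    {"coordinates", "unambiguous_name", "admin_division", "ambiguous_name", "genus_only"}
)

#: Binomials (and one species-group label) accepted in the curated data set.
ACCEPTED_NAMES = frozenset(
    {
        "Ixodes ricinus",
        "Ixodes canisuga",
        "Ixodes hexagonus",
        "Ixodes gibbosus",
        "Dermacentor marginatus",
        "Dermacentor reticulatus",
        "Haemaphysalis punctata",
        "Haemaphysalis sulcata",
        "Hyalomma marginatum",
        "Hyalomma lusitanicum",
        "Hyalomma impeltatum",
        "Hyalomma anatolicum",
        "Hyalomma excavatum",
        "Hyalomma scupense",
        "Rhipicephalus annulatus",
        "Rhipicephalus bursa",
        "Rhipicephalus sanguineus group",
    }
)

#: Synonym / species-complex harmonization.  R. sanguineus and R. turanicus
#: cannot be reliably separated in the literature and are collapsed to the
#: sanguineus group label; Hy. detritum is a junior synonym of Hy. scupense.
DEFAULT_SYNONYMS: Mapping[str, str] = {
    "Rhipicephalus sanguineus": "Rhipicephalus sanguineus group",
    "Rhipicephalus turanicus": "Rhipicephalus sanguineus group",
    "Rhipicephalus sanguineus group": "Rhipicephalus sanguineus group",
    "Hyalomma detritum": "Hyalomma scupense",
}

#: Minimal host-name -> host-order lookup (Artiodactyla split by family, as
#: is conventional for tick host tabulations).  Keys are lower-case.
DEFAULT_HOST_TAXONOMY: Mapping[str, str] = {
    "cattle": "Artiodactyla (Bovidae)",
    "cow": "Artiodactyla (Bovidae)",
    "goat": "Artiodactyla (Bovidae)",
    "sheep": "Artiodactyla (Ovidae)",
    "mouflon": "Artiodactyla (Ovidae)",
    "pig": "Artiodactyla (Suidae)",
    "wild boar": "Artiodactyla (Suidae)",
    "camel": "Artiodactyla (Camelidae)",
    "horse": "Perissodactyla",
    "donkey": "Perissodactyla",
    "dog": "Carnivora",
    "red fox": "Carnivora",
    "fox": "Carnivora",
    "cat": "Carnivora",
    "mouse": "Rodentia",
    "vole": "Rodentia",
    "squirrel": "Rodentia",
    "hedgehog": "Insectivora",
    "shrew": "Insectivora",
    "hare": "Lagomorpha",
    "rabbit": "Lagomorpha",
    "human": "Hominidae",
    "blackbird": "Aves",
    "pheasant": "Aves",
    "robin": "Aves",
    "lizard": "Reptilia",
    "tortoise": "Reptilia",
}

CSV_COLUMNS = (
    "species",
    "lon",
    "lat",
    "year",
    "day_of_year",
    "host_name",
    "stage",
    "collection_method",
    "source_id",
    "locality_quality",
    "region_tag",
)

MANDATORY_COLUMNS = ("species", "lon", "lat", "locality_quality")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceRecord:
    """One curated tick observation.

    ``species_raw`` preserves the name as published; ``species`` holds the
    harmonized accepted binomial or group label (``None`` until harmonized,
    and left equal to ``species_raw`` with ``species_accepted=False`` when the
    name is on neither the accepted list nor the synonym table).
    """

    species_raw: str
    lon: float
    lat: float
    locality_quality: str
    species: str | None = None
    species_accepted: bool | None = None
    year: int | None = None
    day_of_year: int | None = None
    host_name: str | None = None
    host_order: str | None = None
    stage: str = "unknown"
    collection_method: str = "unknown"
    source_id: str = ""
    region_tag: str | None = None

    def __post_init__(self) -> None:
        if self.locality_quality not in LOCALITY_QUALITIES:
            raise ValueError(f"unknown locality_quality {self.locality_quality!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.collection_method not in COLLECTION_METHODS:
            raise ValueError(f"unknown collection_method {self.collection_method!r}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if self.day_of_year is not None and not 1 <= self.day_of_year <= 366:
            raise ValueError(f"day_of_year {self.day_of_year} outside 1..366")


@dataclass
class RowError:
    """A malformed input row, reported rather than silently dropped."""

    row_number: int  # 1-based, counting the header as row 1
    message: str


@dataclass
class RecordSet:
    """An ordered collection of records plus curation bookkeeping."""

    records: list[OccurrenceRecord] = field(default_factory=list)
    provenance: str = ""
    n_rejected_by_rule: dict[str, int] = field(default_factory=dict)
    row_errors: list[RowError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class StudyWindow:
    """Geographic inclusion box with named region exceptions.

    Bounds are closed intervals.  Region tags (not geometry) drive the
    island exceptions, because the Canaries lie south of the nominal box yet
    belong to the surveyed territory, while Iceland and the Azores do not.
    """

    lon_min: float = -11.0
    lon_max: float = 45.0
    lat_min: float = 29.0
    lat_max: float = 71.0
    inclusion_exceptions: tuple[str, ...] = ("Canary Islands",)
    exclusion_regions: tuple[str, ...] = ("Iceland", "Azores")

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("window bounds must satisfy min < max")

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.lon_min <= lon <= self.lon_max
            and self.lat_min <= lat <= self.lat_max
        )


WESTERN_PALEARCTIC = StudyWindow()


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _parse_optional_int(text: str | None, what: str) -> int | None:
    if text is None or text.strip() == "":
        return None
    try:
        return int(text)
    except ValueError as exc:
        raise ValueError(f"unparsable {what} {text!r}") from exc


def read_records(path: str | Path, provenance: str | None = None) -> RecordSet:
    """Parse a records CSV into a :class:`RecordSet`.

    Every well-formed row yields one record, in input order.  Malformed rows
    (unparsable coordinates, out-of-range values, unknown vocabulary) are
    collected in ``RecordSet.row_errors`` with their 1-based row numbers.
    A missing mandatory column raises :class:`SchemaError`.
    """
    path = Path(path)
    rs = RecordSet(provenance=provenance or str(path))
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        missing = [c for c in MANDATORY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
        unknown = [c for c in reader.fieldnames if c not in CSV_COLUMNS]
        if unknown:
            raise SchemaError(f"{path}: unknown column(s) {unknown}")
        for i, row in enumerate(reader, start=2):
            try:
                rs.records.append(_row_to_record(row))
            except (ValueError, KeyError) as exc:
                rs.row_errors.append(RowError(row_number=i, message=str(exc)))
    if rs.row_errors:
        logger.warning(
            "%s: %d malformed row(s) reported", path, len(rs.row_errors)
        )
    return rs


class SchemaError(ValueError):
    """The input file does not match the documented column schema."""


def _row_to_record(row: Mapping[str, str | None]) -> OccurrenceRecord:
    def get(col: str) -> str | None:
        v = row.get(col)
        if v is None:
            return None
        v = v.strip()
        return v or None

    species_raw = get("species")
    if not species_raw:
        raise ValueError("empty species name")
    lon_text, lat_text = get("lon"), get("lat")
    quality = get("locality_quality") or "coordinates"
    if quality == "coordinates" and (lon_text is None or lat_text is None):
        raise ValueError("locality_quality=coordinates but lon/lat missing")
    try:
        lon = float(lon_text) if lon_text is not None else float("nan")
        lat = float(lat_text) if lat_text is not None else float("nan")
    except ValueError as exc:
        raise ValueError(f"unparsable coordinate lon={lon_text!r} lat={lat_text!r}") from exc
    if lon != lon or lat != lat:  # NaN from a name-only locality
        raise ValueError("missing coordinates; records must arrive georeferenced")
    return OccurrenceRecord(
        species_raw=species_raw,
        lon=lon,
        lat=lat,
        locality_quality=quality,
        year=_parse_optional_int(get("year"), "year"),
        day_of_year=_parse_optional_int(get("day_of_year"), "day_of_year"),
        host_name=get("host_name"),
        stage=get("stage") or "unknown",
        collection_method=get("collection_method") or "unknown",
        source_id=get("source_id") or "",
        region_tag=get("region_tag"),
    )


def write_records(rs: RecordSet, path: str | Path) -> None:
    """Write a RecordSet back to the documented CSV dialect."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in rs.records:
            writer.writerow(
                [
                    r.species or r.species_raw,
                    repr(r.lon),
                    repr(r.lat),
                    "" if r.year is None else r.year,
                    "" if r.day_of_year is None else r.day_of_year,
                    r.host_name or "",
                    r.stage,
                    r.collection_method,
                    r.source_id,
                    r.locality_quality,
                    r.region_tag or "",
                ]
            )


def read_key_value_table(path: str | Path) -> dict[str, str]:
    """Read a plain-text ``key = value`` table (synonyms, host taxonomy)."""
    table: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed table line {line!r} (expected 'key = value')")
        key, value = (part.strip() for part in line.split("=", 1))
        table[key] = value
    return table


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def harmonize_species(
    name: str,
    synonyms: Mapping[str, str] | None = None,
    accepted: Iterable[str] | None = None,
) -> tuple[str, bool]:
    """Map a published name to its accepted binomial or group label.

    Returns ``(label, accepted_flag)``.  Unknown names are never silently
    passed through: they come back unchanged with ``accepted_flag=False``.
    Pure function of its inputs.
    """
    synonyms = DEFAULT_SYNONYMS if synonyms is None else synonyms
    accepted_set = ACCEPTED_NAMES if accepted is None else frozenset(accepted)
    name = " ".join(name.split())
    if name in synonyms:
        return synonyms[name], True
    if name in accepted_set:
        return name, True
    return name, False


def harmonize_records(
    rs: RecordSet,
    synonyms: Mapping[str, str] | None = None,
    accepted: Iterable[str] | None = None,
) -> RecordSet:
    """Harmonize every record's species in place; flag unaccepted names."""
    for rec in rs.records:
        if rec.species is not None and rec.species_accepted:
            continue
        label, ok = harmonize_species(rec.species_raw, synonyms, accepted)
        rec.species = label
        rec.species_accepted = ok
        if not ok:
            logger.warning("unaccepted name %r (source %s)", rec.species_raw, rec.source_id)
    return rs


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

#: Rejection rules in the order they are checked.  Locality defects dominate
#: (a genus-only record is rejected as genus_only even if the name would also
#: fail harmonization), then the name, then geography.
REJECTION_RULES = (
    "genus_only",
    "admin_division",
    "ambiguous_name",
    "unaccepted_name",
    "excluded_region",
    "outside_window",
)


def filter_records(
    rs: RecordSet,
    window: StudyWindow | None = None,
    synonyms: Mapping[str, str] | None = None,
    accepted: Iterable[str] | None = None,
) -> RecordSet:
    """Apply the inclusion criteria; idempotent and order-preserving.

    Retained records have ``locality_quality`` of ``coordinates`` or
    ``unambiguous_name``, an accepted species-level name, and fall inside the
    closed study window (or carry an inclusion-exception region tag).
    Rejections are a normal outcome, tallied per rule in
    ``n_rejected_by_rule``.
    """
    window = window or WESTERN_PALEARCTIC
    kept: list[OccurrenceRecord] = []
    tally: dict[str, int] = {}
    for rec in rs.records:
        rule = _rejection_rule(rec, window, synonyms, accepted)
        if rule is None:
            kept.append(rec)
        else:
            tally[rule] = tally.get(rule, 0) + 1
    for rule, n in sorted(tally.items()):
        logger.info("filter_records: rejected %d record(s) under rule %s", n, rule)
    return RecordSet(
        records=kept,
        provenance=rs.provenance,
        n_rejected_by_rule=tally,
        row_errors=list(rs.row_errors),
    )


def _rejection_rule(
    rec: OccurrenceRecord,
    window: StudyWindow,
    synonyms: Mapping[str, str] | None,
    accepted: Iterable[str] | None,
) -> str | None:
    if rec.locality_quality in ("genus_only", "admin_division", "ambiguous_name"):
        return rec.locality_quality
    if rec.species is None or rec.species_accepted is None:
        label, ok = harmonize_species(rec.species_raw, synonyms, accepted)
        rec.species, rec.species_accepted = label, ok
    if not rec.species_accepted:
        return "unaccepted_name"
    if rec.region_tag in window.exclusion_regions:
        return "excluded_region"
    if rec.region_tag in window.inclusion_exceptions:
        return None
    if not window.contains(rec.lon, rec.lat):
        return "outside_window"
    return None


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def round_half_up(x: float | int | Decimal, decimals: int = 1) -> float:
    """Round half away from zero at the given decimal place (table style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_counts(rs: "RecordSet | Mapping[str, int]") -> pd.DataFrame:
    """Per-species counts and half-up one-decimal percentages.

    Accepts either a harmonized RecordSet or a precomputed ``species -> N``
    mapping (a printed count table).  Returns columns ``species``, ``n``,
    ``percent``; rows sorted by species name; ``n`` sums to the total.  Empty
    input gives an empty table.
    """
    if isinstance(rs, RecordSet):
        counts: dict[str, int] = {}
        for rec in rs.records:
            label = rec.species or rec.species_raw
            counts[label] = counts.get(label, 0) + 1
    else:
        counts = dict(rs)
    species = sorted(counts)
    total = sum(counts.values())
    if total == 0:
        return pd.DataFrame(columns=["species", "n", "percent"])
    percents = [
        float(
            (Decimal(100) * Decimal(counts[s]) / Decimal(total)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        for s in species
    ]
    return pd.DataFrame(
        {"species": species, "n": [counts[s] for s in species], "percent": percents}
    )


@dataclass
class HostCrosstab:
    """Species x host-order tabulation.

    ``percentages`` rows are per-species shares over that species'
    host-attributed records (summing to 100 within rounding) plus a final
    ``Totals`` row giving each order's share of all host-attributed records.
    Records without a resolvable host are excluded from denominators and
    counted in ``unresolved_by_species``.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    unresolved_by_species: dict[str, int]


def host_crosstab(
    rs: RecordSet, host_taxonomy: Mapping[str, str] | None = None
) -> HostCrosstab:
    """Cross-tabulate species against host taxonomic order."""
    taxonomy = DEFAULT_HOST_TAXONOMY if host_taxonomy is None else host_taxonomy
    taxonomy = {k.lower(): v for k, v in taxonomy.items()}
    cell_counts: dict[tuple[str, str], int] = {}
    unresolved: dict[str, int] = {}
    for rec in rs.records:
        species = rec.species or rec.species_raw
        order = rec.host_order
        if order is None and rec.host_name is not None:
            order = taxonomy.get(rec.host_name.lower())
            if order is None:
                logger.warning("host name %r not in taxonomy", rec.host_name)
        if order is None:
            unresolved[species] = unresolved.get(species, 0) + 1
            continue
        cell_counts[(species, order)] = cell_counts.get((species, order), 0) + 1
    if not cell_counts:
        empty = pd.DataFrame()
        return HostCrosstab(counts=empty, percentages=empty.copy(), unresolved_by_species=unresolved)
    species_labels = sorted({s for s, _ in cell_counts})
    orders = sorted({o for _, o in cell_counts})
    counts = pd.DataFrame(0, index=species_labels, columns=orders, dtype=int)
    for (s, o), n in cell_counts.items():
        counts.loc[s, o] = n
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    grand = counts.sum(axis=0)
    pct.loc["Totals"] = grand / grand.sum() * 100.0
    pct = pct.map(lambda v: round_half_up(v, 1))
    return HostCrosstab(counts=counts, percentages=pct, unresolved_by_species=unresolved)
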