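"""Structured-review tabulation of UV crop-reflectance studies.

Ships a transcribed record table (one row per species × plant part ×
reference measurement) and the categorisers used to summarise it:
instruments collapse into four classes (camera, videometer,
spectrometer/spectroradiometer, spectrophotometer) and plant parts into five
(flower, stem, leaf, fruit, root).  Summary shares are computed over two
deliberately different denominators, recorded in the summary metadata:
instrument shares count measurement rows (one instrument per measurement
event), while part shares count part components after exploding compound
labels such as "bark/leaf" (both parts were measured in that one event).
Exact duplicate rows are dropped, with a warning, before any counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .spectra import assign_spectral_bins

logger = logging.getLogger(__name__)

__all__ = [
    "StudyRecord",
    "MetaSummary",
    "UncategorizedError",
    "INSTRUMENT_CATEGORIES",
    "PART_CATEGORIES",
    "categorize_instrument",
    "categorize_part",
    "split_part_components",
    "load_table1_records",
    "records_from_frame",
    "summarize_records",
    "flower_film_share",
    "records_per_year",
    "spectral_bins_for_record",
]

INSTRUMENT_CATEGORIES = ("camera", "videometer", "spectrometer_class", "spectrophotometer")
PART_CATEGORIES = ("flower", "stem", "leaf", "fruit", "root")


class UncategorizedError(ValueError):
    """Raised when a raw label matches no category keyword."""


@dataclass(frozen=True)
class StudyRecord:
    """One review entry: a species × part measurement from one reference."""

    family: str
    species: str
    common_name: str
    part_raw: str
    range_lo: float
    range_hi: float
    instrument_raw: str
    year: int
    reference_key: str

    def __post_init__(self) -> None:
        if not self.family or not self.species:
            raise ValueError("family and species must be non-empty")
        if self.range_lo > self.range_hi:
            raise ValueError("range_lo exceeds range_hi")
        if not 1960 <= self.year <= 2021:
            raise ValueError(f"year {self.year} outside the review window 1960-2021")


@dataclass(frozen=True)
class MetaSummary:
    """Counts and percentage shares for a set of study records.

    Shares are stored unrounded; ``to_frames`` rounds to one decimal for
    export.  ``meta`` records the denominator conventions.
    """

    n_records: int
    n_families: int
    n_species: int
    share_by_instrument: dict[str, float]
    share_by_part: dict[str, float]
    share_by_family: dict[str, float]
    per_year: dict[int, int]
    meta: dict = field(default_factory=dict)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        def frame(d: dict[str, float]) -> pd.DataFrame:
            return pd.DataFrame(
                {"category": list(d), "share_percent": [round(v, 1) for v in d.values()]}
            )

        return {
            "instrument": frame(self.share_by_instrument),
            "part": frame(self.share_by_part),
            "family": frame(self.share_by_family),
            "per_year": pd.DataFrame(
                {"year": list(self.per_year), "n_rows": list(self.per_year.values())}
            ).sort_values("year", ignore_index=True),
        }


# Longest keyword first so e.g. "spectrophotometer" never falls through to
# a shorter match; scanners are imaging devices and belong with cameras.
_INSTRUMENT_KEYWORDS = [
    ("spectrophotometer", "spectrophotometer"),
    ("spectroradiometer", "spectrometer_class"),
    ("spectrometer", "spectrometer_class"),
    ("spectroscopy", "spectrometer_class"),
    ("videometer", "videometer"),
    ("scanner", "camera"),
    ("camera", "camera"),
]

_PART_KEYWORDS = {
    # reproductive structures
    "flower": "flower", "anther": "flower", "stamen": "flower",
    "petal": "flower", "sepal": "flower",
    # dermal/vascular/ground tissue
    "stem": "stem", "stock": "stem", "stalk": "stem", "bark": "stem",
    "cork": "stem", "wood": "stem", "xylem": "stem", "phloem": "stem",
    # seed and/or ripened ovary
    "fruit": "fruit", "seed": "fruit", "grain": "fruit", "berry": "fruit",
    # leaves, either surface
    "leaf": "leaf", "leaves": "leaf",
    # tubers as well as roots themselves
    "root": "root", "tuber": "root",
}


def categorize_instrument(raw: str) -> str:
    """Map a raw instrument description onto one of the four categories."""
    if not raw or not raw.strip():
        raise UncategorizedError("empty instrument label")
    low = raw.lower()
    for keyword, category in _INSTRUMENT_KEYWORDS:
        if keyword in low:
            return category
    raise UncategorizedError(f"uncategorized instrument: {raw!r}")


def split_part_components(raw: str) -> list[str]:
    """Split a compound part label ("bark/leaf") into its components."""
    parts = [p.strip() for p in raw.split("/") if p.strip()]
    if not parts:
        raise UncategorizedError("empty part label")
    return parts


def categorize_part(raw: str) -> str:
    """Map a part label onto one of the five categories.

    A compound label whose components all map to the same category (e.g.
    "tuber/root") resolves to that category; mixed compounds must be
    exploded upstream with :func:`split_part_components` and raise here.
    """
    cats = []
    for component in split_part_components(raw):
        token = component.lower()
        if token not in _PART_KEYWORDS:
            raise UncategorizedError(f"uncategorized plant part: {component!r}")
        cats.append(_PART_KEYWORDS[token])
    unique = sorted(set(cats))
    if len(unique) > 1:
        raise UncategorizedError(
            f"compound part {raw!r} spans categories {unique}; explode it first"
        )
    return unique[0]


def load_table1_records() -> pd.DataFrame:
    """Load the packaged review record table."""
    with resources.files("floravis.data").joinpath("table1_records.csv").open() as fh:
        return pd.read_csv(fh)


def records_from_frame(frame: pd.DataFrame) -> list[StudyRecord]:
    return [
        StudyRecord(
            family=row.family,
            species=row.species,
            common_name=row.common_name,
            part_raw=row.part_raw,
            range_lo=float(row.range_lo),
            range_hi=float(row.range_hi),
            instrument_raw=row.instrument_raw,
            year=int(row.year),
            reference_key=row.reference_key,
        )
        for row in frame.itertuples(index=False)
    ]


def _dedupe(records: list[StudyRecord]) -> list[StudyRecord]:
    seen: set[StudyRecord] = set()
    out: list[StudyRecord] = []
    for rec in records:
        if rec in seen:
            logger.warning("dropping exact duplicate row: %s / %s / %s", rec.species, rec.part_raw, rec.reference_key)
            continue
        seen.add(rec)
        out.append(rec)
    return out


def summarize_records(records: list[StudyRecord]) -> MetaSummary:
    """Counts and shares for a record set.

    * ``n_records`` — distinct references;
    * ``n_families`` — distinct plant families;
    * ``n_species`` — distinct tabulated species entries
      (family, species, common name, part), matching how review tables list
      a species once per measured crop/part;
    * instrument and family shares over measurement rows;
    * part shares over part components after exploding compound labels.
    """
    records = _dedupe(list(records))
    if not records:
        return MetaSummary(0, 0, 0, {}, {}, {}, {}, meta={"n_rows": 0})
    n_rows = len(records)
    instruments = [categorize_instrument(r.instrument_raw) for r in records]
    part_components: list[str] = []
    for r in records:
        cats = {categorize_part(c) for c in split_part_components(r.part_raw)}
        part_components.extend(sorted(cats))

    def shares(labels: list[str]) -> dict[str, float]:
        s = pd.Series(labels).value_counts()
        return {k: 100.0 * v / len(labels) for k, v in s.items()}

    per_year = pd.Series([r.year for r in records]).value_counts().sort_index()
    return MetaSummary(
        n_records=len({r.reference_key for r in records}),
        n_families=len({r.family for r in records}),
        n_species=len({(r.family, r.species, r.common_name, r.part_raw) for r in records}),
        share_by_instrument=shares(instruments),
        share_by_part=shares(part_components),
        share_by_family=shares([r.family for r in records]),
        per_year={int(y): int(n) for y, n in per_year.items()},
        meta={
            "n_rows": n_rows,
            "n_part_components": len(part_components),
            "instrument_denominator": "measurement rows (exact duplicates dropped)",
            "part_denominator": "part components after compound-label explosion",
        },
    )


def flower_film_share(records: list[StudyRecord]) -> float:
    """Percent of flower-part measurement rows captured on photographic film."""
    records = _dedupe(list(records))
    flower_rows = [
        r
        for r in records
        if any(categorize_part(c) == "flower" for c in split_part_components(r.part_raw))
    ]
    if not flower_rows:
        raise ValueError("no flower-part rows; film share undefined")
    film = [
        r
        for r in flower_rows
        if categorize_instrument(r.instrument_raw) == "camera"
        and "film" in r.instrument_raw.lower()
    ]
    return 100.0 * len(film) / len(flower_rows)


def records_per_year(records: list[StudyRecord]) -> pd.DataFrame:
    """Per-year measurement-row counts, for trend plots."""
    summary = summarize_records(records)
    return summary.to_frames()["per_year"]


def spectral_bins_for_record(record: StudyRecord) -> list[str]:
    """Which of the four wavelength bands a record's measured range touches."""
    return assign_spectral_bins(record.range_lo, record.range_hi)
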