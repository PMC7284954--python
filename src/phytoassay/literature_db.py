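"""Literature microbe-report model: lineage/tissue rules, filters, overlaps.

Each record is a single literature report of a microbe on or near a host
plant.  This module assigns host lineages from geography and collection
year, normalizes free-text tissue descriptions to a closed vocabulary,
filters reports down to comparable community samples, and computes taxon
overlaps and coverage fractions between named sets.
"""

from __future__ import annotations

import enum
import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import percent

logger = logging.getLogger(__name__)

__all__ = [
    "CONTINENTS",
    "GROUPS",
    "MicrobeReport",
    "LineageLabel",
    "TissueCategory",
    "LineageRules",
    "CommunitySample",
    "TissueMappingError",
    "assign_lineage",
    "normalize_tissue",
    "load_tissue_synonyms",
    "filter_communities",
    "community_table",
    "taxon_overlap",
    "OverlapResult",
    "species_level_subset",
    "collection_coverage",
    "taxon_key",
    "read_report_table",
    "write_report_table",
]

CONTINENTS = frozenset(
    {"Africa", "Asia", "Australia", "Europe", "North America", "South America"}
)
GROUPS = frozenset({"fungus", "oomycete", "bacterium", "archaeon", "virus"})


class TissueMappingError(KeyError):
    """Raised for a tissue term absent from the synonym dictionary."""


class LineageLabel(str, enum.Enum):
    AMERICANUS = "americanus"
    AUSTRALIS = "australis"
    ALTISSIMUS = "altissimus"
    GULF_EXCLUDED = "gulf_excluded"
    UNCERTAIN = "uncertain"


class TissueCategory(str, enum.Enum):
    LEAF = "leaf"
    SHEATH = "sheath"
    STEM = "stem"
    SEED = "seed"
    INFLORESCENCE = "inflorescence"
    ROOT_ASSOCIATED = "root_associated"
    RHIZOSPHERE_SOIL = "rhizosphere_soil"

    @property
    def compartment(self) -> str:
        if self is TissueCategory.RHIZOSPHERE_SOIL:
            return "soil"
        if self is TissueCategory.ROOT_ASSOCIATED:
            return "rhizosphere"
        return "phyllosphere"


@dataclass(frozen=True)
class MicrobeReport:
    """One literature record of a microbe identified on the host plant."""

    report_id: str
    taxon_name: str
    taxonomic_rank: str
    group: str
    study_id: str
    continent: str
    country: str = ""
    region_hint: str = ""
    sh_code: str = ""
    culture_dependent: bool = True
    collection_year: int | None = None
    host_lineage_stated: str = ""
    tissue: str = ""
    tissue_alive: bool | None = None
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown organism group: {self.group!r} (expected one of {sorted(GROUPS)})")
        if self.continent and self.continent not in CONTINENTS:
            raise ValueError(f"unknown continent: {self.continent!r}")
        if self.collection_year is not None and not 1700 <= self.collection_year <= 2100:
            raise ValueError(f"implausible collection year: {self.collection_year}")


# ---------------------------------------------------------------------------
# lineage assignment

# Curated fallback when no coordinates exist: states/provinces counted as
# central/western North America.  The split is a configurable
# operationalization (longitude west of -85 by default).
_CENTRAL_WESTERN_REGIONS = frozenset(
    {
        "michigan", "wisconsin", "illinois", "indiana", "minnesota", "iowa",
        "missouri", "north dakota", "south dakota", "nebraska", "kansas",
        "oklahoma", "texas", "montana", "wyoming", "colorado", "new mexico",
        "idaho", "utah", "arizona", "nevada", "washington", "oregon",
        "california", "alaska", "manitoba", "saskatchewan", "alberta",
        "british columbia", "yukon", "northwest territories",
    }
)


@dataclass(frozen=True)
class LineageRules:
    """Geography/era rules mapping a report to a host lineage."""

    altissimus_countries: frozenset = frozenset({"Spain", "Portugal", "Italy", "Egypt", "Morocco"})
    uncertain_countries: frozenset = frozenset({"Romania"})
    americanus_year_cutoff: int = 1910
    central_western_longitude: float = -85.0
    central_western_regions: frozenset = _CENTRAL_WESTERN_REGIONS
    stated_aliases: Mapping[str, LineageLabel] = field(
        default_factory=lambda: {
            "americanus": LineageLabel.AMERICANUS,
            "australis": LineageLabel.AUSTRALIS,
            "altissimus": LineageLabel.ALTISSIMUS,
            "gulf": LineageLabel.GULF_EXCLUDED,
            "delta": LineageLabel.AUSTRALIS,
            "greeny": LineageLabel.AUSTRALIS,
            "uncertain": LineageLabel.UNCERTAIN,
        }
    )


DEFAULT_LINEAGE_RULES = LineageRules()


def _is_central_western(report: MicrobeReport, rules: LineageRules) -> bool:
    if report.longitude is not None:
        return report.longitude < rules.central_western_longitude
    return report.region_hint.strip().lower() in rules.central_western_regions


def assign_lineage(
    report: MicrobeReport, rules: LineageRules = DEFAULT_LINEAGE_RULES
) -> LineageLabel:
    """Assign a host lineage label by precedence.

    1. an author-stated lineage always wins (Gulf maps to the excluded
       label); 2. old collections from central/western North America are the
       native lineage; 3. a fixed Mediterranean country list; 4. Romania is
       uncertain (hybrid zone); 5. remaining Europe, and 6. Asia / Australia
       / Africa, default to the cosmopolitan lineage.  Anything else is
       uncertain with a logged warning.
    """
    stated = report.host_lineage_stated.strip().lower()
    if stated:
        try:
            return rules.stated_aliases[stated]
        except KeyError:
            raise ValueError(f"unrecognized stated lineage: {report.host_lineage_stated!r}") from None
    if not report.continent:
        raise ValueError(f"report {report.report_id!r}: continent is required for lineage assignment")

    if report.continent == "North America":
        if (
            report.collection_year is not None
            and report.collection_year < rules.americanus_year_cutoff
            and _is_central_western(report, rules)
        ):
            return LineageLabel.AMERICANUS
        logger.warning(
            "report %s: North American report without stated lineage or pre-%d "
            "central/western provenance; labeled uncertain",
            report.report_id,
            rules.americanus_year_cutoff,
        )
        return LineageLabel.UNCERTAIN
    if report.continent == "Europe":
        if report.country in rules.altissimus_countries:
            return LineageLabel.ALTISSIMUS
        if report.country in rules.uncertain_countries:
            return LineageLabel.UNCERTAIN
        return LineageLabel.AUSTRALIS
    if report.continent in ("Asia", "Australia", "Africa"):
        # Mediterranean Africa belongs to the altissimus country list.
        if report.country in rules.altissimus_countries:
            return LineageLabel.ALTISSIMUS
        return LineageLabel.AUSTRALIS
    logger.warning("report %s: continent %s not covered by lineage rules; labeled uncertain",
                   report.report_id, report.continent)
    return LineageLabel.UNCERTAIN


# ---------------------------------------------------------------------------
# tissue normalization

DEFAULT_TISSUE_SYNONYMS: dict[str, TissueCategory] = {
    "leaf": TissueCategory.LEAF,
    "leaves": TissueCategory.LEAF,
    "leaf blade": TissueCategory.LEAF,
    "blade": TissueCategory.LEAF,
    "foliage": TissueCategory.LEAF,
    "sheath": TissueCategory.SHEATH,
    "leaf sheath": TissueCategory.SHEATH,
    "stem": TissueCategory.STEM,
    "stems": TissueCategory.STEM,
    "culm": TissueCategory.STEM,
    "stalk": TissueCategory.STEM,
    "shoot": TissueCategory.STEM,
    "seed": TissueCategory.SEED,
    "seeds": TissueCategory.SEED,
    "caryopsis": TissueCategory.SEED,
    "grain": TissueCategory.SEED,
    "inflorescence": TissueCategory.INFLORESCENCE,
    "panicle": TissueCategory.INFLORESCENCE,
    "spikelet": TissueCategory.INFLORESCENCE,
    "flower": TissueCategory.INFLORESCENCE,
    "inflorescence branch": TissueCategory.INFLORESCENCE,
    "root": TissueCategory.ROOT_ASSOCIATED,
    "roots": TissueCategory.ROOT_ASSOCIATED,
    "primary root": TissueCategory.ROOT_ASSOCIATED,
    "secondary root": TissueCategory.ROOT_ASSOCIATED,
    "root mixture": TissueCategory.ROOT_ASSOCIATED,
    "rhizome": TissueCategory.ROOT_ASSOCIATED,
    "rhizomes": TissueCategory.ROOT_ASSOCIATED,
    "rhizosphere": TissueCategory.RHIZOSPHERE_SOIL,
    "rhizosphere soil": TissueCategory.RHIZOSPHERE_SOIL,
    "soil": TissueCategory.RHIZOSPHERE_SOIL,
}


def normalize_tissue(
    raw_tissue: str, synonyms: Mapping[str, TissueCategory] | None = None
) -> TissueCategory:
    """Map a free-text tissue description onto the closed vocabulary.

    Unknown terms raise :class:`TissueMappingError` naming the term — there
    is deliberately no silent catch-all bucket.
    """
    if isinstance(raw_tissue, TissueCategory):
        return raw_tissue
    table = DEFAULT_TISSUE_SYNONYMS if synonyms is None else synonyms
    key = " ".join(str(raw_tissue).split()).lower()
    try:
        return table[key]
    except KeyError:
        raise TissueMappingError(
            f"tissue term {raw_tissue!r} has no entry in the synonym dictionary"
        ) from None


def load_tissue_synonyms(path) -> dict[str, TissueCategory]:
    """Read a two-column TSV (term, category) into a synonym dictionary."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "category"], comment="#")
    out = {}
    for row in df.itertuples():
        out[" ".join(str(row.term).split()).lower()] = TissueCategory(str(row.category))
    return out


# ---------------------------------------------------------------------------
# taxon identity and filters


def taxon_key(report_or_name, sh_code: str = "") -> str:
    """Identity key: SH code when present, else normalized taxon name."""
    if isinstance(report_or_name, MicrobeReport):
        sh_code = report_or_name.sh_code
        name = report_or_name.taxon_name
    else:
        name = report_or_name
    if sh_code:
        return sh_code.strip()
    return " ".join(str(name).split()).lower()


@dataclass
class CommunitySample:
    """One community: all reports from one study x tissue x organism group."""

    sample_id: str
    study_id: str
    tissue: TissueCategory
    group: str
    taxon_counts: Counter
    continent: str = ""
    lineage: str = ""

    @property
    def n_isolates(self) -> int:
        return sum(self.taxon_counts.values())


def filter_communities(
    reports: Iterable[MicrobeReport],
    min_isolates: int = 10,
    synonyms: Mapping[str, TissueCategory] | None = None,
    exclude_dead_tissue: bool = True,
) -> list[CommunitySample]:
    """Reduce reports to comparable community samples.

    Keeps culture-dependent studies only, drops reports from dead tissue
    (unknown vitality is treated as alive and logged), groups the remainder
    by study x tissue category x organism group, and keeps groups with at
    least ``min_isolates`` reports.  Output order is deterministic and
    independent of input row order.
    """
    kept: dict[tuple, list[MicrobeReport]] = {}
    unknown_vitality = 0
    for report in reports:
        if not report.culture_dependent:
            continue
        if report.tissue_alive is None:
            unknown_vitality += 1
        elif exclude_dead_tissue and not report.tissue_alive:
            continue
        category = normalize_tissue(report.tissue, synonyms)
        kept.setdefault((report.study_id, category, report.group), []).append(report)
    if unknown_vitality:
        logger.info("filter_communities: %d reports with unknown tissue vitality treated as alive",
                    unknown_vitality)

    samples = []
    for (study, category, group) in sorted(kept, key=lambda k: (k[0], k[1].value, k[2])):
        members = kept[(study, category, group)]
        if len(members) < min_isolates:
            continue
        counts = Counter(taxon_key(r) for r in members)
        continents = Counter(r.continent for r in members)
        samples.append(
            CommunitySample(
                sample_id=f"{study}|{category.value}|{group}",
                study_id=study,
                tissue=category,
                group=group,
                taxon_counts=counts,
                continent=continents.most_common(1)[0][0] if continents else "",
            )
        )
    if not samples:
        logger.info("filter_communities: no community passed the filters")
    return samples


def community_table(samples: Sequence[CommunitySample]) -> pd.DataFrame:
    """Samples-x-taxa abundance matrix (DataFrame) from community samples."""
    taxa = sorted({t for s in samples for t in s.taxon_counts})
    data = [[s.taxon_counts.get(t, 0) for t in taxa] for s in samples]
    return pd.DataFrame(data, index=[s.sample_id for s in samples], columns=taxa)


# ---------------------------------------------------------------------------
# overlaps and coverage


@dataclass(frozen=True)
class OverlapResult:
    set_sizes: dict
    region_counts: dict | None
    pairwise: dict
    union_size: int
    shared_two_or_more: int


def taxon_overlap(sets: Mapping[str, Iterable[str]]) -> OverlapResult:
    """Exact region cardinalities of the set-intersection lattice.

    For two or three named sets every exclusive region is enumerated (keys
    are '&'-joined sorted name tuples); for more than three sets only the
    pairwise numbers are produced (logged).  Pairwise entries hold
    ``(shared, shared/|A|, shared/|B|)``.
    """
    named = {name: set(values) for name, values in sets.items()}
    if len(named) < 2:
        raise ValueError("need at least two named sets")
    names = sorted(named)
    union = set().union(*named.values())

    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        shared = len(named[a] & named[b])
        frac_a = shared / len(named[a]) if named[a] else 0.0
        frac_b = shared / len(named[b]) if named[b] else 0.0
        pairwise[(a, b)] = (shared, frac_a, frac_b)

    region_counts = None
    if len(named) <= 3:
        region_counts = {}
        for r in range(1, len(names) + 1):
            for inside in itertools.combinations(names, r):
                region = set.intersection(*(named[n] for n in inside))
                for outside in names:
                    if outside not in inside:
                        region -= named[outside]
                region_counts["&".join(inside)] = len(region)
    else:
        logger.info("taxon_overlap: %d sets; emitting pairwise counts only", len(named))

    membership = Counter()
    for members in named.values():
        membership.update(members)
    shared_multi = sum(1 for count in membership.values() if count >= 2)

    return OverlapResult(
        set_sizes={n: len(named[n]) for n in names},
        region_counts=region_counts,
        pairwise=pairwise,
        union_size=len(union),
        shared_two_or_more=shared_multi,
    )


def species_level_subset(
    reports: Sequence[MicrobeReport],
) -> tuple[list[MicrobeReport], int]:
    """Reports resolved to species level or carrying an SH code.

    Returns the retained reports and the retained share as a whole percent
    (half-up).
    """
    kept = [
        r
        for r in reports
        if r.taxonomic_rank.strip().lower() == "species" or r.sh_code.strip()
    ]
    pct = percent(len(kept), len(reports)) if reports else 0
    return kept, pct


def collection_coverage(
    collection_taxa: Iterable[str],
    reported_taxa: Mapping,
) -> dict:
    """Share of each reported taxon set present in the collection.

    ``reported_taxa`` maps a key (e.g. ``(region, group)``) to a taxon set;
    values are whole percents.  An empty reported set is an error, not 100%.
    """
    collection = set(collection_taxa)
    out = {}
    for key, reported in reported_taxa.items():
        reported = set(reported)
        if not reported:
            raise ValueError(f"empty reported taxon set for {key!r}")
        out[key] = percent(len(collection & reported), len(reported))
    return out


# ---------------------------------------------------------------------------
# table I/O

REPORT_COLUMNS = [
    "report_id", "taxon_name", "taxonomic_rank", "group", "study_id",
    "continent", "country", "region_hint", "sh_code", "culture_dependent",
    "collection_year", "host_lineage_stated", "tissue", "tissue_alive",
    "latitude", "longitude",
]

_OPTIONAL_FLOATS = ("latitude", "longitude")


def read_report_table(path) -> list[MicrobeReport]:
    """Load a report TSV with the standard column set."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report table is missing columns: {sorted(missing)}")
    reports = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        year = rec["collection_year"]
        alive = rec["tissue_alive"]
        reports.append(
            MicrobeReport(
                report_id=rec["report_id"],
                taxon_name=rec["taxon_name"],
                taxonomic_rank=rec["taxonomic_rank"],
                group=rec["group"],
                study_id=rec["study_id"],
                continent=rec["continent"],
                country=rec["country"],
                region_hint=rec["region_hint"],
                sh_code=rec["sh_code"],
                culture_dependent=rec["culture_dependent"] in ("1", "true", "True"),
                collection_year=int(float(year)) if year != "" else None,
                host_lineage_stated=rec["host_lineage_stated"],
                tissue=rec["tissue"],
                tissue_alive=None if alive == "" else alive in ("1", "true", "True"),
                latitude=float(rec["latitude"]) if rec["latitude"] != "" else None,
                longitude=float(rec["longitude"]) if rec["longitude"] != "" else None,
            )
        )
    return reports


def write_report_table(reports: Sequence[MicrobeReport], path) -> None:
    rows = []
    for r in reports:
        rows.append(
            {
                "report_id": r.report_id,
                "taxon_name": r.taxon_name,
                "taxonomic_rank": r.taxonomic_rank,
                "group": r.group,
                "study_id": r.study_id,
                "continent": r.continent,
                "country": r.country,
                "region_hint": r.region_hint,
                "sh_code": r.sh_code,
                "culture_dependent": int(r.culture_dependent),
                "collection_year": "" if r.collection_year is None else r.collection_year,
                "host_lineage_stated": r.host_lineage_stated,
                "tissue": r.tissue,
                "tissue_alive": "" if r.tissue_alive is None else int(r.tissue_alive),
                "latitude": "" if r.latitude is None else r.latitude,
                "longitude": "" if r.longitude is None else r.longitude,
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)
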