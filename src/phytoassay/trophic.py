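"""Trophic-mode assignment from a guild lookup table and from bioassays.

Predicted modes come from a local guild-table snapshot (taxon, rank,
trophic_mode, guild, confidence); experimentally supported modes are derived
from the seedling, mature-leaf, and saprophyte assays via an explicit,
swappable precedence policy.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .assay_scoring import PathClass

logger = logging.getLogger(__name__)

__all__ = [
    "GuildEntry",
    "GuildTable",
    "TrophicRatio",
    "SaprophyteOutcome",
    "TrophicPolicy",
    "DEFAULT_POLICY",
    "load_guild_table",
    "assign_guild",
    "trophic_ratio",
    "experimental_trophic_class",
    "saprophyte_summary",
    "SaprophyteSummary",
]

CONFIDENCE_LEVELS = ("possible", "probable", "highly probable")

# ranks at or above family carry too little signal for a mode call
_RANKS_BELOW_FAMILY = {"form", "variety", "subspecies", "species", "genus"}
_RANKS_FAMILY_OR_HIGHER = {"family", "order", "class", "phylum", "kingdom", "domain"}


class SaprophyteOutcome(str, enum.Enum):
    SPORULATING = "sporulating"
    STERILE_HYPHAE_ONLY = "sterile_hyphae_only"
    NO_GROWTH = "no_growth"


@dataclass(frozen=True)
class GuildEntry:
    taxon: str
    rank: str
    trophic_mode: str
    guild: str
    confidence: str

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"confidence must be one of {CONFIDENCE_LEVELS}, got {self.confidence!r}")
        rank = self.rank.strip().lower()
        if rank not in _RANKS_BELOW_FAMILY | _RANKS_FAMILY_OR_HIGHER:
            raise ValueError(f"unknown taxonomic rank: {self.rank!r}")


class GuildTable:
    """Lookup of guild entries keyed by normalized taxon name."""

    def __init__(self, entries: Iterable[GuildEntry]):
        self._by_key: dict[str, GuildEntry] = {}
        for entry in entries:
            self._by_key[_norm(entry.taxon)] = entry

    def __len__(self) -> int:
        return len(self._by_key)

    def lookup(self, taxon_name: str) -> GuildEntry | None:
        """Most specific match: full name first, then the genus epithet."""
        key = _norm(taxon_name)
        if key in self._by_key:
            return self._by_key[key]
        genus = key.split(" ")[0]
        return self._by_key.get(genus)


def _norm(name: str) -> str:
    return " ".join(str(name).split()).lower()


def load_guild_table(path) -> GuildTable:
    """Read the guild TSV; malformed rows raise with their row number."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"taxon", "rank", "trophic_mode", "guild", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"guild table is missing columns: {sorted(missing)}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            entries.append(
                GuildEntry(
                    taxon=row.taxon,
                    rank=row.rank,
                    trophic_mode=row.trophic_mode,
                    guild=row.guild,
                    confidence=row.confidence,
                )
            )
        except ValueError as exc:
            raise ValueError(f"guild table row {i}: {exc}") from exc
    return GuildTable(entries)


def assign_guild(taxon_name: str, guild_table: GuildTable) -> str:
    """Predicted trophic mode for a taxon, or ``"unassigned"``.

    Matches that are merely "possible" or resolved only at family rank or
    higher are discarded.
    """
    entry = guild_table.lookup(taxon_name)
    if entry is None:
        return "unassigned"
    if entry.confidence == "possible":
        return "unassigned"
    if entry.rank.strip().lower() in _RANKS_FAMILY_OR_HIGHER:
        return "unassigned"
    return entry.trophic_mode


@dataclass(frozen=True)
class TrophicRatio:
    pathogen: int
    endophyte: int
    saprophyte: int
    normalized: tuple[int, int, int] | None
    defined: bool


def trophic_ratio(counts: Sequence[int]) -> TrophicRatio:
    """Pathogen:Endophyte:Saprophyte ratio scaled so endophyte = 1.

    Each normalized term is rounded half-up to the nearest integer.  With a
    zero endophyte count the normalization is flagged undefined and only the
    raw counts are reported.
    """
    p, e, s = (int(c) for c in counts)
    if min(p, e, s) < 0:
        raise ValueError("trophic counts must be non-negative")
    if e == 0:
        return TrophicRatio(p, e, s, normalized=None, defined=False)
    normalized = (int(round_half_up(p / e)), 1, int(round_half_up(s / e)))
    return TrophicRatio(p, e, s, normalized=normalized, defined=True)


@dataclass(frozen=True)
class TrophicPolicy:
    """Precedence rule turning the three assay outcomes into one mode.

    Pathogen beats saprophyte beats endophyte.  This reconstruction is
    intentionally isolated so alternative rules can be swapped in.
    """

    pathogen_seedling_classes: frozenset = frozenset({PathClass.PATHOGEN, PathClass.STRONG_PATHOGEN})
    pathogen_mature_classes: frozenset = frozenset({PathClass.STRONG_PATHOGEN})

    def classify(
        self,
        seedling_class: PathClass | None,
        mature_class: PathClass | None,
        saprophyte_outcome: SaprophyteOutcome | None,
        isolated_from_living_tissue: bool = True,
    ) -> str:
        if seedling_class is None or mature_class is None or saprophyte_outcome is None:
            logger.warning("missing assay outcome; isolate left Unclassified")
            return "Unclassified"
        if (
            seedling_class in self.pathogen_seedling_classes
            or mature_class in self.pathogen_mature_classes
        ):
            return "Pathogen"
        if saprophyte_outcome is SaprophyteOutcome.SPORULATING:
            return "Saprophyte"
        if saprophyte_outcome is SaprophyteOutcome.STERILE_HYPHAE_ONLY:
            return "Endophyte"
        if saprophyte_outcome is SaprophyteOutcome.NO_GROWTH and isolated_from_living_tissue:
            return "Endophyte"
        return "Unclassified"


DEFAULT_POLICY = TrophicPolicy()


def experimental_trophic_class(
    seedling_class: PathClass | None,
    mature_class: PathClass | None,
    saprophyte_outcome: SaprophyteOutcome | str | None,
    isolated_from_living_tissue: bool = True,
    policy: TrophicPolicy = DEFAULT_POLICY,
) -> str:
    """Experimentally supported trophic mode for one isolate."""
    if isinstance(saprophyte_outcome, str):
        saprophyte_outcome = SaprophyteOutcome(saprophyte_outcome)
    return policy.classify(seedling_class, mature_class, saprophyte_outcome,
                           isolated_from_living_tissue)


@dataclass(frozen=True)
class SaprophyteSummary:
    sporulating: int
    sterile_hyphae_only: int
    no_growth: int
    completing_numerator: int
    completing_denominator: int

    @property
    def completing_fraction(self) -> float:
        return float(Fraction(self.completing_numerator, self.completing_denominator))


def saprophyte_summary(outcomes: Iterable[tuple[str, SaprophyteOutcome | str]]) -> SaprophyteSummary:
    """Tally saprophyte-assay outcomes across isolates.

    The life-cycle-completion share is kept as an explicit numerator /
    denominator (sporulating / total) because the appropriate denominator is
    a judgment call best left visible.
    """
    seen: set[str] = set()
    tally: Counter = Counter()
    total = 0
    for isolate_id, outcome in outcomes:
        if isolate_id in seen:
            raise ValueError(f"duplicate isolate id: {isolate_id!r}")
        seen.add(isolate_id)
        if isinstance(outcome, str):
            outcome = SaprophyteOutcome(outcome)
        tally[outcome] += 1
        total += 1
    if total == 0:
        raise ValueError("no saprophyte outcomes provided")
    return SaprophyteSummary(
        sporulating=tally[SaprophyteOutcome.SPORULATING],
        sterile_hyphae_only=tally[SaprophyteOutcome.STERILE_HYPHAE_ONLY],
        no_growth=tally[SaprophyteOutcome.NO_GROWTH],
        completing_numerator=tally[SaprophyteOutcome.SPORULATING],
        completing_denominator=total,
    )
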