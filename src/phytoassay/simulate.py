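"""Synthetic data generators with the statistical structure the pipeline assumes.

Every generator takes an explicit seed, returns both the observable tables
(in the exact schemas the scoring / literature modules consume) and a truth
record, and is byte-deterministic: the same config and seed always produce
identical output.  Defaults echo the familiar marginals of the motivating
assay (162 isolates split 2 strong / 20 weak / 140 nonpathogenic) purely as
a fixture, not as a reconstruction of any real dataset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .literature_db import MicrobeReport, write_report_table

__all__ = [
    "SeedlingSimConfig",
    "MatureSimConfig",
    "LiteratureSimConfig",
    "simulate_seedling_assay",
    "simulate_mature_assay",
    "simulate_literature",
    "simulate_communities",
    "write_preset",
]

_CLASS_NAMES = ("strong", "weak", "nonpathogen")


def _class_counts(mixture: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment so class counts are deterministic."""
    mixture = [float(m) for m in mixture]
    if abs(sum(mixture) - 1.0) > 1e-9:
        raise ValueError("mixture proportions must sum to 1")
    raw = [m * n for m in mixture]
    counts = [math.floor(r) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


@dataclass(frozen=True)
class SeedlingSimConfig:
    """Linear-in-time disease progression with ordered leaf categories."""

    n_isolates: int = 162
    mixture: tuple[float, float, float] = (2 / 162, 20 / 162, 140 / 162)  # strong, weak, non
    # Ranges keep each class away from its decision boundary by more than the
    # worst-case leaf-count discretization error, so noiseless runs classify
    # exactly.  The saturation of DI at 4 biases recovered strong slopes low;
    # the 0.45 floor absorbs that.
    slope_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "strong": (0.45, 0.80),
            "weak": (0.015, 0.18),
            "nonpathogen": (0.0, 0.003),
        }
    )
    observation_days: tuple[float, ...] = (2, 4, 6, 8, 10)
    n_replicates: int = 3
    initial_leaves: int = 4
    leaf_growth: float = 0.4  # leaves/day
    noise: bool = True
    lineage: str = "australis"
    scale_max: float = 4.0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        for name, (lo, hi) in self.slope_ranges.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid slope range for {name!r}: ({lo}, {hi})")
        if self.n_isolates < 1 or self.n_replicates < 1:
            raise ValueError("need at least one isolate and one replicate")


def _leaf_split(total: int, di: float, rng: np.random.Generator, noise: bool) -> list[int]:
    """Spread ``total`` leaves over the two categories adjacent to ``di``.

    The resulting weighted index has expectation ``di`` exactly; binomial
    spread when ``noise`` is on, half-up rounding otherwise.
    """
    counts = [0, 0, 0, 0, 0]
    lo = min(int(math.floor(di)), 4)
    frac = di - lo
    if lo >= 4:
        counts[4] = total
        return counts
    if noise:
        n_hi = int(rng.binomial(total, frac))
    else:
        n_hi = int(round_half_up(total * frac))
    counts[lo] = total - n_hi
    counts[lo + 1] = n_hi
    return counts


def simulate_seedling_assay(
    config: SeedlingSimConfig = SeedlingSimConfig(), seed: int | None = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a seedling observation table plus its ground truth.

    Latent index ``DI(t) = clip(slope * t, 0, 4)``; death (DI = 4) is
    absorbing, with leaf production frozen from the first dead observation.
    Returns ``(observations, truth)`` where observations carry the scoring
    schema columns and truth has one row per isolate x replicate with the
    true slope and mixture class.
    """
    rng = np.random.default_rng(seed)
    counts = _class_counts(config.mixture, config.n_isolates)
    classes = [name for name, k in zip(_CLASS_NAMES, counts) for _ in range(k)]

    obs_rows, truth_rows = [], []
    for idx, cls in enumerate(classes):
        isolate = f"ISO{idx:04d}"
        lo, hi = config.slope_ranges[cls]
        for rep in range(1, config.n_replicates + 1):
            slope = float(rng.uniform(lo, hi))
            frozen_total: int | None = None
            for day in config.observation_days:
                di = min(config.scale_max, slope * day)
                total = max(1, int(round_half_up(config.initial_leaves + config.leaf_growth * day)))
                if di >= config.scale_max:
                    if frozen_total is None:
                        frozen_total = total
                    total = frozen_total
                n = _leaf_split(total, di, rng, config.noise)
                obs_rows.append(
                    {
                        "isolate_id": isolate,
                        "lineage": config.lineage,
                        "replicate": rep,
                        "day": day,
                        "n0": n[0], "n1": n[1], "n2": n[2], "n3": n[3], "n4": n[4],
                    }
                )
            truth_rows.append(
                {
                    "isolate_id": isolate,
                    "lineage": config.lineage,
                    "replicate": rep,
                    "true_slope": slope,
                    "true_standardized": 10.0 * slope,
                    "true_class": cls,
                }
            )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class MatureSimConfig:
    """Mature-leaf section scores in {0, 0.5, 1} with class structure."""

    n_isolates: int = 162
    mixture: tuple[float, float, float] = (2 / 162, 20 / 162, 140 / 162)
    section_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "strong": (0.05, 0.25, 0.70),
            "weak": (0.35, 0.45, 0.20),
            "nonpathogen": (0.90, 0.08, 0.02),
        }
    )
    n_sections_range: tuple[int, int] = (3, 7)
    lesion_inducer_count: int | None = None
    inducer_probs: tuple[float, float, float] = (0.30, 0.50, 0.20)
    min_lesion_mean: float = 0.1
    lineage: str = "australis"
    abraded: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")


_SECTION_SCORES = np.array([0.0, 0.5, 1.0])


def _draw_sections(probs, n: int, rng: np.random.Generator) -> np.ndarray:
    return _SECTION_SCORES[rng.choice(3, size=n, p=np.asarray(probs, dtype=float))]


def simulate_mature_assay(
    config: MatureSimConfig = MatureSimConfig(), seed: int | None = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a mature-leaf section table plus truth.

    With ``lesion_inducer_count`` set, exactly that many isolates are
    lesion-capable: their section draws are rejection-sampled until the
    replicate mean reaches ``min_lesion_mean``, and all other isolates score
    zero everywhere.  Otherwise sections follow the per-class multinomial.
    """
    rng = np.random.default_rng(seed)
    counts = _class_counts(config.mixture, config.n_isolates)
    classes = [name for name, k in zip(_CLASS_NAMES, counts) for _ in range(k)]

    capable = [True] * config.n_isolates
    if config.lesion_inducer_count is not None:
        if not 0 <= config.lesion_inducer_count <= config.n_isolates:
            raise ValueError("lesion_inducer_count outside [0, n_isolates]")
        capable = [False] * config.n_isolates
        for i in rng.choice(config.n_isolates, size=config.lesion_inducer_count, replace=False):
            capable[i] = True

    lo, hi = config.n_sections_range
    section_rows, truth_rows = [], []
    for idx, cls in enumerate(classes):
        isolate = f"ISO{idx:04d}"
        n_sections = int(rng.integers(lo, hi + 1))
        if config.lesion_inducer_count is None:
            scores = _draw_sections(config.section_probs[cls], n_sections, rng)
        elif capable[idx]:
            scores = _draw_sections(config.inducer_probs, n_sections, rng)
            while scores.mean() < config.min_lesion_mean:
                scores = _draw_sections(config.inducer_probs, n_sections, rng)
        else:
            scores = np.zeros(n_sections)
        for score in scores:
            section_rows.append(
                {
                    "isolate_id": isolate,
                    "lineage": config.lineage,
                    "abraded": int(config.abraded),
                    "section_score": score,
                }
            )
        probs = np.asarray(
            config.inducer_probs if (config.lesion_inducer_count is not None and capable[idx])
            else config.section_probs[cls],
            dtype=float,
        )
        truth_rows.append(
            {
                "isolate_id": isolate,
                "lineage": config.lineage,
                "true_class": cls,
                "lesion_capable": capable[idx],
                "n_sections": n_sections,
                "expected_mean": float(_SECTION_SCORES @ probs) if capable[idx] else 0.0,
            }
        )
    return pd.DataFrame(section_rows), pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class LiteratureSimConfig:
    """Literature report tables with continent / lineage / tissue structure."""

    continents: tuple[str, ...] = ("Europe", "North America", "Asia")
    n_unique_taxa_per_continent: int = 30
    n_shared_taxa: int = 10
    shared_fraction: float | None = None  # alternative spec; must be <= 1
    n_studies_per_continent: int = 6
    culture_dependent_fraction: float = 0.85
    isolates_per_study_range: tuple[int, int] = (5, 30)
    tissues: tuple[str, ...] = ("leaf", "stem", "root", "rhizosphere soil")
    group: str = "fungus"
    species_level_fraction: float = 1.0
    year_range: tuple[int, int] = (1950, 2018)
    countries: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "Europe": ("Germany", "France", "Poland", "Netherlands", "Denmark"),
            "North America": ("United States", "Canada"),
            "Asia": ("China", "Japan"),
            "Africa": ("South Africa",),
            "Australia": ("Australia",),
        }
    )

    def __post_init__(self) -> None:
        if self.shared_fraction is not None and self.shared_fraction > 1:
            raise ValueError("shared fraction cannot exceed 1")
        if self.n_shared_taxa < 0 or self.n_unique_taxa_per_continent < 0:
            raise ValueError("taxon pool sizes must be non-negative")


def _resolved_shared_count(config: LiteratureSimConfig) -> int:
    if config.shared_fraction is None:
        return config.n_shared_taxa
    pool = config.n_unique_taxa_per_continent + config.n_shared_taxa
    return int(round_half_up(config.shared_fraction * pool))


def simulate_literature(
    config: LiteratureSimConfig = LiteratureSimConfig(), seed: int | None = 0
) -> tuple[list[MicrobeReport], dict]:
    """Simulate a literature report table plus truth.

    Continental taxon pools share exactly the configured number of taxa
    (guaranteed present on every continent, so the analyzer's
    two-or-more-continents count recovers the configuration exactly);
    continent-unique taxa never cross continents.  Each study samples one
    tissue and a random number of isolates.
    """
    rng = np.random.default_rng(seed)
    n_shared = _resolved_shared_count(config)
    shared_pool = [f"Sharedgenus species{i:03d}" for i in range(n_shared)]
    unique_pools = {
        cont: [f"{cont.split()[0]}genus species{i:03d}" for i in range(config.n_unique_taxa_per_continent)]
        for cont in config.continents
    }

    reports: list[MicrobeReport] = []
    report_no = 0
    truth_communities = []
    for cont in config.continents:
        pool = shared_pool + unique_pools[cont]
        # queue shared taxa first so every one is reported on this continent
        pending_shared = list(shared_pool)
        countries = config.countries.get(cont, ("",))
        for s in range(config.n_studies_per_continent):
            study_id = f"{cont.replace(' ', '')}_study{s:02d}"
            culture_dep = bool(rng.random() < config.culture_dependent_fraction)
            tissue = str(rng.choice(config.tissues))
            n_isolates = int(rng.integers(*config.isolates_per_study_range))
            country = str(rng.choice(countries))
            year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
            taxa = []
            for _ in range(n_isolates):
                if pending_shared:
                    taxa.append(pending_shared.pop())
                else:
                    taxa.append(str(rng.choice(pool)))
            for taxon in taxa:
                report_no += 1
                species_level = bool(rng.random() < config.species_level_fraction)
                reports.append(
                    MicrobeReport(
                        report_id=f"R{report_no:06d}",
                        taxon_name=taxon if species_level else taxon.split(" ")[0] + " sp.",
                        taxonomic_rank="species" if species_level else "genus",
                        group=config.group,
                        study_id=study_id,
                        continent=cont,
                        country=country,
                        culture_dependent=culture_dep,
                        collection_year=year,
                        tissue=tissue,
                        tissue_alive=True,
                    )
                )
            truth_communities.append(
                {
                    "study_id": study_id,
                    "continent": cont,
                    "tissue": tissue,
                    "group": config.group,
                    "culture_dependent": culture_dep,
                    "n_isolates": n_isolates,
                }
            )
        if pending_shared:
            raise ValueError(
                f"continent {cont!r} drew too few isolates to host all "
                f"{n_shared} shared taxa; increase studies or isolates per study"
            )

    continent_taxa = {
        cont: sorted(
            {r.taxon_name for r in reports if r.continent == cont and r.taxonomic_rank == "species"}
        )
        for cont in config.continents
    }
    truth = {
        "n_shared_configured": n_shared,
        "shared_taxa": sorted(shared_pool),
        "continent_taxa": continent_taxa,
        "communities": truth_communities,
        "n_communities_min10": sum(
            1 for c in truth_communities if c["culture_dependent"] and c["n_isolates"] >= 10
        ),
    }
    return reports, truth


def simulate_communities(
    n_per_group: Sequence[int] = (8, 8),
    n_taxa: int = 30,
    effect_size: float = 0.0,
    n_affected: int = 10,
    seed: int | None = 0,
) -> tuple[np.ndarray, list[str]]:
    """Abundance matrices for two or more groups with an optional group effect.

    Baseline abundances are lognormal; in every group after the first, the
    first ``n_affected`` taxa have their abundances scaled by
    ``exp(effect_size)``.  ``effect_size=0`` is an exact null.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for g, n in enumerate(n_per_group):
        for _ in range(n):
            abundance = rng.lognormal(mean=1.0, sigma=0.6, size=n_taxa)
            if g > 0 and effect_size != 0.0:
                abundance[:n_affected] *= math.exp(effect_size)
            rows.append(abundance)
            labels.append(f"g{g}")
    return np.vstack(rows), labels


def write_preset(preset: str, seed: int, out_dir) -> dict:
    """Materialize a named preset to ``out_dir`` (CSV/TSV + truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if preset == "seedling":
        obs, truth = simulate_seedling_assay(SeedlingSimConfig(), seed=seed)
        obs.to_csv(out / "seedling_observations.csv", index=False)
        truth.to_csv(out / "seedling_truth.csv", index=False)
        summary = {"preset": preset, "seed": seed, "n_isolates": int(truth["isolate_id"].nunique())}
    elif preset == "mature":
        sections, truth = simulate_mature_assay(MatureSimConfig(), seed=seed)
        sections.to_csv(out / "mature_sections.csv", index=False)
        truth.to_csv(out / "mature_truth.csv", index=False)
        summary = {"preset": preset, "seed": seed, "n_isolates": int(truth["isolate_id"].nunique())}
    elif preset == "literature":
        reports, truth = simulate_literature(LiteratureSimConfig(), seed=seed)
        write_report_table(reports, out / "literature_reports.tsv")
        summary = {"preset": preset, "seed": seed, **{k: truth[k] for k in ("n_shared_configured", "n_communities_min10")}}
        (out / "literature_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    else:
        raise ValueError(f"unknown preset: {preset!r}")
    (out / "truth_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
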