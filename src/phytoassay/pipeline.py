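"""End-to-end orchestration: score, classify, summarize, meta-analyze.

Stages run in a fixed order with stage-labeled error reporting; the summary
is a JSON document validated against the schema shipped with the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import percent, round_half_up
from .assay_scoring import (
    ClassificationThresholds,
    DEFAULT_THRESHOLDS,
    PathClass,
    classify_seedling,
    score_mature_table,
    score_seedling_table,
)
from .comparative_stats import bonferroni, bray_curtis_matrix, paired_t_test, permanova
from .literature_db import (
    community_table,
    filter_communities,
    read_report_table,
    species_level_subset,
    taxon_key,
    taxon_overlap,
)
from .trophic import (
    experimental_trophic_class,
    load_guild_table,
    assign_guild,
    saprophyte_summary,
    trophic_ratio,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_full_pipeline", "validate_summary"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name in the message."""


@dataclass
class RunConfig:
    """Inputs and settings for a full pipeline run."""

    out_dir: str
    seedling_table: str | None = None
    mature_table: str | None = None
    saprophyte_table: str | None = None
    report_table: str | None = None
    guild_table: str | None = None
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    min_isolates: int = 10
    permanova_factor: str = "continent"
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int | None = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = ClassificationThresholds.from_dict(data.pop("thresholds", {}))
        data.update(overrides)
        return cls(thresholds=thresholds, **data)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("seedling")
def _run_seedling(config: RunConfig, out: Path) -> dict:
    scored = score_seedling_table(config.seedling_table, config.thresholds)
    scored.to_csv(out / "seedling_scored.tsv", sep="\t", index=False)
    counts = scored["class"].value_counts().to_dict()
    n_path = int(
        sum(
            1
            for di in scored["standardized_di"]
            if classify_seedling(di, config.thresholds)
            in (PathClass.PATHOGEN, PathClass.STRONG_PATHOGEN)
        )
    )
    return {
        "n_isolates": int(scored["isolate_id"].nunique()),
        "class_counts": counts,
        "n_pathogenic": n_path,
        "scored_table": "seedling_scored.tsv",
    }


@_stage("mature")
def _run_mature(config: RunConfig, out: Path) -> dict:
    scored = score_mature_table(config.mature_table, config.thresholds)
    scored.to_csv(out / "mature_scored.tsv", sep="\t", index=False)
    inducers = int((scored["mean_lesion_score"] >= config.thresholds.minor_lesion_min).sum())
    return {
        "n_isolates": int(scored["isolate_id"].nunique()),
        "class_counts": scored["class"].value_counts().to_dict(),
        "n_lesion_inducers": inducers,
        "pct_lesion_inducers": percent(inducers, len(scored)) if len(scored) else 0,
        "scored_table": "mature_scored.tsv",
    }


@_stage("lineage_comparison")
def _run_lineage_comparison(config: RunConfig, out: Path) -> dict:
    """Paired per-isolate comparison between the two host lineages."""
    scored = score_seedling_table(config.seedling_table, config.thresholds)
    wide = scored.pivot_table(index="isolate_id", columns="lineage", values="standardized_di")
    lineages = list(wide.columns)
    if len(lineages) < 2:
        return {"note": "fewer than two lineages scored; comparison skipped"}
    a, b = lineages[:2]
    paired = wide.dropna(subset=[a, b])
    result = paired_t_test(paired[a].to_numpy(), paired[b].to_numpy())
    adjusted, flags = bonferroni([result.p], alpha=config.alpha)
    return {
        "lineages": [a, b],
        "n_pairs": int(len(paired)),
        "t": result.t,
        "df": result.df,
        "p": result.p,
        "p_bonferroni": adjusted[0],
        "significant": bool(flags[0]),
    }


@_stage("literature")
def _run_literature(config: RunConfig, out: Path) -> dict:
    reports = read_report_table(config.report_table)
    kept, pct = species_level_subset(reports)
    samples = filter_communities(kept, min_isolates=config.min_isolates)
    table = community_table(samples)
    table.to_csv(out / "community_table.tsv", sep="\t")

    by_continent: dict[str, set] = {}
    for r in kept:
        by_continent.setdefault(r.continent, set()).add(taxon_key(r))
    overlap = taxon_overlap(by_continent) if len(by_continent) >= 2 else None

    result: dict = {
        "n_reports": len(reports),
        "n_species_level": len(kept),
        "pct_species_level": pct,
        "n_communities": len(samples),
        "community_table": "community_table.tsv",
    }
    if overlap is not None:
        result["overlap"] = {
            "set_sizes": overlap.set_sizes,
            "region_counts": overlap.region_counts,
            "shared_two_or_more": overlap.shared_two_or_more,
            "union_size": overlap.union_size,
        }

    factor_values = [getattr(s, config.permanova_factor, s.continent) for s in samples]
    groups = [str(v) for v in factor_values]
    if len(samples) >= 3 and len(set(groups)) >= 2 and len(samples) - len(set(groups)) >= 1:
        dist = bray_curtis_matrix(table.to_numpy())
        res = permanova(dist, groups, n_permutations=config.n_permutations, seed=config.seed)
        result["permanova"] = {
            "factor": config.permanova_factor,
            "pseudo_F": res.pseudo_F,
            "r_squared": res.r_squared,
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
            "seed": res.seed,
        }
    else:
        result["permanova"] = {"note": "not enough communities or groups"}
    return result


@_stage("trophic")
def _run_trophic(config: RunConfig, out: Path) -> dict:
    result: dict = {}
    if config.guild_table and config.report_table:
        guilds = load_guild_table(config.guild_table)
        reports = read_report_table(config.report_table)
        kept, _ = species_level_subset(reports)
        taxa = sorted({r.taxon_name for r in kept if r.group in ("fungus", "oomycete")})
        modes = {t: assign_guild(t, guilds) for t in taxa}
        counts = {
            "Pathogen": sum(1 for m in modes.values() if "Pathotroph" in m),
            "Endophyte": sum(1 for m in modes.values() if "Symbiotroph" in m),
            "Saprophyte": sum(1 for m in modes.values() if "Saprotroph" in m),
        }
        ratio = trophic_ratio((counts["Pathogen"], counts["Endophyte"], counts["Saprophyte"]))
        result["predicted"] = {
            "n_taxa": len(taxa),
            "n_assigned": sum(1 for m in modes.values() if m != "unassigned"),
            "counts": counts,
            "ratio": list(ratio.normalized) if ratio.defined else None,
        }
    if config.saprophyte_table:
        sap = pd.read_csv(config.saprophyte_table, sep=None, engine="python")
        summary = saprophyte_summary(list(zip(sap["isolate_id"], sap["outcome"])))
        result["saprophyte_assay"] = {
            "sporulating": summary.sporulating,
            "sterile_hyphae_only": summary.sterile_hyphae_only,
            "no_growth": summary.no_growth,
            "completing_fraction": summary.completing_fraction,
            "completing": f"{summary.completing_numerator}/{summary.completing_denominator}",
        }
    if config.saprophyte_table and config.seedling_table and config.mature_table:
        seed_scored = score_seedling_table(config.seedling_table, config.thresholds)
        mat_scored = score_mature_table(config.mature_table, config.thresholds)
        sap = pd.read_csv(config.saprophyte_table, sep=None, engine="python")
        merged = (
            seed_scored.groupby("isolate_id").first()[["class"]]
            .rename(columns={"class": "seedling_class"})
            .join(
                mat_scored.groupby("isolate_id").first()[["class"]].rename(
                    columns={"class": "mature_class"}
                ),
                how="outer",
            )
            .join(sap.set_index("isolate_id")[["outcome"]], how="outer")
        )
        classes = {
            isolate: experimental_trophic_class(
                PathClass.from_label(row.seedling_class) if isinstance(row.seedling_class, str) else None,
                PathClass.from_label(row.mature_class) if isinstance(row.mature_class, str) else None,
                row.outcome if isinstance(row.outcome, str) else None,
            )
            for isolate, row in merged.iterrows()
        }
        tallies = pd.Series(classes).value_counts().to_dict()
        ratio = trophic_ratio(
            (tallies.get("Pathogen", 0), tallies.get("Endophyte", 0), tallies.get("Saprophyte", 0))
        )
        result["experimental"] = {
            "class_counts": tallies,
            "ratio": list(ratio.normalized) if ratio.defined else None,
            "ratio_defined": ratio.defined,
        }
    return result


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write the validated JSON summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "versions": {"phytoassay": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "thresholds": asdict(config.thresholds),
        "stages": {},
    }
    if config.seedling_table:
        summary["stages"]["seedling"] = _run_seedling(config, out)
        summary["stages"]["lineage_comparison"] = _run_lineage_comparison(config, out)
    if config.mature_table:
        summary["stages"]["mature"] = _run_mature(config, out)
    if config.report_table:
        summary["stages"]["literature"] = _run_literature(config, out)
    if config.guild_table or config.saprophyte_table:
        summary["stages"]["trophic"] = _run_trophic(config, out)

    validate_summary(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text(
        "\n".join(
            [
                f"phytoassay {__version__}",
                f"seed: {config.seed}",
                f"thresholds: {asdict(config.thresholds)}",
                f"stages: {sorted(summary['stages'])}",
            ]
        )
        + "\n"
    )
    return summary


# ---------------------------------------------------------------------------
# schema validation (minimal, dependency-free)


def _load_schema() -> dict:
    text = resources.files("phytoassay").joinpath("schemas/summary_schema.json").read_text()
    return json.loads(text)


_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def _check(instance, schema: dict, path: str) -> None:
    stated = schema.get("type")
    if stated is not None:
        types = stated if isinstance(stated, list) else [stated]
        expected = tuple(
            t for name in types for t in (
                _TYPE_MAP[name] if isinstance(_TYPE_MAP[name], tuple) else (_TYPE_MAP[name],)
            )
        )
        if not isinstance(instance, expected) or (
            isinstance(instance, bool) and "boolean" not in types
        ):
            raise ValueError(f"summary{path}: expected {stated}, got {type(instance).__name__}")
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                raise ValueError(f"summary{path}: missing required key {key!r}")
        for key, subschema in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], subschema, f"{path}.{key}")


def validate_summary(summary: dict) -> None:
    """Validate a summary document against the bundled JSON schema."""
    _check(summary, _load_schema(), "")
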