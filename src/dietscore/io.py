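"""Consumption-table I/O and the full comparison pipeline.

A consumption table is a plain delimited file with one row per
(country, gender stratum, food category): columns ``country``,
``gender`` (total/female/male), ``category``, ``mean_g_day``, and
optionally ``survey_id``, ``category_level`` and ``n_subjects``. Both
decimal-point and decimal-comma dialects are accepted, and a column map
can rename arbitrary export headers onto the canonical ones.

:func:`run_full_mapping` ties the stages together: crosswalk mapping ->
scoring under all three indices -> min-max normalization and summaries
-> the five cluster analyses (WISH 2.0 component points and EAT-Lancet
component points for the total population and stratified by gender,
plus raw g/day intakes), each with Gower distances, generalized Ward
agglomeration, a silhouette report and — when a region map is supplied —
a cluster x region concordance. Everything is deterministic given the
inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cluster import (
    ClusterTree,
    ConcordanceReport,
    FeatureTable,
    SilhouetteReport,
    choose_k,
    cut_dendrogram,
    gower_matrix,
    region_concordance,
    silhouette,
    ward_agglomerate,
)
from .errors import SchemaError
from .mapping import Crosswalk, apply_crosswalk, default_crosswalk, load_crosswalk_config
from .model import Gender, IntakeProfile, PopulationId, builtin_index, canonical_index_name
from .normalize import NormalizedScore, ScoreSummary, min_max_normalize, summarize_scores
from .scoring import IndexScore, compute_index_score

__all__ = [
    "REQUIRED_COLUMNS",
    "ConsumptionTable",
    "read_consumption_table",
    "write_consumption_table",
    "consumption_table_from_profiles",
    "RunConfig",
    "ClusterAnalysis",
    "ResultBundle",
    "run_full_mapping",
]

log = logging.getLogger("dietscore")

REQUIRED_COLUMNS = ("country", "gender", "category", "mean_g_day")
OPTIONAL_COLUMNS = ("survey_id", "category_level", "n_subjects")


@dataclass(frozen=True)
class ConsumptionTable:
    """Validated long-format country x gender x category intake table."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.reset_index(drop=True).copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        bad_gender = sorted(set(df["gender"]) - {g.value for g in Gender})
        if bad_gender:
            raise SchemaError(f"unknown gender stratum value(s): {bad_gender}")
        intakes = pd.to_numeric(df["mean_g_day"], errors="coerce")
        invalid = df.index[intakes.isna() | ~np.isfinite(intakes)]
        if len(invalid):
            raise SchemaError(f"non-numeric mean_g_day at row {invalid[0] + 1}")
        negative = df.index[intakes < 0]
        if len(negative):
            raise SchemaError(f"negative mean_g_day at row {negative[0] + 1}")
        df["mean_g_day"] = intakes.astype(float)
        keys = df[["country", "gender", "category"]]
        if keys.duplicated().any():
            dupe = keys[keys.duplicated()].iloc[0]
            raise SchemaError(
                f"duplicate (country, gender, category) key: "
                f"({dupe['country']}, {dupe['gender']}, {dupe['category']})"
            )
        object.__setattr__(self, "data", df)

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["country"].unique()))

    def strata(self) -> tuple[PopulationId, ...]:
        pairs = self.data[["country", "gender"]].drop_duplicates().itertuples(index=False)
        return tuple(sorted(PopulationId(c, Gender(g)) for c, g in pairs))

    def raw_intakes(self, stratum: PopulationId) -> dict[str, float]:
        sel = self.data[
            (self.data["country"] == stratum.country)
            & (self.data["gender"] == stratum.gender.value)
        ]
        return dict(zip(sel["category"], sel["mean_g_day"]))


def read_consumption_table(
    path: Union[str, Path, IO[str]],
    sep: str = "\t",
    decimal: str = ".",
    column_map: Mapping[str, str] | None = None,
) -> ConsumptionTable:
    """Read and schema-validate a delimited consumption table.

    ``decimal=","`` accepts decimal-comma exports; ``column_map``
    renames export-specific headers onto the canonical column names.
    """
    df = pd.read_csv(path, sep=sep, decimal=decimal, dtype={"country": str, "category": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    return ConsumptionTable(df)


def write_consumption_table(table: ConsumptionTable, path: Union[str, Path], sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index=False)


def consumption_table_from_profiles(profiles: Sequence[IntakeProfile], survey_id: str = "synthetic") -> ConsumptionTable:
    """Assemble a long-format table from raw-category intake profiles."""
    rows = [
        {
            "country": p.population_id.country,
            "survey_id": survey_id,
            "gender": p.population_id.gender.value,
            "category": category,
            "mean_g_day": grams,
        }
        for p in profiles
        for category, grams in sorted(p.intakes.items())
    ]
    return ConsumptionTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# pipeline

@dataclass(frozen=True)
class RunConfig:
    """Options for :func:`run_full_mapping`.

    ``k`` is either ``"auto"`` (silhouette-maximizing cut over
    2..n-1) or a fixed cluster count applied to every analysis.
    """

    indices: tuple[str, ...] = ("WISH", "WISH2.0", "EAT-Lancet")
    crosswalk_path: str | None = None
    k: Union[int, str] = "auto"
    region_map: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "indices", tuple(canonical_index_name(n) for n in self.indices)
        )
        if self.k != "auto":
            object.__setattr__(self, "k", int(self.k))
        if self.crosswalk_path is not None and not Path(self.crosswalk_path).exists():
            raise SchemaError(f"crosswalk file not found: {self.crosswalk_path}")

    def crosswalk(self, index_name: str) -> Crosswalk:
        if self.crosswalk_path is None:
            return default_crosswalk(index_name)
        with open(self.crosswalk_path) as fh:
            cfg = load_crosswalk_config(fh)
        return cfg["crosswalks"][canonical_index_name(index_name)]

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "indices": self.indices,
                "crosswalk_path": self.crosswalk_path,
                "k": self.k,
                "region_map": dict(self.region_map) if self.region_map else None,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ClusterAnalysis:
    """One of the five cluster analyses, with all diagnostics."""

    name: str
    feature_kind: str  # "points" | "grams"
    index_name: str | None
    by_gender: bool
    units: tuple[str, ...]
    features: pd.DataFrame
    tree: ClusterTree
    k: int
    labels: np.ndarray
    silhouette: SilhouetteReport
    silhouette_by_k: Mapping[int, float]
    concordance: ConcordanceReport | None = None


@dataclass(frozen=True)
class ResultBundle:
    """Scores, summaries and cluster analyses for one pipeline run."""

    scores: Mapping[str, tuple[IndexScore, ...]]  # index name -> scores per stratum
    normalized: Mapping[str, tuple[NormalizedScore, ...]]
    summaries: Mapping[str, ScoreSummary]  # over country totals
    analyses: tuple[ClusterAnalysis, ...]
    notices: tuple[str, ...]
    provenance: Mapping[str, str]

    def score_table(self) -> pd.DataFrame:
        rows = []
        for index_name, scores in self.scores.items():
            for s in scores:
                for c in s.components:
                    rows.append(
                        {
                            "country": s.population_id.country,
                            "gender": s.population_id.gender.value,
                            "index": index_name,
                            "component": c.component_id,
                            "points": c.points,
                            "total": s.total,
                        }
                    )
        return pd.DataFrame(rows)

    def write(self, outdir: Union[str, Path]) -> None:
        """Write delimited score/summary/cluster artifacts to ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.score_table().to_csv(out / "scores.tsv", sep="\t", index=False)
        summary = {
            "provenance": dict(self.provenance),
            "notices": list(self.notices),
            "summaries": {
                name: {"n": s.n, "mean": round(s.mean, 4), "sd": round(s.sd, 4)}
                for name, s in self.summaries.items()
            },
            "analyses": {
                a.name: {
                    "k": a.k,
                    "overall_silhouette": round(a.silhouette.overall, 4),
                    "ari": None if a.concordance is None else round(a.concordance.ari, 4),
                }
                for a in self.analyses
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        for a in self.analyses:
            a.silhouette.to_frame().to_csv(out / f"silhouette_{a.name}.tsv", sep="\t")
            pd.DataFrame(
                a.tree.merges, columns=["cluster_a", "cluster_b", "height", "size"]
            ).to_csv(out / f"linkage_{a.name}.tsv", sep="\t", index=False)
            (out / f"dendrogram_{a.name}.newick").write_text(a.tree.to_newick() + "\n")


def _score_all(
    table: ConsumptionTable, config: RunConfig
) -> dict[str, dict[PopulationId, IndexScore]]:
    scored: dict[str, dict[PopulationId, IndexScore]] = {}
    for index_name in config.indices:
        index = builtin_index(index_name)
        xw = config.crosswalk(index_name)
        per_stratum: dict[PopulationId, IndexScore] = {}
        for stratum in table.strata():
            raw = table.raw_intakes(stratum)
            profile, unmapped = apply_crosswalk(raw, xw, index, stratum, strict=False)
            if unmapped:
                log.warning("%s/%s: unmapped categories %s", index_name, stratum, unmapped)
            per_stratum[stratum] = compute_index_score(profile, index)
        scored[index_name] = per_stratum
        log.info("scored %d strata under %s", len(per_stratum), index_name)
    return scored


def _points_features(
    scores: Mapping[PopulationId, IndexScore], genders: tuple[Gender, ...]
) -> pd.DataFrame:
    rows = {
        str(pid): score.points_by_component()
        for pid, score in sorted(scores.items())
        if pid.gender in genders
    }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def _grams_features(table: ConsumptionTable) -> pd.DataFrame:
    sel = table.data[table.data["gender"] == Gender.TOTAL.value]
    wide = sel.pivot(index="country", columns="category", values="mean_g_day")
    wide.index = [str(PopulationId(c)) for c in wide.index]
    return wide.sort_index()


def _analysis_region_map(
    units: Sequence[str], region_map: Mapping[str, str]
) -> dict[str, str]:
    # units are "country|gender" strings; regions are keyed by country
    return {u: region_map[u.split("|")[0]] for u in units if u.split("|")[0] in region_map}


def _cluster_one(
    name: str,
    features: pd.DataFrame,
    feature_kind: str,
    index_name: str | None,
    by_gender: bool,
    config: RunConfig,
) -> ClusterAnalysis:
    table = FeatureTable(data=features)
    D = gower_matrix(table)
    tree = ward_agglomerate(D)
    n = D.n
    if config.k == "auto":
        chosen = choose_k(tree, D, range(2, n))
        k, by_k = chosen.k, chosen.silhouette_by_k
    else:
        k = min(int(config.k), n)
        by_k = {k: np.nan}
    labels = cut_dendrogram(tree, k)
    sil = silhouette(D, labels)
    if config.k != "auto":
        by_k = {k: sil.overall}
    concordance = None
    if config.region_map:
        rmap = _analysis_region_map(D.ids, config.region_map)
        if set(rmap) == set(D.ids):
            concordance = region_concordance(D.ids, labels, rmap)
    return ClusterAnalysis(
        name=name,
        feature_kind=feature_kind,
        index_name=index_name,
        by_gender=by_gender,
        units=D.ids,
        features=features,
        tree=tree,
        k=k,
        labels=labels,
        silhouette=sil,
        silhouette_by_k=by_k,
        concordance=concordance,
    )


def run_full_mapping(config: RunConfig, table: ConsumptionTable) -> ResultBundle:
    """Execute mapping, scoring, normalization and the five cluster
    analyses on a consumption table.

    Clustering needs at least three strata (a 2..n-1 cut range);
    smaller inputs skip it with an explicit notice while scores and
    summaries are still produced where defined.
    """
    notices: list[str] = []
    scored = _score_all(table, config)

    normalized: dict[str, tuple[NormalizedScore, ...]] = {}
    summaries: dict[str, ScoreSummary] = {}
    for index_name, per_stratum in scored.items():
        index = builtin_index(index_name)
        norm = tuple(
            NormalizedScore(pid, index_name, min_max_normalize(s.total, index))
            for pid, s in sorted(per_stratum.items())
        )
        normalized[index_name] = norm
        totals_only = [v for v in norm if v.population_id.gender is Gender.TOTAL]
        if len(totals_only) >= 2:
            summaries[index_name] = summarize_scores(totals_only)
        else:
            notices.append(f"{index_name}: n<2 country totals, summary skipped")

    analyses: list[ClusterAnalysis] = []
    n_countries = len(table.countries)
    if n_countries < 3:
        notices.append(f"clustering skipped: n={n_countries} < 3 countries")
    else:
        plans = [
            ("wish2_points_total", "WISH2.0", (Gender.TOTAL,), False),
            ("eat_points_total", "EAT-Lancet", (Gender.TOTAL,), False),
            ("wish2_points_gender", "WISH2.0", (Gender.FEMALE, Gender.MALE), True),
            ("eat_points_gender", "EAT-Lancet", (Gender.FEMALE, Gender.MALE), True),
        ]
        for name, index_name, genders, by_gender in plans:
            if index_name not in scored:
                continue
            features = _points_features(scored[index_name], genders)
            if len(features) < 3:
                notices.append(f"{name}: fewer than 3 units, skipped")
                continue
            analyses.append(
                _cluster_one(name, features, "points", index_name, by_gender, config)
            )
        grams = _grams_features(table)
        if len(grams) >= 3:
            analyses.append(_cluster_one("grams_total", grams, "grams", None, False, config))
        else:
            notices.append("grams_total: fewer than 3 units, skipped")

    provenance = {"tool": "dietscore", "version": _version, "config_hash": config.config_hash()}
    return ResultBundle(
        scores={name: tuple(v for _, v in sorted(per.items())) for name, per in scored.items()},
        normalized=normalized,
        summaries=summaries,
        analyses=tuple(analyses),
        notices=tuple(notices),
        provenance=provenance,
    )
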