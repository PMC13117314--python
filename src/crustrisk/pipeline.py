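"""End-to-end orchestration: substitute -> summarize -> compare ->
associate -> risk, with a versioned run manifest.

Identical config + seed yields byte-identical artifacts; every stage
output is a CSV or JSON file under the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .core import (
    ConcentrationTable, CongenerCatalog, ConfigurationError,
    default_catalog, load_concentration_table, substitute_nondetects,
)
from .profiles import (
    class_composition, congener_means, congener_share,
    detection_frequency_table, summarize,
)
from .risk import (
    ExposureGroup, MCSConfig, default_groups, deterministic_assessment,
    load_exposure_groups, mcs_assessment,
)
from .simulate import GeneratorConfig, survey_calibrated_config, simulate_cohort
from .stats import cluster_congeners, holm_adjust, kruskal_wallis, spearman_matrix

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def make_survey_fixture() -> tuple[dict[str, float], CongenerCatalog,
                                  tuple[ExposureGroup, ...]]:
    """The published study substrate: 22 congener means, the catalog
    (with the 10 published RfDs), and the 3 age groups."""
    return dict(datasets.CONGENER_MEANS), default_catalog(), default_groups()


_DEFAULT_STRATA = {
    ("freshwater_shrimp", "Hangzhou", m, 2024): 16 for m in range(5, 10)
}
_DEFAULT_STRATA.update(
    {("marine_prawn", "Zhoushan", m, 2024): 14 for m in range(5, 10)})
_DEFAULT_STRATA.update(
    {("marine_crab", "Ningbo", m, 2024): 6 for m in range(5, 10)})


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Exactly one of ``input_path`` (a long-format concentration CSV) or
    ``generator`` (a synthetic-cohort config; None with
    use_generator=True means the survey-calibrated default) may be set.
    """

    input_path: str | None = None
    use_generator: bool = False
    generator: GeneratorConfig | None = None
    n_per_stratum: dict[tuple[str, str, int, int], int] = field(
        default_factory=lambda: dict(_DEFAULT_STRATA))
    catalog_path: str | None = None
    exposure_groups_path: str | None = None
    substitution_policy: str = "zero"
    compare_by: tuple[str, ...] = ("species", "region", "month")
    dominant_subset: tuple[str, ...] = ("TiBP", "TEP", "TCEP")
    cluster_k: int = 3
    cluster_linkage: str = "average"
    mcs: MCSConfig = field(default_factory=MCSConfig)
    out_dir: str = "crustrisk_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if bool(self.input_path) == bool(self.use_generator or self.generator):
            raise ConfigurationError(
                "exactly one of input_path / generator must be supplied")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mcs" in raw and isinstance(raw["mcs"], dict):
            raw["mcs"] = MCSConfig(**raw["mcs"])
        if "n_per_stratum" in raw:
            raw["n_per_stratum"] = {
                (d["species"], d["region"], int(d["month"]), int(d["year"])):
                int(d["n"]) for d in raw["n_per_stratum"]}
        for key in ("compare_by", "dominant_subset"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class RunReport:
    """Manifest of a pipeline run: inputs, config hash, outputs, warnings."""

    version: str
    config_hash: str
    seed: int
    n_samples: int
    outputs: dict[str, str]
    warnings: list[str]
    hi: dict[str, float]
    classification: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis chain and write all artifacts."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    warnings: list[str] = []

    catalog = (CongenerCatalog.from_csv(config.catalog_path)
               if config.catalog_path else default_catalog())
    groups = (load_exposure_groups(config.exposure_groups_path)
              if config.exposure_groups_path else default_groups())

    # --- input ---------------------------------------------------------
    if config.input_path:
        table = _stage("load")(load_concentration_table)(config.input_path, catalog)
    else:
        gen = config.generator or survey_calibrated_config(catalog, seed=config.seed)
        if config.generator is None:
            warnings.append("generator: using survey-calibrated default config")
        table = _stage("simulate")(simulate_cohort)(
            gen, config.n_per_stratum, catalog)
        path = out / "cohort.csv"
        from .core import write_concentration_table
        write_concentration_table(table, path)
        outputs["cohort"] = str(path)

    # --- substitute + summarize ---------------------------------------
    table = _stage("substitute")(substitute_nondetects)(
        table, config.substitution_policy)

    def _write_summary(stats_map, path):
        rows = []
        for key, s in stats_map.items():
            row = {"group": key if not isinstance(key, tuple) else "|".join(map(str, key))}
            row.update(dataclasses.asdict(s))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    summ = _stage("summarize")(summarize)
    _write_summary(summ(table, by=("congener",)), out / "congener_summary.csv")
    outputs["congener_summary"] = str(out / "congener_summary.csv")
    _write_summary(summ(table, by=("species",)), out / "species_summary.csv")
    outputs["species_summary"] = str(out / "species_summary.csv")

    shares = _stage("composition")(class_composition)(table)
    dominant = _stage("composition")(congener_share)(
        table, config.dominant_subset)
    det = _stage("detection")(detection_frequency_table)(table)
    det.to_csv(out / "detection_frequencies.csv")
    outputs["detection_frequencies"] = str(out / "detection_frequencies.csv")
    with open(out / "composition.json", "w") as fh:
        json.dump({"class_shares_percent": shares,
                   "dominant_subset": list(config.dominant_subset),
                   "dominant_share_percent": dominant}, fh, indent=2)
    outputs["composition"] = str(out / "composition.json")

    # --- compare -------------------------------------------------------
    sums = table.sum_opes()
    meta = table.sample_meta()
    comparisons = []
    for factor in config.compare_by:
        grouped = {str(level): sums[meta[factor] == level].tolist()
                   for level in sorted(meta[factor].unique())}
        grouped = {k: v for k, v in grouped.items() if v}
        if len(grouped) < 2:
            warnings.append(f"compare: factor {factor!r} has < 2 levels, skipped")
            continue
        res = _stage("compare")(kruskal_wallis)(grouped)
        comparisons.append({"factor": factor, "H": res.statistic,
                            "df": res.df, "p": res.p_value})
    if comparisons:
        pvals = [c["p"] for c in comparisons]
        for c, adj in zip(comparisons, holm_adjust(pvals)):
            c["p_holm"] = adj
    pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False)
    outputs["comparisons"] = str(out / "comparisons.csv")

    # --- associate -----------------------------------------------------
    corr = _stage("associate")(spearman_matrix)(table)
    pd.DataFrame(corr.rho, index=corr.labels, columns=corr.labels).to_csv(
        out / "spearman_rho.csv")
    outputs["spearman_rho"] = str(out / "spearman_rho.csv")
    if corr.excluded:
        warnings.append(
            f"associate: zero-variance congeners excluded: {list(corr.excluded)}")
    clusters = _stage("associate")(cluster_congeners)(
        corr, k=config.cluster_k, linkage=config.cluster_linkage)
    with open(out / "clusters.json", "w") as fh:
        json.dump(clusters.as_dict(), fh, indent=2)
    outputs["clusters"] = str(out / "clusters.json")

    # --- risk ----------------------------------------------------------
    means = {a: float(m) for a, m in congener_means(table).items()}
    risk_table = _stage("risk")(deterministic_assessment)(means, catalog, groups)
    risk_table.rows.to_csv(out / "risk_table.csv", index=False)
    outputs["risk_table"] = str(out / "risk_table.csv")
    if risk_table.excluded_congeners:
        warnings.append(
            "risk: congeners without RfD excluded from THQ/HI: "
            f"{sorted(risk_table.excluded_congeners)}")
    mcs_cfg = dataclasses.replace(config.mcs, seed=config.seed)
    mcs = _stage("risk")(mcs_assessment)(table, catalog, groups, mcs_cfg)
    mcs.edi_stats.to_csv(out / "mcs_edi.csv", index=False)
    mcs.thq_stats.to_csv(out / "mcs_thq.csv", index=False)
    mcs.hi_stats.to_csv(out / "mcs_hi.csv", index=False)
    outputs["mcs_edi"] = str(out / "mcs_edi.csv")
    outputs["mcs_thq"] = str(out / "mcs_thq.csv")
    outputs["mcs_hi"] = str(out / "mcs_hi.csv")
    with open(out / "hi_summary.json", "w") as fh:
        json.dump({"hi": risk_table.hi,
                   "classification": risk_table.classification,
                   "hi_mcs_sum_of_medians": mcs.hi_sum_of_medians}, fh, indent=2)
    outputs["hi_summary"] = str(out / "hi_summary.json")

    missing = [p for p in outputs.values() if not Path(p).exists()]
    if missing:  # pragma: no cover - defensive
        raise RuntimeError(f"partial outputs missing: {missing}")
    report = RunReport(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        n_samples=table.n_samples,
        outputs={k: str(Path(p).relative_to(out)) for k, p in outputs.items()},
        warnings=warnings,
        hi=risk_table.hi,
        classification=risk_table.classification,
    )
    report.to_json(out / "run_report.json")
    return report
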