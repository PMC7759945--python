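"""End-to-end orchestration: records -> events -> densities -> overlap ->
co-occurrence -> matrix association, with a run manifest.

One root seed spawns named substreams per stage, so rerunning a single
stage with its substream reproduces the pipeline-level result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import spawn_rng
from . import duikerdata
from .cooccur import build_detection_matrix, effect_size_matrix, pairwise_cooccurrence
from .density import activity_level, circular_median_hour, hermans_rasson_test, trig_sum_density, total_variation_distance, vm_kernel_density
from .events import (
    EmptyResultError,
    SolarSchedule,
    diel_summary_table,
    event_series,
    filter_independent_events,
    read_detections,
    retain_informative_stations,
)
from .mantel import mantel_test
from .overlap import overlap_matrix, pairwise_overlap

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    records: pd.DataFrame | str | Path
    seed: int
    solar: SolarSchedule = field(default_factory=SolarSchedule)
    window_minutes: float = 60.0
    exclude: tuple[str, ...] = duikerdata.EXCLUDED_FROM_PAIRWISE
    n_boot: int = 1000
    alpha: float = 0.05
    deployed_stations: int | None = None
    min_events_per_species: int = 10
    out_dir: str | Path | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        solar = raw.pop("solar", None)
        cfg = cls(**raw)
        if solar:
            cfg.solar = SolarSchedule(**solar)
        if "exclude" in raw:
            cfg.exclude = tuple(raw["exclude"])
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a bundle of tables plus a manifest.

    Stage failures raise with a stage-tagged message; tables computed before
    the failure are written if ``out_dir`` is set.
    """
    bundle: dict = {}
    manifest: dict = {"seed": config.seed}
    try:
        _run_stages(config, bundle, manifest)
    except Exception as err:
        stage = manifest.get("stage", "unknown")
        _write_outputs(config, bundle, manifest)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
    _write_outputs(config, bundle, manifest)
    return bundle


def _run_stages(config: RunConfig, bundle: dict, manifest: dict) -> None:
    manifest["stage"] = "ingest"
    records = config.records
    if not isinstance(records, pd.DataFrame):
        records = read_detections(records)
    if records.empty:
        raise EmptyResultError("no detection records supplied")
    manifest["n_records"] = int(len(records))

    manifest["stage"] = "events"
    events = filter_independent_events(records, config.window_minutes)
    series = event_series(events)
    kept, retention = retain_informative_stations(events, config.deployed_stations)
    bundle["events"] = events
    manifest["n_events"] = int(len(events))
    manifest["n_stations_kept"] = len(kept)
    manifest["retention_pct"] = retention
    manifest["events_per_species"] = {sp: s.n for sp, s in series.items()}

    manifest["stage"] = "diel"
    bundle["diel"] = diel_summary_table(series, config.solar)

    manifest["stage"] = "density"
    rng_d = spawn_rng(config.seed, "density")
    rows = []
    for sp in sorted(series):
        s = series[sp]
        if s.n < config.min_events_per_species:
            log.warning("skipping %s: only %d events", sp, s.n)
            continue
        kde = vm_kernel_density(s.times)
        trig = trig_sum_density(s.times)
        unif = hermans_rasson_test(s.times, n_boot=config.n_boot, seed=rng_d)
        act = activity_level(s.times, n_boot=config.n_boot, seed=rng_d)
        rows.append(
            {
                "species": sp,
                "n": s.n,
                "median_hour": circular_median_hour(s.times),
                "hr_statistic": unif.statistic,
                "hr_p": unif.p_value,
                "activity_level": act.estimate,
                "activity_ci_low": act.ci_low,
                "activity_ci_high": act.ci_high,
                "kde_trig_tv_distance": total_variation_distance(kde, trig),
                "kde_kappa": kde.params["kappa"],
            }
        )
    bundle["density"] = pd.DataFrame(rows)

    manifest["stage"] = "overlap"
    analysed = {sp: s for sp, s in series.items() if sp not in config.exclude and s.n >= config.min_events_per_species}
    bundle["overlap"] = pairwise_overlap(
        analysed, n_boot=config.n_boot, seed=spawn_rng(config.seed, "overlap")
    )

    manifest["stage"] = "cooccurrence"
    matrix = build_detection_matrix(series, stations=kept)
    bundle["detection_matrix"] = matrix
    bundle["cooccurrence"] = pairwise_cooccurrence(
        matrix, alpha=config.alpha, exclude=config.exclude
    )

    manifest["stage"] = "mantel"
    species_order = sorted(analysed)
    m_overlap = overlap_matrix(bundle["overlap"], species_order)
    m_effect = effect_size_matrix(
        bundle["cooccurrence"][
            bundle["cooccurrence"]["species_a"].isin(species_order)
            & bundle["cooccurrence"]["species_b"].isin(species_order)
        ],
        species_order,
    )
    res = mantel_test(m_overlap, m_effect, seed=spawn_rng(config.seed, "mantel"))
    bundle["mantel"] = pd.DataFrame(
        [{"r": res.r, "p_value": res.p_value, "n_perm": res.n_perm, "exact": res.exact}]
    )
    manifest["stage"] = "done"
    bundle["manifest"] = manifest


def _write_outputs(config: RunConfig, bundle: dict, manifest: dict) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=name == "detection_matrix")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
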