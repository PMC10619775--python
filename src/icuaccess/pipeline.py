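"""End-to-end run orchestration: region -> catchments -> ratios -> levels -> tables.

A run takes either an on-disk region file set or a synthetic region
config, evaluates catchments at each requested drive-time threshold
(default 60 minutes; the sensitivity sweep adds 30 and 90), and writes per
threshold: access records, band thresholds, classified block groups, and
the stratified population tables.  A manifest records the config hash,
seed, package version and ratio variant so any run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .accessibility import VARIANTS, compute_access_records
from .catchment import build_catchments, no_access_set
from .classification import AccessLevel, classify_records, compute_thresholds
from .stratification import LEVEL_COLUMNS, aggregate, state_summary_stats
from .synthetic import (
    RegionConfig,
    SyntheticRegion,
    generate_region,
    read_region,
)

__all__ = ["RunConfig", "PipelineError", "run", "validate_inputs", "ValidationReport"]

log = logging.getLogger(__name__)

TABLE_FILES = {
    "race": "national_by_race.csv",
    "urbanization": "national_by_urbanization.csv",
    "region": "by_region.csv",
    "region_x_race": "region_by_race.csv",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    output_dir: str
    region_dir: str | None = None
    synthetic: RegionConfig | None = None
    thresholds_minutes: tuple[float, ...] = (60.0,)
    ratio_variant: str = "sum_of_facility_ratios"
    exclude_top_fraction: float = 0.01
    band: float = 0.5
    snap_walk_speed_kmh: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.region_dir is None and self.synthetic is None:
            raise ValueError("either region_dir or a synthetic RegionConfig is required")
        if not self.thresholds_minutes:
            raise ValueError("at least one drive-time threshold is required")
        if list(self.thresholds_minutes) != sorted(self.thresholds_minutes):
            raise ValueError("thresholds_minutes must be sorted ascending")
        if any(t <= 0 for t in self.thresholds_minutes):
            raise ValueError("all thresholds must be > 0 minutes")
        if self.ratio_variant not in VARIANTS:
            raise ValueError(f"ratio_variant must be one of {VARIANTS}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    # identifies the analysis, not its destination or verbosity
    d = config.to_dict()
    d.pop("output_dir", None)
    d.pop("log_level", None)
    payload = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _load_region(config: RunConfig) -> SyntheticRegion:
    if config.region_dir is not None:
        return read_region(config.region_dir)
    synth = config.synthetic
    if synth.seed != config.seed:
        synth = dataclasses.replace(synth, seed=config.seed)
    return generate_region(synth)


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Per threshold T the output directory gains a ``t<T>/`` subdirectory
    with: catchments.csv, access_records.csv, thresholds.json,
    classified_block_groups.csv, the four stratified tables, and
    summary_stats.json.  Identical config+seed gives byte-identical
    outputs.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        region = _load_region(config)
    except Exception as exc:
        raise PipelineError(f"stage load_region: {exc}") from exc

    populated = [bg for bg in region.block_groups if bg.populated]
    n_zero = len(region.block_groups) - len(populated)
    log.info(
        "region: %d facilities, %d block groups (%d zero-population, excluded)",
        len(region.facilities),
        len(region.block_groups),
        n_zero,
    )

    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "ratio_variant": config.ratio_variant,
        "thresholds_minutes": list(config.thresholds_minutes),
        "n_facilities": len(region.facilities),
        "n_block_groups": len(region.block_groups),
        "n_zero_population_excluded": n_zero,
        "per_threshold": {},
    }

    for T in config.thresholds_minutes:
        tdir = outdir / f"t{T:g}"
        tdir.mkdir(exist_ok=True)
        try:
            stats = _run_threshold(region, config, T, tdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage threshold_{T:g}: {exc}") from exc
        manifest["per_threshold"][f"{T:g}"] = stats

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _run_threshold(region: SyntheticRegion, config: RunConfig, T: float, tdir: Path) -> dict:
    index = build_catchments(
        region.network,
        region.facilities,
        region.block_groups,
        T,
        snap_walk_speed_kmh=config.snap_walk_speed_kmh,
    )

    pairs = pd.DataFrame(
        [
            {"facility_id": i, "blockgroup_id": j, "travel_minutes": t}
            for (i, j), t in sorted(index.travel_minutes.items())
        ],
        columns=["facility_id", "blockgroup_id", "travel_minutes"],
    )
    pairs.to_csv(tdir / "catchments.csv", index=False)

    records = compute_access_records(
        region.block_groups, region.facilities, index, config.ratio_variant
    )
    rec_df = pd.DataFrame(
        [
            {
                "blockgroup_id": r.blockgroup_id,
                "covered": r.covered,
                "ratio": r.ratio,
                "threshold_minutes": r.threshold_minutes,
                "variant": config.ratio_variant,
            }
            for r in records
        ]
    )
    rec_df.to_csv(tdir / "access_records.csv", index=False)

    covered = [r.ratio for r in records if r.covered]
    if len(covered) >= 2:
        thresholds = compute_thresholds(covered, config.exclude_top_fraction, config.band)
        levels = classify_records(records, thresholds)
        thr_payload = thresholds.to_dict()
    elif len(covered) == 0:
        # nothing reachable (e.g. a facility-free region): everyone is NO_ACCESS
        thresholds = None
        levels = {r.blockgroup_id: AccessLevel.NO_ACCESS for r in records}
        thr_payload = None
    else:
        raise PipelineError(
            f"stage thresholds: only {len(covered)} covered block group; need >= 2"
        )
    with open(tdir / "thresholds.json", "w") as fh:
        json.dump(
            {
                "threshold_minutes": T,
                "variant": config.ratio_variant,
                "thresholds": thr_payload,
            },
            fh,
            indent=1,
            sort_keys=True,
        )

    cls_df = rec_df[["blockgroup_id", "covered", "ratio"]].copy()
    cls_df["access_level"] = [levels[b].value for b in cls_df["blockgroup_id"]]
    cls_df.to_csv(tdir / "classified_block_groups.csv", index=False)

    tables = {}
    for stratifier, fname in TABLE_FILES.items():
        table = aggregate(region.block_groups, levels, stratifier)
        out = table.counts.copy()
        pct = table.percentages()
        for col in LEVEL_COLUMNS:
            out[f"{col}_pct"] = pct[col]
        out.to_csv(tdir / fname)
        tables[stratifier] = table

    region_pct = tables["region"].percentages().drop(index="Total")
    summary = state_summary_stats(region_pct)
    with open(tdir / "summary_stats.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)

    no_access_ids = no_access_set(index, region.block_groups)
    pop_by_id = {bg.id: bg.pop_total for bg in region.block_groups}
    n_excl = thresholds.n_excluded if thresholds else 0
    return {
        "n_covered": len(covered),
        "n_no_access": len(no_access_ids),
        "no_access_population": int(sum(pop_by_id[j] for j in no_access_ids)),
        "n_excluded_top_fraction": n_excl,
    }


@dataclass
class ValidationReport:
    """Input-file check results: fatal errors vs non-fatal warnings."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(region_dir) -> ValidationReport:
    """Schema, value-range and referential checks on a region file set."""
    region_dir = Path(region_dir)
    report = ValidationReport()

    fac_path = region_dir / "facilities.csv"
    bg_path = region_dir / "block_groups.geojson"
    nodes_path = region_dir / "network_nodes.csv"
    edges_path = region_dir / "network_edges.csv"
    for p in (fac_path, bg_path, nodes_path, edges_path):
        if not p.exists():
            report.errors.append(f"{p.name}: file missing")
    if report.errors:
        return report

    fac = pd.read_csv(fac_path)
    missing = [c for c in ("id", "x_km", "y_km", "adult_icu_beds", "region_code") if c not in fac]
    if missing:
        report.errors.append(f"facilities.csv: missing column(s) {missing}")
    else:
        for i, beds in fac["adult_icu_beds"].items():
            if beds < 1:
                report.errors.append(
                    f"facilities.csv: record {i}: adult_icu_beds={beds} (must be >= 1)"
                )

    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    if {"u", "v", "length_km", "speed_kmh"} <= set(edges.columns):
        bad = edges[(edges["length_km"] <= 0) | (edges["speed_kmh"] <= 0)]
        for i in bad.index:
            report.errors.append(f"network_edges.csv: record {i}: non-positive length or speed")
        if "id" in nodes.columns:
            known = set(nodes["id"])
            dangling = edges[~(edges["u"].isin(known) & edges["v"].isin(known))]
            for i in dangling.index:
                report.errors.append(f"network_edges.csv: record {i}: unknown endpoint node")
    else:
        report.errors.append("network_edges.csv: missing column(s)")

    try:
        with open(bg_path) as fh:
            collection = json.load(fh)
    except json.JSONDecodeError as exc:
        report.errors.append(f"block_groups.geojson: invalid JSON: {exc}")
        return report
    fac_regions = set(fac["region_code"]) if "region_code" in fac else set()
    bg_regions = set()
    for i, feature in enumerate(collection.get("features", [])):
        props = feature.get("properties", {})
        if "pop_total" not in props:
            report.errors.append(f"block_groups.geojson: feature {i}: missing pop_total")
            continue
        pop = props["pop_total"]
        if pop < 0:
            report.errors.append(f"block_groups.geojson: feature {i}: negative pop_total")
        elif pop == 0:
            report.warnings.append(
                f"block_groups.geojson: feature {i}: pop_total=0, excluded from analysis"
            )
        for k, v in props.items():
            if k.startswith("pop_") and k != "pop_total" and v < 0:
                report.errors.append(f"block_groups.geojson: feature {i}: negative {k}")
        bg_regions.add(props.get("region_code"))
    orphan = fac_regions - bg_regions
    if orphan:
        report.warnings.append(
            f"facilities.csv: region code(s) {sorted(orphan)} have no block groups"
        )
    return report
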