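"""End-to-end orchestration: simulate -> average -> segment -> graph -> f-vector -> stats.

A :class:`RunConfig` declares the whole study grid: populations (cohorts
differing in noise smoothness), regions (parameter presets differing in
evoked amplitude), and the conditions to analyse (task labels, or ``whole``
for the unsegmented series).  :func:`run_pipeline` simulates each cohort,
averages it (graphs are always built from the cohort-average series, never
averaged themselves), builds the visibility graph per condition, computes
both f-vector conventions and the classical summary, writes every
intermediate artifact to the output directory, and assembles a
:class:`ComparisonReport` with per-cell results and pairwise contrasts.

Reports are byte-identical across reruns of the same config: no timestamps
enter the report, the manifest records the config hash, seed and package
version, and all orderings are canonical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__
from .netstats import NetworkSummary, network_summary
from .series import BlockDesign, TimeSeries, extract_condition, write_design, write_series
from .simplicial import FVector, f_vector, write_fvector
from .synthetic import (
    BlockDesignSpec,
    BoldParams,
    CohortSpec,
    average_cohort,
    make_design,
    simulate_cohort,
)
from .visibility import visibility_graph, write_edgelist

__all__ = [
    "RunConfig",
    "ComparisonReport",
    "PipelineError",
    "default_config",
    "run_pipeline",
    "compare_fvectors",
]

logger = logging.getLogger("boldvis")

#: Pseudo-condition meaning "analyse the full, unsegmented series".
WHOLE_TASK = "whole"

_POPULATION_KEYS = {"n_subjects", "ar_coefficient", "noise_sd", "seed"}
_REGION_KEYS = {"baseline", "amplitude_word", "amplitude_nonword"}


class PipelineError(RuntimeError):
    """A stage failure annotated with its (population, region, condition) context."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one full analysis run.

    ``populations`` maps a name to ``{n_subjects, ar_coefficient, noise_sd}``;
    ``regions`` maps a name to ``{baseline, amplitude_word,
    amplitude_nonword}``; a cohort's :class:`BoldParams` is the merge of its
    region preset and population preset.  ``seed`` is mandatory — there is no
    silent default.
    """

    seed: int
    output_dir: str
    populations: dict[str, dict[str, float]]
    regions: dict[str, dict[str, float]]
    conditions: tuple[str, ...] = ("word", "nonword", WHOLE_TASK)
    design: BlockDesignSpec = field(default_factory=BlockDesignSpec)
    segmentation_mode: str = "concatenated"
    collinear_blocks: bool = True
    fvector_convention: str = "all_faces"
    contrasts: tuple[tuple[str, str], ...] | None = None  # population pairs

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory in the run config")
        if not self.populations:
            raise ValueError("at least one population is required")
        if not self.regions:
            raise ValueError("at least one region is required")
        for name, spec in self.populations.items():
            bad = set(spec) - _POPULATION_KEYS
            if bad:
                raise ValueError(f"population {name!r}: unknown keys {sorted(bad)}")
        for name, spec in self.regions.items():
            bad = set(spec) - _REGION_KEYS
            if bad:
                raise ValueError(f"region {name!r}: unknown keys {sorted(bad)}")
        if self.contrasts is not None:
            for a, b in self.contrasts:
                for p in (a, b):
                    if p not in self.populations:
                        raise ValueError(f"contrast references unknown population {p!r}")
        object.__setattr__(self, "conditions", tuple(self.conditions))

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "populations": self.populations,
            "regions": self.regions,
            "conditions": list(self.conditions),
            "design": asdict(self.design) | {"section_order": list(self.design.section_order)},
            "segmentation_mode": self.segmentation_mode,
            "collinear_blocks": self.collinear_blocks,
            "fvector_convention": self.fvector_convention,
            "contrasts": [list(c) for c in self.contrasts] if self.contrasts else None,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        if "seed" not in d or d["seed"] is None:
            raise ValueError("config must set an explicit integer seed")
        design = d.get("design", {})
        if isinstance(design, dict):
            if "section_order" in design:
                design = design | {"section_order": tuple(design["section_order"])}
            design = BlockDesignSpec(**design)
        contrasts = d.get("contrasts")
        if contrasts is not None:
            contrasts = tuple((a, b) for a, b in contrasts)
        return cls(
            seed=int(d["seed"]),
            output_dir=str(d.get("output_dir", "boldvis_out")),
            populations={k: dict(v) for k, v in d["populations"].items()},
            regions={k: dict(v) for k, v in d["regions"].items()},
            conditions=tuple(d.get("conditions", ("word", "nonword", WHOLE_TASK))),
            design=design,
            segmentation_mode=d.get("segmentation_mode", "concatenated"),
            collinear_blocks=bool(d.get("collinear_blocks", True)),
            fvector_convention=d.get("fvector_convention", "all_faces"),
            contrasts=contrasts,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def default_config(seed: int, output_dir: str | Path = "boldvis_out") -> RunConfig:
    """The study-shaped default grid: 2 populations x 2 regions x 3 conditions.

    Five subjects per cohort, 240 samples at 3 s in the standard
    word/rest/nonword/rest block design; adult and child cohorts differ in
    noise smoothness, high- and low-activity regions in evoked amplitude.
    """
    return RunConfig(
        seed=seed,
        output_dir=str(output_dir),
        populations={
            "adults": {"n_subjects": 5, "ar_coefficient": 0.4, "noise_sd": 1.0},
            "children": {"n_subjects": 5, "ar_coefficient": 0.8, "noise_sd": 0.6},
        },
        regions={
            "high_activity": {"amplitude_word": 2.0, "amplitude_nonword": 2.0},
            "low_activity": {"amplitude_word": 0.4, "amplitude_nonword": 0.4},
        },
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Per-cell results plus the requested pairwise contrasts.

    ``cells`` maps ``"population/region/condition"`` to a record holding both
    f-vectors, ``q_max``, the node count and (for connected graphs) the
    classical summary.  Every delta in ``contrasts`` is recomputable from the
    stored f-vectors.
    """

    cells: dict[str, dict[str, Any]]
    contrasts: list[dict[str, Any]]
    manifest: dict[str, Any]

    def to_json(self) -> str:
        payload = {
            "manifest": self.manifest,
            "cells": self.cells,
            "contrasts": self.contrasts,
        }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"


def compare_fvectors(a: FVector, b: FVector) -> dict[str, Any]:
    """Element-wise f-vector differences (a - b) with zero-padded tails."""
    m = max(len(a), len(b))
    pa = list(a.counts) + [0] * (m - len(a))
    pb = list(b.counts) + [0] * (m - len(b))
    return {
        "delta_counts": [x - y for x, y in zip(pa, pb)],
        "q_max_delta": a.q_max - b.q_max,
    }


# ---------------------------------------------------------------------------
# Pipeline proper
# ---------------------------------------------------------------------------


def _cell_params(config: RunConfig, population: str, region: str) -> BoldParams:
    pop = dict(config.populations[population])
    pop.pop("n_subjects", None)
    pop.pop("seed", None)
    return BoldParams(**{**config.regions[region], **pop})


def _sum_fvectors(fvs: Sequence[FVector], convention: str) -> FVector:
    m = max(len(f) for f in fvs)
    counts = [0] * m
    for f in fvs:
        for q, c in enumerate(f.counts):
            counts[q] += c
    return FVector(tuple(counts), convention=convention)  # type: ignore[arg-type]


def _analyse_series(
    ts: TimeSeries, collinear_blocks: bool
) -> tuple[Any, FVector, FVector, NetworkSummary]:
    g = visibility_graph(ts, collinear_blocks=collinear_blocks)
    fv_all = f_vector(g, "all_faces")
    fv_max = f_vector(g, "maximal_only")
    summary = network_summary(g)
    return g, fv_all, fv_max, summary


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Execute the full grid and write all artifacts under ``config.output_dir``.

    In ``per_block`` segmentation a condition spans several disconnected
    block graphs: the reported f-vectors are the sums over blocks (simplex
    counts are additive over disjoint graphs) and the path-based summary is
    omitted (``null``), since the diameter of a disconnected union is
    undefined.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = make_design(config.design)
    cells: dict[str, dict[str, Any]] = {}
    summary_rows: list[dict[str, Any]] = []

    for p_idx, population in enumerate(config.populations):
        for r_idx, region in enumerate(config.regions):
            # per-population seed override makes cohorts repeatable across
            # populations (identical spec + identical seed => identical cells)
            pop_seed = config.populations[population].get("seed")
            base = int(pop_seed) if pop_seed is not None else config.seed + 1000 * p_idx
            cell_seed = base + 100 * r_idx
            params = _cell_params(config, population, region)
            n_subjects = int(config.populations[population].get("n_subjects", 5))
            cohort_spec = CohortSpec(
                n_subjects=n_subjects,
                bold_params=params,
                design=config.design,
                seed=cell_seed,
            )
            cell_dir = out / f"{population}_{region}"
            cell_dir.mkdir(exist_ok=True)
            logger.info(
                "simulating cohort %s/%s: %d subjects, seed %d",
                population, region, n_subjects, cell_seed,
            )
            cohort = simulate_cohort(cohort_spec)
            for k, ts in enumerate(cohort):
                write_series(ts, cell_dir / f"subject_{k}.csv")
            avg = average_cohort(cohort)
            write_series(avg, cell_dir / "average.csv")
            write_design(design, cell_dir / "design.csv")

            for condition in config.conditions:
                key = f"{population}/{region}/{condition}"
                try:
                    cells[key] = _run_cell(
                        avg, design, condition, config, cell_dir, summary_rows,
                        population, region,
                    )
                except Exception as e:
                    raise PipelineError(f"[{key}] {type(e).__name__}: {e}") from e

    contrasts = _build_contrasts(config, cells)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "config": config.to_dict(),
    }
    report = ComparisonReport(cells=cells, contrasts=contrasts, manifest=manifest)
    (out / "report.json").write_text(report.to_json())
    _write_summary_table(summary_rows, out / "summary_table.csv")
    logger.info("pipeline complete: %d cells, %d contrasts", len(cells), len(contrasts))
    return report


def _run_cell(
    avg: TimeSeries,
    design: BlockDesign,
    condition: str,
    config: RunConfig,
    cell_dir: Path,
    summary_rows: list[dict[str, Any]],
    population: str,
    region: str,
) -> dict[str, Any]:
    cond_dir = cell_dir / condition
    cond_dir.mkdir(exist_ok=True)

    if condition == WHOLE_TASK:
        segments: list[TimeSeries] = [avg]
    else:
        cond = extract_condition(avg, design, condition, mode=config.segmentation_mode)
        segments = list(cond.segments)
        manifest_lines = ["segment,source_start,source_stop"]
        if config.segmentation_mode == "per_block":
            for s_idx, (a, b) in enumerate(cond.source_ranges):
                manifest_lines.append(f"{s_idx},{a},{b}")
        else:
            manifest_lines += [f"0,{a},{b}" for a, b in cond.source_ranges]
        (cond_dir / "segments_manifest.csv").write_text(
            "\n".join(manifest_lines) + "\n"
        )

    fvs_all: list[FVector] = []
    fvs_max: list[FVector] = []
    summary: NetworkSummary | None = None
    for s_idx, seg in enumerate(segments):
        g, fv_all, fv_max, seg_summary = _analyse_series(seg, config.collinear_blocks)
        suffix = f"_block{s_idx}" if len(segments) > 1 else ""
        write_series(seg, cond_dir / f"series{suffix}.csv")
        write_edgelist(g, cond_dir / f"graph{suffix}.edges")
        logger.debug(
            "%s/%s/%s%s: %d nodes, %d edges, q_max=%d",
            population, region, condition, suffix,
            g.number_of_nodes(), g.number_of_edges(), fv_all.q_max,
        )
        fvs_all.append(fv_all)
        fvs_max.append(fv_max)
        if len(segments) == 1:
            summary = seg_summary

    fv_all = _sum_fvectors(fvs_all, "all_faces")
    fv_max = _sum_fvectors(fvs_max, "maximal_only")
    write_fvector(fv_all, cond_dir / "fvector_all_faces.csv")
    write_fvector(fv_max, cond_dir / "fvector_maximal_only.csv")

    if summary is not None:
        summary_rows.append(
            {"population": population, "region": region, "condition": condition}
            | summary.as_dict()
        )
    return {
        "population": population,
        "region": region,
        "condition": condition,
        "n_samples": int(fv_all.counts[0]),
        "fvector_all_faces": list(fv_all.counts),
        "fvector_maximal_only": list(fv_max.counts),
        "q_max": fv_all.q_max,
        "summary": summary.as_dict() if summary is not None else None,
    }


def _build_contrasts(
    config: RunConfig, cells: dict[str, dict[str, Any]]
) -> list[dict[str, Any]]:
    pops = list(config.populations)
    if config.contrasts is not None:
        pairs = list(config.contrasts)
    else:
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    conv = config.fvector_convention
    fv_key = "fvector_all_faces" if conv == "all_faces" else "fvector_maximal_only"
    out: list[dict[str, Any]] = []
    for a, b in pairs:
        for region in config.regions:
            for condition in config.conditions:
                ka, kb = f"{a}/{region}/{condition}", f"{b}/{region}/{condition}"
                if ka not in cells or kb not in cells:
                    continue
                fa = FVector(tuple(cells[ka][fv_key]), convention=conv)  # type: ignore[arg-type]
                fb = FVector(tuple(cells[kb][fv_key]), convention=conv)  # type: ignore[arg-type]
                out.append(
                    {
                        "a": ka,
                        "b": kb,
                        "convention": conv,
                        **compare_fvectors(fa, fb),
                    }
                )
    return out


def _write_summary_table(rows: list[dict[str, Any]], path: Path) -> None:
    cols = ["population", "region", "condition", "d_avg", "c_avg", "l_avg", "diameter"]
    lines = [",".join(cols)]
    for row in rows:
        lines.append(",".join(str(row[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")
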