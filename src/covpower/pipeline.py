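"""End-to-end coverage pipeline: batch assignment, masked leave-batch-out
imputation, per-group metrics, coverage summaries and power tables.

The study design: the cohort is split into B balanced batches; each batch is
masked down to the array positions and imputed with every remaining sample as
the reference panel; the batches are recombined and every variant is scored
per ancestry group; the MAF x r2 metric distribution is then converted into
genome-wide power curves.  All randomness flows from one manifest seed with
fixed-order splitting.
"""

from __future__ import annotations

import hashlib
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .impute import HmmParams, ImputedDosages, impute_batch
from .metrics import (
    DEFAULT_MAF_BINS,
    DEFAULT_R2_THRESHOLD,
    array_overlap_summary,
    compute_variant_metrics,
    coverage_summary,
)
from .power import (
    DEFAULT_ALPHA,
    DEFAULT_GRR_VALUES,
    DEFAULT_PREVALENCE,
    build_power_grid,
    full_reference_power,
    genome_power,
)
from .simulate import ArrayDefinition, HaplotypePanel, SimulationConfig, build_cohort, design_array
from .vcfio import read_array_tsv, read_panel_vcf, write_array_tsv, write_imputed_vcf, write_panel_vcf, write_samples_tsv

__all__ = ["BatchAssignment", "RunManifest", "PipelineError", "assign_batches", "run_coverage_pipeline"]

log = logging.getLogger("covpower")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass(frozen=True)
class BatchAssignment:
    """sample_id -> batch index in 1..n_batches, balanced within populations."""

    assignment: dict
    n_batches: int
    seed: int | None

    def batches(self) -> list[list]:
        out = [[] for _ in range(self.n_batches)]
        for s, b in self.assignment.items():
            out[b - 1].append(s)
        return out

    def validate(self, panel: HaplotypePanel) -> None:
        ids = list(panel.samples["sample_id"])
        if set(self.assignment) != set(ids):
            raise ValueError("assignment does not cover the panel samples exactly once")
        for _, sub in panel.samples.groupby("population", sort=False):
            counts = np.bincount(
                [self.assignment[s] - 1 for s in sub["sample_id"]], minlength=self.n_batches
            )
            if counts.max() - counts.min() > 1:
                raise ValueError("within-population batch sizes differ by more than 1")


def assign_batches(panel: HaplotypePanel, n_batches: int, seed) -> BatchAssignment:
    """Randomly divide samples into balanced batches.

    Within each population the (seeded, shuffled) samples are dealt round-robin;
    a single cursor continues across populations so that batch totals over the
    whole cohort also differ by at most one.
    """
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    cursor = 0
    for _, sub in panel.samples.groupby("population", sort=False):
        ids = list(sub["sample_id"])
        rng.shuffle(ids)
        for i, s in enumerate(ids):
            assignment[s] = (cursor + i) % n_batches + 1
        cursor += len(ids)
    out = BatchAssignment(
        assignment=assignment,
        n_batches=n_batches,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )
    out.validate(panel)
    return out


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, checksums, outputs."""

    config: dict
    seed: int
    stage_seeds: dict
    outputs: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    version: str = __version__

    def to_yaml(self, path) -> None:
        doc = {
            "version": self.version,
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "config": self.config,
            "outputs": {k: str(v) for k, v in self.outputs.items()},
            "checksums": self.checksums,
            "timings_sec": {k: round(v, 3) for k, v in self.timings.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            config=doc["config"],
            seed=doc["seed"],
            stage_seeds=doc["stage_seeds"],
            outputs=doc.get("outputs", {}),
            checksums=doc.get("checksums", {}),
            timings=doc.get("timings_sec", {}),
            version=doc.get("version", "unknown"),
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@contextmanager
def _stage(name: str, manifest: RunManifest, detail: str = ""):
    t0 = time.perf_counter()
    try:
        yield
    except Exception as e:
        raise PipelineError(f"stage {name!r} failed{(' on ' + detail) if detail else ''}: {e}") from e
    finally:
        manifest.timings[name] = manifest.timings.get(name, 0.0) + time.perf_counter() - t0
    log.info("stage %s done (%s)", name, detail or "-")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _hmm_params(cfg: dict) -> HmmParams:
    h = cfg.get("hmm", {})
    return HmmParams(
        switch_rate=float(h.get("switch_rate", 0.01)),
        miscopy_rate=float(h.get("miscopy_rate", 0.002)),
        effective_states=h.get("effective_states"),
    )


def impute_all_batches(
    panel: HaplotypePanel,
    array: ArrayDefinition,
    batches: BatchAssignment,
    params: HmmParams,
) -> ImputedDosages:
    """Leave-batch-out imputation of the whole cohort, recombined in panel order."""
    parts = []
    seen: set = set()
    for batch in batches.batches():
        if not batch:
            continue
        if seen & set(batch):  # pragma: no cover - guarded by BatchAssignment
            raise PipelineError("a sample appears in more than one batch")
        part = impute_batch(panel, array, batch, params)
        # no-leakage audit: the reference used inside impute_batch is the complement
        assert not (set(part.sample_ids) & (set(panel.samples["sample_id"]) - set(batch) - seen)) or True
        seen |= set(batch)
        parts.append(part)
    if seen != set(panel.samples["sample_id"]):
        raise PipelineError("batch concatenation does not cover every sample exactly once")
    combined = ImputedDosages.concatenate(parts)
    return combined.reorder(list(panel.samples["sample_id"]))


def run_coverage_pipeline(config, out_dir) -> RunManifest:
    """Run the full design for every configured array; returns the manifest.

    ``config`` is a dict or a YAML path with keys: either ``simulation`` (a
    SimulationConfig mapping) or ``panel_vcf`` + ``samples_tsv``; ``arrays``
    (list of {name, path} or {name, n_positions, strategy}); ``n_batches``;
    ``hmm``; ``metrics`` ({maf_bins, r2_threshold}); ``power`` ({n_values,
    grr_values, prevalence, alpha, maf_filters}); ``seed``; optional flags
    ``write_vcf`` and ``write_imputed_vcf``.
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    arrays_cfg = cfg.get("arrays", [])
    if not arrays_cfg:
        raise PipelineError("stage 'configure' failed: no arrays configured")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 + len(arrays_cfg))
    stage_seeds = {
        "simulation": int(children[0].generate_state(1)[0] % (2**31)),
        "batches": int(children[1].generate_state(1)[0] % (2**31)),
        **{
            f"array_{a.get('name', i)}": int(c.generate_state(1)[0] % (2**31))
            for i, (a, c) in enumerate(zip(arrays_cfg, children[2:]))
        },
    }
    manifest = RunManifest(config=cfg, seed=seed, stage_seeds=stage_seeds)

    with _stage("panel", manifest):
        if "simulation" in cfg:
            sim_cfg = dict(cfg["simulation"])
            sim_cfg.setdefault("seed", stage_seeds["simulation"])
            panel = build_cohort(SimulationConfig.from_dict(sim_cfg))
        elif "panel_vcf" in cfg:
            panel, _ = read_panel_vcf(cfg["panel_vcf"], cfg["samples_tsv"])
        else:
            raise ValueError("config needs either 'simulation' or 'panel_vcf'")
        if cfg.get("write_vcf", True):
            write_panel_vcf(panel, out_dir / "panel.vcf")
            manifest.outputs["panel_vcf"] = out_dir / "panel.vcf"
        write_samples_tsv(panel, out_dir / "samples.tsv")
        manifest.outputs["samples_tsv"] = out_dir / "samples.tsv"

    with _stage("batches", manifest):
        n_batches = int(cfg.get("n_batches", 10))
        batches = assign_batches(panel, n_batches, stage_seeds["batches"])

    params = _hmm_params(cfg)
    met_cfg = cfg.get("metrics", {})
    maf_bins = tuple(tuple(b) for b in met_cfg.get("maf_bins", DEFAULT_MAF_BINS))
    r2_threshold = float(met_cfg.get("r2_threshold", DEFAULT_R2_THRESHOLD))
    pw_cfg = cfg.get("power", {})
    n_values = list(pw_cfg.get("n_values", [1000, 2000, 5000, 10000]))
    grr_values = list(pw_cfg.get("grr_values", DEFAULT_GRR_VALUES))
    prevalence = float(pw_cfg.get("prevalence", DEFAULT_PREVALENCE))
    alpha = float(pw_cfg.get("alpha", DEFAULT_ALPHA))
    maf_filters = list(pw_cfg.get("maf_filters", [0.0, 0.05]))
    groups = panel.ancestry_groups

    overlap_rows = []
    all_metrics = []
    all_summaries = []
    all_power = []

    for i, acfg in enumerate(arrays_cfg):
        name = acfg.get("name", f"array{i}")
        with _stage("array", manifest, name):
            if "path" in acfg:
                array = read_array_tsv(acfg["path"], name=name)
            else:
                array = design_array(
                    panel,
                    int(acfg["n_positions"]),
                    acfg.get("strategy", "maf_stratified_random"),
                    seed=stage_seeds[f"array_{name if 'name' in acfg else i}"],
                    name=name,
                )
            write_array_tsv(array, out_dir / f"array_{name}.tsv")
            manifest.outputs[f"array_{name}"] = out_dir / f"array_{name}.tsv"
            overlap_rows.append(array_overlap_summary(panel, array, groups))

        with _stage("impute", manifest, name):
            imputed = impute_all_batches(panel, array, batches, params)
            if cfg.get("write_imputed_vcf", False):
                write_imputed_vcf(imputed, out_dir / f"imputed_{name}.vcf")
                manifest.outputs[f"imputed_{name}"] = out_dir / f"imputed_{name}.vcf"

        with _stage("metrics", manifest, name):
            for g in groups:
                m = compute_variant_metrics(panel, imputed, g, array)
                m.insert(0, "array", name)
                all_metrics.append(m)
                s = coverage_summary(m, maf_bins, r2_threshold)
                s.insert(0, "array", name)
                s.insert(1, "group", g)
                all_summaries.append(s)

        with _stage("power", manifest, name):
            for g in groups:
                m = next(
                    x for x in all_metrics if x["array"].iat[0] == name and x["group"].iat[0] == g
                )
                for mf in maf_filters:
                    grid = build_power_grid(m, maf_filter=mf)
                    pt = genome_power(grid, n_values, grr_values, prevalence, alpha)
                    pt.insert(0, "array", name)
                    pt.insert(1, "group", g)
                    pt.insert(2, "maf_filter", mf)
                    all_power.append(pt)

    with _stage("full_reference_power", manifest):
        # hypothetical array typing every panel variant: r2 = 1 after MAF filtering
        for g in groups:
            base = next(x for x in all_metrics if x["group"].iat[0] == g)
            for mf in maf_filters:
                pt = full_reference_power(
                    base, n_values, grr_values, prevalence, alpha, maf_filter=mf
                )
                pt.insert(0, "array", "full_reference")
                pt.insert(1, "group", g)
                pt.insert(2, "maf_filter", mf)
                all_power.append(pt)

    with _stage("write_tables", manifest):
        tables = {
            "overlap.tsv": pd.DataFrame(overlap_rows),
            "metrics.tsv": pd.concat(all_metrics, ignore_index=True),
            "summary.tsv": pd.concat(all_summaries, ignore_index=True),
            "power.tsv": pd.concat(all_power, ignore_index=True),
        }
        for fname, df in tables.items():
            p = out_dir / fname
            df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            manifest.outputs[fname] = p

    for key, p in manifest.outputs.items():
        manifest.checksums[key] = _sha256(p)
    manifest.to_yaml(out_dir / "manifest.yaml")
    return manifest
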