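"""End-to-end orchestration: model -> reduction -> data integration ->
ensemble inversion -> differential comparison.

The workflow validates the whole configuration (paths, parses, column
mappings) before any computation starts, runs each stage with explicit
error attribution, and writes every matrix, a ranked interaction summary
and a run manifest sufficient to reproduce all outputs bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as mio
from .inference import (
    MetaboliteDataset,
    covariance_from_replicates,
    differential_jacobian,
    entry_significance,
    normalize_ensemble,
    run_ensemble,
    shrink_covariance,
    structure_mask_from_interactions,
)
from .network import build_interaction_matrix, project_to_measured, read_sbml_file


class WorkflowError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Configuration of one inference run.

    ``measured_map`` maps replicate-table column names to model species ids;
    when empty, column names are taken as species ids directly.
    """

    model_path: str
    data_paths: dict  # condition label -> replicate table path
    out_dir: str
    measured_map: dict = field(default_factory=dict)
    n_iterations: int = 100_000
    seed: int = 0
    alpha: float = 0.05
    include_first_neighbors: bool = False
    d_sign: str = "abs"  # or "signed"
    ttest: str = "batch_median"  # or "full"
    shrinkage: float = 0.0
    fdr: str = "none"  # or "bh"
    max_path_length: int = 6

    def validate(self) -> None:
        if not Path(self.model_path).exists():
            raise WorkflowError("validate", f"model file not found: {self.model_path}")
        for label, p in self.data_paths.items():
            if not Path(p).exists():
                raise WorkflowError("validate", f"data file for {label!r} not found: {p}")
        if self.d_sign not in ("abs", "signed"):
            raise WorkflowError("validate", f"unknown d_sign {self.d_sign!r}")
        if self.ttest not in ("batch_median", "full"):
            raise WorkflowError("validate", f"unknown ttest mode {self.ttest!r}")
        if self.fdr not in ("none", "bh"):
            raise WorkflowError("validate", f"unknown fdr mode {self.fdr!r}")


def _condition_seeds(seed: int, labels) -> dict:
    # both conditions share the run seed: the ensembles then use common
    # random fluctuation matrices (a paired design), so identical data give
    # an exactly zero differential Jacobian
    return {lab: int(seed) for lab in labels}


def run_workflow(config: RunConfig) -> dict:
    """Execute the full inference workflow described by ``config``.

    With one condition the result is a normalized Jacobian; with exactly two
    conditions the differential Jacobian and per-entry significance are
    computed as well.  Returns a result bundle (all intermediate objects)
    after writing outputs and the manifest to ``config.out_dir``.
    """
    config.validate()
    labels = sorted(config.data_paths)
    if not 1 <= len(labels) <= 2:
        raise WorkflowError("validate", f"need 1 or 2 conditions, got {len(labels)}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "stages": {}}
    # the manifest is always written before any other output
    mio.write_manifest(out / "manifest.json", manifest)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except WorkflowError:
            raise
        except Exception as exc:
            mio.write_manifest(out / "manifest.json", manifest)
            raise WorkflowError(name, str(exc)) from exc

    network = stage("parse_model", read_sbml_file, config.model_path)
    matrix = stage("build_interaction_matrix", build_interaction_matrix, network)

    datasets = {}
    for label in labels:
        ds = stage("read_data", MetaboliteDataset.read_table, config.data_paths[label], label)
        colmap = config.measured_map or {c: c for c in ds.pool_ids}
        missing_cols = sorted(set(colmap) - set(ds.pool_ids))
        if missing_cols:
            raise WorkflowError(
                "validate", f"mapped columns absent from {label!r} table: {missing_cols}"
            )
        unmapped = sorted(set(ds.pool_ids) - set(colmap))
        if unmapped:
            raise WorkflowError(
                "validate", f"columns in {label!r} table without species mapping: {unmapped}"
            )
        order = [c for c in ds.pool_ids]
        ds = MetaboliteDataset(
            pool_ids=[colmap[c] for c in order],
            values=ds.values,
            condition_label=label,
            n_dropped=ds.n_dropped,
        )
        datasets[label] = ds

    measured = list(dict.fromkeys(datasets[labels[0]].pool_ids))
    for label in labels[1:]:
        if list(datasets[label].pool_ids) != list(datasets[labels[0]].pool_ids):
            raise WorkflowError("validate", "conditions measure different pools or orders")

    projected = stage(
        "project_to_measured", project_to_measured, matrix, measured,
        include_first_neighbors=False, max_path_length=config.max_path_length,
    )
    mio.write_matrix(
        out / "interaction_matrix.tsv", projected.values,
        projected.species_order, projected.interaction_order,
    )
    (out / "interaction_provenance.tsv").write_text(projected.provenance_table(), encoding="utf-8")
    if config.include_first_neighbors:
        extended = stage(
            "project_to_measured", project_to_measured, matrix, measured,
            include_first_neighbors=True, max_path_length=config.max_path_length,
        )
        mio.write_matrix(
            out / "interaction_matrix_extended.tsv", extended.values,
            extended.species_order, extended.interaction_order,
        )
        (out / "interaction_provenance_extended.tsv").write_text(
            extended.provenance_table(), encoding="utf-8"
        )
    else:
        extended = None

    # inference runs on the measured pools, in the projected species order
    pool_order = list(projected.species_order)
    mask = structure_mask_from_interactions(projected.values)
    seeds = _condition_seeds(config.seed, labels)

    ensembles, normalized = {}, {}
    for label in labels:
        ds = datasets[label]
        perm = [ds.pool_ids.index(p) for p in pool_order]
        ds_ordered = MetaboliteDataset(
            pool_ids=pool_order, values=ds.values[:, perm], condition_label=label,
        )
        cov = stage("covariance", covariance_from_replicates, ds_ordered)
        if config.shrinkage:
            cov = stage("covariance", shrink_covariance, cov, config.shrinkage)
        mio.write_matrix(out / f"covariance_{label}.tsv", cov.values, pool_order, pool_order)
        ens = stage(
            "ensemble", run_ensemble, cov, mask, config.n_iterations, seeds[label],
            pool_ids=pool_order, signed_d=(config.d_sign == "signed"),
        )
        norm = stage("normalize", normalize_ensemble, ens)
        for tag, m in (
            ("median", norm.median_matrix),
            ("iqr", norm.iqr_matrix),
            ("normalized", norm.normalized_matrix),
        ):
            mio.write_matrix(out / f"{tag}_{label}.tsv", m, pool_order, pool_order)
        ensembles[label], normalized[label] = ens, norm
        manifest["stages"][label] = {
            "seed": seeds[label],
            "n_iterations": config.n_iterations,
            "n_failed": ens.n_failed,
            "ols_fallbacks": ens.metadata["ols_fallbacks"],
            "operator_rank": ens.metadata["operator_rank"],
            "nullspace_dim": ens.metadata["nullspace_dim"],
            "n_replicates": ds.n_replicates,
            "dropped_replicates": ds.n_dropped,
        }

    result = {
        "network": network,
        "interaction_matrix": projected,
        "extended_matrix": extended,
        "datasets": datasets,
        "ensembles": ensembles,
        "normalized": normalized,
    }

    if len(labels) == 2:
        a, b = labels
        dj = stage("differential", differential_jacobian, normalized[a], normalized[b])
        sig = stage(
            "significance", entry_significance, ensembles[a], ensembles[b],
            alpha=config.alpha, procedure=config.ttest, fdr=config.fdr,
        )
        dj.pvalues, dj.significance_mask, dj.alpha = sig.pvalues, sig.significant, sig.alpha
        mio.write_matrix(out / "differential_jacobian.tsv", dj.entries, pool_order, pool_order)
        mio.write_matrix(out / "pvalues.tsv", sig.pvalues, pool_order, pool_order)
        lines = [
            f"# differential Jacobian ranking, conditions {a!r} vs {b!r}",
            f"# alpha={sig.alpha} procedure={sig.procedure} effective_n={sig.effective_n}",
            "rank\teffect_pool\twrt_pool\tdJ\tp\tsignificant",
        ]
        for r, (i, j, v) in enumerate(dj.ranked_entries(), start=1):
            p = sig.pvalues[i, j]
            lines.append(
                f"{r}\t{pool_order[i]}\t{pool_order[j]}\t{v:.6g}\t"
                f"{'NA' if not np.isfinite(p) else format(p, '.3g')}\t"
                f"{bool(sig.significant[i, j])}"
            )
        (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
        manifest["stages"]["significance"] = {
            "procedure": sig.procedure,
            "effective_n": sig.effective_n,
            "fdr": sig.fdr,
        }
        result["differential"] = dj
        result["significance"] = sig

    mio.write_manifest(out / "manifest.json", manifest)
    result["manifest"] = manifest
    return result


def run_from_manifest(manifest_path) -> dict:
    """Re-run a workflow from a previously written manifest."""
    manifest = mio.read_manifest(manifest_path)
    return run_workflow(RunConfig(**manifest["config"]))
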