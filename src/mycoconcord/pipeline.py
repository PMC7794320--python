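"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes the stages — profile processing, diversity and
ordination, the permutation-null SVM, and co-inertia against paired blocks —
on the inputs named in a :class:`PipelineConfig` (typically loaded from
YAML), writing every stage artifact plus a ``manifest.json`` that records
the config, package version, per-stage wall-clock and SHA-256 checksums of
all outputs.  A failing stage leaves earlier outputs intact and is recorded
in the manifest before the error propagates.

The global seed fans out deterministically to per-stage seeds, so identical
config + inputs reproduce identical artifacts for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coinertia import build_triplet, coinertia, coinertia_permutation_test
from .diversity import (
    axis_feature_correlation,
    bray_curtis,
    group_tests,
    pcoa,
    permanova,
    richness,
    shannon,
)
from .io import (
    read_blacklist,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    write_feature_table,
)
from .ml import CVConfig, coefficient_significance, compare_auc_distributions, run_repeated_cv
from .processing import (
    filter_blacklist,
    filter_prevalence,
    hellinger_transform,
    log10_transform,
    logit_transform,
    normalize_relative,
)

#: Per-block transform applied before co-inertia.
_BLOCK_TRANSFORMS = {"bacteriome": "hellinger", "metabolome": "log10", "diet": "none"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records the failure point."""


@dataclass
class PipelineConfig:
    """Input paths, stage toggles and per-stage parameters."""

    mycobiome: Path
    metadata: Path
    output_dir: Path
    taxonomy: Path | None = None
    blacklist: Path | None = None
    bacteriome: Path | None = None
    metabolome: Path | None = None
    diet: Path | None = None
    stages: dict = field(
        default_factory=lambda: {
            "processing": True, "diversity": True, "ml": True, "coinertia": True,
        }
    )
    prevalence_min_fraction: float = 0.10
    permutations: int = 999
    ml_folds: int = 10
    ml_iterations: int = 100
    coinertia_permutations: int = 999
    axis_correlation_axis: int = 2  # 1-based axis number; 2 = secondary axis
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        inputs = raw.get("inputs", {})
        params = raw.get("params", {})
        cfg = cls(
            mycobiome=Path(inputs["mycobiome"]),
            metadata=Path(inputs["metadata"]),
            output_dir=Path(raw["output_dir"]),
            taxonomy=Path(inputs["taxonomy"]) if "taxonomy" in inputs else None,
            blacklist=Path(inputs["blacklist"]) if "blacklist" in inputs else None,
            bacteriome=Path(inputs["bacteriome"]) if "bacteriome" in inputs else None,
            metabolome=Path(inputs["metabolome"]) if "metabolome" in inputs else None,
            diet=Path(inputs["diet"]) if "diet" in inputs else None,
            stages={"processing": True, "diversity": True, "ml": True,
                    "coinertia": True, **raw.get("stages", {})},
            **{k: v for k, v in params.items() if k in {
                "prevalence_min_fraction", "permutations", "ml_folds",
                "ml_iterations", "coinertia_permutations",
                "axis_correlation_axis", "seed"}},
        )
        return cfg

    def validate(self) -> None:
        for name in ("mycobiome", "metadata", "taxonomy", "blacklist",
                     "bacteriome", "metabolome", "diet"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in vars(config).items()
        },
        "stages": {},
    }
    state: dict = {}

    def _record(stage: str, outputs: dict[str, Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "status": "completed",
            "seconds": round(time.monotonic() - t0, 3),
            "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                        for k, p in outputs.items()},
        }

    stage_fns = {
        "processing": _stage_processing,
        "diversity": _stage_diversity,
        "ml": _stage_ml,
        "coinertia": _stage_coinertia,
    }
    try:
        for stage, fn in stage_fns.items():
            if not config.stages.get(stage, False):
                manifest["stages"][stage] = {"status": "skipped"}
                continue
            t0 = time.monotonic()
            outputs = fn(config, state, outdir)
            _record(stage, outputs, t0)
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_processing(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    metadata = read_metadata(config.metadata)
    counts = read_feature_table(
        config.mycobiome, units="counts", sample_ids=list(metadata.index)
    )
    orphans = [s for s in counts.sample_ids if s not in metadata.index]
    if orphans:
        raise ValueError(f"samples missing from metadata: {orphans}")
    counts = counts.subset_samples(
        [s for s in metadata.index if s in counts.sample_ids]
    )
    if config.blacklist:
        counts = filter_blacklist(counts, read_blacklist(config.blacklist))
    relative = normalize_relative(counts)
    filtered = filter_prevalence(relative, config.prevalence_min_fraction)
    state["metadata"] = metadata.loc[counts.sample_ids]
    state["counts"] = counts
    state["filtered_relative"] = filtered
    state["logit"] = logit_transform(filtered)
    state["log10"] = log10_transform(filtered)
    if config.taxonomy:
        state["taxonomy"] = read_taxonomy(config.taxonomy)
    outputs = {
        "filtered_relative": write_feature_table(filtered, outdir / "filtered_relative.tsv"),
        "logit": write_feature_table(state["logit"], outdir / "logit.tsv"),
        "log10": write_feature_table(state["log10"], outdir / "log10.tsv"),
    }
    return outputs


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise PipelineError(f"stage {stage!r} requires the processing stage")
    return state[key]


def _stage_diversity(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    counts = _require(state, "counts", "diversity")
    metadata = state["metadata"]
    groups = metadata["group"]
    alpha = pd.DataFrame({"richness": richness(counts), "shannon": shannon(counts)})
    dist = bray_curtis(state["log10"])
    ordination = pcoa(dist)
    perm = permanova(
        dist, groups, n_permutations=config.permutations,
        seed=config.stage_seed("permanova"),
    )
    axis0 = config.axis_correlation_axis - 1
    corr = axis_feature_correlation(state["log10"], ordination, axis_index=axis0)
    tests = {
        name: vars(group_tests(alpha[name], groups)) for name in ("richness", "shannon")
    }
    outputs: dict[str, Path] = {}
    alpha_path = outdir / "alpha_diversity.tsv"
    alpha.rename_axis("sample_id").to_csv(alpha_path, sep="\t")
    outputs["alpha_diversity"] = alpha_path
    coords_path = outdir / "pcoa_coordinates.tsv"
    ordination.coordinates.to_csv(coords_path, sep="\t")
    outputs["pcoa_coordinates"] = coords_path
    eig_path = outdir / "pcoa_eigenvalues.tsv"
    pd.DataFrame({
        "eigenvalue": ordination.eigenvalues,
    }).rename_axis("axis").to_csv(eig_path, sep="\t")
    outputs["pcoa_eigenvalues"] = eig_path
    perm_path = outdir / "permanova.json"
    perm_path.write_text(json.dumps(vars(perm), indent=2))
    outputs["permanova"] = perm_path
    corr_path = outdir / f"axis{config.axis_correlation_axis}_correlations.tsv"
    corr.to_csv(corr_path, sep="\t")
    outputs["axis_correlations"] = corr_path
    tests_path = outdir / "alpha_group_tests.json"
    tests_path.write_text(json.dumps(tests, indent=2))
    outputs["alpha_group_tests"] = tests_path
    state["ordination"] = ordination
    state["distance"] = dist
    return outputs


def _stage_ml(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    logit = _require(state, "logit", "ml")
    groups = state["metadata"]["group"]
    base = dict(n_folds=config.ml_folds, n_iterations=config.ml_iterations)
    true_res = run_repeated_cv(
        logit, groups,
        CVConfig(**base, shuffle_labels=False, seed=config.stage_seed("ml-true")),
        positive_label="control",
    )
    null_res = run_repeated_cv(
        logit, groups,
        CVConfig(**base, shuffle_labels=True, seed=config.stage_seed("ml-null")),
        positive_label="control",
    )
    signif = coefficient_significance(true_res, null_res)
    if "taxonomy" in state:
        signif = signif.assign(
            lineage=[state["taxonomy"].get(f, "") for f in signif.index]
        )
    auc_cmp = compare_auc_distributions(true_res, null_res)
    outputs: dict[str, Path] = {}
    auc_path = outdir / "ml_auc_distributions.tsv"
    pd.DataFrame({
        "iteration": np.arange(len(true_res.auc)),
        "auc_true": true_res.auc, "auc_shuffled": null_res.auc,
        "sensitivity_true": true_res.sensitivity,
        "specificity_true": true_res.specificity,
    }).to_csv(auc_path, sep="\t", index=False)
    outputs["auc_distributions"] = auc_path
    coef_path = outdir / "ml_coefficients.tsv"
    pd.DataFrame(true_res.coefficients, columns=list(true_res.feature_ids)).to_csv(
        coef_path, sep="\t", index_label="iteration"
    )
    outputs["coefficients"] = coef_path
    signif_path = outdir / "ml_significance.tsv"
    signif.to_csv(signif_path, sep="\t")
    outputs["significance"] = signif_path
    summary_path = outdir / "ml_summary.json"
    summary_path.write_text(json.dumps({
        "auc_true_mean": float(true_res.auc.mean()),
        "auc_true_sd": float(true_res.auc.std(ddof=1)),
        "auc_shuffled_mean": float(null_res.auc.mean()),
        "auc_shuffled_sd": float(null_res.auc.std(ddof=1)),
        "sensitivity_mean": float(true_res.sensitivity.mean()),
        "specificity_mean": float(true_res.specificity.mean()),
        "auc_comparison": vars(auc_cmp),
        "n_significant_features": int(signif["significant"].sum()),
    }, indent=2))
    outputs["summary"] = summary_path
    return outputs


def _stage_coinertia(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    log10_myco = _require(state, "log10", "coinertia")
    outputs: dict[str, Path] = {}
    summaries = {}
    for block_name in ("bacteriome", "metabolome", "diet"):
        path = getattr(config, block_name)
        if path is None:
            continue
        units = {"bacteriome": "relative", "metabolome": "intensity",
                 "diet": "per_week"}[block_name]
        block = read_feature_table(path, units=units,
                                   sample_ids=log10_myco.sample_ids)
        shared = [s for s in log10_myco.sample_ids if s in block.sample_ids]
        if len(shared) < 3:
            raise ValueError(f"fewer than 3 samples shared with {block_name}")
        transform = _BLOCK_TRANSFORMS[block_name]
        if transform == "hellinger":
            block = hellinger_transform(block.subset_samples(shared))
        elif transform == "log10":
            block = log10_transform(block.subset_samples(shared))
        else:
            block = block.subset_samples(shared)
        x = build_triplet(log10_myco.subset_samples(shared))
        y = build_triplet(block)
        result = coinertia(x, y)
        seed = config.stage_seed(f"coinertia-{block_name}")
        perm = coinertia_permutation_test(
            x, y, n_permutations=config.coinertia_permutations, seed=seed
        )
        summaries[block_name] = {
            "rv": result.rv,
            "total_coinertia": result.total_coinertia,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations,
            "n_samples": len(shared),
            "seed": seed,
        }
        scores_path = outdir / f"coinertia_{block_name}_scores.tsv"
        pd.concat(
            {"mycobiome": result.x_scores.iloc[:, :2], block_name: result.y_scores.iloc[:, :2]},
            axis=1,
        ).to_csv(scores_path, sep="\t")
        outputs[f"{block_name}_scores"] = scores_path
    summary_path = outdir / "coinertia_summary.json"
    summary_path.write_text(json.dumps(summaries, indent=2))
    outputs["summary"] = summary_path
    return outputs
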