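"""End-to-end run orchestration: generator -> accelerometry -> features ->
association -> ordination, with artifact hashing and exclusion accounting.

Every stage writes plain-text artifacts into the run directory and the
manifest records a SHA-256 hash per artifact together with the seed and
configuration, so re-running with the same configuration is bit-for-bit
reproducible for the deterministic stages (all of them: every random draw
is seeded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accelerometry, compositional, features, synthetic
from .association import FeatureAssociationModel, ModelSpec
from .errors import ActigutError, ConfigurationError
from .ordination import PartialDBRDA, alpha_regression

__all__ = ["RunConfig", "run_pipeline", "simulate_read_counts"]


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, sizes and seeds of a full pipeline run."""

    out_dir: str = "actigut_run"
    n_participants: int = 120
    n_days: int = 7
    n_species: int = 80
    n_modules: int = 10
    effect_table: tuple[tuple[str, str, float], ...] = ()
    confounder_strength: float = 0.0
    zero_inflation: float = 0.1
    seed: int = 0
    min_valid_days: int = 4
    min_wear_minutes: int = 600
    rarefaction_depth: int = 50_000
    read_depth_range: tuple[int, int] = (55_000, 120_000)
    fdr_threshold: float = 0.05
    n_perm: int = 199

    def __post_init__(self) -> None:
        if self.min_valid_days < 1 or self.min_wear_minutes < 1 or self.rarefaction_depth < 1:
            raise ConfigurationError("thresholds must be positive")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "effect_table" in raw:
            raw["effect_table"] = tuple(tuple(e) for e in raw["effect_table"])
        if "read_depth_range" in raw:
            raw["read_depth_range"] = tuple(raw["read_depth_range"])
        return cls(**raw)

    def synth_config(self) -> synthetic.SynthConfig:
        return synthetic.SynthConfig(
            n_participants=self.n_participants, n_days=self.n_days,
            n_species=self.n_species, n_modules=self.n_modules,
            effect_table=self.effect_table,
            confounder_strength=self.confounder_strength,
            zero_inflation=self.zero_inflation, seed=self.seed,
        )


def simulate_read_counts(
    species_rel: pd.DataFrame, depth_range: tuple[int, int], rng: np.random.Generator
) -> pd.DataFrame:
    """Multinomial read counts per sample at a random sequencing depth."""
    lo, hi = depth_range
    depths = rng.integers(lo, hi + 1, len(species_rel))
    rows = [rng.multinomial(d, p / p.sum()) for d, p in
            zip(depths, species_rel.to_numpy(dtype=float))]
    return pd.DataFrame(rows, index=species_rel.index, columns=species_rel.columns)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "exclusions": {}}
    stage = "init"
    try:
        # ---- stage 1: synthetic data -------------------------------------
        stage = "synth"
        scfg = config.synth_config()
        covariates = synthetic.generate_covariates(scfg)
        counts, gt = synthetic.generate_counts(scfg)
        counts.to_csv(out / "counts.csv", index=False)
        covariates.to_csv(out / "covariates.csv")
        with open(out / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump({"effect_table": [list(e) for e in gt.effect_table],
                            "covariate_effects": gt.covariate_effects}, fh)
        manifest["stages"]["synth"] = ["counts.csv", "covariates.csv", "ground_truth.yaml"]

        # ---- stage 2: accelerometry --------------------------------------
        stage = "accel"
        comp, excl = accelerometry.summarize_participants(
            counts, min_valid_days=config.min_valid_days,
            min_wear_minutes=config.min_wear_minutes)
        alr = accelerometry.alr_transform(comp)
        alr = accelerometry.standardize_alr(alr)
        timeuse = comp.merge(alr, on="participant_id").set_index("participant_id")
        timeuse.to_csv(out / "timeuse.tsv", sep="\t")
        excl.to_csv(out / "accel_exclusions.tsv", sep="\t", index=False)
        manifest["stages"]["accel"] = ["timeuse.tsv", "accel_exclusions.tsv"]
        manifest["exclusions"]["accelerometry"] = {
            "participants_in": int(counts["participant_id"].nunique()),
            "retained": int(len(timeuse)),
            "insufficient_valid_days": int(len(excl)),
        }

        # ---- stage 3: microbiome features --------------------------------
        stage = "features"
        cov_kept = covariates.loc[timeuse.index]
        exposures = timeuse[[c for c in timeuse.columns if c.startswith("z_alr_")]]
        species_rel, genes = synthetic.generate_microbiome(scfg, exposures, cov_kept)
        species_rel.to_csv(out / "species_relabund.tsv", sep="\t")
        genes.to_csv(out / "orthologs.tsv", sep="\t")

        rng = np.random.default_rng([config.seed, 10])
        reads = simulate_read_counts(species_rel, config.read_depth_range, rng)
        rarefied, rare_report = features.rarefy(reads, config.rarefaction_depth,
                                                np.random.default_rng([config.seed, 11]))
        if rarefied.empty:
            raise ActigutError(
                f"rarefaction depth {config.rarefaction_depth} exceeds every sample total; "
                "no samples left for diversity analysis")
        alpha = features.alpha_diversity_table(rarefied)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        bc = features.bray_curtis(species_rel)
        bc.to_csv(out / "bray_curtis.tsv", sep="\t")

        defs = synthetic.synthetic_module_definitions(scfg)
        features.write_module_definitions(defs, out / "module_definitions.txt")
        modules_raw, mod_report = features.score_modules(genes, defs)
        module_rel = modules_raw.div(modules_raw.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)

        sp_filt, sp_report = compositional.prevalence_filter(species_rel, kind="species")
        mod_filt, _ = compositional.prevalence_filter(module_rel, kind="module")
        sp_clr = compositional.clr_transform(sp_filt, compositional.ClrPolicy.species())
        mod_clr = compositional.clr_transform(mod_filt, compositional.ClrPolicy.modules())
        sp_clr.to_csv(out / "species_clr.tsv", sep="\t")
        mod_clr.to_csv(out / "modules_clr.tsv", sep="\t")
        manifest["stages"]["features"] = [
            "species_relabund.tsv", "orthologs.tsv", "alpha_diversity.tsv",
            "bray_curtis.tsv", "module_definitions.txt", "species_clr.tsv", "modules_clr.tsv",
        ]
        manifest["exclusions"]["rarefaction"] = {
            "samples_in": int(len(reads)),
            "retained": int(len(rarefied)),
            "below_depth": int((~rare_report["included"]).sum()),
        }
        manifest["exclusions"]["prevalence_filter"] = {
            "species_in": int(species_rel.shape[1]),
            "species_kept": int(sp_filt.shape[1]),
            "modules_in": int(module_rel.shape[1]),
            "modules_kept": int(mod_filt.shape[1]),
        }

        # ---- stage 4: association ----------------------------------------
        stage = "assoc"
        cov_full = pd.concat([cov_kept, timeuse[["wear_minutes", "pct_weekend_wear"]]], axis=1)
        spec = ModelSpec(fdr_threshold=config.fdr_threshold)
        results = {}
        for label, table in (("species", sp_clr), ("modules", mod_clr)):
            res = FeatureAssociationModel(table, exposures, cov_full, spec).fit()
            res.table.to_csv(out / f"assoc_{label}.tsv", sep="\t")
            results[label] = res
        manifest["stages"]["assoc"] = ["assoc_species.tsv", "assoc_modules.tsv"]
        manifest["exclusions"]["association"] = {
            "incomplete_covariates": results["species"].model.n_excluded_incomplete,
        }

        # ---- stage 5: ordination -----------------------------------------
        stage = "ordinate"
        alpha_tab = alpha_regression(alpha, exposures.loc[alpha.index],
                                     cov_full.loc[alpha.index], list(spec.covariates))
        alpha_tab.to_csv(out / "alpha_regression.tsv", sep="\t", index=False)
        from .association import design_matrix
        cond = design_matrix(cov_full, list(spec.covariates)).drop(columns=["Intercept"])
        ord_res = PartialDBRDA(bc, exposures, cond).fit(
            n_perm=config.n_perm, seed=config.seed)
        with open(out / "ordination.json", "w") as fh:
            json.dump({
                "total_inertia": ord_res.total_inertia,
                "conditioned_inertia": ord_res.conditioned_inertia,
                "constrained_inertia": ord_res.constrained_inertia,
                "residual_inertia": ord_res.residual_inertia,
                "adj_r2": ord_res.adj_r2,
                "p_value": ord_res.p_value,
                "n_permutations": ord_res.n_permutations,
                "per_constraint": ord_res.per_constraint.to_dict(orient="index"),
            }, fh, indent=2, sort_keys=True)
        manifest["stages"]["ordinate"] = ["alpha_regression.tsv", "ordination.json"]
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise ActigutError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    artifacts = {}
    for files in manifest["stages"].values():
        for f in files:
            artifacts[f] = _sha256(out / f)
    manifest["artifact_sha256"] = artifacts
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
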