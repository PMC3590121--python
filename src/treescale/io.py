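"""File I/O, validation, run manifests and pipeline orchestration.

Tabular data travels as CSV, structured results as JSON, configuration
as YAML — all plain text and diffable.  A run manifest captures the
config snapshot, seeds and output hashes so any artifact can be
regenerated from manifest plus raw input alone.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import make_report
from .model import ModelConfig
from .ppc import pb_statistics
from .preprocess import (
    RECORD_COLUMNS,
    TRAITS,
    ObservationTable,
    TopologyError,
    filter_and_log,
)
from .sampler import (
    PosteriorSamples,
    SamplerConfig,
    heidelberger_welch,
    rhat,
    run_mcmc,
    summarize_level,
)
from .synthetic import GeneratorConfig, generate_dataset, to_observation_table

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Input table does not match the branch-record schema."""


class ConvergenceError(RuntimeError):
    """Convergence gate failed (R-hat above threshold)."""


# ---------------------------------------------------------------- records


def read_branch_csv(path) -> pd.DataFrame:
    """Read and validate a branch-record CSV.

    Raises :class:`SchemaError` for missing columns, duplicate
    (tree_id, branch_id) pairs or non-positive diameters, and
    :class:`~treescale.preprocess.TopologyError` for orphan parents —
    each naming the offending row.
    """
    df = pd.read_csv(path, dtype={"species_id": str, "tree_id": str,
                                  "branch_id": str, "parent_id": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    dup = df.duplicated(subset=["tree_id", "branch_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(f"{path}: duplicate (tree_id, branch_id) at row {row}")
    bad_d = ~(df["diameter_cm"] > 0)
    if bad_d.any():
        row = int(np.flatnonzero(bad_d.to_numpy())[0])
        raise SchemaError(f"{path}: non-positive diameter at row {row}")
    for tree, group in df.groupby("tree_id", sort=False):
        ids = set(group["branch_id"])
        for idx, p in group["parent_id"].items():
            if pd.isna(p) or p == "":
                continue
            if p not in ids:
                raise TopologyError(
                    f"{path}: row {idx}: parent_id {p!r} absent from tree {tree!r}"
                )
    return df


def write_branch_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_observation_csv(table: ObservationTable, path, report_path=None) -> None:
    table.to_frame().to_csv(path, index=False)
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(table.meta, fh, indent=2)


def read_observation_csv(path) -> ObservationTable:
    return ObservationTable.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------- samples


def write_posterior_samples(samples: PosteriorSamples, out_dir,
                            include_latents: bool = True) -> None:
    """Persist draws as one CSV per chain plus a JSON parameter registry."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names, arr = samples.flat(include_latents=include_latents)
    for c in range(samples.n_chains):
        pd.DataFrame(arr[c], columns=names).to_csv(
            out / f"chain_{c}.csv", index=False
        )
    samples.registry().to_json(out / "registry.json", orient="records")
    with open(out / "meta.json", "w") as fh:
        json.dump(
            {
                "trait_names": list(samples.trait_names),
                "species_labels": list(samples.species_labels),
                "tree_labels": list(samples.tree_labels),
                "tree_species": samples.tree_species.tolist(),
                "acceptance": samples.acceptance,
                "sampler_config": samples.sampler_config,
                "model_config": samples.model_config,
                "include_latents": include_latents,
            },
            fh,
            indent=2,
        )


def read_posterior_samples(sample_dir) -> PosteriorSamples:
    """Rebuild a PosteriorSamples object from a persisted directory."""
    d = Path(sample_dir)
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    traits = tuple(meta["trait_names"])
    species = tuple(meta["species_labels"])
    trees = tuple(meta["tree_labels"])
    chains = sorted(d.glob("chain_*.csv"))
    frames = [pd.read_csv(p) for p in chains]
    C, K = len(frames), len(frames[0])
    S, T, J = len(species), len(trees), len(traits)

    def block(prefix, labels=None):
        if labels is None:
            cols = [f"{prefix}[{tr}]" for tr in traits]
            out = np.empty((C, K, J))
            for c, f in enumerate(frames):
                out[c] = f[cols].to_numpy()
            return out
        out = np.empty((C, K, len(labels), J))
        for c, f in enumerate(frames):
            for i, lab in enumerate(labels):
                out[c, :, i, :] = f[[f"{prefix}[{lab},{tr}]" for tr in traits]].to_numpy()
        return out

    Sigma = np.empty((C, K, J, J))
    for c, f in enumerate(frames):
        for i, ti in enumerate(traits):
            for j, tj in enumerate(traits):
                a, b = (i, j) if j >= i else (j, i)
                Sigma[c, :, i, j] = f[f"Sigma[{traits[a]},{traits[b]}]"].to_numpy()
    latent_cols = [c for c in frames[0].columns if c.startswith("log_rho[")]
    log_rho = None
    if latent_cols:
        log_rho = np.empty((C, K, len(latent_cols)))
        for c, f in enumerate(frames):
            log_rho[c] = f[latent_cols].to_numpy()
    return PosteriorSamples(
        trait_names=traits,
        species_labels=species,
        tree_labels=trees,
        tree_species=np.asarray(meta["tree_species"], dtype=int),
        global_alpha=block("global_alpha"),
        global_b=block("global_b"),
        species_alpha=block("species_alpha", species),
        species_b=block("species_b", species),
        tree_alpha=block("tree_alpha", trees),
        tree_b=block("tree_b", trees),
        sd_tree_alpha=block("sd_tree_alpha"),
        sd_tree_b=block("sd_tree_b"),
        sd_species_alpha=block("sd_species_alpha"),
        sd_species_b=block("sd_species_b"),
        Sigma=Sigma,
        log_rho=log_rho,
        acceptance=meta.get("acceptance", {}),
        sampler_config=meta.get("sampler_config", {}),
        model_config=meta.get("model_config", {}),
    )


def write_posterior_summary(samples: PosteriorSamples, out_dir) -> dict:
    """Write exponent summaries, variance components and diagnostics.

    Produces ``exponent_summary.csv`` (per trait x level x unit),
    ``variance_components.csv`` (per trait: tree- and species-level
    exponent variances, posterior mean with 95% CI), and
    ``diagnostics.json`` (R-hat and Heidelberger-Welch per global
    parameter).  Returns the written summary paths.
    """
    if samples.n_draws == 0:
        raise ValueError("no posterior draws to summarize")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frames = []
    for trait in samples.trait_names:
        for level in ("tree", "species", "global"):
            for kind in ("alpha", "b"):
                s = summarize_level(samples, level, trait, kind)
                s.insert(0, "kind", kind)
                s.insert(0, "level", level)
                s.insert(0, "trait", trait)
                frames.append(s)
    summary = pd.concat(frames, ignore_index=True)
    summary_path = out / "exponent_summary.csv"
    summary.to_csv(summary_path, index=False)

    rows = []
    for j, trait in enumerate(samples.trait_names):
        row = {"trait": trait}
        for label, arr in (
            ("tree_level_variance", samples.sd_tree_b[..., j] ** 2),
            ("species_level_variance", samples.sd_species_b[..., j] ** 2),
        ):
            pooled = arr.ravel()
            row[f"{label}_mean"] = float(pooled.mean())
            row[f"{label}_q2_5"] = float(np.quantile(pooled, 0.025))
            row[f"{label}_q97_5"] = float(np.quantile(pooled, 0.975))
        rows.append(row)
    var_path = out / "variance_components.csv"
    pd.DataFrame(rows).to_csv(var_path, index=False)

    diag: dict = {"rhat": {}, "heidelberger": {}}
    for kind in ("alpha", "b"):
        arr = getattr(samples, f"global_{kind}")
        for j, trait in enumerate(samples.trait_names):
            name = f"global_{kind}[{trait}]"
            chains = arr[..., j]
            diag["rhat"][name] = float(rhat(chains))
            if samples.n_draws >= 100:
                hw = [heidelberger_welch(chains[c]) for c in range(samples.n_chains)]
                diag["heidelberger"][name] = [
                    {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                     for k, v in h.items()}
                    for h in hw
                ]
    diag_path = out / "diagnostics.json"
    with open(diag_path, "w") as fh:
        json.dump(diag, fh, indent=2)
    return {"summary": summary_path, "variance": var_path, "diagnostics": diag_path,
            "rhat": diag["rhat"]}


# ---------------------------------------------------------------- manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seeds: dict, files=()) -> Path:
    out = Path(out_dir)
    manifest = {
        "package": "treescale",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds,
        "files": {
            str(Path(f).relative_to(out)): _sha256(Path(f)) for f in files
        },
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


# ---------------------------------------------------------------- pipeline

DEFAULT_CONFIG: dict = {
    "generator": {},          # GeneratorConfig overrides; {} = study design
    "mode": "model-exact",    # or "raw-field"
    "input_csv": None,        # fit real records instead of simulating
    "dry_wet_ratios": None,   # per-species mapping for input_csv mode
    "model": {},              # ModelConfig overrides
    "sampler": {"n_chains": 3, "n_iterations": 6000, "burn_in": 2000, "thin": 2},
    "ppc": {"n_replicates": 400},
    "rhat_threshold": 1.1,
    "min_diameter": 2.0,
    "write_samples": False,
}


def load_config(path=None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if k not in cfg:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(cfg[k], dict) and isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


@dataclass
class PipelineResult:
    status: int
    out_dir: Path
    rhat: dict
    paths: dict


def run_pipeline(config=None, seed: int | None = None, out_dir="treescale_run") -> PipelineResult:
    """Generate/ingest -> preprocess -> fit -> diagnostics -> ppc -> compare.

    Returns status 0 on success or 3 when the R-hat convergence gate
    fails (partial outputs are still written).
    """
    cfg = load_config(config) if not isinstance(config, dict) else {**load_config(), **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    gen_overrides = dict(cfg["generator"] or {})
    if seed is not None:
        gen_overrides["seed"] = int(seed)
    truth = None
    if cfg["input_csv"]:
        records = read_branch_csv(cfg["input_csv"])
        ratios = cfg["dry_wet_ratios"]
        if not ratios:
            raise ValueError("dry_wet_ratios required when fitting an input CSV")
        table = filter_and_log(records, ratios, cfg["min_diameter"])
    else:
        gcfg = GeneratorConfig.from_dict(gen_overrides) if gen_overrides else GeneratorConfig()
        records, truth = generate_dataset(gcfg, mode=cfg["mode"])
        write_branch_csv(records, out / "dataset.csv")
        truth.to_json(out / "truth.json")
        paths["dataset"] = out / "dataset.csv"
        if cfg["mode"] == "model-exact":
            table = to_observation_table(records, truth)
        else:
            ratios = {
                f"sp{s + 1}": r for s, r in enumerate(gcfg.dry_wet_ratios)
            }
            table = filter_and_log(records, ratios, cfg["min_diameter"])
    write_observation_csv(table, out / "observations.csv", out / "preprocess_report.json")
    paths["observations"] = out / "observations.csv"

    mcfg = ModelConfig.from_dict(cfg["model"]) if cfg["model"] else ModelConfig()
    s_over = dict(cfg["sampler"])
    if seed is not None:
        s_over["seed"] = int(seed)
    scfg = SamplerConfig(**s_over)
    samples = run_mcmc(table, mcfg, scfg)
    if cfg["write_samples"]:
        write_posterior_samples(samples, out / "samples")
        paths["samples"] = out / "samples"

    written = write_posterior_summary(samples, out)
    paths.update({k: written[k] for k in ("summary", "variance", "diagnostics")})

    ppc_res = pb_statistics(
        samples, table, n_replicates=cfg["ppc"]["n_replicates"],
        seed=scfg.seed,
    )
    ppc_res.to_frame().to_csv(out / "ppc.csv", index=False)
    ppc_res.to_json(out / "ppc.json")
    paths["ppc"] = out / "ppc.csv"

    report = make_report(samples)
    report.inclusion_table.to_csv(out / "model_comparison.csv", index=False)
    report.contrasts.to_csv(out / "species_contrasts.csv", index=False)
    with open(out / "model_comparison.json", "w") as fh:
        json.dump(
            {"percentages": report.percentages, "best": list(report.best)},
            fh, indent=2,
        )
    with open(out / "report.txt", "w") as fh:
        fh.write(report.to_text() + "\n")
    paths["comparison"] = out / "model_comparison.csv"

    file_list = [p for p in paths.values() if Path(p).is_file()]
    write_manifest(
        out,
        config={k: v for k, v in cfg.items() if k != "input_csv"} |
               {"input_csv": str(cfg["input_csv"]) if cfg["input_csv"] else None},
        seeds={"sampler": scfg.seed,
               "generator": gen_overrides.get("seed", GeneratorConfig().seed)},
        files=file_list,
    )

    gate = cfg["rhat_threshold"]
    bad = {k: v for k, v in written["rhat"].items() if v > gate}
    status = 0
    if bad:
        log.error("convergence gate failed (R-hat > %.3f): %s", gate, bad)
        status = 3
    return PipelineResult(status=status, out_dir=out, rhat=written["rhat"], paths=paths)
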