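"""End-to-end orchestration: cohort -> screening -> GCA -> windows -> ALPS.

A run is driven by a plain key/value (YAML) config, writes every artifact
into a fresh run directory (never overwritten) and records provenance:
config hash, seeds, package version and the cognition-ordering hash that
every causal statement is conditioned on.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .group_stats import region_selection, velocity_alps_table
from .pseudotime_gca import build_pseudotime, permutation_significance
from .sliding_window import sliding_gca
from .synthetic_data import CohortSpec, generate_cohort

DEFAULT_CONFIG = {
    "stages": ["cohort", "stats", "gca", "sliding", "alps"],
    "cohort_csv": None,  # path; if absent, a synthetic cohort is generated
    "seed": 0,
    "n_perm": 1000,
    "window_length": 50,
    "alpha": 0.05,
    "fdr_q": 0.05,
    "restrict_to_selected": True,
    "cohort": {},  # CohortSpec overrides for synthetic mode
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = {**DEFAULT_CONFIG, **user}
    config["cohort"] = {**DEFAULT_CONFIG["cohort"], **(user.get("cohort") or {})}
    return config


def validate_config(config: dict) -> dict:
    config = {**DEFAULT_CONFIG, **config}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if config["cohort_csv"] is not None and not Path(config["cohort_csv"]).exists():
        raise FileNotFoundError(f"cohort_csv not found: {config['cohort_csv']}")
    return config


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured stages; returns the run directory."""
    config = validate_config(config)
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"run directory {out} already exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    seed = int(config["seed"])
    report = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "stages_run": [],
        "defaults": {
            "ordering": "mmse desc, ravlt_immediate desc, subject_id asc",
            "gca": "bivariate lag-1, z-scored series, no intercept",
            "p_value": "add-one permutation convention",
            "ancova": "nested linear-model F, covariates age/sex/education",
        },
    }

    if config["cohort_csv"]:
        cohort = pd.read_csv(config["cohort_csv"])
    elif "cohort" in stages:
        cohort = generate_cohort(CohortSpec(seed=seed, **config["cohort"]))
        cohort.to_csv(out / "cohort.csv", index=False)
        report["stages_run"].append("cohort")
    else:
        raise ValueError("no cohort source: provide cohort_csv or enable 'cohort'")

    pseudo = build_pseudotime(cohort)
    report["ordering_hash"] = pseudo.ordering_hash

    selected = list(pseudo.region_names)
    if "stats" in stages:
        screen = region_selection(cohort, q_threshold=config["fdr_q"])
        screen.to_csv(out / "region_screen.csv", index=False)
        if config["restrict_to_selected"]:
            selected = screen.loc[screen["selected"], "region"].tolist()
        report["stages_run"].append("stats")
        report["n_selected_regions"] = len(selected)

    drivers = []
    if "gca" in stages:
        if len(selected) < 2:
            raise RuntimeError("gca stage: fewer than 2 regions after screening")
        perm = permutation_significance(
            pseudo,
            n_perm=int(config["n_perm"]),
            seed=seed,
            alpha=config["alpha"],
            regions=selected,
        )
        perm.observed.to_dataframe().to_csv(out / "gca_matrix.csv")
        perm.scores.table.to_csv(out / "driving_scores.csv", index=False)
        pd.DataFrame(
            perm.coefficient_p,
            index=perm.observed.region_names,
            columns=perm.observed.region_names,
        ).to_csv(out / "coefficient_p.csv")
        drivers = perm.significant_positive()
        report["stages_run"].append("gca")
        report["positive_driving_regions"] = drivers
        report["negative_driving_regions"] = perm.significant_negative()

    if "sliding" in stages and drivers:
        win = sliding_gca(
            pseudo,
            drivers,
            window_length=int(config["window_length"]),
            n_perm=int(config["n_perm"]),
            seed=seed + 1,
            alpha=config["alpha"],
        )
        win.to_dataframe().to_csv(out / "sliding_gca.csv", index=False)
        if win.group_counts is not None:
            win.group_counts.to_csv(out / "window_group_counts.csv")
        report["stages_run"].append("sliding")

    if "alps" in stages and "alps_index" in cohort.columns:
        assoc = velocity_alps_table(cohort)
        assoc.to_csv(out / "velocity_alps.csv", index=False)
        report["stages_run"].append("alps")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return out
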