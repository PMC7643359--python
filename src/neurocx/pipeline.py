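"""Pipeline orchestration: simulate -> epochs -> mMSE -> features -> gf -> PLSR.

One structured config drives every stage; a master seed spawns
independent child seeds per stage, all intermediate artifacts are plain
CSV, and a resolved-config snapshot plus per-artifact checksums make
reruns verifiable: the same config reproduces byte-identical outputs.
Each stage can also be run standalone on the previous stage's files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import inference, io, synthetic
from .entropy import MMSEParams, subject_profile
from .exceptions import ConfigError
from .schema import CHANNEL_SETS, SET_NAMES, TEST_NAMES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run."""

    out_dir: str = "neurocx_run"
    # inputs: either simulate, or point at existing artifacts
    simulate: bool = False
    recordings_dir: str | None = None
    cohort_csv: str | None = None
    features_csv: str | None = None
    # simulation
    n_subjects: int = 20
    n_samples: int = 10_240
    pink_range: tuple[float, float] = (0.0, 0.4)
    alpha_amp: float = 0.0
    gf_noise_sd: float = 0.2
    # epoching
    epoch_length: int = io.DEFAULT_EPOCH_LENGTH
    amp_threshold: float | None = io.DEFAULT_AMP_THRESHOLD
    # mMSE
    m: int = 2
    tau: int = 1
    r: float = 0.15
    eps_max: int = 12
    variant: str = "per_channel"
    sets: tuple[str, ...] = SET_NAMES
    # inference
    groups: tuple[str, ...] = ("all",)
    n_components: int | None = None
    component_method: str = "local_min"
    max_components: int = 10
    n_perm: int = 10_000
    n_boot: int = 10_000
    ci_method: str = "percentile"
    alpha: float = 0.05
    # master seed
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("pink_range", "sets", "groups"):
            value = getattr(cfg, name)
            if isinstance(value, list):
                object.__setattr__(cfg, name, tuple(value))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def mmse_params(self) -> MMSEParams:
        return MMSEParams(
            M=self.m, tau=self.tau, r=self.r, eps_max=self.eps_max, variant=self.variant
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Report-only validation: returns a list of findings.

    Findings prefixed ``ERROR`` make :func:`run_pipeline` abort before
    any compute; ``WARN`` findings are informational (e.g. the
    p*10^max(M) sample-count guideline at the coarsest scale).
    """
    findings: list[str] = []
    unknown_sets = [s for s in config.sets if s not in CHANNEL_SETS]
    if unknown_sets:
        findings.append(f"ERROR: unknown channel set name(s): {unknown_sets}")
    unknown_groups = [g for g in config.groups if g not in ("all", "men", "women")]
    if unknown_groups:
        findings.append(f"ERROR: unknown group(s): {unknown_groups}")
    if not config.simulate and config.features_csv is None:
        if config.recordings_dir is None or config.cohort_csv is None:
            findings.append(
                "ERROR: no inputs: set simulate=true, or provide "
                "recordings_dir + cohort_csv, or features_csv"
            )
        else:
            if not Path(config.recordings_dir).exists():
                findings.append(f"ERROR: recordings_dir not found: {config.recordings_dir}")
            if not Path(config.cohort_csv).exists():
                findings.append(f"ERROR: cohort_csv not found: {config.cohort_csv}")
    if config.features_csv is not None and not Path(config.features_csv).exists():
        findings.append(f"ERROR: features_csv not found: {config.features_csv}")

    p = 4  # channels per set
    n_coarse = config.epoch_length // config.eps_max
    recommended = p * 10**config.m
    if n_coarse < recommended:
        findings.append(
            f"WARN: only {n_coarse} samples at scale {config.eps_max}; "
            f"sample-count guideline p*10^m = {recommended} is violated"
        )
    if config.simulate and config.n_samples < config.epoch_length:
        findings.append(
            f"ERROR: simulated n_samples {config.n_samples} < epoch_length "
            f"{config.epoch_length}"
        )
    return findings


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunResult:
    """Artifacts of one pipeline run."""

    out_dir: Path
    profiles_csv: Path | None
    features_csv: Path
    reports: dict[str, Path]
    checksums: dict[str, str]
    findings: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute every stage of the pipeline from one config."""
    findings = validate_config(config)
    errors = [f for f in findings if f.startswith("ERROR")]
    if errors:
        raise ConfigError("; ".join(errors))
    for f in findings:
        logger.warning(f)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    sim_seed, gf_seed, perm_seed, boot_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )
    checksums: dict[str, str] = {}
    params = config.mmse_params()

    # ----- stage: inputs (simulate or load) --------------------------------
    profiles_csv: Path | None = None
    if config.features_csv is not None:
        table = io.read_feature_table(config.features_csv)
        logger.info("stage features: loaded %d subjects from %s", len(table), config.features_csv)
    else:
        if config.simulate:
            spec_map = synthetic.linked_signal_specs(
                config.n_subjects,
                pink_range=config.pink_range,
                n_samples=config.n_samples,
                alpha_amp=config.alpha_amp,
                seed=sim_seed,
            )
            cohort_spec = synthetic.CohortSpec(
                n_subjects=config.n_subjects, noise_sd=config.gf_noise_sd, seed=sim_seed
            )
            recordings, gf = synthetic.generate_end_to_end_cohort(cohort_spec, spec_map)
            scores = synthetic.generate_test_scores(gf.to_numpy(), seed=gf_seed)
            cohort = pd.DataFrame(
                {
                    "subject_id": gf.index,
                    "sex": synthetic._sex_labels(len(gf)),
                    "gf": gf.to_numpy(),
                }
            )
            cohort = pd.concat([cohort, scores], axis=1)
            synthetic.write_cohort(recordings, cohort, out / "cohort")
            logger.info("stage simulate: wrote %d subjects", len(recordings))
            rec_dir, cohort_path = out / "cohort", out / "cohort" / "cohort.csv"
        else:
            rec_dir, cohort_path = Path(config.recordings_dir), Path(config.cohort_csv)
            recordings = None

        cohort = pd.read_csv(cohort_path)
        if "subject_id" not in cohort.columns:
            raise ConfigError("cohort CSV needs a subject_id column")
        cohort["subject_id"] = cohort["subject_id"].astype(str)

        # ----- stage: gf (factor from test scores when available) ----------
        if all(t in cohort.columns for t in TEST_NAMES):
            factor = inference.extract_gf_factor(cohort)
            cohort["gf"] = factor.scores
            logger.info(
                "stage gf: factor explains %.2f%% (eigenvalue %.3f)",
                factor.explained_variance_pct,
                factor.eigenvalue,
            )
        elif "gf" not in cohort.columns:
            raise ConfigError("cohort CSV needs either gf or the six test-score columns")
        cohort.to_csv(out / "gf.csv", index=False, float_format="%.12g")
        checksums["gf.csv"] = _checksum(out / "gf.csv")

        # ----- stage: epochs + mMSE ----------------------------------------
        rows = []
        profiles: dict[str, dict[str, object]] = {}
        for subject in cohort["subject_id"]:
            if recordings is not None and subject in recordings:
                rec = recordings[subject]
            else:
                rec = io.read_recording(rec_dir / f"{subject}.csv", subject_id=subject)
            epochs = io.extract_epochs(
                rec, epoch_length=config.epoch_length, amp_threshold=config.amp_threshold
            )
            per_set = {}
            for set_name in config.sets:
                mats = [
                    io.select_channel_set(ep, set_name, rec.channel_labels)
                    for ep in epochs
                ]
                prof = subject_profile(
                    mats, params, channel_set=set_name, subject_id=subject
                )
                per_set[set_name] = prof
                for scale, (value, n_ep) in enumerate(
                    zip(prof.values, prof.n_epochs), start=1
                ):
                    rows.append(
                        {
                            "subject_id": subject,
                            "set": set_name,
                            "scale": scale,
                            "value": value,
                            "n_epochs": int(n_ep),
                        }
                    )
            profiles[subject] = per_set
        profiles_csv = out / "profiles.csv"
        pd.DataFrame(rows).to_csv(profiles_csv, index=False, float_format="%.12g")
        checksums["profiles.csv"] = _checksum(profiles_csv)
        logger.info("stage mmse: %d profiles", len(profiles) * len(config.sets))

        # ----- stage: features ---------------------------------------------
        gf_map = cohort.set_index("subject_id")["gf"]
        sex_map = cohort.set_index("subject_id")["sex"]
        table = feat.assemble_features(profiles, gf_map, sex_map)

    features_csv = out / "features.csv"
    io.write_feature_table(table, features_csv)
    checksums["features.csv"] = _checksum(features_csv)

    # ----- stage: PLSR per group ------------------------------------------
    reports: dict[str, Path] = {}
    for group in config.groups:
        cfg = inference.AnalysisConfig(
            n_components=config.n_components,
            max_components=config.max_components,
            component_method=config.component_method,  # type: ignore[arg-type]
            n_perm=config.n_perm,
            alpha=config.alpha,
            n_boot=config.n_boot,
            ci_method=config.ci_method,  # type: ignore[arg-type]
            seed=boot_seed,
        )
        result = inference.run_group_analysis(table, group, cfg)
        path = out / f"report_{group}.csv"
        result.report.frame.to_csv(path, index=False, float_format="%.12g")
        checksums[f"report_{group}.csv"] = _checksum(path)
        reports[group] = path
        logger.info(
            "stage plsr[%s]: %d LV, %d relevant predictors",
            group,
            result.results.n_components,
            int(result.report.frame["relevant"].sum()),
        )

    config.to_yaml(out / "resolved_config.yaml")
    with open(out / "checksums.json", "w") as fh:
        json.dump(checksums, fh, indent=2, sort_keys=True)
    return RunResult(
        out_dir=out,
        profiles_csv=profiles_csv,
        features_csv=features_csv,
        reports=reports,
        checksums=checksums,
        findings=findings,
    )
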