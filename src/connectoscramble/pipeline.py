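"""End-to-end experiment orchestration with a single master seed.

An :class:`ExperimentConfig` fixes the cohort (synthetic spec or container
paths), the balancing, member and ensemble settings, the networks file and
the output directory. ``run_full_experiment`` executes the stages in order —
balance -> ensemble -> CAM -> occlusion -> growth fit — logging every
stage's seeds and writing each stage's outputs as it completes, so a failed
stage leaves its predecessors' results on disk. All stage seeds derive
deterministically from the master seed; rerunning an identical config
reproduces all outputs bit for bit on one device.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import atlas, balancing, cohort, ensemble, io, member, occlusion, saliency

log = logging.getLogger("connectoscramble")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one full experiment."""

    out_dir: str = "results"
    master_seed: int = 0
    # cohort: either a synthetic spec ...
    n_subjects: int = 600
    effect_network: str | None = "SAL"
    effect_condition: str = "rest"
    effect_size: float = 1.0
    effect_bands: tuple[int, ...] = (0, 1, 2)
    # ... or paths to a phenotype CSV + connectome container
    phenotypes_path: str | None = None
    connectomes_path: str | None = None
    # stage settings
    networks_path: str | None = None
    covariates: tuple[str, ...] = balancing.DEFAULT_COVARIATES
    p_threshold: float = 0.10
    n_members: int = 10
    epochs: int = 10
    batch_size: int = 64
    occlusion_k: int = 0              # members per occlusion arm; 0 = skip
    occlusion_modes: tuple[str, ...] = ("inner",)
    occlusion_networks: tuple[str, ...] = ("SAL",)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("effect_bands", "covariates", "occlusion_modes",
                    "occlusion_networks"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def validate_config(config: ExperimentConfig) -> list[str]:
    """Issues preventing a run; empty list iff runnable."""
    issues = []
    if config.n_members < 1:
        issues.append("n_members must be >= 1")
    if config.epochs < 1:
        issues.append("epochs must be >= 1")
    if not 0.0 < config.p_threshold < 1.0:
        issues.append("p_threshold must lie in (0, 1)")
    if config.occlusion_k < 0:
        issues.append("occlusion_k must be >= 0")
    if (config.phenotypes_path is None) != (config.connectomes_path is None):
        issues.append("phenotypes_path and connectomes_path must be set together")
    if config.phenotypes_path is None and config.n_subjects < 60:
        issues.append("n_subjects too small to split 4:1:1 with both classes")
    for path_attr in ("phenotypes_path", "connectomes_path", "networks_path"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            issues.append(f"{path_attr} does not exist: {p}")
    try:
        networks = atlas.load_networks(config.networks_path)
    except Exception as exc:
        issues.append(f"networks file invalid: {exc}")
        networks = {}
    if config.effect_network is not None and networks and (
        config.effect_network not in networks
    ):
        issues.append(f"effect_network {config.effect_network!r} not defined")
    for name in config.occlusion_networks:
        if networks and name not in networks:
            issues.append(f"occlusion network {name!r} not defined")
    for mode in config.occlusion_modes:
        if mode not in ("inner", "connecting"):
            issues.append(f"occlusion mode {mode!r} not inner|connecting")
    return issues


def _stage_seeds(master_seed: int) -> dict[str, int]:
    names = ("cohort", "balance", "ensemble", "occlusion")
    seqs = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2 ** 31))
            for n, s in zip(names, seqs)}


def load_or_generate_cohort(config: ExperimentConfig, seeds: dict):
    """(table, connectome stacks) from container paths or the synthetic spec."""
    if config.phenotypes_path is not None:
        table = io.load_phenotypes(config.phenotypes_path)
        stacks, _ = io.load_connectomes(
            config.connectomes_path, table["subject_id"]
        )
        return table, stacks
    networks = atlas.load_networks(config.networks_path)
    effects = ()
    if config.effect_network is not None and config.effect_size != 0.0:
        effects = (cohort.EffectEntry(
            nodes=networks[config.effect_network].nodes,
            condition=config.effect_condition,
            d=config.effect_size,
            bands=config.effect_bands,
        ),)
    spec = cohort.CohortSpec(
        n_subjects=config.n_subjects, seed=seeds["cohort"],
        effect_plan=effects,
    )
    table = cohort.generate_phenotypes(spec)
    stacks = cohort.generate_connectomes(table, spec)
    return table, stacks


def run_full_experiment(config: ExperimentConfig) -> Path:
    """Execute all stages; returns the output directory.

    Outputs: phenotypes.csv, balance certificates + retained ids, ensemble
    results JSON + votes CSV + curve CSV, growth-fit JSON, per-subject CAM
    container + effect-size CSV, occlusion report CSV (when occlusion_k > 0).
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    (out / "config.yaml").write_text(config.to_yaml())
    io.save_json({"stage_seeds": seeds}, out / "seeds.json")
    networks = atlas.load_networks(config.networks_path)

    timer = time.time()
    table, stacks = load_or_generate_cohort(config, seeds)
    io.save_phenotypes(table, out / "phenotypes.csv")
    log.info("cohort stage: n=%d (%.1fs)", len(table), time.time() - timer)

    timer = time.time()
    bal_cfg = balancing.BalanceConfig(
        covariates=config.covariates, p_threshold=config.p_threshold,
        seed=seeds["balance"],
    )
    ids, certs = balancing.balance_two_factor(table, bal_cfg)
    io.save_id_list(table.loc[ids, "subject_id"], out / "retained_ids.txt")
    for factor, cert in certs.items():
        io.save_certificate(cert, out / f"balance_{factor}.json")
        if not cert.success:
            raise RuntimeError(
                f"balancing stage failed on {factor}: {cert.failing_covariates}"
            )
    log.info("balance stage: retained=%d (%.1fs)", len(ids), time.time() - timer)

    timer = time.time()
    ens_cfg = ensemble.EnsembleConfig(
        n_members=config.n_members,
        member=member.MemberConfig(
            epochs=config.epochs, batch_size=config.batch_size,
        ),
        balance=bal_cfg,
        seed=seeds["ensemble"],
    )
    result = ensemble.run_ensemble(stacks, table, ens_cfg)
    result.votes.to_csv(out / "votes.csv", index=False)
    result.curve.to_csv(out / "ensemble_curve.csv", index=False)
    io.save_json({
        "member_aurocs": result.member_aurocs,
        "member_auroc_mean": result.member_auroc_mean,
        "member_auroc_sd": result.member_auroc_sd,
        "ensemble_auroc": result.ensemble_auroc,
        "stratum_aurocs": result.stratum_aurocs,
        "coverage": result.coverage,
    }, out / "ensemble_results.json")
    log.info("ensemble stage: AUROC=%.4f (%.1fs)",
             result.ensemble_auroc, time.time() - timer)

    timer = time.time()
    cams = saliency.aggregate_cams(
        result.members, stacks, table["subject_id"].to_numpy()
    )
    np.savez_compressed(
        out / "cams.npz",
        **{sid: scam.cam.astype(np.float32) for sid, scam in cams.items()},
    )
    effect_report = saliency.network_effect_sizes(cams, networks, table)
    effect_report.to_csv(out / "cam_effect_sizes.csv", index=False)
    log.info("saliency stage: %d subject CAMs (%.1fs)",
             len(cams), time.time() - timer)

    if config.occlusion_k > 0:
        timer = time.time()
        designs = [
            occlusion.OcclusionDesign(
                network_name=name, nodes=networks[name].nodes,
                edge_mode=mode, n_members=config.occlusion_k,
            )
            for name in config.occlusion_networks
            for mode in config.occlusion_modes
        ]
        occ_cfg = dataclasses.replace(ens_cfg, seed=seeds["occlusion"])
        report = occlusion.run_occlusion(stacks, table, designs, occ_cfg)
        report.to_csv(out / "occlusion_report.csv", index=False)
        log.info("occlusion stage: %d cells (%.1fs)",
                 len(report), time.time() - timer)

    if len(result.curve) >= 4:
        fit = ensemble.fit_growth_curve(
            result.curve["ensemble_size"], result.curve["auroc"]
        )
        io.save_json({
            "a": fit.a, "b": fit.b, "k": fit.k,
            "a_ci": list(fit.a_ci), "flags": list(fit.flags),
        }, out / "growth_fit.json")
    return out


def results_summary(out_dir) -> dict:
    """Load the JSON results a finished run wrote (for quick inspection)."""
    out = Path(out_dir)
    summary = {}
    for name in ("ensemble_results", "growth_fit", "seeds"):
        path = out / f"{name}.json"
        if path.exists():
            summary[name] = json.loads(path.read_text())
    return summary
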