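"""Half-edge occlusion experiments for a-priori networks.

For each network and edge mode (inner or connecting edges), two arms of K
members each are trained on exactly half of the 6670 unique edges (3335,
grid 115x29): the include arm's halves always contain the network's edge
set, the exclude arm's halves never intersect it, and the remaining slots
are filled with fresh random non-network edges per member. Comparing the
two arms' test AUROC distributions (two-sided Mann-Whitney U, Holm-corrected
across all cells of the report) measures how much classification signal the
network's edges carry — overall and within the rest/task strata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from . import edges, ensemble as ensemble_mod, member as member_mod


@dataclass(frozen=True)
class OcclusionDesign:
    """One cell of the occlusion grid: a network, an edge mode, K per arm."""

    network_name: str
    nodes: tuple[int, ...]
    edge_mode: str                    # "inner" | "connecting"
    n_members: int = 300

    def __post_init__(self):
        if self.edge_mode not in ("inner", "connecting"):
            raise ValueError("edge_mode must be 'inner' or 'connecting'")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")

    @property
    def edge_set(self) -> np.ndarray:
        if self.edge_mode == "inner":
            return edges.inner_edges(self.nodes)
        return edges.connecting_edges(self.nodes)


def experiment_grid_size(n_modes: int, n_conditions: int,
                         n_networks: int, k: int) -> int:
    """Total training runs of the full occlusion grid (e.g. 2x2x3x300 = 3600)."""
    for v in (n_modes, n_conditions, n_networks, k):
        if v < 0:
            raise ValueError("grid factors must be non-negative")
    return n_modes * n_conditions * n_networks * k


def build_masks(
    design: OcclusionDesign, seed: int,
    half: int = member_mod.HALF_EDGES,
    n_edges: int = edges.N_EDGES,
) -> dict[str, list[np.ndarray]]:
    """Per-member edge masks for both arms of one design cell.

    Include masks are the network edge set plus a fresh random fill of
    non-network edges to ``half`` (3335); exclude masks are ``half`` random
    non-network edges. One mask per member per arm.
    """
    net_edges = np.unique(design.edge_set)
    if len(net_edges) > half:
        raise ValueError(
            f"network edge set ({len(net_edges)}) exceeds half the edges ({half})"
        )
    others = np.setdiff1d(np.arange(n_edges), net_edges)
    rng = np.random.default_rng(seed)
    masks = {"include": [], "exclude": []}
    for _ in range(design.n_members):
        fill = rng.choice(others, size=half - len(net_edges), replace=False)
        masks["include"].append(np.sort(np.concatenate([net_edges, fill])))
        masks["exclude"].append(
            np.sort(rng.choice(others, size=half, replace=False))
        )
    for m in masks["include"]:
        assert np.isin(net_edges, m).all()
    for m in masks["exclude"]:
        assert not np.isin(m, net_edges).any()
    return masks


def run_occlusion(
    connectomes: np.ndarray,
    table: pd.DataFrame,
    designs: list[OcclusionDesign],
    ensemble_config: ensemble_mod.EnsembleConfig,
) -> pd.DataFrame:
    """Train both arms of every design cell and compare AUROC distributions.

    Returns one row per (network, mode, stratum) with mean +/- sd member
    AUROC per arm, ensemble AUROCs per arm, the Mann-Whitney U statistic,
    raw two-sided p and Holm-corrected p (family = all rows of this report).
    K = 1 per arm yields rows with undefined (NaN) p-values.
    """
    table = table.reset_index(drop=True)
    labels_all = table["sex"].to_numpy()
    conds_all = table["condition"].to_numpy()
    id_to_row = {sid: i for i, sid in enumerate(table["subject_id"])}

    rows = []
    for d_idx, design in enumerate(designs):
        masks = build_masks(design, seed=ensemble_config.seed + 7919 * d_idx)
        arm_results = {}
        for arm in ("include", "exclude"):
            arm_aurocs = {"all": [], "rest": [], "task": []}
            # train K single-member "ensembles" so each member gets its own
            # balanced subsample AND its own mask; aggregate votes manually
            prob_sum = np.zeros(len(labels_all))
            prob_count = np.zeros(len(labels_all), dtype=int)
            for k in range(design.n_members):
                cfg_k = replace(
                    ensemble_config, n_members=1,
                    seed=int(
                        np.random.SeedSequence(
                            [ensemble_config.seed, d_idx,
                             0 if arm == "include" else 1, k]
                        ).generate_state(1)[0] % (2 ** 31)
                    ),
                )
                res = ensemble_mod.run_ensemble(
                    connectomes, table, cfg_k, mask=masks[arm][k],
                    keep_members=False, compute_curve=False,
                )
                tm_votes = res.votes
                rows_k = np.array(
                    [id_to_row[s] for s in tm_votes["subject_id"]]
                )
                prob_sum[rows_k] += (
                    tm_votes["mean_probability"].to_numpy()
                    * tm_votes["n_models"].to_numpy()
                )
                prob_count[rows_k] += tm_votes["n_models"].to_numpy()
                arm_aurocs["all"].append(float(res.member_aurocs[0]))
                for stratum, code in (("rest", 0), ("task", 1)):
                    sel = tm_votes["condition"] == code
                    lab = tm_votes.loc[sel, "label"]
                    arm_aurocs[stratum].append(
                        ensemble_mod.auroc(
                            tm_votes.loc[sel, "mean_probability"], lab
                        ) if lab.nunique() == 2 else np.nan
                    )
            covered = prob_count > 0
            ens_votes = {}
            vote_vals = prob_sum[covered] / prob_count[covered]
            ens_votes["all"] = ensemble_mod.auroc(
                vote_vals, labels_all[covered]
            )
            for stratum, code in (("rest", 0), ("task", 1)):
                sel = conds_all[covered] == code
                lab = labels_all[covered][sel]
                ens_votes[stratum] = (
                    ensemble_mod.auroc(vote_vals[sel], lab)
                    if len(np.unique(lab)) == 2 else np.nan
                )
            arm_results[arm] = (arm_aurocs, ens_votes)

        for stratum in ("all", "rest", "task"):
            inc = np.asarray(arm_results["include"][0][stratum], dtype=float)
            exc = np.asarray(arm_results["exclude"][0][stratum], dtype=float)
            inc, exc = inc[~np.isnan(inc)], exc[~np.isnan(exc)]
            if len(inc) > 1 and len(exc) > 1 and (
                np.ptp(np.concatenate([inc, exc])) > 0
            ):
                u = mannwhitneyu(inc, exc, alternative="two-sided")
                u_stat, p_raw = float(u.statistic), float(u.pvalue)
            else:
                u_stat, p_raw = np.nan, np.nan
            rows.append({
                "network": design.network_name,
                "mode": design.edge_mode,
                "stratum": stratum,
                "k": design.n_members,
                "auroc_include_mean": float(np.mean(inc)) if len(inc) else np.nan,
                "auroc_include_sd": float(np.std(inc, ddof=1)) if len(inc) > 1 else np.nan,
                "auroc_exclude_mean": float(np.mean(exc)) if len(exc) else np.nan,
                "auroc_exclude_sd": float(np.std(exc, ddof=1)) if len(exc) > 1 else np.nan,
                "ensemble_include": arm_results["include"][1][stratum],
                "ensemble_exclude": arm_results["exclude"][1][stratum],
                "u_statistic": u_stat,
                "p_raw": p_raw,
                "direction": (
                    "include>exclude"
                    if len(inc) and len(exc) and np.mean(inc) >= np.mean(exc)
                    else "exclude>include"
                ),
            })
    report = pd.DataFrame(rows)
    report["p_holm"] = holm_correct(report["p_raw"].to_numpy())
    return report


def holm_correct(p_raw: np.ndarray) -> np.ndarray:
    """Holm step-down correction; NaNs are passed through untouched."""
    out = np.full_like(p_raw, np.nan, dtype=float)
    valid = ~np.isnan(p_raw)
    if valid.any():
        out[valid] = multipletests(p_raw[valid], method="holm")[1]
    return out
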