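"""Multivariate confound balancing by iterative binning and matching.

The balancer curates a subset of a cohort in which every named covariate is
distributionally indistinguishable between two classes. Continuous covariates
are discretized into equal-width bins; within each multivariate bin, subjects
of the two classes are matched (randomly, seeded). Starting from one bin per
covariate, the bin count of the covariate with the worst (smallest) two-sided
Mann-Whitney U p-value between the retained classes is incremented and the
matching re-run, until every covariate's p exceeds the threshold (default
p > .10) or a bin ceiling is reached. The first passing configuration —
i.e. the minimum total bin count reached by this greedy refinement — is
returned together with a certificate of the achieved p-values.

With ``force_ratio=(1, 1)`` each bin contributes min(nA, nB) subjects per
class, so the retained classes are exactly equal in size. Without a forced
ratio each bin contributes subjects in proportion to the global class ratio,
which matches distribution shapes while leaving the prevalence untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

DEFAULT_COVARIATES = ("age", "mfd", "icv", "dvars", "spike_pct")


@dataclass(frozen=True)
class BalanceConfig:
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    p_threshold: float = 0.10
    force_ratio: tuple[int, int] | None = (1, 1)
    max_bins_per_covariate: int = 64
    seed: int = 0

    def __post_init__(self):
        if not self.covariates:
            raise ValueError("covariates must be non-empty")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.force_ratio is not None and self.force_ratio != (1, 1):
            raise ValueError("only force_ratio=(1, 1) or None is supported")
        if self.max_bins_per_covariate < 1:
            raise ValueError("max_bins_per_covariate must be >= 1")


@dataclass(frozen=True)
class BinningScheme:
    """Equal-width bin edges per covariate, computed over the full table."""

    covariates: tuple[str, ...]
    bin_counts: tuple[int, ...]
    edges: tuple[np.ndarray, ...]

    @classmethod
    def fit(cls, table: pd.DataFrame, covariates, bin_counts) -> "BinningScheme":
        all_edges = []
        for cov, k in zip(covariates, bin_counts):
            vals = table[cov].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValueError(f"covariate {cov!r} contains non-finite values")
            lo, hi = (vals.min(), vals.max()) if len(vals) else (0.0, 1.0)
            if lo == hi:
                all_edges.append(np.array([lo, hi]))  # single degenerate bin
            else:
                all_edges.append(np.linspace(lo, hi, k + 1))
        return cls(tuple(covariates), tuple(int(k) for k in bin_counts),
                   tuple(all_edges))


def discretize(table: pd.DataFrame, scheme: BinningScheme) -> np.ndarray:
    """Multivariate bin index per subject: integer array (n, n_covariates)."""
    out = np.empty((len(table), len(scheme.covariates)), dtype=np.int64)
    for c, (cov, edge) in enumerate(zip(scheme.covariates, scheme.edges)):
        vals = table[cov].to_numpy(dtype=float)
        # right-closed last bin so the maximum falls in the top bin
        idx = np.clip(np.searchsorted(edge, vals, side="right") - 1,
                      0, len(edge) - 2)
        out[:, c] = idx
    return out


def match_within_bins(
    table: pd.DataFrame,
    scheme: BinningScheme,
    config: BalanceConfig,
    class_column: str,
    rng: np.random.Generator | None = None,
) -> pd.Index:
    """Seeded random matching within multivariate bins; returns retained index.

    The two classes are the sorted unique values of ``class_column`` (exactly
    two required). Retention per bin is min(nA, nB) per class under a forced
    1:1 ratio, or proportional to the global class ratio otherwise.
    """
    classes = np.sort(table[class_column].unique())
    if len(classes) != 2:
        raise ValueError(
            f"{class_column!r} must carry exactly two classes, got {list(classes)}"
        )
    rng = rng or np.random.default_rng(config.seed)
    bins = discretize(table, scheme)
    keys = pd.DataFrame(bins, index=table.index).apply(tuple, axis=1)
    labels = table[class_column].to_numpy()
    n_a = int((labels == classes[0]).sum())
    n_b = int((labels == classes[1]).sum())

    retained = []
    for _, members in table.groupby(keys, sort=False).groups.items():
        members = pd.Index(members)
        a = members[table.loc[members, class_column] == classes[0]]
        b = members[table.loc[members, class_column] == classes[1]]
        if config.force_ratio == (1, 1):
            k_a = k_b = min(len(a), len(b))
        else:
            # proportional retention: keep the bin's shape at the global ratio
            if n_a == 0 or n_b == 0:
                k_a = k_b = 0
            else:
                scale = min(len(a) / n_a, len(b) / n_b)
                k_a = int(round(scale * n_a))
                k_b = int(round(scale * n_b))
        if k_a == 0 or k_b == 0:
            continue
        retained.extend(rng.choice(a, size=k_a, replace=False))
        retained.extend(rng.choice(b, size=k_b, replace=False))
    return pd.Index(sorted(retained))


@dataclass(frozen=True)
class BalanceCertificate:
    status: str                       # "success" | "failure"
    p_values: dict = field(default_factory=dict)
    retained_counts: dict = field(default_factory=dict)
    bin_counts: dict = field(default_factory=dict)
    failing_covariates: tuple[str, ...] = ()

    @property
    def success(self) -> bool:
        return self.status == "success"


def _covariate_pvalues(table, covariates, class_column) -> dict:
    classes = np.sort(table[class_column].unique())
    if len(classes) != 2:
        return {cov: np.nan for cov in covariates}
    a = table[table[class_column] == classes[0]]
    b = table[table[class_column] == classes[1]]
    out = {}
    for cov in covariates:
        x, y = a[cov].to_numpy(), b[cov].to_numpy()
        if len(x) == 0 or len(y) == 0:
            out[cov] = np.nan
        elif np.ptp(np.concatenate([x, y])) == 0:
            out[cov] = 1.0            # identical constants: indistinguishable
        else:
            out[cov] = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return out


def balance(
    table: pd.DataFrame,
    config: BalanceConfig,
    class_column: str = "sex",
) -> tuple[pd.Index, BalanceCertificate]:
    """Iterative bin refinement until all covariates pass, or failure.

    Returns (retained index, certificate). The certificate's p-values are
    computed on the retained subset — the quantity the balance claim is
    about — and can be recomputed independently from the retained rows.
    """
    classes = table[class_column].unique() if len(table) else []
    if len(classes) != 2:
        return pd.Index([]), BalanceCertificate(
            status="failure",
            failing_covariates=tuple(config.covariates),
            p_values={c: np.nan for c in config.covariates},
        )
    rng = np.random.default_rng(config.seed)
    bin_counts = {cov: 1 for cov in config.covariates}

    while True:
        scheme = BinningScheme.fit(
            table, config.covariates,
            [bin_counts[c] for c in config.covariates],
        )
        retained = match_within_bins(table, scheme, config, class_column, rng)
        if len(retained) == 0:
            return retained, BalanceCertificate(
                status="failure", bin_counts=dict(bin_counts),
                failing_covariates=tuple(config.covariates),
                p_values={c: np.nan for c in config.covariates},
            )
        sub = table.loc[retained]
        pvals = _covariate_pvalues(sub, config.covariates, class_column)
        counts = sub[class_column].value_counts().to_dict()
        if all(p > config.p_threshold for p in pvals.values()):
            return retained, BalanceCertificate(
                status="success", p_values=pvals,
                retained_counts={str(k): int(v) for k, v in counts.items()},
                bin_counts=dict(bin_counts),
            )
        worst = min(pvals, key=lambda c: (pvals[c], config.covariates.index(c)))
        if bin_counts[worst] >= config.max_bins_per_covariate:
            failing = tuple(c for c, p in pvals.items()
                            if not p > config.p_threshold)
            return retained, BalanceCertificate(
                status="failure", p_values=pvals,
                retained_counts={str(k): int(v) for k, v in counts.items()},
                bin_counts=dict(bin_counts), failing_covariates=failing,
            )
        bin_counts[worst] += 1


def balance_two_factor(
    table: pd.DataFrame,
    config: BalanceConfig,
    first: str = "sex",
    second: str = "condition",
    max_rounds: int = 10,
) -> tuple[pd.Index, dict[str, BalanceCertificate]]:
    """Two-factor balancing: by sex with forced 1:1, then by condition with
    no forced ratio, yielding four divisions with matched covariates.

    Because the second stage subsamples the first stage's output, it can
    disturb the first factor's covariate balance; the pair of stages is
    therefore alternated (each round starting from the previous round's
    retained subset) until the final subset passes both factors' tests, or
    ``max_rounds`` is exhausted.
    """
    from dataclasses import replace

    stage1_cfg = replace(config, force_ratio=(1, 1))
    current = table
    cert1 = cert2 = None
    for round_idx in range(max_rounds):
        seed_shift = 2 * round_idx
        ids1, cert1 = balance(
            current, replace(stage1_cfg, seed=config.seed + seed_shift),
            class_column=first,
        )
        if not cert1.success:
            return ids1, {first: cert1}
        ids2, cert2 = balance(
            current.loc[ids1],
            replace(config, force_ratio=None, seed=config.seed + seed_shift + 1),
            class_column=second,
        )
        if not cert2.success:
            return ids2, {first: cert1, second: cert2}
        # verify the first factor survived the second stage's subsampling
        final = current.loc[ids2]
        p_first = _covariate_pvalues(final, config.covariates, first)
        if all(p > config.p_threshold for p in p_first.values()):
            cert1 = BalanceCertificate(
                status="success", p_values=p_first,
                retained_counts={
                    str(k): int(v)
                    for k, v in final[first].value_counts().items()
                },
                bin_counts=cert1.bin_counts,
            )
            return ids2, {first: cert1, second: cert2}
        current = final
    failing = tuple(c for c, p in p_first.items() if not p > config.p_threshold)
    cert1 = BalanceCertificate(
        status="failure", p_values=p_first, bin_counts=cert1.bin_counts,
        failing_covariates=failing,
    )
    return ids2, {first: cert1, second: cert2}
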