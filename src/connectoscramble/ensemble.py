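"""Ensembles of scrambled-CNN members and the AUROC growth projection.

K members are trained independently, each on a freshly drawn class- and
covariate-balanced subsample of the cohort, with its own edge permutation
and 4:1:1 train/validation/test split. A subject's ensemble vote is the mean
predicted class-1 probability over every member in whose held-out test set
the subject appeared; since members never mix their own train and test data,
no subject's vote contains a prediction from a model that trained on it, and
no subject is counted twice in any AUROC.

The dependence of ensemble AUROC on the number of aggregated members is
summarized by a logistic growth fit y = a / (1 + b e^(-kx)), k > 0, whose
asymptote a estimates the accuracy ceiling of vote averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.metrics import roc_auc_score

from . import balancing, member


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve: P(random positive outscores random negative),
    ties counted half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


@dataclass(frozen=True)
class EnsembleConfig:
    n_members: int = 300
    member: member.MemberConfig = field(default_factory=member.MemberConfig)
    balance: balancing.BalanceConfig = field(
        default_factory=balancing.BalanceConfig
    )
    subsample_fraction: float = 1.0   # of the balanced pool, per member
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")


@dataclass
class EnsembleResult:
    member_aurocs: np.ndarray                 # (K,)
    votes: pd.DataFrame                       # subject_id, n_models, mean_probability, label, condition
    ensemble_auroc: float
    stratum_aurocs: dict                      # {"rest": ..., "task": ...}
    coverage: float                           # fraction of cohort in >=1 test set
    members: list = field(default_factory=list)
    curve: pd.DataFrame | None = None         # ensemble size vs AUROC

    @property
    def member_auroc_mean(self) -> float:
        return float(np.mean(self.member_aurocs))

    @property
    def member_auroc_sd(self) -> float:
        return float(np.std(self.member_aurocs, ddof=1)) if len(
            self.member_aurocs) > 1 else 0.0


def _member_subsample(table, ens_config, bins_scheme, rng):
    """Fresh seeded matching draw from fixed bins for one member."""
    cfg = replace(ens_config.balance, force_ratio=(1, 1))
    idx = balancing.match_within_bins(table, bins_scheme, cfg, "sex", rng)
    if ens_config.subsample_fraction < 1.0:
        keep = rng.choice(
            len(idx), int(len(idx) * ens_config.subsample_fraction),
            replace=False,
        )
        idx = idx[np.sort(keep)]
    return idx


def run_ensemble(
    connectomes: np.ndarray,
    table: pd.DataFrame,
    config: EnsembleConfig,
    mask: np.ndarray | None = None,
    keep_members: bool = True,
    compute_curve: bool = True,
) -> EnsembleResult:
    """Train K members on independently balanced subsamples and aggregate.

    ``connectomes`` is (n, 3, 116, 116) aligned with ``table`` rows (columns
    subject_id, sex, condition + balancing covariates). The global balancing
    stage fixes the bin scheme; each member redraws the within-bin matching
    with a fresh seed, then splits 4:1:1. Votes aggregate test-set
    predictions only.
    """
    table = table.reset_index(drop=True)
    ids, cert = balancing.balance(table, config.balance, "sex")
    if not cert.success:
        raise ValueError(
            f"cohort failed covariate balancing: {cert.failing_covariates}"
        )
    scheme = balancing.BinningScheme.fit(
        table, config.balance.covariates,
        [cert.bin_counts[c] for c in config.balance.covariates],
    )
    root = np.random.SeedSequence(config.seed)
    labels_all = table["sex"].to_numpy()

    members, aurocs = [], []
    prob_sum = np.zeros(len(table))
    prob_count = np.zeros(len(table), dtype=int)
    per_member_tests = []
    for k, ss in enumerate(root.spawn(config.n_members)):
        rng = np.random.default_rng(ss)
        sub_idx = _member_subsample(table, config, scheme, rng)
        sub_idx = np.asarray(sub_idx, dtype=np.int64)
        m_cfg = replace(config.member,
                        seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        try:
            tm = member.train_member(
                connectomes[sub_idx], labels_all[sub_idx], m_cfg,
                subject_ids=sub_idx, mask=mask,
            )
        except Exception as exc:
            raise RuntimeError(f"member {k} failed: {exc}") from exc
        test_rows = tm.test_ids
        p1 = tm.test_probabilities[:, 1]
        aurocs.append(auroc(p1, labels_all[test_rows]))
        prob_sum[test_rows] += p1
        prob_count[test_rows] += 1
        per_member_tests.append((test_rows, p1))
        if keep_members:
            members.append(tm)

    covered = prob_count > 0
    votes = pd.DataFrame({
        "subject_id": table.loc[covered, "subject_id"].to_numpy(),
        "n_models": prob_count[covered],
        "mean_probability": prob_sum[covered] / prob_count[covered],
        "label": labels_all[covered],
        "condition": table.loc[covered, "condition"].to_numpy(),
    })
    overall = auroc(votes["mean_probability"], votes["label"])
    strata = {}
    for name, code in (("rest", 0), ("task", 1)):
        sel = votes["condition"] == code
        strata[name] = (
            auroc(votes.loc[sel, "mean_probability"], votes.loc[sel, "label"])
            if sel.sum() and votes.loc[sel, "label"].nunique() == 2 else np.nan
        )
    curve = ensemble_curve(per_member_tests, labels_all) if compute_curve else None
    return EnsembleResult(
        member_aurocs=np.array(aurocs), votes=votes,
        ensemble_auroc=overall, stratum_aurocs=strata,
        coverage=float(covered.mean()), members=members, curve=curve,
    )


def ensemble_curve(per_member_tests, labels_all) -> pd.DataFrame:
    """Ensemble AUROC after aggregating the first m members, m = 1..K.

    Members enter in training order, matching the cumulative construction of
    the growth-curve figure; reproducible from saved member outputs.
    """
    n = len(labels_all)
    prob_sum = np.zeros(n)
    prob_count = np.zeros(n, dtype=int)
    sizes, values = [], []
    for m, (test_rows, p1) in enumerate(per_member_tests, start=1):
        prob_sum[test_rows] += p1
        prob_count[test_rows] += 1
        covered = prob_count > 0
        lab = labels_all[covered]
        if len(np.unique(lab)) == 2:
            votes = prob_sum[covered] / prob_count[covered]
            sizes.append(m)
            values.append(auroc(votes, lab))
    return pd.DataFrame({"ensemble_size": sizes, "auroc": values})


@dataclass(frozen=True)
class LogisticFit:
    """y = a / (1 + b e^(-kx)) with k > 0; a is the projected ceiling."""

    a: float
    b: float
    k: float
    a_ci: tuple[float, float]
    converged: bool = True
    flags: tuple[str, ...] = ()


def fit_growth_curve(sizes, values) -> LogisticFit:
    """Least-squares logistic-growth fit of AUROC versus ensemble size.

    Requires >= 4 strictly increasing sizes. 95% confidence bounds on the
    asymptote come from the asymptotic covariance of the nonlinear fit.
    Degenerate inputs (flat or decreasing series) are fitted anyway and
    flagged rather than rejected.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("growth-curve fit needs at least 4 points")
    if not np.all(np.diff(x) > 0):
        raise ValueError("ensemble sizes must be strictly increasing")

    def model(x, a, b, k):
        return a / (1.0 + b * np.exp(-k * x))

    flags = []
    if np.ptp(y) < 1e-12:
        flags.append("flat series: k unidentifiable")
    if len(y) > 1 and y[-1] < y[0]:
        flags.append("decreasing series: growth model misspecified")
    a0 = max(y.max(), 1e-6)
    b0 = max(a0 / max(y[0], 1e-6) - 1.0, 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # the asymptote is an AUROC ceiling, so a is confined to (0, 1]
            popt, pcov = curve_fit(
                model, x, y, p0=[min(a0, 1.0), b0, 0.05],
                bounds=([1e-9, 0.0, 1e-9], [1.0, np.inf, np.inf]),
                maxfev=20000,
            )
    except RuntimeError as exc:
        raise RuntimeError(f"growth-curve fit did not converge: {exc}") from exc
    a, b, k = (float(v) for v in popt)
    a_sd = float(np.sqrt(max(pcov[0, 0], 0.0)))
    if not np.isfinite(a_sd):
        a_sd = np.inf
        flags.append("unbounded asymptote variance")
    return LogisticFit(
        a=a, b=b, k=k,
        a_ci=(a - 1.96 * a_sd, a + 1.96 * a_sd),
        converged=True, flags=tuple(flags),
    )
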