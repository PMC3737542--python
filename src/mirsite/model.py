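"""Nonlinear logistic ensemble over balanced subsamples, and its evaluation.

The classifier is a logistic regression on the enriched features with
pairwise interaction (quadratic) terms,

    log[P(X) / (1 - P(X))] = alpha + sum_i beta_i X_i + sum_{i<j} gamma_ij X_i X_j,

trained to predict IP+ (1) vs IP- (0).  Because the IP- set is much larger
than the IP+ set, each of the (default 10) ensemble members is fitted on the
whole IP+ set plus a fresh equal-sized random IP- subsample; the ensemble
prediction is the average of the member probabilities, and a site is called
positive when that average reaches the threshold q.

Evaluation follows ROC/Youden practice: TPR against FPR over the threshold
grid, Youden's J = TPR - FPR, precision among the top-ranked fraction, with
10-fold cross-validation for intra-dataset and a train-on-A/test-on-B
protocol for inter-dataset validation.  Cross-validated reports carry both
the per-fold mean of max-J (protocol average) and the max-J of the pooled
out-of-fold predictions; the pooled statistic is the headline number because
the per-fold maximum is upward-biased on small holdouts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .enrichment import CATEGORICAL_FEATURES, enrichment_table
from .io_formats import RunConfig

log = logging.getLogger(__name__)


@dataclass
class DesignSpec:
    """Covariates, interactions and the training-derived constants.

    ``interactions="all"`` expands to every unordered pair of covariates.
    Categorical covariates are replaced by their training-set per-category
    odds ratios before standardization; standardization constants always
    come from training data.
    """

    covariates: list
    interactions: object = "all"     # "all" | list[tuple[str, str]] | None
    standardize: bool = True
    encoders: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    fitted: bool = False

    def interaction_pairs(self) -> list[tuple[str, str]]:
        if self.interactions == "all":
            c = list(self.covariates)
            return [(c[i], c[j]) for i in range(len(c)) for j in range(i + 1, len(c))]
        if self.interactions is None:
            return []
        pairs = [tuple(p) for p in self.interactions]
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-interaction {a!r} not allowed")
            if a not in self.covariates or b not in self.covariates:
                raise ValueError(f"interaction ({a}, {b}) references unknown covariate")
        return pairs

    def column_names(self) -> list[str]:
        return list(self.covariates) + [
            f"{a}*{b}" for a, b in self.interaction_pairs()
        ]

    def clone_unfitted(self) -> "DesignSpec":
        return DesignSpec(list(self.covariates), self.interactions, self.standardize)


def _fit_encoders(df: pd.DataFrame, spec: DesignSpec) -> None:
    cats = [c for c in spec.covariates if c in CATEGORICAL_FEATURES]
    if not cats:
        return
    from .enrichment import BinSpec
    table = enrichment_table(df, [BinSpec(c, "categorical") for c in cats])
    for c in cats:
        spec.encoders[c] = table.category_odds(c)


def _encode_column(values, mapping: dict) -> np.ndarray:
    out = np.empty(len(values), dtype=float)
    for k, v in enumerate(np.asarray(values, dtype=object)):
        key = str(v)
        if key in mapping:
            out[k] = mapping[key]
        else:
            log.warning("category %r unseen in training; encoded as 1.0", v)
            out[k] = 1.0
    return out


def build_design(
    df: pd.DataFrame, spec: DesignSpec, fit: bool = False
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Design matrix (standardized mains, then interaction products).

    Returns ``(X, y, kept)`` where ``kept`` is the boolean row mask after
    dropping rows with a missing covariate (count logged); ``y`` is None
    when ``df`` has no ``ip_label`` column.  With ``fit=True`` the
    categorical encoders and standardization constants are (re)computed
    from ``df``, which must then carry labels.
    """
    missing = [c for c in spec.covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates missing from table: {missing}")
    if fit:
        if "ip_label" not in df.columns:
            raise ValueError("fitting a DesignSpec requires ip_label")
        spec.encoders = {}
        _fit_encoders(df, spec)
    cols = {}
    for c in spec.covariates:
        if c in spec.encoders:
            cols[c] = _encode_column(df[c], spec.encoders[c])
        elif c in CATEGORICAL_FEATURES:
            raise ValueError(f"categorical covariate {c!r} has no fitted encoder")
        else:
            cols[c] = df[c].to_numpy(dtype=float)
    raw = np.column_stack([cols[c] for c in spec.covariates])
    kept = ~np.isnan(raw).any(axis=1)
    if "cons_excluded" in df.columns and any(
        c.startswith("cons_") for c in spec.covariates
    ):
        kept &= ~df["cons_excluded"].astype(bool).to_numpy()
    dropped = int((~kept).sum())
    if dropped:
        log.info("dropped %d rows with missing covariates", dropped)
    raw = raw[kept]
    if fit:
        spec.means = {c: float(raw[:, k].mean()) for k, c in enumerate(spec.covariates)}
        spec.sds = {}
        for k, c in enumerate(spec.covariates):
            sd = float(raw[:, k].std())
            spec.sds[c] = sd if sd > 0 else 1.0
        spec.fitted = True
    if not spec.fitted:
        raise ValueError("DesignSpec not fitted; call with fit=True on training data")
    if spec.standardize:
        mu = np.array([spec.means[c] for c in spec.covariates])
        sd = np.array([spec.sds[c] for c in spec.covariates])
        raw = (raw - mu) / sd
    parts = [raw]
    idx = {c: k for k, c in enumerate(spec.covariates)}
    for a, b in spec.interaction_pairs():
        parts.append((raw[:, idx[a]] * raw[:, idx[b]])[:, None])
    X = np.hstack(parts)
    y = None
    if "ip_label" in df.columns:
        y = df["ip_label"].astype(bool).to_numpy()[kept].astype(float)
    return X, y, kept


# ---------------------------------------------------------------------------
# fitting


def fit_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-6
) -> np.ndarray:
    """Maximum-likelihood logistic coefficients (intercept first).

    A small L2 ridge (never on the intercept) keeps the fit defined under
    complete separation; convergence to gradient norm <= 1e-6 is verified
    and a failure is logged, not raised.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes are required")
    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])

    def nll(w):
        eta = Xa @ w
        # log(1 + e^eta) - y*eta, computed stably
        val = np.logaddexp(0.0, eta) - y * eta
        pen = 0.5 * ridge * np.dot(w[1:], w[1:])
        return val.sum() + pen

    def grad(w):
        r = expit(Xa @ w) - y
        g = Xa.T @ r
        g[1:] += ridge * w[1:]
        return g

    w0 = np.zeros(p + 1)
    res = minimize(nll, w0, jac=grad, method="L-BFGS-B",
                   options={"maxiter": 500, "gtol": 1e-8, "ftol": 1e-12})
    w = res.x
    # Newton polish: L-BFGS stops on relative progress; a few damped Newton
    # steps drive the gradient to the convergence contract
    for _ in range(25):
        g = grad(w)
        if np.linalg.norm(g) <= 1e-8:
            break
        mu = expit(Xa @ w)
        H = (Xa * (mu * (1 - mu))[:, None]).T @ Xa
        H[np.arange(1, p + 1), np.arange(1, p + 1)] += ridge
        H[np.arange(p + 1), np.arange(p + 1)] += 1e-10
        step = np.linalg.solve(H, g)
        new = w - step
        if nll(new) <= nll(w) + 1e-12:
            w = new
        else:
            for _ in range(30):
                step *= 0.5
                new = w - step
                if nll(new) <= nll(w):
                    w = new
                    break
            else:
                break
    gn = float(np.linalg.norm(grad(w)))
    if gn > 1e-6:
        log.warning("logistic fit gradient norm %.2e > 1e-6 (possible separation)", gn)
    return w


@dataclass
class LogisticEnsemble:
    """k logistic fits on balanced subsamples; prediction = mean probability."""

    coefficients: np.ndarray        # (k, 1 + n_columns)
    spec: DesignSpec
    n_pos: int
    n_neg: int
    seed: int

    def to_json(self, path) -> None:
        data = {
            "coefficients": self.coefficients.tolist(),
            "covariates": list(self.spec.covariates),
            "interactions": (
                self.spec.interactions
                if isinstance(self.spec.interactions, str)
                else [list(p) for p in self.spec.interaction_pairs()]
            ),
            "standardize": self.spec.standardize,
            "encoders": self.spec.encoders,
            "means": self.spec.means,
            "sds": self.spec.sds,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "LogisticEnsemble":
        with open(path) as fh:
            data = json.load(fh)
        spec = DesignSpec(
            covariates=data["covariates"],
            interactions=(
                data["interactions"] if isinstance(data["interactions"], str)
                else [tuple(p) for p in data["interactions"]]
            ),
            standardize=data["standardize"],
            encoders=data["encoders"],
            means=data["means"],
            sds=data["sds"],
            fitted=True,
        )
        return cls(np.array(data["coefficients"]), spec,
                   data["n_pos"], data["n_neg"], data["seed"])


def fit_balanced_ensemble(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    k: int = 10,
    seed: int = 0,
    spec: DesignSpec | None = None,
    ridge: float = 1e-6,
) -> LogisticEnsemble:
    """Fit k members, each on all IP+ rows plus an equal random IP- subsample.

    Subsamples are drawn without replacement within a member.  If the IP+
    set is the larger one the roles are swapped (flagged).  Deterministic
    given the seed.
    """
    if min(len(X_pos), len(X_neg)) < 10:
        raise ValueError(
            f"too few sites per class ({len(X_pos)} IP+, {len(X_neg)} IP-)"
        )
    swap = len(X_neg) < len(X_pos)
    if swap:
        log.warning("IP+ set larger than IP-: subsampling IP+ instead")
    small, big = (X_neg, X_pos) if swap else (X_pos, X_neg)
    y_small, y_big = (0.0, 1.0) if swap else (1.0, 0.0)
    rng = np.random.default_rng(seed)
    coefs = []
    for _ in range(k):
        idx = rng.choice(len(big), size=len(small), replace=False)
        X = np.vstack([small, big[idx]])
        y = np.concatenate([
            np.full(len(small), y_small), np.full(len(small), y_big)
        ])
        coefs.append(fit_logistic(X, y, ridge))
    return LogisticEnsemble(
        np.array(coefs), spec or DesignSpec([]), len(X_pos), len(X_neg), seed
    )


def predict(ensemble: LogisticEnsemble, X: np.ndarray) -> np.ndarray:
    """Averaged member probability per row (rows must match the DesignSpec)."""
    n = X.shape[0]
    Xa = np.hstack([np.ones((n, 1)), X])
    probs = expit(Xa @ ensemble.coefficients.T)
    return probs.mean(axis=1)


def classify(prob, q: float = 0.5):
    """Deterministic call: positive iff the averaged probability >= q."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0,1)")
    return np.asarray(prob) >= q


# ---------------------------------------------------------------------------
# evaluation


def roc_curve(probs, labels):
    """(fpr, tpr, thresholds) at every distinct score, plus the endpoints.

    Thresholds descend; the first point is (0,0) (threshold above every
    score) and the last (1,1).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes are required for a ROC curve")
    order = np.argsort(-probs, kind="stable")
    sorted_labels = labels[order]
    sorted_probs = probs[order]
    distinct = np.r_[np.diff(sorted_probs) != 0, True]
    tp = np.cumsum(sorted_labels)[distinct]
    fp = np.cumsum(~sorted_labels)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, sorted_probs[distinct]]
    return fpr, tpr, thresholds


def youden_j(tpr: float, fpr: float) -> float:
    """Youden's J statistic: TPR - FPR (= sensitivity + specificity - 1)."""
    return tpr - fpr


def auc_of(fpr, tpr) -> float:
    return float(np.trapezoid(tpr, fpr))


def top_fraction_tpr(probs, labels, fraction: float) -> float:
    """Precision among the ceil(fraction * n) highest-probability sites.

    Ties are broken by stable input order (logged when present).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    k = int(np.ceil(fraction * len(probs)))
    order = np.argsort(-probs, kind="stable")
    if len(probs) > k and probs[order[k - 1]] == probs[order[k]]:
        log.warning("tie at the top-%g%% cutoff broken by input order",
                    100 * fraction)
    return float(labels[order[:k]].mean())


@dataclass
class EvalReport:
    """ROC, Youden and top-ranked metrics for one evaluation."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    max_j: float
    max_j_threshold: float
    auc: float
    j_at_q: float
    top_tpr: dict
    fold_metrics: list = field(default_factory=list)
    mean_fold_max_j: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "max_j": self.max_j,
            "max_j_threshold": self.max_j_threshold,
            "auc": self.auc,
            "j_at_q": self.j_at_q,
            "top_tpr": {str(k): v for k, v in self.top_tpr.items()},
            "mean_fold_max_j": self.mean_fold_max_j,
            "fold_metrics": self.fold_metrics,
            "roc": {
                "fpr": self.fpr.tolist(),
                "tpr": self.tpr.tolist(),
                "thresholds": [
                    None if np.isinf(t) else float(t) for t in self.thresholds
                ],
            },
        }


def evaluate(probs, labels, q: float = 0.5,
             top_fractions=(0.01, 0.05, 0.10)) -> EvalReport:
    fpr, tpr, thr = roc_curve(probs, labels)
    j = tpr - fpr
    best = int(np.argmax(j))
    preds = classify(probs, q)
    labels = np.asarray(labels, dtype=bool)
    tpr_q = float(preds[labels].mean()) if labels.any() else float("nan")
    fpr_q = float(preds[~labels].mean()) if (~labels).any() else float("nan")
    return EvalReport(
        fpr=fpr, tpr=tpr, thresholds=thr,
        max_j=float(j[best]),
        max_j_threshold=float(thr[best]),
        auc=auc_of(fpr, tpr),
        j_at_q=youden_j(tpr_q, fpr_q),
        top_tpr={f: top_fraction_tpr(probs, labels, f) for f in top_fractions},
    )


def _fold_split(n: int, n_folds: int, rng) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(idx, n_folds)]


def cross_validate_10fold(
    df: pd.DataFrame,
    spec: DesignSpec,
    seed: int = 0,
    config: RunConfig | None = None,
) -> EvalReport:
    """Intra-dataset validation by stratified 10-fold cross-validation.

    The IP+ and IP- sets are each divided into 10 subsets; at repetition i
    the i-th subset of each is held out, a balanced ensemble is trained on
    the remaining nine (encoders and standardization refitted on the
    training part only), and the holdout is scored.  Fold metrics are
    averaged; ROC and the headline max-J come from the pooled out-of-fold
    predictions.
    """
    config = config or RunConfig()
    n_folds = config.n_folds
    labels_all = df["ip_label"].astype(bool).to_numpy()
    pos_idx = np.flatnonzero(labels_all)
    neg_idx = np.flatnonzero(~labels_all)
    if min(len(pos_idx), len(neg_idx)) < n_folds:
        raise ValueError("too few sites per class for cross-validation")
    rng = np.random.default_rng(seed)
    pos_folds = _fold_split(len(pos_idx), n_folds, rng)
    neg_folds = _fold_split(len(neg_idx), n_folds, rng)
    member_seeds = rng.integers(0, 2**31 - 1, size=n_folds)
    pooled_probs, pooled_labels, fold_metrics = [], [], []
    for i in range(n_folds):
        hold = np.r_[pos_idx[pos_folds[i]], neg_idx[neg_folds[i]]]
        train = np.setdiff1d(np.arange(len(df)), hold)
        fold_spec = spec.clone_unfitted()
        Xtr, ytr, _ = build_design(df.iloc[train], fold_spec, fit=True)
        ens = fit_balanced_ensemble(
            Xtr[ytr == 1], Xtr[ytr == 0], config.ensemble_size,
            int(member_seeds[i]), fold_spec, config.ridge,
        )
        Xte, yte, _ = build_design(df.iloc[hold], fold_spec)
        probs = predict(ens, Xte)
        rep = evaluate(probs, yte, config.q_threshold)
        fold_metrics.append({
            "fold": i, "max_j": rep.max_j, "auc": rep.auc, "j_at_q": rep.j_at_q,
            "n_pos": int(yte.sum()), "n_neg": int(len(yte) - yte.sum()),
        })
        pooled_probs.append(probs)
        pooled_labels.append(yte)
    probs = np.concatenate(pooled_probs)
    labels = np.concatenate(pooled_labels)
    report = evaluate(probs, labels, config.q_threshold)
    report.fold_metrics = fold_metrics
    report.mean_fold_max_j = float(np.mean([m["max_j"] for m in fold_metrics]))
    return report


def inter_dataset_validate(
    train_df: pd.DataFrame,
    test_df: pd.DataFrame,
    spec: DesignSpec,
    seed: int = 0,
    config: RunConfig | None = None,
) -> EvalReport:
    """Train fully on dataset A, evaluate on dataset B.

    No information flows from B to A: encoders and standardization
    constants come from A alone.  Raises if B lacks any covariate.
    """
    config = config or RunConfig()
    missing = [c for c in spec.covariates if c not in test_df.columns]
    if missing:
        raise ValueError(f"test dataset lacks covariates: {missing}")
    fit_spec = spec.clone_unfitted()
    Xtr, ytr, _ = build_design(train_df, fit_spec, fit=True)
    ens = fit_balanced_ensemble(
        Xtr[ytr == 1], Xtr[ytr == 0], config.ensemble_size, seed,
        fit_spec, config.ridge,
    )
    Xte, yte, _ = build_design(test_df, fit_spec)
    return evaluate(predict(ens, Xte), yte, config.q_threshold)
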