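"""Prognostic miRNA signature: censoring-aware features, penalty-weighted
elastic-net logistic selection under leave-one-out cross-validation, model
averaging, scoring and per-feature AUC.

Each miRNA contributes the linear feature F = max_cycles − Cq, which is 0
exactly for censored (non-detected) measurements and grows with urinary
concentration.  The design holds, for P species, the P main features, a
women indicator, and P sex-by-feature interactions (2P + 1 columns), so a
measurement may carry a different prognostic weight in women.

Selection minimizes the penalized negative log-likelihood

    -(1/n) l(b0, b) + lambda * sum_j w_j * (alpha*|b_j| + (1-alpha)/2*b_j^2)

by IRLS with cyclic coordinate descent and soft-thresholding (features are
not standardized: they share the cycle scale).  The per-feature penalty
factors w_j encode prior biology: w = (1 + renal_count)^(-gamma), so
miRNAs predicted to bind more kidney-relevant genes are shrunk less;
gamma = 0 recovers the unweighted "concentration-only" model and the
gamma grid is tuned by LOCV alongside lambda.  All hyperparameter
settings tied at the optimal LOCV misclassification are refit on the full
data and coefficient-averaged into the reported composite model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qpcr_io import CqMatrix, SampleTable, load_table2_fixture

__all__ = [
    "FeatureMatrix",
    "SignatureModel",
    "build_features",
    "renal_penalty_weights",
    "fit_signature",
    "score",
    "signature_membership",
    "feature_auc",
    "load_table2_models",
    "locv_error_path",
    "ElasticNetSignature",
]

INTERACTION_SUFFIX = " X Women"
SEX_COLUMN = "Women"

DEFAULT_GAMMA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)


@dataclass
class FeatureMatrix:
    """Samples x predictors design (2P+1 columns for P miRNA species)."""

    frame: pd.DataFrame  # rows = samples, columns = predictors
    species: list[str]
    max_cycles: int = 40

    @property
    def predictors(self) -> list[str]:
        return list(self.frame.columns)

    def X(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


@dataclass
class SignatureModel:
    """Fitted (or transcribed) prognostic model.

    ``coefficients`` map predictor name to log-odds per feature unit; the
    linear predictor is ``intercept + sum(coef * feature)`` and its
    logistic transform is the probability of future microalbuminuria.
    """

    intercept: float
    coefficients: dict[str, float]
    hyperparameters: dict = field(default_factory=dict)
    penalty_weights: dict[str, float] = field(default_factory=dict)
    locv_misclassification: float | None = None
    averaged_from: int = 1

    def summary(self) -> pd.DataFrame:
        rows = [{"predictor": "Intercept", "log_odds": self.intercept}]
        for name, c in self.coefficients.items():
            if c != 0.0:
                rows.append({"predictor": name, "log_odds": c})
        df = pd.DataFrame(rows)
        df.attrs["locv_misclassification"] = self.locv_misclassification
        df.attrs["hyperparameters"] = dict(self.hyperparameters)
        return df

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.summary().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def build_features(
    cq: CqMatrix,
    samples: SampleTable,
    exclude: Sequence[str] = (),
) -> FeatureMatrix:
    """F = max_cycles − Cq per species, a women indicator and interactions.

    Requires the matrix to be imputed (censored cells at ``max_cycles``, so
    their features are exactly 0).  ``exclude`` drops control rows
    (reference panel, spike-in) from the design.
    """
    if set(cq.sample_ids) != set(samples.ids):
        raise ValueError("cq and sample table cover different samples")
    order = [cq.sample_ids.index(i) for i in samples.ids]
    species = [s for s in cq.species_ids if s not in set(exclude)]
    idx = [cq.species_index(s) for s in species]
    F = (cq.max_cycles - cq.cq[np.ix_(idx, order)]).T  # samples x species
    women = (samples.sex_labels() == "F").astype(float)
    inter = F * women[:, None]
    frame = pd.DataFrame(
        np.column_stack([F, women, inter]),
        index=samples.ids,
        columns=[*species, SEX_COLUMN, *(s + INTERACTION_SUFFIX for s in species)],
    )
    return FeatureMatrix(frame=frame, species=species, max_cycles=cq.max_cycles)


def renal_penalty_weights(
    counts: Mapping[str, int],
    gamma: float,
    species: Sequence[str] | None = None,
) -> dict[str, float]:
    """w = (1 + renal_count)^(-gamma) per species, applied identically to
    the main and interaction columns; the sex indicator keeps weight 1.

    Species absent from ``counts`` count 0 renal targets.  gamma = 0 gives
    uniform weights (the concentration-only model).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    species = list(species) if species is not None else sorted(counts)
    weights: dict[str, float] = {SEX_COLUMN: 1.0}
    for sp in species:
        c = counts.get(sp, 0)
        if c < 0:
            raise ValueError(f"negative renal count for {sp!r}")
        w = float((1.0 + c) ** (-gamma))
        weights[sp] = w
        weights[sp + INTERACTION_SUFFIX] = w
    return weights


# ---------------------------------------------------------------------------
# elastic-net logistic solver (IRLS + cyclic coordinate descent).
# The kernel is numba-compiled: LOCV refits the path n times per
# hyperparameter setting, which is prohibitive in interpreted Python.

from numba import njit

_WMIN = 1e-5  # floor on IRLS weights, as in standard glm path fitting


@njit(cache=True)
def _irls_cd(X, y, lam, alpha, pf, beta, b0, tol, max_outer, max_inner):
    n, p = X.shape
    wn = np.empty(n)
    r = np.empty(n)
    for _outer in range(max_outer):
        # quadratic approximation at the current linear predictor
        wsum = 0.0
        for i in range(n):
            eta = b0
            for j in range(p):
                eta += X[i, j] * beta[j]
            mu = 1.0 / (1.0 + np.exp(-eta))
            # saturate extreme fitted probabilities (standard glm path
            # practice) so working residuals stay bounded near separation
            if mu > 1.0 - _WMIN:
                mu = 1.0
                w = _WMIN
            elif mu < _WMIN:
                mu = 0.0
                w = _WMIN
            else:
                w = mu * (1.0 - mu)
            wn[i] = w / n
            wsum += wn[i]
            r[i] = (y[i] - mu) / w  # z - eta
        xv = np.empty(p)  # (1/n) sum_i w_i x_ij^2
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += wn[i] * X[i, j] * X[i, j]
            xv[j] = s
        beta_out = beta.copy()
        b0_out = b0
        # active-set strategy: full sweep, then iterate the nonzero set to
        # convergence, then re-check the full set for violations
        full_sweep = True
        for _inner in range(max_inner):
            delta = 0.0
            for j in range(p):
                if not full_sweep and beta[j] == 0.0:
                    continue
                bj = beta[j]
                rho = xv[j] * bj
                for i in range(n):
                    rho += wn[i] * X[i, j] * r[i]
                thr = lam * alpha * pf[j]
                if rho > thr:
                    new = (rho - thr) / (xv[j] + lam * (1.0 - alpha) * pf[j])
                elif rho < -thr:
                    new = (rho + thr) / (xv[j] + lam * (1.0 - alpha) * pf[j])
                else:
                    new = 0.0
                if new != bj:
                    diff = new - bj
                    for i in range(n):
                        r[i] -= X[i, j] * diff
                    beta[j] = new
                    if abs(diff) > delta:
                        delta = abs(diff)
            db0 = 0.0
            for i in range(n):
                db0 += wn[i] * r[i]
            db0 /= wsum
            if db0 != 0.0:
                b0 += db0
                for i in range(n):
                    r[i] -= db0
                if abs(db0) > delta:
                    delta = abs(db0)
            if delta < tol:
                if full_sweep:
                    break  # converged with no violations on the full set
                full_sweep = True
            else:
                full_sweep = False
        chg = abs(b0 - b0_out)
        for j in range(p):
            if abs(beta[j] - beta_out[j]) > chg:
                chg = abs(beta[j] - beta_out[j])
        if chg < 10.0 * tol:
            break
    return b0


def _enet_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    pf: np.ndarray,
    beta0: np.ndarray | None = None,
    b0: float = 0.0,
    tol: float = 1e-7,
    max_outer: int = 10,
    max_inner: int = 1000,
) -> tuple[float, np.ndarray]:
    """Penalized logistic fit; returns (intercept, coefficients).

    ``pf`` are per-feature penalty factors; the intercept is never
    penalized.  Convergence: max absolute coefficient change < ``tol``
    within the working quadratic, outer loop to a fixed point of the IRLS
    reweighting.
    """
    beta = np.zeros(X.shape[1]) if beta0 is None else beta0.copy()
    b0 = _irls_cd(
        np.ascontiguousarray(X, dtype=np.float64),
        np.asarray(y, dtype=np.float64),
        float(lam), float(alpha), np.asarray(pf, dtype=np.float64),
        beta, float(b0), float(tol), max_outer, max_inner,
    )
    return float(b0), beta


def _lambda_grid(X, y, alpha, pf, n_lambda=20, ratio=0.01) -> np.ndarray:
    n = X.shape[0]
    pbar = y.mean()
    grad = np.abs(X.T @ (y - pbar)) / n
    with np.errstate(divide="ignore"):
        lam_max = np.max(grad / (max(alpha, 1e-3) * pf))
    lam_max = float(max(lam_max, 1e-6)) * 1.05
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _predict_class(b0: float, beta: np.ndarray, x: np.ndarray) -> int:
    return int((b0 + x @ beta) > 0.0)  # probability threshold 0.5


def locv_error_path(
    X: np.ndarray,
    y: np.ndarray,
    lams: Sequence[float],
    alpha: float,
    pf: np.ndarray,
) -> np.ndarray:
    """Leave-one-out misclassification rate at each lambda (descending).

    n refits per lambda, warm-started along the path within each fold;
    training folds that collapse to a single class predict that class.
    """
    n, p = X.shape
    lams = np.sort(np.asarray(lams, dtype=float))[::-1]
    errors = np.zeros(len(lams))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        if ytr.min() == ytr.max():
            errors += int(ytr[0]) != int(y[i])
            continue
        beta = np.zeros(p)
        b0 = 0.0
        for li, lam in enumerate(lams):
            b0, beta = _enet_logistic(Xtr, ytr, lam, alpha, pf, beta, b0)
            errors[li] += _predict_class(b0, beta, X[i]) != int(y[i])
    return errors / n


def fit_signature(
    features: FeatureMatrix,
    outcome: Sequence[str] | np.ndarray,
    weights: Mapping[str, float] | None = None,
    alpha: float = 0.5,
    lambda_grid: Sequence[float] | None = None,
    seed: int | None = None,
    renal_counts: Mapping[str, int] | None = None,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    positive: str = "MA",
) -> SignatureModel:
    """Elastic-net logistic selection with LOCV over lambda (and gamma).

    ``outcome`` holds MA/N labels (``positive`` is the event class).  When
    ``renal_counts`` is given, penalty factors (1+count)^(-gamma) are tuned
    over ``gamma_grid`` jointly with lambda; otherwise ``weights`` (uniform
    if None) fix a single gamma setting.  Every (gamma, lambda) is scored
    by leave-one-out misclassification at probability threshold 0.5; ties
    at the optimum break toward larger lambda (sparser), then smaller
    gamma, and all tied settings are refit on the full data with their
    coefficient vectors averaged into the returned composite.
    """
    y = (np.asarray(outcome) == positive).astype(float)
    if len(y) != len(features.frame):
        raise ValueError("outcome length does not match feature rows")
    if len(y) < 4 or y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need n >= 4 with at least 2 samples per class")
    X = features.X()
    names = features.predictors
    n, p = X.shape

    if renal_counts is not None:
        settings = [
            (g, renal_penalty_weights(renal_counts, g, features.species))
            for g in gamma_grid
        ]
    else:
        settings = [(None, dict(weights) if weights else {})]

    candidates = []  # (misclass, -lambda, gamma_rank, gamma, lam, pf)
    for g_rank, (gamma, wmap) in enumerate(settings):
        pf = np.array([wmap.get(nm, 1.0) for nm in names], dtype=float)
        lams = (
            np.asarray(lambda_grid, dtype=float)
            if lambda_grid is not None
            else _lambda_grid(X, y, alpha, pf)
        )
        lams = np.sort(lams)[::-1]
        errors = locv_error_path(X, y, lams, alpha, pf)
        for li, lam in enumerate(lams):
            candidates.append((errors[li], -lam, g_rank, gamma, float(lam), pf))

    best_err = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] == best_err]
    # selection for reporting: largest lambda, then smallest gamma
    tied.sort(key=lambda c: (c[1], c[2]))
    sel_err, _, _, sel_gamma, sel_lam, _ = tied[0]

    # averaged composite over all tied settings, each refit on the full data
    betas, b0s = [], []
    for _, _, _, gamma, lam, pf in tied:
        b0, beta = _enet_logistic(X, y, lam, alpha, pf)
        betas.append(beta)
        b0s.append(b0)
    beta_avg = np.mean(betas, axis=0)
    b0_avg = float(np.mean(b0s))

    sel_pf = tied[0][5]
    return SignatureModel(
        intercept=b0_avg,
        coefficients={nm: float(b) for nm, b in zip(names, beta_avg)},
        hyperparameters={"alpha": alpha, "lambda": sel_lam, "gamma": sel_gamma},
        penalty_weights={nm: float(w) for nm, w in zip(names, sel_pf)},
        locv_misclassification=float(sel_err),
        averaged_from=len(tied),
    )


def score(
    model: SignatureModel, features: Mapping[str, float] | pd.Series
) -> tuple[float, float]:
    """(log-odds, probability) for one sample's feature row.

    The log-odds score is the intercept plus the coefficient-weighted sum
    of features; features the row does not provide are treated as 0 with a
    warning.  For men the women indicator and every interaction feature
    are 0, so "X Women" terms contribute nothing.
    """
    if isinstance(features, pd.Series):
        features = features.to_dict()
    total = model.intercept
    missing = []
    for name, coef in model.coefficients.items():
        if coef == 0.0:
            continue
        if name in features:
            total += coef * float(features[name])
        else:
            missing.append(name)
    if missing:
        warnings.warn(
            f"features treated as 0 (absent from sample): {missing}", stacklevel=2
        )
    prob = 1.0 / (1.0 + np.exp(-total))
    return float(total), float(prob)


def sample_features(
    cq_values: Mapping[str, float], sex: str, max_cycles: int = 40
) -> dict[str, float]:
    """Build one sample's feature row from raw Cq values (censored = 40)."""
    women = 1.0 if sex == "F" else 0.0
    feats: dict[str, float] = {SEX_COLUMN: women}
    for sp, cqv in cq_values.items():
        f = float(max_cycles) - float(cqv)
        feats[sp] = f
        feats[sp + INTERACTION_SUFFIX] = f * women
    return feats


def signature_membership(model: SignatureModel) -> set[str]:
    """Distinct miRNAs carrying any nonzero coefficient (main or
    interaction; the sex indicator itself is not a miRNA)."""
    members = set()
    for name, coef in model.coefficients.items():
        if coef == 0.0 or name == SEX_COLUMN:
            continue
        members.add(name.removesuffix(INTERACTION_SUFFIX))
    return members


def feature_auc(values: Sequence[float], outcome: Sequence[str],
                positive: str = "MA") -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    from sklearn.metrics import roc_auc_score

    y = (np.asarray(outcome) == positive).astype(int)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    return float(roc_auc_score(y, np.asarray(values, dtype=float)))


def load_table2_models() -> dict[str, SignatureModel]:
    """The two packaged published models as SignatureModel objects."""
    df = load_table2_fixture()
    out = {}
    for col in df.columns:
        coefs = df[col].dropna()
        out[col] = SignatureModel(
            intercept=float(coefs.loc["Intercept"]),
            coefficients={k: float(v) for k, v in coefs.items() if k != "Intercept"},
            hyperparameters={"source": "packaged"},
        )
    return out


class ElasticNetSignature:
    """Model object: elastic-net prognostic signature selection.

    Thin statsmodels-style wrapper over :func:`fit_signature`; ``fit``
    returns the :class:`SignatureModel` results object.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        outcome: Sequence[str],
        alpha: float = 0.5,
        weights: Mapping[str, float] | None = None,
        renal_counts: Mapping[str, int] | None = None,
        gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
        lambda_grid: Sequence[float] | None = None,
    ) -> None:
        self.features = features
        self.outcome = np.asarray(outcome)
        self.alpha = alpha
        self.weights = weights
        self.renal_counts = renal_counts
        self.gamma_grid = gamma_grid
        self.lambda_grid = lambda_grid

    @classmethod
    def from_cq(cls, cq: CqMatrix, samples: SampleTable,
                exclude: Sequence[str] = (), **kw) -> "ElasticNetSignature":
        feats = build_features(cq, samples, exclude=exclude)
        return cls(feats, samples.group_labels(), **kw)

    def fit(self, seed: int | None = None) -> SignatureModel:
        return fit_signature(
            self.features,
            self.outcome,
            weights=self.weights,
            alpha=self.alpha,
            lambda_grid=self.lambda_grid,
            seed=seed,
            renal_counts=self.renal_counts,
            gamma_grid=self.gamma_grid,
        )
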