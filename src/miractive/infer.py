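"""Per-patient elastic-net regression of gene differential expression on the
signed target matrix.

For each patient the genome-wide normalized differential expression y is
modelled as y ~ N @ beta, where N is the genes x miRNAs matrix of -1/0
target indicators and beta holds one signed "influence" per miRNA.  The
coefficients minimize

    1/(2 * n_genes) * ||y - N beta||^2
        + lambda * (alpha * ||beta||_1 + (1 - alpha)/2 * ||beta||_2^2)

— the scaling by the number of genes makes lambda comparable across gene
spaces of different size.  No intercept is fitted (y is already centred on
the healthy cohort) and predictor columns are not re-standardized by
default: they are -1/0 indicators on a shared, meaningful scale.

The penalty weight lambda is chosen by K-fold cross-validation where the
*genes* (the regression's observations) are partitioned into folds; the
cohort is then refit at the arithmetic mean of the per-patient selections so
every patient's sparsity level is directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from sklearn.linear_model import ElasticNet

from .io import RunConfig, ValidationError
from .network import SignedTargetMatrix
from .preprocess import NormalizedDEMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetSpec",
    "InfluenceVector",
    "LambdaCV",
    "CohortFit",
    "lambda_max",
    "lambda_path",
    "fit_patient",
    "cross_validate_lambda",
    "select_lambda_cv",
    "fit_cohort",
]

#: number of penalty values on the cross-validation path
PATH_LENGTH = 100
#: ratio of the smallest to the largest path penalty
PATH_MIN_RATIO = 1e-3
#: solver tolerance (sklearn duality-gap criterion)
SOLVER_TOL = 1e-7
SOLVER_MAX_ITER = 100_000


@dataclass(frozen=True)
class ElasticNetSpec:
    """Penalty specification: ``alpha`` is the L1 mixing weight in (0, 1],
    ``lam`` the overall penalty scale (lambda >= 0)."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValidationError("alpha must be in (0, 1]")
        if self.lam < 0:
            raise ValidationError("lambda must be nonnegative")


@dataclass(frozen=True)
class InfluenceVector:
    """One patient's fitted miRNA influence coefficients.

    A positive coefficient means the miRNA's targets are shifted in the
    direction its differential expression would shift them if the miRNA
    itself rose — i.e. the influence sign is directly comparable with the
    sign of the miRNA's own differential expression.
    """

    patient_id: str
    mirna_ids: tuple[str, ...]
    beta: np.ndarray
    lambda_used: float
    alpha_used: float

    def __post_init__(self) -> None:
        if len(self.beta) != len(self.mirna_ids):
            raise ValidationError("beta length must equal number of miRNA ids")
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("beta must be finite")
        if self.lambda_used < 0:
            raise ValidationError("lambda_used must be nonnegative")

    def nonzero(self) -> dict[str, float]:
        return {
            m: float(b)
            for m, b in zip(self.mirna_ids, self.beta)
            if b != 0.0
        }


def _as_design(N: SignedTargetMatrix | np.ndarray) -> np.ndarray:
    if isinstance(N, SignedTargetMatrix):
        return N.dense()
    return np.asfortranarray(np.asarray(N, dtype=float))


def _solve(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    gram: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize the stated objective; exact least squares when lam == 0."""
    if lam == 0.0:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef
    model = ElasticNet(
        alpha=lam,
        l1_ratio=alpha,
        fit_intercept=False,
        tol=SOLVER_TOL,
        max_iter=SOLVER_MAX_ITER,
        precompute=gram if gram is not None else False,
    )
    model.fit(X, y, check_input=False)
    return model.coef_


def lambda_max(y: np.ndarray, X: np.ndarray, alpha: float) -> float:
    """Smallest penalty at which the solution is exactly zero:
    max_j |X_j' y| / (n * alpha)."""
    n = X.shape[0]
    return float(np.max(np.abs(X.T @ y)) / (n * alpha))


def lambda_path(y: np.ndarray, X: np.ndarray, alpha: float) -> np.ndarray:
    """Log-spaced penalty path from lambda_max down to 1e-3 * lambda_max."""
    lmax = lambda_max(y, X, alpha)
    if lmax == 0.0:
        return np.zeros(PATH_LENGTH)
    return lmax * np.logspace(0.0, np.log10(PATH_MIN_RATIO), PATH_LENGTH)


def _standardized(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = X.std(axis=0, ddof=0)
    if np.any(scale == 0):
        raise ValidationError("cannot standardize a constant predictor column")
    return np.asfortranarray(X / scale), scale


def fit_patient(
    y: np.ndarray,
    N: SignedTargetMatrix | np.ndarray,
    spec: ElasticNetSpec,
    patient_id: str = "",
    gram: np.ndarray | None = None,
    standardize: bool = False,
) -> InfluenceVector:
    """Fit one patient's influence vector at a fixed penalty.

    ``gram`` may carry a precomputed ``X.T @ X`` for the design (used heavily
    during cross-validation); passing it does not change the solution.
    """
    X = _as_design(N)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != X.shape[0]:
        raise ValidationError(
            f"y has shape {y.shape}, expected ({X.shape[0]},) to match N's rows"
        )
    if standardize:
        Xs, scale = _standardized(X)
        coef = _solve(Xs, y, spec.lam, spec.alpha, None) / scale
    else:
        coef = _solve(X, y, spec.lam, spec.alpha, gram)
    mirna_ids = (
        N.mirna_ids
        if isinstance(N, SignedTargetMatrix)
        else tuple(f"m{j}" for j in range(X.shape[1]))
    )
    return InfluenceVector(
        patient_id=patient_id,
        mirna_ids=mirna_ids,
        beta=coef,
        lambda_used=spec.lam,
        alpha_used=spec.alpha,
    )


@dataclass(frozen=True)
class LambdaCV:
    """Cross-validation trace: the penalty path, per-fold held-out errors,
    their means/standard errors, and the two selection rules' choices."""

    path: np.ndarray
    fold_errors: np.ndarray  # (n_folds, len(path))
    mean_errors: np.ndarray
    se_errors: np.ndarray
    lambda_min: float
    lambda_1se: float

    def selected(self, rule: str = "min") -> float:
        if rule == "min":
            return self.lambda_min
        if rule == "1se":
            return self.lambda_1se
        raise ValidationError(f"unknown lambda rule {rule!r}")


def _fold_assignment(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), n_folds)


def cross_validate_lambda(
    y: np.ndarray,
    N: SignedTargetMatrix | np.ndarray,
    alpha: float,
    n_folds: int = 10,
    seed: int = 0,
) -> LambdaCV:
    """K-fold cross-validation over the penalty path.

    Genes are the observations: a seeded random partition assigns each gene
    to one fold; for every path penalty the model is refit on the training
    genes of each fold and scored by mean squared error on the held-out
    genes.  ``lambda_min`` minimizes the fold-mean error (ties broken
    towards the larger penalty, since the path descends); ``lambda_1se`` is
    the largest penalty whose mean error is within one standard error of
    that minimum.
    """
    X = _as_design(N)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if y.shape != (n,):
        raise ValidationError("y must be one column aligned to N's rows")
    if n_folds < 2 or n_folds > n:
        raise ValidationError("n_folds must be in [2, n_genes]")

    path = lambda_path(y, X, alpha)
    folds = _fold_assignment(n, n_folds, seed)
    errors = np.empty((n_folds, len(path)))
    mask = np.ones(n, dtype=bool)
    for f, test_idx in enumerate(folds):
        mask[:] = True
        mask[test_idx] = False
        X_train = np.asfortranarray(X[mask])
        y_train = y[mask]
        X_test = X[test_idx]
        y_test = y[test_idx]
        gram = X_train.T @ X_train
        for k, lam in enumerate(path):
            coef = _solve(X_train, y_train, lam, alpha, gram)
            resid = y_test - X_test @ coef
            errors[f, k] = float(resid @ resid) / len(test_idx)

    mean_err = errors.mean(axis=0)
    se_err = errors.std(axis=0, ddof=1) / np.sqrt(n_folds)
    k_min = int(np.argmin(mean_err))  # first index = largest lambda on ties
    threshold = mean_err[k_min] + se_err[k_min]
    k_1se = int(np.argmax(mean_err <= threshold))
    return LambdaCV(
        path=path,
        fold_errors=errors,
        mean_errors=mean_err,
        se_errors=se_err,
        lambda_min=float(path[k_min]),
        lambda_1se=float(path[k_1se]),
    )


def select_lambda_cv(
    y: np.ndarray,
    N: SignedTargetMatrix | np.ndarray,
    alpha: float,
    n_folds: int = 10,
    seed: int = 0,
    rule: str = "min",
) -> float:
    """Cross-validated penalty for one patient (see :func:`cross_validate_lambda`)."""
    return cross_validate_lambda(y, N, alpha, n_folds=n_folds, seed=seed).selected(rule)


@dataclass(frozen=True)
class CohortFit:
    """All patients refit at the cohort penalty.

    Iterates as a sequence of :class:`InfluenceVector`.  ``patient_lambdas``
    keeps each patient's own cross-validated choice, ``lambda_bar`` their
    arithmetic mean, the penalty actually used for the refits.
    """

    influences: tuple[InfluenceVector, ...]
    patient_lambdas: dict[str, float]
    lambda_bar: float
    alpha: float

    def __iter__(self) -> Iterator[InfluenceVector]:
        return iter(self.influences)

    def __len__(self) -> int:
        return len(self.influences)

    def __getitem__(self, i: int) -> InfluenceVector:
        return self.influences[i]

    @property
    def mirna_ids(self) -> tuple[str, ...]:
        return self.influences[0].mirna_ids

    def beta_matrix(self) -> np.ndarray:
        """miRNAs x patients grid of influence coefficients."""
        return np.column_stack([v.beta for v in self.influences])


def _patient_seeds(seed: int, n: int) -> np.ndarray:
    """Derive one fold-assignment seed per patient from the run seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31)


def fit_cohort(
    Y: NormalizedDEMatrix,
    N: SignedTargetMatrix,
    config: RunConfig,
) -> CohortFit:
    """Cross-validate a penalty per patient, average, and refit everyone.

    Y's feature order must equal N's gene order exactly (align and subset
    before calling).  The per-patient penalties and their mean are logged.
    """
    if list(Y.feature_ids) != list(N.gene_ids):
        raise ValidationError("Y feature order must match N gene order exactly")
    X = N.dense()
    values = Y.values
    patients = Y.patient_ids
    seeds = _patient_seeds(config.seed, len(patients))

    lambdas: dict[str, float] = {}
    for i, pid in enumerate(patients):
        cv = cross_validate_lambda(
            values[:, i], X, config.alpha, n_folds=config.cv_folds, seed=int(seeds[i])
        )
        lambdas[pid] = cv.selected(config.lambda_rule)
    lam_bar = float(np.mean(list(lambdas.values())))
    logger.info(
        "cohort lambda: mean %.6g over %d patients (rule=%s)",
        lam_bar,
        len(patients),
        config.lambda_rule,
    )

    gram = X.T @ X
    spec = ElasticNetSpec(alpha=config.alpha, lam=lam_bar)
    influences = tuple(
        fit_patient(
            values[:, i],
            N,
            spec,
            patient_id=pid,
            gram=gram,
            standardize=config.standardize,
        )
        for i, pid in enumerate(patients)
    )
    return CohortFit(
        influences=influences,
        patient_lambdas=lambdas,
        lambda_bar=lam_bar,
        alpha=config.alpha,
    )
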