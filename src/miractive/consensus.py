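"""Cohort-level consensus calls, sign validation, and the permutation test.

A miRNA becomes a consensus call when its fitted influence is nonzero *with
the same sign* in more than a configured fraction of patients.  Because the
fraction must exceed 0.5, at most one sign can qualify.  Calls are then
checked against observed miRNA differential expression: a call validates
when the measured sign agrees with the predicted influence sign in more
than a configured fraction of the measured patients (a zero measurement
never counts as concordant).  Significance of the whole call set is
assessed by re-running the validation rule on randomly drawn miRNA sets
with random signs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .infer import InfluenceVector
from .io import ValidationError
from .preprocess import NormalizedDEMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusCall",
    "ConsensusCallSet",
    "call_active",
    "validate_calls",
    "permutation_pvalue",
]


@dataclass(frozen=True)
class ConsensusCall:
    """One consensus-active miRNA.

    ``fraction_validated`` and ``validated_flag`` stay ``None`` until
    measurements are supplied; ``measured=False`` marks miRNAs absent from
    the measurement matrix (retained but unvalidatable).
    """

    mirna_id: str
    sign: int
    fraction_active: float
    fraction_validated: float | None = None
    validated_flag: bool | None = None
    measured: bool = True

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValidationError("sign must be -1 or +1")
        if not (0 <= self.fraction_active <= 1):
            raise ValidationError("fraction_active must lie in [0, 1]")
        if self.fraction_validated is not None and not (
            0 <= self.fraction_validated <= 1
        ):
            raise ValidationError("fraction_validated must lie in [0, 1]")


@dataclass(frozen=True)
class ConsensusCallSet:
    """The calls plus the thresholds that produced them.

    ``not_assessable`` lists miRNAs that never entered the regression (no
    targets in the gene space), so absence from ``calls`` says nothing
    about them.
    """

    calls: tuple[ConsensusCall, ...]
    consensus_fraction: float | None = None
    validation_fraction: float | None = None
    not_assessable: tuple[str, ...] = field(default=())

    def __iter__(self) -> Iterator[ConsensusCall]:
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def signs(self) -> dict[str, int]:
        return {c.mirna_id: c.sign for c in self.calls}

    def validation_rate(self) -> float:
        """Fraction of measured calls that passed the validation rule."""
        measured = [c for c in self.calls if c.measured]
        if not measured:
            return 0.0
        return sum(bool(c.validated_flag) for c in measured) / len(measured)


def call_active(
    influences: Iterable[InfluenceVector],
    consensus_fraction: float,
    not_assessable: Sequence[str] = (),
) -> ConsensusCallSet:
    """Call miRNAs whose influence sign recurs in > ``consensus_fraction``
    of patients.

    The denominator is the full cohort: patients with a zero coefficient
    count against the fraction.
    """
    vectors = list(influences)
    if not vectors:
        raise ValidationError("empty cohort: no influence vectors")
    if not (0.5 < consensus_fraction <= 1):
        raise ValidationError("consensus_fraction must be in (0.5, 1]")
    mirna_ids = vectors[0].mirna_ids
    for v in vectors:
        if v.mirna_ids != mirna_ids:
            raise ValidationError("all influence vectors must share one miRNA vocabulary")

    B = np.column_stack([v.beta for v in vectors])  # miRNAs x patients
    n = B.shape[1]
    pos = (B > 0).sum(axis=1) / n
    neg = (B < 0).sum(axis=1) / n

    calls = []
    for j, mirna in enumerate(mirna_ids):
        if pos[j] > consensus_fraction:
            calls.append(
                ConsensusCall(mirna_id=mirna, sign=1, fraction_active=float(pos[j]))
            )
        elif neg[j] > consensus_fraction:
            calls.append(
                ConsensusCall(mirna_id=mirna, sign=-1, fraction_active=float(neg[j]))
            )
    logger.info("called %d of %d miRNAs active", len(calls), len(mirna_ids))
    return ConsensusCallSet(
        calls=tuple(calls),
        consensus_fraction=consensus_fraction,
        not_assessable=tuple(not_assessable),
    )


def _concordance_fractions(
    mirna_de: NormalizedDEMatrix, patient_ids: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Per-miRNA fraction of patients with strictly positive measured DE."""
    data = mirna_de.data
    if patient_ids is not None:
        data = data[[p for p in patient_ids if p in data.columns]]
    values = data.to_numpy()
    pos_frac = (values > 0).mean(axis=1)
    return list(data.index), pos_frac


def validate_calls(
    calls: ConsensusCallSet,
    mirna_de: NormalizedDEMatrix,
    validation_fraction: float,
    patient_ids: Sequence[str] | None = None,
) -> ConsensusCallSet:
    """Check each call's sign against observed miRNA differential expression.

    For a call with sign s, ``fraction_validated`` is the fraction of
    measured patients whose miRNA DE sign equals s (zeros count as
    discordant); the call validates when that fraction strictly exceeds
    ``validation_fraction``.  miRNAs missing from the measurement matrix are
    kept, flagged unmeasured.
    """
    if not (0.5 < validation_fraction <= 1):
        raise ValidationError("validation_fraction must be in (0.5, 1]")
    data = mirna_de.data
    if patient_ids is not None:
        overlap = [p for p in patient_ids if p in data.columns]
        if not overlap:
            raise ValidationError("no overlapping patients between calls and measurements")
        data = data[overlap]
    values = data.to_numpy()
    row_of = {m: i for i, m in enumerate(data.index)}

    updated = []
    for c in calls:
        i = row_of.get(c.mirna_id)
        if i is None:
            updated.append(
                replace(c, fraction_validated=None, validated_flag=None, measured=False)
            )
            continue
        concordant = (np.sign(values[i]) == c.sign).mean()
        updated.append(
            replace(
                c,
                fraction_validated=float(concordant),
                validated_flag=bool(concordant > validation_fraction),
                measured=True,
            )
        )
    return ConsensusCallSet(
        calls=tuple(updated),
        consensus_fraction=calls.consensus_fraction,
        validation_fraction=validation_fraction,
        not_assessable=calls.not_assessable,
    )


def permutation_pvalue(
    calls: ConsensusCallSet,
    mirna_de: NormalizedDEMatrix,
    validation_fraction: float,
    n_permutations: int = 10_000,
    seed: int = 0,
    plus_one_correction: bool = True,
    return_distribution: bool = False,
):
    """Permutation p-value for the call set's validation rate.

    Each permutation draws, without replacement, as many measured miRNAs as
    there are calls, assigns each an independent random sign, and applies
    the same validation rule; the p-value is the fraction of permutations
    whose validation rate strictly exceeds the method's own (with a
    +1/(n+1) correction by default so the reported p is never exactly 0).
    """
    if len(calls) == 0:
        raise ValidationError("nothing to test: empty call set")
    validated = validate_calls(calls, mirna_de, validation_fraction)
    observed_rate = validated.validation_rate()

    mirna_ids, pos_frac = _concordance_fractions(mirna_de)
    n_universe = len(mirna_ids)
    k = len(calls)
    if n_universe < k:
        raise ValidationError(
            f"only {n_universe} measured miRNAs but {k} calls to emulate"
        )
    # a random +1 call passes iff pos_frac > vf; a -1 call iff neg_frac > vf
    pass_pos = pos_frac > validation_fraction
    neg_frac = (mirna_de.values < 0).mean(axis=1)
    pass_neg = neg_frac > validation_fraction

    rng = np.random.default_rng(seed)
    keys = rng.random((n_permutations, n_universe))
    drawn = np.argpartition(keys, k - 1, axis=1)[:, :k]
    signs_positive = rng.random((n_permutations, k)) < 0.5
    passed = np.where(signs_positive, pass_pos[drawn], pass_neg[drawn])
    rates = passed.mean(axis=1)

    exceed = int((rates > observed_rate).sum())
    if plus_one_correction:
        p = (exceed + 1) / (n_permutations + 1)
    else:
        p = exceed / n_permutations
    logger.info(
        "permutation test: observed rate %.3f, %d/%d permutations exceed, p=%.4g",
        observed_rate,
        exceed,
        n_permutations,
        p,
    )
    if return_distribution:
        return float(p), rates
    return float(p)
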