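"""Reading and writing of expression matrices, interaction networks and result tables.

All on-disk formats are plain text:

* expression — TSV, one row per feature (gene or miRNA), first column holds
  feature ids, header row holds sample ids, body is strictly positive
  linear-scale intensities;
* network — two-column TSV edge list ``mirna_id<TAB>gene_id`` (a GMT file
  where each set is a miRNA and its members are target genes is also
  accepted);
* consensus calls — TSV with one row per called miRNA;
* run configuration — YAML or JSON.

Feature and sample identifiers are treated as opaque strings and matched
exactly; no symbol normalization is attempted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "EdgeList",
    "RunConfig",
    "ValidationError",
    "read_expression",
    "write_expression",
    "read_network",
    "write_results",
    "read_results",
    "read_config",
    "write_config",
]


class ValidationError(ValueError):
    """An input violated a schema or value constraint."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what} ids: {sorted(set(dups))[:10]}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features x samples grid of strictly positive, linear-scale intensities.

    The positivity requirement exists because the first processing step is a
    logarithm; zeros or negatives must be handled (imputed/offset) upstream.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("ExpressionMatrix.data must be a DataFrame")
        _check_unique(list(df.index), "feature")
        _check_unique(list(df.columns), "sample")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite (no NaN/inf)")
        if np.any(values <= 0):
            bad = df.index[(values <= 0).any(axis=1)].tolist()
            raise ValidationError(
                f"expression values must be strictly positive; offending features: {bad[:10]}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class EdgeList:
    """A deduplicated set of (mirna_id, gene_id) interaction pairs."""

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if not m or not g:
                raise ValidationError(f"empty id in edge {(m, g)!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "EdgeList":
        return cls(frozenset((str(m), str(g)) for m, g in pairs))

    @property
    def mirnas(self) -> list[str]:
        return sorted({m for m, _ in self.edges})

    @property
    def genes(self) -> list[str]:
        return sorted({g for _, g in self.edges})

    def __len__(self) -> int:
        return len(self.edges)


_LAMBDA_RULES = ("min", "1se")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of an inference + consensus + validation run.

    alpha
        Elastic-net mixing parameter (L1 weight), in (0, 1].  0.25 by default:
        small enough that groups of miRNAs with overlapping target sets are
        selected together rather than one-of-many.
    consensus_fraction, validation_fraction
        A miRNA is called active when the same influence sign recurs in more
        than ``consensus_fraction`` of patients, and a call is validated when
        the observed miRNA differential-expression sign agrees in more than
        ``validation_fraction`` of measured patients.  Both must exceed 0.5 so
        at most one sign can qualify.
    s0
        Additive stabilizer in the normalization denominator, guarding
        against near-zero variance features.
    cancer_var_weight
        Weight of the tumour-cohort standard deviation in the normalization
        denominator; penalizes features that are wildly variable across
        patients.
    lambda_rule
        "min" selects the cross-validated penalty with the minimal mean
        held-out error; "1se" selects the sparsest penalty within one
        standard error of that minimum.
    """

    alpha: float = 0.25
    consensus_fraction: float = 0.7
    validation_fraction: float = 0.7
    n_permutations: int = 10_000
    cv_folds: int = 10
    seed: int = 0
    s0: float = 0.1
    cancer_var_weight: float = 1.0
    lambda_rule: str = "min"
    standardize: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValidationError("alpha must be in (0, 1]")
        for name in ("consensus_fraction", "validation_fraction"):
            v = getattr(self, name)
            if not (0.5 < v <= 1):
                raise ValidationError(f"{name} must be in (0.5, 1]")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be positive")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.s0 < 0:
            raise ValidationError("s0 must be nonnegative")
        if self.cancer_var_weight < 0:
            raise ValidationError("cancer_var_weight must be nonnegative")
        if self.lambda_rule not in _LAMBDA_RULES:
            raise ValidationError(f"lambda_rule must be one of {_LAMBDA_RULES}")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a features x samples TSV with a sample-id header row.

    Raises :class:`ValidationError` on duplicate ids or nonpositive values,
    and a parse error naming the offending cell for non-numeric entries.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        numeric = df.astype(float)
    except ValueError:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise ValidationError(
                    f"{path}: non-numeric value at row {row!r}, column {col!r}"
                ) from None
        raise
    mat = ExpressionMatrix(numeric)
    logger.info(
        "read expression %s: %d features x %d samples", path, *mat.shape
    )
    return mat


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(Path(path), sep="\t", index_label="feature")


def _read_gmt(path: Path) -> EdgeList:
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{i}: GMT line needs >= 3 fields")
            mirna = fields[0]
            pairs.extend((mirna, g) for g in fields[2:] if g)
    return EdgeList.from_pairs(pairs)


def read_network(path: str | Path) -> EdgeList:
    """Read a miRNA->gene edge list (2-column TSV, or GMT by extension).

    A header line is tolerated when its first token is literally ``mirna``
    (case-insensitive).  Duplicate pairs collapse to a single edge.
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        edges = _read_gmt(path)
    else:
        pairs: list[tuple[str, str]] = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValidationError(
                        f"{path}:{i}: expected 2 tab-separated fields, got {len(fields)}"
                    )
                if i == 1 and fields[0].strip().lower() == "mirna":
                    continue
                pairs.append((fields[0], fields[1]))
        edges = EdgeList.from_pairs(pairs)
    logger.info(
        "read network %s: %d miRNAs, %d genes, %d edges",
        path,
        len(edges.mirnas),
        len(edges.genes),
        len(edges),
    )
    return edges


_RESULT_COLUMNS = [
    "mirna_id",
    "sign",
    "fraction_active",
    "fraction_validated",
    "validated_flag",
]


def write_results(calls, path: str | Path) -> None:
    """Write a consensus call set as TSV.

    Rows are ordered by descending ``fraction_active`` then by miRNA id so
    repeated runs produce byte-identical files.  ``fraction_validated`` and
    ``validated_flag`` are left empty for miRNAs without measurements.
    """
    rows = []
    for c in sorted(calls, key=lambda c: (-c.fraction_active, c.mirna_id)):
        rows.append(
            {
                "mirna_id": c.mirna_id,
                "sign": c.sign,
                "fraction_active": repr(c.fraction_active),
                "fraction_validated": ""
                if c.fraction_validated is None
                else repr(c.fraction_validated),
                "validated_flag": ""
                if c.validated_flag is None
                else str(c.validated_flag),
            }
        )
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(Path(path), sep="\t", index=False)


def read_results(path: str | Path):
    """Read a call table written by :func:`write_results`."""
    from .consensus import ConsensusCall, ConsensusCallSet

    df = pd.read_csv(Path(path), sep="\t", dtype={"mirna_id": str})
    calls = []
    for _, row in df.iterrows():
        fv = row["fraction_validated"]
        flag = row["validated_flag"]
        calls.append(
            ConsensusCall(
                mirna_id=str(row["mirna_id"]),
                sign=int(row["sign"]),
                fraction_active=float(row["fraction_active"]),
                fraction_validated=None if pd.isna(fv) else float(fv),
                validated_flag=None if pd.isna(flag) else str(flag) == "True",
            )
        )
    return ConsensusCallSet(calls=tuple(calls))


def read_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            d = json.load(fh)
        else:
            d = yaml.safe_load(fh)
    return RunConfig.from_dict(d)


def write_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
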