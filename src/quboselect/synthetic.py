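"""Synthetic Likert-style survey data with planted relevance structure.

The real mental-health survey this package targets (hundreds of respondents,
low-cardinality ordinal items, a continuous summed depression score) is not
publicly available, so every downstream stage is exercised on generated
tables whose ground truth is known.  Three feature classes are planted:

* ``relevant``  — independent uniform Likert items that drive the target,
* ``redundant`` — noisy per-entry copies of a relevant parent item,
* ``noise``     — independent uniform items with no effect on the target.

The target is a linear function of centered level scores of the relevant
items plus Gaussian noise, mimicking a summed questionnaire score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "SurveyTable", "generate", "write_csv", "read_csv"]

TARGET_COLUMN = "target"


class ConfigError(ValueError):
    """Invalid generator or pipeline configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the planted-model survey generator.

    Defaults mirror the target study's scale at desk size: 751 respondents
    and 40 items (5 relevant, 5 redundant, 30 noise) with 5 Likert levels.
    """

    n_respondents: int = 751
    n_relevant: int = 5
    n_redundant: int = 5
    n_noise: int = 30
    n_levels: int = 5
    effect_size: float = 1.0
    redundancy_rho: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ConfigError(f"n_respondents must be positive, got {self.n_respondents}")
        for name in ("n_relevant", "n_redundant", "n_noise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.n_relevant + self.n_redundant + self.n_noise < 2:
            raise ConfigError("need at least 2 features in total")
        if self.n_redundant > 0 and self.n_relevant == 0:
            raise ConfigError("n_redundant > 0 requires n_relevant >= 1 (redundant items copy a relevant parent)")
        if self.n_levels < 2:
            raise ConfigError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.effect_size < 0:
            raise ConfigError(f"effect_size must be non-negative, got {self.effect_size}")
        if not 0.0 <= self.redundancy_rho <= 1.0:
            raise ConfigError(f"redundancy_rho must lie in [0, 1], got {self.redundancy_rho}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be non-negative, got {self.noise_sd}")

    @property
    def n_features(self) -> int:
        return self.n_relevant + self.n_redundant + self.n_noise


@dataclass
class SurveyTable:
    """Respondents x items integer codes plus one continuous target.

    ``features`` holds integer Likert codes (pandas nullable ``Int64`` when a
    missingness mask is present, plain ``int64`` otherwise); ``target`` is a
    float series named ``target``.
    """

    features: pd.DataFrame
    target: pd.Series

    def __post_init__(self) -> None:
        if len(self.features) != len(self.target):
            raise ValueError("features and target row counts differ")
        self.target = self.target.rename(TARGET_COLUMN)

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def has_missing(self) -> bool:
        return bool(self.features.isna().any().any())

    @property
    def X(self) -> np.ndarray:
        """Dense integer code matrix; requires a complete table."""
        if self.has_missing:
            raise ValueError("table has missing values; preprocess first")
        return self.features.to_numpy(dtype=np.int64)

    @property
    def y(self) -> np.ndarray:
        return self.target.to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.features, self.target], axis=1)


def level_scores(n_levels: int) -> np.ndarray:
    """Centered equally spaced scores -(L-1)/2 ... +(L-1)/2 per Likert level."""
    return np.arange(n_levels, dtype=float) - (n_levels - 1) / 2.0


def generate(config: GeneratorConfig) -> tuple[SurveyTable, dict[str, str]]:
    """Generate a survey table plus a per-feature ground-truth label map.

    The target is ``effect_size * sum_j z(X_j) + N(0, noise_sd)`` over the
    relevant items, with z the centered level-score map.  Each redundant
    item copies its parent entry-wise with probability ``redundancy_rho``
    and resamples uniformly otherwise; noise items are i.i.d. uniform.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, L = config.n_respondents, config.n_levels

    cols: list[np.ndarray] = []
    labels: list[str] = []

    x_rel = rng.integers(0, L, size=(n, config.n_relevant))
    for j in range(config.n_relevant):
        cols.append(x_rel[:, j])
        labels.append("relevant")

    for j in range(config.n_redundant):
        parent = x_rel[:, j % max(config.n_relevant, 1)]
        keep = rng.random(n) < config.redundancy_rho
        col = np.where(keep, parent, rng.integers(0, L, size=n))
        cols.append(col)
        labels.append("redundant")

    for _ in range(config.n_noise):
        cols.append(rng.integers(0, L, size=n))
        labels.append("noise")

    z = level_scores(L)
    signal = config.effect_size * z[x_rel].sum(axis=1) if config.n_relevant else np.zeros(n)
    y = signal + rng.normal(0.0, config.noise_sd, size=n)

    names = [f"f{i + 1}" for i in range(config.n_features)]
    features = pd.DataFrame(
        np.column_stack(cols).astype(np.int64), columns=names
    )
    table = SurveyTable(features=features, target=pd.Series(y, name=TARGET_COLUMN))
    return table, dict(zip(names, labels))


def write_csv(table: SurveyTable, path, labels: dict[str, str] | None = None) -> None:
    """Write a table to CSV (features then ``target``; no index column).

    If ``labels`` is given, the ground-truth map is written to a sidecar
    JSON file next to the CSV (same stem, ``.labels.json`` suffix).
    """
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    if labels is not None:
        sidecar = path.with_suffix(".labels.json")
        sidecar.write_text(json.dumps(labels, indent=1))


def read_csv(path) -> SurveyTable:
    """Read a survey CSV back into a :class:`SurveyTable`.

    Features must be integers (missing cells are allowed and preserved in a
    nullable integer column); the ``target`` column must be present, numeric
    and complete.  Violations raise ``ValueError`` naming the offending
    row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if TARGET_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing required column {TARGET_COLUMN!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: table has a header but no rows")

    target = pd.to_numeric(df[TARGET_COLUMN], errors="coerce")
    if target.isna().any():
        row = int(target.index[target.isna()][0])
        raise ValueError(f"{path}: non-numeric or missing target at row {row}")

    feats = df.drop(columns=[TARGET_COLUMN])
    out = {}
    for colname in feats.columns:
        col = pd.to_numeric(feats[colname], errors="coerce")
        bad = col.isna() & feats[colname].notna()
        if bad.any():
            row = int(bad.index[bad][0])
            raise ValueError(f"{path}: non-numeric feature cell at row {row}, column {colname!r}")
        observed = col.dropna()
        if not np.allclose(observed, np.round(observed)):
            row = int((col != np.round(col)).idxmax())
            raise ValueError(f"{path}: non-integer feature cell at row {row}, column {colname!r}")
        if col.isna().any():
            out[colname] = col.round().astype("Int64")
        else:
            out[colname] = col.astype(np.int64)
    features = pd.DataFrame(out, columns=list(feats.columns))
    return SurveyTable(features=features, target=target.astype(float))
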