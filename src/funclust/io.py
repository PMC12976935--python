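"""Tables, run configuration and grouping files.

Abundance and function tables are plain delimiter-separated text: one header
row of feature/function names, first column of sample identifiers. Samples
are rows, features are columns (the usual orientation of exported amplicon
or metagenome tables). ``.csv`` means comma-separated; anything else is read
as tab-separated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AbundanceMatrix",
    "FunctionMatrix",
    "RunConfig",
    "TableError",
    "DuplicateIdentifierError",
    "NegativeAbundanceError",
    "NonNumericEntryError",
    "read_abundance_table",
    "read_function_table",
    "write_table",
    "pair_samples",
    "write_grouping",
    "read_grouping",
]


class TableError(ValueError):
    """Base class for malformed input tables."""


class DuplicateIdentifierError(TableError):
    pass


class NegativeAbundanceError(TableError):
    pass


class NonNumericEntryError(TableError):
    pass


@dataclass
class AbundanceMatrix:
    """N samples x n features of non-negative, finite abundances."""

    sample_ids: list
    feature_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdentifierError("duplicate sample identifiers")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DuplicateIdentifierError("duplicate feature identifiers")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise TableError("values shape does not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise NonNumericEntryError("non-finite abundance entry")
        if np.any(self.values < 0):
            raise NegativeAbundanceError("negative abundance")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class FunctionMatrix:
    """N samples x m functional measurements; NaN marks a missing value
    (the sample is dropped when paired with abundances)."""

    sample_ids: list
    function_names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdentifierError("duplicate sample identifiers")
        if len(set(self.function_names)) != len(self.function_names):
            raise DuplicateIdentifierError("duplicate function names")
        if self.values.shape != (len(self.sample_ids), len(self.function_names)):
            raise TableError("values shape does not match identifier lists")
        if len(self.function_names) < 1:
            raise TableError("need at least one function column")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.function_names)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_frame(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    if len(set(header)) != len(header):
        # checked on the raw header because pandas de-duplicates column names
        raise DuplicateIdentifierError("duplicate column identifiers")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise NonNumericEntryError(f"non-numeric entry in column {col!r}")
    return df


def read_abundance_table(path) -> AbundanceMatrix:
    """Read a sample-by-feature abundance table; rejects negatives and NaN."""
    df = _read_frame(path)
    return AbundanceMatrix(
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def read_function_table(path) -> FunctionMatrix:
    """Read a sample-by-function table; NaN entries are kept (dropped at pairing)."""
    df = _read_frame(path)
    return FunctionMatrix(
        sample_ids=[str(s) for s in df.index],
        function_names=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_table(path, table) -> None:
    # %.17g keeps read(write(x)) exact for doubles
    table.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.17g")


def pair_samples(X: AbundanceMatrix, F: FunctionMatrix):
    """Restrict both tables to shared samples with complete function rows.

    Output order follows the abundance table. Samples whose function row has
    any missing value are dropped. Raises on an empty intersection.
    """
    f_index = {s: i for i, s in enumerate(F.sample_ids)}
    keep = [
        (i, f_index[s])
        for i, s in enumerate(X.sample_ids)
        if s in f_index and np.all(np.isfinite(F.values[f_index[s]]))
    ]
    if len(keep) < 2:
        raise TableError("fewer than 2 shared samples with complete function rows")
    xi = [i for i, _ in keep]
    fi = [j for _, j in keep]
    Xp = AbundanceMatrix(
        sample_ids=[X.sample_ids[i] for i in xi],
        feature_ids=list(X.feature_ids),
        values=X.values[xi],
    )
    Fp = FunctionMatrix(
        sample_ids=[F.sample_ids[j] for j in fi],
        function_names=list(F.function_names),
        values=F.values[fi],
    )
    return Xp, Fp


@dataclass
class RunConfig:
    """Hyperparameters of one ensemble run.

    ``tau_max``/``tau_min``/``tau_rate`` control the exponential temperature
    annealing of the Gumbel-softmax; ``gate_strength`` is the L1 gate penalty
    beta (0 disables gating); ``hidden_layers`` are the widths of the
    structure-function network.
    """

    n_clusters: int = 3
    train_fraction: float = 0.8
    n_ensemble: int = 12
    learning_rate: float = 1e-2
    tau_max: float = 1.0
    tau_min: float = 0.1
    tau_rate: float = 1e-3
    gate_strength: float = 0.0
    max_iters: int = 20000
    early_stop_patience: int = 200
    seed: int = 0
    hidden_layers: tuple = (128, 128, 128)
    activation: str = "tanh"
    standardize_function: str = "auto"  # "auto" | "on" | "off"
    top_fraction: float = 0.5
    optimizer: str = "adam"  # "adam" | "sgd"
    eval_every: int = 2  # held-out loss evaluation cadence (iterations)

    def __post_init__(self):
        self.hidden_layers = tuple(int(h) for h in self.hidden_layers)
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0,1)")
        if self.n_clusters < 1:
            # n_clusters = 1 is allowed for the degenerate point of a
            # cluster-number scan; normal runs use >= 2
            raise ValueError("n_clusters must be >= 1")
        if not self.tau_min < self.tau_max:
            raise ValueError("need tau_min < tau_max")
        for name in ("learning_rate", "tau_max", "tau_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_rate < 0 or self.gate_strength < 0:
            raise ValueError("tau_rate and gate_strength must be non-negative")
        if self.n_ensemble < 1 or self.max_iters < 1 or self.early_stop_patience < 1:
            raise ValueError("counts must be positive")
        if self.eval_every < 1:
            raise ValueError("eval_every must be positive")

    @property
    def gated(self) -> bool:
        return self.gate_strength > 0

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_layers"] = list(self.hidden_layers)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def write_grouping(path, grouping) -> None:
    """Write a consensus grouping as TSV with columns feature_id, group_label,
    active_flag, agreement_fraction."""
    df = pd.DataFrame(
        {
            "feature_id": grouping.feature_ids,
            "group_label": grouping.labels,
            "active_flag": grouping.active,
            "agreement_fraction": grouping.agreement,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_grouping(path):
    from .consensus import ConsensusGrouping

    df = pd.read_csv(path, sep="\t")
    return ConsensusGrouping(
        feature_ids=[str(f) for f in df["feature_id"]],
        labels=df["group_label"].to_numpy(dtype=int),
        active=df["active_flag"].to_numpy(dtype=bool),
        agreement=df["agreement_fraction"].to_numpy(dtype=float),
    )
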