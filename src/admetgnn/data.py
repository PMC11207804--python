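"""Dataset readers and statistics.

Input tables are CSV (header row, configurable SMILES/label column names).
Records with unparsable SMILES are dropped and counted, never silently
ignored.  The six public ADMET benchmarks (Lipophilicity AZ, AqSolDB and the
four CYP inhibition sets) are fetched through the Therapeutics Data Commons
client when it is installed; otherwise :func:`load_benchmark` raises a clear
offline error directing the caller to :func:`read_smiles_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .molgraph import SmilesParseError, parse_smiles

BENCHMARKS = {
    "lipo_az": ("Lipophilicity_AstraZeneca", "regression"),
    "aqsoldb": ("Solubility_AqSolDB", "regression"),
    "cyp2c9": ("CYP2C9_Veith", "classification"),
    "cyp2c19": ("CYP2C19_Veith", "classification"),
    "cyp2d6": ("CYP2D6_Veith", "classification"),
    "cyp3a4": ("CYP3A4_Veith", "classification"),
}


class EmptyDatasetError(ValueError):
    pass


class BenchmarkUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class LabeledRecord:
    id: str
    smiles: str
    label: float


@dataclass
class DatasetStats:
    n_total: int
    n_dropped: int
    max_atoms: int
    task: str
    n_positive: int | None = None
    n_negative: int | None = None
    positive_fraction: float | None = None
    label_quantiles: dict[str, float] | None = None

    def __str__(self) -> str:
        lines = [f"n_total:           {self.n_total}",
                 f"n_dropped:         {self.n_dropped}",
                 f"max_heavy_atoms:   {self.max_atoms}"]
        if self.task == "classification":
            lines += [f"n_positive:        {self.n_positive}",
                      f"n_negative:        {self.n_negative}",
                      f"positive_fraction: {self.positive_fraction:.4f}"]
        else:
            lines += [f"label_quantiles:   {self.label_quantiles}"]
        return "\n".join(lines)


def dataset_stats(records: list[LabeledRecord], task: str = "classification",
                  n_dropped: int = 0) -> DatasetStats:
    """Counts, prevalence (classification) or label quantiles (regression),
    and the maximum heavy-atom count (which sets the padding size n_max)."""
    if not records:
        raise EmptyDatasetError("no records to summarize")
    labels = np.array([r.label for r in records], dtype=float)
    max_atoms = max(parse_smiles(r.smiles).n_atoms for r in records)
    if task == "classification":
        n_pos = int((labels == 1).sum())
        return DatasetStats(n_total=len(records), n_dropped=n_dropped,
                            max_atoms=max_atoms, task=task,
                            n_positive=n_pos, n_negative=len(records) - n_pos,
                            positive_fraction=n_pos / len(records))
    qs = np.quantile(labels, [0.0, 0.25, 0.5, 0.75, 1.0])
    return DatasetStats(n_total=len(records), n_dropped=n_dropped,
                        max_atoms=max_atoms, task=task,
                        label_quantiles={k: float(v) for k, v in
                                         zip(("min", "q25", "median", "q75", "max"), qs)})


def read_smiles_csv(path, smiles_col: str = "smiles", label_col: str = "label",
                    task: str = "classification",
                    ) -> tuple[list[LabeledRecord], DatasetStats]:
    """Read a SMILES/label table, dropping (and counting) unparsable rows."""
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyDatasetError(f"{path} contains no rows")
    for col in (smiles_col, label_col):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found; available: {list(df.columns)}")
    records, n_dropped = [], 0
    for i, row in df.iterrows():
        smiles = str(row[smiles_col])
        try:
            parse_smiles(smiles)
        except SmilesParseError:
            n_dropped += 1
            continue
        label = float(row[label_col])
        if task == "classification" and label not in (0.0, 1.0):
            raise ValueError(f"row {i}: classification label must be 0/1, got {label}")
        records.append(LabeledRecord(id=str(row.get("id", i)), smiles=smiles,
                                     label=label))
    if not records:
        raise EmptyDatasetError(f"{path}: no parsable records")
    return records, dataset_stats(records, task, n_dropped)


def load_benchmark(name: str, cache_dir=None
                   ) -> tuple[list[LabeledRecord], DatasetStats]:
    """Load one of the six public ADMET benchmarks via the TDC client.

    Requires network access (or a populated cache) and the ``PyTDC``
    package; raises :class:`BenchmarkUnavailableError` with an offline
    workaround otherwise.
    """
    if name not in BENCHMARKS:
        raise KeyError(f"unknown benchmark {name!r}; choose from {sorted(BENCHMARKS)}")
    tdc_name, task = BENCHMARKS[name]
    try:
        from tdc.single_pred import ADME, Tox  # noqa: F401
    except ImportError as exc:
        raise BenchmarkUnavailableError(
            f"benchmark {name!r} needs the PyTDC package and network access; "
            "offline, export the table to CSV and use read_smiles_csv()"
        ) from exc
    kwargs = {"path": str(cache_dir)} if cache_dir else {}
    try:
        data = ADME(name=tdc_name, **kwargs).get_data(format="df")
    except Exception as exc:  # fetch/IO failure
        raise BenchmarkUnavailableError(
            f"could not fetch benchmark {name!r} ({exc}); offline, use "
            "read_smiles_csv() on a local export instead") from exc
    records, n_dropped = [], 0
    for _, row in data.iterrows():
        try:
            parse_smiles(row["Drug"])
        except SmilesParseError:
            n_dropped += 1
            continue
        records.append(LabeledRecord(id=str(row["Drug_ID"]), smiles=row["Drug"],
                                     label=float(row["Y"])))
    return records, dataset_stats(records, task, n_dropped)


def records_to_frame(records: list[LabeledRecord]) -> pd.DataFrame:
    return pd.DataFrame({"id": [r.id for r in records],
                         "smiles": [r.smiles for r in records],
                         "label": [r.label for r in records]})


def write_records_csv(records: list[LabeledRecord], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False)
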