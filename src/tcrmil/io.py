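"""Reading and writing repertoire files, labels, predictions and checkpoints.

Repertoire files are tab-separated immuneACCESS-style exports: one row per
clone, with a CDR3 amino-acid column and a clone frequency/abundance column.
Column names vary between exports, so a small dialect table maps the common
variants; callers can override either column name explicitly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TCRInstance",
    "RepertoireBag",
    "ConfigurationError",
    "InputError",
    "read_repertoire_tsv",
    "load_labeled_dataset",
    "write_predictions",
    "read_predictions",
    "write_repertoire_tsv",
    "save_checkpoint",
    "load_checkpoint",
]

#: Candidate column names for each required field, tried in order.
DIALECT = {
    "cdr3": ("amino_acid", "aminoAcid", "CDR3.aa", "cdr3", "CDR3"),
    "frequency": ("frequency", "frequencyCount", "count", "freq"),
}


class ConfigurationError(ValueError):
    """A configuration problem: missing column, unmapped class name, ..."""


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class TCRInstance:
    """One CDR3 amino-acid sequence with its clone frequency (one MIL instance)."""

    cdr3: str
    frequency: float

    def __post_init__(self):
        if not self.cdr3:
            raise InputError("empty CDR3 sequence")
        if self.frequency < 0:
            raise InputError(f"negative frequency for {self.cdr3!r}")


@dataclass
class RepertoireBag:
    """One subject's repertoire: an ordered collection of TCR instances (one
    MIL bag), optionally carrying a binary label (1 = cancer, 0 = healthy)."""

    sample_id: str
    instances: list[TCRInstance] = field(default_factory=list)
    label: int | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise InputError(f"label must be 0/1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.instances)

    def total_frequency(self) -> float:
        return float(sum(i.frequency for i in self.instances))


def _resolve_column(columns: Sequence[str], field_name: str, override: str | None) -> str:
    if override is not None:
        if override not in columns:
            raise ConfigurationError(
                f"column {override!r} (for {field_name}) not present in file"
            )
        return override
    for cand in DIALECT[field_name]:
        if cand in columns:
            return cand
    raise ConfigurationError(
        f"no {field_name} column found; tried {DIALECT[field_name]}, "
        f"file has {list(columns)}"
    )


def read_repertoire_tsv(path: str | os.PathLike, cdr3_column: str | None = None,
                        frequency_column: str | None = None) -> RepertoireBag:
    """Read one repertoire TSV into an unlabeled bag.

    Rows with identical CDR3 sequences are merged by summing their
    frequencies, so downstream top-k selection ranks distinct clonotypes.
    The sample id is the file's base name without extension.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read repertoire file {path}: {exc}") from exc
    cdr3_col = _resolve_column(df.columns, "cdr3", cdr3_column)
    freq_col = _resolve_column(df.columns, "frequency", frequency_column)
    sample_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    if len(df) == 0:
        return RepertoireBag(sample_id=sample_id)
    freqs = pd.to_numeric(df[freq_col], errors="coerce")
    if freqs.isna().any():
        bad = df[freq_col][freqs.isna()].iloc[0]
        raise InputError(f"non-numeric frequency value {bad!r} in {path}")
    merged = (
        pd.DataFrame({"cdr3": df[cdr3_col].astype(str), "frequency": freqs})
        .groupby("cdr3", sort=False)["frequency"].sum()
    )
    instances = [TCRInstance(c, float(f)) for c, f in merged.items()]
    return RepertoireBag(sample_id=sample_id, instances=instances)


def load_labeled_dataset(manifest: str | os.PathLike,
                         label_map: dict[str, int] | None = None,
                         cdr3_column: str | None = None,
                         frequency_column: str | None = None) -> list[RepertoireBag]:
    """Load a labeled collection of bags.

    `manifest` is either a two-column TSV (`path`, `class`; paths relative to
    the manifest) or a directory with one subdirectory per class.  Class
    names are mapped to {0, 1} through `label_map` (default:
    ``{"health": 0, "cancer": 1}``).
    """
    if label_map is None:
        label_map = {"health": 0, "cancer": 1}
    entries: list[tuple[str, str]] = []  # (file path, class name)
    manifest = os.fspath(manifest)
    if os.path.isdir(manifest):
        for cls in sorted(os.listdir(manifest)):
            sub = os.path.join(manifest, cls)
            if not os.path.isdir(sub):
                continue
            for fname in sorted(os.listdir(sub)):
                if fname.endswith(".tsv"):
                    entries.append((os.path.join(sub, fname), cls))
    else:
        mdf = pd.read_csv(manifest, sep="\t", dtype=str)
        if not {"path", "class"}.issubset(mdf.columns):
            raise ConfigurationError("manifest must have 'path' and 'class' columns")
        base = os.path.dirname(manifest)
        for _, row in mdf.iterrows():
            entries.append((os.path.join(base, row["path"]), row["class"]))
    bags: list[RepertoireBag] = []
    seen: set[str] = set()
    counts: dict[int, int] = {0: 0, 1: 0}
    for path, cls in entries:
        if cls not in label_map:
            raise ConfigurationError(f"class {cls!r} missing from label_map {label_map}")
        bag = read_repertoire_tsv(path, cdr3_column, frequency_column)
        if bag.sample_id in seen:
            raise InputError(f"duplicate sample_id {bag.sample_id!r}")
        seen.add(bag.sample_id)
        bag.label = int(label_map[cls])
        counts[bag.label] += 1
        bags.append(bag)
    import logging

    logging.getLogger(__name__).info(
        "loaded %d bags (%d negative, %d positive)", len(bags), counts[0], counts[1]
    )
    return bags


def write_predictions(bags: Sequence[RepertoireBag], probabilities: Sequence[float],
                      threshold: float, path: str | os.PathLike) -> None:
    """Write per-sample probabilities and thresholded labels.

    A sample is called positive only when probability strictly exceeds the
    threshold (a probability equal to the threshold is classified 0).
    """
    if len(bags) != len(probabilities):
        raise InputError(
            f"{len(bags)} bags but {len(probabilities)} probabilities"
        )
    probs = np.asarray(probabilities, dtype=float)
    if len(probs) and (probs.min() < 0 or probs.max() > 1):
        raise InputError("probabilities must lie in [0, 1]")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tprobability\tpredicted_label\n")
        for bag, p in zip(bags, probs):
            fh.write(f"{bag.sample_id}\t{float(p)!r}\t{int(p > threshold)}\n")


def read_predictions(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"sample_id": str, "probability": float,
                              "predicted_label": int})


def write_repertoire_tsv(bag: RepertoireBag, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("amino_acid\tfrequency\n")
        for inst in bag.instances:
            fh.write(f"{inst.cdr3}\t{float(inst.frequency)!r}\n")


CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | os.PathLike, config: dict,
                    state: dict[str, np.ndarray]) -> None:
    """Persist model configuration + parameter arrays; round-trips bit-exactly."""
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": config})
    np.savez(path, __meta__=np.frombuffer(meta.encode("utf-8"), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | os.PathLike) -> tuple[dict, dict[str, np.ndarray]]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise InputError(f"unsupported checkpoint version {meta.get('version')}")
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    return meta["config"], state
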