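"""Numeric encoding of CDR3 sequences.

Each residue is mapped to a 15-dimensional physicochemical vector from a
packaged 20x15 PCA embedding matrix; sequences are zero-padded on the right
to 24 rows (the maximum retained CDR3 length), giving a fixed 24x15 instance
matrix.  Sinusoidal positional encodings are then added residue-wise:

    PE(pos, 2i)   = sin(pos / 10000^(2i / d_model))
    PE(pos, 2i+1) = cos(pos / 10000^(2i / d_model))

with 0-based positions.  For the odd model width d_model = 15 the sine
columns are 0, 2, ..., 14 and the cosine columns 1, 3, ..., 13; the final
sine column has no cosine partner.  The table is built up to a configurable
maximum position (default 100) although only rows 0..23 are consumed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .io import InputError, RepertoireBag
from .preprocess import CANONICAL_AA

__all__ = [
    "MAX_SEQ_LEN",
    "EMBED_DIM",
    "EmbeddingMatrix",
    "EncodedInstance",
    "EncodedBag",
    "PositionalEncodingTable",
    "load_embedding_matrix",
    "encode_sequence",
    "positional_encoding_table",
    "apply_positional_encoding",
    "encode_bag",
]

MAX_SEQ_LEN = 24   # retained CDR3 length bound; also the padded matrix height
EMBED_DIM = 15     # width of the residue embedding
DEFAULT_MAX_POS = 100

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@dataclass(frozen=True)
class EmbeddingMatrix:
    """20x15 residue embedding; row order is the canonical alphabetical
    one-letter order ACDEFGHIKLMNPQRSTVWY."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(CANONICAL_AA), EMBED_DIM):
            raise InputError(f"embedding matrix must be 20x{EMBED_DIM}, got {v.shape}")
        if not np.isfinite(v).all():
            raise InputError("embedding matrix contains non-finite entries")
        object.__setattr__(self, "values", v)

    def row(self, residue: str) -> np.ndarray:
        try:
            return self.values[_AA_INDEX[residue]]
        except KeyError:
            raise InputError(f"residue {residue!r} outside canonical alphabet") from None


@dataclass(frozen=True)
class EncodedInstance:
    """A CDR3 rendered as a 24x15 matrix; rows >= `length` are zero padding."""

    matrix: np.ndarray
    length: int


@dataclass
class EncodedBag:
    """A bag's instances stacked into a fixed-size block with a validity mask.

    matrices: (bag_size, 24, 15); mask: (bag_size,) with True where a slot
    holds a real instance.  Slot order is the bag's instance order, i.e.
    descending clone frequency after preprocessing.
    """

    sample_id: str
    matrices: np.ndarray
    mask: np.ndarray
    lengths: np.ndarray
    label: int | None = None


@dataclass(frozen=True)
class PositionalEncodingTable:
    values: np.ndarray  # (max_pos, d_model)

    @property
    def max_pos(self) -> int:
        return self.values.shape[0]

    @property
    def d_model(self) -> int:
        return self.values.shape[1]


def load_embedding_matrix(source: str | None = None) -> EmbeddingMatrix:
    """Load the residue embedding from `source`, or the packaged default.

    The packaged default is a synthetic PCA compression of classical
    amino-acid property scales (see scripts/make_embedding_matrix.py).
    Rows may appear in any order in the file; they are reordered to the
    canonical alphabetical order.
    """
    if source is None:
        ref = importlib.resources.files("tcrmil.data") / "aa_pca_embedding_synthetic.tsv"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    rows: dict[str, np.ndarray] = {}
    for ln in lines[1:]:  # first line is the header
        parts = ln.split("\t")
        aa, vals = parts[0], parts[1:]
        if aa not in _AA_INDEX:
            raise InputError(f"unknown residue label {aa!r} in embedding file")
        if len(vals) != EMBED_DIM:
            raise InputError(f"row {aa}: expected {EMBED_DIM} values, got {len(vals)}")
        if aa in rows:
            raise InputError(f"duplicate residue row {aa!r}")
        rows[aa] = np.array([float(v) for v in vals])
    if len(rows) != len(CANONICAL_AA):
        raise InputError(f"expected 20 residue rows, got {len(rows)}")
    return EmbeddingMatrix(np.stack([rows[aa] for aa in CANONICAL_AA]))


def encode_sequence(cdr3: str, M: EmbeddingMatrix) -> EncodedInstance:
    """Map a preprocessed CDR3 to its padded 24x15 embedding matrix."""
    if len(cdr3) > MAX_SEQ_LEN:
        raise InputError(f"CDR3 longer than {MAX_SEQ_LEN}: {cdr3!r}")
    out = np.zeros((MAX_SEQ_LEN, EMBED_DIM))
    for j, aa in enumerate(cdr3):
        out[j] = M.row(aa)
    return EncodedInstance(matrix=out, length=len(cdr3))


def positional_encoding_table(max_pos: int = DEFAULT_MAX_POS,
                              d_model: int = EMBED_DIM) -> PositionalEncodingTable:
    """Sinusoidal position table; see the module docstring for the formula."""
    if max_pos < 1 or d_model < 1:
        raise ValueError("max_pos and d_model must be >= 1")
    pos = np.arange(max_pos)[:, None]
    two_i = np.arange(0, d_model, 2)
    angle = pos / np.power(10000.0, two_i / d_model)
    table = np.zeros((max_pos, d_model))
    table[:, 0::2] = np.sin(angle)
    table[:, 1::2] = np.cos(angle[:, : (d_model // 2)])
    return PositionalEncodingTable(values=table)


def apply_positional_encoding(inst: EncodedInstance, table: PositionalEncodingTable,
                              dropout_rate: float = 0.0, training: bool = False,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Add position rows 0..23 to the instance matrix, with optional
    (training-only) inverted dropout on the result.

    Padding rows receive the positional signal too; instance validity is
    handled downstream by the bag mask, not by zeroing residue rows.
    """
    if table.d_model != inst.matrix.shape[1]:
        raise InputError(
            f"table d_model {table.d_model} != instance width {inst.matrix.shape[1]}"
        )
    if table.max_pos < inst.matrix.shape[0]:
        raise InputError("positional table shorter than the padded sequence length")
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must be in [0, 1)")
    out = inst.matrix + table.values[: inst.matrix.shape[0]]
    if training and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - dropout_rate
        out = out * (rng.random(out.shape) < keep) / keep
    return out


def encode_bag(bag: RepertoireBag, M: EmbeddingMatrix, bag_size: int = 100,
               dtype=np.float64) -> EncodedBag:
    """Encode a preprocessed bag into a fixed (bag_size, 24, 15) block.

    Instances keep their bag order (descending clone frequency), so the slot
    index is the abundance rank; unused slots are zero with mask False.
    """
    if len(bag) > bag_size:
        raise InputError(f"bag {bag.sample_id} has {len(bag)} > bag_size={bag_size}")
    mats = np.zeros((bag_size, MAX_SEQ_LEN, EMBED_DIM), dtype=dtype)
    mask = np.zeros(bag_size, dtype=bool)
    lengths = np.zeros(bag_size, dtype=np.int64)
    for slot, tcr in enumerate(bag.instances):
        enc = encode_sequence(tcr.cdr3, M)
        mats[slot] = enc.matrix
        mask[slot] = True
        lengths[slot] = enc.length
    return EncodedBag(sample_id=bag.sample_id, matrices=mats, mask=mask,
                      lengths=lengths, label=bag.label)
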