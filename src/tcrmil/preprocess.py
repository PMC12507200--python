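"""Repertoire cleaning: sequence filters, top-k selection, sample screening.

Five rules, applied in order to every bag:

1. drop CDR3s shorter than 10 or longer than 24 residues (bounds inclusive
   on the retained range [10, 24]);
2. drop CDR3s containing any character outside the 20-letter amino-acid
   alphabet (X, *, +, lowercase, ...);
3. drop CDR3s that do not start with cysteine (C) or do not end with
   phenylalanine (F), per the IMGT junction convention;
4. keep only the top 100 clones by frequency (ties broken by ascending
   lexicographic CDR3 so the selection is deterministic);
5. reject whole samples with fewer than 10 surviving clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import RepertoireBag

__all__ = [
    "CANONICAL_AA",
    "PreprocessConfig",
    "FilterResult",
    "RejectionRecord",
    "instance_passes_filters",
    "select_top_k",
    "preprocess_bag",
    "preprocess_dataset",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(CANONICAL_AA)

#: Failure reason codes, evaluated in this fixed order.
REASON_LENGTH = "length"
REASON_ALPHABET = "alphabet"
REASON_IMGT = "imgt"
REASON_PASS = "pass"


@dataclass(frozen=True)
class PreprocessConfig:
    min_len: int = 10
    max_len: int = 24
    top_k: int = 100
    min_instances: int = 10
    alphabet: frozenset = field(default=_AA_SET)

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if not (self.top_k >= self.min_instances >= 1):
            raise ValueError("need top_k >= min_instances >= 1")


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str  # REASON_PASS / REASON_LENGTH / REASON_ALPHABET / REASON_IMGT

    def __bool__(self) -> bool:
        return self.passed


@dataclass(frozen=True)
class RejectionRecord:
    """Record of a sample removed by the minimum-instance screen."""

    sample_id: str
    surviving_count: int


def instance_passes_filters(cdr3: str, cfg: PreprocessConfig = PreprocessConfig()) -> FilterResult:
    """Check one CDR3 against rules 1-3; reports the first failing rule."""
    if not (cfg.min_len <= len(cdr3) <= cfg.max_len):
        return FilterResult(False, REASON_LENGTH)
    if not set(cdr3) <= cfg.alphabet:
        return FilterResult(False, REASON_ALPHABET)
    if cdr3[0] != "C" or cdr3[-1] != "F":
        return FilterResult(False, REASON_IMGT)
    return FilterResult(True, REASON_PASS)


def select_top_k(bag: RepertoireBag, k: int) -> RepertoireBag:
    """Keep the min(k, |bag|) highest-frequency clones, sorted by descending
    frequency with ties broken by ascending lexicographic CDR3."""
    ranked = sorted(bag.instances, key=lambda inst: (-inst.frequency, inst.cdr3))
    return RepertoireBag(sample_id=bag.sample_id, instances=ranked[:k], label=bag.label)


def preprocess_bag(bag: RepertoireBag,
                   cfg: PreprocessConfig = PreprocessConfig()
                   ) -> RepertoireBag | RejectionRecord:
    """Apply sequence filters then top-k selection; reject small samples.

    Returns the cleaned bag, or a :class:`RejectionRecord` when fewer than
    `cfg.min_instances` clones survive.
    """
    kept = [i for i in bag.instances if instance_passes_filters(i.cdr3, cfg)]
    filtered = RepertoireBag(sample_id=bag.sample_id, instances=kept, label=bag.label)
    selected = select_top_k(filtered, cfg.top_k)
    if len(selected) < cfg.min_instances:
        return RejectionRecord(sample_id=bag.sample_id, surviving_count=len(selected))
    return selected


def preprocess_dataset(bags: list[RepertoireBag],
                       cfg: PreprocessConfig = PreprocessConfig()
                       ) -> tuple[list[RepertoireBag], list[RejectionRecord]]:
    """Preprocess every bag; accepted bags and rejection records separately."""
    accepted: list[RepertoireBag] = []
    rejected: list[RejectionRecord] = []
    for bag in bags:
        out = preprocess_bag(bag, cfg)
        if isinstance(out, RejectionRecord):
            rejected.append(out)
        else:
            accepted.append(out)
    return accepted, rejected
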