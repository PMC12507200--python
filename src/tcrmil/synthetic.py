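"""Synthetic repertoire generator with planted cancer-associated motifs.

Emulates the statistical structure the classifier assumes: each subject is
a bag of CDR3 amino-acid sequences of length 10-24 that start with C and
end with F, with heavy-tailed (Zipf-like) clone frequencies.  Positive
(cancer) bags additionally carry a configurable fraction of instances in
which a short amino-acid motif has been written into an interior window —
a stand-in for shared biochemical features of cancer-associated receptors.

Motifs are planted by overwriting rather than insertion, so the length
distribution is identical between classes and a classifier must learn
sequence composition, not length.  With ``planted_fraction=0`` the positive
and negative generators are identical in distribution (a null dataset).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io import RepertoireBag, TCRInstance, write_repertoire_tsv
from .preprocess import CANONICAL_AA

__all__ = ["SimConfig", "sample_background_cdr3", "plant_motif",
           "generate_bag", "generate_dataset", "write_dataset"]


def _uniform_lengths() -> dict[int, float]:
    return {length: 1.0 / 15.0 for length in range(10, 25)}


@dataclass(frozen=True)
class SimConfig:
    n_positive: int = 60
    n_negative: int = 60
    min_instances: int = 80    # pre-filter clones per subject (uniform draw)
    max_instances: int = 150
    length_distribution: dict[int, float] = field(default_factory=_uniform_lengths)
    residue_distribution: dict[str, float] | None = None  # default: uniform
    motifs: tuple[str, ...] = ("WQDR",)
    planted_fraction: float = 0.3
    abundance_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must be in [0, 1]")
        for m in self.motifs:
            if not (3 <= len(m) <= 6) or not set(m) <= set(CANONICAL_AA):
                raise ValueError(f"motif {m!r} must be 3-6 canonical residues")
        if not (1 <= self.min_instances <= self.max_instances):
            raise ValueError("need 1 <= min_instances <= max_instances")
        for length in self.length_distribution:
            if not (10 <= length <= 24):
                raise ValueError("lengths must lie in [10, 24]")

    def _length_table(self) -> tuple[np.ndarray, np.ndarray]:
        lengths = np.array(sorted(self.length_distribution))
        probs = np.array([self.length_distribution[l] for l in lengths], dtype=float)
        return lengths, probs / probs.sum()

    def _residue_table(self) -> tuple[np.ndarray, np.ndarray]:
        if self.residue_distribution is None:
            return (np.array(list(CANONICAL_AA)),
                    np.full(len(CANONICAL_AA), 1.0 / len(CANONICAL_AA)))
        residues = np.array(sorted(self.residue_distribution))
        probs = np.array([self.residue_distribution[str(r)] for r in residues])
        return residues, probs / probs.sum()


def sample_background_cdr3(cfg: SimConfig, rng: np.random.Generator) -> str:
    """One background CDR3: C + i.i.d. interior residues + F."""
    lengths, lprobs = cfg._length_table()
    residues, rprobs = cfg._residue_table()
    length = int(rng.choice(lengths, p=lprobs))
    interior = rng.choice(residues, size=length - 2, p=rprobs)
    return "C" + "".join(interior) + "F"


def plant_motif(cdr3: str, motif: str, rng: np.random.Generator) -> str:
    """Overwrite a uniformly chosen interior window with `motif`.

    The window never touches position 0 or the final position, so the IMGT
    anchors (C..F) and the length are preserved.
    """
    if len(motif) > len(cdr3) - 2:
        raise ValueError(f"motif {motif!r} too long for {cdr3!r}")
    start = int(rng.integers(1, len(cdr3) - len(motif)))
    return cdr3[:start] + motif + cdr3[start + len(motif):]


def generate_bag(label: int, cfg: SimConfig, rng: np.random.Generator,
                 sample_id: str = "sample") -> RepertoireBag:
    """One labeled bag with Zipf-like clone frequencies summing to 1.

    For positive bags, ceil(planted_fraction * count) distinct instances
    carry a motif drawn uniformly from cfg.motifs.  Frequencies follow
    rank^(-abundance_exponent) over a random permutation of the instances,
    so motif-bearing clones are not systematically the most abundant.
    """
    count = int(rng.integers(cfg.min_instances, cfg.max_instances + 1))
    seqs = [sample_background_cdr3(cfg, rng) for _ in range(count)]
    if label == 1 and cfg.planted_fraction > 0 and cfg.motifs:
        n_plant = int(np.ceil(cfg.planted_fraction * count))
        chosen = rng.choice(count, size=n_plant, replace=False)
        for i in chosen:
            motif = cfg.motifs[int(rng.integers(len(cfg.motifs)))]
            seqs[i] = plant_motif(seqs[i], motif, rng)
    ranks = rng.permutation(count) + 1
    freqs = ranks.astype(float) ** (-cfg.abundance_exponent)
    freqs /= freqs.sum()
    # duplicate sequences would later be merged; regenerate collisions so the
    # emitted bag has `count` distinct clones (collisions are ~impossible at
    # 20^8+ sequence spaces but cheap to guard against)
    seen: dict[str, int] = {}
    instances = []
    for seq, freq in zip(seqs, freqs):
        while seq in seen:
            seq = sample_background_cdr3(cfg, rng)
        seen[seq] = 1
        instances.append(TCRInstance(cdr3=seq, frequency=float(freq)))
    return RepertoireBag(sample_id=sample_id, instances=instances, label=int(label))


def generate_dataset(cfg: SimConfig) -> list[RepertoireBag]:
    """n_negative healthy + n_positive cancer bags; reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    bags = []
    for i in range(cfg.n_negative):
        bags.append(generate_bag(0, cfg, rng, sample_id=f"health_{i:04d}"))
    for i in range(cfg.n_positive):
        bags.append(generate_bag(1, cfg, rng, sample_id=f"cancer_{i:04d}"))
    return bags


def write_dataset(bags: list[RepertoireBag], out_dir: str) -> str:
    """Write per-sample TSVs plus a manifest compatible with
    :func:`tcrmil.io.load_labeled_dataset`; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for bag in bags:
        fname = f"{bag.sample_id}.tsv"
        write_repertoire_tsv(bag, os.path.join(out_dir, fname))
        rows.append((fname, "cancer" if bag.label == 1 else "health"))
    manifest = os.path.join(out_dir, "manifest.tsv")
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write("path\tclass\n")
        for path, cls in rows:
            fh.write(f"{path}\t{cls}\n")
    return manifest
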