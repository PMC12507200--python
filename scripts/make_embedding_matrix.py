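"""Regenerate the packaged synthetic amino-acid PCA embedding matrix.

The classifier encodes each CDR3 residue as a 15-dimensional vector taken
from a 20x15 matrix of PCA-compressed physicochemical descriptors.  The
matrix shipped in ``tcrmil/data/aa_pca_embedding_synthetic.tsv`` is a
synthetic stand-in built here from a small table of widely used amino-acid
property scales (hydropathy, size, charge, aromaticity, secondary-structure
propensities, ...).  Several scale values are rounded/approximate; the matrix
is meant to give residues distinct, physicochemically structured coordinates,
not to reproduce any published index compilation verbatim.

Usage::

    python scripts/make_embedding_matrix.py [out.tsv]
"""

from __future__ import annotations

import sys

import numpy as np

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# One row per residue in AA_ORDER. Columns:
#  kd      Kyte-Doolittle hydropathy
#  mass    average residue mass (Da, minus water)
#  vol     side-chain van der Waals volume (A^3, approximate)
#  sasa    accessible surface area in Gly-X-Gly (A^2, approximate)
#  charge  net charge at pH 7 (His partial)
#  pI      isoelectric point of the free amino acid (approximate)
#  arom    aromatic ring indicator
#  polar   polar side chain indicator
#  aliph   aliphatic side chain indicator
#  hbd     side-chain H-bond donor count
#  hba     side-chain H-bond acceptor count
#  flex    backbone flexibility index (B-factor derived, approximate)
#  helix   Chou-Fasman alpha-helix propensity (approximate)
#  sheet   Chou-Fasman beta-sheet propensity (approximate)
#  turn    Chou-Fasman turn propensity (approximate)
#  bulk    Zimmerman bulkiness (approximate)
#  polz    polarizability proxy (approximate)
#  nC      side-chain carbon count
PROPS = {
    #      kd    mass    vol  sasa chg   pI  ar po al hbd hba flex helix sheet turn  bulk  polz nC
    "A": [ 1.8,  71.08,  67, 113, 0.0, 6.00, 0, 0, 1, 0, 0, 0.36, 1.42, 0.83, 0.66, 11.5, 0.05, 1],
    "C": [ 2.5, 103.14,  86, 140, 0.0, 5.07, 0, 0, 0, 1, 0, 0.35, 0.70, 1.19, 1.19, 13.5, 0.13, 1],
    "D": [-3.5, 115.09,  91, 151, -1., 2.77, 0, 1, 0, 1, 4, 0.51, 1.01, 0.54, 1.46, 11.7, 0.11, 2],
    "E": [-3.5, 129.12, 109, 183, -1., 3.22, 0, 1, 0, 1, 4, 0.50, 1.51, 0.37, 0.74, 13.6, 0.15, 3],
    "F": [ 2.8, 147.18, 135, 218, 0.0, 5.48, 1, 0, 0, 0, 0, 0.31, 1.13, 1.38, 0.60, 19.8, 0.29, 7],
    "G": [-0.4,  57.05,  48,  85, 0.0, 5.97, 0, 0, 0, 0, 0, 0.54, 0.57, 0.75, 1.56,  3.4, 0.00, 0],
    "H": [-3.2, 137.14, 118, 194, 0.1, 7.59, 1, 1, 0, 1, 1, 0.32, 1.00, 0.87, 0.95, 13.7, 0.23, 4],
    "I": [ 4.5, 113.16, 124, 182, 0.0, 6.02, 0, 0, 1, 0, 0, 0.46, 1.08, 1.60, 0.47, 21.4, 0.19, 4],
    "K": [-3.9, 128.17, 135, 211, 1.0, 9.74, 0, 1, 0, 2, 0, 0.47, 1.16, 0.74, 1.01, 15.7, 0.22, 4],
    "L": [ 3.8, 113.16, 124, 180, 0.0, 5.98, 0, 0, 1, 0, 0, 0.37, 1.21, 1.30, 0.59, 21.4, 0.19, 4],
    "M": [ 1.9, 131.20, 124, 204, 0.0, 5.74, 0, 0, 0, 0, 0, 0.30, 1.45, 1.05, 0.60, 16.3, 0.22, 3],
    "N": [-3.5, 114.10,  96, 158, 0.0, 5.41, 0, 1, 0, 2, 2, 0.46, 0.67, 0.89, 1.56, 12.8, 0.13, 2],
    "P": [-1.6,  97.12,  90, 143, 0.0, 6.30, 0, 0, 0, 0, 0, 0.51, 0.57, 0.55, 1.52, 17.4, 0.13, 3],
    "Q": [-3.5, 128.13, 114, 189, 0.0, 5.65, 0, 1, 0, 2, 2, 0.49, 1.11, 1.10, 0.98, 14.5, 0.18, 3],
    "R": [-4.5, 156.19, 148, 241, 1.0,10.76, 0, 1, 0, 4, 0, 0.53, 0.98, 0.93, 0.95, 14.3, 0.29, 4],
    "S": [-0.8,  87.08,  73, 122, 0.0, 5.68, 0, 1, 0, 1, 1, 0.51, 0.77, 0.75, 1.43,  9.5, 0.06, 1],
    "T": [-0.7, 101.10,  93, 146, 0.0, 5.60, 0, 1, 0, 1, 1, 0.44, 0.83, 1.19, 0.96, 15.8, 0.11, 2],
    "V": [ 4.2,  99.13, 105, 160, 0.0, 5.96, 0, 0, 1, 0, 0, 0.39, 1.06, 1.70, 0.50, 21.6, 0.14, 3],
    "W": [-0.9, 186.21, 163, 259, 0.0, 5.89, 1, 0, 0, 1, 0, 0.31, 1.08, 1.37, 0.96, 21.7, 0.41, 9],
    "Y": [-1.3, 163.18, 141, 229, 0.0, 5.66, 1, 1, 0, 1, 1, 0.42, 0.69, 1.47, 1.14, 18.0, 0.30, 7],
}

N_COMPONENTS = 15


def build_matrix() -> np.ndarray:
    X = np.array([PROPS[a] for a in AA_ORDER], dtype=float)
    # z-score each property, PCA via SVD, keep the leading 15 components
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :N_COMPONENTS] * s[:N_COMPONENTS]
    # unit variance per component; sign fixed so the largest-|.| loading is +
    scores /= scores.std(axis=0)
    for j in range(scores.shape[1]):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def main(out_path: str) -> None:
    M = build_matrix()
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("residue\t" + "\t".join(f"pc{j + 1}" for j in range(N_COMPONENTS)) + "\n")
        for aa, row in zip(AA_ORDER, M):
            fh.write(aa + "\t" + "\t".join(f"{v:.8f}" for v in row) + "\n")
    print(f"wrote {M.shape[0]}x{M.shape[1]} matrix to {out_path}")


if __name__ == "__main__":
    main(sys.argv[1] if len(sys.argv) > 1 else "src/tcrmil/data/aa_pca_embedding_synthetic.tsv")
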