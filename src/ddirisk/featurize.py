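"""Node attribute construction: Morgan fingerprints, PCA, edge features.

Drug nodes are featurized from chemistry alone: each SMILES is encoded as a
Morgan (circular, ECFP-style) fingerprint bit vector, the 0/1 vectors are
stacked into a real matrix X, and principal component analysis maps the
n-bit space down to k orthogonal components:

    Y = (X - mean) P,   D = (1/m) Y^T Y diagonal,

where the columns of P are the top-k eigenvectors of the (1/m)-scaled
covariance of mean-centered X and D holds the matching eigenvalues
(explained variances).  Edge attributes are the concatenation of the two
endpoint node features, ordered along the directed arc.

Defaults: radius 2, 2048 bits (the field-standard ECFP4 equivalent) and
k = 300 components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .graph import DrugRecord

DEFAULT_K = 300


@dataclass(frozen=True)
class FingerprintConfig:
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be nonnegative")
        if self.n_bits < 64:
            raise ValueError("n_bits must be at least 64")


def fingerprint(smiles: str, config: FingerprintConfig = FingerprintConfig()
                ) -> np.ndarray:
    """Morgan fingerprint of one molecule as a 0/1 uint8 vector.

    Deterministic in (smiles, config) and invariant under re-spelling of
    the same molecule (the generator canonicalizes internally).  Raises
    ``ValueError`` on unparseable SMILES; an empty molecule (e.g. ``""``)
    yields the all-zero vector, which is a distinct, valid outcome.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(config.n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(drugs: list[DrugRecord],
                       config: FingerprintConfig = FingerprintConfig()
                       ) -> np.ndarray:
    """Stack fingerprints for a drug list (row order = list order) and
    store each vector back onto its record."""
    rows = []
    for d in drugs:
        fp = fingerprint(d.smiles, config)
        d.fingerprint = fp
        rows.append(fp)
    return np.array(rows, dtype=np.float64)


@dataclass
class PCAModel:
    mean: np.ndarray
    projection: np.ndarray          # n x k, orthonormal columns
    explained_variance: np.ndarray  # length k, nonincreasing


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """Top-k principal components of X via eigendecomposition of the
    (1/m)-scaled covariance of the mean-centered data.

    Eigenvector sign is fixed by forcing the largest-magnitude entry of
    each column positive, for reproducibility across linear-algebra
    backends.  Zero-variance input is an error.
    """
    X = np.asarray(X, dtype=np.float64)
    m, n = X.shape
    if m < 2:
        raise ValueError("need at least 2 samples to fit PCA")
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k={k} outside [1, min(m, n)={min(m, n)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / m
    total_var = np.trace(cov)
    if total_var <= 0:
        raise ValueError("zero-variance input: PCA undefined")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    evals = np.maximum(evals[order], 0.0)
    P = evecs[:, order]
    # sign convention: largest-magnitude entry of each column positive
    flip = np.sign(P[np.abs(P).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    P = P * flip
    return PCAModel(mean=mean, projection=P, explained_variance=evals)


def apply_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X: (X - mean) P."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns, "
            f"model expects {model.mean.shape[0]}")
    return (X - model.mean) @ model.projection


def explained_variance_sweep(X: np.ndarray, ks: list[int]) -> np.ndarray:
    """Cumulative explained-variance fraction at each target dimension k.

    A cheap proxy for the feature-dimension sweep: the curve rises with k
    and plateaus once k exceeds the effective rank of the fingerprint
    matrix, mirroring the performance-versus-dimension experiment in shape.
    """
    kmax = max(ks)
    model = fit_pca(X, min(kmax, min(X.shape)))
    Xc = np.asarray(X, dtype=np.float64) - X.mean(axis=0)
    total = (Xc * Xc).sum() / X.shape[0]
    cum = np.cumsum(model.explained_variance)
    out = []
    for k in ks:
        idx = min(k, len(cum)) - 1
        out.append(cum[idx] / total)
    return np.array(out)


def assemble_edge_features(node_features: np.ndarray,
                           arcs: np.ndarray) -> np.ndarray:
    """Per-arc feature = concat(f_u, f_v) following the arc's direction,
    so an undirected edge is represented by both orderings of its
    double-entry arcs."""
    arcs = np.asarray(arcs, dtype=np.int64).reshape(-1, 2)
    return np.concatenate([node_features[arcs[:, 0]],
                           node_features[arcs[:, 1]]], axis=1)


def featurize_nodes(drugs: list[DrugRecord],
                    config: FingerprintConfig = FingerprintConfig(),
                    k: int = DEFAULT_K) -> tuple[np.ndarray, PCAModel]:
    """Fingerprint + PCA pipeline for a drug list.

    ``k`` is clipped to the feasible range for small inputs.  Fitting uses
    all drugs: features derive only from chemistry, never labels, so no
    label leakage is possible (restrict the list to training drugs for a
    stricter protocol).
    """
    X = fingerprint_matrix(drugs, config)
    k_eff = min(k, min(X.shape))
    model = fit_pca(X, k_eff)
    return apply_pca(model, X), model
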