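"""Fingerprint-based structural similarity, screening and clustering.

Drugs are represented as fixed-length binary fingerprints (hashed
topological path fingerprints when derived from structures). Similarity is
bit-set Tanimoto |a AND b| / |a OR b|; the clustering distance is the Soergel
distance (1 - Tanimoto for binary vectors). Distance thresholds quoted on
the Tanimoto scale are translated through s = 1/(1 + d), so the 0.15 Soergel
cut corresponds to ~87% Tanimoto similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintLibrary",
    "fingerprints_from_smiles",
    "tanimoto",
    "tanimoto_matrix",
    "soergel_to_tanimoto",
    "tanimoto_to_soergel",
    "cross_set_screen",
    "cluster_drugs",
]

DEFAULT_N_BITS = 2048
SOERGEL_CUT = 0.15
SCREEN_THRESHOLD = 0.80


@dataclass
class FingerprintLibrary:
    """A set of equal-length binary fingerprints keyed by drug id."""

    ids: list[str]
    bits: np.ndarray  # bool, shape (n_drugs, n_bits)
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.ids):
            raise ValueError("bits must be (n_drugs, n_bits) matching ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate drug ids")
        empty = ~self.bits.any(axis=1)
        if empty.any():
            bad = [self.ids[i] for i in np.flatnonzero(empty)]
            raise ValueError(f"all-zero fingerprints rejected: {bad}")

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[str]) -> "FingerprintLibrary":
        index = {d: i for i, d in enumerate(self.ids)}
        rows = [index[d] for d in ids]
        return FingerprintLibrary(ids=list(ids), bits=self.bits[rows], origin=self.origin)


def fingerprints_from_smiles(
    records: list[tuple[str, str]], n_bits: int = DEFAULT_N_BITS
) -> tuple[FingerprintLibrary, list[str]]:
    """Fingerprint (drug_id, SMILES) records with hashed path fingerprints.

    SMILES are canonicalised and salts stripped by the largest-fragment rule
    before fingerprinting, so different spellings of one molecule yield one
    fingerprint. Unparsable records are skipped; their ids are returned and
    logged. Raises if no record parses.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdmolops

    RDLogger.DisableLog("rdApp.error")
    ids, rows, skipped = [], [], []
    for drug_id, smiles in records:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            skipped.append(drug_id)
            continue
        frags = Chem.GetMolFrags(mol, asMols=True)
        if len(frags) > 1:
            mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
            logger.info("kept largest fragment of %s", drug_id)
        fp = rdmolops.RDKFingerprint(mol, fpSize=n_bits)
        arr = np.zeros(n_bits, dtype=bool)
        arr[list(fp.GetOnBits())] = True
        ids.append(drug_id)
        rows.append(arr)
    if skipped:
        logger.warning("skipped %d unparsable structures: %s", len(skipped), skipped)
    if not ids:
        raise ValueError("zero valid structures")
    return FingerprintLibrary(ids=ids, bits=np.array(rows), origin="from_structure"), skipped


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Bit-set Tanimoto similarity |a AND b| / |a OR b| in [0, 1]."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValueError("both fingerprints are all-zero")
    return float(np.logical_and(a, b).sum()) / union


def tanimoto_matrix(lib_a: FingerprintLibrary, lib_b: FingerprintLibrary) -> np.ndarray:
    """All-pairs Tanimoto between two libraries (rows: A, cols: B)."""
    if lib_a.n_bits != lib_b.n_bits:
        raise ValueError("fingerprint length mismatch between libraries")
    a = lib_a.bits.astype(np.int32)
    b = lib_b.bits.astype(np.int32)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    return inter / union


def soergel_to_tanimoto(d: float) -> float:
    """Translate a Soergel distance threshold to Tanimoto, s = 1/(1 + d)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 / (1.0 + d)


def tanimoto_to_soergel(s: float) -> float:
    """Inverse translation, d = (1 - s)/s; undefined at s = 0."""
    if not 0 < s <= 1:
        raise ValueError("similarity must be in (0, 1]")
    return (1.0 - s) / s


@dataclass
class ScreenReport:
    """Result of a cross-set similarity screen at a Tanimoto threshold."""

    matrix: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    threshold: float
    flagged: list[tuple[str, str, float]]
    per_row_max: list[tuple[str, str, float]] | None = None


def cross_set_screen(
    lib_a: FingerprintLibrary,
    lib_b: FingerprintLibrary,
    threshold: float = SCREEN_THRESHOLD,
    reduce_max: bool = False,
) -> ScreenReport:
    """Screen set A against set B, flagging pairs with Tanimoto >= threshold.

    With ``reduce_max`` each A-drug additionally reports its single most
    similar B-drug (the maximum over B).
    """
    if len(lib_a) == 0 or len(lib_b) == 0:
        raise ValueError("cannot screen an empty set")
    sims = tanimoto_matrix(lib_a, lib_b)
    flagged = [
        (lib_a.ids[i], lib_b.ids[j], float(sims[i, j]))
        for i, j in zip(*np.nonzero(sims >= threshold))
    ]
    flagged.sort(key=lambda t: (-t[2], t[0], t[1]))
    per_row_max = None
    if reduce_max:
        best = sims.argmax(axis=1)
        per_row_max = [
            (lib_a.ids[i], lib_b.ids[int(j)], float(sims[i, int(j)])) for i, j in enumerate(best)
        ]
    return ScreenReport(
        matrix=sims, row_ids=list(lib_a.ids), col_ids=list(lib_b.ids),
        threshold=threshold, flagged=flagged, per_row_max=per_row_max,
    )


@dataclass
class ClusterAssignment:
    """Flat cluster labels from cutting a hierarchical tree."""

    labels: dict[str, int]
    linkage_method: str
    cut_distance: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def cluster_drugs(
    library: FingerprintLibrary, cut: float = SOERGEL_CUT, linkage_method: str = "complete"
) -> ClusterAssignment:
    """Agglomerative clustering on the Soergel distance matrix, cut at ``cut``.

    Complete linkage guarantees every within-cluster pairwise distance is at
    most the cut. Labels are contiguous from 1 in order of first appearance
    over the id-sorted library, making the result independent of input
    order. Singletons are allowed.
    """
    if len(library) < 2:
        raise ValueError("need at least 2 drugs to cluster")
    ordered = library.subset(sorted(library.ids))
    dist = 1.0 - tanimoto_matrix(ordered, ordered)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = hierarchy.linkage(condensed, method=linkage_method)
    raw = hierarchy.fcluster(tree, t=cut, criterion="distance")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for drug, lab in zip(ordered.ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[drug] = relabel[lab]
    return ClusterAssignment(labels=labels, linkage_method=linkage_method, cut_distance=cut)
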