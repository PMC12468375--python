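"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a 64-bit seed, and
each returns (or writes alongside its artifact) a machine-readable "truth"
record describing what was planted, so that downstream recovery — planted
differentially expressed genes, true reverser drugs, structural clusters,
synergy deltas — can be scored without re-reading the generator call.

The generators emulate the study's input regime: quantile-normalised
log2-scale expression matrices with case/control groups, top-50
reverser-first drug lists from several repurposing tools over several
datasets, binary fingerprint libraries with planted structural clusters,
and factorial dose-response surfaces built under each synergy model's null
plus a planted deviation. They do not emulate probe-level artifacts, batch
effects, or platform differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .consensus import RankedDrugList
from .de import ExpressionDataset
from .structsim import FingerprintLibrary
from .synergy import DoseResponseSurface, HillFit, _loewe_expected

__all__ = [
    "PlantedExpressionTruth",
    "PlantedToolTruth",
    "PlantedSynergyTruth",
    "gen_expression",
    "gen_tool_outputs",
    "gen_fingerprints",
    "gen_dose_response",
    "write_truth",
]

#: expression baseline on the log2-like scale
BASELINE = 8.0

# fixed sub-stream offsets so each generator draws from an independent
# stream of the same master seed
_STREAM_EXPRESSION = 1
_STREAM_TOOLS = 2
_STREAM_FINGERPRINTS = 3
_STREAM_DOSE_RESPONSE = 4


@dataclass
class PlantedExpressionTruth:
    """Which genes were perturbed, by how much, against what noise."""

    de_genes_up: set[str]
    de_genes_down: set[str]
    effect_size: float
    noise_sd: float

    def __post_init__(self) -> None:
        self.de_genes_up = set(self.de_genes_up)
        self.de_genes_down = set(self.de_genes_down)
        if self.de_genes_up & self.de_genes_down:
            raise ValueError("up and down planted sets must be disjoint")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    def as_json(self) -> dict:
        return {
            "kind": "expression",
            "de_genes_up": sorted(self.de_genes_up),
            "de_genes_down": sorted(self.de_genes_down),
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
        }


@dataclass
class PlantedToolTruth:
    """Which drugs are true reversers and how strongly tools favour them."""

    true_reversers: set[str]
    n_tools: int = 3
    n_datasets: int = 4
    top_k: int = 50
    rank_advantage: float = 0.9

    def __post_init__(self) -> None:
        self.true_reversers = set(self.true_reversers)
        if not 0.5 <= self.rank_advantage <= 1.0:
            raise ValueError("rank_advantage must be in [0.5, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.n_tools < 1 or self.n_datasets < 1:
            raise ValueError("need at least one tool and one dataset")

    def as_json(self) -> dict:
        return {
            "kind": "tool_outputs",
            "true_reversers": sorted(self.true_reversers),
            "n_tools": self.n_tools,
            "n_datasets": self.n_datasets,
            "top_k": self.top_k,
            "rank_advantage": self.rank_advantage,
        }


@dataclass
class PlantedSynergyTruth:
    """Null model, planted deviation and monotherapy Hill parameters."""

    model: str
    delta: float
    hill_params_a: tuple[float, float, float, float]  # (min, max, midpoint, slope)
    hill_params_b: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.model not in {"zip", "loewe", "hsa", "bliss"}:
            raise ValueError(f"unknown synergy model {self.model!r}")
        for params in (self.hill_params_a, self.hill_params_b):
            y_min, y_max, midpoint, _ = params
            if midpoint <= 0:
                raise ValueError("Hill midpoint must be > 0")
            if y_min > y_max:
                raise ValueError("Hill min must be <= max")

    def as_json(self) -> dict:
        return {
            "kind": "dose_response",
            "model": self.model,
            "delta": self.delta,
            "hill_params_a": list(self.hill_params_a),
            "hill_params_b": list(self.hill_params_b),
        }


def write_truth(truth, path: str | Path) -> Path:
    """Write a truth sidecar next to a generated artifact (.truth.json)."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".truth.json") if not str(path).endswith(".truth.json") else path
    sidecar.write_text(json.dumps(truth.as_json(), indent=2) + "\n")
    return sidecar


def gen_expression(
    n_genes: int,
    n_cases: int,
    n_controls: int,
    truth: PlantedExpressionTruth,
    seed: int,
    stage: str = "MM",
    dataset_id: str = "synthetic",
) -> ExpressionDataset:
    """Gaussian expression matrix with planted differential genes.

    Controls are N(baseline, noise_sd^2) per gene; cases are shifted by
    +effect_size on the planted up genes and -effect_size on the planted
    down genes, and match controls in expectation elsewhere. Planted gene
    identifiers must be drawn from GENE0000..GENE{n_genes-1}.
    """
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least 2 samples per group")
    planted = truth.de_genes_up | truth.de_genes_down
    if len(planted) > n_genes:
        raise ValueError("planted gene sets exceed n_genes")
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    unknown = planted - set(genes)
    if unknown:
        raise ValueError(f"planted genes outside the universe: {sorted(unknown)[:5]}")

    rng = np.random.default_rng([seed, _STREAM_EXPRESSION])
    matrix = BASELINE + truth.noise_sd * rng.standard_normal((n_genes, n_cases + n_controls))
    shift = np.zeros(n_genes)
    index = {g: i for i, g in enumerate(genes)}
    for g in truth.de_genes_up:
        shift[index[g]] = truth.effect_size
    for g in truth.de_genes_down:
        shift[index[g]] = -truth.effect_size
    matrix[:, :n_cases] += shift[:, None]

    samples = [f"case_{i:03d}" for i in range(n_cases)] + [f"ctrl_{i:03d}" for i in range(n_controls)]
    groups = pd.Series(["case"] * n_cases + ["control"] * n_controls, index=samples)
    return ExpressionDataset(
        matrix=pd.DataFrame(matrix, index=genes, columns=samples),
        groups=groups,
        stage=stage,
        dataset_id=dataset_id,
    )


def _latent_strengths(rng: np.random.Generator, n: int, is_true: np.ndarray, advantage: float) -> np.ndarray:
    """Latent ordering variable: smaller = stronger reverser.

    Decoys draw U(0,1). True reversers draw Beta(1/p - 1, 1), which beats an
    independent uniform with probability exactly p; p = 1 degenerates to a
    strictly negative latent (always wins).
    """
    latent = rng.random(n)
    n_true = int(is_true.sum())
    if n_true:
        if advantage >= 1.0:
            latent[is_true] = -rng.random(n_true)
        else:
            a = 1.0 / advantage - 1.0
            latent[is_true] = rng.beta(a, 1.0, size=n_true)
    return latent


def gen_tool_outputs(
    drug_universe: list[str],
    truth: PlantedToolTruth,
    seed: int,
    stage: str = "MM",
) -> dict[str, list[RankedDrugList]]:
    """Per-dataset collections of reverser-first top-k tool lists.

    Every tool x dataset list holds exactly top_k drugs with strictly
    decreasing reverser strength (inhibition scores on [-100, 0), most
    negative first); planted true reversers outrank decoys in pairwise
    contests with probability rank_advantage. Returns
    {dataset_id: [RankedDrugList per tool]}.
    """
    universe = list(drug_universe)
    if not universe:
        raise ValueError("empty drug universe")
    if truth.top_k > len(universe):
        raise ValueError("top_k exceeds the drug universe")
    extra = truth.true_reversers - set(universe)
    if extra:
        raise ValueError(f"true reversers outside the universe: {sorted(extra)[:5]}")

    is_true = np.array([d in truth.true_reversers for d in universe])
    out: dict[str, list[RankedDrugList]] = {}
    for di in range(truth.n_datasets):
        dataset_id = f"DS{di + 1}"
        lists = []
        for ti in range(truth.n_tools):
            rng = np.random.default_rng([seed, _STREAM_TOOLS, di, ti])
            latent = _latent_strengths(rng, len(universe), is_true, truth.rank_advantage)
            order = np.argsort(latent, kind="stable")[: truth.top_k]
            entries = [
                (universe[idx], -100.0 * (truth.top_k - r) / truth.top_k)
                for r, idx in enumerate(order)
            ]
            lists.append(
                RankedDrugList(entries=entries, tool_id=f"tool{ti + 1}", dataset_id=dataset_id, stage=stage)
            )
        out[dataset_id] = lists
    return out


def _flip_probability(target_tanimoto: float, density: float) -> float:
    """Bit-flip rate q giving the requested expected within-cluster Tanimoto.

    Members copy a prototype of bit density d and flip each bit with
    probability q; the expected Tanimoto between two members is
    [d(1-q)^2 + (1-d)q^2] / [d(1-q^2) + (1-d)(2q - q^2)]. At q = 0 this is 1
    and it falls toward the random-vector baseline d/(2-d) as q -> 0.5, so a
    target at or below the baseline is infeasible and flagged.
    """
    def expected(q: float) -> float:
        inter = density * (1 - q) ** 2 + (1 - density) * q**2
        union = density * (1 - q**2) + (1 - density) * (2 * q - q**2)
        return inter / union

    baseline = density / (2.0 - density)
    if target_tanimoto <= baseline:
        raise ValueError(
            f"within-cluster Tanimoto {target_tanimoto} is infeasible: at or below "
            f"the random baseline {baseline:.3f} for bit density {density}"
        )
    if target_tanimoto >= 1.0:
        return 0.0
    return float(brentq(lambda q: expected(q) - target_tanimoto, 1e-12, 0.5 - 1e-12))


def gen_fingerprints(
    n_drugs: int,
    n_bits: int,
    n_clusters: int,
    within_cluster_tanimoto: float,
    seed: int,
    density: float = 0.25,
) -> tuple[FingerprintLibrary, dict[str, int]]:
    """Binary fingerprint library with planted structural clusters.

    Each cluster has a random prototype of the given bit density; members
    copy it with a per-bit flip rate calibrated so the expected
    within-cluster Tanimoto meets the target, while between-cluster
    similarity stays near the random baseline d/(2-d). Returns the library
    and the planted drug -> cluster assignment.
    """
    if n_bits < 64:
        raise ValueError("n_bits must be >= 64")
    if not 0 < within_cluster_tanimoto <= 1:
        raise ValueError("within_cluster_tanimoto must be in (0, 1]")
    if n_clusters < 1 or n_drugs < n_clusters:
        raise ValueError("need 1 <= n_clusters <= n_drugs")

    q = _flip_probability(within_cluster_tanimoto, density)
    rng = np.random.default_rng([seed, _STREAM_FINGERPRINTS])
    prototypes = rng.random((n_clusters, n_bits)) < density
    # guarantee non-empty prototypes
    for proto in prototypes:
        if not proto.any():
            proto[rng.integers(n_bits)] = True

    assignment = np.arange(n_drugs) % n_clusters
    flips = rng.random((n_drugs, n_bits)) < q
    bits = prototypes[assignment] ^ flips
    for row, proto in zip(bits, prototypes[assignment]):
        if not row.any():  # re-instate one prototype bit rather than emit an empty vector
            row[np.flatnonzero(proto)[0]] = True

    ids = [f"DRUG{i:04d}" for i in range(n_drugs)]
    library = FingerprintLibrary(ids=ids, bits=bits, origin="synthetic")
    return library, {drug: int(c) + 1 for drug, c in zip(ids, assignment)}


def _null_surface(
    model: str,
    fit_a: HillFit,
    fit_b: HillFit,
    conc_r: np.ndarray,
    conc_c: np.ndarray,
) -> np.ndarray:
    """Noise-free response surface under a model's no-interaction null."""
    y_a = np.asarray(fit_a.predict(conc_r), dtype=float)
    y_b = np.asarray(fit_b.predict(conc_c), dtype=float)
    surface = np.empty((conc_r.size, conc_c.size))
    surface[:, 0] = y_a
    surface[0, :] = y_b
    surface[0, 0] = 0.5 * (y_a[0] + y_b[0])
    for i, x_a in enumerate(conc_r[1:], start=1):
        for j, x_b in enumerate(conc_c[1:], start=1):
            if model in ("bliss", "zip"):
                surface[i, j] = y_a[i] + y_b[j] - y_a[i] * y_b[j] / 100.0
            elif model == "hsa":
                surface[i, j] = max(y_a[i], y_b[j])
            else:  # loewe
                surface[i, j] = _loewe_expected(fit_a, fit_b, float(x_a), float(x_b))
    return surface


def gen_dose_response(
    truth: PlantedSynergyTruth,
    dose_grid_a: np.ndarray,
    dose_grid_b: np.ndarray,
    noise_sd: float,
    seed: int,
    drug_row: str = "drugA",
    drug_col: str = "drugB",
) -> DoseResponseSurface:
    """Dose-response surface under a synergy model's null plus planted delta.

    Monotherapy margins follow the stated Hill curves exactly (plus noise);
    combination cells (both doses positive) equal the chosen model's
    no-interaction expectation plus ``truth.delta`` plus Gaussian noise.
    """
    conc_r = np.asarray(dose_grid_a, dtype=float)
    conc_c = np.asarray(dose_grid_b, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for grid in (conc_r, conc_c):
        if grid.size == 0:
            raise ValueError("empty dose grid")
        if grid[0] != 0 or np.any(np.diff(grid) <= 0) or np.any(grid < 0):
            raise ValueError("dose grids must be strictly increasing and start at 0")

    def to_fit(params: tuple[float, float, float, float]) -> HillFit:
        y_min, y_max, midpoint, slope = params
        return HillFit(y_min, y_max, midpoint, slope, converged=True, rmse=0.0)

    fit_a, fit_b = to_fit(truth.hill_params_a), to_fit(truth.hill_params_b)
    response = _null_surface(truth.model, fit_a, fit_b, conc_r, conc_c)
    response[1:, 1:] += truth.delta
    if noise_sd > 0:
        rng = np.random.default_rng([seed, _STREAM_DOSE_RESPONSE])
        response = response + noise_sd * rng.standard_normal(response.shape)
    return DoseResponseSurface(
        drug_row=drug_row, drug_col=drug_col, conc_r=conc_r, conc_c=conc_c,
        response=response, block_id=f"{truth.model}-seed{seed}",
    )
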