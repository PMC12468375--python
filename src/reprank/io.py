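"""Readers and writers for the pipeline's plain-text formats.

All tabular outputs carry a leading ``#`` header comment (tool version,
seed, config hash when available); all readers skip such comments.
Formats: expression TSV (genes x samples) with a sample-sheet TSV,
long-format tool-output CSV, fingerprint CSV (hex-encoded bit-vectors),
long-format dose-response CSV (DrugComb-style columns), GMT gene sets,
two-column signature TSV, and plain GRP gene lists.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import RankedDrugList
from .de import ExpressionDataset, Signature
from .structsim import FingerprintLibrary
from .synergy import DoseResponseSurface

__all__ = [
    "header_comment",
    "write_table",
    "read_table",
    "write_expression",
    "read_expression",
    "write_tool_outputs",
    "read_tool_outputs",
    "write_signature",
    "read_signature",
    "write_fingerprints",
    "read_fingerprints",
    "write_dose_response",
    "read_dose_response",
    "write_gmt",
    "read_gmt",
    "read_smiles",
    "read_sdf",
    "read_drug_targets",
]


def header_comment(seed: int | None = None, config_hash: str | None = None) -> str:
    parts = [f"reprank v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return "# " + " ".join(parts) + "\n"


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",", index: bool = False,
                seed: int | None = None, config_hash: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header_comment(seed, config_hash))
        df.to_csv(fh, sep=sep, index=index)
    return path


def read_table(path: str | Path, sep: str = ",", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


# -- expression ---------------------------------------------------------------

def write_expression(dataset: ExpressionDataset, matrix_path: str | Path,
                     samples_path: str | Path, seed: int | None = None) -> None:
    write_table(dataset.matrix, matrix_path, sep="\t", index=True, seed=seed)
    sheet = pd.DataFrame({"sample_id": dataset.groups.index, "group": dataset.groups.values})
    write_table(sheet, samples_path, sep="\t", seed=seed)


def read_expression(matrix_path: str | Path, samples_path: str | Path,
                    stage: str = "", dataset_id: str = "") -> ExpressionDataset:
    matrix = read_table(matrix_path, sep="\t", index_col=0)
    sheet = read_table(samples_path, sep="\t")
    groups = pd.Series(sheet["group"].values, index=sheet["sample_id"].values)
    return ExpressionDataset(matrix=matrix, groups=groups, stage=stage, dataset_id=dataset_id)


# -- tool outputs -------------------------------------------------------------

def write_tool_outputs(per_dataset: dict[str, list[RankedDrugList]], path: str | Path,
                       seed: int | None = None) -> Path:
    rows = []
    for dataset_id, lists in per_dataset.items():
        for ranked in lists:
            for drug, score in ranked.entries:
                rows.append((drug, score, ranked.tool_id, dataset_id, ranked.stage))
    df = pd.DataFrame(rows, columns=["drug_id", "inhibition_score", "tool_id", "dataset_id", "stage"])
    return write_table(df, path, seed=seed)


def read_tool_outputs(path: str | Path) -> dict[str, dict[str, list[RankedDrugList]]]:
    """Read the long CSV back into {stage: {dataset_id: [lists per tool]}}."""
    df = read_table(path)
    out: dict[str, dict[str, list[RankedDrugList]]] = {}
    for (stage, dataset_id, tool_id), chunk in df.groupby(["stage", "dataset_id", "tool_id"], sort=True):
        chunk = chunk.sort_values(["inhibition_score", "drug_id"], kind="mergesort")
        ranked = RankedDrugList(
            entries=list(zip(chunk["drug_id"], chunk["inhibition_score"])),
            tool_id=str(tool_id), dataset_id=str(dataset_id), stage=str(stage),
        )
        out.setdefault(str(stage), {}).setdefault(str(dataset_id), []).append(ranked)
    return out


# -- signatures ---------------------------------------------------------------

def write_signature(sig: Signature, path: str | Path, seed: int | None = None,
                    grp_dir: str | Path | None = None) -> Path:
    df = pd.DataFrame(
        {"gene": sig.up + sig.down, "direction": ["up"] * len(sig.up) + ["down"] * len(sig.down)}
    )
    out = write_table(df, path, sep="\t", seed=seed)
    if grp_dir is not None:
        grp_dir = Path(grp_dir)
        grp_dir.mkdir(parents=True, exist_ok=True)
        stem = Path(path).stem
        for direction, genes in (("up", sig.up), ("down", sig.down)):
            (grp_dir / f"{stem}_{direction}.grp").write_text("\n".join(genes) + "\n")
    return out


def read_signature(path: str | Path, stage: str = "", dataset_id: str = "") -> Signature:
    df = read_table(path, sep="\t")
    return Signature(
        up=list(df.loc[df["direction"] == "up", "gene"]),
        down=list(df.loc[df["direction"] == "down", "gene"]),
        stage=stage, dataset_id=dataset_id,
    )


# -- fingerprints -------------------------------------------------------------

def write_fingerprints(library: FingerprintLibrary, path: str | Path,
                       seed: int | None = None) -> Path:
    hex_width = -(-library.n_bits // 4)
    rows = []
    for drug, bits in zip(library.ids, library.bits):
        value = int("".join("1" if b else "0" for b in bits), 2)
        rows.append((drug, format(value, f"0{hex_width}x")))
    df = pd.DataFrame(rows, columns=["drug_id", "fingerprint_hex"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header_comment(seed))
        fh.write(f"# n_bits={library.n_bits} origin={library.origin}\n")
        df.to_csv(fh, index=False)
    return path


def read_fingerprints(path: str | Path) -> FingerprintLibrary:
    n_bits = None
    origin = "synthetic"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "n_bits=" in line:
                for token in line[1:].split():
                    key, _, value = token.partition("=")
                    if key == "n_bits":
                        n_bits = int(value)
                    elif key == "origin":
                        origin = value
            if not line.startswith("#"):
                break
    df = read_table(path)
    if n_bits is None:
        n_bits = len(df["fingerprint_hex"].iloc[0]) * 4
    bits = np.zeros((len(df), n_bits), dtype=bool)
    for i, hexstr in enumerate(df["fingerprint_hex"]):
        as_bits = bin(int(str(hexstr), 16))[2:].zfill(n_bits)
        bits[i] = np.frombuffer(as_bits.encode(), dtype=np.uint8) == ord("1")
    return FingerprintLibrary(ids=list(df["drug_id"]), bits=bits, origin=origin)


# -- dose-response ------------------------------------------------------------

def write_dose_response(surfaces: list[DoseResponseSurface], path: str | Path,
                        seed: int | None = None) -> Path:
    rows = []
    for surf in surfaces:
        for i, cr in enumerate(surf.conc_r):
            for j, cc in enumerate(surf.conc_c):
                rows.append((surf.block_id or surf.pair_id, surf.drug_row, surf.drug_col,
                             cr, cc, surf.response[i, j]))
    df = pd.DataFrame(rows, columns=["block_id", "drug_row", "drug_col", "conc_r", "conc_c", "response"])
    return write_table(df, path, seed=seed)


def read_dose_response(path: str | Path) -> list[DoseResponseSurface]:
    df = read_table(path)
    surfaces = []
    for block_id, chunk in df.groupby("block_id", sort=True):
        conc_r = np.sort(chunk["conc_r"].unique())
        conc_c = np.sort(chunk["conc_c"].unique())
        grid = chunk.pivot_table(index="conc_r", columns="conc_c", values="response")
        grid = grid.reindex(index=conc_r, columns=conc_c)
        if grid.isna().any().any():
            raise ValueError(f"block {block_id}: incomplete dose grid")
        surfaces.append(DoseResponseSurface(
            drug_row=str(chunk["drug_row"].iloc[0]), drug_col=str(chunk["drug_col"].iloc[0]),
            conc_r=conc_r, conc_c=conc_c, response=grid.to_numpy(), block_id=str(block_id),
        ))
    return surfaces


# -- gene sets ----------------------------------------------------------------

def write_gmt(sets: dict[str, tuple[str, list[str] | frozenset[str]]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for term in sorted(sets):
            desc, genes = sets[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = (fields[1], frozenset(g for g in fields[2:] if g))
    return sets


# -- chemistry ----------------------------------------------------------------

def read_smiles(path: str | Path) -> list[tuple[str, str]]:
    """Whitespace-delimited .smi: SMILES first, then the identifier."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        drug_id = parts[1].strip() if len(parts) > 1 else smiles
        records.append((drug_id, smiles))
    return records


def read_sdf(path: str | Path) -> list[tuple[str, str]]:
    """Multi-record SDF to (id, SMILES) via RDKit."""
    from rdkit import Chem

    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            records.append((f"record_{i}", "<unparsable>"))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record_{i}"
        records.append((name, Chem.MolToSmiles(mol)))
    return records


def read_drug_targets(path: str | Path) -> dict[str, set[str]]:
    """Drug-target CSV (drug, target[, source]) to drug -> target-set."""
    df = read_table(path)
    cols = {c.lower(): c for c in df.columns}
    drug_col = cols.get("drug", cols.get("drug_id"))
    target_col = cols.get("target", cols.get("gene"))
    if drug_col is None or target_col is None:
        raise ValueError("drug-target CSV needs 'drug' and 'target' columns")
    mapping: dict[str, set[str]] = {}
    for drug, target in zip(df[drug_col], df[target_col]):
        mapping.setdefault(str(drug), set()).add(str(target).upper())
    return mapping
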