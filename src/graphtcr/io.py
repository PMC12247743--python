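"""Tabular readers/writers and run configuration.

TSV is the canonical format (CSV accepted on read).  Residue positions are
0-based half-open everywhere.  Every pipeline run writes its resolved
configuration next to its outputs so runs are reproducible from the input
file and the config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import BindingPair
from .peptide_graph import AMINO_ACIDS
from .wl import EmbeddingMatrix

logger = logging.getLogger("graphtcr")

_VDJDB_COLUMNS = {"cdr3": "cdr3", "antigen.epitope": "epitope",
                  "antigen.gene": "antigen_group"}


@dataclass
class PairsTable:
    frame: pd.DataFrame  # columns: id, cdr3, epitope, label, antigen_group
    n_dropped: int = 0

    def to_pairs(self) -> list[BindingPair]:
        out = []
        for row in self.frame.itertuples(index=False):
            label = int(row.label)
            out.append(BindingPair(tcr=row.cdr3, epitope=row.epitope,
                                   label=label,
                                   origin="observed" if label else "shuffled",
                                   pair_id=int(row.id)))
        return out

    def groups(self) -> dict[str, str] | None:
        if self.frame["antigen_group"].isna().all():
            return None
        g = self.frame.dropna(subset=["antigen_group"])
        return dict(zip(g["epitope"], g["antigen_group"]))


@dataclass
class RunConfig:
    wl_iterations: int = 5
    dimensions: int = 256
    epochs: int = 10
    seed: int = 0
    min_tcrs: int = 1000
    test_fraction: float = 0.2
    negative_strategy: str = "shuffle"
    negative_ratio: float = 1.0
    n_trees: int = 500
    max_depth: int | None = None
    eps_min: float = 0.01
    eps_max: float = 20.0
    eps_points: int = 50
    min_points: int = 5
    reduced_dims: int = 24
    cluster_metric: str = "manhattan"
    motif_min_tcrs: int = 5
    motif_min_occurrences: int = 20
    gap_penalty: int = 4
    trim_n: int = 3
    trim_c: int = 2
    non_attributed: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"empty table: {path}")
    return df


def read_pairs(path: str | Path, dialect: str = "generic") -> PairsTable:
    """Read a pairs table; rows with out-of-alphabet residues are dropped
    (counted, with row-numbered warnings)."""
    df = _read_table(path)
    if dialect == "vdjdb":
        missing = [c for c in ("cdr3", "antigen.epitope") if c not in df.columns]
        if missing:
            raise ValueError(f"missing VDJdb columns: {missing}")
        df = df.rename(columns=_VDJDB_COLUMNS)
    elif dialect == "generic":
        missing = [c for c in ("cdr3", "epitope") if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if "label" not in df.columns:
        df["label"] = 1
    if "antigen_group" not in df.columns:
        df["antigen_group"] = pd.NA
    if "id" not in df.columns:
        df["id"] = np.arange(len(df))

    alphabet = set(AMINO_ACIDS)
    ok = df.apply(lambda r: set(str(r.cdr3)) <= alphabet
                  and set(str(r.epitope)) <= alphabet
                  and len(str(r.cdr3)) > 0 and len(str(r.epitope)) > 0, axis=1)
    for i in df.index[~ok]:
        logger.warning("row %d dropped: invalid residues (%s / %s)",
                       i, df.at[i, "cdr3"], df.at[i, "epitope"])
    dropped = int((~ok).sum())
    df = df[ok].reset_index(drop=True)
    if df["id"].duplicated().any():
        raise ValueError("duplicate ids in pairs table")
    return PairsTable(frame=df[["id", "cdr3", "epitope", "label",
                                "antigen_group"]], n_dropped=dropped)


def write_pairs(pairs: list[BindingPair], path: str | Path) -> None:
    pd.DataFrame([{"id": p.pair_id, "cdr3": p.tcr, "epitope": p.epitope,
                   "label": p.label, "antigen_group": pd.NA,
                   "origin": p.origin} for p in pairs]
                 ).to_csv(path, sep="\t", index=False)


def write_embeddings(emb: EmbeddingMatrix, path: str | Path) -> None:
    df = pd.DataFrame(emb.vectors,
                      columns=[f"dim_{i}" for i in range(emb.dimensions)])
    df.insert(0, "id", emb.graph_ids)
    df.to_csv(path, sep="\t", index=False)
    Path(str(path) + ".meta.json").write_text(
        json.dumps(emb.training_meta, indent=2, sort_keys=True))


def read_embeddings(path: str | Path) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t")
    dims = [c for c in df.columns if c.startswith("dim_")]
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return EmbeddingMatrix(graph_ids=df["id"].astype(str).tolist(),
                           vectors=df[dims].to_numpy(),
                           dimensions=len(dims), training_meta=meta)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
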