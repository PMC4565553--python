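"""Readers and writers for the pipeline's interchange formats.

FASTA sequence files, Newick tree sets with optional posterior weights,
kinetics trace CSVs, JSON run configurations, and stage-timed logging.
Gap characters are normalized to ``-`` ('.' is accepted on input); taxon
labels keep their underscores.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "WeightedTreeSet",
    "read_tree_set",
    "write_tree_set",
    "TraceTable",
    "read_traces",
    "write_traces",
    "load_config",
    "save_config",
    "get_logger",
    "StageTimer",
    "file_checksum",
    "write_manifest",
]

PHASES = ("association", "dissociation")


@dataclass
class SequenceRecord:
    """A single labelled sequence (residues or nucleotides)."""

    id: str
    seq: str


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file, preserving record order and gap characters.

    '.' gaps are normalized to '-'.  Duplicate ids and empty files raise
    ``ValueError``.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).replace(".", "-").upper()))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class WeightedTreeSet:
    """Topologies with branch lengths plus normalized posterior weights.

    The carrier of topology uncertainty: every downstream quantity that is
    integrated over topologies is averaged with these weights.  All trees
    share one taxon set.
    """

    trees: dendropy.TreeList
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.trees) != len(self.weights):
            raise ValueError(
                f"{len(self.trees)} trees but {len(self.weights)} weights"
            )
        if np.any(self.weights < 0):
            raise ValueError("tree weights must be nonnegative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("tree weights must not all be zero")
        self.weights = self.weights / total
        leafsets = [frozenset(l.taxon.label for l in t.leaf_node_iter())
                    for t in self.trees]
        if len(set(leafsets)) > 1:
            raise ValueError("all trees in a set must share one taxon set")

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(zip(self.trees, self.weights))

    @property
    def taxon_labels(self) -> frozenset:
        return frozenset(l.taxon.label for l in self.trees[0].leaf_node_iter())


def read_tree_set(newick_path, weights_path=None) -> WeightedTreeSet:
    """Read one Newick tree per line, with an optional weights file (one
    nonnegative number per tree).  Weights are normalized to sum 1; absent
    weights default to uniform."""
    trees = dendropy.TreeList.get(
        path=str(newick_path), schema="newick", preserve_underscores=True
    )
    if len(trees) == 0:
        raise ValueError(f"no trees found in {newick_path}")
    if weights_path is None:
        weights = np.ones(len(trees))
    else:
        with open(weights_path) as fh:
            weights = np.array(
                [float(line) for line in fh if line.strip()], dtype=float
            )
        if len(weights) != len(trees):
            raise ValueError(
                f"weight count ({len(weights)}) does not match tree count "
                f"({len(trees)})"
            )
    return WeightedTreeSet(trees, weights)


def write_tree_set(tree_set: WeightedTreeSet, newick_path, weights_path=None) -> None:
    with open(newick_path, "w") as fh:
        for tree in tree_set.trees:
            fh.write(tree.as_string(schema="newick", suppress_rooting=True,
                                    unquoted_underscores=True).strip() + "\n")
    if weights_path is not None:
        with open(weights_path, "w") as fh:
            for w in tree_set.weights:
                fh.write(f"{w:.12g}\n")


# ---------------------------------------------------------------------------
# kinetics traces
# ---------------------------------------------------------------------------

@dataclass
class TraceTable:
    """Association/dissociation traces across concentrations and replicates.

    Wraps a DataFrame with columns ``time`` (s), ``signal`` (nm),
    ``concentration_M``, ``replicate`` and ``phase``; rows are sorted by
    (concentration, replicate, phase, time) with time strictly increasing
    within each series.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"time", "signal", "concentration_M", "replicate", "phase"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trace table missing columns: {sorted(missing)}")
        bad = set(self.data["phase"].unique()) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase label(s): {sorted(bad)}")
        for key, grp in self.data.groupby(
            ["concentration_M", "replicate", "phase"], sort=False
        ):
            t = grp["time"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"time not strictly increasing within series {key}"
                )
        phase_order = {p: i for i, p in enumerate(PHASES)}
        df = self.data.copy()
        df["_p"] = df["phase"].map(phase_order)
        df = df.sort_values(
            ["concentration_M", "replicate", "_p", "time"], kind="stable"
        ).drop(columns="_p").reset_index(drop=True)
        self.data = df

    def series(self, concentration, replicate, phase="association"):
        """(time, signal) arrays for one trace."""
        m = (
            np.isclose(self.data["concentration_M"], concentration,
                       rtol=1e-9, atol=0.0)
            & (self.data["replicate"] == replicate)
            & (self.data["phase"] == phase)
        )
        sub = self.data[m]
        return sub["time"].to_numpy(), sub["signal"].to_numpy()

    @property
    def concentrations(self) -> np.ndarray:
        c = np.unique(self.data["concentration_M"].to_numpy())
        return c[c > 0]

    @property
    def replicates(self) -> np.ndarray:
        return np.unique(self.data["replicate"].to_numpy())

    def has_blank(self) -> bool:
        return bool(np.any(self.data["concentration_M"] == 0))


def read_traces(csv_path) -> TraceTable:
    """Read a trace CSV (columns time, signal, concentration_M, replicate,
    phase).  Concentrations are molar and times seconds."""
    df = pd.read_csv(csv_path)
    df["concentration_M"] = df["concentration_M"].astype(float)
    df["time"] = df["time"].astype(float)
    df["signal"] = df["signal"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    return TraceTable(df)


def write_traces(table: TraceTable, path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration, logging, manifests
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
        fh.write("\n")


def get_logger(name: str = "cardevol", logfile=None, verbose: bool = False):
    logger = logging.getLogger(name)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(str(logfile))
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger


class StageTimer:
    """Context manager logging wall-clock duration of a pipeline stage."""

    def __init__(self, logger, stage: str):
        self.logger = logger
        self.stage = stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.logger.info("stage %s: started", self.stage)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            self.logger.info("stage %s: finished in %.2fs", self.stage, dt)
        else:
            self.logger.error("stage %s: failed after %.2fs: %s",
                              self.stage, dt, exc)
        return False


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(directory, manifest_path, exclude=()) -> dict:
    """Checksum every file under ``directory`` into a JSON manifest."""
    directory = Path(directory)
    entries = {}
    for p in sorted(directory.rglob("*")):
        if p.is_file() and p.name not in exclude:
            entries[str(p.relative_to(directory))] = file_checksum(p)
    with open(manifest_path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return entries
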