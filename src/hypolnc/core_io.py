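"""Readers and writers for the formats the pipeline touches.

Sequences are held internally in the DNA alphabet (``T``, never ``U``);
RNA input is converted on read and can be converted back on write. The
only ambiguity code accepted is ``N``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger("hypolnc")

_VALID_CHARS = frozenset("ACGTN")

#: Cytoscape-style node-type prefixes: mRNA target, lncRNA target,
#: mRNA mimic (decoy), lncRNA mimic (decoy).
NODE_PREFIXES = {
    "mRNA_target": "MT",
    "lncRNA_target": "LT",
    "mRNA_mimic": "MD",
    "lncRNA_mimic": "LD",
    "miRNA": "miRNA",
}


class FastaError(ValueError):
    pass


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing sample: tissue, oxygen level (% O2) and replicate."""

    sample_id: str
    tissue: str
    oxygen_pct: float
    replicate: int

    def __post_init__(self) -> None:
        if self.oxygen_pct <= 0:
            raise ValueError(f"oxygen_pct must be > 0, got {self.oxygen_pct}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def group(self) -> tuple[str, float]:
        return (self.tissue, self.oxygen_pct)


@dataclass
class FilterConfig:
    """Thresholds of the stepwise lncRNA identification pipeline.

    ``external_evalues`` is record-keeping for the external homology /
    coding-potential tools whose outputs enter the pipeline as id lists;
    the values are never applied by this package.
    """

    min_len_nt: int = 200
    max_orf_nt: int = 300
    fpkm_min: float = 1.0
    min_expressed_samples: int = 2
    external_evalues: dict = field(
        default_factory=lambda: {
            "swissprot_blastx": 1e-10,
            "nr_blastx": 1e-10,
            "pfam_phmmer": 1e-5,
            "rfam_blastn": 1e-5,
            "cpat_cutoff": 0.44,
        }
    )

    def __post_init__(self) -> None:
        if self.min_len_nt < 0 or self.max_orf_nt < 0 or self.fpkm_min < 0:
            raise ValueError("filter thresholds must be non-negative")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"min_len_nt = {self.min_len_nt}\n")
            fh.write(f"max_orf_nt = {self.max_orf_nt}\n")
            fh.write(f"fpkm_min = {self.fpkm_min}\n")
            fh.write(f"min_expressed_samples = {self.min_expressed_samples}\n")
            for name, ev in self.external_evalues.items():
                fh.write(f"evalue.{name} = {ev}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterConfig":
        kwargs: dict = {}
        evalues: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key.startswith("evalue."):
                    evalues[key[len("evalue."):]] = float(value)
                elif key in ("min_len_nt", "max_orf_nt", "min_expressed_samples"):
                    kwargs[key] = int(value)
                elif key == "fpkm_min":
                    kwargs[key] = float(value)
                else:
                    raise ValueError(f"unknown config key {key!r} in {path}")
        if evalues:
            kwargs["external_evalues"] = evalues
        return cls(**kwargs)


@dataclass
class ExpressionMatrix:
    """Transcripts x samples expression values plus sample metadata.

    ``values`` is a DataFrame indexed by transcript id with one column per
    sample; ``samples`` is indexed by sample_id with columns tissue,
    oxygen_pct and replicate, one row per matrix column.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        # align metadata row order to matrix column order
        self.samples = self.samples.loc[list(self.values.columns)]
        if (self.values.values < 0).any():
            bad = (self.values < 0).stack()
            t, s = bad[bad].index[0]
            raise ValueError(f"negative expression value at transcript {t!r}, sample {s!r}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> dict[tuple[str, float], list[str]]:
        """Map (tissue, oxygen_pct) -> sample ids, in metadata order."""
        out: dict[tuple[str, float], list[str]] = {}
        for sid, row in self.samples.iterrows():
            out.setdefault((row["tissue"], float(row["oxygen_pct"])), []).append(sid)
        return out

    def subset(self, transcript_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(transcript_ids)], self.samples.copy())


def _normalize_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in _VALID_CHARS:
            raise FastaError(
                f"invalid character {ch!r} at position {pos} in record {record_id!r}"
            )
    return seq


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs.

    Ids are the first whitespace-delimited header token. Sequences are
    uppercased and U is normalized to T regardless of ``alphabet`` (which
    is accepted for interface symmetry; both alphabets normalize the same
    way). Duplicate ids and non-ACGT/U/N characters raise ``FastaError``.
    """
    if alphabet not in ("dna", "rna", "auto"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            rid = header.split()[0] if header.split() else header
            if rid in seen:
                raise FastaError(f"duplicate FASTA id {rid!r} in {path}")
            seen.add(rid)
            records.append((rid, _normalize_sequence(seq, rid)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                alphabet: str = "dna", width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA; ``alphabet='rna'`` emits U."""
    with open(path, "w") as fh:
        for rid, seq in records:
            if alphabet == "rna":
                seq = seq.replace("T", "U")
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    required = {"sample_id", "tissue", "oxygen_pct", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in metadata")
    if (meta["oxygen_pct"] <= 0).any():
        raise ValueError("oxygen_pct must be > 0")
    return meta.set_index("sample_id", drop=False)


def read_expression(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column transcript ids, header of
    sample ids) with its sample-metadata table."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = read_sample_meta(meta_path)
    missing = [c for c in values.columns if c not in meta.index]
    if missing:
        raise ValueError(f"matrix samples absent from metadata: {missing}")
    values = values.astype(float)
    if not np.isfinite(values.values).all():
        raise ValueError("expression matrix contains non-finite values")
    return ExpressionMatrix(values, meta)


def write_expression(em: ExpressionMatrix, path: str | Path,
                     meta_path: str | Path | None = None) -> None:
    em.values.to_csv(path, sep="\t", index_label="transcript_id")
    if meta_path is not None:
        em.samples[["sample_id", "tissue", "oxygen_pct", "replicate"]].to_csv(
            meta_path, sep="\t", index=False)


def export_network(graph: nx.Graph, path_prefix: str | Path,
                   fmt: str = "sif") -> list[Path]:
    """Export a typed interaction graph for external viewers.

    ``sif`` writes Cytoscape SIF plus a node-attribute TSV; ``graphml``
    writes GraphML; ``edge_tsv`` writes an edge list TSV that round-trips
    through :func:`read_edge_tsv`. Node ids are expected to carry a
    ``node_type`` attribute.
    """
    prefix = Path(path_prefix)
    written: list[Path] = []
    if fmt == "sif":
        sif = prefix.with_suffix(".sif")
        with open(sif, "w") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{data.get('relation', 'interacts')}\t{v}\n")
            for node in sorted(graph.nodes):
                if graph.degree[node] == 0:
                    fh.write(f"{node}\n")
        written.append(sif)
        nodes = prefix.parent / (prefix.name + ".nodes.tsv")
        with open(nodes, "w") as fh:
            fh.write("node_id\tnode_type\n")
            for node, data in sorted(graph.nodes(data=True)):
                fh.write(f"{node}\t{data.get('node_type', 'unknown')}\n")
        written.append(nodes)
    elif fmt == "graphml":
        out = prefix.with_suffix(".graphml")
        nx.write_graphml(graph, out)
        written.append(out)
    elif fmt == "edge_tsv":
        out = prefix.parent / (prefix.name + ".edges.tsv")
        with open(out, "w") as fh:
            fh.write("source\ttarget\trelation\n")
            for u, v, data in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data.get('relation', 'interacts')}\n")
        written.append(out)
        nodes = prefix.parent / (prefix.name + ".nodes.tsv")
        with open(nodes, "w") as fh:
            fh.write("node_id\tnode_type\n")
            for node, data in sorted(graph.nodes(data=True)):
                fh.write(f"{node}\t{data.get('node_type', 'unknown')}\n")
        written.append(nodes)
    else:
        raise ValueError(f"unknown network export format {fmt!r}")
    return written


def read_edge_tsv(edge_path: str | Path,
                  node_path: str | Path | None = None) -> nx.Graph:
    """Re-import a graph written by ``export_network(..., fmt='edge_tsv')``."""
    g = nx.Graph()
    edges = pd.read_csv(edge_path, sep="\t")
    for _, row in edges.iterrows():
        g.add_edge(str(row["source"]), str(row["target"]),
                   relation=str(row.get("relation", "interacts")))
    if node_path is not None:
        nodes = pd.read_csv(node_path, sep="\t")
        for _, row in nodes.iterrows():
            g.add_node(str(row["node_id"]), node_type=str(row["node_type"]))
    return g


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def revcomp(seq: str) -> str:
    """Reverse complement in the internal DNA alphabet (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
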