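"""Readers and writers for the tabular and graph formats the pipeline touches.

All readers are strict: malformed input raises :class:`FormatError` rather than
being silently dropped. Benign normalisations (self-loop removal, duplicate-row
collapsing) are logged with counts.

File layouts
------------
expression      TSV, first column = gene symbol, header row = sample ids.
interactome     BioGRID tab format (``Official Symbol Interactor A``/``B``
                columns) or a plain two-column file of gene-symbol pairs.
tf_targets      two columns, no header: TF symbol, target gene symbol.
drug catalog    TSV with header ``drug_id  drug_name  target``, one target per row.
instance matrix TSV, genes x instance ids (header row of instance ids).
instance meta   TSV with header ``instance_id  drug_id  cell_line  time_h  dose``.
screening       TSV with header ``drug_name  growth_rate``.
gene list       one symbol per line; blank lines and ``#`` comments ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "Interactome",
    "TFTargetMap",
    "DrugRecord",
    "DrugCatalog",
    "InstanceProfileSet",
    "ScreeningTable",
    "read_expression_table",
    "read_interactome",
    "read_tf_targets",
    "read_drug_catalog",
    "read_instance_profiles",
    "read_gene_list",
    "read_screening_table",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """A file violated the documented layout or an invariant of its type."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample intensity matrix with case/control group labels.

    ``values`` is indexed by gene symbol with one column per sample;
    ``groups`` maps each sample id to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    @property
    def case_ids(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == "case"]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == "control"]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class Interactome:
    """Undirected protein-protein interaction graph over gene symbols.

    Self-loops are removed on load; edges are unordered pairs with duplicates
    (including reversed duplicates) collapsed.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}


@dataclass
class TFTargetMap:
    """Transcription factor -> set of regulated target genes."""

    targets: dict[str, frozenset[str]]

    def __contains__(self, tf: str) -> bool:
        return tf in self.targets

    def __getitem__(self, tf: str) -> frozenset[str]:
        return self.targets[tf]

    @property
    def tfs(self) -> list[str]:
        return sorted(self.targets)

    @property
    def all_targets(self) -> set[str]:
        out: set[str] = set()
        for t in self.targets.values():
            out |= t
        return out


@dataclass
class DrugRecord:
    drug_id: str
    name: str
    targets: frozenset[str]


@dataclass
class DrugCatalog:
    """Drug id -> (name, target gene set)."""

    entries: dict[str, DrugRecord]

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.entries

    def __getitem__(self, drug_id: str) -> DrugRecord:
        return self.entries[drug_id]

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.entries)


@dataclass
class InstanceProfileSet:
    """Drug perturbation instances with metadata and z-score profiles.

    ``metadata`` is indexed by instance id with columns ``drug_id``,
    ``cell_line``, ``time_h``, ``dose``; ``profiles`` is a gene x instance-id
    matrix of differential-expression z-scores.
    """

    metadata: pd.DataFrame
    profiles: pd.DataFrame

    @property
    def instance_ids(self) -> list[str]:
        return list(self.metadata.index)

    def profile(self, instance_id: str) -> pd.Series:
        return self.profiles[instance_id]

    def subset(self, instance_ids: Iterable[str]) -> "InstanceProfileSet":
        ids = [i for i in self.instance_ids if i in set(instance_ids)]
        return InstanceProfileSet(
            metadata=self.metadata.loc[ids].copy(),
            profiles=self.profiles[ids].copy(),
        )

    def orphans(self, catalog: DrugCatalog) -> list[str]:
        """Instance ids whose drug is absent from the catalog."""
        return [
            i for i in self.instance_ids
            if self.metadata.at[i, "drug_id"] not in catalog
        ]


@dataclass
class ScreeningTable:
    """Drug name -> mean growth rate from a cell-line screen (lower = more
    growth suppression)."""

    rates: dict[str, float]

    def __len__(self) -> int:
        return len(self.rates)

    def __getitem__(self, name: str) -> float:
        return self.rates[name]

    @property
    def drug_names(self) -> list[str]:
        return sorted(self.rates)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path,
    case_ids: Iterable[str],
    control_ids: Iterable[str],
    collapse: Literal["mean", "max"] = "mean",
) -> ExpressionMatrix:
    """Read a gene x sample expression TSV and attach group labels.

    Duplicate gene rows (e.g. multiple probes per gene) are collapsed by
    ``collapse`` (arithmetic mean by default). Values must be finite and
    non-negative.
    """
    case_ids = [str(s) for s in case_ids]
    control_ids = [str(s) for s in control_ids]
    if not case_ids or not control_ids:
        raise FormatError("need at least one case and one control sample id")
    overlap = set(case_ids) & set(control_ids)
    if overlap:
        raise FormatError(f"sample ids in both groups: {sorted(overlap)}")

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]

    wanted = case_ids + control_ids
    missing = [s for s in wanted if s not in df.columns]
    if missing:
        raise FormatError(f"sample id(s) not found in {path}: {missing}")
    df = df[wanted]

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise FormatError(
            f"non-numeric expression value at gene {gene!r}, sample {col!r}"
        )
    if not np.isfinite(numeric.to_numpy(dtype=float)).all():
        raise FormatError("expression values must be finite")
    if (numeric.to_numpy(dtype=float) < 0).any():
        raise FormatError("expression intensities must be non-negative")

    n_dup = int(numeric.index.duplicated().sum())
    if n_dup:
        agg = {"mean": "mean", "max": "max"}[collapse]
        numeric = numeric.groupby(level=0, sort=True).agg(agg)
        logger.info("collapsed %d duplicate gene rows by %s", n_dup, collapse)

    groups = {s: "case" for s in case_ids}
    groups.update({s: "control" for s in control_ids})
    return ExpressionMatrix(values=numeric, groups=groups)


_BIOGRID_A = "Official Symbol Interactor A"
_BIOGRID_B = "Official Symbol Interactor B"


def read_interactome(
    path: str | Path,
    dialect: Literal["biogrid_tab", "two_column"] = "two_column",
) -> Interactome:
    """Read an undirected interactome edge list.

    ``biogrid_tab`` uses the official-symbol interactor columns of the BioGRID
    tab format; ``two_column`` expects whitespace-separated symbol pairs.
    Self-loops are removed and duplicate / reversed-duplicate edges collapsed.
    """
    pairs: list[tuple[str, str]] = []
    if dialect == "two_column":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}: line {lineno}: expected 2 fields, got {len(parts)}"
                    )
                pairs.append((parts[0], parts[1]))
    elif dialect == "biogrid_tab":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.lstrip("#").strip(): c for c in df.columns}
        if _BIOGRID_A not in cols or _BIOGRID_B not in cols:
            raise FormatError(
                f"{path}: BioGRID tab format requires columns "
                f"{_BIOGRID_A!r} and {_BIOGRID_B!r}"
            )
        for lineno, (a, b) in enumerate(
            zip(df[cols[_BIOGRID_A]], df[cols[_BIOGRID_B]]), start=2
        ):
            if pd.isna(a) or pd.isna(b):
                raise FormatError(f"{path}: line {lineno}: missing interactor symbol")
            pairs.append((str(a).strip(), str(b).strip()))
    else:
        raise FormatError(f"unknown interactome dialect {dialect!r}")

    g = nx.Graph()
    n_self = 0
    for a, b in pairs:
        if not a or not b:
            raise FormatError("empty gene symbol in interactome")
        if a == b:
            n_self += 1
            continue
        g.add_edge(a, b)
    if n_self:
        logger.info("removed %d self-interaction edges", n_self)
    n_dup = len(pairs) - n_self - g.number_of_edges()
    if n_dup:
        logger.info("collapsed %d duplicate edges", n_dup)
    return Interactome(graph=g)


def read_tf_targets(path: str | Path) -> TFTargetMap:
    """Read a two-column TF -> target table (no header)."""
    targets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(parts)}"
                )
            tf, tgt = parts[0].strip(), parts[1].strip()
            if not tf or not tgt:
                raise FormatError(f"{path}: line {lineno}: empty symbol")
            targets.setdefault(tf, set()).add(tgt)
    return TFTargetMap(targets={tf: frozenset(t) for tf, t in targets.items()})


def read_drug_catalog(path: str | Path) -> DrugCatalog:
    """Read a drug catalog TSV (``drug_id  drug_name  target``, one target
    per row, header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug_id", "drug_name", "target"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: drug catalog needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    entries: dict[str, DrugRecord] = {}
    names: dict[str, str] = {}
    targets: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        did = str(row["drug_id"]).strip()
        name = str(row["drug_name"]).strip()
        tgt = str(row["target"]).strip()
        if not did or not name or not tgt:
            raise FormatError(f"{path}: empty field in drug catalog row {row.to_dict()}")
        if did in names and names[did] != name:
            raise FormatError(
                f"{path}: drug id {did!r} has conflicting names "
                f"{names[did]!r} and {name!r}"
            )
        names[did] = name
        targets.setdefault(did, set()).add(tgt)
    for did, name in names.items():
        entries[did] = DrugRecord(drug_id=did, name=name, targets=frozenset(targets[did]))
    return DrugCatalog(entries=entries)


def read_instance_profiles(
    matrix_path: str | Path, metadata_path: str | Path
) -> InstanceProfileSet:
    """Read a gene x instance z-score matrix and its metadata sidecar."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"instance_id", "drug_id", "cell_line", "time_h", "dose"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"{metadata_path}: instance metadata needs columns {sorted(required)}, "
            f"got {list(meta.columns)}"
        )
    meta["instance_id"] = meta["instance_id"].str.strip()
    dup = meta["instance_id"][meta["instance_id"].duplicated()].tolist()
    if dup:
        raise FormatError(f"{metadata_path}: duplicate instance ids: {sorted(set(dup))}")
    meta = meta.set_index("instance_id")
    meta["time_h"] = pd.to_numeric(meta["time_h"], errors="raise")

    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str).str.strip()
    mat.columns = [str(c).strip() for c in mat.columns]
    missing = [i for i in meta.index if i not in mat.columns]
    if missing:
        raise FormatError(
            f"instance id(s) in {metadata_path} absent from matrix columns: {missing}"
        )
    if not np.isfinite(mat.to_numpy(dtype=float)).all():
        raise FormatError(f"{matrix_path}: z-scores must be finite")
    return InstanceProfileSet(metadata=meta, profiles=mat[list(meta.index)].astype(float))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list, de-duplicated, order preserved."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            if sym not in seen:
                seen.add(sym)
                out.append(sym)
    return out


def read_screening_table(path: str | Path) -> ScreeningTable:
    """Read a drug screening TSV (``drug_name  growth_rate``, header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug_name", "growth_rate"}.issubset(df.columns):
        raise FormatError(
            f"{path}: screening table needs columns ['drug_name', 'growth_rate'], "
            f"got {list(df.columns)}"
        )
    names = df["drug_name"].str.strip()
    dup = names[names.duplicated()].tolist()
    if dup:
        raise FormatError(f"{path}: duplicate drug names: {sorted(set(dup))}")
    rates = pd.to_numeric(df["growth_rate"], errors="raise").astype(float)
    if not np.isfinite(rates.to_numpy()).all():
        raise FormatError(f"{path}: growth rates must be finite")
    return ScreeningTable(rates=dict(zip(names, rates)))


# ---------------------------------------------------------------------------
# network output
# ---------------------------------------------------------------------------

# imported lazily to avoid a cycle: netbuild defines SignalingNetwork and uses
# this module's Interactome


def _nodes_companion(path: Path) -> Path:
    return path.with_name(path.stem + ".nodes.tsv")


def write_network(net, path: str | Path, format: str = "edge_tsv") -> None:
    """Write a signaling network as SIF, GraphML or edge TSV.

    ``edge_tsv`` writes the edge list plus a companion ``<stem>.nodes.tsv``
    carrying per-node roles, so the round trip through :func:`read_network`
    preserves nodes, edges and roles. GraphML carries roles as a node
    attribute ``role`` (comma-joined, sorted). SIF does not carry roles.
    """
    path = Path(path)
    g = net.graph
    if g.number_of_nodes() == 0:
        raise FormatError("refusing to write an empty network")
    edges = sorted((min(a, b), max(a, b), d.get("kind", "ppi")) for a, b, d in g.edges(data=True))

    if format == "sif":
        with open(path, "w") as fh:
            for a, b, kind in edges:
                fh.write(f"{a}\t{kind}\t{b}\n")
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tkind\n")
            for a, b, kind in edges:
                fh.write(f"{a}\t{b}\t{kind}\n")
        with open(_nodes_companion(path), "w") as fh:
            fh.write("gene\troles\n")
            for n in sorted(g.nodes):
                roles = ",".join(sorted(g.nodes[n].get("roles", set())))
                fh.write(f"{n}\t{roles}\n")
    elif format == "graphml":
        h = nx.Graph()
        for n, d in g.nodes(data=True):
            h.add_node(n, role=",".join(sorted(d.get("roles", set()))))
        for a, b, kind in edges:
            h.add_edge(a, b, kind=kind)
        for k, v in net.provenance.items():
            if v is not None:
                h.graph[k] = str(v)
        nx.write_graphml(h, path)
    else:
        raise FormatError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "edge_tsv"):
    """Read a network written by :func:`write_network` (edge_tsv or graphml)."""
    from .netbuild import SignalingNetwork  # local import, avoids cycle

    path = Path(path)
    g = nx.Graph()
    provenance: dict[str, str] = {}
    if format == "edge_tsv":
        edges = pd.read_csv(path, sep="\t", dtype=str)
        if not {"source", "target", "kind"}.issubset(edges.columns):
            raise FormatError(f"{path}: not an edge TSV written by write_network")
        for _, row in edges.iterrows():
            g.add_edge(row["source"], row["target"], kind=row["kind"])
        nodes = pd.read_csv(_nodes_companion(path), sep="\t", dtype=str)
        for _, row in nodes.iterrows():
            roles = set(str(row["roles"]).split(",")) if pd.notna(row["roles"]) and row["roles"] else set()
            g.add_node(row["gene"], roles=roles)
    elif format == "graphml":
        h = nx.read_graphml(path)
        for n, d in h.nodes(data=True):
            role = d.get("role", "")
            g.add_node(n, roles=set(role.split(",")) if role else set())
        for a, b, d in h.edges(data=True):
            g.add_edge(a, b, kind=d.get("kind", "ppi"))
        provenance = {k: v for k, v in h.graph.items()}
    else:
        raise FormatError(f"cannot read network format {format!r}")
    return SignalingNetwork(graph=g, provenance=provenance)
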