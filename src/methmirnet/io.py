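"""Readers and writers for every external artifact the pipeline touches.

Canonical dialect: TSV, UTF-8, Unix newlines, missing values encoded as
``NA``. Matrices are features x samples with the feature id in the first
column and sample ids in the header; each matrix has a companion
sample-annotation TSV (sample_id, condition, dataset_id, patient_id).
Gene sets use GMT (name TAB description TAB members...). Networks are
exported as GraphML (full attributes), SIF (``mirna targets gene``) and
Cytoscape-importable node/edge TSV tables.

Every reader validates its invariants strictly: a malformed file raises
:class:`~methmirnet.errors.FormatError` naming the offending element; it is
never silently repaired.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import ClinicalTable, GeneSetCollection, InteractionTable, OmicsMatrix
from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

NA = "NA"
NETWORK_FORMATS = ("graphml", "sif", "tsv")


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False, **kw)
    except FormatError:
        raise
    except Exception as exc:  # malformed text → format error, not pandas internals
        raise FormatError(f"cannot parse {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Omics matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path, annotation_path, layer: str = "mRNA") -> OmicsMatrix:
    """Read a features x samples TSV plus its sample-annotation TSV.

    Raises :class:`FormatError` for duplicate feature rows, samples missing
    from the annotation, or non-numeric cells.
    """
    raw = _read_tsv(path, dtype={0: str})
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: matrix needs a feature column and >=1 sample column")
    feat_col = raw.columns[0]
    features = raw[feat_col].astype(str).str.strip()
    if features.duplicated().any():
        dup = features[features.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate feature {dup!r}")
    try:
        values = raw.drop(columns=[feat_col]).astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric matrix cell ({exc})") from exc
    values.index = pd.Index(features, name="feature_id")

    ann = _read_tsv(annotation_path, dtype=str)
    for col in ("sample_id", "condition", "dataset_id"):
        if col not in ann.columns:
            raise FormatError(f"{annotation_path}: missing column {col!r}")
    if "patient_id" not in ann.columns:
        ann["patient_id"] = pd.NA
    ann = ann.set_index("sample_id")
    missing = values.columns.difference(ann.index)
    if len(missing):
        raise FormatError(
            f"{path}: sample {missing[0]!r} absent from annotation {annotation_path}"
        )
    return OmicsMatrix(
        layer=layer,
        values=values,
        condition=ann["condition"],
        dataset_id=ann["dataset_id"],
        patient_id=ann["patient_id"],
    )


def write_expression_matrix(matrix: OmicsMatrix, path, annotation_path) -> None:
    out = matrix.values.copy()
    out.insert(0, "feature_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep=NA, lineterminator="\n")
    matrix.annotation_frame().to_csv(
        annotation_path, sep="\t", index=False, na_rep=NA, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB member...`` per line.

    Trailing empty member tokens are dropped; a line with fewer than three
    fields or a duplicated set name raises :class:`FormatError` with the
    line number.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            name = name.strip()
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Clinical and interaction tables
# ---------------------------------------------------------------------------

def read_clinical(path) -> ClinicalTable:
    df = _read_tsv(path, dtype=str)
    if "patient_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'patient_id'")
    df = df.set_index("patient_id")
    for col in ClinicalTable.COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    for col in ("os_time", "os_event", "rfs_time", "rfs_event"):
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric {col} ({exc})") from exc
    return ClinicalTable(data=df[list(ClinicalTable.COLUMNS)])


def write_clinical(table: ClinicalTable, path) -> None:
    out = table.data.copy()
    out.insert(0, "patient_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep=NA, lineterminator="\n")


def read_interactions(path) -> InteractionTable:
    df = _read_tsv(path)
    for col in ("mirna_id", "gene_id", "confidence"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    try:
        df["confidence"] = df["confidence"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric confidence ({exc})") from exc
    df["mirna_id"] = df["mirna_id"].astype(str).str.strip()
    df["gene_id"] = df["gene_id"].astype(str).str.strip()
    return InteractionTable(data=df[["mirna_id", "gene_id", "confidence"]])


def write_interactions(table: InteractionTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, na_rep=NA, lineterminator="\n")


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

def write_network(network, directory, formats=("graphml", "sif", "tsv")) -> dict:
    """Export a meth-miRNA-mRNA network for Cytoscape-compatible viewers.

    GraphML carries the full node attributes (node_type, direction,
    meth_flag) and the edge confidence; SIF uses the relation ``targets``;
    the TSV pair (nodes/edges) is importable via Cytoscape's table import.
    Returns a manifest mapping format -> written path(s).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    unknown = set(formats) - set(NETWORK_FORMATS)
    if unknown:
        raise ParameterError(
            f"unknown network format(s) {sorted(unknown)}; expected subset of {NETWORK_FORMATS}"
        )
    stem = f"{network.network_role}_network"
    manifest: dict[str, object] = {}
    if "graphml" in formats:
        g = network.to_graph()
        p = directory / f"{stem}.graphml"
        nx.write_graphml(g, p, named_key_ids=True)
        manifest["graphml"] = str(p)
    if "sif" in formats:
        p = directory / f"{stem}.sif"
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            for mirna, gene, _conf in network.edges:
                fh.write(f"{mirna}\ttargets\t{gene}\n")
        manifest["sif"] = str(p)
    if "tsv" in formats:
        nodes_p = directory / f"{stem}_nodes.tsv"
        edges_p = directory / f"{stem}_edges.tsv"
        network.node_table().to_csv(nodes_p, sep="\t", index=False, lineterminator="\n")
        network.edge_table().to_csv(edges_p, sep="\t", index=False, lineterminator="\n")
        manifest["tsv"] = [str(nodes_p), str(edges_p)]
    return manifest


def read_network_graphml(path):
    """Re-load a GraphML export as a :class:`MethMirnaMrnaNetwork`."""
    from .network import MethMirnaMrnaNetwork  # local import avoids a cycle

    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    g = nx.read_graphml(path)
    nodes = [
        (str(n), d["node_type"], d["direction"], d.get("meth_flag", "none"))
        for n, d in g.nodes(data=True)
    ]
    edges = [(str(u), str(v), float(d["confidence"])) for u, v, d in g.edges(data=True)]
    role = g.graph.get("network_role", "tumor_suppressor")
    return MethMirnaMrnaNetwork.from_parts(nodes=nodes, edges=edges, network_role=role)


def read_sif(path) -> list[tuple[str, str, str]]:
    """Parse a SIF file into (source, relation, target) triples."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    triples = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: SIF line must have 3 fields")
            triples.append(tuple(fields))
    return triples
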