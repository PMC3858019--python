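"""Readers and writers for the package's plain-text interchange formats.

Dialects:

* formulas — TSV ``formula_id<TAB>herb1,herb2,...`` or JSON
  ``[{"id": ..., "herbs": [...]}, ...]`` (chosen by extension);
* descriptor tables — CSV with header ``compound_id,herb_id[,mass],d1..dp``;
* pair sets — TSV ``herb_a<TAB>herb_b[<TAB>label]``;
* networks — a pinned Pajek ``.net`` dialect: ``*Vertices N`` with 1-based
  indices and quoted labels, then ``*Edges`` lines ``i j w`` with integer
  co-occurrence weights (Pajek variants differ; this one round-trips).

Lines starting with ``#`` are comments everywhere (writers use them for
provenance: tool version and seed); every writer/reader pair is a lossless
round trip on valid objects.
"""

from __future__ import annotations

import json
import os
import shlex
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .errors import ParseError
from .feature_space import CompoundDescriptorTable, SpaceEmbedding
from .formula_network import FormulaCollection
from .pairs import PairSet
from .report import PairDistanceReport

__all__ = [
    "read_formulas",
    "write_formulas",
    "read_descriptors",
    "write_descriptors",
    "read_pairset",
    "write_pairset",
    "read_pajek",
    "write_pajek",
    "read_report",
    "write_report",
    "write_embedding",
    "write_study",
]


def _provenance(seed=None) -> list[str]:
    lines = [f"# tcmspace {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def _check_overwrite(path, force: bool):
    if not force and os.path.exists(path):
        raise FileExistsError(f"refusing to overwrite {path} (use force/--force)")


def _data_lines(path):
    """Yield (1-based line number, stripped content) skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for n, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield n, line


def read_formulas(path) -> FormulaCollection:
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as e:
            raise ParseError(f"invalid JSON: {e.msg}", path=path, line=e.lineno) from None
        if not isinstance(payload, list):
            raise ParseError("expected a JSON array of {id, herbs} objects", path=path)
        records = []
        for i, rec in enumerate(payload):
            if not isinstance(rec, dict) or "id" not in rec or "herbs" not in rec:
                raise ParseError(f"record {i} lacks 'id'/'herbs'", path=path)
            records.append((rec["id"], list(rec["herbs"])))
        return FormulaCollection.from_records(records)
    records = []
    for n, line in _data_lines(path):
        if "\t" not in line:
            raise ParseError("expected 'formula_id<TAB>herb1,herb2,...'", path=path, line=n)
        fid, herbs = line.split("\t", 1)
        records.append((fid, [h for h in herbs.split(",") if h.strip()]))
    if not records:
        raise ParseError("no formula records found", path=path)
    return FormulaCollection.from_records(records)


def write_formulas(collection: FormulaCollection, path, seed=None, force: bool = True):
    path = Path(path)
    _check_overwrite(path, force)
    if path.suffix.lower() == ".json":
        payload = [{"id": fid, "herbs": list(hs)} for fid, hs in collection]
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
        return
    lines = _provenance(seed)
    for fid, herbs in collection:
        lines.append(f"{fid}\t{','.join(herbs)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_descriptors(path) -> CompoundDescriptorTable:
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            comment="#",
            dtype={"compound_id": str, "herb_id": str},
            float_precision="round_trip",
        )
    except Exception as e:  # malformed CSV structure
        raise ParseError(f"could not parse CSV: {e}", path=path) from None
    from .errors import ValidationError

    try:
        return CompoundDescriptorTable.from_dataframe(df)
    except ValidationError as e:
        raise ParseError(str(e), path=path) from None


def write_descriptors(table: CompoundDescriptorTable, path, seed=None, force: bool = True):
    path = Path(path)
    _check_overwrite(path, force)
    with open(path, "w", encoding="utf-8") as fh:
        for line in _provenance(seed):
            fh.write(line + "\n")
        cols = ["compound_id", "herb_id", "mass", *table.descriptor_columns]
        # repr is the shortest exact round-trip representation of a float
        table.data[cols].to_csv(
            fh, index=False, lineterminator="\n", float_format=lambda v: repr(float(v))
        )


def read_pairset(path, label: str = "incompatible") -> PairSet:
    pairs = []
    labels = set()
    for n, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError("expected 'herb_a<TAB>herb_b[<TAB>label]'", path=path, line=n)
        pairs.append((fields[0], fields[1]))
        if len(fields) > 2 and fields[2].strip():
            labels.add(fields[2].strip())
    if not pairs:
        raise ParseError("no pairs found", path=path)
    if len(labels) == 1:
        label = labels.pop()
    return PairSet.from_pairs(pairs, label=label)


def write_pairset(pairs: PairSet, path, seed=None, force: bool = True):
    path = Path(path)
    _check_overwrite(path, force)
    lines = _provenance(seed)
    for a, b in pairs:
        lines.append(f"{a}\t{b}\t{pairs.label}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_pajek(net: nx.Graph, path, force: bool = True):
    """Write the pinned Pajek dialect; nodes in sorted label order."""
    path = Path(path)
    _check_overwrite(path, force)
    nodes = sorted(net.nodes)
    index = {h: i + 1 for i, h in enumerate(nodes)}
    lines = [f"*Vertices {len(nodes)}"]
    for h in nodes:
        lines.append(f'{index[h]} "{h}"')
    if net.number_of_edges():
        lines.append("*Edges")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            w = int(net.edges[a, b].get("count", 1))
            lines.append(f"{index[a]} {index[b]} {w}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pajek(path) -> nx.Graph:
    path = Path(path)
    net = nx.Graph()
    labels: dict[int, str] = {}
    section = None
    n_vertices = None
    for n, line in _data_lines(path):
        token = line.strip()
        if token.lower().startswith("*vertices"):
            parts = token.split()
            if len(parts) != 2 or not parts[1].isdigit():
                raise ParseError("malformed *Vertices header", path=path, line=n)
            n_vertices = int(parts[1])
            section = "vertices"
            continue
        if token.lower().startswith("*edges"):
            if section is None:
                raise ParseError("*Edges before *Vertices", path=path, line=n)
            section = "edges"
            continue
        if token.startswith("*"):
            raise ParseError(f"unsupported section {token.split()[0]!r}", path=path, line=n)
        if section == "vertices":
            try:
                parts = shlex.split(token)
                idx = int(parts[0])
                label = parts[1]
            except (ValueError, IndexError):
                raise ParseError("malformed vertex line", path=path, line=n) from None
            labels[idx] = label
            net.add_node(label)
        elif section == "edges":
            parts = token.split()
            try:
                i, j = int(parts[0]), int(parts[1])
                w = int(parts[2]) if len(parts) > 2 else 1
            except (ValueError, IndexError):
                raise ParseError("malformed edge line", path=path, line=n) from None
            if i not in labels or j not in labels:
                raise ParseError(f"edge references unknown vertex {i} or {j}", path=path, line=n)
            net.add_edge(labels[i], labels[j], count=w)
        else:
            raise ParseError("data before *Vertices header", path=path, line=n)
    if n_vertices is None:
        raise ParseError("missing *Vertices header", path=path)
    if len(labels) != n_vertices:
        raise ParseError(
            f"*Vertices declares {n_vertices} but {len(labels)} vertex lines found", path=path
        )
    return net


def write_report(report: PairDistanceReport, path, force: bool = True):
    path = Path(path)
    _check_overwrite(path, force)
    path.write_text(report.to_json(indent=2) + "\n", encoding="utf-8")


def read_report(path) -> PairDistanceReport:
    path = Path(path)
    try:
        return PairDistanceReport.from_dict(json.loads(path.read_text(encoding="utf-8")))
    except (json.JSONDecodeError, KeyError) as e:
        raise ParseError(f"invalid report JSON: {e}", path=path) from None


def write_embedding(emb: SpaceEmbedding, prefix, seed=None, force: bool = True):
    """Write ``<prefix>_coordinates.csv`` and ``<prefix>_meta.json``."""
    prefix = Path(prefix)
    coords_path = prefix.parent / (prefix.name + "_coordinates.csv")
    meta_path = prefix.parent / (prefix.name + "_meta.json")
    _check_overwrite(coords_path, force)
    _check_overwrite(meta_path, force)
    with open(coords_path, "w", encoding="utf-8") as fh:
        for line in _provenance(seed):
            fh.write(line + "\n")
        emb.coordinates.to_csv(fh, lineterminator="\n", float_format=lambda v: repr(float(v)))
    meta = {
        "explained_variance_ratios": list(emb.explained_variance_ratios),
        "cumulative_ratio": emb.cumulative_ratio,
        "scaled": emb.scaled,
        "dropped_descriptors": list(emb.dropped_descriptors),
        "loadings": {c: emb.loadings[c].round(12).to_dict() for c in emb.loadings.columns},
        "space_id": emb.space_id,
    }
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n", encoding="utf-8")


def write_study(study, outdir, force: bool = False) -> dict:
    """Write a synthetic study's standard input files into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = study.config.seed
    paths = {
        "formulas": outdir / "formulas.tsv",
        "chemical": outdir / "chemical_descriptors.csv",
        "metabolism": outdir / "metabolism_descriptors.csv",
        "truth": outdir / "truth.json",
    }
    write_formulas(study.formulas, paths["formulas"], seed=seed, force=force)
    write_descriptors(study.chemical, paths["chemical"], seed=seed, force=force)
    write_descriptors(study.metabolism, paths["metabolism"], seed=seed, force=force)
    if study.pairs is not None:
        paths["pairs"] = outdir / "pairs.tsv"
        write_pairset(study.pairs, paths["pairs"], seed=seed, force=force)
    truth = {
        "config": study.config.to_dict(),
        "cluster_labels": {
            c: study.cluster_labels[c].to_dict() for c in study.cluster_labels.columns
        },
        "true_chemical_centroids": study.true_chemical_centroids.round(12).to_dict("index"),
        "true_metabolism_centroids": study.true_metabolism_centroids.round(12).to_dict("index"),
    }
    _check_overwrite(paths["truth"], force)
    paths["truth"].write_text(json.dumps(truth, sort_keys=True) + "\n", encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
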