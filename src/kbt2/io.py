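"""Readers and writers for the external formats the pipeline consumes.

Expression tables are tab-separated ``identifier(s)<TAB>ratio`` files with
semicolon-delimited multi-identifier fields.  Gene sets come in three
dialects: GMT lines, KEGG KGML pathway XML, or a Reactome-style two-column
pathway→protein mapping.  Protein–protein interaction (PPI) confidence
scores are three-column ``a<TAB>b<TAB>score`` tables, on either a 0–1
probability scale or the 0–1000 integer scale used by STRING exports.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from lxml import etree

log = logging.getLogger(__name__)

__all__ = [
    "RawRatioRecord",
    "PathwayDefinition",
    "PathwayCollection",
    "InteractionScores",
    "read_expression_table",
    "read_gene_sets",
    "read_interaction_scores",
    "read_id_mapping",
    "write_gene_sets_gmt",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class RawRatioRecord:
    """One row of an expression table: identifier(s) plus one ratio.

    The ratio is an experiment/control fold change, or a signed log2 value
    when the table was declared pre-logged.  Scale is tracked by the caller,
    not the record.
    """

    identifiers: tuple[str, ...]
    ratio: float

    def __post_init__(self) -> None:
        if not self.identifiers:
            raise ValueError("record needs at least one identifier")
        for ident in self.identifiers:
            if not ident or any(ch.isspace() for ch in ident):
                raise ValueError(f"bad identifier token: {ident!r}")
        if not math.isfinite(self.ratio):
            raise ValueError("ratio must be finite")


@dataclass(frozen=True)
class PathwayDefinition:
    """A named gene set: pathway id, human-readable title, member accessions."""

    pathway_id: str
    title: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id} has no members")


class PathwayCollection:
    """An ordered set of pathways with unique ids."""

    def __init__(self, pathways: Iterable[PathwayDefinition] = ()) -> None:
        self._pathways: dict[str, PathwayDefinition] = {}
        for p in pathways:
            self.add(p)

    def add(self, pathway: PathwayDefinition) -> None:
        if pathway.pathway_id in self._pathways:
            raise ValueError(f"duplicate pathway id: {pathway.pathway_id}")
        self._pathways[pathway.pathway_id] = pathway

    def __iter__(self) -> Iterator[PathwayDefinition]:
        # deterministic: lexicographic by pathway id
        for pid in sorted(self._pathways):
            yield self._pathways[pid]

    def __len__(self) -> int:
        return len(self._pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def __getitem__(self, pathway_id: str) -> PathwayDefinition:
        return self._pathways[pathway_id]


class InteractionScores:
    """Symmetric map from unordered protein pairs to confidence scores in (0,1].

    Lookup is symmetric by construction: ``get(a, b) == get(b, a)``.
    Self-pairs are rejected.
    """

    def __init__(self, scores: Mapping[frozenset[str], float] | None = None) -> None:
        self._scores: dict[frozenset[str], float] = {}
        if scores:
            for pair, c in scores.items():
                key = frozenset(pair)
                if len(key) != 2:
                    raise ValueError(f"not an unordered pair of two proteins: {set(pair)}")
                if not (0.0 < c <= 1.0):
                    raise ValueError(f"score {c} outside (0, 1] for pair {set(pair)}")
                self._scores[key] = float(c)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "InteractionScores":
        """Build from (a, b, score) triples; duplicates keep the maximum score."""
        acc: dict[frozenset[str], float] = {}
        for a, b, c in edges:
            if a == b:
                continue
            key = frozenset((a, b))
            if key not in acc or c > acc[key]:
                acc[key] = float(c)
        return cls(acc)

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        return self._scores.get(frozenset((a, b)), default)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._scores

    def __len__(self) -> int:
        return len(self._scores)

    def pairs(self) -> list[tuple[str, str, float]]:
        """All scored pairs as (a, b, score), lexicographically sorted."""
        out = []
        for key, c in self._scores.items():
            a, b = sorted(key)
            out.append((a, b, c))
        out.sort()
        return out

    def values(self) -> list[float]:
        return [c for _, _, c in self.pairs()]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionScores):
            return NotImplemented
        return self._scores == other._scores


def read_expression_table(
    path: str | os.PathLike, already_logged: bool = False
) -> tuple[list[RawRatioRecord], int]:
    """Read a tab-separated expression table.

    Each row holds one or more semicolon-delimited protein identifiers and
    one ratio.  Rows whose ratio cannot be parsed as a finite number are
    dropped; the drop count is returned alongside the records.

    Returns (records, n_dropped).  Raises if the file is missing or no row
    parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")
    records: list[RawRatioRecord] = []
    n_dropped = 0
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                n_dropped += 1
                continue
            idents = tuple(tok.strip() for tok in fields[0].split(";") if tok.strip())
            try:
                ratio = float(fields[1])
            except ValueError:
                n_dropped += 1
                continue
            if not idents or not math.isfinite(ratio):
                n_dropped += 1
                continue
            records.append(RawRatioRecord(idents, ratio))
    if n_dropped:
        log.warning("dropped %d unparsable row(s) from %s", n_dropped, path)
    if not records:
        raise ValueError(f"no parsable expression rows in {path}")
    return records, n_dropped


def _read_gmt(path: Path) -> PathwayCollection:
    collection = PathwayCollection()
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                log.warning("GMT line with no members skipped: %r", line[:60])
                continue
            pid, title = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                log.warning("pathway %s has no members; skipped", pid)
                continue
            collection.add(PathwayDefinition(pid, title, members))
    return collection


# KGML entry types whose identifiers map onto gene products
_KGML_KEEP = {"gene", "enzyme"}


def _read_kgml_file(path: Path) -> PathwayDefinition | None:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed KGML in {path.name}: {exc}") from exc
    root = tree.getroot()
    pid = root.get("name", path.stem)
    title = root.get("title", pid)
    entries_by_id: dict[str, etree._Element] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        if eid is not None:
            entries_by_id[eid] = entry
    members: set[str] = set()
    for entry in root.findall("entry"):
        etype = entry.get("type", "")
        if etype in _KGML_KEEP:
            members.update(entry.get("name", "").split())
        elif etype == "group":
            # groups are complexes of other entries; expand to the component
            # gene/enzyme entries' identifiers
            for comp in entry.findall("component"):
                ref = entries_by_id.get(comp.get("id", ""))
                if ref is not None and ref.get("type", "") in _KGML_KEEP:
                    members.update(ref.get("name", "").split())
    members.discard("undefined")
    if not members:
        log.warning("KGML pathway %s has no gene/enzyme/group members; skipped", pid)
        return None
    return PathwayDefinition(pid, title, frozenset(members))


def _read_kgml(path: Path) -> PathwayCollection:
    files = sorted(path.glob("*.xml")) if path.is_dir() else [path]
    collection = PathwayCollection()
    for f in files:
        p = _read_kgml_file(f)
        if p is not None:
            collection.add(p)
    return collection


def _read_reactome(path: Path) -> PathwayCollection:
    members: dict[str, set[str]] = {}
    titles: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            pid, protein = fields[0], fields[1]
            members.setdefault(pid, set()).add(protein)
            if len(fields) >= 3 and fields[2]:
                titles[pid] = fields[2]
    collection = PathwayCollection()
    for pid in sorted(members):
        if not members[pid]:
            continue
        collection.add(
            PathwayDefinition(pid, titles.get(pid, pid), frozenset(members[pid]))
        )
    return collection


def read_gene_sets(path: str | os.PathLike, dialect: str) -> PathwayCollection:
    """Read a pathway collection in one of three dialects.

    ``gmt``: one pathway per line (name, description, members...).
    ``kgml``: KEGG pathway XML; one file per pathway, or a directory of
    ``*.xml`` files; members are the union of identifiers from entries of
    type gene/enzyme, with group entries expanded to their components.
    ``reactome``: tab-delimited (pathway_id, protein[, title]) accumulation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene set file not found: {path}")
    if dialect == "gmt":
        return _read_gmt(path)
    if dialect == "kgml":
        return _read_kgml(path)
    if dialect == "reactome":
        return _read_reactome(path)
    raise ValueError(f"unknown gene-set dialect: {dialect!r}")


def write_gene_sets_gmt(collection: PathwayCollection, path: str | os.PathLike) -> None:
    """Write a collection in GMT (members lexicographically sorted)."""
    with Path(path).open("w") as fh:
        for p in collection:
            fh.write("\t".join([p.pathway_id, p.title, *sorted(p.members)]) + "\n")


def read_interaction_scores(
    path: str | os.PathLike, min_score: float = 0.4
) -> InteractionScores:
    """Read a three-column PPI confidence table.

    Self-pairs are dropped; duplicate pairs keep their maximum score.  When
    any score exceeds 1 the whole file is taken to be on the STRING 0–1000
    integer scale and divided by 1000.  Pairs below ``min_score`` (after
    normalization) are excluded — the default 0.4 is the STRING
    medium-confidence floor.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PPI score table not found: {path}")
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                continue
            a, b = fields[0], fields[1]
            try:
                c = float(fields[2])
            except ValueError:
                continue
            if not (0.0 <= c <= 1000.0):
                raise ValueError(f"score {c} outside [0, 1000] for pair ({a}, {b})")
            edges.append((a, b, c))
    if edges and max(c for _, _, c in edges) > 1.0:
        edges = [(a, b, c / 1000.0) for a, b, c in edges]
    edges = [(a, b, c) for a, b, c in edges if c >= min_score and c > 0.0]
    if not edges:
        log.warning("no PPI pairs retained from %s at min_score=%.3f", path, min_score)
        return InteractionScores()
    return InteractionScores.from_edges(edges)


def read_id_mapping(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Read a two-column source→target identifier map (multimap both ways)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"identifier map not found: {path}")
    mapping: dict[str, set[str]] = {}
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"identifier map row needs two columns: {line!r}")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return {k: frozenset(v) for k, v in mapping.items()}


_RESULT_COLUMNS = [
    "pathway_id",
    "title",
    "n_mapped",
    "rank_q",
    "T2",
    "p_value",
    "delegate_id",
    "group_members",
    "p_bh",
]


def write_results(results, groups, path: str | os.PathLike) -> None:
    """Write per-pathway test results joined with their pathway groups.

    One row per result; rows ordered by the size of the containing group
    (descending) and then pathway id, so reruns produce byte-identical
    files.  Floats are rendered with 6 significant digits.
    """
    if not results:
        raise ValueError("no results to write")
    group_of: dict[str, object] = {}
    for g in groups:
        for pid in g.member_ids:
            group_of[pid] = g

    def sort_key(r):
        g = group_of.get(r.pathway_id)
        size = len(g.member_ids) if g is not None else 1
        return (-size, r.pathway_id)

    rows = []
    for r in sorted(results, key=sort_key):
        g = group_of.get(r.pathway_id)
        rows.append(
            {
                "pathway_id": r.pathway_id,
                "title": r.title,
                "n_mapped": r.n_mapped,
                "rank_q": r.rank_q,
                "T2": f"{r.T2:.6g}",
                "p_value": f"{r.p_value:.6g}",
                "delegate_id": g.delegate_id if g is not None else "",
                "group_members": ",".join(g.member_ids) if g is not None else "",
                "p_bh": f"{r.p_bh:.6g}" if r.p_bh is not None else "",
            }
        )
    frame = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    """Re-read a results table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", dtype={"pathway_id": str, "delegate_id": str})
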