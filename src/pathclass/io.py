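"""Readers for pathway, sequence, annotation and label inputs.

Supported pathway formats:

* KGML (KEGG XML): gene-type ``entry`` elements become vertices, ``relation``
  elements become directed arcs.  Relation subtypes (activation, inhibition,
  ...) are ignored — the graph model uses unlabeled arcs.
* An edge-list TSV dialect with a header row and columns
  ``pathway_id    source    target``; a row with an empty ``target`` declares
  an isolated vertex.  One file may hold several pathways.

Sequences come from FASTA (Biopython); annotations from a two-column TSV
``protein_id    GO_id`` (one pair per row, no header); labels from a
two-column TSV ``pathway_id    class``.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

from Bio import SeqIO
from lxml import etree

from .datamodel import AnnotationUniverse, Pathway, ProteinRecord

log = logging.getLogger(__name__)


class KGMLParseError(ValueError):
    pass


def parse_kgml(source) -> Pathway:
    """Parse one KGML document into a :class:`Pathway`.

    ``source`` may be a path, a file object or an XML string/bytes.  Only
    gene-type entries become vertices; relations referencing dropped or
    unknown entries are skipped with a warning.  Group entries are dropped
    and counted.
    """
    try:
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            tree = etree.parse(str(source))
            root = tree.getroot()
        elif isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str):
            root = etree.fromstring(source.encode("utf-8"))
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(
            f"malformed KGML at line {exc.lineno}, column {exc.offset}: {exc.msg}"
        ) from exc

    pathway_id = root.get("name") or root.get("title") or "pathway"
    entry_to_protein: dict[str, str] = {}
    vertices: list[str] = []
    seen: set[str] = set()
    n_groups = 0
    for entry in root.findall("entry"):
        etype = entry.get("type")
        eid = entry.get("id")
        if etype == "group":
            n_groups += 1
            continue
        if etype != "gene":
            continue
        name = (entry.get("name") or "").split()
        protein = name[0] if name else f"entry{eid}"
        entry_to_protein[eid] = protein
        if protein not in seen:
            seen.add(protein)
            vertices.append(protein)
    if n_groups:
        log.info("%s: dropped %d group entries", pathway_id, n_groups)

    arcs: set[tuple[str, str]] = set()
    n_skipped = 0
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 in entry_to_protein and e2 in entry_to_protein:
            arcs.add((entry_to_protein[e1], entry_to_protein[e2]))
        else:
            n_skipped += 1
    if n_skipped:
        warnings.warn(
            f"{pathway_id}: skipped {n_skipped} relation(s) referencing "
            "non-gene or unknown entries",
            stacklevel=2,
        )
    return Pathway(id=pathway_id, vertices=vertices, arcs=arcs)


def read_edge_list(path) -> list[Pathway]:
    """Read the internal edge-list TSV dialect (possibly multiple pathways)."""
    order: list[str] = []
    verts: dict[str, list[str]] = {}
    arcs: dict[str, set[tuple[str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["pathway_id", "source", "target"]:
            raise ValueError(
                f"{path}: expected header 'pathway_id\\tsource\\ttarget', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                fields.append("")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            pid, src, tgt = fields
            if pid not in verts:
                order.append(pid)
                verts[pid] = []
                arcs[pid] = set()
            for v in (src, tgt):
                if v and v not in verts[pid]:
                    verts[pid].append(v)
            if src and tgt:
                arcs[pid].add((src, tgt))
    return [Pathway(id=p, vertices=verts[p], arcs=arcs[p]) for p in order]


def write_edge_list(pathways: list[Pathway], path) -> None:
    """Serialize pathways to the edge-list TSV dialect (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tsource\ttarget\n")
        for pw in pathways:
            with_arcs = {v for a in pw.arcs for v in a}
            for src, tgt in sorted(pw.arcs):
                fh.write(f"{pw.id}\t{src}\t{tgt}\n")
            for v in pw.vertices:
                if v not in with_arcs:
                    fh.write(f"{pw.id}\t{v}\t\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into id -> raw sequence (sanitized later by ProteinRecord)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_annotations(path) -> dict[str, set[str]]:
    """Read a two-column protein_id / GO_id TSV into protein -> term set."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def read_labels(path) -> dict[str, str]:
    """Read a two-column pathway_id / class TSV."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[fields[0]] = fields[1]
    return out


def load_dataset(
    pathway_files,
    fasta,
    annotations_tsv,
    labels_tsv=None,
    terms: list[str] | None = None,
    background_size: int | None = None,
):
    """Load a full dataset.

    Returns ``(pathways, proteins, universe)``.  KGML files are recognized by
    a ``.xml`` / ``.kgml`` suffix; anything else is read as edge-list TSV.
    The universe term list is the sorted union of annotated terms unless an
    explicit ``terms`` list is given; the background size defaults to the
    number of distinct annotated proteins.
    """
    pathways: list[Pathway] = []
    for f in pathway_files:
        if str(f).lower().endswith((".xml", ".kgml")):
            pathways.append(parse_kgml(f))
        else:
            pathways.extend(read_edge_list(f))

    sequences = read_fasta(fasta)
    annotations = read_annotations(annotations_tsv)
    proteins: dict[str, ProteinRecord] = {}
    for pid in set(sequences) | set(annotations):
        proteins[pid] = ProteinRecord(
            id=pid,
            sequence=sequences.get(pid, ""),
            go_terms=set(annotations.get(pid, set())),
        )
    # pathway vertices with neither sequence nor annotation still need records
    for pw in pathways:
        for v in pw.vertices:
            proteins.setdefault(v, ProteinRecord(id=v))

    universe = AnnotationUniverse.from_annotations(
        annotations, terms=terms, background_size=background_size
    )
    if labels_tsv is not None:
        labels = read_labels(labels_tsv)
        for pw in pathways:
            pw.label = labels.get(pw.id, pw.label)
    return pathways, proteins, universe


def filter_benchmark(
    pathways: list[Pathway],
    proteins: dict[str, ProteinRecord],
    min_proteins: int = 3,
) -> list[Pathway]:
    """Apply the benchmark filtering rules.

    Proteins without GO annotation or without a (non-empty, sanitized)
    sequence are removed from every pathway, with incident arcs; pathways
    left with fewer than ``min_proteins`` proteins are excluded.  Pathway
    order is preserved.
    """
    usable = {
        pid
        for pid, rec in proteins.items()
        if rec.go_terms and rec.sequence
    }
    kept: list[Pathway] = []
    for pw in pathways:
        sub = pw.subgraph(usable)
        if sub.n_vertices >= min_proteins:
            kept.append(sub)
        else:
            log.info(
                "pathway %s excluded: %d protein(s) survive filtering",
                pw.id,
                sub.n_vertices,
            )
    if not kept:
        warnings.warn("benchmark filtering left no pathways", stacklevel=2)
    return kept
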