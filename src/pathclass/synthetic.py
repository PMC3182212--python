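"""Synthetic labeled pathway datasets with controllable class signal.

The generator emulates the structure of a multi-class regulatory-pathway
benchmark: each functional class owns a disjoint set of signature GO terms;
proteins of a class-c pathway carry each signature term with probability
``p_sig`` and every background term with probability ``p_bg``, and their
sequences are drawn from a class-biased residue distribution.  Topology is
an Erdos–Renyi digraph over distinct ordered pairs at rate ``arc_density``.
All randomness flows from the single integer seed.

Defaults reflect the study conditions used throughout the test-bench: six
functional classes with twenty pathways each, a 200-term universe with five
signature terms per class at p_sig = 0.9 vs p_bg = 0.05.

Datasets can be written in exactly the external formats the loaders read
(edge-list TSV, FASTA, annotation TSV, labels TSV) so fixtures exercise the
real parsers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    STANDARD_RESIDUES,
    AnnotationUniverse,
    Pathway,
    ProteinRecord,
)
from .io import write_edge_list

CLASS_NAMES = (
    "Metabolism",
    "Genetic Information Processing",
    "Environmental Information Processing",
    "Cellular Processes",
    "Organismal Systems",
    "Human Diseases",
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic benchmark generator."""

    n_classes: int = 6
    pathways_per_class: int = 20
    proteins_per_pathway: tuple[int, int] = (3, 25)
    universe_size: int = 200
    signature_terms_per_class: int = 5
    p_sig: float = 0.9
    p_bg: float = 0.05
    residue_bias: float = 0.05
    arc_density: float = 0.15
    sequence_length: tuple[int, int] = (50, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bg <= self.p_sig <= 1.0:
            raise ValueError("need 0 <= p_bg <= p_sig <= 1")
        if self.universe_size < self.n_classes * self.signature_terms_per_class:
            raise ValueError("universe too small for the class signatures")
        if self.proteins_per_pathway[0] < 1:
            raise ValueError("pathways need at least one protein")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    pathways: list[Pathway]
    proteins: dict[str, ProteinRecord]
    universe: AnnotationUniverse
    labels: dict[str, str] = field(default_factory=dict)

    def write(self, outdir) -> dict[str, Path]:
        """Write edge-list / FASTA / annotation / label files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "edges": outdir / "pathways.tsv",
            "fasta": outdir / "proteins.fasta",
            "annotations": outdir / "annotations.tsv",
            "labels": outdir / "labels.tsv",
        }
        write_edge_list(self.pathways, paths["edges"])
        with open(paths["fasta"], "w", encoding="utf-8") as fh:
            for pid in sorted(self.proteins):
                rec = self.proteins[pid]
                fh.write(f">{pid}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")
        with open(paths["annotations"], "w", encoding="utf-8") as fh:
            for pid in sorted(self.proteins):
                for t in sorted(self.proteins[pid].go_terms):
                    fh.write(f"{pid}\t{t}\n")
        with open(paths["labels"], "w", encoding="utf-8") as fh:
            for pw in self.pathways:
                fh.write(f"{pw.id}\t{pw.label}\n")
        return paths


def _class_names(n: int) -> list[str]:
    if n <= len(CLASS_NAMES):
        return list(CLASS_NAMES[:n])
    return list(CLASS_NAMES) + [f"class_{i}" for i in range(len(CLASS_NAMES), n)]


def _residue_distribution(cls_idx: int, bias: float) -> np.ndarray:
    """Uniform residue frequencies tilted toward 4 class-specific residues."""
    base = np.full(20, 1.0 / 20)
    profile = np.zeros(20)
    offset = (4 * cls_idx) % 20
    profile[[(offset + i) % 20 for i in range(4)]] = 1.0 / 4
    return (1.0 - bias) * base + bias * profile


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a dataset; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.universe_size))
    terms = [f"GO:{i + 1:0{max(7, width)}d}" for i in range(spec.universe_size)]
    names = _class_names(spec.n_classes)
    term_arr = np.array(terms)
    sig_slices = {
        names[c]: slice(
            c * spec.signature_terms_per_class,
            (c + 1) * spec.signature_terms_per_class,
        )
        for c in range(spec.n_classes)
    }
    residues = np.array(list(STANDARD_RESIDUES))

    pathways: list[Pathway] = []
    proteins: dict[str, ProteinRecord] = {}
    labels: dict[str, str] = {}
    annotations: dict[str, set[str]] = {}
    lo, hi = spec.proteins_per_pathway
    for c, cname in enumerate(names):
        freq = _residue_distribution(c, spec.residue_bias)
        # every term is carried at the background rate except the class's
        # own signature terms, which are carried at p_sig
        p_vec = np.full(spec.universe_size, spec.p_bg)
        p_vec[sig_slices[cname]] = spec.p_sig
        for k in range(spec.pathways_per_class):
            pid = f"path_c{c}_{k}"
            n_prot = int(rng.integers(lo, hi + 1))
            vertex_ids = [f"{pid}_p{j}" for j in range(n_prot)]
            for v in vertex_ids:
                hits = rng.random(spec.universe_size) < p_vec
                go: set[str] = set(term_arr[hits])
                length = int(rng.integers(*spec.sequence_length))
                seq = "".join(rng.choice(residues, size=length, p=freq))
                proteins[v] = ProteinRecord(id=v, sequence=seq, go_terms=go)
                annotations[v] = go
            arcs: set[tuple[str, str]] = set()
            for a in vertex_ids:
                for b in vertex_ids:
                    if a != b and rng.random() < spec.arc_density:
                        arcs.add((a, b))
            pathways.append(
                Pathway(id=pid, vertices=vertex_ids, arcs=arcs, label=cname)
            )
            labels[pid] = cname

    universe = AnnotationUniverse.from_annotations(annotations, terms=terms)
    return SyntheticDataset(
        spec=spec,
        pathways=pathways,
        proteins=proteins,
        universe=universe,
        labels=labels,
    )
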