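"""Assembly of the full pathway x feature table.

Column layout is fixed: the 88 graph features, then the 264 physicochemical
features, then one enrichment score per universe term — 88 + 264 + |universe|
columns (5570 for the original 5218-term universe).  The table is written as
TSV with a two-row header (block tag, feature name) plus pathway id and
label columns, so it diffs cleanly and round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AnnotationUniverse, Pathway, ProteinRecord
from .enrichment import SCORE_CAP, enrichment_block
from .graph_features import N_GRAPH_FEATURES, graph_feature_block
from .ontology import weight_graph
from .physchem import (
    N_PHYSCHEM_FEATURES,
    CorpusStandardizer,
    descriptor_matrix,
    physchem_block,
)

BLOCKS = ("graph", "physchem", "functional")


@dataclass
class FeatureTable:
    """Pathways x named features, with per-column block provenance."""

    pathway_ids: list[str]
    feature_names: list[str]
    blocks: list[str]
    matrix: np.ndarray
    labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.pathway_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match ids/names")
        if len(self.blocks) != len(self.feature_names):
            raise ValueError("one block tag per feature required")
        if not self.labels:
            self.labels = [None] * len(self.pathway_ids)
        bad = ~np.isfinite(self.matrix)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value for pathway {self.pathway_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def block_slice(self, block: str) -> np.ndarray:
        cols = [i for i, b in enumerate(self.blocks) if b == block]
        return self.matrix[:, cols]

    def block_size(self, block: str) -> int:
        return sum(1 for b in self.blocks if b == block)

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_arrays(
            [self.blocks, self.feature_names], names=["block", "feature"]
        )
        df = pd.DataFrame(self.matrix, index=self.pathway_ids, columns=cols)
        df.index.name = "pathway_id"
        return df


def build_table(
    pathways: list[Pathway],
    proteins: dict[str, ProteinRecord],
    universe: AnnotationUniverse,
    standardizer: CorpusStandardizer | None = None,
    ss_codes: dict[str, str] | None = None,
    acc_codes: dict[str, str] | None = None,
    cap: float = SCORE_CAP,
    neighbor_degree: str = "total",
    t4_denominator: str = "out",
) -> FeatureTable:
    """Compute the full feature vector for every pathway.

    Standardization statistics for the physicochemical descriptors are
    fitted on the whole protein corpus unless a frozen
    :class:`CorpusStandardizer` is supplied.
    """
    desc = descriptor_matrix(proteins, ss_codes=ss_codes, acc_codes=acc_codes)
    if standardizer is None:
        standardizer = CorpusStandardizer.fit(desc)
    standardized = standardizer.transform(desc)

    names: list[str] | None = None
    blocks: list[str] = []
    rows = []
    for pw in pathways:
        wg = weight_graph(pw, proteins, universe)
        gblock = graph_feature_block(
            wg,
            proteins,
            universe,
            neighbor_degree=neighbor_degree,
            t4_denominator=t4_denominator,
        )
        pblock = physchem_block(pw, standardized)
        fblock = enrichment_block(pw, proteins, universe, cap=cap)
        if names is None:
            names = list(gblock) + list(pblock) + list(fblock)
            blocks = (
                ["graph"] * len(gblock)
                + ["physchem"] * len(pblock)
                + ["functional"] * len(fblock)
            )
        rows.append(
            [gblock[n] for n in names[: len(gblock)]]
            + [pblock[n] for n in names[len(gblock) : len(gblock) + len(pblock)]]
            + [fblock[n] for n in names[len(gblock) + len(pblock) :]]
        )
    if names is None:  # no pathways: emit the full header anyway
        from .graph_features import graph_feature_names

        gnames = graph_feature_names()
        pnames = [f"{agg}.{d}" for d in standardized.columns for agg in ("mean", "max")]
        fnames = [f"{t}.enrich" for t in universe.terms]
        names = gnames + pnames + fnames
        blocks = (
            ["graph"] * len(gnames)
            + ["physchem"] * len(pnames)
            + ["functional"] * len(fnames)
        )
        rows = []

    expected = N_GRAPH_FEATURES + N_PHYSCHEM_FEATURES + len(universe)
    if len(names) != expected:
        raise AssertionError(f"{len(names)} columns, expected {expected}")
    matrix = np.array(rows, dtype=float).reshape(len(pathways), len(names))
    return FeatureTable(
        pathway_ids=[p.id for p in pathways],
        feature_names=names,
        blocks=blocks,
        matrix=matrix,
        labels=[p.label for p in pathways],
    )


def write_table(table: FeatureTable, path) -> None:
    """TSV with a two-row header: block tags, then feature names."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("block\tmeta\t" + "\t".join(table.blocks) + "\n")
        fh.write("pathway_id\tlabel\t" + "\t".join(table.feature_names) + "\n")
        for i, pid in enumerate(table.pathway_ids):
            label = table.labels[i] if table.labels[i] is not None else ""
            vals = "\t".join(format(x, ".17g") for x in table.matrix[i])
            fh.write(f"{pid}\t{label}\t{vals}\n" if table.n_features else f"{pid}\t{label}\n")


def read_table(path) -> FeatureTable:
    with open(path, encoding="utf-8") as fh:
        block_row = fh.readline().rstrip("\n").split("\t")
        name_row = fh.readline().rstrip("\n").split("\t")
        if block_row[:2] != ["block", "meta"] or name_row[:2] != ["pathway_id", "label"]:
            raise ValueError(f"{path}: not a feature-table TSV")
        blocks = block_row[2:]
        names = name_row[2:]
        ids, labels, rows = [], [], []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            ids.append(fields[0])
            labels.append(fields[1] or None)
            rows.append([float(x) for x in fields[2:]])
    matrix = np.array(rows, dtype=float).reshape(len(ids), len(names))
    return FeatureTable(
        pathway_ids=ids, feature_names=names, blocks=blocks, matrix=matrix, labels=labels
    )
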