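"""Core containers for pathway classification.

A regulatory pathway is modelled as a simple directed graph whose vertices
are proteins and whose arcs are directed regulatory relations.  Proteins
carry an amino-acid sequence and a set of GO annotations; the annotation
universe fixes the ordered GO term list used for binary GO vectors and for
enrichment scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field


STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_RESIDUES)


def sanitize_sequence(seq: str) -> str:
    """Uppercase and strip every character outside the 20 standard residues.

    Non-standard letters (B, J, O, U, X, Z) and any non-alphabetic character
    are deleted: the property alphabets used for CTD descriptors are defined
    only for the standard residues.
    """
    return "".join(c for c in seq.upper() if c in _STANDARD_SET)


@dataclass
class ProteinRecord:
    """A protein: identifier, (sanitized) sequence and GO term set."""

    id: str
    sequence: str = ""
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        self.sequence = sanitize_sequence(self.sequence)


@dataclass
class Pathway:
    """A directed protein graph with an optional functional class label.

    Arc endpoints must be members of ``vertices``; self-loops are allowed and
    duplicate arcs collapse (the arc container is a set), so the graph is a
    simple digraph.
    """

    id: str
    vertices: list[str] = field(default_factory=list)
    arcs: set[tuple[str, str]] = field(default_factory=set)
    label: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError(f"pathway {self.id}: duplicate vertices")
        vset = set(self.vertices)
        for a, b in self.arcs:
            if a not in vset or b not in vset:
                raise ValueError(
                    f"pathway {self.id}: arc ({a}, {b}) references unknown vertex"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def subgraph(self, keep: set[str]) -> "Pathway":
        """Induced sub-digraph on ``keep``, preserving vertex order."""
        vertices = [v for v in self.vertices if v in keep]
        vset = set(vertices)
        arcs = {(a, b) for a, b in self.arcs if a in vset and b in vset}
        return Pathway(id=self.id, vertices=vertices, arcs=arcs, label=self.label)


@dataclass
class AnnotationUniverse:
    """Ordered GO term list with background counts for enrichment scoring.

    ``background_size`` is N, the number of background proteins;
    ``term_counts[t]`` is M_t, the number of background proteins annotated
    with term t.  The term ordering is fixed and defines both the dimension
    of the binary GO vectors and the layout of the enrichment feature block.
    """

    terms: list[str]
    background_size: int
    term_counts: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("universe terms must be unique")
        if self.background_size < 0:
            raise ValueError("background_size must be >= 0")
        for t in self.terms:
            m = self.term_counts.get(t, 0)
            if not 0 <= m <= self.background_size:
                raise ValueError(
                    f"term {t}: count {m} outside [0, {self.background_size}]"
                )
        self._index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def index_of(self, term: str) -> int | None:
        return self._index.get(term)

    @classmethod
    def from_annotations(
        cls,
        annotations: dict[str, set[str]],
        terms: list[str] | None = None,
        background_size: int | None = None,
    ) -> "AnnotationUniverse":
        """Build a universe from a protein -> GO-term-set mapping.

        Unless an explicit term list is supplied, the universe is the sorted
        union of all terms seen; the background defaults to the number of
        distinct annotated proteins.
        """
        annotated = {p for p, ts in annotations.items() if ts}
        if terms is None:
            terms = sorted(set().union(*annotations.values()) if annotations else set())
        counts = {t: 0 for t in terms}
        term_set = set(terms)
        for p in annotated:
            for t in annotations[p] & term_set:
                counts[t] += 1
        n = len(annotated) if background_size is None else background_size
        return cls(terms=list(terms), background_size=n, term_counts=counts)
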