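"""Biochemical / physicochemical pathway descriptors.

Each protein sequence is recoded into property pseudo-sequences and
summarized by composition / transition / distribution (CTD) statistics,
plus plain amino-acid composition — 132 protein-level descriptors:

* hydrophobicity, normalized van der Waals volume, polarity,
  polarizability, secondary structure: 3-class alphabets, 21 descriptors
  each (3 C + 3 T + 15 D);
* solvent accessibility: 2-class (buried/exposed), 7 descriptors
  (C and five D for the buried class, one T);
* amino-acid composition: 20 percentages.

Descriptors are z-standardized column-wise across the whole protein corpus
and then aggregated per pathway as the mean and the maximum over the
pathway's proteins, giving the 264 pathway features.

The first four class tables are the Dubchak CTD groups.  Secondary
structure and solvent accessibility are, in the original setting, predicted
per residue by external programs; here the default coders are deterministic
residue-class tables (Chou–Fasman-style conformational preference; sign of
the Kyte–Doolittle hydropathy for burial) and externally precomputed coded
strings are accepted wherever a sequence is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import STANDARD_RESIDUES, Pathway, ProteinRecord


def _alphabet(name: str, groups: dict[str, str]) -> "PropertyAlphabet":
    residue_map = {}
    for cls, residues in groups.items():
        for r in residues:
            residue_map[r] = cls
    return PropertyAlphabet(name=name, classes="".join(groups), residue_map=residue_map)


@dataclass(frozen=True)
class PropertyAlphabet:
    """A residue -> property-class recoding (2 or 3 class letters)."""

    name: str
    classes: str
    residue_map: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.residue_map)
        if missing:
            raise ValueError(f"{self.name}: unmapped residues {sorted(missing)}")


HYDROPHOBICITY = _alphabet(
    "hydrophobicity", {"P": "RKEDQN", "N": "GASTPHY", "H": "CLVIMFW"}
)
VAN_DER_WAALS = _alphabet(
    "vdw_volume", {"1": "GASTPDC", "2": "NVEQIL", "3": "MHKFRYW"}
)
POLARITY = _alphabet(
    "polarity", {"1": "LIFWCMVY", "2": "PATGS", "3": "HQRKNED"}
)
POLARIZABILITY = _alphabet(
    "polarizability", {"1": "GASDT", "2": "CPNVEQIL", "3": "KMHFRYW"}
)
# Deterministic conformational-preference classes (helix/strand/coil formers)
SECONDARY_STRUCTURE = _alphabet(
    "secondary_structure", {"H": "AELMQKRH", "E": "VIYCWFT", "C": "GNPSD"}
)
# Kyte–Doolittle hydropathy > 0 -> buried (H), else exposed (E)
SOLVENT_ACCESSIBILITY = _alphabet(
    "solvent_accessibility", {"H": "ACFILMV", "E": "DEGHKNPQRSTWY"}
)

THREE_CLASS_PROPERTIES = (
    HYDROPHOBICITY,
    VAN_DER_WAALS,
    POLARITY,
    POLARIZABILITY,
    SECONDARY_STRUCTURE,
)

_D_QUANTS = ("first", "q25", "q50", "q75", "last")


def encode_sequence(seq: str, alphabet: PropertyAlphabet) -> str:
    """Recode a sanitized sequence into its property pseudo-sequence."""
    try:
        return "".join(alphabet.residue_map[c] for c in seq)
    except KeyError as exc:
        raise ValueError(f"residue {exc} not in alphabet {alphabet.name}") from exc


def _distribution(coded: str, cls: str) -> list[float]:
    """Positions (as % of length) of the 1st, 25%, 50%, 75% and last
    occurrence of ``cls`` (ceiling rank); five zeros if absent."""
    positions = [i + 1 for i, c in enumerate(coded) if c == cls]
    m = len(positions)
    if m == 0:
        return [0.0] * 5
    L = len(coded)
    ranks = [1] + [max(1, int(np.ceil(q * m))) for q in (0.25, 0.5, 0.75)] + [m]
    return [100.0 * positions[r - 1] / L for r in ranks]


def ctd(coded: str, classes: str, d_classes: str | None = None) -> dict[str, float]:
    """Composition / transition / distribution of a coded string.

    ``d_classes`` restricts which classes get C and D descriptors (used by
    the 2-class solvent-accessibility alphabet, which reports only the
    buried class); transitions always cover every unordered class pair.
    Single-character strings have no transitions (denominator 0 -> 0).
    """
    if len(coded) < 1:
        raise ValueError("coded string must be non-empty")
    if d_classes is None:
        d_classes = classes
    L = len(coded)
    out: dict[str, float] = {}
    for cls in d_classes:
        out[f"C.{cls}"] = 100.0 * coded.count(cls) / L
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a, b = classes[i], classes[j]
            n = sum(
                1
                for k in range(L - 1)
                if {coded[k], coded[k + 1]} == {a, b}
            )
            out[f"T.{a}{b}"] = 100.0 * n / (L - 1) if L > 1 else 0.0
    for cls in d_classes:
        for q, v in zip(_D_QUANTS, _distribution(coded, cls)):
            out[f"D.{cls}.{q}"] = v
    return out


def aa_composition(seq: str) -> dict[str, float]:
    """Percentage of each standard residue, fixed alphabetical order."""
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    return {f"aac.{r}": 100.0 * seq.count(r) / L for r in STANDARD_RESIDUES}


def protein_descriptors(
    record: ProteinRecord,
    ss_codes: dict[str, str] | None = None,
    acc_codes: dict[str, str] | None = None,
) -> dict[str, float]:
    """The 132 protein-level descriptors of one protein.

    ``ss_codes`` / ``acc_codes`` optionally supply precomputed coded strings
    (e.g. from a structure predictor) keyed by protein id; otherwise the
    deterministic residue-class coders are used.
    """
    seq = record.sequence
    if not seq:
        raise ValueError(f"protein {record.id}: empty sequence")
    out: dict[str, float] = {}
    for alphabet in THREE_CLASS_PROPERTIES:
        if alphabet is SECONDARY_STRUCTURE and ss_codes and record.id in ss_codes:
            coded = ss_codes[record.id]
        else:
            coded = encode_sequence(seq, alphabet)
        for k, v in ctd(coded, alphabet.classes).items():
            out[f"{alphabet.name}.{k}"] = v
    if acc_codes and record.id in acc_codes:
        coded = acc_codes[record.id]
    else:
        coded = encode_sequence(seq, SOLVENT_ACCESSIBILITY)
    for k, v in ctd(coded, SOLVENT_ACCESSIBILITY.classes, d_classes="H").items():
        out[f"{SOLVENT_ACCESSIBILITY.name}.{k}"] = v
    out.update(aa_composition(seq))
    assert len(out) == 132
    return out


def descriptor_matrix(
    proteins: dict[str, ProteinRecord],
    ss_codes: dict[str, str] | None = None,
    acc_codes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Protein x descriptor matrix for every protein with a sequence."""
    rows = {
        pid: protein_descriptors(rec, ss_codes=ss_codes, acc_codes=acc_codes)
        for pid, rec in proteins.items()
        if rec.sequence
    }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class CorpusStandardizer:
    """Column-wise z-scaling frozen on a protein corpus.

    Uses the population standard deviation; constant columns map to 0.  The
    fitted statistics can be persisted (TSV) so held-out pathways are
    standardized identically.
    """

    means: pd.Series
    stds: pd.Series

    @classmethod
    def fit(cls, matrix: pd.DataFrame) -> "CorpusStandardizer":
        return cls(means=matrix.mean(axis=0), stds=matrix.std(axis=0, ddof=0))

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        stds = self.stds.replace(0.0, np.inf)  # constant columns -> 0
        return (matrix - self.means) / stds

    def to_tsv(self, path) -> None:
        pd.DataFrame({"mean": self.means, "std": self.stds}).to_csv(
            path, sep="\t", index_label="descriptor", float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path) -> "CorpusStandardizer":
        df = pd.read_csv(path, sep="\t", index_col="descriptor")
        return cls(means=df["mean"], stds=df["std"])


def physchem_block(
    pathway: Pathway, standardized: pd.DataFrame
) -> dict[str, float]:
    """Mean and max over the pathway's proteins of each standardized
    descriptor: 132 x 2 = 264 pathway features."""
    missing = [v for v in pathway.vertices if v not in standardized.index]
    if missing:
        raise ValueError(
            f"pathway {pathway.id}: no descriptors for protein(s) {missing} "
            "(empty sequence?)"
        )
    sub = standardized.loc[pathway.vertices]
    means = sub.mean(axis=0)
    maxes = sub.max(axis=0)
    out: dict[str, float] = {}
    for desc in standardized.columns:
        out[f"mean.{desc}"] = float(means[desc])
        out[f"max.{desc}"] = float(maxes[desc])
    assert len(out) == 2 * standardized.shape[1]
    return out


N_PHYSCHEM_FEATURES = 264
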